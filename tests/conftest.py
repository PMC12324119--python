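import pytest

from methconcord import synthetic
from methconcord.meth_io import CallSet, CpGCall


@pytest.fixture(scope="session")
def small_sim():
    """One 100-kb chromosome with default architecture, fixed seed."""
    cfg = synthetic.SimConfig(
        seed=11, n_chroms=1, chrom_len=100_000,
        islands_per_chrom=3, tandem_per_chrom=2, line_per_chrom=2,
        sine_per_chrom=3, genes_per_chrom=3,
    )
    genome = synthetic.simulate_genome(cfg)
    return cfg, genome


@pytest.fixture(scope="session")
def small_calls(small_sim):
    cfg, genome = small_sim
    cs_a, cs_b, truth = synthetic.simulate_calls(cfg, genome)
    return cs_a, cs_b, truth


def make_callset(entries, label="test", genome_id="g"):
    """entries: iterable of (chrom, pos, n_meth, n_unmeth)."""
    cs = CallSet(platform_label=label, genome_id=genome_id)
    for chrom, pos, nm, nu in entries:
        cs.add(CpGCall(chrom, pos, nm, nu))
    return cs
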