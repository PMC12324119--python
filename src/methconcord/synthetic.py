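"""Synthetic two-platform methylation data generator.

Builds a small reference genome (FASTA + UCSC-like annotation tables + GTF +
regulatory BEDs) and paired-platform call sets with the statistical structure
the analysis assumes:

* platform A ("long-read"): depth ~ round(Normal(29, 4)) truncated >= 1 —
  unimodal, symmetric, peaking near 28-30x;
* platform B ("bisulfite"): depth ~ NegativeBinomial — right-skewed with most
  sites at 4-10x — plus random site dropout;
* context-dependent methylation: per-CpG true level drawn from a Beta
  distribution whose mean depends on the CpG-island context (islands and
  promoters low; shores intermediate; shelves/gene bodies high);
* non-CpG (CHH/CHG) records methylated at a small conversion-failure rate.

Everything is deterministic under the config seed, and the retained ground
truth supports parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from methconcord.annotation import (
    ContextCatalog,
    Gene,
    build_cpg_context,
    build_gene_features,
    find_cpg_positions,
)
from methconcord.meth_io import CallSet, CpGCall, write_callset

__all__ = ["SimConfig", "SimGenome", "SimTruth", "simulate_genome",
           "simulate_calls", "write_genome_files", "paper_like_config"]


@dataclass
class SimConfig:
    seed: int = 17
    n_chroms: int = 2
    chrom_len: int = 500_000
    background_gc: float = 0.40
    # island architecture
    islands_per_chrom: int = 12
    island_len_range: tuple[int, int] = (600, 1500)
    island_gc: float = 0.60
    island_cpg_boost: float = 0.25  # probability a position starts a CG
    # repeat architecture
    tandem_per_chrom: int = 6
    tandem_len_range: tuple[int, int] = (300, 900)
    tandem_unit: str = "CACG"
    line_per_chrom: int = 5
    line_len_range: tuple[int, int] = (1000, 3000)
    sine_per_chrom: int = 10
    sine_len_range: tuple[int, int] = (150, 400)
    # gene architecture
    genes_per_chrom: int = 8
    gene_len_range: tuple[int, int] = (4000, 15000)
    exons_per_gene: int = 4
    # regulatory
    regulatory_per_chrom: int = 8
    regulatory_len_range: tuple[int, int] = (200, 1000)
    # methylation model: Beta mean per context label
    context_means: dict[str, float] = field(
        default_factory=lambda: {
            "island": 0.10,
            "shore": 0.50,
            "shelf": 0.85,
            "open_sea": 0.80,
        }
    )
    promoter_mean: float = 0.10
    body_mean: float = 0.85
    beta_concentration: float = 10.0
    # platform observation models
    depth_a_mean: float = 29.0
    depth_a_sd: float = 4.0
    depth_b_nbinom_n: float = 3.0
    depth_b_mean: float = 8.0
    level_jitter_sd: float = 0.02  # on the probability scale, per platform
    platform_b_offset: float = 0.0  # optional mean shift for platform B
    dropout_b: float = 0.05  # platform B loses this fraction of sites
    conversion_failure_rate: float = 0.028
    n_chh_sites: int = 2000


def paper_like_config(seed: int = 17, n_cpg_target: int = 50_000) -> SimConfig:
    """Preset sized so the genome carries roughly ``n_cpg_target`` CpGs.

    Background CpG incidence is about background_gc^2/4 + island boosts; a
    500-kb chromosome at 40% GC carries ~ 25k CpGs, so size scales off that.
    """
    cfg = SimConfig(seed=seed)
    approx_per_chrom = 25_000
    cfg.n_chroms = max(1, round(n_cpg_target / approx_per_chrom))
    return cfg


@dataclass
class SimGenome:
    config: SimConfig
    sequences: dict[str, str]
    islands: dict[str, list[tuple[int, int]]]
    tandem: dict[str, list[tuple[int, int]]]
    line: dict[str, list[tuple[int, int]]]
    sine: dict[str, list[tuple[int, int]]]
    genes: list[Gene]
    exons: dict[str, list[tuple[int, int, str]]]  # gene_id kept per exon
    open_chromatin: dict[str, list[tuple[int, int]]]
    enhancers: dict[str, list[tuple[int, int]]]

    @property
    def genome_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class SimTruth:
    sites: list[tuple[str, int]]
    theta: np.ndarray  # true methylation probability per CpG
    label: list[str]  # generating context label per CpG
    context_means: dict[str, float]


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    len_range: tuple[int, int],
    chrom_len: int,
    occupied: list[tuple[int, int]],
    margin: int = 500,
) -> list[tuple[int, int]]:
    """Random non-overlapping placements avoiding already-occupied spans."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n and attempts < 200 * n:
        attempts += 1
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        start = int(rng.integers(margin, max(margin + 1, chrom_len - length - margin)))
        span = (start - margin, start + length + margin)
        if any(s < span[1] and span[0] < e for s, e in occupied + placed):
            continue
        placed.append((start, start + length))
    placed.sort()
    return placed


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bases[rng.choice(4, size=n, p=p)]


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Generate sequences and annotation geometry.

    Islands are GC- and CpG-enriched tracts; tandem tracts repeat a short
    CpG-containing unit (low entropy); LINE/SINE spans are annotation-only.
    Gene loci avoid island/tandem overlap so context labels stay clean.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB10]))
    sequences: dict[str, str] = {}
    islands: dict[str, list[tuple[int, int]]] = {}
    tandem: dict[str, list[tuple[int, int]]] = {}
    line: dict[str, list[tuple[int, int]]] = {}
    sine: dict[str, list[tuple[int, int]]] = {}
    open_chromatin: dict[str, list[tuple[int, int]]] = {}
    enhancers: dict[str, list[tuple[int, int]]] = {}
    genes: list[Gene] = []
    exons: dict[str, list[tuple[int, int, str]]] = {}

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        n = cfg.chrom_len
        seq = _random_seq(rng, n, cfg.background_gc)

        isl = _place_nonoverlapping(
            rng, cfg.islands_per_chrom, cfg.island_len_range, n, [],
            margin=4500,
        )
        # CpG sprinkling overwrites ~2b/(1+b) of island bases with pure GC;
        # compensate the background draw so measured GC lands on island_gc
        b = cfg.island_cpg_boost
        frac_cg = 2 * b / (1 + b)
        base_gc = min(1.0, max(0.0, (cfg.island_gc - frac_cg) / (1 - frac_cg)))
        for s, e in isl:
            block = _random_seq(rng, e - s, base_gc)
            # sprinkle CG dinucleotides to make the tract CpG-dense
            k = 0
            while k < e - s - 1:
                if rng.random() < cfg.island_cpg_boost:
                    block[k] = b"C"
                    block[k + 1] = b"G"
                    k += 2
                else:
                    k += 1
            seq[s:e] = block

        occupied = [(s - 4500, e + 4500) for s, e in isl]
        tnd = _place_nonoverlapping(
            rng, cfg.tandem_per_chrom, cfg.tandem_len_range, n, occupied
        )
        unit = np.frombuffer(cfg.tandem_unit.encode(), dtype="S1")
        for s, e in tnd:
            reps = int(np.ceil((e - s) / len(unit)))
            seq[s:e] = np.tile(unit, reps)[: e - s]
        occupied += tnd
        lin = _place_nonoverlapping(
            rng, cfg.line_per_chrom, cfg.line_len_range, n, occupied
        )
        occupied += lin
        sin_ = _place_nonoverlapping(
            rng, cfg.sine_per_chrom, cfg.sine_len_range, n, occupied
        )
        occupied += sin_

        gene_spans = _place_nonoverlapping(
            rng, cfg.genes_per_chrom, cfg.gene_len_range, n,
            [(s - 4500, e + 4500) for s, e in isl] + tnd,
            margin=2500,
        )
        exons[chrom] = []
        for gi, (gs, ge) in enumerate(gene_spans):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{chrom}.g{gi + 1}"
            genes.append(
                Gene(gene_id, chrom, gs, ge, strand, gene_type="protein_coding")
            )
            # evenly spaced exon blocks inside the gene
            n_ex = cfg.exons_per_gene
            block = (ge - gs) // (2 * n_ex)
            for xi in range(n_ex):
                xs = gs + 2 * xi * block
                exons[chrom].append((xs, min(xs + block, ge), gene_id))

        reg = _place_nonoverlapping(
            rng, 2 * cfg.regulatory_per_chrom, cfg.regulatory_len_range, n, []
        )
        open_chromatin[chrom] = reg[0::2]
        enhancers[chrom] = reg[1::2]

        sequences[chrom] = seq.tobytes().decode()
        islands[chrom] = isl
        tandem[chrom] = tnd
        line[chrom] = lin
        sine[chrom] = sin_

    return SimGenome(
        config=cfg,
        sequences=sequences,
        islands=islands,
        tandem=tandem,
        line=line,
        sine=sine,
        genes=genes,
        exons=exons,
        open_chromatin=open_chromatin,
        enhancers=enhancers,
    )


def _context_label(
    genome: SimGenome,
    cpg_catalog: ContextCatalog,
    gene_catalog: ContextCatalog,
    chrom: str,
    pos: int,
) -> str:
    """Generating label: promoter/body override the CpG context in open sea."""
    base = cpg_catalog.label_of(chrom, pos) or "open_sea"
    feats = gene_catalog.labels_at(chrom, pos)
    if "promoter" in feats:
        return "promoter"
    if base == "open_sea" and "gene" in feats:
        return "body"
    return base


def simulate_calls(
    cfg: SimConfig,
    genome: SimGenome,
    cpg_catalog: ContextCatalog | None = None,
    gene_catalog: ContextCatalog | None = None,
    gtf_path: str | Path | None = None,
) -> tuple[CallSet, CallSet, SimTruth]:
    """Observe one true methylome through both platform models.

    Per CpG: theta ~ Beta(mean*k, (1-mean)*k) with the mean set by context;
    counts ~ Binomial(depth, clip(theta + jitter)). Platform B drops a
    fraction of sites entirely (low-coverage loss).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCA11]))
    if cpg_catalog is None:
        cpg_catalog = build_cpg_context(genome.islands, genome.genome_sizes)
    if gene_catalog is None and gtf_path is not None:
        gene_catalog = build_gene_features(gtf_path, genome.genome_sizes)

    means = dict(cfg.context_means)
    means["promoter"] = cfg.promoter_mean
    means["body"] = cfg.body_mean
    kappa = cfg.beta_concentration

    sites: list[tuple[str, int]] = []
    labels: list[str] = []
    for chrom in sorted(genome.sequences):
        for pos in find_cpg_positions(genome.sequences[chrom]):
            pos = int(pos)
            sites.append((chrom, pos))
            if gene_catalog is not None:
                labels.append(
                    _context_label(genome, cpg_catalog, gene_catalog, chrom, pos)
                )
            else:
                labels.append(cpg_catalog.label_of(chrom, pos) or "open_sea")

    n = len(sites)
    mu = np.array([means[lab] for lab in labels])
    theta = rng.beta(mu * kappa, (1 - mu) * kappa)

    depth_a = np.maximum(
        1, np.rint(rng.normal(cfg.depth_a_mean, cfg.depth_a_sd, n)).astype(int)
    )
    p_nb = cfg.depth_b_nbinom_n / (cfg.depth_b_nbinom_n + cfg.depth_b_mean)
    depth_b = rng.negative_binomial(cfg.depth_b_nbinom_n, p_nb, n)

    jitter_a = rng.normal(0.0, cfg.level_jitter_sd, n)
    jitter_b = rng.normal(0.0, cfg.level_jitter_sd, n)
    p_a = np.clip(theta + jitter_a, 0.0, 1.0)
    p_b = np.clip(theta + jitter_b + cfg.platform_b_offset, 0.0, 1.0)
    k_a = rng.binomial(depth_a, p_a)
    k_b = rng.binomial(depth_b, p_b)
    drop_b = rng.random(n) < cfg.dropout_b

    cs_a = CallSet(platform_label="platform_a", genome_id="sim")
    cs_b = CallSet(platform_label="platform_b", genome_id="sim")
    for i, (chrom, pos) in enumerate(sites):
        cs_a.add(CpGCall(chrom, pos, int(k_a[i]), int(depth_a[i] - k_a[i])))
        if not drop_b[i] and depth_b[i] > 0:
            cs_b.add(CpGCall(chrom, pos, int(k_b[i]), int(depth_b[i] - k_b[i])))

    truth = SimTruth(
        sites=sites, theta=theta, label=labels, context_means=means
    )
    return cs_a, cs_b, truth


def simulate_chh_calls(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> CallSet:
    """CHH-context records methylated at the conversion-failure rate."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC44]))
    cs = CallSet(platform_label="platform_b_chh", genome_id="sim")
    p_nb = cfg.depth_b_nbinom_n / (cfg.depth_b_nbinom_n + cfg.depth_b_mean)
    depths = np.maximum(
        1, rng.negative_binomial(cfg.depth_b_nbinom_n, p_nb, cfg.n_chh_sites)
    )
    meth = rng.binomial(depths, cfg.conversion_failure_rate)
    for i in range(cfg.n_chh_sites):
        cs.add(CpGCall("chrCHH", i, int(meth[i]), int(depths[i] - meth[i])))
    return cs


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_genome_files(genome: SimGenome, out_dir: str | Path) -> dict[str, Path]:
    """Emit FASTA, UCSC-like tables, a GTF and regulatory BEDs.

    Every emitted file parses with the annotation module's readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    paths["fasta"] = fasta

    isl = out / "cpgIslandExt.txt"
    with open(isl, "w") as fh:
        for chrom in sorted(genome.islands):
            for s, e in genome.islands[chrom]:
                fh.write(f"0\t{chrom}\t{s}\t{e}\tCpG\t{e - s}\n")
    paths["islands"] = isl

    srep = out / "simpleRepeat.txt"
    with open(srep, "w") as fh:
        for chrom in sorted(genome.tandem):
            for s, e in genome.tandem[chrom]:
                fh.write(f"0\t{chrom}\t{s}\t{e}\ttrf\n")
    paths["simple_repeat"] = srep

    rmsk = out / "rmsk.txt"
    with open(rmsk, "w") as fh:
        for chrom in sorted(genome.line):
            for cls, track in (("LINE", genome.line), ("SINE", genome.sine)):
                for s, e in track.get(chrom, []):
                    fh.write(
                        f"0\t0\t0\t0\t0\t{chrom}\t{s}\t{e}\t0\t+\t"
                        f"{cls}1\t{cls}\n"
                    )
    paths["rmsk"] = rmsk

    gtf = out / "genes.gtf"
    with open(gtf, "w") as fh:
        for gene in genome.genes:
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_type "protein_coding";'
            )
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            tx_attrs = attrs + f' transcript_id "{gene.gene_id}.t1";'
            fh.write(
                f"{gene.chrom}\tsim\ttranscript\t{gene.start + 1}\t{gene.end}"
                f"\t.\t{gene.strand}\t.\t{tx_attrs}\n"
            )
            gene_exons = [
                (s, e)
                for s, e, gid in genome.exons[gene.chrom]
                if gid == gene.gene_id
            ]
            for s, e in gene_exons:
                fh.write(
                    f"{gene.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{gene.strand}"
                    f"\t.\t{tx_attrs}\n"
                )
            # first and last exon halves as UTRs, the rest as CDS
            for s, e in gene_exons:
                fh.write(
                    f"{gene.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}"
                    f"\t.\t{tx_attrs}\n"
                )
    paths["gtf"] = gtf

    for name, track in (
        ("open_chromatin", genome.open_chromatin),
        ("enhancers", genome.enhancers),
    ):
        bed = out / f"{name}.bed"
        with open(bed, "w") as fh:
            for chrom in sorted(track):
                for s, e in track[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        paths[name] = bed

    sizes = out / "genome.sizes"
    with open(sizes, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f"{chrom}\t{len(genome.sequences[chrom])}\n")
    paths["sizes"] = sizes
    return paths


def write_call_files(
    cs_a: CallSet, cs_b: CallSet, out_dir: str | Path
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a = out / "platform_a.bedmethyl.tsv"
    b = out / "platform_b.bismark.cov"
    write_callset(cs_a, a, dialect="bedmethyl")
    write_callset(cs_b, b, dialect="bismark_cov")
    return {"platform_a": a, "platform_b": b}
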