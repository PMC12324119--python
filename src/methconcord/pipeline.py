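"""End-to-end pipeline orchestration and report bundle emission.

Stages: simulate (or ingest) -> annotate -> compare -> context stats ->
depth-matched downsampling -> metaprofile -> sequence stats. Every stage's
tables land in the output directory as TSV/JSON; the bundle is deterministic
given the config seed (timings go to stderr only).
"""

from __future__ import annotations

import csv
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from methconcord import annotation as anno
from methconcord import context_stats, depth_matching, mc_sets, metaprofile
from methconcord import seqstats as seqstats_mod
from methconcord import synthetic

logger = logging.getLogger("methconcord")

SCHEMA_VERSION = "1"

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "methconcord_out"
    seed: int = 17
    # simulate preset; when input paths are given they take precedence
    simulate: bool = True
    n_cpg_target: int = 50_000
    input_a: str | None = None  # bedMethyl-like
    input_b: str | None = None  # bismark-coverage-like
    fasta: str | None = None
    islands: str | None = None
    simple_repeat: str | None = None
    rmsk: str | None = None
    gtf: str | None = None
    open_chromatin: str | None = None
    enhancers: str | None = None
    variants: str | None = None
    min_level: float = 50.0
    min_depth: int = 4
    alt_min_level: float = 80.0
    downsample_replicates: int = 100
    downsample_mode: str = "per_replicate_r"
    depth_edges: list[int] = field(
        default_factory=lambda: [5, 10, 15, 20, 25, 30, 40, 50, 60]
    )
    flank_bp: int = 2000
    log_level: str = "INFO"


def _write_tsv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


class _Stage:
    """Context manager logging stage timing to stderr."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.monotonic()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        if exc_type is not None:
            logger.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
            return False
        logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).
    """
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(out / "config.json", asdict(cfg))

    with _Stage("inputs"):
        if cfg.simulate and not (cfg.input_a and cfg.input_b):
            sim_cfg = synthetic.paper_like_config(cfg.seed, cfg.n_cpg_target)
            genome = synthetic.simulate_genome(sim_cfg)
            paths = synthetic.write_genome_files(genome, out / "sim")
            sequences = genome.genome_sizes and genome.sequences
            genome_sizes = genome.genome_sizes
            islands = genome.islands
            simple_repeat = genome.tandem
            rmsk = {"LINE": genome.line, "SINE": genome.sine}
            gtf_path = paths["gtf"]
            open_chromatin = genome.open_chromatin
            enhancers = genome.enhancers
            genes = genome.genes
            cpg_catalog = anno.build_cpg_context(islands, genome_sizes)
            gene_catalog = anno.build_gene_features(gtf_path, genome_sizes)
            cs_a, cs_b, _truth = synthetic.simulate_calls(
                sim_cfg, genome, cpg_catalog, gene_catalog
            )
            chh = synthetic.simulate_chh_calls(sim_cfg)
            synthetic.write_call_files(cs_a, cs_b, out / "sim")
        else:
            from methconcord.meth_io import read_bedmethyl, read_bismark_coverage

            for name in ("input_a", "input_b", "fasta", "islands", "gtf"):
                if getattr(cfg, name) is None:
                    raise ValueError(f"missing required input: {name}")
            sequences = anno.read_fasta(cfg.fasta)
            genome_sizes = {c: len(s) for c, s in sequences.items()}
            cs_a = read_bedmethyl(cfg.input_a, platform_label="platform_a",
                                  genome_id="user")
            cs_b = read_bismark_coverage(
                cfg.input_b, reference=sequences,
                platform_label="platform_b", genome_id="user",
            )
            islands = anno.read_cpg_islands(cfg.islands)
            simple_repeat = (
                anno.read_simple_repeat(cfg.simple_repeat)
                if cfg.simple_repeat else {}
            )
            rmsk = anno.read_rmsk(cfg.rmsk) if cfg.rmsk else {}
            gtf_path = cfg.gtf
            open_chromatin = (
                anno.read_bed(cfg.open_chromatin) if cfg.open_chromatin else {}
            )
            enhancers = anno.read_bed(cfg.enhancers) if cfg.enhancers else {}
            genes = anno.read_gtf_genes(gtf_path)
            cpg_catalog = anno.build_cpg_context(islands, genome_sizes)
            gene_catalog = anno.build_gene_features(gtf_path, genome_sizes)
            chh = None

    with _Stage("annotate"):
        gc_catalog = anno.build_gc_density(sequences)
        repeat_catalog = anno.build_repeats(simple_repeat, rmsk, genome_sizes)
        regulatory = anno.build_regulatory(
            open_chromatin, enhancers, genome_sizes
        )
        chrom_catalog = anno.build_chromosome_catalog(genome_sizes)
        catalogs = [
            cpg_catalog, gc_catalog, repeat_catalog, gene_catalog,
            regulatory, chrom_catalog,
        ]
        index = anno.index_reference_cpgs(sequences, catalogs)
        for cat in catalogs:
            anno.write_catalog_beds(cat, out / "annotation")

    with _Stage("compare"):
        variants = None
        if cfg.variants:
            var_track = anno.read_bed(cfg.variants)
            variants = {
                (chrom, pos)
                for chrom, ivs in var_track.items()
                for s, e in ivs
                for pos in range(s, e)
            }
        crit = mc_sets.MCCriteria(cfg.min_level, cfg.min_depth)
        report = mc_sets.decompose(cs_a, cs_b, crit, variants)
        _write_json(out / "mc_sets.json", report.summary())
        site_rows = []
        for name, sites, expl in (
            ("overlap", report.overlap, None),
            ("unique_a", report.unique_a, report.explanations_a),
            ("unique_b", report.unique_b, report.explanations_b),
        ):
            for chrom, pos in sorted(sites):
                site_rows.append(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "set": name,
                        "explanation": expl[(chrom, pos)] if expl else "",
                    }
                )
        _write_tsv(out / "mc_sites.tsv", site_rows)
        tc = mc_sets.threshold_consistency(
            cs_a,
            mc_sets.MCCriteria(cfg.min_level, cfg.min_depth),
            mc_sets.MCCriteria(cfg.alt_min_level, cfg.min_depth),
        )

    with _Stage("context_stats"):
        summary_rows = []
        for cat in catalogs:
            for cs_sum in context_stats.summarize_context(
                report, cs_a, cs_b, index, cat
            ):
                summary_rows.append(cs_sum.as_dict())
        _write_tsv(out / "context_summary.tsv", summary_rows)
        binned = context_stats.depth_binned_concordance(
            cs_a, cs_b, cfg.depth_edges, matched_only=False,
            final_open_bin=True,
        )
        _write_tsv(out / "depth_binned.tsv", binned.as_table())

    with _Stage("downsample"):
        ds_cfg = depth_matching.DownsampleConfig(
            n_replicates=cfg.downsample_replicates,
            seed=cfg.seed,
            min_shared_depth=cfg.min_depth,
            mode=cfg.downsample_mode,
        )
        run = depth_matching.run_depth_matched(
            cs_a, cs_b, ds_cfg, catalog=cpg_catalog
        )
        _write_tsv(
            out / "downsample_r_by_depth.tsv",
            depth_matching.r_by_depth_level(run),
        )
        import numpy as np

        ctx_rows = []
        for lab, r_vals in sorted(run.r_strata.get("context", {}).items()):
            finite = r_vals[np.isfinite(r_vals)]
            if finite.size == 0:
                continue
            q = np.quantile(finite, [0.0, 0.25, 0.5, 0.75, 1.0])
            ctx_rows.append(
                {
                    "label": lab,
                    "r_min": float(q[0]),
                    "r_q1": float(q[1]),
                    "r_median": float(q[2]),
                    "r_q3": float(q[3]),
                    "r_max": float(q[4]),
                }
            )
        _write_tsv(out / "downsample_r_by_context.tsv", ctx_rows)

    with _Stage("metaprofile"):
        protein_coding = [
            g for g in genes if g.gene_type in ("protein_coding", "")
        ]
        prof_rows = []
        for cs in (cs_a, cs_b):
            prof = metaprofile.profile(
                cs, protein_coding, cfg.flank_bp, cfg.min_depth
            )
            for row in prof.as_rows():
                row["platform"] = cs.platform_label
                prof_rows.append(row)
        _write_tsv(out / "metaprofile.tsv", prof_rows)

    with _Stage("seqstats"):
        entropy_catalog = seqstats_mod.collapse_repeats_for_entropy(
            repeat_catalog
        )
        entropy = seqstats_mod.entropy_by_category(sequences, entropy_catalog)
        _write_tsv(
            out / "entropy.tsv",
            [
                {
                    "category": r.category,
                    "n_windows": r.n_windows,
                    "mean_H": r.mean_H,
                }
                for r in entropy
            ],
        )
        conversion = None
        if chh is not None:
            qc = seqstats_mod.conversion_efficiency(chh)
            conversion = {
                "pct_meth_chh": qc.pct_meth_chh,
                "efficiency": qc.efficiency,
            }

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "criteria": {"min_level": cfg.min_level, "min_depth": cfg.min_depth},
        "n_calls_a": len(cs_a),
        "n_calls_b": len(cs_b),
        "mc_sets": report.summary(),
        "threshold_consistency": {
            "n_low": tc.n_low,
            "n_high": tc.n_high,
            "overlap_of_high": tc.overlap_of_high,
            "retained_fraction": tc.retained_fraction,
        },
        "conversion_qc": conversion,
        "n_context_rows": len(summary_rows),
        "n_reference_cpg": index.total,
    }
    _write_json(out / "summary.json", summary)
    return summary
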