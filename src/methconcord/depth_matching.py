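"""Site-level depth-matched downsampling.

At every CpG shared between the two platforms, the methylated/unmethylated
read counts of both platforms are randomly subsampled *without replacement*
(hypergeometric) to the minimum of the two depths at that site, repeated over
many replicates, and Pearson correlations of the resampled levels are
derived genome-wide, per context label, and per depth stratum.

Randomness uses one root seed expanded into per-(replicate, platform) Philox
streams, so runs are byte-reproducible and independent of replicate
execution order; within a replicate sites are processed in a canonical
sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from methconcord.annotation import ContextCatalog
from methconcord.context_stats import pearson
from methconcord.meth_io import CallSet

__all__ = [
    "DownsampleConfig",
    "DownsampleRun",
    "downsample_site",
    "r_by_depth_level",
    "run_depth_matched",
]


def downsample_site(
    n_meth: int, n_unmeth: int, target: int, rng: np.random.Generator
) -> int:
    """Draw the methylated count of a ``target``-read subsample.

    Without replacement: k ~ Hypergeometric(N=n_meth+n_unmeth, K=n_meth,
    n=target). The unmethylated part of the subsample is ``target - k``.
    """
    depth = n_meth + n_unmeth
    if target > depth:
        raise ValueError(f"target {target} exceeds depth {depth}")
    if target == depth:
        return n_meth
    return int(rng.hypergeometric(n_meth, n_unmeth, target))


@dataclass(frozen=True)
class DownsampleConfig:
    n_replicates: int = 1000
    seed: int = 0
    min_shared_depth: int = 4
    mode: str = "per_replicate_r"  # or "averaged_levels"
    with_replacement: bool = False  # binomial sensitivity mode

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mode not in ("per_replicate_r", "averaged_levels"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DownsampleRun:
    """Results of a depth-matched downsampling experiment."""

    config: DownsampleConfig
    sites: list[tuple[str, int]]
    matched_depth: np.ndarray  # d = min(depth_a, depth_b) per site
    depth_a: np.ndarray  # pre-matching platform-A depth per site
    #: replicate-wise genome-wide r (length n_replicates)
    r_global: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: stratum kind -> stratum value -> replicate-wise r array
    r_strata: dict[str, dict, ] = field(default_factory=dict)
    #: per-site mean resampled level over replicates, per platform
    mean_level_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_level_b: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: averaged-levels mode: one r per stratum from the mean levels
    averaged_r: dict = field(default_factory=dict)
    context_labels: list[str] | None = None


def _replicate_rng(seed: int, replicate: int, platform: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(
            np.random.SeedSequence([seed, replicate, platform, 0x6D657468])
        )
    )


def _draw(
    rng: np.random.Generator,
    n_meth: np.ndarray,
    n_unmeth: np.ndarray,
    target: np.ndarray,
    with_replacement: bool,
) -> np.ndarray:
    if with_replacement:
        depth = n_meth + n_unmeth
        return rng.binomial(target, n_meth / depth)
    full = target == n_meth + n_unmeth
    k = rng.hypergeometric(n_meth, n_unmeth, target)
    # a full draw returns the original counts exactly
    return np.where(full, n_meth, k)


def run_depth_matched(
    cs_a: CallSet,
    cs_b: CallSet,
    cfg: DownsampleConfig = DownsampleConfig(),
    catalog: ContextCatalog | None = None,
) -> DownsampleRun:
    """Depth-match every shared CpG and derive concordance distributions.

    Shared sites require depth >= cfg.min_shared_depth on both platforms.
    The two platforms are resampled with independent draws. Strata emitted:
    ``matched_depth`` (d), ``platform_a_depth`` (pre-matching A depth), and
    ``context`` labels when ``catalog`` is given.
    """
    sites = []
    for key, call_a in sorted(cs_a.calls.items()):
        call_b = cs_b.calls.get(key)
        if call_b is None:
            continue
        if call_a.depth >= cfg.min_shared_depth and \
                call_b.depth >= cfg.min_shared_depth:
            sites.append(key)
    if not sites:
        raise ValueError("no shared sites with sufficient depth")

    nm_a = np.array([cs_a.calls[s].n_meth for s in sites])
    nu_a = np.array([cs_a.calls[s].n_unmeth for s in sites])
    nm_b = np.array([cs_b.calls[s].n_meth for s in sites])
    nu_b = np.array([cs_b.calls[s].n_unmeth for s in sites])
    depth_a = nm_a + nu_a
    depth_b = nm_b + nu_b
    d = np.minimum(depth_a, depth_b)

    strata: dict[str, dict] = {"matched_depth": {}, "platform_a_depth": {}}
    masks: dict[str, dict[object, np.ndarray]] = {
        "matched_depth": {
            int(v): d == v for v in np.unique(d)
        },
        "platform_a_depth": {
            int(v): depth_a == v for v in np.unique(depth_a)
        },
    }
    labels = None
    if catalog is not None:
        site_labels = [catalog.labels_at(*s) for s in sites]
        labels = sorted({lab for ls in site_labels for lab in ls})
        masks["context"] = {
            lab: np.array([lab in ls for ls in site_labels])
            for lab in labels
        }
        strata["context"] = {}

    n = len(sites)
    r_global = np.empty(cfg.n_replicates)
    sum_level_a = np.zeros(n)
    sum_level_b = np.zeros(n)
    r_strata = {
        kind: {key: np.empty(cfg.n_replicates) for key in masks[kind]}
        for kind in masks
    }
    for rep in range(cfg.n_replicates):
        k_a = _draw(_replicate_rng(cfg.seed, rep, 0), nm_a, nu_a, d,
                    cfg.with_replacement)
        k_b = _draw(_replicate_rng(cfg.seed, rep, 1), nm_b, nu_b, d,
                    cfg.with_replacement)
        lev_a = 100.0 * k_a / d
        lev_b = 100.0 * k_b / d
        sum_level_a += lev_a
        sum_level_b += lev_b
        r = pearson(lev_a, lev_b)
        r_global[rep] = np.nan if r is None else r
        for kind, kind_masks in masks.items():
            for key, mask in kind_masks.items():
                r = pearson(lev_a[mask], lev_b[mask]) if mask.sum() >= 2 \
                    else None
                r_strata[kind][key][rep] = np.nan if r is None else r

    mean_a = sum_level_a / cfg.n_replicates
    mean_b = sum_level_b / cfg.n_replicates
    averaged_r: dict = {}
    if cfg.mode == "averaged_levels":
        averaged_r["global"] = pearson(mean_a, mean_b)
        for kind, kind_masks in masks.items():
            averaged_r[kind] = {
                key: pearson(mean_a[mask], mean_b[mask])
                if mask.sum() >= 2 else None
                for key, mask in kind_masks.items()
            }
    return DownsampleRun(
        config=cfg,
        sites=sites,
        matched_depth=d,
        depth_a=depth_a,
        r_global=r_global,
        r_strata=r_strata,
        mean_level_a=mean_a,
        mean_level_b=mean_b,
        averaged_r=averaged_r,
        context_labels=labels,
    )


def r_by_depth_level(
    run: DownsampleRun,
    min_sites: int = 50,
    stratum: str = "matched_depth",
) -> list[dict]:
    """Replicate-r quantiles per depth level with at least ``min_sites`` sites.

    Returns rows of (depth, n_sites, min, q1, median, q3, max); depth levels
    below the site-count floor are excluded.
    """
    if stratum not in run.r_strata:
        raise KeyError(f"unknown stratum {stratum!r}")
    depth_arr = run.matched_depth if stratum == "matched_depth" else run.depth_a
    rows = []
    for depth, r_vals in sorted(run.r_strata[stratum].items()):
        n_sites = int((depth_arr == depth).sum())
        if n_sites < min_sites:
            continue
        finite = r_vals[np.isfinite(r_vals)]
        if finite.size == 0:
            continue
        q = np.quantile(finite, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {
                "depth": int(depth),
                "n_sites": n_sites,
                "r_min": float(q[0]),
                "r_q1": float(q[1]),
                "r_median": float(q[2]),
                "r_q3": float(q[3]),
                "r_max": float(q[4]),
            }
        )
    return rows
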