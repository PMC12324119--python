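"""Per-context concordance statistics.

For every catalog label: normalized mC proportions (counts divided by the
reference CpG count of the label), mean methylation levels at overlapping
well-covered sites, and the Pearson correlation of the two platforms' levels
at those sites. Depth-stratified concordance uses closed integer depth bins
("5-10x", "11-15x", ...) with a per-bin 2D level histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from methconcord.annotation import ContextCatalog, ReferenceCpGIndex
from methconcord.mc_sets import MCSetReport
from methconcord.meth_io import CallSet

__all__ = [
    "ContextSummary",
    "DepthBin",
    "DepthBinnedConcordance",
    "depth_binned_concordance",
    "pearson",
    "shared_well_covered_sites",
    "summarize_context",
]


def pearson(x, y) -> float | None:
    """Product-moment correlation; None (never 0) for undefined cases.

    Undefined when fewer than 2 points or either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2 or not (np.isfinite(x).all() and np.isfinite(y).all()):
        return None
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        return None
    return float((dx @ dy) / math.sqrt(sx * sy))


@dataclass
class ContextSummary:
    """Concordance summary for one (catalog, label) stratum."""

    catalog: str
    label: str
    n_ref_cpg: int
    n_mc_a: int
    n_mc_b: int
    n_overlap: int
    n_unique_a: int
    n_unique_b: int
    mean_level_a: float | None
    mean_level_b: float | None
    pearson_r: float | None
    n_sites_corr: int

    @property
    def prop_mc_a(self) -> float | None:
        return self.n_mc_a / self.n_ref_cpg if self.n_ref_cpg else None

    @property
    def prop_mc_b(self) -> float | None:
        return self.n_mc_b / self.n_ref_cpg if self.n_ref_cpg else None

    @property
    def prop_overlap(self) -> float | None:
        return self.n_overlap / self.n_ref_cpg if self.n_ref_cpg else None

    @property
    def prop_unique_a(self) -> float | None:
        return self.n_unique_a / self.n_ref_cpg if self.n_ref_cpg else None

    @property
    def prop_unique_b(self) -> float | None:
        return self.n_unique_b / self.n_ref_cpg if self.n_ref_cpg else None

    @property
    def delta_unique(self) -> int:
        return self.n_unique_a - self.n_unique_b

    @property
    def delta_unique_prop(self) -> float | None:
        if not self.n_ref_cpg:
            return None
        return self.delta_unique / self.n_ref_cpg

    def as_dict(self) -> dict:
        return {
            "catalog": self.catalog,
            "label": self.label,
            "n_ref_cpg": self.n_ref_cpg,
            "n_mc_a": self.n_mc_a,
            "n_mc_b": self.n_mc_b,
            "n_overlap": self.n_overlap,
            "n_unique_a": self.n_unique_a,
            "n_unique_b": self.n_unique_b,
            "prop_mc_a": self.prop_mc_a,
            "prop_mc_b": self.prop_mc_b,
            "prop_overlap": self.prop_overlap,
            "delta_unique": self.delta_unique,
            "delta_unique_prop": self.delta_unique_prop,
            "mean_level_a": self.mean_level_a,
            "mean_level_b": self.mean_level_b,
            "pearson_r": self.pearson_r,
            "n_sites_corr": self.n_sites_corr,
        }


def shared_well_covered_sites(
    cs_a: CallSet, cs_b: CallSet, min_depth: int = 4
) -> list[tuple[str, int]]:
    """Sites called on both platforms with depth >= min_depth on both."""
    out = []
    for key, call_a in cs_a.calls.items():
        call_b = cs_b.calls.get(key)
        if call_b is None:
            continue
        if call_a.depth >= min_depth and call_b.depth >= min_depth:
            out.append(key)
    out.sort()
    return out


def summarize_context(
    report: MCSetReport,
    cs_a: CallSet,
    cs_b: CallSet,
    index: ReferenceCpGIndex,
    catalog: ContextCatalog,
) -> list[ContextSummary]:
    """One :class:`ContextSummary` per label of ``catalog``.

    Mean levels and the correlation are computed over sites called with
    sufficient depth on BOTH platforms (the overlapping-site convention),
    using the unweighted per-site mean.
    """
    shared = shared_well_covered_sites(cs_a, cs_b, report.crit.min_depth)
    site_label: dict[tuple[str, int], list[str]] = {}

    def _labels(site: tuple[str, int]) -> list[str]:
        if site not in site_label:
            site_label[site] = catalog.labels_at(*site)
        return site_label[site]

    per_label_sites: dict[str, list[tuple[str, int]]] = {
        lab: [] for lab in catalog.label_order
    }
    for site in shared:
        for lab in _labels(site):
            per_label_sites[lab].append(site)

    def _count(sites: set[tuple[str, int]], lab: str) -> int:
        return sum(1 for s in sites if lab in _labels(s))

    out = []
    for lab in catalog.label_order:
        sites = per_label_sites[lab]
        la = np.array([cs_a.calls[s].level for s in sites], dtype=float)
        lb = np.array([cs_b.calls[s].level for s in sites], dtype=float)
        out.append(
            ContextSummary(
                catalog=catalog.name,
                label=lab,
                n_ref_cpg=index.count(catalog.name, lab),
                n_mc_a=_count(report.mc_a, lab),
                n_mc_b=_count(report.mc_b, lab),
                n_overlap=_count(report.overlap, lab),
                n_unique_a=_count(report.unique_a, lab),
                n_unique_b=_count(report.unique_b, lab),
                mean_level_a=float(la.mean()) if la.size else None,
                mean_level_b=float(lb.mean()) if lb.size else None,
                pearson_r=pearson(la, lb),
                n_sites_corr=len(sites),
            )
        )
    return out


@dataclass
class DepthBin:
    """One closed integer depth bin [lo, hi]."""

    lo: int
    hi: int
    n_sites: int
    pearson_r: float | None
    hist2d: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def label(self) -> str:
        if self.hi < 0:
            return f">{self.lo - 1}x"
        return f"{self.lo}-{self.hi}x"


@dataclass
class DepthBinnedConcordance:
    bins: list[DepthBin]
    matched_only: bool
    level_bin_width: float

    def as_table(self) -> list[dict]:
        return [
            {
                "bin": b.label,
                "lo": b.lo,
                "hi": b.hi,
                "n_sites": b.n_sites,
                "pearson_r": b.pearson_r,
            }
            for b in self.bins
        ]


def depth_binned_concordance(
    cs_a: CallSet,
    cs_b: CallSet,
    edges: list[int],
    matched_only: bool = False,
    level_bin_width: float = 2.0,
    final_open_bin: bool = False,
) -> DepthBinnedConcordance:
    """Per-depth-bin Pearson r with a 2D (level_a, level_b) histogram.

    ``edges`` [5, 10, 15] produce closed bins [5, 10] and [11, 15], matching
    "5-10x, 11-15x" labels. With ``matched_only`` only sites where the two
    depths are equal enter, binned by that depth; otherwise sites are binned
    by platform-B depth. ``final_open_bin`` appends ">last edge".
    """
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    spans = [(edges[0], edges[1])] + [
        (lo + 1, hi) for lo, hi in zip(edges[1:], edges[2:])
    ]
    if final_open_bin:
        spans.append((edges[-1] + 1, np.iinfo(np.int64).max))

    depth_of: list[int] = []
    la: list[float] = []
    lb: list[float] = []
    for key, call_a in cs_a.calls.items():
        call_b = cs_b.calls.get(key)
        if call_b is None or call_a.depth == 0 or call_b.depth == 0:
            continue
        if matched_only:
            if call_a.depth != call_b.depth:
                continue
            d = call_a.depth
        else:
            d = call_b.depth
        depth_of.append(d)
        la.append(call_a.level)
        lb.append(call_b.level)
    depth_arr = np.array(depth_of)
    la_arr = np.array(la)
    lb_arr = np.array(lb)

    n_level_bins = int(np.ceil(100.0 / level_bin_width))
    bins = []
    for lo, hi in spans:
        mask = (depth_arr >= lo) & (depth_arr <= hi) if depth_arr.size else \
            np.zeros(0, dtype=bool)
        xa, xb = la_arr[mask], lb_arr[mask]
        hist, _, _ = np.histogram2d(
            xa, xb, bins=n_level_bins, range=[[0, 100], [0, 100]]
        )
        bins.append(
            DepthBin(
                lo=lo,
                hi=hi if hi < np.iinfo(np.int64).max else -1,
                n_sites=int(mask.sum()),
                pearson_r=pearson(xa, xb) if mask.sum() >= 2 else None,
                hist2d=hist,
            )
        )
    return DepthBinnedConcordance(
        bins=bins, matched_only=matched_only, level_bin_width=level_bin_width
    )
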