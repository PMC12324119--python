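"""Sequence-derived statistics.

* Shannon entropy of nucleotide composition, averaged over CpG-containing
  100-bp windows per repeat category;
* cytosine context classification (CpG / CHG / CHH);
* bisulfite conversion efficiency: 100 - (% CHH methylation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from methconcord.annotation import ContextCatalog, find_cpg_positions
from methconcord.intervals import union_tracks
from methconcord.meth_io import CallSet

__all__ = [
    "ConversionQC",
    "EntropyResult",
    "classify_cytosine_context",
    "collapse_repeats_for_entropy",
    "conversion_efficiency",
    "entropy_by_category",
    "shannon_entropy",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def shannon_entropy(seq: str) -> float | None:
    """H = -sum p_i log2 p_i over A/C/G/T frequencies, in bits.

    Non-ACGT symbols are excluded from the frequency denominator; a sequence
    with no ACGT bases has undefined entropy (None). 0*log(0) := 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = [seq.count(b) for b in "ACGT"]
    total = sum(counts)
    if total == 0:
        return None
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def collapse_repeats_for_entropy(repeats: ContextCatalog) -> ContextCatalog:
    """Collapse the 5-label repeat partition into the three entropy
    categories: tandem, interspersed (LINE+SINE+other), non_repetitive."""
    interspersed = union_tracks(
        repeats.tracks.get("LINE", {}),
        repeats.tracks.get("SINE", {}),
        repeats.tracks.get("other_repeat", {}),
    )
    return ContextCatalog(
        name="entropy_categories",
        tracks={
            "tandem": repeats.tracks.get("tandem", {}),
            "interspersed": interspersed,
            "non_repetitive": repeats.tracks.get("non_repetitive", {}),
        },
        partition=True,
        genome_sizes=dict(repeats.genome_sizes),
        label_order=["tandem", "interspersed", "non_repetitive"],
    )


@dataclass
class EntropyResult:
    category: str
    n_windows: int
    mean_H: float | None
    per_window: list[float] | None = None


def entropy_by_category(
    sequences: Mapping[str, str],
    catalog: ContextCatalog,
    window: int = 100,
    centered: bool = False,
    keep_per_window: bool = False,
) -> list[EntropyResult]:
    """Mean entropy of CpG-containing windows per category.

    Default placement tiles each chromosome with non-overlapping ``window``-bp
    windows anchored at 0; ``centered=True`` instead takes one window centered
    on every CpG. A window is kept if it contains at least one CpG C-position
    and counts toward every category whose intervals it overlaps.
    """
    acc: dict[str, list[float]] = {lab: [] for lab in catalog.label_order}
    for chrom, seq in sequences.items():
        cpg = find_cpg_positions(seq)
        if centered:
            windows = sorted(
                {
                    (max(0, int(p) - window // 2),
                     min(len(seq), int(p) - window // 2 + window))
                    for p in cpg
                }
            )
        else:
            windows = [
                (w, min(w + window, len(seq)))
                for w in range(0, len(seq), window)
            ]
        for w0, w1 in windows:
            lo = np.searchsorted(cpg, w0)
            hi = np.searchsorted(cpg, w1)
            if hi == lo:  # no CpG C-position inside
                continue
            h = shannon_entropy(seq[w0:w1])
            if h is None:
                continue
            for lab in catalog.label_order:
                ivs = catalog.tracks[lab].get(chrom, [])
                if any(s < w1 and w0 < e for s, e in ivs):
                    acc[lab].append(h)
    return [
        EntropyResult(
            category=lab,
            n_windows=len(vals),
            mean_H=float(np.mean(vals)) if vals else None,
            per_window=vals if keep_per_window else None,
        )
        for lab, vals in acc.items()
    ]


def classify_cytosine_context(
    sequences: Mapping[str, str], chrom: str, pos: int, strand: str = "+"
) -> str | None:
    """CpG / CHG / CHH classification of a cytosine by its next two bases.

    On the minus strand the reverse-complement is read leftwards. Returns
    None when the context is truncated by the chromosome end.
    """
    seq = sequences[chrom].upper()
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]}, not C")
        if pos + 1 >= len(seq):
            return None
        if seq[pos + 1] == "G":
            return "CpG"
        if pos + 2 >= len(seq):
            return None
        return "CHG" if seq[pos + 2] == "G" else "CHH"
    if seq[pos] != "G":
        raise ValueError(f"{chrom}:{pos}(-) is {seq[pos]}, not C")
    if pos - 1 < 0:
        return None
    if seq[pos - 1] == "C":
        return "CpG"
    if pos - 2 < 0:
        return None
    return "CHG" if seq[pos - 2] == "C" else "CHH"


@dataclass
class ConversionQC:
    """Bisulfite conversion QC from context-level methylation summaries."""

    pct_meth_cpg: float | None
    pct_meth_chg: float | None
    pct_meth_chh: float

    @property
    def efficiency(self) -> float:
        return 100.0 - self.pct_meth_chh


def _pct_meth(cs: CallSet, per_site_mean: bool) -> float | None:
    if per_site_mean:
        levels = [c.level for c in cs if c.level is not None]
        return float(np.mean(levels)) if levels else None
    total = cs.total_depth()
    if total == 0:
        return None
    return 100.0 * sum(c.n_meth for c in cs) / total


def conversion_efficiency(
    chh_calls: CallSet,
    cpg_calls: CallSet | None = None,
    chg_calls: CallSet | None = None,
    per_site_mean: bool = False,
) -> ConversionQC:
    """Estimate conversion efficiency as 100 - (% CHH methylation).

    % methylation is read-weighted by default (total methylated reads over
    total reads); ``per_site_mean`` switches to the mean of per-site levels.
    """
    pct_chh = _pct_meth(chh_calls, per_site_mean)
    if pct_chh is None:
        raise ValueError("CHH call set has zero total depth")
    return ConversionQC(
        pct_meth_cpg=_pct_meth(cpg_calls, per_site_mean) if cpg_calls else None,
        pct_meth_chg=_pct_meth(chg_calls, per_site_mean) if chg_calls else None,
        pct_meth_chh=pct_chh,
    )
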