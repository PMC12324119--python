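"""Methylated-CpG classification and two-platform set decomposition.

A CpG is classified methylated (an "mC") when its methylation level and read
depth both meet inclusive thresholds (defaults: level >= 50%, depth >= 4;
the alternative stringency uses level >= 80%). The two platforms' mC sets
are decomposed into overlap and unique components, and every unique site is
given exactly one discordance explanation by inspecting the other platform's
call at the same position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from methconcord.meth_io import CallSet

__all__ = [
    "EXPLANATION_CATEGORIES",
    "MCCriteria",
    "MCSetReport",
    "ThresholdConsistency",
    "classify_mc",
    "decompose",
    "threshold_consistency",
]

Site = tuple[str, int]

EXPLANATION_CATEGORIES = (
    "variant_position",
    "low_depth_other",
    "sub_threshold_other",
    "absent_other",
)


@dataclass(frozen=True)
class MCCriteria:
    """Inclusive thresholds for calling a CpG methylated."""

    min_level: float = 50.0
    min_depth: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.min_level <= 100:
            raise ValueError("min_level outside [0, 100]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def classify_mc(cs: CallSet, crit: MCCriteria = MCCriteria()) -> set[Site]:
    """Sites with level >= min_level and depth >= min_depth (both inclusive).

    Depth-0 sites have undefined level and are never included.
    """
    out = set()
    for call in cs:
        if call.depth >= crit.min_depth and call.level is not None \
                and call.level >= crit.min_level:
            out.add(call.key)
    return out


def _explain(
    site: Site,
    other: CallSet,
    crit: MCCriteria,
    variants: set[Site] | None,
) -> str:
    """Assign the single discordance category for a one-platform-only mC.

    Fixed precedence: variant position, then insufficient depth on the other
    platform (including the site being absent there), then a sub-threshold
    level, then a residual category.
    """
    if variants is not None and site in variants:
        return "variant_position"
    call = other.get(*site)
    if call is None or call.depth < crit.min_depth:
        return "low_depth_other"
    if call.level is not None and call.level < crit.min_level:
        return "sub_threshold_other"
    return "absent_other"


@dataclass
class MCSetReport:
    """mC sets for two platforms plus overlap/unique decomposition."""

    crit: MCCriteria
    platform_a: str
    platform_b: str
    mc_a: set[Site]
    mc_b: set[Site]
    overlap: set[Site]
    unique_a: set[Site]
    unique_b: set[Site]
    explanations_a: dict[Site, str] = field(default_factory=dict)
    explanations_b: dict[Site, str] = field(default_factory=dict)

    @property
    def delta_unique(self) -> int:
        return len(self.unique_a) - len(self.unique_b)

    def explanation_fractions(self, which: str = "a") -> dict[str, float]:
        expl = self.explanations_a if which == "a" else self.explanations_b
        n = len(expl)
        if n == 0:
            return {cat: 0.0 for cat in EXPLANATION_CATEGORIES}
        return {
            cat: sum(1 for v in expl.values() if v == cat) / n
            for cat in EXPLANATION_CATEGORIES
        }

    def overlap_fractions(self) -> dict[str, float | None]:
        """Overlap share under each denominator choice (Venn logic)."""
        union = len(self.mc_a | self.mc_b)
        return {
            "of_a": len(self.overlap) / len(self.mc_a) if self.mc_a else None,
            "of_b": len(self.overlap) / len(self.mc_b) if self.mc_b else None,
            "of_union": len(self.overlap) / union if union else None,
        }

    def summary(self) -> dict:
        return {
            "criteria": {
                "min_level": self.crit.min_level,
                "min_depth": self.crit.min_depth,
            },
            "platform_a": self.platform_a,
            "platform_b": self.platform_b,
            "n_mc_a": len(self.mc_a),
            "n_mc_b": len(self.mc_b),
            "n_overlap": len(self.overlap),
            "n_unique_a": len(self.unique_a),
            "n_unique_b": len(self.unique_b),
            "delta_unique": self.delta_unique,
            "overlap_fractions": self.overlap_fractions(),
            "explanation_fractions_a": self.explanation_fractions("a"),
            "explanation_fractions_b": self.explanation_fractions("b"),
        }


def decompose(
    cs_a: CallSet,
    cs_b: CallSet,
    crit: MCCriteria = MCCriteria(),
    variants: set[Site] | None = None,
) -> MCSetReport:
    """Decompose two platforms' mC sets and explain every unique site."""
    if cs_a.genome_id != cs_b.genome_id:
        raise ValueError(
            f"genome mismatch: {cs_a.genome_id!r} vs {cs_b.genome_id!r}"
        )
    mc_a = classify_mc(cs_a, crit)
    mc_b = classify_mc(cs_b, crit)
    overlap = mc_a & mc_b
    unique_a = mc_a - mc_b
    unique_b = mc_b - mc_a
    return MCSetReport(
        crit=crit,
        platform_a=cs_a.platform_label,
        platform_b=cs_b.platform_label,
        mc_a=mc_a,
        mc_b=mc_b,
        overlap=overlap,
        unique_a=unique_a,
        unique_b=unique_b,
        explanations_a={
            s: _explain(s, cs_b, crit, variants) for s in unique_a
        },
        explanations_b={
            s: _explain(s, cs_a, crit, variants) for s in unique_b
        },
    )


@dataclass(frozen=True)
class ThresholdConsistency:
    """Cross-threshold overlap of mC sets (stringent vs default criteria)."""

    n_low: int
    n_high: int
    n_common: int

    @property
    def overlap_of_high(self) -> float | None:
        """|mc(high) & mc(low)| / |mc(high)|; None when mc(high) is empty."""
        return self.n_common / self.n_high if self.n_high else None

    @property
    def retained_fraction(self) -> float | None:
        """|mc(high)| / |mc(low)|; the share surviving the stricter cutoff."""
        return self.n_high / self.n_low if self.n_low else None


def threshold_consistency(
    cs: CallSet,
    crit_low: MCCriteria = MCCriteria(min_level=50.0),
    crit_high: MCCriteria = MCCriteria(min_level=80.0),
) -> ThresholdConsistency:
    if crit_high.min_level < crit_low.min_level:
        raise ValueError("crit_high.min_level must be >= crit_low.min_level")
    mc_low = classify_mc(cs, crit_low)
    mc_high = classify_mc(cs, crit_high)
    return ThresholdConsistency(
        n_low=len(mc_low),
        n_high=len(mc_high),
        n_common=len(mc_low & mc_high),
    )
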