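"""Readers/writers for per-CpG methylation call files.

Two dialects are supported:

* bedMethyl-like TSV (0-based, half-open) as emitted by long-read CpG
  pipelines; column positions for level/coverage are configurable via
  :class:`BedMethylDialect`.
* Bismark-coverage-like TSV (1-based) with explicit methylated/unmethylated
  counts, as emitted by bisulfite pipelines.

All positions are normalized internally to the 0-based position of the C of
the CpG dinucleotide on the forward strand. Files ending in ``.gz`` are read
and written transparently.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "BedMethylDialect",
    "CpGCall",
    "CallSet",
    "MethFileError",
    "read_bedmethyl",
    "read_bismark_coverage",
    "write_callset",
]


class MethFileError(ValueError):
    """Raised for malformed or inconsistent methylation call files."""


@dataclass(frozen=True)
class CpGCall:
    """A single CpG site observed on one platform.

    ``pos`` is the 0-based forward-strand position of the C of the CpG.
    ``level`` is percent methylation in [0, 100]; it is ``None`` (undefined,
    not 0) when ``depth == 0``.
    """

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative read counts")

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float | None:
        if self.depth == 0:
            return None
        return 100.0 * self.n_meth / self.depth

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class CallSet:
    """All CpG calls from one platform, keyed by (chrom, pos)."""

    platform_label: str = ""
    genome_id: str = ""
    calls: dict[tuple[str, int], CpGCall] = field(default_factory=dict)

    def add(self, call: CpGCall) -> None:
        if call.key in self.calls:
            raise MethFileError(
                f"duplicate CpG at {call.chrom}:{call.pos} "
                f"(platform {self.platform_label!r})"
            )
        self.calls[call.key] = call

    def get(self, chrom: str, pos: int) -> CpGCall | None:
        return self.calls.get((chrom, pos))

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CpGCall]:
        return iter(self.calls.values())

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.calls

    def sorted_calls(self) -> list[CpGCall]:
        return [self.calls[k] for k in sorted(self.calls)]

    def positions(self) -> set[tuple[str, int]]:
        return set(self.calls)

    def total_depth(self) -> int:
        return sum(c.depth for c in self.calls.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return self.calls == other.calls


@dataclass(frozen=True)
class BedMethylDialect:
    """1-based column positions inside a bedMethyl-like TSV.

    ``level_col``/``depth_col`` are required; when ``nmeth_col`` is absent
    the methylated count is reconstructed as round-half-up(level*depth/100).
    """

    level_col: int = 7
    depth_col: int = 8
    nmeth_col: int | None = 9


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def read_bedmethyl(
    path: str | Path,
    dialect: BedMethylDialect = BedMethylDialect(),
    min_fields: int = 3,
    platform_label: str = "bedmethyl",
    genome_id: str = "",
) -> CallSet:
    """Read a bedMethyl-like TSV (0-based, half-open) into a :class:`CallSet`.

    Lines whose ``end != start + 1`` are rejected with a warning (they do not
    describe a single CpG); malformed lines raise :class:`MethFileError`
    naming the line number.
    """
    cs = CallSet(platform_label=platform_label, genome_id=genome_id)
    needed = max(
        min_fields, dialect.level_col, dialect.depth_col, dialect.nmeth_col or 0
    )
    n_rejected = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < needed:
                raise MethFileError(
                    f"{path}: line {lineno}: expected >= {needed} fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                level = float(fields[dialect.level_col - 1])
                depth = int(fields[dialect.depth_col - 1])
            except (ValueError, IndexError) as exc:
                raise MethFileError(f"{path}: line {lineno}: {exc}") from exc
            if end != start + 1:
                n_rejected += 1
                continue
            if dialect.nmeth_col is not None and len(fields) >= dialect.nmeth_col:
                n_meth = int(fields[dialect.nmeth_col - 1])
            else:
                n_meth = _round_half_up(level * depth / 100.0)
            cs.add(CpGCall(chrom, start, n_meth, depth - n_meth))
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} non-CpG record(s) with end != start+1",
            stacklevel=2,
        )
    return cs


def _merge_reverse_records(
    records: dict[tuple[str, int], tuple[int, int]],
    reference: Mapping[str, str] | None,
) -> dict[tuple[str, int], tuple[int, int]]:
    """Fold G-strand records at p into the forward CpG record at p-1.

    With a reference, a record is reverse-strand iff the base at its position
    is G and the preceding base is C. Without one, the paired-position
    heuristic is used: walking each chromosome left to right, a record whose
    predecessor position carries a forward record is reverse.
    """
    merged: dict[tuple[str, int], tuple[int, int]] = {}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in records:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        positions.sort()
        forward: set[int] = set()
        for pos in positions:
            nm, nu = records[(chrom, pos)]
            if reference is not None:
                seq = reference[chrom]
                is_rev = (
                    0 < pos < len(seq)
                    and seq[pos].upper() == "G"
                    and seq[pos - 1].upper() == "C"
                )
            else:
                is_rev = (pos - 1) in forward
            if is_rev:
                fm, fu = merged.get((chrom, pos - 1), (0, 0))
                merged[(chrom, pos - 1)] = (fm + nm, fu + nu)
            else:
                forward.add(pos)
                fm, fu = merged.get((chrom, pos), (0, 0))
                merged[(chrom, pos)] = (fm + nm, fu + nu)
    return merged


def read_bismark_coverage(
    path: str | Path,
    merge_strands: bool = True,
    reference: Mapping[str, str] | None = None,
    platform_label: str = "bismark",
    genome_id: str = "",
) -> CallSet:
    """Read a Bismark-coverage-like TSV (1-based) into a :class:`CallSet`.

    Columns: chrom, start(1-based), end, level%, count_meth, count_unmeth.
    Positions are shifted to 0-based. With ``merge_strands``, G-strand
    records are summed into the forward-strand CpG at pos-1 (see
    `_merge_reverse_records` for how strand is judged). A printed level that
    disagrees with the counts by more than 0.5 percentage points triggers a
    warning; counts win.
    """
    records: dict[tuple[str, int], tuple[int, int]] = {}
    n_inconsistent = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise MethFileError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start1 = int(fields[1])
                level = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise MethFileError(f"{path}: line {lineno}: {exc}") from exc
            pos = start1 - 1
            depth = n_meth + n_unmeth
            if depth > 0 and abs(level - 100.0 * n_meth / depth) > 0.5:
                n_inconsistent += 1
            key = (chrom, pos)
            if key in records:
                raise MethFileError(
                    f"{path}: line {lineno}: duplicate CpG at {chrom}:{pos}"
                )
            records[key] = (n_meth, n_unmeth)
    if n_inconsistent:
        warnings.warn(
            f"{path}: {n_inconsistent} record(s) with level inconsistent with "
            "counts by >0.5 points; counts used",
            stacklevel=2,
        )
    if merge_strands:
        records = _merge_reverse_records(records, reference)
    cs = CallSet(platform_label=platform_label, genome_id=genome_id)
    for (chrom, pos), (nm, nu) in sorted(records.items()):
        cs.add(CpGCall(chrom, pos, nm, nu))
    return cs


def _format_level(call: CpGCall) -> str:
    return "0.0" if call.level is None else f"{call.level:.6g}"


def write_callset(
    cs: CallSet, path: str | Path, dialect: str = "bedmethyl"
) -> Path:
    """Write a CallSet as TSV, sorted by (chrom, pos).

    ``dialect`` is ``bedmethyl`` (0-based, 9 columns: chrom start end name
    score strand level depth n_meth) or ``bismark_cov`` (1-based, 6 columns).
    Round-trips exactly through the matching reader.
    """
    path = Path(path)
    if dialect not in ("bedmethyl", "bismark_cov"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with _open_text(path, "wt") as fh:
        for call in cs.sorted_calls():
            if dialect == "bedmethyl":
                fh.write(
                    f"{call.chrom}\t{call.pos}\t{call.pos + 1}\t.\t"
                    f"{min(call.depth, 1000)}\t+\t{_format_level(call)}\t"
                    f"{call.depth}\t{call.n_meth}\n"
                )
            else:
                fh.write(
                    f"{call.chrom}\t{call.pos + 1}\t{call.pos + 1}\t"
                    f"{_format_level(call)}\t{call.n_meth}\t{call.n_unmeth}\n"
                )
    return path
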