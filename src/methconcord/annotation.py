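"""Genomic-context catalogs from standard annotation files and a reference.

Two catalog families are built:

* primary (sequence-level): CpG islands/shores/shelves, GC density in 5-base
  tiles, repeat classes (tandem, LINE, SINE, other, non-repetitive);
* secondary (functional-level): gene features (promoter, exon, intron, UTRs,
  CDS, gene, intergenic), regulatory tracks, chromosomes.

Partition catalogs cover every base exactly once under an explicit priority
order; overlay catalogs may label a base several times. A CpG site is always
assigned to a context by the position of its C only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from methconcord.intervals import (
    Interval,
    Track,
    clip_track,
    complement,
    contains,
    merge,
    subtract,
    union_tracks,
)

__all__ = [
    "ContextCatalog",
    "Gene",
    "ReferenceCpGIndex",
    "build_chromosome_catalog",
    "build_cpg_context",
    "build_gc_density",
    "build_gene_features",
    "build_regulatory",
    "build_repeats",
    "find_cpg_positions",
    "index_reference_cpgs",
    "read_bed",
    "read_cpg_islands",
    "read_fasta",
    "read_gtf",
    "read_rmsk",
    "read_simple_repeat",
    "write_catalog_beds",
]


@dataclass
class ContextCatalog:
    """Named, labelled interval sets with partition or overlay semantics."""

    name: str
    tracks: dict[str, Track]
    partition: bool
    genome_sizes: dict[str, int] = field(default_factory=dict)
    #: label order; for partition catalogs this is the priority order used
    label_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_order:
            self.label_order = list(self.tracks)

    @property
    def labels(self) -> list[str]:
        return list(self.label_order)

    def labels_at(self, chrom: str, pos: int) -> list[str]:
        """All labels covering ``pos`` (at most one for a partition)."""
        out = []
        for label in self.label_order:
            ivs = self.tracks[label].get(chrom, [])
            if contains(ivs, pos):
                out.append(label)
                if self.partition:
                    break
        return out

    def label_of(self, chrom: str, pos: int) -> str | None:
        labels = self.labels_at(chrom, pos)
        return labels[0] if labels else None

    def validate_partition(self) -> None:
        """Check pairwise disjointness and full genome coverage."""
        if not self.partition:
            return
        for chrom, n in self.genome_sizes.items():
            covered = merge(
                iv
                for t in self.tracks.values()
                for iv in t.get(chrom, [])
            )
            if covered != [(0, n)]:
                raise ValueError(
                    f"catalog {self.name}: chromosome {chrom} not fully covered"
                )
            total = sum(
                sum(e - s for s, e in t.get(chrom, []))
                for t in self.tracks.values()
            )
            if total != n:
                raise ValueError(
                    f"catalog {self.name}: labels overlap on {chrom} "
                    f"({total} labelled bases over {n})"
                )


# ---------------------------------------------------------------------------
# annotation file readers (UCSC table dumps, GTF, BED, FASTA)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into memory as a dict of upper-case sequences."""
    try:
        from pyfaidx import Fasta
    except ImportError:  # pragma: no cover
        Fasta = None
    if Fasta is not None:
        fa = Fasta(str(path), rebuild=True)
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:  # pragma: no cover - fallback path
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def _split_fields(line: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    return fields if len(fields) > 1 else line.split()


def read_bed(path: str | Path) -> Track:
    """Read chrom/start/end from a BED file into a merged track."""
    raw: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split_fields(line)
            raw.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return {c: merge(ivs) for c, ivs in raw.items()}


def _read_ucsc_table(path: str | Path, chrom_col: int, start_col: int,
                     end_col: int, extra_cols: Sequence[int] = ()) -> list[tuple]:
    """Read selected columns from a UCSC table dump.

    UCSC dumps carry a leading ``bin`` integer column; files without it are
    detected by the first column not parsing as an integer when the declared
    chrom column does not look like a name.
    """
    rows = []
    cols = (chrom_col, start_col, end_col, *extra_cols)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = _split_fields(line)
            # UCSC dumps carry a leading integer bin column; tolerate dumps
            # without it (then every declared index shifts left by one)
            offset = 0 if f[0].lstrip("-").isdigit() else -1
            rows.append(tuple(f[c + offset] for c in cols))
    return rows


def read_cpg_islands(path: str | Path) -> Track:
    """Read a cpgIslandExt-style dump (bin, chrom, chromStart, chromEnd, ...)."""
    raw: dict[str, list[Interval]] = {}
    for chrom, s, e in _read_ucsc_table(path, 1, 2, 3):
        raw.setdefault(chrom, []).append((int(s), int(e)))
    return {c: merge(ivs) for c, ivs in raw.items()}


def read_simple_repeat(path: str | Path) -> Track:
    """Read a simpleRepeat-style dump (bin, chrom, chromStart, chromEnd, ...)."""
    raw: dict[str, list[Interval]] = {}
    for chrom, s, e in _read_ucsc_table(path, 1, 2, 3):
        raw.setdefault(chrom, []).append((int(s), int(e)))
    return {c: merge(ivs) for c, ivs in raw.items()}


def read_rmsk(path: str | Path) -> dict[str, Track]:
    """Read an rmsk-style dump; returns tracks keyed by repClass.

    Columns used: genoName(5), genoStart(6), genoEnd(7), repClass(11),
    0-based after the leading bin column.
    """
    raw: dict[str, dict[str, list[Interval]]] = {}
    for chrom, s, e, rep_class in _read_ucsc_table(path, 5, 6, 7, (11,)):
        raw.setdefault(rep_class, {}).setdefault(chrom, []).append(
            (int(s), int(e))
        )
    return {
        cls: {c: merge(ivs) for c, ivs in track.items()}
        for cls, track in raw.items()
    }


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_type: str = ""

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> dict[str, list[dict]]:
    """Parse a GTF into records grouped by feature type.

    Each record: chrom, start(0-based), end, strand, feature, attrs. Only the
    columns the catalogs need are retained.
    """
    by_feature: dict[str, list[dict]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            rec = {
                "chrom": f[0],
                "feature": f[2],
                "start": int(f[3]) - 1,  # GTF is 1-based inclusive
                "end": int(f[4]),
                "strand": f[6],
                "attrs": _gtf_attributes(f[8]),
            }
            by_feature.setdefault(f[2], []).append(rec)
    return by_feature


def read_gtf_genes(path: str | Path) -> list[Gene]:
    genes = []
    for rec in read_gtf(path).get("gene", []):
        genes.append(
            Gene(
                gene_id=rec["attrs"].get("gene_id", ""),
                chrom=rec["chrom"],
                start=rec["start"],
                end=rec["end"],
                strand=rec["strand"],
                gene_type=rec["attrs"].get("gene_type", ""),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# catalog builders
# ---------------------------------------------------------------------------


def build_cpg_context(
    islands: Track,
    genome_sizes: dict[str, int],
    flank_shore: int = 2000,
    flank_shelf_outer: int = 4000,
) -> ContextCatalog:
    """Island/shore/shelf/open-sea partition.

    Shores are the +-``flank_shore`` flanks of merged islands minus the
    islands themselves; shelves extend from ``flank_shore`` to
    ``flank_shelf_outer``; priority island > shore > shelf resolves flank
    collisions between nearby islands; everything else is open sea.
    """
    islands = clip_track(islands, genome_sizes)
    tracks: dict[str, Track] = {
        "island": {},
        "shore": {},
        "shelf": {},
        "open_sea": {},
    }
    for chrom, n in genome_sizes.items():
        isl = islands.get(chrom, [])
        shore_raw = merge(
            (max(0, s - flank_shore), min(n, e + flank_shore)) for s, e in isl
        )
        shelf_raw = merge(
            (max(0, s - flank_shelf_outer), min(n, e + flank_shelf_outer))
            for s, e in isl
        )
        shore = subtract(shore_raw, isl)
        shelf = subtract(subtract(shelf_raw, isl), shore_raw)
        open_sea = complement(merge([*isl, *shore, *shelf]), n)
        tracks["island"][chrom] = isl
        tracks["shore"][chrom] = shore
        tracks["shelf"][chrom] = shelf
        tracks["open_sea"][chrom] = open_sea
    return ContextCatalog(
        name="cpg_context",
        tracks=tracks,
        partition=True,
        genome_sizes=dict(genome_sizes),
        label_order=["island", "shore", "shelf", "open_sea"],
    )


GC_LABELS = ("20", "40", "60", "80", "100")


def build_gc_density(
    sequences: Mapping[str, str], window: int = 5
) -> ContextCatalog:
    """Label non-overlapping ``window``-base tiles by percent G|C.

    A tile with k G/C bases gets label 100*k/window; tiles with zero G/C (or
    all-N tiles) are unlabelled — no CpG can sit in them. Ambiguous bases
    count as non-GC.
    """
    labels = [str(round(100 * k / window)) for k in range(1, window + 1)]
    tracks: dict[str, Track] = {lab: {} for lab in labels}
    genome_sizes = {c: len(s) for c, s in sequences.items()}
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        is_gc = (arr == b"G") | (arr == b"C")
        n_tiles = len(seq) // window
        per_tile: dict[str, list[Interval]] = {lab: [] for lab in labels}
        if n_tiles:
            counts = is_gc[: n_tiles * window].reshape(n_tiles, window).sum(1)
            for t, k in enumerate(counts):
                if k > 0:
                    per_tile[labels[int(k) - 1]].append(
                        (t * window, (t + 1) * window)
                    )
        # trailing partial tile: labelled by GC count over window size
        tail = len(seq) % window
        if tail:
            k = int(is_gc[n_tiles * window:].sum())
            if k > 0:
                per_tile[labels[k - 1]].append((n_tiles * window, len(seq)))
        for lab in labels:
            tracks[lab][chrom] = merge(per_tile[lab])
    return ContextCatalog(
        name="gc_density",
        tracks=tracks,
        partition=False,  # unlabelled zero-GC tiles -> not a full partition
        genome_sizes=genome_sizes,
        label_order=labels,
    )


REPEAT_PRIORITY = ["tandem", "LINE", "SINE", "other_repeat", "non_repetitive"]


def build_repeats(
    simple_repeat: Track,
    rmsk: dict[str, Track],
    genome_sizes: dict[str, int],
    priority: Sequence[str] = ("tandem", "LINE", "SINE", "other_repeat"),
) -> ContextCatalog:
    """Repeat-class partition with priority tandem > LINE > SINE > other.

    ``rmsk`` maps repClass -> track; classes other than LINE/SINE are folded
    into ``other_repeat``. Non-repetitive is the genomic complement of all
    repeat intervals.
    """
    other = union_tracks(
        *[t for cls, t in rmsk.items() if cls not in ("LINE", "SINE")]
    )
    sources: dict[str, Track] = {
        "tandem": clip_track(simple_repeat, genome_sizes),
        "LINE": clip_track(rmsk.get("LINE", {}), genome_sizes),
        "SINE": clip_track(rmsk.get("SINE", {}), genome_sizes),
        "other_repeat": clip_track(other, genome_sizes),
    }
    tracks: dict[str, Track] = {lab: {} for lab in REPEAT_PRIORITY}
    for chrom, n in genome_sizes.items():
        taken: list[Interval] = []
        for lab in priority:
            ivs = subtract(sources.get(lab, {}).get(chrom, []), taken)
            tracks[lab][chrom] = ivs
            taken = merge([*taken, *ivs])
        tracks["non_repetitive"][chrom] = complement(taken, n)
    return ContextCatalog(
        name="repeats",
        tracks=tracks,
        partition=True,
        genome_sizes=dict(genome_sizes),
        label_order=REPEAT_PRIORITY,
    )


def build_gene_features(
    gtf_path: str | Path,
    genome_sizes: dict[str, int],
    promoter_up: int = 2000,
) -> ContextCatalog:
    """Overlay catalog of gene features.

    promoter = the ``promoter_up`` bases upstream of each TSS (strand-aware);
    exon = union over all transcripts; intron = gene minus exons;
    intergenic = genome minus (CDS u promoter u gene).
    """
    feats = read_gtf(gtf_path)
    raw: dict[str, dict[str, list[Interval]]] = {
        lab: {}
        for lab in (
            "promoter",
            "gene",
            "exon",
            "CDS",
            "five_prime_UTR",
            "three_prime_UTR",
            "UTR",
        )
    }

    def _add(lab: str, chrom: str, s: int, e: int) -> None:
        if s < e:
            raw[lab].setdefault(chrom, []).append((s, e))

    utr_map = {
        "five_prime_utr": "five_prime_UTR",
        "5utr": "five_prime_UTR",
        "three_prime_utr": "three_prime_UTR",
        "3utr": "three_prime_UTR",
        "utr": "UTR",
    }
    tx_has_exons: set[str] = set()
    for rec in feats.get("exon", []):
        _add("exon", rec["chrom"], rec["start"], rec["end"])
        tx_has_exons.add(rec["attrs"].get("transcript_id", ""))
    n_empty_tx = sum(
        1
        for rec in feats.get("transcript", [])
        if rec["attrs"].get("transcript_id", "") not in tx_has_exons
    )
    if n_empty_tx:
        warnings.warn(f"{n_empty_tx} transcript(s) without exons skipped",
                      stacklevel=2)
    for rec in feats.get("CDS", []):
        _add("CDS", rec["chrom"], rec["start"], rec["end"])
    for feature, recs in feats.items():
        lab = utr_map.get(feature.lower())
        if lab:
            for rec in recs:
                _add(lab, rec["chrom"], rec["start"], rec["end"])
    for rec in feats.get("gene", []):
        chrom, s, e = rec["chrom"], rec["start"], rec["end"]
        _add("gene", chrom, s, e)
        if rec["strand"] == "-":
            _add("promoter", chrom, e, e + promoter_up)
        else:
            _add("promoter", chrom, max(0, s - promoter_up), s)

    tracks: dict[str, Track] = {
        lab: clip_track(
            {c: merge(ivs) for c, ivs in track.items()}, genome_sizes
        )
        for lab, track in raw.items()
    }
    # introns and intergenic are derived by set algebra
    tracks["intron"] = {
        c: subtract(tracks["gene"].get(c, []), tracks["exon"].get(c, []))
        for c in genome_sizes
    }
    blocked = union_tracks(tracks["CDS"], tracks["promoter"], tracks["gene"])
    tracks["intergenic"] = {
        c: complement(blocked.get(c, []), n) for c, n in genome_sizes.items()
    }
    order = [
        "promoter",
        "exon",
        "intron",
        "five_prime_UTR",
        "three_prime_UTR",
        "UTR",
        "CDS",
        "gene",
        "intergenic",
    ]
    # drop UTR labels never seen in this GTF
    order = [
        lab
        for lab in order
        if lab not in ("five_prime_UTR", "three_prime_UTR", "UTR")
        or any(tracks[lab].get(c) for c in tracks[lab])
    ]
    tracks = {lab: tracks[lab] for lab in order}
    return ContextCatalog(
        name="gene_features",
        tracks=tracks,
        partition=False,
        genome_sizes=dict(genome_sizes),
        label_order=order,
    )


def build_regulatory(
    open_chromatin: Track,
    enhancers: Track,
    genome_sizes: dict[str, int],
) -> ContextCatalog:
    return ContextCatalog(
        name="regulatory",
        tracks={
            "open_chromatin": clip_track(open_chromatin, genome_sizes),
            "enhancer": clip_track(enhancers, genome_sizes),
        },
        partition=False,
        genome_sizes=dict(genome_sizes),
        label_order=["open_chromatin", "enhancer"],
    )


def build_chromosome_catalog(genome_sizes: dict[str, int]) -> ContextCatalog:
    return ContextCatalog(
        name="chromosome",
        tracks={c: {c: [(0, n)]} for c, n in genome_sizes.items()},
        partition=True,
        genome_sizes=dict(genome_sizes),
        label_order=list(genome_sizes),
    )


# ---------------------------------------------------------------------------
# reference CpG index
# ---------------------------------------------------------------------------


def find_cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide (overlap-tolerant)."""
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    hits = (arr[:-1] == b"C") & (arr[1:] == b"G")
    return np.flatnonzero(hits).astype(np.int64)


@dataclass
class ReferenceCpGIndex:
    """All reference CpG positions plus per-(catalog, label) CpG counts."""

    positions: dict[str, np.ndarray]
    counts: dict[tuple[str, str], int]
    catalog_names: list[str]

    @property
    def total(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def count(self, catalog: str, label: str) -> int:
        return self.counts.get((catalog, label), 0)


def _count_in_track(positions: np.ndarray, ivs: list[Interval]) -> int:
    if not ivs or len(positions) == 0:
        return 0
    starts = np.fromiter((s for s, _ in ivs), dtype=np.int64, count=len(ivs))
    ends = np.fromiter((e for _, e in ivs), dtype=np.int64, count=len(ivs))
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    return int((hi - lo).sum())


def index_reference_cpgs(
    sequences: Mapping[str, str],
    catalogs: Iterable[ContextCatalog],
) -> ReferenceCpGIndex:
    """Index every reference CpG and count members per (catalog, label).

    For partition catalogs the per-position label is determined by catalog
    priority so counts over labels conserve the total. Overlay catalogs count
    each label independently.
    """
    catalogs = list(catalogs)
    positions = {c: find_cpg_positions(s) for c, s in sequences.items()}
    counts: dict[tuple[str, str], int] = {}
    for cat in catalogs:
        for chrom, n in (cat.genome_sizes or
                         {c: len(s) for c, s in sequences.items()}).items():
            if chrom not in positions:
                raise ValueError(
                    f"catalog {cat.name} references chromosome {chrom!r} "
                    "absent from FASTA"
                )
        if cat.partition:
            # peel positions off in priority order so overlaps (if any after
            # construction) cannot double count
            for chrom, pos in positions.items():
                remaining = pos
                for label in cat.label_order:
                    ivs = cat.tracks[label].get(chrom, [])
                    if not ivs or len(remaining) == 0:
                        counts.setdefault((cat.name, label), 0)
                        continue
                    mask = np.zeros(len(remaining), dtype=bool)
                    for s, e in ivs:
                        lo = np.searchsorted(remaining, s, side="left")
                        hi = np.searchsorted(remaining, e, side="left")
                        mask[lo:hi] = True
                    counts[(cat.name, label)] = (
                        counts.get((cat.name, label), 0) + int(mask.sum())
                    )
                    remaining = remaining[~mask]
        else:
            for label in cat.label_order:
                total = 0
                for chrom, pos in positions.items():
                    total += _count_in_track(
                        pos, cat.tracks[label].get(chrom, [])
                    )
                counts[(cat.name, label)] = total
    return ReferenceCpGIndex(
        positions=positions,
        counts=counts,
        catalog_names=[c.name for c in catalogs],
    )


def write_catalog_beds(catalog: ContextCatalog, out_dir: str | Path) -> list[Path]:
    """One BED file per label, named ``<catalog>.<label>.bed``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for label in catalog.label_order:
        path = out_dir / f"{catalog.name}.{label}.bed"
        with open(path, "w") as fh:
            for chrom in sorted(catalog.tracks[label]):
                for s, e in catalog.tracks[label][chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")
        written.append(path)
    return written
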