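"""Core domain types and readers/writers for the standard formats.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  Formats that use 1-based
inclusive coordinates (AGP, show-coords tables, human-readable reports) are
converted at the parse/write boundary.  Strand is carried as ``"+"``/``"-"``;
minus-strand MAF rows are normalized to forward-strand intervals at parse
time so downstream code never sees reverse-complement coordinates.

Soft-mask case (lowercase = repeat-annotated base) is preserved on read and
write; all base comparisons elsewhere in the package are case-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Assembly",
    "GenomicInterval",
    "AlignedBlock",
    "ContigPlacement",
    "ScaffoldGap",
    "ScaffoldLayout",
    "read_fasta",
    "write_fasta",
    "read_agp",
    "read_maf_blocks",
    "merge_intervals",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTNacgtn")
_IUPAC_AMBIG = frozenset("RYSWKMBDHVryswkmbdhv")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement preserving case; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


class AssemblyError(ValueError):
    """Malformed assembly input (duplicate ids, illegal characters...)."""


@dataclass
class Assembly:
    """An ordered collection of named nucleotide sequences.

    ``sequences`` maps sequence id -> nucleotide string over
    ``{A,C,G,T,N,a,c,g,t,n}`` (lowercase = soft-masked).  Insertion order is
    record order.  ``headers`` keeps the full FASTA description line (id token
    plus free text) when one was present.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    headers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.sequences:
            if not sid:
                raise AssemblyError("empty sequence id")

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def slice(self, interval: "GenomicInterval") -> str:
        return self.sequences[interval.seq_id][interval.start : interval.end]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignmentRow:
    """One gapped row of a pairwise alignment block (forward coordinates)."""

    seq_id: str
    start: int
    end: int
    strand: str
    text: str  # gapped sequence, '-' for gaps

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.end - self.start:
            raise ValueError(
                f"row {self.seq_id}:{self.start}-{self.end}: ungapped length "
                f"{ungapped} != interval length {self.end - self.start}"
            )


@dataclass(frozen=True)
class AlignedBlock:
    """A base-level pairwise alignment block: two gapped rows of equal width."""

    row_a: AlignmentRow
    row_b: AlignmentRow
    block_id: str = ""

    def __post_init__(self) -> None:
        if len(self.row_a.text) != len(self.row_b.text):
            raise ValueError(f"block {self.block_id}: row lengths differ")
        if any(
            ca == "-" and cb == "-"
            for ca, cb in zip(self.row_a.text, self.row_b.text)
        ):
            raise ValueError(f"block {self.block_id}: gap-in-both column")

    def columns(self) -> Iterator[tuple[str, str]]:
        return zip(self.row_a.text, self.row_b.text)


@dataclass(frozen=True)
class ContigPlacement:
    contig_id: str
    scaffold_interval: GenomicInterval
    contig_interval: GenomicInterval
    orientation: str  # '+' or '-'


@dataclass(frozen=True)
class ScaffoldGap:
    interval: GenomicInterval
    gap_length: int
    gap_type: str


@dataclass
class ScaffoldLayout:
    """AGP-derived composition of scaffolds: contig placements and gaps.

    Components tile each scaffold without overlap, sorted by start.
    """

    scaffolds: dict[str, list[ContigPlacement | ScaffoldGap]] = field(
        default_factory=dict
    )

    def contigs_of(self, scaffold_id: str) -> list[ContigPlacement]:
        return [
            c for c in self.scaffolds[scaffold_id] if isinstance(c, ContigPlacement)
        ]

    def gaps_of(self, scaffold_id: str) -> list[ScaffoldGap]:
        return [c for c in self.scaffolds[scaffold_id] if isinstance(c, ScaffoldGap)]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, map_ambiguous: bool = False) -> Assembly:
    """Read a (multi-record, possibly wrapped) FASTA file into an Assembly.

    Record order and base case are preserved.  Duplicate ids and characters
    outside ``{A,C,G,T,N}`` (either case) are rejected; with
    ``map_ambiguous=True`` IUPAC ambiguity codes are mapped to N instead.
    """
    sequences: dict[str, str] = {}
    headers: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise AssemblyError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq)
        bad = _first_illegal(seq, allow_ambiguous=map_ambiguous)
        if bad is not None:
            raise AssemblyError(
                f"illegal character {seq[bad]!r} in sequence {rec.id!r} at offset {bad}"
            )
        if map_ambiguous:
            seq = re.sub(f"[{''.join(_IUPAC_AMBIG)}]", "N", seq)
        sequences[rec.id] = seq
        headers[rec.id] = rec.description
    return Assembly(sequences=sequences, headers=headers)


def _first_illegal(seq: str, allow_ambiguous: bool) -> int | None:
    allowed = _VALID_BASES | (_IUPAC_AMBIG if allow_ambiguous else frozenset())
    if set(seq) <= allowed:  # fast path
        return None
    for i, c in enumerate(seq):
        if c not in allowed:
            return i
    return None


def write_fasta(assembly: Assembly, path, line_width: int = 60) -> None:
    """Write an Assembly to FASTA, wrapping at ``line_width`` columns."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    records = (
        SeqRecord(Seq(seq), id=sid, description=assembly.headers.get(sid, sid))
        for sid, seq in assembly.sequences.items()
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# AGP v2.x


def read_agp(path) -> ScaffoldLayout:
    """Read an AGP v2.0/2.1 file (component and gap lines) into a layout.

    AGP 1-based inclusive coordinates become 0-based half-open.  The tiling
    invariant (components cover each scaffold contiguously without overlap)
    is verified; violations raise with the scaffold id and line number.
    """
    layout = ScaffoldLayout()
    expected_next: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"AGP line {lineno}: fewer than 8 columns")
            obj, obj_beg, obj_end, _part, comp_type = f[0], int(f[1]), int(f[2]), f[3], f[4]
            start, end = obj_beg - 1, obj_end
            nxt = expected_next.get(obj, 0)
            if start != nxt:
                raise ValueError(
                    f"AGP line {lineno}: scaffold {obj!r} components do not tile "
                    f"(expected start {nxt + 1}, got {obj_beg})"
                )
            expected_next[obj] = end
            iv = GenomicInterval(obj, start, end)
            if comp_type in ("N", "U"):
                gap_len = int(f[5])
                gap_type = f[6] if len(f) > 6 else ""
                comp: ContigPlacement | ScaffoldGap = ScaffoldGap(iv, gap_len, gap_type)
            else:
                comp_id, comp_beg, comp_end, orientation = f[5], int(f[6]), int(f[7]), (
                    f[8] if len(f) > 8 else "+"
                )
                if orientation not in ("+", "-"):
                    orientation = "+"  # AGP '?', '0', 'na' treated as '+'
                comp = ContigPlacement(
                    comp_id, iv, GenomicInterval(comp_id, comp_beg - 1, comp_end), orientation
                )
            layout.scaffolds.setdefault(obj, []).append(comp)
    return layout


def write_agp(layout: ScaffoldLayout, path) -> None:
    """Write a layout as AGP v2.1 (inverse of :func:`read_agp`)."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for sid, comps in layout.scaffolds.items():
            for part, comp in enumerate(comps, 1):
                if isinstance(comp, ScaffoldGap):
                    iv = comp.interval
                    fh.write(
                        f"{sid}\t{iv.start + 1}\t{iv.end}\t{part}\tN\t"
                        f"{comp.gap_length}\t{comp.gap_type or 'scaffold'}\tyes\tna\n"
                    )
                else:
                    iv, civ = comp.scaffold_interval, comp.contig_interval
                    fh.write(
                        f"{sid}\t{iv.start + 1}\t{iv.end}\t{part}\tW\t"
                        f"{comp.contig_id}\t{civ.start + 1}\t{civ.end}\t{comp.orientation}\n"
                    )


# ---------------------------------------------------------------------------
# MAF (pairwise)


def read_maf_blocks(path) -> list[AlignedBlock]:
    """Read a pairwise MAF file into AlignedBlocks.

    Each alignment block must contain exactly two ``s`` rows.  MAF
    minus-strand coordinates (offsets on the reverse strand) are normalized
    to forward-strand intervals; the gapped text is kept verbatim.
    """
    blocks: list[AlignedBlock] = []
    rows: list[AlignmentRow] = []
    in_block = False

    def flush(block_index: int) -> None:
        nonlocal rows
        if not rows:
            return
        if len(rows) != 2:
            raise ValueError(
                f"MAF block {block_index}: expected 2 's' rows, got {len(rows)}"
            )
        if len(rows[0].text) != len(rows[1].text):
            raise ValueError(f"MAF block {block_index}: row length mismatch")
        blocks.append(AlignedBlock(rows[0], rows[1], block_id=f"maf_{block_index}"))
        rows = []

    with open(path) as fh:
        for line in fh:
            if line.startswith("a"):
                if in_block:
                    flush(len(blocks))
                in_block = True
            elif line.startswith("s"):
                _tag, src, start, size, strand, src_size, text = line.split()[:7]
                start, size, src_size = int(start), int(size), int(src_size)
                if strand == "-":
                    fwd_start = src_size - start - size
                else:
                    fwd_start = start
                rows.append(
                    AlignmentRow(src, fwd_start, fwd_start + size, strand, text)
                )
            elif not line.strip():
                if in_block:
                    flush(len(blocks))
                    in_block = False
    flush(len(blocks))
    return blocks


# ---------------------------------------------------------------------------
# Interval arithmetic


def merge_intervals(
    intervals: Iterable[tuple[int, int]] | Iterable[GenomicInterval],
) -> list:
    """Merge possibly-overlapping intervals into a sorted disjoint union.

    Accepts either ``(start, end)`` tuples (one coordinate axis) or
    GenomicIntervals (merged per sequence, returned sorted by
    ``(seq_id, start)``).  Touching intervals ([0,5),[5,9)) are coalesced.
    """
    items = list(intervals)
    if not items:
        return []
    if isinstance(items[0], GenomicInterval):
        by_seq: dict[str, list[tuple[int, int]]] = {}
        for iv in items:
            by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))
        out: list[GenomicInterval] = []
        for sid in sorted(by_seq):
            out.extend(
                GenomicInterval(sid, s, e) for s, e in merge_intervals(by_seq[sid])
            )
        return out
    items.sort()
    merged: list[tuple[int, int]] = []
    cur_s, cur_e = items[0]
    for s, e in items[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    return merged
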