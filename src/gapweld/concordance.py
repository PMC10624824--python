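"""Base-level concordance between two assemblies in synteny blocks.

Counts matched and mismatched bases per chromosome over pairwise
alignment blocks and computes synteny coverage (fraction of a genome
covered by the union of blocks).  Indel columns are excluded from both
match and mismatch counts, so the reported total is match + mismatch
only; N versus anything counts as mismatch by default (``skip_n``
excludes those columns instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core import AlignedBlock, GenomicInterval, merge_intervals

__all__ = ["MatchStats", "count_match_mismatch", "synteny_coverage", "write_concordance_table"]


@dataclass
class MatchStats:
    """Per-sequence matched/mismatched base counts with assembly totals."""

    per_sequence: dict[str, tuple[int, int]] = field(default_factory=dict)
    decimals: int = 3

    @property
    def total_match(self) -> int:
        return sum(m for m, _ in self.per_sequence.values())

    @property
    def total_mismatch(self) -> int:
        return sum(mm for _, mm in self.per_sequence.values())

    def ratio(self, seq_id: str | None = None) -> float | None:
        """match / (match + mismatch), rounded to ``decimals``; None if empty."""
        if seq_id is None:
            m, mm = self.total_match, self.total_mismatch
        else:
            m, mm = self.per_sequence[seq_id]
        if m + mm == 0:
            return None
        return round(m / (m + mm), self.decimals)


def count_match_mismatch(
    blocks: list[AlignedBlock],
    group_by: str = "a",
    skip_n: bool = False,
    dedup: bool = False,
    decimals: int = 3,
) -> MatchStats:
    """Count matched and mismatched bases per sequence of one side.

    Per column: skipped if either row has a gap character; match when the
    two bases are equal case-insensitively; N against anything is a
    mismatch unless ``skip_n``.  ``group_by`` chooses which row's sequence
    ids key the per-sequence table ('a' or 'b').  Overlapping blocks are
    counted as given (with a warning) unless ``dedup`` merges by A-side
    coordinates first.
    """
    if group_by not in ("a", "b"):
        raise ValueError("group_by must be 'a' or 'b'")
    if dedup:
        blocks = _dedup_blocks(blocks)
    elif _has_overlaps(blocks):
        warnings.warn("overlapping alignment blocks counted as given", stacklevel=2)
    stats = MatchStats(decimals=decimals)
    for blk in blocks:
        key = (blk.row_a if group_by == "a" else blk.row_b).seq_id
        m, mm = stats.per_sequence.get(key, (0, 0))
        for ca, cb in blk.columns():
            if ca == "-" or cb == "-":
                continue
            ua, ub = ca.upper(), cb.upper()
            if ua == "N" or ub == "N":
                if not skip_n:
                    mm += 1
                continue
            if ua == ub:
                m += 1
            else:
                mm += 1
        stats.per_sequence[key] = (m, mm)
    return stats


def _has_overlaps(blocks: list[AlignedBlock]) -> bool:
    ivs = sorted(
        (b.row_a.seq_id, b.row_a.start, b.row_a.end) for b in blocks
    )
    return any(
        a[0] == b[0] and b[1] < a[2] for a, b in zip(ivs, ivs[1:])
    )


def _dedup_blocks(blocks: list[AlignedBlock]) -> list[AlignedBlock]:
    """Drop blocks whose A-side interval overlaps an earlier-kept block."""
    kept: list[AlignedBlock] = []
    seen: dict[str, list[tuple[int, int]]] = {}
    for blk in sorted(blocks, key=lambda b: (b.row_a.seq_id, b.row_a.start)):
        ivs = seen.setdefault(blk.row_a.seq_id, [])
        if any(s < blk.row_a.end and blk.row_a.start < e for s, e in ivs):
            continue
        ivs.append((blk.row_a.start, blk.row_a.end))
        kept.append(blk)
    return kept


def synteny_coverage(
    blocks_or_intervals: list[AlignedBlock] | list[GenomicInterval],
    genome_size: int,
    side: str = "a",
) -> float:
    """Union length of the chosen side's block intervals over genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    items = list(blocks_or_intervals)
    if items and isinstance(items[0], AlignedBlock):
        ivs = [
            GenomicInterval(*(
                (b.row_a.seq_id, b.row_a.start, b.row_a.end)
                if side == "a"
                else (b.row_b.seq_id, b.row_b.start, b.row_b.end)
            ))
            for b in items
        ]
    else:
        ivs = items
    covered = sum(len(iv) for iv in merge_intervals(ivs))
    if covered > genome_size:
        raise ValueError(f"block union {covered} exceeds genome size {genome_size}")
    return covered / genome_size


def write_concordance_table(stats: MatchStats, path) -> None:
    """One row per sequence plus a Total row; ratios to ``stats.decimals``."""
    fmt = f"{{:.{stats.decimals}f}}"
    with open(path, "w") as fh:
        fh.write("Chromosome\tMatch\tMismatch\tMatch/Total\n")
        for sid, (m, mm) in stats.per_sequence.items():
            r = stats.ratio(sid)
            fh.write(f"{sid}\t{m}\t{mm}\t{'' if r is None else fmt.format(r)}\n")
        tr = stats.ratio()
        fh.write(
            f"Total\t{stats.total_match}\t{stats.total_mismatch}\t"
            f"{'' if tr is None else fmt.format(tr)}\n"
        )
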