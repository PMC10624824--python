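"""Gap-flank extraction and flank-to-donor local alignment.

For every assembly gap, up-to-``F`` bp of sequence is taken from each side
(default F = 10,000) and placed on the donor assembly.  Placement can come
from the built-in deterministic aligner below, or from an externally
produced coordinate table (show-coords-style TSV) via :func:`read_coords`.

Built-in aligner
----------------
A seed-and-chain design:

1. exact k-mer anchors (default k = 15) between flank and donor, both
   strands, located with a sorted-array index of 2-bit donor k-mer codes
   (k-mers containing N never anchor; hyper-repetitive donor k-mers with
   more than ``max_hits`` occurrences are skipped);
2. anchors colinear on one donor sequence and strand are chained: tight
   diagonal bands (so nearby repeat copies cannot hijack a chain) split
   at inter-anchor gaps > ``max_anchor_gap`` (default 500 bp), then
   strictly colinear chains are re-merged across larger indels;
3. clusters whose anchored query span >= ``min_cluster`` (default 25 bp)
   are kept;
4. each kept cluster's spanned query/donor substrings are globally aligned
   (edlib, Needleman-Wunsch mode) and matches / aligned columns counted
   from the resulting path: a column is a match only when both bases are
   equal case-insensitively and neither is N; gap columns stay in the
   denominator, so ``pct_identity = 100 * matches / aligned_columns``
   follows the coordinate-table convention of counting indel columns.

The defaults k=15 / min_cluster=25 mirror the minimum-match and
minimum-cluster lengths commonly used when placing 10 kb flanks with a
genome aligner.  Output is deterministic for identical inputs and
parameters and invariant to donor record order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .core import Assembly, GenomicInterval, revcomp
from .gaps import Gap

__all__ = [
    "Flank",
    "FlankPair",
    "LocalAlignment",
    "extract_flanks",
    "flanks_to_fasta",
    "DonorIndex",
    "align_flank",
    "best_alignment",
    "read_coords",
    "write_coords",
]

DEFAULT_FLANK = 10_000


@dataclass(frozen=True)
class Flank:
    role: str  # 'L' or 'R'
    interval: GenomicInterval | None  # None when zero-length
    sequence: str

    @property
    def evaluable(self) -> bool:
        return self.interval is not None and len(self.sequence) > 0


@dataclass(frozen=True)
class FlankPair:
    gap_id: str
    left: Flank
    right: Flank
    flank_size: int  # configured F


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment of a flank (query) to a donor sequence.

    Query coordinates are 0-based half-open on the forward flank sequence;
    donor coordinates are forward-strand regardless of ``strand``.
    ``matches``/``aligned_columns`` are None for records ingested from a
    coordinate table (where only the identity percentage is available).
    """

    gap_id: str
    flank_role: str  # 'L' or 'R'
    query_start: int
    query_end: int
    donor_seq_id: str
    donor_start: int
    donor_end: int
    strand: str
    pct_identity: float
    matches: int | None = None
    aligned_columns: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.matches is not None and self.aligned_columns is not None:
            if self.matches > self.aligned_columns:
                raise ValueError("matches exceed aligned columns")

    @property
    def align_len_query(self) -> int:
        return self.query_end - self.query_start

    def sort_key(self):
        return (
            -self.align_len_query,
            -self.pct_identity,
            self.donor_seq_id,
            self.donor_start,
        )


# ---------------------------------------------------------------------------
# Flank extraction


def extract_flanks(
    assembly: Assembly,
    gap: Gap,
    flank_size: int = DEFAULT_FLANK,
    all_gaps: list[Gap] | None = None,
) -> FlankPair:
    """Extract the two gap-flanking sequences (verbatim target bases).

    The left flank ends at ``gap.start``, the right starts at ``gap.end``;
    each is truncated at the sequence bounds and, when ``all_gaps`` is
    given, at the nearest neighbouring gap edge.  A zero-length flank is
    flagged unevaluable on that side.
    """
    if flank_size < 1:
        raise ValueError("flank_size must be >= 1")
    iv = gap.interval
    seq = assembly[iv.seq_id]
    left_limit, right_limit = 0, len(seq)
    if all_gaps:
        for other in all_gaps:
            oiv = other.interval
            if oiv.seq_id != iv.seq_id or oiv == iv:
                continue
            if oiv.end <= iv.start:
                left_limit = max(left_limit, oiv.end)
            elif oiv.start >= iv.end:
                right_limit = min(right_limit, oiv.start)
    ls = max(left_limit, iv.start - flank_size)
    re_ = min(right_limit, iv.end + flank_size)
    left = Flank(
        "L",
        GenomicInterval(iv.seq_id, ls, iv.start) if ls < iv.start else None,
        seq[ls : iv.start],
    )
    right = Flank(
        "R",
        GenomicInterval(iv.seq_id, iv.end, re_) if iv.end < re_ else None,
        seq[iv.end : re_],
    )
    return FlankPair(gap.gap_id, left, right, flank_size)


def flanks_to_fasta(pairs: list[FlankPair], path) -> None:
    """Write flanks as FASTA with ``<gap_id>|L`` / ``<gap_id>|R`` headers."""
    with open(path, "w") as fh:
        for p in pairs:
            for fl in (p.left, p.right):
                if fl.evaluable:
                    fh.write(f">{p.gap_id}|{fl.role}\n{fl.sequence}\n")


# ---------------------------------------------------------------------------
# Built-in aligner

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-mer start; invalid where any base is non-ACGT."""
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    valid = ~np.any(win > 3, axis=1)
    return codes, valid


class DonorIndex:
    """Sorted k-mer code index over all donor sequences (build once, query many)."""

    def __init__(self, donor: Assembly, k: int = 15):
        self.donor = donor
        self.k = k
        # deterministic, order-independent frame: sequences indexed by sorted id
        self.seq_ids = sorted(donor.sequences)
        codes_parts, pos_parts, seq_parts = [], [], []
        for si, sid in enumerate(self.seq_ids):
            codes, valid = _kmer_codes(_encode(donor[sid]), k)
            idx = np.nonzero(valid)[0]
            codes_parts.append(codes[idx])
            pos_parts.append(idx)
            seq_parts.append(np.full(idx.shape[0], si, dtype=np.int32))
        all_codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
        self._pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        self._seq = np.concatenate(seq_parts) if seq_parts else np.empty(0, np.int32)
        order = np.argsort(all_codes, kind="stable")
        self._codes = all_codes[order]
        self._pos = self._pos[order]
        self._seq = self._seq[order]

    def anchors(self, query: str, max_hits: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(query_pos, donor_seq_index, donor_pos) for all exact k-mer hits."""
        qcodes, qvalid = _kmer_codes(_encode(query), self.k)
        qpos = np.nonzero(qvalid)[0]
        qcodes = qcodes[qpos]
        if qcodes.shape[0] == 0 or self._codes.shape[0] == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z.astype(np.int32), z
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= max_hits)
        qpos, lo, counts = qpos[keep], lo[keep], counts[keep]
        total = int(counts.sum())
        if total == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z.astype(np.int32), z
        # expand [lo_i, lo_i + counts_i) ranges into one flat index array
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        flat = np.repeat(lo - starts, counts) + np.arange(total)
        return np.repeat(qpos, counts), self._seq[flat], self._pos[flat]


def _cluster_anchors(
    q: np.ndarray,
    seq_idx: np.ndarray,
    d: np.ndarray,
    k: int,
    max_anchor_gap: int,
    max_diag_drift: int = 30,
) -> list[tuple[int, int, int, int, int]]:
    """Chain colinear anchors into clusters -> (seq_idx, q0, q1, d0, d1).

    Two stages: anchors are first grouped into tight diagonal bands
    (drift <= ``max_diag_drift``, the small-indel budget — a tight band
    keeps anchors of nearby repeat copies out of each other's chains),
    then bands are split at inter-anchor gaps > ``max_anchor_gap`` and the
    resulting clusters merged when strictly colinear (query and donor both
    advancing, gaps within ``max_anchor_gap``), which re-joins chains that
    a larger indel broke across diagonals.
    """
    if q.shape[0] == 0:
        return []
    diag = d - q
    order = np.lexsort((q, diag, seq_idx))
    q, d, diag, seq_idx = q[order], d[order], diag[order], seq_idx[order]
    band_break = np.empty(q.shape[0], dtype=bool)
    band_break[0] = True
    band_break[1:] = (np.diff(seq_idx) != 0) | (np.abs(np.diff(diag)) > max_diag_drift)
    clusters: list[tuple[int, int, int, int, int]] = []
    band_starts = np.nonzero(band_break)[0]
    band_ends = np.append(band_starts[1:], q.shape[0])
    for bs, be in zip(band_starts, band_ends):
        bq, bd = q[bs:be], d[bs:be]
        o = np.lexsort((bd, bq))
        bq, bd = bq[o], bd[o]
        brk = np.empty(bq.shape[0], dtype=bool)
        brk[0] = True
        if bq.shape[0] > 1:
            dq, dd = np.diff(bq), np.diff(bd)
            brk[1:] = (dq > max_anchor_gap + k) | (dd > max_anchor_gap + k)
        cs = np.nonzero(brk)[0]
        ce = np.append(cs[1:], bq.shape[0])
        for s, e in zip(cs, ce):
            clusters.append(
                (
                    int(seq_idx[bs]),
                    int(bq[s:e].min()),
                    int(bq[s:e].max()) + k,
                    int(bd[s:e].min()),
                    int(bd[s:e].max()) + k,
                )
            )
    return _merge_colinear(clusters, k, max_anchor_gap)


def _merge_colinear(
    clusters: list[tuple[int, int, int, int, int]], k: int, max_anchor_gap: int
) -> list[tuple[int, int, int, int, int]]:
    """Greedily merge clusters that continue each other colinearly."""
    clusters.sort()
    merged: list[list[int]] = []
    for si, q0, q1, d0, d1 in clusters:
        if merged:
            m = merged[-1]
            if (
                m[0] == si
                and q0 >= m[2] - k
                and d0 >= m[4] - k
                and q0 - m[2] <= max_anchor_gap
                and d0 - m[4] <= max_anchor_gap
                and q1 > m[2]
                and d1 > m[4]
            ):
                m[2], m[4] = q1, d1
                continue
        merged.append([si, q0, q1, d0, d1])
    return [tuple(m) for m in merged]


def _count_path(qsub: str, dsub: str) -> tuple[int, int]:
    """Global-align two substrings; return (matches, aligned_columns).

    N never matches anything (including N); comparisons case-insensitive;
    gap columns are counted in aligned_columns.
    """
    qu, du = qsub.upper(), dsub.upper()
    res = edlib.align(qu, du, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, qu, du)
    qa, da = nice["query_aligned"], nice["target_aligned"]
    matches = sum(
        1 for a, b in zip(qa, da) if a == b and a != "-" and a != "N"
    )
    return matches, len(qa)


def align_flank(
    flank_seq: str,
    donor: Assembly | DonorIndex,
    k: int = 15,
    min_cluster: int = 25,
    max_anchor_gap: int = 500,
    max_hits: int = 100,
    gap_id: str = "",
    flank_role: str = "",
) -> list[LocalAlignment]:
    """Locally align one flank against the donor (both strands).

    Returns one LocalAlignment per kept anchor cluster, sorted by
    descending align_len_query, then descending pct_identity, then
    (donor_seq_id, donor_start) ascending.  Empty list when nothing aligns.
    """
    if not flank_seq:
        return []
    index = donor if isinstance(donor, DonorIndex) else DonorIndex(donor, k)
    if index.k != k:
        raise ValueError(f"index built with k={index.k}, requested k={k}")
    L = len(flank_seq)
    out: list[LocalAlignment] = []
    for strand, qseq in (("+", flank_seq), ("-", revcomp(flank_seq))):
        q, seq_idx, d = index.anchors(qseq, max_hits)
        for si, q0, q1, d0, d1 in _cluster_anchors(q, seq_idx, d, k, max_anchor_gap):
            if q1 - q0 < min_cluster:
                continue
            sid = index.seq_ids[si]
            matches, cols = _count_path(qseq[q0:q1], index.donor[sid][d0:d1])
            if strand == "+":
                fq0, fq1 = q0, q1
            else:  # map reverse-complement query coords back to forward flank
                fq0, fq1 = L - q1, L - q0
            out.append(
                LocalAlignment(
                    gap_id=gap_id,
                    flank_role=flank_role,
                    query_start=fq0,
                    query_end=fq1,
                    donor_seq_id=sid,
                    donor_start=d0,
                    donor_end=d1,
                    strand=strand,
                    pct_identity=100.0 * matches / cols if cols else 0.0,
                    matches=matches,
                    aligned_columns=cols,
                )
            )
    out.sort(key=LocalAlignment.sort_key)
    return out


def best_alignment(
    alignments: list[LocalAlignment], policy: str = "default"
) -> LocalAlignment | None:
    """Reduce a flank's candidate alignments to one record (or None).

    The default policy picks longest query coverage, breaking ties by
    higher identity, then by (donor_seq_id, donor_start); fully specified
    so selection is deterministic across platforms.
    """
    if policy != "default":
        raise ValueError(f"unknown policy {policy!r}")
    if not alignments:
        return None
    return min(alignments, key=LocalAlignment.sort_key)


# ---------------------------------------------------------------------------
# Coordinate-table ingestion (show-coords-style TSV)

_ROLE_RE = re.compile(r"^(?P<gap>.+)\|(?P<role>[LR])$")

_COORDS_HEADER = [
    "query_id",
    "target_id",
    "query_start",
    "query_end",
    "target_start",
    "target_end",
    "pct_identity",
    "strand",
]


def read_coords(path) -> list[LocalAlignment]:
    """Read a tab-separated alignment coordinate table.

    Columns (1-based inclusive coordinates): query id, target id, query
    start, query end, target start, target end, % identity, strand.  The
    query id must follow the ``<gap_id>|L`` / ``<gap_id>|R`` naming scheme
    emitted by :func:`flanks_to_fasta`.  Reversed target coordinates denote
    a minus-strand hit and are normalized to a forward donor interval.
    """
    out: list[LocalAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "query_id":  # header row
                continue
            m = _ROLE_RE.match(f[0])
            if not m:
                raise ValueError(
                    f"coords line {lineno}: query id {f[0]!r} lacks the "
                    "'<gap_id>|L' / '<gap_id>|R' flank-role suffix"
                )
            qs, qe = int(f[2]) - 1, int(f[3])
            ts, te = int(f[4]), int(f[5])
            strand = f[7] if len(f) > 7 else "+"
            if ts > te:  # reversed target coordinates
                strand = "-"
                ds, de = te - 1, ts
            else:
                ds, de = ts - 1, te
            out.append(
                LocalAlignment(
                    gap_id=m.group("gap"),
                    flank_role=m.group("role"),
                    query_start=qs,
                    query_end=qe,
                    donor_seq_id=f[1],
                    donor_start=ds,
                    donor_end=de,
                    strand=strand,
                    pct_identity=float(f[6]),
                )
            )
    return out


def write_coords(alignments: list[LocalAlignment], path) -> None:
    """Write alignments as the coordinate-table dialect read_coords accepts."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COORDS_HEADER) + "\n")
        for a in alignments:
            if a.strand == "-":
                ts, te = a.donor_end, a.donor_start + 1
            else:
                ts, te = a.donor_start + 1, a.donor_end
            fh.write(
                f"{a.gap_id}|{a.flank_role}\t{a.donor_seq_id}\t"
                f"{a.query_start + 1}\t{a.query_end}\t{ts}\t{te}\t"
                f"{a.pct_identity!r}\t{a.strand}\n"
            )
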