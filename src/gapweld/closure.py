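"""Reference-guided gap closure: the four-criterion closure test and fill.

A gap of the target assembly is considered closed when its two flank
alignments against the donor satisfy all of:

  c1  each chosen alignment covers strictly more than ``min_aln_len`` bp of
      its flank (default 5,000);
  c2  the mean of the two chosen alignments' percent identities is strictly
      greater than ``min_mean_identity`` (default 90.0);
  c3  the two alignments land on the same donor sequence, on the same
      strand, with donor order consistent with target order (on '+' the
      left-flank placement lies entirely before the right-flank placement;
      on '-' the reverse);
  c4  the donor bases under both placements contain no N.

Both thresholds are strict inequalities: an alignment of exactly 5,000 bp
fails c1 and a mean identity of exactly 90.0 fails c2.  When closed, the
donor segment between the two placements (extended by any unaligned
gap-proximal flank tails, which are target sequence that must not be
represented twice) replaces the gap's N-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Assembly, GenomicInterval, revcomp
from .flanks import (
    DonorIndex,
    FlankPair,
    LocalAlignment,
    best_alignment,
    extract_flanks,
    align_flank,
)
from .gaps import Gap, find_gaps

__all__ = [
    "ClosureThresholds",
    "ClosureDecision",
    "ClosureReport",
    "evaluate_gap",
    "extract_fill",
    "apply_closures",
    "closure_totals",
    "close_gaps",
]


@dataclass(frozen=True)
class ClosureThresholds:
    min_aln_len: int = 5_000  # bp, strict >
    min_mean_identity: float = 90.0  # percent, strict >
    require_fill_n_free: bool = False
    max_overlap: int = 0  # bp of tolerated negative fill

    def __post_init__(self) -> None:
        if self.min_aln_len < 0:
            raise ValueError("min_aln_len must be >= 0")
        if not 0.0 <= self.min_mean_identity <= 100.0:
            raise ValueError("min_mean_identity must be in [0,100]")


@dataclass
class ClosureDecision:
    gap_id: str
    gap_interval: GenomicInterval
    left: LocalAlignment | None
    right: LocalAlignment | None
    c1: bool = False
    c2: bool = False
    c3: bool = False
    c4: bool = False
    status: str = "unevaluable"  # closed | rejected | unevaluable
    reason: str = ""
    fill_seq_id: str | None = None
    fill_start: int | None = None  # donor forward coordinates
    fill_end: int | None = None
    fill_strand: str | None = None
    fill_len: int = 0
    overlap_len: int = 0

    @property
    def criteria_met(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4


@dataclass
class ClosureReport:
    decisions: list[ClosureDecision] = field(default_factory=list)


def evaluate_gap(
    flank_pair: FlankPair,
    left_alns: list[LocalAlignment],
    right_alns: list[LocalAlignment],
    thresholds: ClosureThresholds = ClosureThresholds(),
    donor: Assembly | None = None,
    gap_interval: GenomicInterval | None = None,
) -> ClosureDecision:
    """Apply the four closure criteria to one gap's flank alignments.

    ``donor`` is needed for c4 (N check under the donor placements); when
    omitted c4 is False.  All failure modes are encoded in status/flags,
    never raised.
    """
    if gap_interval is None:
        sid, rng = flank_pair.gap_id.rsplit(":", 1)
        s, e = rng.split("-")
        gap_interval = GenomicInterval(sid, int(s), int(e))
    dec = ClosureDecision(flank_pair.gap_id, gap_interval, None, None)
    if not (flank_pair.left.evaluable and flank_pair.right.evaluable):
        dec.reason = "unevaluable-flank"
        return dec
    la = best_alignment(left_alns)
    ra = best_alignment(right_alns)
    dec.left, dec.right = la, ra
    if la is None or ra is None:
        dec.reason = "no-alignment"
        return dec
    dec.c1 = (
        la.align_len_query > thresholds.min_aln_len
        and ra.align_len_query > thresholds.min_aln_len
    )
    dec.c2 = (la.pct_identity + ra.pct_identity) / 2.0 > thresholds.min_mean_identity
    same_frame = la.donor_seq_id == ra.donor_seq_id and la.strand == ra.strand
    if same_frame and la.strand == "+":
        ordered = la.donor_end <= ra.donor_start
    elif same_frame:
        ordered = ra.donor_end <= la.donor_start
    else:
        ordered = False
    dec.c3 = same_frame and ordered
    if donor is not None:
        dec.c4 = not _donor_has_n(donor, la) and not _donor_has_n(donor, ra)
    dec.status = "closed" if dec.criteria_met else "rejected"
    if dec.status == "rejected":
        dec.reason = "criteria:" + "".join(
            c for c, ok in zip(("1", "2", "3", "4"), (dec.c1, dec.c2, dec.c3, dec.c4)) if not ok
        )
    return dec


def _donor_has_n(donor: Assembly, aln: LocalAlignment) -> bool:
    seg = donor[aln.donor_seq_id][aln.donor_start : aln.donor_end]
    return "N" in seg or "n" in seg


def extract_fill(
    decision: ClosureDecision,
    donor: Assembly,
    flank_pair: FlankPair,
    thresholds: ClosureThresholds = ClosureThresholds(),
) -> str:
    """Derive the donor fill sequence for a closed gap (updates decision).

    The gap-proximal alignment ends are projected onto the donor and
    extended by the unaligned gap-proximal flank tails; the donor segment
    between the two projected points is the fill (reverse-complemented on
    '-').  A negative span (flanks overlapping in the donor) yields an
    empty fill and is tolerated up to ``max_overlap`` bp, beyond which the
    decision is downgraded to rejected with reason "overlap-too-large".
    """
    if decision.status != "closed":
        raise ValueError("extract_fill requires a closed decision")
    la, ra = decision.left, decision.right
    assert la is not None and ra is not None
    Ll = len(flank_pair.left.sequence)
    left_tail = Ll - la.query_end  # unaligned gap-proximal tail of left flank
    right_head = ra.query_start  # unaligned gap-proximal head of right flank
    strand = la.strand
    donor_len = len(donor[la.donor_seq_id])
    if strand == "+":
        gpl = la.donor_end + left_tail
        gpr = ra.donor_start - right_head
        lo, hi = gpl, gpr
    else:
        gpl = la.donor_start - left_tail
        gpr = ra.donor_end + right_head
        lo, hi = gpr, gpl
    if not (0 <= min(lo, hi) and max(lo, hi) <= donor_len):
        decision.status = "rejected"
        decision.reason = "fill-out-of-bounds"
        return ""
    if hi <= lo:
        decision.overlap_len = lo - hi
        if decision.overlap_len > thresholds.max_overlap:
            decision.status = "rejected"
            decision.reason = "overlap-too-large"
            return ""
        decision.fill_seq_id = la.donor_seq_id
        decision.fill_start = decision.fill_end = lo
        decision.fill_strand = strand
        decision.fill_len = 0
        return ""
    fill = donor[la.donor_seq_id][lo:hi]
    if strand == "-":
        fill = revcomp(fill)
    if thresholds.require_fill_n_free and ("N" in fill or "n" in fill):
        decision.status = "rejected"
        decision.reason = "fill-contains-n"
        return ""
    decision.fill_seq_id = la.donor_seq_id
    decision.fill_start, decision.fill_end = lo, hi
    decision.fill_strand = strand
    decision.fill_len = len(fill)
    return fill


def apply_closures(
    assembly: Assembly,
    decisions: list[ClosureDecision],
    donor: Assembly,
) -> tuple[Assembly, ClosureReport]:
    """Substitute each closed gap's N-run with its donor fill.

    Closures on one sequence are applied in descending start order so
    earlier coordinates stay valid; all non-gap bases are byte-identical
    in the output.  Overlapping gap intervals are rejected up front.
    """
    ivs = sorted((d.gap_interval for d in decisions), key=lambda v: (v.seq_id, v.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping gap intervals {a} and {b}")
    new_seqs = dict(assembly.sequences)
    for dec in sorted(
        decisions, key=lambda d: (d.gap_interval.seq_id, -d.gap_interval.start)
    ):
        if dec.status != "closed":
            continue
        iv = dec.gap_interval
        fill = donor[dec.fill_seq_id][dec.fill_start : dec.fill_end]
        if dec.fill_strand == "-":
            fill = revcomp(fill)
        s = new_seqs[iv.seq_id]
        new_seqs[iv.seq_id] = s[: iv.start] + fill + s[iv.end :]
    closed = Assembly(sequences=new_seqs, headers=dict(assembly.headers))
    return closed, ClosureReport(decisions=list(decisions))


def new_coordinates(report: ClosureReport) -> dict[str, tuple[int, int]]:
    """Map each closed gap_id to its (start, end) in post-closure coordinates."""
    out: dict[str, tuple[int, int]] = {}
    by_seq: dict[str, list[ClosureDecision]] = {}
    for d in report.decisions:
        if d.status == "closed":
            by_seq.setdefault(d.gap_interval.seq_id, []).append(d)
    for decs in by_seq.values():
        decs.sort(key=lambda d: d.gap_interval.start)
        shift = 0
        for d in decs:
            out[d.gap_id] = (d.gap_interval.start + shift, d.gap_interval.start + shift + d.fill_len)
            shift += d.fill_len - len(d.gap_interval)
    return out


def closure_totals(report: ClosureReport, donor: Assembly | None = None) -> dict:
    """Summary counts: evaluated/closed/rejected, N replaced, non-N fill added."""
    rejected_by: dict[str, int] = {}
    closed = n_total = fill_nonn = 0
    for d in report.decisions:
        if d.status == "closed":
            closed += 1
            n_total += len(d.gap_interval)
            if donor is not None and d.fill_len:
                seg = donor[d.fill_seq_id][d.fill_start : d.fill_end]
                fill_nonn += d.fill_len - seg.upper().count("N")
            else:
                fill_nonn += d.fill_len
        elif d.status == "rejected":
            rejected_by[d.reason] = rejected_by.get(d.reason, 0) + 1
    return {
        "evaluated": len(report.decisions),
        "closed": closed,
        "rejected": sum(rejected_by.values()),
        "unevaluable": sum(1 for d in report.decisions if d.status == "unevaluable"),
        "rejected_by_reason": rejected_by,
        "closed_gap_n_bases": n_total,
        "fill_non_n_bases": fill_nonn,
    }


def close_gaps(
    target: Assembly,
    donor: Assembly,
    gaps: list[Gap] | None = None,
    thresholds: ClosureThresholds = ClosureThresholds(),
    flank_size: int = 10_000,
    min_gap_len: int = 10,
    aligner_params: dict | None = None,
    alignments: list[LocalAlignment] | None = None,
) -> tuple[Assembly, ClosureReport]:
    """End-to-end closure pipeline: find gaps, align flanks, decide, apply.

    ``alignments`` (e.g. from :func:`gapweld.flanks.read_coords`) bypasses
    the built-in aligner; records are routed to gaps by their gap_id and
    flank_role.
    """
    if gaps is None:
        gaps = find_gaps(target, min_len=min_gap_len)
    params = aligner_params or {}
    index = None
    if alignments is None:
        index = DonorIndex(donor, k=params.get("k", 15))
    by_flank: dict[tuple[str, str], list[LocalAlignment]] = {}
    if alignments is not None:
        for a in alignments:
            by_flank.setdefault((a.gap_id, a.flank_role), []).append(a)
    decisions: list[ClosureDecision] = []
    pairs: dict[str, FlankPair] = {}
    for gap in gaps:
        fp = extract_flanks(target, gap, flank_size, all_gaps=gaps)
        pairs[gap.gap_id] = fp
        if alignments is None:
            la = (
                align_flank(fp.left.sequence, index, gap_id=gap.gap_id, flank_role="L", **params)
                if fp.left.evaluable
                else []
            )
            ra = (
                align_flank(fp.right.sequence, index, gap_id=gap.gap_id, flank_role="R", **params)
                if fp.right.evaluable
                else []
            )
        else:
            la = by_flank.get((gap.gap_id, "L"), [])
            ra = by_flank.get((gap.gap_id, "R"), [])
        dec = evaluate_gap(fp, la, ra, thresholds, donor=donor, gap_interval=gap.interval)
        if dec.status == "closed":
            extract_fill(dec, donor, fp, thresholds)
        decisions.append(dec)
    closed_assembly, report = apply_closures(target, decisions, donor)
    return closed_assembly, report


def write_closure_report(report: ClosureReport, path) -> None:
    """TSV report: one row per evaluated gap (1-based inclusive coordinates)."""
    cols = [
        "gap_id", "status", "reason", "c1", "c2", "c3", "c4",
        "left_donor", "left_span", "right_donor", "right_span",
        "fill_seq", "fill_start", "fill_end", "fill_strand", "fill_len", "overlap_len",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for d in report.decisions:
            def span(a: LocalAlignment | None) -> tuple[str, str]:
                if a is None:
                    return ".", "."
                return a.donor_seq_id, f"{a.donor_start + 1}-{a.donor_end}({a.strand})"

            ld, ls = span(d.left)
            rd, rs = span(d.right)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        d.gap_id, d.status, d.reason or ".",
                        int(d.c1), int(d.c2), int(d.c3), int(d.c4),
                        ld, ls, rd, rs,
                        d.fill_seq_id or ".",
                        "." if d.fill_start is None else d.fill_start + 1,
                        "." if d.fill_end is None else d.fill_end,
                        d.fill_strand or ".", d.fill_len, d.overlap_len,
                    )
                )
                + "\n"
            )
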