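"""Assembly gap discovery: maximal N-runs and their summary statistics.

A gap is a maximal run of N/n bases inside an assembled sequence, marking
unresolved sequence between contigs.  Gaps can be discovered by scanning the
sequence or ingested from a BED3 file (e.g. the official gap annotation of a
public assembly); both paths yield the same Gap records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core import Assembly, GenomicInterval

__all__ = ["Gap", "GapReport", "find_gaps", "load_gaps_bed", "write_gaps_bed", "gap_summary"]

_N_RUN = re.compile(r"[Nn]+")


@dataclass(frozen=True)
class Gap:
    """An N-run interval on a target sequence.

    ``terminal`` flags gaps that touch a sequence end: their missing flank
    means closure criterion evaluation cannot succeed on that side.
    """

    interval: GenomicInterval
    terminal: bool = False

    @property
    def n_length(self) -> int:
        return len(self.interval)

    @property
    def gap_id(self) -> str:
        iv = self.interval
        return f"{iv.seq_id}:{iv.start}-{iv.end}"


@dataclass
class GapReport:
    per_sequence: dict[str, tuple[int, int]] = field(default_factory=dict)  # (count, N bp)

    @property
    def total_count(self) -> int:
        return sum(c for c, _ in self.per_sequence.values())

    @property
    def total_n(self) -> int:
        return sum(n for _, n in self.per_sequence.values())


def find_gaps(assembly: Assembly, min_len: int = 10) -> list[Gap]:
    """Discover all maximal N-runs of length >= ``min_len``.

    Detection is case-insensitive; output is sorted by (seq_id, start).
    Gaps abutting a sequence end are kept but flagged terminal.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    gaps: list[Gap] = []
    for sid in sorted(assembly.sequences):
        seq = assembly.sequences[sid]
        for m in _N_RUN.finditer(seq):
            if m.end() - m.start() >= min_len:
                gaps.append(
                    Gap(
                        GenomicInterval(sid, m.start(), m.end()),
                        terminal=(m.start() == 0 or m.end() == len(seq)),
                    )
                )
    return gaps


def load_gaps_bed(path, assembly: Assembly, verify: bool = True) -> list[Gap]:
    """Load gap intervals from BED3, validating them against the assembly.

    With ``verify`` (default) every interval must be all-N in the assembly;
    offenders are collected and reported together.
    """
    gaps: list[Gap] = []
    offenders: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            sid, start, end = f[0], int(f[1]), int(f[2])
            if sid not in assembly:
                raise ValueError(f"BED line {lineno}: unknown sequence {sid!r}")
            seq = assembly[sid]
            if not (0 <= start < end <= len(seq)):
                raise ValueError(f"BED line {lineno}: interval out of bounds")
            if verify and set(seq[start:end].upper()) != {"N"}:
                offenders.append(f"line {lineno}: {sid}:{start}-{end} not all-N")
                continue
            gaps.append(
                Gap(
                    GenomicInterval(sid, start, end),
                    terminal=(start == 0 or end == len(seq)),
                )
            )
    if offenders:
        raise ValueError("non-N gap intervals: " + "; ".join(offenders))
    return sorted(gaps, key=lambda g: (g.interval.seq_id, g.interval.start))


def write_gaps_bed(gaps: list[Gap], path) -> None:
    with open(path, "w") as fh:
        for g in gaps:
            iv = g.interval
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{g.gap_id}\n")


def gap_summary(gaps: list[Gap], assembly: Assembly | None = None) -> GapReport:
    """Per-sequence and assembly-wide gap counts and N totals."""
    report = GapReport()
    if assembly is not None:
        for sid in assembly.sequences:
            report.per_sequence[sid] = (0, 0)
    for g in gaps:
        sid = g.interval.seq_id
        c, n = report.per_sequence.get(sid, (0, 0))
        report.per_sequence[sid] = (c + 1, n + g.n_length)
    return report
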