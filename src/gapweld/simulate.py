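"""Seeded synthetic-genome generator with machine-readable truth.

Produces a donor assembly (random background plus soft-masked repeat
families), a degraded target derived from it (planted N-gaps whose true
fill is recorded, point mutations, optional flank inversions and donor
N-islands), long-insert mate-pair tables, and annotation fixtures (GFF3
genes, VCF variants, callable-length TSV) — everything the pipeline
stages consume, with the expected outcome of every stage recorded in a
TruthSet.

Truth statuses are computed analytically from the edit plan, never by
running the pipeline, so generator bugs and pipeline bugs cannot cancel.
The default configuration ("paper-scale-mini") is a 5 Mbp donor with 200
planted gaps and 10 kb flanks — the study conditions scaled to desk size.
All outputs are deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    Assembly,
    ContigPlacement,
    GenomicInterval,
    ScaffoldGap,
    ScaffoldLayout,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "PlannedGap",
    "TruthSet",
    "simulate_donor",
    "degrade_to_target",
    "simulate_mate_pairs",
    "emit_annotation_fixtures",
    "scaffold_layout_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic donor/target pair.

    Defaults are the "paper-scale-mini" conditions: a 5 Mbp donor in five
    1 Mbp sequences carrying two soft-masked repeat families, 200 planted
    gaps with 10 kb closure flanks, mate-pair fragments of 12.5 +/- 1.25 kb
    (the 10-15 kb long-insert library), and no point mutations unless
    requested.
    """

    seed: int = 42
    n_sequences: int = 5
    sequence_length: int = 1_000_000
    # repeat families: (copies per sequence, unit length)
    repeat_families: tuple[tuple[int, int], ...] = ((40, 300), (20, 600))
    n_gaps: int = 200
    gap_n_min: int = 100  # planted N-run length range
    gap_n_max: int = 2_000
    fill_min: int = 100  # deleted donor segment length range
    fill_max: int = 2_000
    flank_size: int = 10_000  # F used by the closure stage
    min_flank_spacing_buffer: int = 1_000  # extra bp beyond the 2F minimum
    mutation_rate: float = 0.0
    inversion_fraction: float = 0.10  # gaps with an inverted target right flank
    n_island_fraction: float = 0.10  # gaps with an N-island in the donor flank image
    n_island_len: int = 200
    # mate-pair plan (the 10-15 kb long-insert library)
    fragment_mean: float = 12_500.0
    fragment_sd: float = 1_250.0
    read_length: int = 151
    pair_depth: float = 5.0  # target physical depth
    pair_anomaly_fraction: float = 0.04  # planted cross-seq / out-of-bounds pairs
    # annotation plan
    genes_per_sequence: int = 30
    variants_per_sequence: int = 10

    def __post_init__(self) -> None:
        for r in (self.mutation_rate, self.inversion_fraction, self.n_island_fraction,
                  self.pair_anomaly_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.fragment_sd < 0 or self.fragment_mean <= 0:
            raise ValueError("fragment plan must be positive")
        if self.read_length >= self.fragment_mean:
            raise ValueError("read length must be below the fragment mean")


@dataclass
class PlannedGap:
    """One planted gap: donor segment deleted, N-run written, planned defect."""

    seq_id: str
    donor_start: int  # deleted donor segment [donor_start, donor_start + fill_len)
    fill_len: int
    n_len: int
    target_start: int = -1  # filled in after coordinate shifts are known
    kind: str = "clean"  # clean | inversion | n_island

    @property
    def gap_id(self) -> str:
        return f"{self.seq_id}:{self.target_start}-{self.target_start + self.n_len}"


@dataclass
class TruthSet:
    gaps: list[PlannedGap] = field(default_factory=list)
    expected_status: dict[str, str] = field(default_factory=dict)  # gap_id -> status
    failing_criterion: dict[str, str] = field(default_factory=dict)  # gap_id -> 'c3'...
    expected_fill: dict[str, str] = field(default_factory=dict)  # gap_id -> sequence
    pair_labels: list[tuple[str, str]] = field(default_factory=list)  # (label, reason)
    variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    gene_starts: list[tuple[str, int, str]] = field(default_factory=list)
    layout: ScaffoldLayout | None = None

    @property
    def gap_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(g.seq_id, g.target_start, g.target_start + g.n_len)
            for g in self.gaps
        ]

    def closable_ids(self) -> set[str]:
        return {gid for gid, st in self.expected_status.items() if st == "closed"}

    def to_json(self, path) -> None:
        doc = {
            "gaps": [asdict(g) for g in self.gaps],
            "expected_status": self.expected_status,
            "failing_criterion": self.failing_criterion,
            "expected_fill": self.expected_fill,
            "pair_labels": self.pair_labels,
            "variants": self.variants,
            "gene_starts": self.gene_starts,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _seq_ids(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_sequences)]


def simulate_donor(config: SimulationConfig) -> tuple[Assembly, list[GenomicInterval]]:
    """Random ACGT background with soft-masked repeat-family copies.

    Each repeat family is one random unit sequence; copies overwrite the
    background (lowercase) at non-overlapping positions.  Returns the
    assembly and the repeat annotation intervals.
    """
    rng = np.random.default_rng([config.seed, 0])
    sequences: dict[str, str] = {}
    repeat_bed: list[GenomicInterval] = []
    units = [
        rng.choice(_BASES, size=unit_len).tobytes().decode("ascii").lower()
        for _copies, unit_len in config.repeat_families
    ]
    total_repeat = sum(c * u for c, u in config.repeat_families)
    if total_repeat > config.sequence_length // 2:
        raise ValueError("repeat plan exceeds half the sequence length")
    for sid in _seq_ids(config):
        seq = rng.choice(_BASES, size=config.sequence_length).tobytes().decode("ascii")
        occupied: list[tuple[int, int]] = []
        chars = list(seq)
        for (copies, unit_len), unit in zip(config.repeat_families, units):
            placed = 0
            while placed < copies:
                pos = int(rng.integers(0, config.sequence_length - unit_len))
                if any(pos < e and s < pos + unit_len for s, e in occupied):
                    continue
                chars[pos : pos + unit_len] = unit
                occupied.append((pos, pos + unit_len))
                repeat_bed.append(GenomicInterval(sid, pos, pos + unit_len))
                placed += 1
        sequences[sid] = "".join(chars)
    repeat_bed.sort(key=lambda iv: (iv.seq_id, iv.start))
    return Assembly(sequences=sequences), repeat_bed


def _plan_gaps(config: SimulationConfig, rng: np.random.Generator) -> list[PlannedGap]:
    sids = _seq_ids(config)
    per_seq = [config.n_gaps // len(sids)] * len(sids)
    for i in range(config.n_gaps % len(sids)):
        per_seq[i] += 1
    F = config.flank_size
    min_spacing = 2 * F + config.fill_max + config.min_flank_spacing_buffer
    plans: list[PlannedGap] = []
    kinds = _plan_kinds(config, rng)
    ki = 0
    for sid, n in zip(sids, per_seq):
        if n == 0:
            continue
        stride = config.sequence_length // (n + 1)
        if stride < min_spacing:
            raise ValueError(
                f"cannot place {n} gaps with >= 2F flank spacing on a "
                f"{config.sequence_length} bp sequence (stride {stride} < {min_spacing})"
            )
        jitter_max = max(1, (stride - min_spacing) // 2 + 1)
        for g in range(n):
            pos = stride * (g + 1) + int(rng.integers(-jitter_max, jitter_max))
            fill_len = int(rng.integers(config.fill_min, config.fill_max + 1))
            n_len = int(rng.integers(config.gap_n_min, config.gap_n_max + 1))
            plans.append(PlannedGap(sid, pos, fill_len, n_len, kind=kinds[ki]))
            ki += 1
    return plans


def _plan_kinds(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_gaps
    n_inv = int(round(n * config.inversion_fraction))
    n_isl = int(round(n * config.n_island_fraction))
    kinds = ["inversion"] * n_inv + ["n_island"] * n_isl + ["clean"] * (n - n_inv - n_isl)
    rng.shuffle(kinds)
    return kinds


def _expected_status(config: SimulationConfig, gap: PlannedGap) -> tuple[str, str]:
    """Analytic truth from the edit plan (never from the pipeline)."""
    if gap.kind == "inversion":
        return "rejected", "c3"
    if gap.kind == "n_island":
        return "rejected", "c4"
    # 2-point margin around the 90% identity threshold: outside it the
    # sampling error of per-flank identity (~0.3 points at 10 kb) cannot
    # flip the outcome, so the analytic status is safe
    expected_identity = 100.0 * (1.0 - config.mutation_rate)
    if expected_identity >= 92.0:
        return "closed", ""
    if expected_identity <= 88.0:
        return "rejected", "c2"
    return "uncertain", "c2"


def degrade_to_target(
    donor: Assembly, config: SimulationConfig
) -> tuple[Assembly, TruthSet]:
    """Derive the degraded target and its truth from the donor.

    Per planned gap a donor segment is deleted and replaced by an N-run
    (the deleted segment is the expected fill), point mutations are
    applied outside N-runs, planned inversions reverse-complement the
    target right flank (expected c3 failures), and planned N-islands are
    written into the donor image of the left flank (expected c4 failures).

    Note: N-islands are planted into ``donor`` **in place** — they must
    exist in the donor the closure stage aligns against, while the target
    keeps the island-free copy.
    """
    rng = np.random.default_rng([config.seed, 1])
    plans = _plan_gaps(config, rng)
    truth = TruthSet(gaps=plans)
    target_seqs: dict[str, str] = {}
    F = config.flank_size
    for sid in donor.sequences:
        dseq = donor[sid]
        seq_plans = sorted(
            (p for p in plans if p.seq_id == sid), key=lambda p: p.donor_start
        )
        for a, b in zip(seq_plans, seq_plans[1:]):
            if a.donor_start + a.fill_len > b.donor_start:
                raise ValueError("overlapping planned edits")
        parts: list[str] = []
        prev = 0
        shift = 0
        for p in seq_plans:
            parts.append(dseq[prev : p.donor_start])
            parts.append("N" * p.n_len)
            p.target_start = p.donor_start + shift
            shift += p.n_len - p.fill_len
            prev = p.donor_start + p.fill_len
        parts.append(dseq[prev:])
        target_seqs[sid] = "".join(parts)
    # inversions: reverse-complement the target right flank
    for p in plans:
        if p.kind != "inversion":
            continue
        s = target_seqs[p.seq_id]
        t_end = p.target_start + p.n_len
        target_seqs[p.seq_id] = (
            s[:t_end] + revcomp(s[t_end : t_end + F]) + s[t_end + F :]
        )
    # point mutations outside N-runs, case-preserving
    if config.mutation_rate > 0:
        for sid, s in target_seqs.items():
            enc = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
            upper = np.where(enc >= ord("a"), enc - 32, enc)
            is_acgt = np.isin(upper, _BASES)
            hit = (rng.random(enc.shape[0]) < config.mutation_rate) & is_acgt
            idx = np.nonzero(hit)[0]
            # substitute a uniformly chosen different base (_BASES is sorted)
            cur = np.searchsorted(_BASES, upper[idx])
            offs = rng.integers(1, 4, size=idx.size)
            new_upper = _BASES[(cur + offs) % 4]
            was_lower = enc[idx] >= ord("a")
            enc[idx] = np.where(was_lower, new_upper + 32, new_upper)
            target_seqs[sid] = enc.tobytes().decode("ascii")
    # N-islands into the donor image of the left flank (donor modified in place)
    for p in plans:
        if p.kind != "n_island":
            continue
        centre = p.donor_start - F // 2
        lo = centre - config.n_island_len // 2
        dseq = donor.sequences[p.seq_id]
        donor.sequences[p.seq_id] = (
            dseq[:lo] + "N" * config.n_island_len + dseq[lo + config.n_island_len :]
        )
    # truth
    for p in plans:
        status, crit = _expected_status(config, p)
        truth.expected_status[p.gap_id] = status
        truth.failing_criterion[p.gap_id] = crit
        if status == "closed":
            truth.expected_fill[p.gap_id] = _expected_fill_of(donor, p)
    target = Assembly(sequences=target_seqs)
    truth.layout = scaffold_layout_truth(target, truth.gap_intervals)
    return target, truth


def _expected_fill_of(donor: Assembly, p: PlannedGap) -> str:
    return donor[p.seq_id][p.donor_start : p.donor_start + p.fill_len]


def scaffold_layout_truth(
    target: Assembly, gap_intervals: list[GenomicInterval]
) -> ScaffoldLayout:
    """Treat each target sequence as a scaffold whose gaps split it into
    contigs; the truth layout for the scaffolding benchmark."""
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in gap_intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    layout = ScaffoldLayout()
    for sid, seq in target.sequences.items():
        comps: list[ContigPlacement | ScaffoldGap] = []
        prev = 0
        ci = 0
        for iv in sorted(by_seq.get(sid, []), key=lambda v: v.start):
            if iv.start > prev:
                ci += 1
                cid = f"{sid}_ctg{ci}"
                comps.append(
                    ContigPlacement(
                        cid,
                        GenomicInterval(sid, prev, iv.start),
                        GenomicInterval(cid, 0, iv.start - prev),
                        "+",
                    )
                )
            comps.append(ScaffoldGap(iv, len(iv), "scaffold"))
            prev = iv.end
        if prev < len(seq):
            ci += 1
            cid = f"{sid}_ctg{ci}"
            comps.append(
                ContigPlacement(
                    cid,
                    GenomicInterval(sid, prev, len(seq)),
                    GenomicInterval(cid, 0, len(seq) - prev),
                    "+",
                )
            )
        layout.scaffolds[sid] = comps
    return layout


def simulate_mate_pairs(
    assembly: Assembly,
    config: SimulationConfig,
    pair_tsv_path=None,
    no_span_gaps: list[GenomicInterval] | None = None,
) -> tuple[list[tuple], TruthSet]:
    """Sample long-insert fragments and emit outer-span pair rows + truth.

    Fragments are placed uniformly along sequences with length ~
    Normal(fragment_mean, fragment_sd) truncated to [read_length, inf);
    a small planted fraction of anomalies (cross-sequence mates,
    too-short and too-long spans) exercises the loader's discard paths.
    ``no_span_gaps`` marks false-join gaps: fragments spanning them are
    rejected during sampling, so those gaps score near-zero physical
    coverage.  Rows: (seq, start1, end1, strand1, start2, end2, strand2
    [, seq2]).  Truth labels (keep/discard + reason) assume the loader's
    default 5-25 kb bounds without orientation filtering.
    """
    rng = np.random.default_rng([config.seed, 2])
    sids = list(assembly.sequences)
    lengths = np.array([len(assembly[s]) for s in sids], dtype=float)
    total = lengths.sum()
    n_frags = int(round(config.pair_depth * total / config.fragment_mean))
    probs = lengths / total
    rows: list[tuple] = []
    truth = TruthSet()
    rl = config.read_length
    no_span = no_span_gaps or []
    made = 0
    while made < n_frags:
        si = int(rng.choice(len(sids), p=probs))
        sid, L = sids[si], int(lengths[si])
        frag = max(rl, int(round(rng.normal(config.fragment_mean, config.fragment_sd))))
        anomaly = rng.random() < config.pair_anomaly_fraction
        kind = int(rng.integers(0, 3)) if anomaly else -1
        if kind == 1:  # too short
            frag = int(rng.integers(rl + 1, 4_000))
        elif kind == 2:  # too long
            frag = int(rng.integers(26_000, 40_000))
        if frag >= L:
            continue
        start = int(rng.integers(0, L - frag))
        if any(
            iv.seq_id == sid and start <= iv.start and start + frag >= iv.end
            for iv in no_span
        ):
            continue  # fragment would span a planted false join: resample
        s1, e1 = start, start + rl
        s2, e2 = start + frag - rl, start + frag
        if kind == 0:  # cross-sequence mate
            other = sids[(si + 1) % len(sids)]
            rows.append((sid, s1, e1, "+", s2, e2, "-", other))
            truth.pair_labels.append(("discard", "cross-sequence"))
        else:
            rows.append((sid, s1, e1, "+", s2, e2, "-"))
            if frag < 5_000:
                truth.pair_labels.append(("discard", "span-too-short"))
            elif frag > 25_000:
                truth.pair_labels.append(("discard", "span-too-long"))
            else:
                truth.pair_labels.append(("keep", ""))
        made += 1
    if pair_tsv_path is not None:
        with open(pair_tsv_path, "w") as fh:
            fh.write("seq\tstart1\tend1\tstrand1\tstart2\tend2\tstrand2\tseq2\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
    return rows, truth


def emit_annotation_fixtures(
    assembly: Assembly,
    config: SimulationConfig,
    gff3_path,
    vcf_path,
    callable_path,
) -> TruthSet:
    """Planted genes (GFF3), variants (VCF) and callable lengths (TSV).

    Callable bases = non-N length per sequence.  Variants are SNPs
    (1 affected reference base) and short deletions (len(REF) affected);
    planted totals are recorded in the returned TruthSet.
    """
    rng = np.random.default_rng([config.seed, 3])
    truth = TruthSet()
    comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        gi = 0
        for sid, seq in assembly.sequences.items():
            for _ in range(config.genes_per_sequence):
                start = int(rng.integers(0, max(1, len(seq) - 5_000)))
                gtype = "protein_coding" if rng.random() < 0.6 else "non_coding"
                gi += 1
                gff.write(
                    f"{sid}\tsim\tgene\t{start + 1}\t{start + 1_000}\t.\t+\t.\t"
                    f"ID=gene{gi};biotype={gtype}\n"
                )
                truth.gene_starts.append((sid, start, gtype))
    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        for sid, seq in assembly.sequences.items():
            vcf.write(f"##contig=<ID={sid},length={len(seq)}>\n")
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for sid, seq in assembly.sequences.items():
            taken: set[int] = set()
            n_planted = 0
            while n_planted < config.variants_per_sequence:
                pos = int(rng.integers(0, len(seq) - 6))
                ref_len = 1 if rng.random() < 0.7 else int(rng.integers(2, 6))
                ref = seq[pos : pos + ref_len].upper()
                if "N" in ref or pos in taken:
                    continue
                taken.add(pos)
                alt = comp[ref[0]] if ref_len == 1 else ref[0]
                vcf.write(f"{sid}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
                truth.variants.append((sid, pos, ref, alt))
                n_planted += 1
    with open(callable_path, "w") as cal:
        cal.write("seq_id\tcallable_bases\n")
        for sid, seq in assembly.sequences.items():
            cal.write(f"{sid}\t{len(seq) - seq.upper().count('N')}\n")
    return truth
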