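"""Assembly QC metrics: QV scores, repeat-ratio windows, group comparisons,
and gene-density binning.

QV follows the standard convention QV = -10*log10(error rate), with the
error rate estimated as error bases / callable bases.  Zero-error
sequences are reported at a configurable cap (default 60) instead of
infinity; raw counts are always carried alongside so users can re-derive
under other conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Assembly, GenomicInterval

__all__ = [
    "QVRecord",
    "WindowStat",
    "MannWhitneyResult",
    "compute_qv",
    "qv_per_sequence",
    "window_repeat_ratios",
    "mannwhitney",
    "compare_window_groups",
    "compare_mapping_rates",
    "gene_density_bins",
]

QV_CAP_DEFAULT = 60.0


@dataclass(frozen=True)
class QVRecord:
    seq_id: str
    error_bases: int
    callable_bases: int
    qv: float


def compute_qv(error_bases: int, callable_bases: int, cap: float = QV_CAP_DEFAULT) -> float:
    """QV = min(cap, -10*log10(error_bases / callable_bases)).

    Zero error bases return the cap (the convention's -infinity avoidance).
    """
    if callable_bases <= 0:
        raise ValueError("callable_bases must be > 0")
    if not 0 <= error_bases <= callable_bases:
        raise ValueError("need 0 <= error_bases <= callable_bases")
    if error_bases == 0:
        return cap
    return min(cap, -10.0 * math.log10(error_bases / callable_bases))


def _variants_from_vcf(path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append((rec.chrom, len(rec.ref)))
    return pd.DataFrame(rows, columns=["seq_id", "affected_bases"])


def qv_per_sequence(
    variant_table: pd.DataFrame | str,
    callable_table: pd.DataFrame | str,
    cap: float = QV_CAP_DEFAULT,
) -> list[QVRecord]:
    """One QVRecord per sequence in the callable table.

    ``variant_table``: DataFrame (seq_id, affected_bases) or a path to a
    TSV with those columns or to a VCF (affected bases = reference-allele
    length: SNP=1, deletion=len(REF), insertion=1 anchor base).
    ``callable_table``: DataFrame (seq_id, callable_bases) or TSV path.
    Sequences with no variants score the cap.
    """
    if isinstance(variant_table, (str,)) or hasattr(variant_table, "__fspath__"):
        p = str(variant_table)
        if p.endswith((".vcf", ".vcf.gz")):
            variant_table = _variants_from_vcf(p)
        else:
            variant_table = pd.read_csv(p, sep="\t")
    if isinstance(callable_table, (str,)) or hasattr(callable_table, "__fspath__"):
        callable_table = pd.read_csv(str(callable_table), sep="\t")
    err = variant_table.groupby("seq_id")["affected_bases"].sum()
    known = set(callable_table["seq_id"])
    unknown = set(err.index) - known
    if unknown:
        raise ValueError(f"variants on sequences absent from callable table: {sorted(unknown)}")
    out = []
    for _, row in callable_table.iterrows():
        e = int(err.get(row["seq_id"], 0))
        c = int(row["callable_bases"])
        out.append(QVRecord(row["seq_id"], e, c, compute_qv(e, c, cap)))
    return out


# ---------------------------------------------------------------------------
# Repeat-ratio windows


@dataclass(frozen=True)
class WindowStat:
    interval: GenomicInterval
    repeat_bases: int
    non_n_bases: int
    group: str = "other"  # 'closed-gap' | 'other'

    @property
    def ratio(self) -> float:
        return self.repeat_bases / self.non_n_bases


def window_repeat_ratios(
    assembly: Assembly,
    window: int = 50_000,
    repeat_bed: list[GenomicInterval] | None = None,
) -> list[WindowStat]:
    """Tile each sequence into non-overlapping windows and compute the
    repeat ratio (repeat bases / non-N bases) per window.

    Repeat bases come from soft-masking (lowercase) by default, or from a
    repeat-annotation interval list.  Terminal partial windows shorter
    than window/2 are dropped, as are windows with no non-N bases.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rep_by_seq: dict[str, np.ndarray] | None = None
    if repeat_bed is not None:
        rep_by_seq = {}
        for iv in repeat_bed:
            arr = rep_by_seq.setdefault(
                iv.seq_id, np.zeros(len(assembly[iv.seq_id]), dtype=bool)
            )
            arr[iv.start : iv.end] = True
    out: list[WindowStat] = []
    for sid, seq in assembly.sequences.items():
        enc = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_n = (enc == ord("N")) | (enc == ord("n"))
        if rep_by_seq is not None:
            is_rep = rep_by_seq.get(sid, np.zeros(len(seq), dtype=bool)) & ~is_n
        else:
            is_rep = (enc >= ord("a")) & (enc <= ord("z")) & ~is_n
        for start in range(0, len(seq), window):
            end = min(start + window, len(seq))
            if end - start < window and end - start < window / 2:
                continue
            non_n = int((~is_n[start:end]).sum())
            if non_n == 0:
                continue
            out.append(
                WindowStat(
                    GenomicInterval(sid, start, end),
                    int(is_rep[start:end].sum()),
                    non_n,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # 'exact' | 'asymptotic'
    median_x: float
    median_y: float
    n_x: int
    n_y: int

    @property
    def direction(self) -> str:
        if self.median_x > self.median_y:
            return "x>y"
        if self.median_x < self.median_y:
            return "x<y"
        return "x=y"


def _u_statistic(ranks_x: np.ndarray, n_x: int, n_y: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2)


def mannwhitney(x, y, exact_max: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over all C(n+m, n) group labelings (midranks for
    ties) when both groups have <= ``exact_max`` observations; otherwise
    the tie-corrected, continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.shape[0], y.shape[0]
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    if n <= exact_max and m <= exact_max:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # midranks
        u_obs = _u_statistic(ranks[:n], n, m)
        mu = n * m / 2.0
        dev = abs(u_obs - mu)
        count = total = 0
        for combo in combinations(range(n + m), n):
            u = _u_statistic(ranks[list(combo)], n, m)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return MannWhitneyResult(
            u_obs, count / total, "exact",
            float(np.median(x)), float(np.median(y)), n, m,
        )
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(
        float(u), float(p), "asymptotic",
        float(np.median(x)), float(np.median(y)), n, m,
    )


def assign_window_groups(
    windows: list[WindowStat], closed_gap_intervals: list[GenomicInterval]
) -> list[WindowStat]:
    """Label each window 'closed-gap' if it overlaps any closed-gap interval
    by >= 1 bp, else 'other'."""
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in closed_gap_intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    out = []
    for w in windows:
        hits = by_seq.get(w.interval.seq_id, [])
        group = "closed-gap" if any(w.interval.overlaps(iv) for iv in hits) else "other"
        out.append(WindowStat(w.interval, w.repeat_bases, w.non_n_bases, group))
    return out


def compare_window_groups(
    windows: list[WindowStat],
    closed_gap_intervals: list[GenomicInterval],
    exact_max: int = 8,
) -> MannWhitneyResult:
    """Mann-Whitney U comparison of repeat ratios: closed-gap vs other windows."""
    labeled = assign_window_groups(windows, closed_gap_intervals)
    gx = [w.ratio for w in labeled if w.group == "closed-gap"]
    gy = [w.ratio for w in labeled if w.group == "other"]
    if not gx or not gy:
        raise ValueError("both window groups must be non-empty")
    return mannwhitney(gx, gy, exact_max=exact_max)


def compare_mapping_rates(
    table: pd.DataFrame | str, exact_max: int = 8
) -> dict[str, MannWhitneyResult]:
    """Per-metric Mann-Whitney U across samples between two assemblies.

    ``table``: rows (sample_id, assembly_id, all_read_rate,
    properly_mapped_rate), percentages, exactly two assembly ids with
    >= 2 samples each.  Returns one result per rate column; the result's
    ``direction`` reports which assembly has the higher median (x is the
    lexicographically first assembly id).
    """
    if isinstance(table, str) or hasattr(table, "__fspath__"):
        table = pd.read_csv(str(table), sep="\t")
    asms = sorted(table["assembly_id"].unique())
    if len(asms) != 2:
        raise ValueError(f"expected exactly two assemblies, got {asms}")
    out = {}
    for metric in ("all_read_rate", "properly_mapped_rate"):
        gx = table.loc[table["assembly_id"] == asms[0], metric].to_numpy()
        gy = table.loc[table["assembly_id"] == asms[1], metric].to_numpy()
        if len(gx) < 2 or len(gy) < 2:
            raise ValueError("need >= 2 samples per assembly")
        out[metric] = mannwhitney(gx, gy, exact_max=exact_max)
    return out


# ---------------------------------------------------------------------------
# Gene density


def gene_density_bins(
    gff3_path,
    assembly: Assembly | None = None,
    bin_size: int = 1_000_000,
    type_attribute: str = "biotype",
    feature_type: str = "gene",
) -> pd.DataFrame:
    """Count genes per (sequence, bin, gene type) with fixed-size bins.

    A gene is assigned to the bin containing its start coordinate.  Gene
    type (e.g. protein_coding / non_coding) is read from the configured
    GFF3 attribute key (fallback "unknown").  Features starting beyond the
    sequence end are clamped into the last bin with a warning.
    """
    import warnings as _warnings

    rows = []
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            seq_id, start = f[0], int(f[3]) - 1  # GFF3 is 1-based inclusive
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gtype = attrs.get(type_attribute, "unknown")
            if assembly is not None and seq_id in assembly:
                seq_len = len(assembly[seq_id])
                if start >= seq_len:
                    _warnings.warn(
                        f"gene at {seq_id}:{start + 1} beyond sequence end; clamped",
                        stacklevel=2,
                    )
                    start = seq_len - 1
            rows.append((seq_id, start // bin_size, gtype))
    df = pd.DataFrame(rows, columns=["seq_id", "bin", "gene_type"])
    if df.empty:
        return pd.DataFrame(columns=["seq_id", "bin", "gene_type", "count"])
    return (
        df.groupby(["seq_id", "bin", "gene_type"])
        .size()
        .reset_index(name="count")
        .sort_values(["seq_id", "bin", "gene_type"], ignore_index=True)
    )
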