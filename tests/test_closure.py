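import pytest

from gapweld.closure import (
    ClosureDecision,
    ClosureThresholds,
    apply_closures,
    close_gaps,
    closure_totals,
    evaluate_gap,
    extract_fill,
    new_coordinates,
)
from gapweld.core import Assembly, GenomicInterval, revcomp
from gapweld.flanks import DonorIndex, Flank, FlankPair, LocalAlignment, align_flank, extract_flanks
from gapweld.gaps import find_gaps
from gapweld.simulate import SimulationConfig, degrade_to_target, simulate_donor


def _pair(gap_id="a:100-200", flank_len=10_000):
    return FlankPair(
        gap_id,
        Flank("L", GenomicInterval("a", 0, flank_len), "A" * flank_len),
        Flank("R", GenomicInterval("a", 200, 200 + flank_len), "A" * flank_len),
        flank_len,
    )


def _aln(role, length=8_000, ident=99.0, donor="d", start=None, strand="+"):
    if start is None:
        start = 0 if role == "L" else 20_000
    return LocalAlignment("a:100-200", role, 0, length, donor, start, start + length,
                          strand, ident)


DONOR_NO_N = Assembly({"d": "A" * 50_000})


class TestCriteria:
    def test_all_pass(self):
        dec = evaluate_gap(_pair(), [_aln("L")], [_aln("R")], donor=DONOR_NO_N)
        assert (dec.c1, dec.c2, dec.c3, dec.c4) == (True, True, True, True)
        assert dec.status == "closed"

    def test_alignment_length_boundary_is_strict(self):
        """Exactly 5,000 bp fails the larger-than-5-kb rule."""
        dec = evaluate_gap(
            _pair(), [_aln("L", length=5_000)], [_aln("R", length=5_000)],
            donor=DONOR_NO_N,
        )
        assert not dec.c1 and dec.status == "rejected"
        dec = evaluate_gap(
            _pair(), [_aln("L", length=5_001)], [_aln("R", length=5_001)],
            donor=DONOR_NO_N,
        )
        assert dec.c1

    @pytest.mark.parametrize(
        "ident_l,ident_r,expect",
        [(92.0, 87.0, False),   # mean 89.5
         (92.0, 88.0, False),   # mean 90.0 exactly: strict >
         (92.0, 89.0, True)],   # mean 90.5
    )
    def test_mean_identity_boundary_is_strict(self, ident_l, ident_r, expect):
        dec = evaluate_gap(
            _pair(), [_aln("L", ident=ident_l)], [_aln("R", ident=ident_r)],
            donor=DONOR_NO_N,
        )
        assert dec.c2 is expect

    def test_order_and_orientation(self):
        # same strand but right placement before left: order violated
        dec = evaluate_gap(
            _pair(), [_aln("L", start=20_000)], [_aln("R", start=0)],
            donor=DONOR_NO_N,
        )
        assert not dec.c3
        # opposite strands
        dec = evaluate_gap(
            _pair(), [_aln("L")], [_aln("R", strand="-")], donor=DONOR_NO_N
        )
        assert not dec.c3
        # minus strand with reversed donor order is consistent
        dec = evaluate_gap(
            _pair(),
            [_aln("L", start=20_000, strand="-")],
            [_aln("R", start=0, strand="-")],
            donor=DONOR_NO_N,
        )
        assert dec.c3

    def test_donor_n_fails_c4(self):
        donor = Assembly({"d": "A" * 4_000 + "N" * 10 + "A" * 46_000})
        dec = evaluate_gap(_pair(), [_aln("L")], [_aln("R")], donor=donor)
        assert not dec.c4 and dec.status == "rejected"

    def test_unevaluable_flank(self):
        fp = FlankPair("a:0-5", Flank("L", None, ""), _pair().right, 10_000)
        dec = evaluate_gap(fp, [], [_aln("R")], donor=DONOR_NO_N)
        assert dec.status == "unevaluable"

    def test_no_alignment(self):
        dec = evaluate_gap(_pair(), [], [_aln("R")], donor=DONOR_NO_N)
        assert dec.status == "unevaluable" and dec.reason == "no-alignment"


class TestExtractFill:
    def _evaluated(self, target, donor, thresholds):
        (gap,) = find_gaps(target, min_len=1)
        fp = extract_flanks(target, gap, flank_size=4)
        la = LocalAlignment(gap.gap_id, "L", 0, 4, "d", 0, 4, "+", 100.0)
        ra = LocalAlignment(gap.gap_id, "R", 0, 4, "d",
                            len(donor["d"]) - 4, len(donor["d"]), "+", 100.0)
        dec = evaluate_gap(fp, [la], [ra], thresholds, donor=donor,
                           gap_interval=gap.interval)
        return dec, fp

    def test_simple_fill(self):
        thr = ClosureThresholds(min_aln_len=0, min_mean_identity=50.0)
        donor = Assembly({"d": "AAAACCCTTTT"})
        target = Assembly({"a": "AAAANNTTTT"})
        dec, fp = self._evaluated(target, donor, thr)
        assert dec.status == "closed"
        assert extract_fill(dec, donor, fp, thr) == "CCC"

    def test_zero_length_fill_is_closed(self):
        thr = ClosureThresholds(min_aln_len=0, min_mean_identity=50.0)
        donor = Assembly({"d": "AAAATTTT"})
        target = Assembly({"a": "AAAANNTTTT"})
        dec, fp = self._evaluated(target, donor, thr)
        assert extract_fill(dec, donor, fp, thr) == ""
        assert dec.status == "closed" and dec.overlap_len == 0

    def test_overlap_beyond_tolerance_rejected(self):
        """Unaligned flank tails projecting past each other reject closure."""
        thr = ClosureThresholds(min_aln_len=0, min_mean_identity=50.0)
        donor = Assembly({"d": "AAAATTTT"})
        target = Assembly({"a": "AAAAGGNNCCTTTT"})
        (gap,) = find_gaps(target, min_len=1)
        fp = extract_flanks(target, gap, flank_size=6)
        # aligned parts are ordered (c3 holds) but the 2 bp tails overlap
        la = LocalAlignment(gap.gap_id, "L", 0, 4, "d", 0, 4, "+", 100.0)
        ra = LocalAlignment(gap.gap_id, "R", 2, 6, "d", 4, 8, "+", 100.0)
        dec = evaluate_gap(fp, [la], [ra], thr, donor=donor, gap_interval=gap.interval)
        assert dec.status == "closed"
        extract_fill(dec, donor, fp, thr)
        assert dec.status == "rejected" and dec.reason == "overlap-too-large"
        assert dec.overlap_len == 4

    def test_unaligned_tail_extends_projection(self):
        """Tail bases of the flank shift the fill boundary so target sequence
        is never double-represented."""
        thr = ClosureThresholds(min_aln_len=0, min_mean_identity=50.0)
        donor = Assembly({"d": "AAAAGGCCCTTTT"})
        target = Assembly({"a": "AAAAGGNNTTTT"})
        (gap,) = find_gaps(target, min_len=1)
        fp = extract_flanks(target, gap, flank_size=6)
        # left alignment covers only the first 4 of 6 flank bases
        la = LocalAlignment(gap.gap_id, "L", 0, 4, "d", 0, 4, "+", 100.0)
        ra = LocalAlignment(gap.gap_id, "R", 0, 4, "d", 9, 13, "+", 100.0)
        dec = evaluate_gap(fp, [la], [ra], thr, donor=donor, gap_interval=gap.interval)
        assert extract_fill(dec, donor, fp, thr) == "CCC"


class TestApplyClosures:
    def _decision(self, gap_iv, fill_start, fill_end, strand="+"):
        d = ClosureDecision("g", gap_iv, None, None, True, True, True, True, "closed")
        d.fill_seq_id, d.fill_start, d.fill_end = "d", fill_start, fill_end
        d.fill_strand, d.fill_len = strand, fill_end - fill_start
        return d

    def test_substitution(self):
        asm = Assembly({"a": "AAAANNTTTT"})
        donor = Assembly({"d": "AAAACCCTTTT"})
        dec = self._decision(GenomicInterval("a", 4, 6), 4, 7)
        out, _ = apply_closures(asm, [dec], donor)
        assert out["a"] == "AAAACCCTTTT"

    def test_no_closures_identity(self):
        asm = Assembly({"a": "AAAANNTTTT"})
        dec = self._decision(GenomicInterval("a", 4, 6), 4, 7)
        dec.status = "rejected"
        out, _ = apply_closures(asm, [dec], Assembly({"d": "AAAACCCTTTT"}))
        assert out.sequences == asm.sequences

    def test_overlapping_gaps_rejected_before_edit(self):
        asm = Assembly({"a": "AANNNNAA"})
        d1 = self._decision(GenomicInterval("a", 2, 5), 0, 1)
        d2 = self._decision(GenomicInterval("a", 4, 6), 0, 1)
        with pytest.raises(ValueError, match="overlapping"):
            apply_closures(asm, [d1, d2], Assembly({"d": "ACGT"}))

    def test_minus_strand_fill_reverse_complemented(self):
        asm = Assembly({"a": "AAAANNTTTT"})
        donor = Assembly({"d": "GGTAC"})  # revcomp(GTACC[0:3]=GGT) etc.
        dec = self._decision(GenomicInterval("a", 4, 6), 0, 3, strand="-")
        out, _ = apply_closures(asm, [dec], donor)
        assert out["a"] == "AAAA" + revcomp("GGT") + "TTTT"


@pytest.fixture(scope="module")
def planted_fixture():
    """20 planted gaps with deliberate c3 (inversion) and c4 (donor
    N-island) violations, mutation-free."""
    cfg = SimulationConfig(
        seed=11, n_sequences=2, sequence_length=300_000, n_gaps=20,
        inversion_fraction=0.2, n_island_fraction=0.2,
    )
    donor, _ = simulate_donor(cfg)
    target, truth = degrade_to_target(donor, cfg)
    closed_asm, report = close_gaps(target, donor)
    return cfg, donor, target, truth, closed_asm, report


def naive_four_rules(fp, left_alns, right_alns, donor, thr):
    """Independent re-statement of the closure rules for cross-checking."""

    def pick(alns):
        best = None
        for a in alns:
            if best is None:
                best = a
                continue
            if (a.align_len_query, a.pct_identity) > (best.align_len_query, best.pct_identity):
                best = a
            elif (a.align_len_query, a.pct_identity) == (
                best.align_len_query, best.pct_identity
            ) and (a.donor_seq_id, a.donor_start) < (best.donor_seq_id, best.donor_start):
                best = a
        return best

    if not (fp.left.evaluable and fp.right.evaluable):
        return "unevaluable", (False,) * 4
    la, ra = pick(left_alns), pick(right_alns)
    if la is None or ra is None:
        return "unevaluable", (False,) * 4
    c1 = min(la.align_len_query, ra.align_len_query) > thr.min_aln_len
    c2 = (la.pct_identity + ra.pct_identity) / 2 > thr.min_mean_identity
    if la.donor_seq_id != ra.donor_seq_id or la.strand != ra.strand:
        c3 = False
    elif la.strand == "+":
        c3 = la.donor_end <= ra.donor_start
    else:
        c3 = ra.donor_end <= la.donor_start
    n_free = all(
        "N" not in donor[a.donor_seq_id][a.donor_start : a.donor_end].upper()
        for a in (la, ra)
    )
    c4 = n_free
    status = "closed" if (c1 and c2 and c3 and c4) else "rejected"
    return status, (c1, c2, c3, c4)


class TestPlantedViolations:
    def test_zero_disagreements_with_naive_oracle(self, planted_fixture):
        cfg, donor, target, truth, _closed, report = planted_fixture
        index = DonorIndex(donor)
        gaps = find_gaps(target)
        thr = ClosureThresholds()
        by_id = {d.gap_id: d for d in report.decisions}
        for gap in gaps:
            fp = extract_flanks(target, gap, cfg.flank_size, all_gaps=gaps)
            la = align_flank(fp.left.sequence, index, gap_id=gap.gap_id, flank_role="L")
            ra = align_flank(fp.right.sequence, index, gap_id=gap.gap_id, flank_role="R")
            status, flags = naive_four_rules(fp, la, ra, donor, thr)
            dec = by_id[gap.gap_id]
            assert (dec.c1, dec.c2, dec.c3, dec.c4) == flags, gap.gap_id
            # the pipeline may further downgrade closed->rejected on fill
            # geometry, which the four-rule oracle does not model
            if status == "closed" and dec.status == "rejected":
                assert dec.reason in ("overlap-too-large", "fill-out-of-bounds")
            else:
                assert dec.status == status, gap.gap_id

    def test_statuses_match_planted_truth(self, planted_fixture):
        _cfg, _donor, _target, truth, _closed, report = planted_fixture
        for dec in report.decisions:
            assert dec.status == truth.expected_status[dec.gap_id]
            crit = truth.failing_criterion[dec.gap_id]
            if crit:
                assert not getattr(dec, crit.replace("c", "c")), dec.gap_id
                assert dec.reason == f"criteria:{crit[1]}"

    def test_inversions_always_fail_c3(self, planted_fixture):
        _cfg, _donor, _target, truth, _closed, report = planted_fixture
        inv_ids = {g.gap_id for g in truth.gaps if g.kind == "inversion"}
        assert inv_ids  # fixture plants some
        for dec in report.decisions:
            if dec.gap_id in inv_ids:
                assert not dec.c3

    def test_fills_byte_exact(self, planted_fixture):
        _cfg, donor, _target, truth, _closed, report = planted_fixture
        closed = [d for d in report.decisions if d.status == "closed"]
        assert {d.gap_id for d in closed} == truth.closable_ids()
        for d in closed:
            fill = donor[d.fill_seq_id][d.fill_start : d.fill_end]
            if d.fill_strand == "-":
                fill = revcomp(fill)
            assert fill == truth.expected_fill[d.gap_id]

    def test_length_bookkeeping(self, planted_fixture):
        _cfg, _donor, target, _truth, closed_asm, report = planted_fixture
        by_seq_delta = {}
        for d in report.decisions:
            if d.status == "closed":
                sid = d.gap_interval.seq_id
                by_seq_delta[sid] = by_seq_delta.get(sid, 0) + d.fill_len - len(d.gap_interval)
        for sid in target.sequences:
            assert len(closed_asm[sid]) == len(target[sid]) + by_seq_delta.get(sid, 0)

    def test_flank_conservation(self, planted_fixture):
        """The 2F bases around every closed gap are unchanged in the output."""
        cfg, _donor, target, _truth, closed_asm, report = planted_fixture
        newc = new_coordinates(report)
        F = cfg.flank_size
        for d in report.decisions:
            if d.status != "closed":
                continue
            iv = d.gap_interval
            ns, ne = newc[d.gap_id]
            assert closed_asm[iv.seq_id][max(0, ns - F) : ns] == \
                target[iv.seq_id][max(0, iv.start - (ns - max(0, ns - F))) : iv.start]
            flank_r = target[iv.seq_id][iv.end : iv.end + F]
            assert closed_asm[iv.seq_id][ne : ne + len(flank_r)] == flank_r

    def test_idempotence(self, planted_fixture):
        """Re-running closure on the closed assembly closes nothing more."""
        _cfg, donor, _target, _truth, closed_asm, _report = planted_fixture
        _out, report2 = close_gaps(closed_asm, donor)
        assert all(d.status != "closed" for d in report2.decisions)


class TestThresholdMonotonicity:
    def test_closed_count_non_increasing(self, mini_sim, mini_flank_alignments):
        from conftest import decide_all

        _cfg, donor, _target, _truth, _ = mini_sim
        grid_aln = [1_000, 2_000, 5_000, 8_000]
        grid_id = [80.0, 90.0, 95.0]
        counts = {}
        for a in grid_aln:
            for i in grid_id:
                decs = decide_all(
                    mini_flank_alignments, donor, ClosureThresholds(a, i)
                )
                counts[(a, i)] = sum(1 for d in decs if d.status == "closed")
        for i in grid_id:
            seq = [counts[(a, i)] for a in grid_aln]
            assert seq == sorted(seq, reverse=True)
        for a in grid_aln:
            seq = [counts[(a, i)] for i in grid_id]
            assert seq == sorted(seq, reverse=True)


class TestTotals:
    def test_simple_totals(self):
        d1 = ClosureDecision("g1", GenomicInterval("a", 10, 15), None, None,
                             True, True, True, True, "closed")
        d1.fill_len = 7
        d1.fill_seq_id, d1.fill_start, d1.fill_end, d1.fill_strand = "d", 0, 7, "+"
        d2 = ClosureDecision("g2", GenomicInterval("a", 100, 103), None, None,
                             True, True, True, True, "closed")
        d2.fill_len = 0
        from gapweld.closure import ClosureReport

        tot = closure_totals(ClosureReport([d1, d2]))
        assert tot["closed"] == 2
        assert tot["closed_gap_n_bases"] == 8
        assert tot["fill_non_n_bases"] == 7

    def test_empty(self):
        from gapweld.closure import ClosureReport

        tot = closure_totals(ClosureReport([]))
        assert tot["evaluated"] == tot["closed"] == tot["fill_non_n_bases"] == 0
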