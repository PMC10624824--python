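import numpy as np
import pytest

from gapweld.closure import (
    ClosureThresholds,
    apply_closures,
    evaluate_gap,
    extract_fill,
)
from gapweld.core import Assembly
from gapweld.flanks import DonorIndex, align_flank, extract_flanks
from gapweld.gaps import find_gaps
from gapweld.simulate import SimulationConfig, degrade_to_target, simulate_donor


@pytest.fixture
def toy_assembly():
    return Assembly({"a": "ACGTNNNNNACGT", "b": "NNN"})


@pytest.fixture(scope="session")
def mini_sim():
    """The paper-scale-mini study conditions: 5 Mbp donor, 200 planted gaps."""
    cfg = SimulationConfig(seed=42)
    donor, repeat_bed = simulate_donor(cfg)
    target, truth = degrade_to_target(donor, cfg)
    return cfg, donor, target, truth, repeat_bed


@pytest.fixture(scope="session")
def mini_flank_alignments(mini_sim):
    """Flank alignments for every mini-fixture gap, computed once so the
    threshold criteria can be re-evaluated cheaply."""
    cfg, donor, target, _truth, _ = mini_sim
    index = DonorIndex(donor)
    gaps = find_gaps(target)
    out = {}
    for gap in gaps:
        fp = extract_flanks(target, gap, cfg.flank_size, all_gaps=gaps)
        la = (
            align_flank(fp.left.sequence, index, gap_id=gap.gap_id, flank_role="L")
            if fp.left.evaluable
            else []
        )
        ra = (
            align_flank(fp.right.sequence, index, gap_id=gap.gap_id, flank_role="R")
            if fp.right.evaluable
            else []
        )
        out[gap.gap_id] = (gap, fp, la, ra)
    return out


def decide_all(flank_alignments, donor, thresholds=ClosureThresholds()):
    """Evaluate every gap under the given thresholds and derive fills."""
    decisions = []
    for gap, fp, la, ra in flank_alignments.values():
        dec = evaluate_gap(fp, la, ra, thresholds, donor=donor, gap_interval=gap.interval)
        if dec.status == "closed":
            extract_fill(dec, donor, fp, thresholds)
        decisions.append(dec)
    return decisions


@pytest.fixture(scope="session")
def mini_closure(mini_sim, mini_flank_alignments):
    _cfg, donor, target, _truth, _ = mini_sim
    decisions = decide_all(mini_flank_alignments, donor)
    closed_asm, report = apply_closures(target, decisions, donor)
    return closed_asm, report


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
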