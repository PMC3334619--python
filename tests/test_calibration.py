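import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from deepamp import simulate
from deepamp.calibration import (
    CalibrationError,
    coverage_floor,
    detect_systematic_noise,
    evaluate_performance,
    matthews_correlation,
    select_threshold,
)
from deepamp.truth import TruthSet

from conftest import make_column, make_table


# ---------------------------------------------------------------------------
# MCC
# ---------------------------------------------------------------------------

def test_mcc_values_and_conventions():
    assert matthews_correlation(10, 0, 1000, 0) == 1.0
    assert matthews_correlation(0, 0, 1000, 10) == 0.0  # zero-factor convention
    tp, fp, tn, fn = 90, 10, 990, 10
    expected = (tp * tn - fp * fn) / math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    assert matthews_correlation(tp, fp, tn, fn) == pytest.approx(expected)
    with pytest.warns(UserWarning):
        assert matthews_correlation(0, 0, 0, 0) == 0.0


@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
def test_mcc_swap_invariance(tp, fp, tn, fn):
    assert matthews_correlation(tp, fp, tn, fn) == pytest.approx(
        matthews_correlation(tn, fn, tp, fp), abs=1e-12
    )


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

def _truth(positions):
    return TruthSet(
        pd.DataFrame(
            [("chr1", p, "A", "C", 0.05) for p in positions],
            columns=["chrom", "pos", "ref", "alt", "prevalence"],
        )
    )


def _candidates(entries):
    return pd.DataFrame(
        [("amp0", "chr1", pos, "A", alt, p) for pos, alt, p in entries],
        columns=["amplicon_id", "chrom", "pos", "ref", "alt", "p"],
    )


def test_threshold_perfectly_separated():
    truth = _truth(range(5))
    cand = _candidates(
        [(i, "C", 1e-6) for i in range(5)] + [(100 + i, "C", 1e-2) for i in range(20)]
    )
    res = select_threshold(cand, truth, n_assayed=1000)
    assert res.p_threshold == 1e-6
    assert res.mcc == 1.0
    assert (res.tp, res.fp, res.fn) == (5, 0, 0)


def brute_force_threshold(cand, truth, n_assayed):
    """Oracle: evaluate MCC at every distinct candidate p by direct loops."""
    truth_alleles = truth.alleles()
    labels = [
        (c, p, a) in truth_alleles
        for c, p, a in zip(cand["chrom"], cand["pos"], cand["alt"])
    ]
    n_truth = len(truth)
    n_neg = n_assayed - n_truth
    best = (-2.0, None)
    for t in sorted(set(cand["p"])):
        tp = sum(1 for lab, pv in zip(labels, cand["p"]) if lab and pv <= t)
        fp = sum(1 for lab, pv in zip(labels, cand["p"]) if not lab and pv <= t)
        mcc = matthews_correlation(tp, fp, n_neg - fp, n_truth - tp)
        if mcc > best[0]:
            best = (mcc, t)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_threshold_matches_brute_force_scan(seed):
    rng = np.random.default_rng(seed)
    n = 50
    positions = rng.choice(10_000, size=n, replace=False)
    truth_pos = positions[: n // 3]
    pvals = 10.0 ** rng.uniform(-12, 0, size=n)
    pvals[: n // 3] *= 1e-3  # truth tends lower but overlaps
    truth = _truth(truth_pos)
    cand = _candidates([(p, "C", pv) for p, pv in zip(positions, pvals)])
    res = select_threshold(cand, truth, n_assayed=5000)
    mcc_o, t_o = brute_force_threshold(cand, truth, 5000)
    assert res.mcc == pytest.approx(mcc_o)
    assert res.p_threshold == t_o


def test_threshold_tie_breaks_to_smallest():
    # n_assayed chosen so MCC(TP=1,FP=0,TN=2,FN=1) == MCC(TP=2,FP=1,TN=1,FN=0)
    truth = _truth([1, 3])
    cand = _candidates([(1, "C", 1e-3), (2, "C", 1e-2), (3, "C", 1e-1)])
    res = select_threshold(cand, truth, n_assayed=4)
    mcc_small = matthews_correlation(1, 0, 2, 1)
    mcc_large = matthews_correlation(2, 1, 1, 0)
    assert mcc_small == pytest.approx(mcc_large)
    assert res.p_threshold == 1e-3


def test_threshold_errors():
    with pytest.raises(CalibrationError, match="truth"):
        select_threshold(_candidates([(1, "C", 0.1)]), _truth([]), 100)
    with pytest.raises(CalibrationError, match="overlap"):
        select_threshold(_candidates([(1, "C", 0.1)]), _truth([99]), 100)


# ---------------------------------------------------------------------------
# Coverage floor
# ---------------------------------------------------------------------------

def test_coverage_floor_nearest_rank():
    cols = [
        make_column(pos=1000 + i, read_pos=1 + i % 122, counts=(i + 1, 0, 0, 0))
        for i in range(100)
    ]
    assert coverage_floor(make_table(cols)) == 5  # nearest-rank 5th pct of 1..100


def test_coverage_floor_constant_distribution():
    cols = [make_column(pos=1000 + i, counts=(77, 0, 0, 0)) for i in range(10)]
    assert coverage_floor(make_table(cols)) == 77


def test_coverage_floor_merges_directions():
    cols = [
        make_column(direction="F", pos=1000, counts=(40, 0, 0, 0)),
        make_column(direction="R", pos=1000, read_pos=100, counts=(60, 0, 0, 0)),
    ]
    assert coverage_floor(make_table(cols)) == 100


def test_coverage_floor_monotone_when_adding_high_coverage(rng):
    depths = rng.integers(10, 5000, size=200)
    cols = [
        make_column(pos=1000 + i, read_pos=1 + i % 122, counts=(int(d), 0, 0, 0))
        for i, d in enumerate(depths)
    ]
    base = coverage_floor(make_table(cols))
    extra = cols + [
        make_column(pos=5000 + i, read_pos=1, counts=(6000 + i, 0, 0, 0))
        for i in range(50)
    ]
    assert coverage_floor(make_table(extra)) >= base


# ---------------------------------------------------------------------------
# Systematic-noise mask
# ---------------------------------------------------------------------------

def _control(seed, spike_pos=None, n_positions=61, depth=2000, rate=0.002):
    rng = np.random.default_rng(seed)
    cols = []
    for i in range(n_positions):
        pos = 1000 + i
        r = rate * 10 if pos == spike_pos else rate
        alt = rng.binomial(depth, r)
        cols.append(
            make_column(
                pos=pos, read_pos=1 + i % 122, counts=(depth - alt, alt, 0, 0)
            )
        )
    return make_table(cols)


def test_spiked_position_masked_in_all_controls():
    controls = [_control(seed=s, spike_pos=1030) for s in range(4)]
    mask = detect_systematic_noise(controls)
    assert ("chrSim", 1030) in mask


def test_recurrence_below_three_not_masked():
    controls = [_control(seed=s, spike_pos=1030 if s < 2 else None) for s in range(4)]
    mask = detect_systematic_noise(controls)
    assert ("chrSim", 1030) not in mask
    row = mask.table.set_index(["chrom", "pos"])
    assert row.loc[("chrSim", 1030), "n_controls_noisy"] == 2


def test_too_few_controls_errors():
    controls = [_control(seed=s) for s in range(2)]
    with pytest.raises(CalibrationError, match="min_recurrence"):
        detect_systematic_noise(controls)


def test_uniform_noise_mask_rate_bounded():
    """Under a flat error field the masked fraction stays within the
    alpha-driven bound (>= 10^4 positions across 3 controls)."""
    designs = simulate.make_design(n_amplicons=50)
    reference = simulate.make_reference(designs, seed=31)
    controls = [
        simulate.simulate_pileup(
            designs, reference, None, simulate.ErrorProfile.flat(0.002),
            mean_depth=2000, seed=40 + s,
        )
        for s in range(3)
    ]
    n_positions = len(controls[0].collapsed_depth())
    assert n_positions >= 10_000
    mask = detect_systematic_noise(controls, min_recurrence=3)
    assert len(mask) / n_positions <= 5e-4


# ---------------------------------------------------------------------------
# Performance evaluation
# ---------------------------------------------------------------------------

def _calls(entries):
    return pd.DataFrame(
        entries, columns=["chrom", "pos", "ref", "alt", "prevalence"]
    )


def test_evaluate_perfect_run():
    truth = _truth([1, 2, 3])
    calls = _calls([("chr1", p, "A", "C", 0.05) for p in (1, 2, 3)])
    m = evaluate_performance(calls, truth, n_assayed=1000)
    assert m["sensitivity"] == 1.0 and m["ppv"] == 1.0 and m["specificity"] == 1.0


def test_evaluate_zero_calls():
    truth = _truth([1, 2])
    m = evaluate_performance(_calls([]), truth, n_assayed=100)
    assert m["sensitivity"] == 0.0
    assert np.isnan(m["ppv"])
    assert np.isnan(m["pearson_r"])


def test_evaluate_hand_tallied_confusion():
    truth = TruthSet(
        pd.DataFrame(
            [
                ("chr1", 1, "A", "C", 0.01),
                ("chr1", 2, "A", "C", 0.05),
                ("chr1", 3, "A", "C", 0.20),
                ("chr1", 4, "A", "C", 0.74),
            ],
            columns=["chrom", "pos", "ref", "alt", "prevalence"],
        )
    )
    calls = _calls(
        [
            ("chr1", 1, "A", "C", 0.012),   # TP at 1%
            ("chr1", 3, "A", "C", 0.21),    # TP at 20%
            ("chr1", 50, "A", "C", 0.01),   # FP
            ("chr1", 51, "A", "C", 0.02),   # FP
        ]
    )
    m = evaluate_performance(calls, truth, n_assayed=104)
    assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (2, 2, 2, 98)
    assert m["sensitivity"] == 0.5
    assert m["ppv"] == 0.5
    assert m["specificity"] == 0.98
    assert m["sensitivity_by_prevalence"] == {0.01: 1.0, 0.05: 0.0, 0.2: 1.0, 0.74: 0.0}
    r = np.corrcoef([0.01, 0.20], [0.012, 0.21])[0, 1]
    assert m["pearson_r"] == pytest.approx(r)
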