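import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from deepamp import simulate
from deepamp.calling import (
    apply_prefilters,
    best_per_position,
    binomial_tail_pvalue,
    call_variants,
    combine_stouffer,
    estimate_prevalence,
    score_candidates,
)

from conftest import make_column, make_table


# ---------------------------------------------------------------------------
# Binomial tail
# ---------------------------------------------------------------------------

def exact_binomial_tail(X: int, N: int, E: Fraction) -> Fraction:
    """Oracle: exhaustive summation of the upper tail in exact rationals
    (integer numerators over the common denominator b^N for E = a/b)."""
    a, b = E.numerator, E.denominator
    num = sum(math.comb(N, k) * a**k * (b - a) ** (N - k) for k in range(X, N + 1))
    return Fraction(num, b**N)


@pytest.mark.parametrize("N", [5, 50, 200, 500])
@pytest.mark.parametrize(
    "E", [Fraction(1, 10000), Fraction(1, 1000), Fraction(1, 100), Fraction(5, 100)]
)
def test_binomial_tail_matches_exact_summation(N, E):
    for X in sorted({0, 1, 2, 3, N // 10, N // 2, N}):
        expected = float(exact_binomial_tail(X, N, E))
        got = binomial_tail_pvalue(X, N, float(E))
        assert got == pytest.approx(expected, rel=1e-10)


def test_binomial_tail_basics():
    assert binomial_tail_pvalue(0, 1000, 0.001) == 1.0
    assert binomial_tail_pvalue(6, 1000, 0.001) < binomial_tail_pvalue(5, 1000, 0.001)
    with pytest.raises(ValueError):
        binomial_tail_pvalue(11, 10, 0.01)
    with pytest.raises(ValueError):
        binomial_tail_pvalue(1, 10, 0.0)


# ---------------------------------------------------------------------------
# Stouffer combination
# ---------------------------------------------------------------------------

def _erfc_inv(y: float) -> float:
    """Bisection inverse of math.erfc on (0, 2) — independent of scipy."""
    lo, hi = -10.0, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if math.erfc(mid) > y:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2))


def _isf(p: float) -> float:
    return math.sqrt(2) * _erfc_inv(2 * p)


def test_stouffer_symmetric_midpoint_and_passthrough():
    assert combine_stouffer(0.5, 800, 0.5, 800) == pytest.approx(0.5, abs=1e-12)
    assert combine_stouffer(0.01, 500, None, 0) == 0.01
    assert combine_stouffer(None, 0, 0.03, 700) == 0.03
    with pytest.raises(ValueError):
        combine_stouffer(None, 0, None, 0)


def test_stouffer_matches_independent_normal_oracle():
    p_f, p_r = 0.01, 0.02
    z = (_isf(p_f) + _isf(p_r)) / math.sqrt(2)
    expected = _sf(z)
    assert combine_stouffer(p_f, 1000, p_r, 1000) == pytest.approx(expected, rel=1e-9)


@given(
    st.floats(1e-12, 1 - 1e-12),
    st.integers(1, 10**6),
    st.floats(1e-12, 1 - 1e-12),
    st.integers(1, 10**6),
)
def test_stouffer_is_symmetric(p1, n1, p2, n2):
    assert combine_stouffer(p1, n1, p2, n2) == pytest.approx(
        combine_stouffer(p2, n2, p1, n1), rel=1e-12
    )


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

def test_prevalence_pooling_and_rejection():
    assert estimate_prevalence(50, 1000, 0, 0) == 0.05
    assert estimate_prevalence(30, 500, 70, 1500) == 0.05
    assert estimate_prevalence(999, 1000, 10, 1000, f_accepted=False) == 0.01
    with pytest.raises(ValueError):
        estimate_prevalence(0, 0, 0, 0)


# ---------------------------------------------------------------------------
# Prefilters
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def one_design():
    return simulate.make_design(n_amplicons=1)


def test_prefilter_primer_positions_removed(one_design):
    (d,) = one_design
    cols = [
        make_column(pos=d.fwd_primer_span[0], read_pos=1, counts=(900, 100, 0, 0)),
        make_column(pos=d.target_start, read_pos=21, counts=(900, 100, 0, 0)),
    ]
    cand, acct = apply_prefilters(make_table(cols), one_design)
    assert acct["PRIMER"] == 1
    assert set(cand["pos"]) == {d.target_start}


def test_prefilter_min_alt_fraction_boundary(one_design):
    (d,) = one_design
    cols = [
        make_column(pos=d.target_start, read_pos=21, counts=(9981, 19, 0, 0)),
        make_column(pos=d.target_start + 1, read_pos=22, counts=(9980, 20, 0, 0)),
    ]
    cand, acct = apply_prefilters(make_table(cols), one_design)
    # 19/10000 = 0.19% removed; 20/10000 = 0.20% retained (strict <)
    assert acct["MIN_ALT_FRAC"] == 1
    assert set(cand["pos"]) == {d.target_start + 1}


def test_prefilter_single_direction_read_end_boundary(one_design):
    (d,) = one_design
    p100 = d.fwd_read_start + 99   # read_pos 100
    p101 = d.fwd_read_start + 100  # read_pos 101
    cols = [
        make_column(pos=p100, read_pos=100, counts=(900, 100, 0, 0)),
        make_column(pos=p101, read_pos=101, counts=(900, 100, 0, 0)),
    ]
    cand, acct = apply_prefilters(make_table(cols), one_design)
    assert acct["READ_END"] == 1
    assert set(cand["pos"]) == {p100}


def test_prefilter_direction_rejection_coverage_ratio(one_design):
    (d,) = one_design
    pos = d.target_start + 70  # covered by both directions
    cols = [
        # F: 10/50 = 20% alt; R: 0/1000 — inconsistent, N_f = 50 < 0.1*1000.
        # F also sits later in its read, so only the coverage rule fires
        # for F and neither rule fires for R.
        make_column(direction="F", pos=pos, read_pos=60, counts=(40, 10, 0, 0)),
        make_column(direction="R", pos=pos, read_pos=50, counts=(1000, 0, 0, 0)),
    ]
    cand, _ = apply_prefilters(make_table(cols), one_design)
    row = cand[cand["alt"] == "C"].iloc[0]
    assert not row["f_accepted"] and row["r_accepted"]
    assert "DIRECTION_REJECTED_F" in row["flags"]
    # boundary: N_f exactly 0.1*N_r is NOT rejected on coverage (strict <)
    cols2 = [
        make_column(direction="F", pos=pos, read_pos=50, counts=(90, 10, 0, 0)),
        make_column(direction="R", pos=pos, read_pos=50, counts=(1000, 0, 0, 0)),
    ]
    cand2, _ = apply_prefilters(make_table(cols2), one_design)
    row2 = cand2[cand2["alt"] == "C"].iloc[0]
    assert row2["f_accepted"] and row2["r_accepted"]


def test_prefilter_direction_rejection_read_position(one_design):
    (d,) = one_design
    pos = d.target_start + 70
    cols = [
        # equal depths, inconsistent calls, F base later in its read
        make_column(direction="F", pos=pos, read_pos=110, counts=(900, 100, 0, 0)),
        make_column(direction="R", pos=pos, read_pos=91, counts=(1000, 0, 0, 0)),
    ]
    cand, _ = apply_prefilters(make_table(cols), one_design)
    row = cand[cand["alt"] == "C"].iloc[0]
    assert not row["f_accepted"] and row["r_accepted"]


def test_prefilters_idempotent(one_design, small_reference):
    designs = simulate.make_design(n_amplicons=2)
    reference = simulate.make_reference(designs, seed=5)
    truth = simulate.make_calibration_pools(designs, reference, n_snps=4, seed=5)[0]
    table = simulate.simulate_pileup(
        designs, reference, truth, simulate.ErrorProfile.gaii(), mean_depth=3000, seed=6
    )
    cand1, _ = apply_prefilters(table, designs)
    surviving = set(zip(cand1["amplicon_id"], cand1["pos"]))
    keep = [
        (a, p) in surviving
        for a, p in zip(table.df["amplicon_id"], table.df["pos"])
    ]
    restricted = make_table(table.df[keep].to_dict("records"))
    cand2, _ = apply_prefilters(restricted, designs)
    pd.testing.assert_frame_equal(
        cand1.sort_values(["pos", "alt"]).reset_index(drop=True),
        cand2.sort_values(["pos", "alt"]).reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Scoring and per-position reduction
# ---------------------------------------------------------------------------

def test_best_allele_selection_and_calls(one_design, small_reference):
    (d,) = one_design
    reference = {d.chrom: "".join("ACGT"[i] for i in
                                  simulate.make_reference(one_design, seed=3)[d.chrom])}
    ref_arr = simulate.make_reference(one_design, seed=3)
    profile = simulate.ErrorProfile.flat(0.001)
    table = simulate.simulate_pileup(one_design, ref_arr, None, profile,
                                     mean_depth=5000, seed=8)
    # plant a strong variant in the dual-covered zone
    pos = d.target_start + 80
    df = table.df
    for direction in "FR":
        i = df[(df.direction == direction) & (df.pos == pos)].index[0]
        ref = df.loc[i, "ref"]
        alt = "A" if ref != "A" else "C"
        moved = int(df.loc[i, "depth"] * 0.2)
        df.loc[i, f"count_{ref}"] -= moved
        df.loc[i, f"count_{alt}"] += moved
    from deepamp.error_model import train_error_model

    model = train_error_model(table, mask={(d.chrom, pos)})
    result = call_variants(table, one_design, model, threshold=1e-10)
    assert len(result.calls) == 1
    call = result.calls.iloc[0]
    assert call["pos"] == pos
    assert call["prevalence"] == pytest.approx(0.2, abs=0.02)
    # best-per-position kept the strongest allele
    assert call["p"] <= result.candidates[result.candidates.pos == pos]["p"].min()
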