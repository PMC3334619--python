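"""Candidate filtering and statistical assessment of low-prevalence variants.

Candidate positions first pass four prefilters:

1. positions inside primer spans are removed (primer bases are synthetic);
2. positions whose pooled non-reference fraction is below a floor
   (default 0.2%, five-fold below a 1% design prevalence) are removed;
3. positions covered by a single read direction are removed when they sit
   more than 100 cycles from the read start, where error rates climb;
4. at positions covered by both directions whose calls disagree, the
   direction with less than a tenth of the other's coverage, or the
   larger distance from its read start, is rejected.

Each surviving non-reference allele is then tested per direction against
the trained error rate E for its (direction, read position, ref -> alt)
bin with an upper-tail binomial test, P(B >= X) for B ~ Binomial(N, E).
When both directions carry accepted evidence the two p-values are
combined with a depth-weighted Stouffer Z:

    Z = (N_f Z_f + N_r Z_r) / sqrt(N_f^2 + N_r^2),   Z_i = Phi^-1(1 - p_i).

The reported variant at a position is the allele with the smallest
combined p-value (ties: larger alt count, then alphabetical order).  The
prevalence estimate is the pooled alt fraction over accepted directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .design import AmpliconDesign
from .error_model import ErrorModel
from .pileup import BASES, BASE_INDEX, COUNT_COLS, PileupTable

P_MIN = 1e-300

FLAG_PRIMER = "PRIMER"
FLAG_MIN_ALT_FRAC = "MIN_ALT_FRAC"
FLAG_READ_END = "READ_END"
FLAG_DIR_REJECTED_F = "DIRECTION_REJECTED_F"
FLAG_DIR_REJECTED_R = "DIRECTION_REJECTED_R"
FLAG_LOW_COVERAGE = "LOW_COVERAGE"
FLAG_ABOVE_THRESHOLD = "ABOVE_THRESHOLD"
FLAG_NOISY = "NOISY_POSITION"


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def binomial_tail_pvalue(X, N, E):
    """Upper-tail binomial p-value P(B >= X), B ~ Binomial(N, E).

    The tail includes X itself, so X = 0 always yields p = 1.  Results
    are clamped to [1e-300, 1] to keep downstream quantile transforms
    finite.  Accepts scalars or arrays.
    """
    X = np.asarray(X)
    N = np.asarray(N)
    E = np.asarray(E, dtype=float)
    if np.any(X < 0) or np.any(X > N):
        raise ValueError("need 0 <= X <= N")
    if np.any(E <= 0) or np.any(E >= 1):
        raise ValueError("error rate E must lie strictly inside (0, 1)")
    p = np.clip(stats.binom.sf(X - 1, N, E), P_MIN, 1.0)
    return float(p) if p.ndim == 0 else p


def _stouffer_vec(p_f, N_f, p_r, N_r):
    """Vectorised Stouffer combination with NaN/absent handling."""
    p_f = np.asarray(p_f, dtype=float)
    p_r = np.asarray(p_r, dtype=float)
    N_f = np.asarray(N_f, dtype=float)
    N_r = np.asarray(N_r, dtype=float)
    has_f = np.isfinite(p_f) & (N_f > 0)
    has_r = np.isfinite(p_r) & (N_r > 0)
    out = np.full(np.broadcast(p_f, p_r).shape, np.nan)
    only_f = has_f & ~has_r
    only_r = has_r & ~has_f
    both = has_f & has_r
    out[only_f] = p_f[only_f]
    out[only_r] = p_r[only_r]
    if both.any():
        zf = stats.norm.isf(np.clip(p_f[both], P_MIN, 1 - 1e-16))
        zr = stats.norm.isf(np.clip(p_r[both], P_MIN, 1 - 1e-16))
        nf, nr = N_f[both], N_r[both]
        z = (nf * zf + nr * zr) / np.sqrt(nf**2 + nr**2)
        out[both] = np.clip(stats.norm.sf(z), P_MIN, 1.0)
    return out


def combine_stouffer(p_f, N_f, p_r, N_r) -> float:
    """Depth-weighted Stouffer combination of per-direction p-values.

    A direction with N = 0 or p = None/NaN is treated as absent and the
    other direction's p-value is returned unchanged; both absent is an
    error.
    """
    p_f = np.nan if p_f is None else p_f
    p_r = np.nan if p_r is None else p_r
    out = _stouffer_vec([p_f], [N_f or 0], [p_r], [N_r or 0])[0]
    if not np.isfinite(out):
        raise ValueError("cannot combine: both directions absent")
    return float(out)


def estimate_prevalence(X_f, N_f, X_r, N_r, f_accepted=True, r_accepted=True) -> float:
    """Pooled alt fraction (X_f + X_r) / (N_f + N_r) over accepted directions."""
    num = (X_f if f_accepted else 0) + (X_r if r_accepted else 0)
    den = (N_f if f_accepted else 0) + (N_r if r_accepted else 0)
    if den <= 0:
        raise ValueError("no accepted direction with positive depth")
    return num / den


# ---------------------------------------------------------------------------
# Prefilters (candidate selection)
# ---------------------------------------------------------------------------

def _merge_directions(df: pd.DataFrame) -> pd.DataFrame:
    keys = ["amplicon_id", "chrom", "pos"]
    f = df[df["direction"] == "F"].drop(columns="direction")
    r = df[df["direction"] == "R"].drop(columns="direction")
    wide = f.merge(r, on=keys, how="outer", suffixes=("_f", "_r"))
    wide["ref"] = wide["ref_f"].where(wide["ref_f"].notna(), wide["ref_r"])
    for side in ("f", "r"):
        for c in COUNT_COLS + ["depth"]:
            wide[f"{c}_{side}"] = wide[f"{c}_{side}"].fillna(0).astype(np.int64)
    return wide


def apply_prefilters(
    table: PileupTable,
    designs: Iterable[AmpliconDesign],
    min_alt_frac: float = 0.002,
    max_read_pos_single: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Run prefilters 1-4 and expand surviving positions into per-allele
    candidates.

    Returns ``(candidates, accounting)``.  ``candidates`` has one row per
    (position, non-reference allele) with per-direction evidence and the
    direction-acceptance outcome of filter 4; ``accounting`` counts the
    positions removed by each positional filter.
    """
    designs = {d.amplicon_id: d for d in designs}
    wide = _merge_directions(table.df)
    n_pos = len(wide)

    # Filter 1: primer spans
    in_primer = np.fromiter(
        (
            designs[a].in_primer(p) if a in designs else False
            for a, p in zip(wide["amplicon_id"], wide["pos"])
        ),
        dtype=bool,
        count=n_pos,
    )
    wide = wide[~in_primer]

    # Filter 2: pooled non-reference fraction below floor (strict <)
    ref_idx = wide["ref"].map(BASE_INDEX).to_numpy()
    cf = wide[[f"{c}_f" for c in COUNT_COLS]].to_numpy()
    cr = wide[[f"{c}_r" for c in COUNT_COLS]].to_numpy()
    rows = np.arange(len(wide))
    total = wide["depth_f"].to_numpy() + wide["depth_r"].to_numpy()
    refcnt = cf[rows, ref_idx] + cr[rows, ref_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_frac = np.where(total > 0, (total - refcnt) / total, 0.0)
    low_frac = pooled_frac < min_alt_frac
    n_low_frac = int(low_frac.sum())
    wide = wide[~low_frac]

    # Filter 3: single-direction positions too far from the read start
    has_f = wide["depth_f"].to_numpy() > 0
    has_r = wide["depth_r"].to_numpy() > 0
    rp_f = wide["read_pos_f"].to_numpy(dtype=float)
    rp_r = wide["read_pos_r"].to_numpy(dtype=float)
    single_rp = np.where(has_f & ~has_r, rp_f, np.where(has_r & ~has_f, rp_r, 0.0))
    read_end = (has_f != has_r) & (single_rp > max_read_pos_single)
    n_read_end = int(read_end.sum())
    wide = wide[~read_end]

    # Allele expansion + filter 4
    ref_idx = wide["ref"].map(BASE_INDEX).to_numpy()
    cf = wide[[f"{c}_f" for c in COUNT_COLS]].to_numpy()
    cr = wide[[f"{c}_r" for c in COUNT_COLS]].to_numpy()
    parts = []
    for ai, alt in enumerate(BASES):
        sel = ref_idx != ai
        if not sel.any():
            continue
        sub = wide.loc[sel, ["amplicon_id", "chrom", "pos", "ref"]].copy()
        sub["alt"] = alt
        sub["X_f"] = cf[sel, ai]
        sub["X_r"] = cr[sel, ai]
        sub["N_f"] = wide.loc[sel, "depth_f"].to_numpy()
        sub["N_r"] = wide.loc[sel, "depth_r"].to_numpy()
        sub["read_pos_f"] = wide.loc[sel, "read_pos_f"].to_numpy(dtype=float)
        sub["read_pos_r"] = wide.loc[sel, "read_pos_r"].to_numpy(dtype=float)
        parts.append(sub)
    if parts:
        cand = pd.concat(parts, ignore_index=True)
    else:
        cand = pd.DataFrame(
            columns=[
                "amplicon_id", "chrom", "pos", "ref", "alt",
                "X_f", "X_r", "N_f", "N_r", "read_pos_f", "read_pos_r",
            ]
        )

    nf = cand["N_f"].to_numpy(dtype=float)
    nr = cand["N_r"].to_numpy(dtype=float)
    has_f = nf > 0
    has_r = nr > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        exceeds_f = np.where(has_f, cand["X_f"] / np.maximum(nf, 1), 0.0) > min_alt_frac
        exceeds_r = np.where(has_r, cand["X_r"] / np.maximum(nr, 1), 0.0) > min_alt_frac
    inconsistent = has_f & has_r & (exceeds_f != exceeds_r)
    rpf = cand["read_pos_f"].to_numpy()
    rpr = cand["read_pos_r"].to_numpy()
    reject_f = inconsistent & ((nf < 0.1 * nr) | (rpf > rpr))
    reject_r = inconsistent & ((nr < 0.1 * nf) | (rpr > rpf))
    cand["f_accepted"] = has_f & ~reject_f
    cand["r_accepted"] = has_r & ~reject_r
    flags = np.where(reject_f, FLAG_DIR_REJECTED_F, "")
    flags = np.char.add(
        flags.astype("U64"),
        np.where(reject_r, np.where(flags != "", ";" + FLAG_DIR_REJECTED_R, FLAG_DIR_REJECTED_R), ""),
    )
    cand["flags"] = flags

    accounting = {
        "n_positions": n_pos,
        FLAG_PRIMER: int(in_primer.sum()),
        FLAG_MIN_ALT_FRAC: n_low_frac,
        FLAG_READ_END: n_read_end,
        "n_surviving_positions": len(wide),
    }
    return cand.reset_index(drop=True), accounting


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_candidates(candidates: pd.DataFrame, model: ErrorModel) -> pd.DataFrame:
    """Attach per-direction and combined p-values plus the prevalence
    estimate to prefiltered candidates."""
    cand = candidates.copy()
    n = len(cand)
    if n == 0:
        for c in ("p_f", "p_r", "p", "prevalence"):
            cand[c] = pd.Series(dtype=float)
        return cand
    ref_idx = cand["ref"].map(BASE_INDEX).to_numpy()
    alt_idx = cand["alt"].map(BASE_INDEX).to_numpy()

    def side_p(dir_index: int, side: str) -> np.ndarray:
        ok = cand[f"{side}_accepted"].to_numpy() & (cand[f"N_{side}"].to_numpy() > 0)
        rp = np.nan_to_num(cand[f"read_pos_{side}"].to_numpy(), nan=1.0).astype(int)
        rp = np.clip(rp, 1, model.rates.shape[1] - 1)
        E = model.rates[dir_index, rp, ref_idx, alt_idx]
        p = np.full(n, np.nan)
        if ok.any():
            p[ok] = binomial_tail_pvalue(
                cand["X_" + side].to_numpy()[ok],
                cand["N_" + side].to_numpy()[ok],
                E[ok],
            )
        return p

    p_f = side_p(0, "f")
    p_r = side_p(1, "r")
    cand["p_f"] = p_f
    cand["p_r"] = p_r
    nf_eff = np.where(cand["f_accepted"], cand["N_f"], 0)
    nr_eff = np.where(cand["r_accepted"], cand["N_r"], 0)
    cand["p"] = _stouffer_vec(p_f, nf_eff, p_r, nr_eff)
    num = np.where(cand["f_accepted"], cand["X_f"], 0) + np.where(
        cand["r_accepted"], cand["X_r"], 0
    )
    den = nf_eff + nr_eff
    with np.errstate(invalid="ignore", divide="ignore"):
        cand["prevalence"] = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return cand


def best_per_position(scored: pd.DataFrame) -> pd.DataFrame:
    """Reduce per-allele candidates to the best allele per position
    (smallest combined p; ties to the larger alt count, then alphabetical
    alt)."""
    if len(scored) == 0:
        return scored.copy()
    df = scored.copy()
    df["_X_total"] = df["X_f"] + df["X_r"]
    df = df.sort_values(
        ["amplicon_id", "chrom", "pos", "p", "_X_total", "alt"],
        ascending=[True, True, True, True, False, True],
        na_position="last",
        kind="mergesort",
    )
    best = df.drop_duplicates(subset=["amplicon_id", "chrom", "pos"], keep="first")
    return best.drop(columns="_X_total").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full per-sample calling
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    calls: pd.DataFrame
    best: pd.DataFrame
    candidates: pd.DataFrame
    accounting: dict = field(default_factory=dict)


def call_variants(
    table: PileupTable,
    designs: Iterable[AmpliconDesign],
    model: ErrorModel,
    threshold: float | None = None,
    coverage_floor_depth: int | None = None,
    noise_mask: set | None = None,
    min_alt_frac: float = 0.002,
    max_read_pos_single: int = 100,
    min_prevalence: float = 0.0,
) -> CallResult:
    """Run prefilters, statistics and post-filters on one sample.

    ``threshold`` is the calibrated p-value cutoff (call iff p <= t);
    ``coverage_floor_depth`` flags positions whose merged coverage falls
    strictly below the calibration sample's floor; ``noise_mask`` is a
    set of recurrently noisy (chrom, pos).  With ``threshold=None`` the
    result's ``best`` frame can be fed to threshold selection.
    """
    designs = list(designs)
    candidates, accounting = apply_prefilters(
        table, designs, min_alt_frac=min_alt_frac, max_read_pos_single=max_read_pos_single
    )
    scored = score_candidates(candidates, model)
    best = best_per_position(scored)

    flags = best["flags"].to_numpy(dtype=object).copy()
    rejected_both = ~(best["f_accepted"].to_numpy() | best["r_accepted"].to_numpy())

    collapsed = table.collapsed_depth()
    if coverage_floor_depth is not None and len(best):
        depth = np.array(
            [collapsed.get((c, p), 0) for c, p in zip(best["chrom"], best["pos"])]
        )
        low = depth < coverage_floor_depth
    else:
        low = np.zeros(len(best), dtype=bool)

    if noise_mask and len(best):
        noisy = np.fromiter(
            ((c, p) in noise_mask for c, p in zip(best["chrom"], best["pos"])),
            dtype=bool,
            count=len(best),
        )
    else:
        noisy = np.zeros(len(best), dtype=bool)

    pvals = best["p"].to_numpy(dtype=float)
    if threshold is not None:
        above = ~(pvals <= threshold)  # NaN counts as above
    else:
        above = np.zeros(len(best), dtype=bool)

    def add_flag(mask: np.ndarray, flag: str) -> None:
        for i in np.nonzero(mask)[0]:
            flags[i] = f"{flags[i]};{flag}" if flags[i] else flag

    add_flag(low, FLAG_LOW_COVERAGE)
    add_flag(noisy, FLAG_NOISY)
    add_flag(above & ~rejected_both, FLAG_ABOVE_THRESHOLD)
    best = best.copy()
    best["flags"] = flags

    callable_mask = ~(rejected_both | low | noisy | above)
    if min_prevalence > 0:
        callable_mask &= best["prevalence"].to_numpy(dtype=float) >= min_prevalence
    calls = best[callable_mask].reset_index(drop=True)

    accounting.update(
        {
            FLAG_LOW_COVERAGE: int(low.sum()),
            FLAG_NOISY: int((noisy & ~low).sum()),
            FLAG_ABOVE_THRESHOLD: int((above & ~rejected_both & ~low & ~noisy).sum()),
            "n_called": len(calls),
        }
    )
    return CallResult(calls=calls, best=best, candidates=scored, accounting=accounting)


def position_allele_pvalues(table: PileupTable, model: ErrorModel) -> pd.DataFrame:
    """Combined p-values for every (position, non-reference allele) with
    no prefiltering or selection — the raw calibration diagnostic of the
    test statistic (under a null sample these should be conservative
    relative to uniform)."""
    wide = _merge_directions(table.df)
    ref_idx = wide["ref"].map(BASE_INDEX).to_numpy()
    cf = wide[[f"{c}_f" for c in COUNT_COLS]].to_numpy()
    cr = wide[[f"{c}_r" for c in COUNT_COLS]].to_numpy()
    parts = []
    for ai, alt in enumerate(BASES):
        sel = ref_idx != ai
        sub = wide.loc[sel, ["amplicon_id", "chrom", "pos", "ref"]].copy()
        sub["alt"] = alt
        sub["X_f"] = cf[sel, ai]
        sub["X_r"] = cr[sel, ai]
        sub["N_f"] = wide.loc[sel, "depth_f"].to_numpy()
        sub["N_r"] = wide.loc[sel, "depth_r"].to_numpy()
        sub["read_pos_f"] = wide.loc[sel, "read_pos_f"].to_numpy(dtype=float)
        sub["read_pos_r"] = wide.loc[sel, "read_pos_r"].to_numpy(dtype=float)
        parts.append(sub)
    cand = pd.concat(parts, ignore_index=True)
    cand["f_accepted"] = cand["N_f"] > 0
    cand["r_accepted"] = cand["N_r"] > 0
    return score_candidates(cand, model)
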