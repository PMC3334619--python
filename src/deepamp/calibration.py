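"""Threshold calibration and performance evaluation.

The caller does not use nominal p-values.  Instead, the full pipeline is
run on a calibration sample whose variant content is known (a pool of
reference DNAs mixed at known proportions), and the p-value threshold is
chosen to maximise the Matthews correlation coefficient (MCC) between
calls and truth — an appropriate criterion given the extreme imbalance
between the handful of true positives and tens of thousands of invariant
bases.  Two further post-filters are derived from calibration data: a
coverage floor (the 5th percentile of the calibration sample's merged
per-base coverage) and a systematic-noise mask built from independent
germline control samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import binomial_tail_pvalue
from .pileup import BASE_INDEX, COUNT_COLS, PileupTable
from .truth import TruthSet


class CalibrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Matthews correlation and threshold selection
# ---------------------------------------------------------------------------

def matthews_correlation(tp, fp, tn, fn):
    """MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

    Any zero factor in the denominator yields 0 by convention.  Accepts
    scalars or arrays.
    """
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    tn = np.asarray(tn, dtype=float)
    fn = np.asarray(fn, dtype=float)
    if np.any(tp < 0) or np.any(fp < 0) or np.any(tn < 0) or np.any(fn < 0):
        raise ValueError("confusion counts must be non-negative")
    if tp.ndim == 0 and (tp + fp + tn + fn) == 0:
        warnings.warn("all confusion counts are zero; MCC set to 0")
    num = tp * tn - fp * fn
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(mcc) if mcc.ndim == 0 else mcc


@dataclass
class ThresholdResult:
    p_threshold: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def confusion(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def select_threshold(
    candidates: pd.DataFrame, truth: TruthSet, n_assayed: int
) -> ThresholdResult:
    """Scan every distinct candidate p-value as a threshold (call iff
    p <= t) and return the MCC-maximising one.

    ``candidates`` must be position-level rows (one best allele per
    position) with columns chrom, pos, alt, p, as produced by running
    the pipeline on the calibration sample itself.  Positives are truth
    positions with a matching allele; negatives are the remaining
    ``n_assayed`` assayed bases.  MCC ties break toward the smallest
    (most stringent) threshold.
    """
    if len(truth) == 0:
        raise CalibrationError("empty truth set: cannot select a threshold")
    cand = candidates[np.isfinite(candidates["p"].to_numpy(dtype=float))]
    if len(cand) == 0:
        raise CalibrationError("no scored candidates to threshold")
    truth_alleles = truth.alleles()
    is_true = np.fromiter(
        (
            (c, p, a) in truth_alleles
            for c, p, a in zip(cand["chrom"], cand["pos"], cand["alt"])
        ),
        dtype=bool,
        count=len(cand),
    )
    if not is_true.any():
        raise CalibrationError("no candidate overlaps the truth set")
    n_truth = len(truth)
    n_neg = n_assayed - n_truth
    if n_neg < 0:
        raise CalibrationError("n_assayed smaller than the truth set")

    p = cand["p"].to_numpy(dtype=float)
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    true_sorted = is_true[order]
    cum_tp = np.cumsum(true_sorted)
    cum_fp = np.cumsum(~true_sorted)
    # last index of each distinct p (calls are inclusive: p <= t)
    last = np.nonzero(np.r_[p_sorted[1:] != p_sorted[:-1], True])[0]
    tp = cum_tp[last]
    fp = cum_fp[last]
    fn = n_truth - tp
    tn = n_neg - fp
    mcc = matthews_correlation(tp, fp, tn, fn)
    best = int(np.argmax(mcc))  # first max = smallest threshold after sort
    i = last[best]
    return ThresholdResult(
        p_threshold=float(p_sorted[i]),
        mcc=float(mcc[best]),
        tp=int(tp[best]),
        fp=int(fp[best]),
        tn=int(tn[best]),
        fn=int(fn[best]),
    )


# ---------------------------------------------------------------------------
# Coverage floor (post-filter on tested samples)
# ---------------------------------------------------------------------------

def coverage_floor(calibration: PileupTable, percentile: float = 5.0) -> int:
    """Nearest-rank percentile of the calibration sample's merged
    (forward + reverse) per-base coverage.

    Tested-sample bases with coverage strictly below the returned value
    are flagged LOW_COVERAGE; a base exactly at the floor is retained.
    """
    depths = calibration.collapsed_depth().to_numpy()
    if len(depths) == 0:
        raise CalibrationError("empty calibration table")
    depths = np.sort(depths)
    rank = max(1, math.ceil(percentile / 100.0 * len(depths)))
    return int(depths[rank - 1])


# ---------------------------------------------------------------------------
# Systematic-noise mask from control samples
# ---------------------------------------------------------------------------

@dataclass
class NoiseMask:
    """Positions recurrently noisy across independent control samples."""

    positions: set = field(default_factory=set)
    table: pd.DataFrame | None = None

    def __contains__(self, key) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self, path: str | Path) -> None:
        df = self.table if self.table is not None else pd.DataFrame(
            sorted(self.positions), columns=["chrom", "pos"]
        )
        out = df.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(path, sep="\t", index=False)


def _control_noisy_positions(
    control: PileupTable, window: int, alpha: float, min_flank: int
) -> set[tuple[str, int]]:
    df = control.df
    ref_idx = df["ref"].map(BASE_INDEX).to_numpy()
    mat = df[COUNT_COLS].to_numpy()
    nonref = df["depth"].to_numpy() - mat[np.arange(len(df)), ref_idx]
    work = pd.DataFrame(
        {
            "amplicon_id": df["amplicon_id"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "depth": df["depth"],
            "nonref": nonref,
        }
    )
    merged = (
        work.groupby(["amplicon_id", "chrom", "pos"], as_index=False)[["depth", "nonref"]]
        .sum()
        .sort_values(["amplicon_id", "pos"], kind="mergesort")
    )
    noisy: set[tuple[str, int]] = set()
    for _, grp in merged.groupby("amplicon_id", sort=False):
        n = grp["depth"].to_numpy(dtype=np.int64)
        x = grp["nonref"].to_numpy(dtype=np.int64)
        L = len(grp)
        cum_n = np.r_[0, np.cumsum(n)]
        cum_x = np.r_[0, np.cumsum(x)]
        chroms = grp["chrom"].to_numpy()
        poss = grp["pos"].to_numpy()
        for i in range(L):
            lo = max(0, i - window)
            hi = min(L, i + window + 1)
            left = i - lo
            right = hi - i - 1
            if left < min_flank or right < min_flank:
                continue  # unassessable near the amplicon edge
            local_n = (cum_n[hi] - cum_n[lo]) - n[i]
            local_x = (cum_x[hi] - cum_x[lo]) - x[i]
            if local_n == 0 or n[i] == 0:
                continue
            rate = local_x / local_n
            if x[i] == 0:
                continue  # p = 1
            if rate <= 0:
                # any mismatch against a zero local background is noise
                p = 0.0
            else:
                p = binomial_tail_pvalue(int(x[i]), int(n[i]), min(rate, 1 - 1e-12))
            if p < alpha:
                noisy.add((chroms[i], int(poss[i])))
    return noisy


def detect_systematic_noise(
    controls: Sequence[PileupTable],
    window: int = 10,
    alpha: float = 5e-4,
    min_recurrence: int = 3,
    min_flank: int = 5,
) -> NoiseMask:
    """Mask positions whose own mismatch count is binomially improbable
    against the local error rate (pooled non-reference fraction of up to
    ``window`` flanking positions each side, truncated at amplicon
    edges) in at least ``min_recurrence`` control samples.

    ``alpha`` is the per-position significance level, already corrected
    for the number of tests in one amplicon.
    """
    controls = list(controls)
    if len(controls) < min_recurrence:
        raise CalibrationError(
            f"{len(controls)} control samples cannot support min_recurrence="
            f"{min_recurrence}; lower min_recurrence explicitly if intended"
        )
    counts: dict[tuple[str, int], int] = {}
    rows = []
    for ctrl in controls:
        for key in _control_noisy_positions(ctrl, window, alpha, min_flank):
            counts[key] = counts.get(key, 0) + 1
    masked = {k for k, v in counts.items() if v >= min_recurrence}
    for (chrom, pos), v in sorted(counts.items()):
        rows.append((chrom, pos, v, v >= min_recurrence))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "n_controls_noisy", "masked"])
    return NoiseMask(positions=masked, table=table)


# ---------------------------------------------------------------------------
# Performance evaluation
# ---------------------------------------------------------------------------

def evaluate_performance(
    calls: pd.DataFrame,
    truth: TruthSet,
    n_assayed: int,
    pileup: PileupTable | None = None,
) -> dict:
    """Confusion metrics of a call set against a truth set.

    Returns overall and per-expected-prevalence sensitivity, PPV,
    specificity over assayed non-truth bases, the Pearson correlation of
    expected vs observed prevalence among detected truth variants, and
    (when a pileup is supplied) amplicon-wise coverage uniformity — the
    fraction of amplicons whose mean coverage lies within 0.5x and 2x of
    the grand mean.
    """
    truth_alleles = truth.alleles()
    prev_map = truth.prevalence_of()
    called_keys = list(zip(calls["chrom"], calls["pos"], calls["alt"]))
    is_tp = np.fromiter(
        (k in truth_alleles for k in called_keys), dtype=bool, count=len(calls)
    )
    tp = int(is_tp.sum())
    fp = int(len(calls) - tp)
    fn = len(truth) - tp
    n_neg = n_assayed - len(truth)
    tn = n_neg - fp

    out: dict = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / len(truth) if len(truth) else float("nan"),
        "ppv": tp / (tp + fp) if (tp + fp) else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
        "mcc": matthews_correlation(tp, fp, tn, fn),
    }

    by_prev: dict[float, float] = {}
    truth_prev = truth.df["prevalence"].to_numpy()
    called_set = {k for k, hit in zip(called_keys, is_tp) if hit}
    for level in sorted(set(np.round(truth_prev, 10))):
        sel = np.isclose(truth_prev, level)
        keys = list(
            zip(
                truth.df["chrom"].to_numpy()[sel],
                truth.df["pos"].to_numpy()[sel],
                truth.df["alt"].to_numpy()[sel],
            )
        )
        found = sum(k in called_set for k in keys)
        by_prev[float(level)] = found / len(keys)
    out["sensitivity_by_prevalence"] = by_prev

    detected = [(prev_map[k], obs) for k, obs, hit in zip(
        called_keys, calls["prevalence"], is_tp
    ) if hit]
    if len(detected) >= 2:
        exp_v = np.array([d[0] for d in detected])
        obs_v = np.array([d[1] for d in detected])
        if np.std(exp_v) > 0 and np.std(obs_v) > 0:
            out["pearson_r"] = float(np.corrcoef(exp_v, obs_v)[0, 1])
        else:
            out["pearson_r"] = float("nan")
    else:
        out["pearson_r"] = float("nan")
    out["n_detected_truth"] = tp

    if pileup is not None and len(pileup.df):
        amp_mean = pileup.df.groupby("amplicon_id")["depth"].mean()
        grand = amp_mean.mean()
        out["coverage_uniformity"] = float(
            ((amp_mean >= 0.5 * grand) & (amp_mean <= 2 * grand)).mean()
        )
    return out
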