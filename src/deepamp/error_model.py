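"""Empirical sequencing-error model trained on a calibration sample.

The error rate of sequencing-by-synthesis depends on the position within
the read, the read direction, and the substitution type (reference base
-> observed base; 4 x 3 = 12 types per direction).  Because every base of
an amplicon sits at a fixed read position, these rates can be estimated
directly from the invariant bases of a calibration sample: positions that
are not known polymorphisms, show at most a small non-reference fraction,
and are adequately covered.

Bins whose depth falls below the average bin depth borrow information
from neighbouring read positions: neighbours at distance d contribute
with weight n_j * r_j, where n_j is the neighbour's depth and
r_j = 1/(d+1) (1 for the bin itself, 1/2 and 1/3 for the first and
second neighbours).  Neighbours are accumulated symmetrically outward
until the summed depth exceeds the average, and the smoothed rate is the
normalised weighted mean

    E_k = sum_j e_j n_j r_j / sum_j n_j r_j.

Empty strata fall back to a floor rate (half the smallest positive
smoothed rate in the model), which also bounds every rate away from zero
so the downstream binomial test is always well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pileup import BASES, BASE_INDEX, COUNT_COLS, PileupTable

log = logging.getLogger(__name__)

N_READ_POS = 122
DEFAULT_FLOOR = 1e-9


class ErrorModelError(ValueError):
    pass


@dataclass
class ErrorModel:
    """Smoothed error rates keyed by (direction, read_pos, ref, alt).

    Arrays are indexed ``[direction, read_pos, ref, alt]`` with direction
    0 = F, 1 = R, read_pos 1..122 (index 0 unused), and bases in ACGT
    order.  ``rates`` is total over its key domain: every off-diagonal
    entry is a usable rate in (0, 1), empty bins having been filled with
    ``floor_rate``.
    """

    rates: np.ndarray           # smoothed E
    raw_rates: np.ndarray       # e (NaN where depth == 0)
    mismatches: np.ndarray
    depths: np.ndarray
    avg_bin_depth: float
    floor_rate: float
    sample_id: str = ""

    DIRECTIONS = ("F", "R")

    def rate(self, direction: str, read_pos, ref, alt):
        """Vectorised lookup of the smoothed rate E."""
        di = 0 if direction == "F" else 1
        rp = np.asarray(read_pos)
        ri = np.asarray([BASE_INDEX[b] for b in np.atleast_1d(ref)])
        ai = np.asarray([BASE_INDEX[b] for b in np.atleast_1d(alt)])
        out = self.rates[di, rp, ri, ai]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for di, direction in enumerate(self.DIRECTIONS):
            for rp in range(1, N_READ_POS + 1):
                for ri, ref in enumerate(BASES):
                    for ai, alt in enumerate(BASES):
                        if ai == ri:
                            continue
                        rows.append(
                            (
                                direction,
                                rp,
                                ref,
                                alt,
                                int(self.mismatches[di, rp, ri, ai]),
                                int(self.depths[di, rp, ri, ai]),
                                self.raw_rates[di, rp, ri, ai],
                                self.rates[di, rp, ri, ai],
                            )
                        )
        return pd.DataFrame(
            rows,
            columns=[
                "direction",
                "read_pos",
                "ref",
                "alt",
                "mismatches",
                "depth",
                "raw_rate",
                "smoothed_rate",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ErrorModel":
        df = pd.read_csv(path, sep="\t", dtype={"direction": str, "ref": str, "alt": str})
        shape = (2, N_READ_POS + 1, 4, 4)
        rates = np.zeros(shape)
        raw = np.full(shape, np.nan)
        mism = np.zeros(shape, dtype=np.int64)
        dep = np.zeros(shape, dtype=np.int64)
        di = (df["direction"] == "R").astype(int).to_numpy()
        rp = df["read_pos"].to_numpy()
        ri = df["ref"].map(BASE_INDEX).to_numpy()
        ai = df["alt"].map(BASE_INDEX).to_numpy()
        rates[di, rp, ri, ai] = df["smoothed_rate"].to_numpy()
        raw[di, rp, ri, ai] = df["raw_rate"].to_numpy()
        mism[di, rp, ri, ai] = df["mismatches"].to_numpy()
        dep[di, rp, ri, ai] = df["depth"].to_numpy()
        positive = rates[rates > 0]
        floor = float(positive.min() / 1.0) if positive.size else DEFAULT_FLOOR
        avg = float(dep.sum() / (2 * N_READ_POS * 12))
        return cls(rates, raw, mism, dep, avg, floor)


# ---------------------------------------------------------------------------
# Step 1a: invariant-site selection
# ---------------------------------------------------------------------------

def collect_invariant_sites(
    table: PileupTable,
    mask: set[tuple[str, int]],
    max_alt_frac: float = 0.05,
    min_depth: int = 10,
) -> PileupTable:
    """Restrict a calibration pileup to invariant training sites.

    Drops every masked (known-polymorphic) position regardless of signal,
    every column with non-reference fraction strictly greater than
    ``max_alt_frac`` (likely unannotated SNP or upstream PCR error), and
    every column covered by fewer than ``min_depth`` reads.
    """
    df = table.df
    if len(df) == 0:
        raise ErrorModelError("empty pileup table: cannot collect invariant sites")
    keys = list(zip(df["chrom"], df["pos"]))
    masked = np.fromiter((k in mask for k in keys), dtype=bool, count=len(df))
    mat = df[COUNT_COLS].to_numpy()
    ref_idx = df["ref"].map(BASE_INDEX).to_numpy()
    ref_count = mat[np.arange(len(df)), ref_idx]
    depth = df["depth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(depth > 0, (depth - ref_count) / depth, 0.0)
    keep = (~masked) & (alt_frac <= max_alt_frac) & (depth >= min_depth)
    out = df[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ErrorModelError("no invariant sites survive filtering: cannot train")
    return PileupTable(out, table.sample_id, dict(table.meta))


# ---------------------------------------------------------------------------
# Step 1b: raw per-bin rates
# ---------------------------------------------------------------------------

def estimate_raw_error_rates(invariant: PileupTable) -> pd.DataFrame:
    """Aggregate invariant columns into (direction, read_pos, ref, alt) bins.

    Returns one row per bin over the full 2 x 122 x 12 domain with summed
    mismatch and depth counts; ``raw_rate`` is NaN for empty bins.
    """
    df = invariant.df
    if len(df) == 0:
        raise ErrorModelError("empty invariant table")
    mism = np.zeros((2, N_READ_POS + 1, 4, 4), dtype=np.int64)
    dep = np.zeros((2, N_READ_POS + 1, 4, 4), dtype=np.int64)
    di = (df["direction"] == "R").astype(int).to_numpy()
    rp = df["read_pos"].to_numpy()
    ri = df["ref"].map(BASE_INDEX).to_numpy()
    mat = df[COUNT_COLS].to_numpy()
    depth = df["depth"].to_numpy()
    for ai in range(4):
        sel = ri != ai
        np.add.at(mism, (di[sel], rp[sel], ri[sel], np.full(sel.sum(), ai)), mat[sel, ai])
        np.add.at(dep, (di[sel], rp[sel], ri[sel], np.full(sel.sum(), ai)), depth[sel])
    rows = []
    for d_i, direction in enumerate(ErrorModel.DIRECTIONS):
        for k in range(1, N_READ_POS + 1):
            for r_i, ref in enumerate(BASES):
                for a_i, alt in enumerate(BASES):
                    if a_i == r_i:
                        continue
                    n = int(dep[d_i, k, r_i, a_i])
                    x = int(mism[d_i, k, r_i, a_i])
                    rows.append(
                        (direction, k, ref, alt, x, n, x / n if n > 0 else np.nan)
                    )
    return pd.DataFrame(
        rows,
        columns=["direction", "read_pos", "ref", "alt", "mismatches", "depth", "raw_rate"],
    )


# ---------------------------------------------------------------------------
# Step 1c: smoothing
# ---------------------------------------------------------------------------

def _smooth_stratum(e: np.ndarray, n: np.ndarray, avg_depth: float) -> np.ndarray:
    """Smooth one (direction, ref, alt) stratum across read positions.

    ``e`` and ``n`` are length-123 arrays (index 0 unused).  Positions at
    or above the average depth keep their raw rate; the rest average
    outward neighbours with weights n_j / (|j-k|+1) until the accumulated
    depth exceeds the average.
    """
    E = np.full_like(e, np.nan, dtype=float)
    for k in range(1, N_READ_POS + 1):
        if n[k] >= avg_depth and n[k] > 0:
            E[k] = e[k]
            continue
        js = [k]
        total = n[k]
        d = 1
        while total <= avg_depth and (k - d >= 1 or k + d <= N_READ_POS):
            for j in (k - d, k + d):
                if 1 <= j <= N_READ_POS:
                    js.append(j)
                    total += n[j]
            d += 1
        num = den = 0.0
        for j in js:
            if n[j] > 0:
                r = 1.0 / (abs(j - k) + 1)
                num += e[j] * n[j] * r
                den += n[j] * r
        E[k] = num / den if den > 0 else np.nan
    return E


def smooth_error_rates(
    bins: pd.DataFrame, avg_depth: float | None = None, sample_id: str = ""
) -> ErrorModel:
    """Build the final error model from raw bins.

    ``avg_depth`` defaults to the mean depth over the full bin domain
    (2 directions x 122 read positions x 12 substitution types).
    """
    shape = (2, N_READ_POS + 1, 4, 4)
    raw = np.full(shape, np.nan)
    mism = np.zeros(shape, dtype=np.int64)
    dep = np.zeros(shape, dtype=np.int64)
    di = (bins["direction"] == "R").astype(int).to_numpy()
    rp = bins["read_pos"].to_numpy()
    ri = bins["ref"].map(BASE_INDEX).to_numpy()
    ai = bins["alt"].map(BASE_INDEX).to_numpy()
    raw[di, rp, ri, ai] = bins["raw_rate"].to_numpy()
    mism[di, rp, ri, ai] = bins["mismatches"].to_numpy()
    dep[di, rp, ri, ai] = bins["depth"].to_numpy()

    if avg_depth is None:
        avg_depth = float(dep.sum() / (2 * N_READ_POS * 12))

    rates = np.zeros(shape)
    n_empty_strata = 0
    for d_i in range(2):
        for r_i in range(4):
            for a_i in range(4):
                if a_i == r_i:
                    continue
                e = np.nan_to_num(raw[d_i, :, r_i, a_i], nan=0.0)
                n = dep[d_i, :, r_i, a_i].astype(float)
                if n.sum() == 0:
                    n_empty_strata += 1
                    rates[d_i, 1:, r_i, a_i] = np.nan
                    continue
                rates[d_i, :, r_i, a_i] = _smooth_stratum(e, n, avg_depth)

    if n_empty_strata:
        warnings.warn(
            f"{n_empty_strata} substitution strata had no data; filled with floor rate"
        )

    flat = rates[:, 1:, :, :]
    positive = flat[np.isfinite(flat) & (flat > 0)]
    floor = float(positive.min() / 2) if positive.size else DEFAULT_FLOOR
    # The floor both fills empty bins and bounds observed-zero bins away
    # from a degenerate zero rate.
    for d_i in range(2):
        for r_i in range(4):
            for a_i in range(4):
                if a_i == r_i:
                    continue
                col = rates[d_i, 1:, r_i, a_i]
                col[~np.isfinite(col) | (col < floor)] = floor
                rates[d_i, 1:, r_i, a_i] = col
    return ErrorModel(
        rates=rates,
        raw_rates=raw,
        mismatches=mism,
        depths=dep,
        avg_bin_depth=float(avg_depth),
        floor_rate=floor,
        sample_id=sample_id,
    )


def train_error_model(
    table: PileupTable,
    mask: set[tuple[str, int]],
    max_alt_frac: float = 0.05,
    min_depth: int = 10,
) -> ErrorModel:
    """Convenience wrapper: invariant-site selection, binning, smoothing."""
    invariant = collect_invariant_sites(table, mask, max_alt_frac, min_depth)
    bins = estimate_raw_error_rates(invariant)
    return smooth_error_rates(bins, sample_id=table.sample_id)
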