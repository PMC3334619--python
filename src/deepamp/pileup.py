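"""Per-direction pileup tables: construction from alignments, TSV I/O,
and binomial downsampling.

A pileup column counts, for one (amplicon, read direction, genomic
position), the A/C/G/T base calls with PHRED quality strictly greater
than the cutoff.  Forward- and reverse-read observations of the same
genomic base are kept as separate columns because sequencing-by-synthesis
error depends strongly on the position within the read, which differs
between the two directions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .design import AmpliconDesign

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COUNT_COLS = ["count_A", "count_C", "count_G", "count_T"]
PILEUP_COLUMNS = [
    "amplicon_id",
    "direction",
    "chrom",
    "pos",
    "read_pos",
    "ref",
    *COUNT_COLS,
    "depth",
]


class PileupError(ValueError):
    """Raised for invalid pileup tables or inconsistent inputs."""


@dataclass
class PileupTable:
    """Collection of pileup columns keyed by (amplicon_id, direction, pos).

    ``df`` columns: amplicon_id, direction ('F'|'R'), chrom, pos (0-based
    internally), read_pos (1-based position within the sequencing read),
    ref, count_A..count_T, depth.  ``meta`` records provenance (source
    file, trim length, quality cutoff).
    """

    df: pd.DataFrame
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self) -> "PileupTable":
        df = self.df
        missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise PileupError(f"missing pileup columns: {missing}")
        sums = df[COUNT_COLS].sum(axis=1)
        bad = df.index[sums.to_numpy() != df["depth"].to_numpy()]
        if len(bad):
            raise PileupError(
                f"depth != sum of counts at row {bad[0]} "
                f"(amplicon {df.loc[bad[0], 'amplicon_id']}, "
                f"pos {df.loc[bad[0], 'pos'] + 1})"
            )
        trim = self.meta.get("trim_len", 122)
        rp = df["read_pos"].to_numpy()
        if len(rp) and (rp.min() < 1 or rp.max() > trim):
            raise PileupError(f"read_pos outside [1,{trim}]")
        if df.duplicated(subset=["amplicon_id", "direction", "pos"]).any():
            raise PileupError("duplicate (amplicon_id, direction, pos) key")
        return self

    @property
    def mean_depth(self) -> float:
        return float(self.df["depth"].mean())

    def collapsed_depth(self) -> pd.Series:
        """Base-wise coverage with forward and reverse reads merged,
        indexed by (chrom, pos)."""
        return self.df.groupby(["chrom", "pos"])["depth"].sum()

    def sorted(self) -> "PileupTable":
        df = self.df.sort_values(
            ["amplicon_id", "direction", "pos"], kind="mergesort"
        ).reset_index(drop=True)
        return PileupTable(df, self.sample_id, dict(self.meta))


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "amplicon_id": pd.Series(dtype=str),
            "direction": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "read_pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            **{c: pd.Series(dtype=np.int64) for c in COUNT_COLS},
            "depth": pd.Series(dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_pileup_tsv(table: PileupTable, path: str | Path) -> None:
    """Write a pileup table; positions become 1-based in the file."""
    df = table.sorted().df.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_pileup_tsv(path: str | Path, sample_id: str = "") -> PileupTable:
    """Read the TSV dialect written by :func:`write_pileup_tsv`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "amplicon_id": str,
            "direction": str,
            "chrom": str,
            "ref": str,
        },
    )
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise PileupError(f"{path}: missing columns {missing}")
    df["pos"] = df["pos"].astype(np.int64) - 1
    table = PileupTable(df, sample_id=sample_id or str(path), meta={"source": str(path)})
    return table.validate().sorted()


# ---------------------------------------------------------------------------
# Pileup construction from alignments
# ---------------------------------------------------------------------------

def _reference_lookup(reference) -> Callable[[str, int], str] | None:
    if reference is None:
        return None
    if callable(reference):
        return reference
    if isinstance(reference, Mapping):
        def lookup(chrom: str, pos: int) -> str:
            seq = reference[chrom]
            return str(seq[pos]).upper()
        return lookup
    raise TypeError("reference must be None, a callable, or a chrom->sequence mapping")


def build_pileup(
    alignments: str | Path | pysam.AlignmentFile,
    designs: Iterable[AmpliconDesign],
    reference=None,
    min_quality: int = 20,
    trim_len: int = 122,
    start_tolerance: int = 0,
    sample_id: str = "",
) -> PileupTable:
    """Build a per-direction pileup from single-end alignments.

    Reads with gapped alignments (any insertion or deletion) are excluded
    entirely.  Each remaining read is assigned to the amplicon and
    direction whose derived sequencing start matches the read's alignment
    start (within ``start_tolerance`` bases; forward reads are matched on
    their leftmost aligned coordinate, reverse reads on their rightmost).
    Reads are trimmed to ``trim_len`` sequencing cycles and only base
    calls with quality strictly greater than ``min_quality`` are counted.

    ``reference`` supplies the reference base per column (mapping
    chrom -> sequence, or callable (chrom, pos) -> base).  When omitted,
    the majority base of each column is used as the reference, which is
    adequate for germline-free high-depth data but is logged as a caveat.
    """
    designs = list(designs)
    own_handle = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own_handle = True

    design_chroms = {d.chrom for d in designs}
    if alignments.references and not design_chroms.intersection(alignments.references):
        raise PileupError(
            "no design chromosome found among alignment references "
            f"({sorted(design_chroms)} vs {list(alignments.references)[:5]}...)"
        )

    fwd_index: dict[tuple[str, int], AmpliconDesign] = {}
    rev_index: dict[tuple[str, int], AmpliconDesign] = {}
    for d in designs:
        fwd_index[(d.chrom, d.fwd_read_start)] = d
        rev_index[(d.chrom, d.rev_read_start)] = d

    def assign(chrom: str, anchor: int, index) -> AmpliconDesign | None:
        for delta in range(-start_tolerance, start_tolerance + 1):
            hit = index.get((chrom, anchor + delta))
            if hit is not None:
                return hit
        return None

    counts: dict[tuple[str, str, int], np.ndarray] = {}
    readpos: dict[tuple[str, str, int], int] = {}
    refbase: dict[tuple[str, str, int], str] = {}
    chrom_of: dict[tuple[str, str, int], str] = {}
    lookup = _reference_lookup(reference)

    n_gapped = n_unassigned = n_used = 0
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        cigar = read.cigartuples or []
        if any(op in (1, 2, 3) for op, _ in cigar):  # I, D, N
            n_gapped += 1
            continue
        chrom = read.reference_name
        if read.is_reverse:
            d = assign(chrom, read.reference_end - 1, rev_index)
            direction = "R"
        else:
            d = assign(chrom, read.reference_start, fwd_index)
            direction = "F"
        if d is None:
            n_unassigned += 1
            continue
        n_used += 1
        seq = read.query_sequence
        quals = read.query_qualities
        qlen = len(seq)
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            # read_pos counts sequencing cycles from the read's true start;
            # for reverse-strand alignments the stored query is the reverse
            # complement of the sequenced read.
            rp = (qlen - qpos) if read.is_reverse else (qpos + 1)
            if rp > trim_len:
                continue
            if quals is not None and quals[qpos] <= min_quality:
                continue
            base = seq[qpos].upper()
            if base not in BASE_INDEX:
                continue
            key = (d.amplicon_id, direction, rpos)
            if key not in counts:
                counts[key] = np.zeros(4, dtype=np.int64)
                readpos[key] = rp
                chrom_of[key] = chrom
            counts[key][BASE_INDEX[base]] += 1

    if own_handle:
        alignments.close()

    if n_unassigned:
        log.info("build_pileup: %d reads unassigned to any amplicon start", n_unassigned)
    if n_used == 0:
        warnings.warn("build_pileup: no reads assigned to any amplicon; empty table")
        return PileupTable(
            _empty_frame(),
            sample_id=sample_id,
            meta={"trim_len": trim_len, "min_quality": min_quality},
        )

    for key, c in counts.items():
        if lookup is not None:
            refbase[key] = lookup(chrom_of[key], key[2])
        else:
            refbase[key] = BASES[int(np.argmax(c))]
    if lookup is None:
        log.info("build_pileup: reference not supplied; using majority base per column")

    rows = {
        "amplicon_id": [k[0] for k in counts],
        "direction": [k[1] for k in counts],
        "chrom": [chrom_of[k] for k in counts],
        "pos": np.array([k[2] for k in counts], dtype=np.int64),
        "read_pos": np.array([readpos[k] for k in counts], dtype=np.int64),
        "ref": [refbase[k] for k in counts],
    }
    mat = np.vstack(list(counts.values()))
    for i, c in enumerate(COUNT_COLS):
        rows[c] = mat[:, i]
    rows["depth"] = mat.sum(axis=1)
    table = PileupTable(
        pd.DataFrame(rows),
        sample_id=sample_id,
        meta={
            "trim_len": trim_len,
            "min_quality": min_quality,
            "n_gapped": n_gapped,
            "n_unassigned": n_unassigned,
            "n_used": n_used,
        },
    )
    return table.validate().sorted()


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_pileup(
    table: PileupTable, target_mean_depth: float, seed: int
) -> PileupTable:
    """Thin every count by an independent binomial draw so the mean depth
    approaches ``target_mean_depth``.

    Column-level binomial thinning is distributionally equivalent to
    sampling reads uniformly for any per-column count statistic, at a
    fraction of the cost.  Deterministic for a fixed seed.
    """
    if target_mean_depth <= 0:
        raise ValueError("target_mean_depth must be positive")
    if len(table.df) == 0:
        raise PileupError("cannot downsample an empty pileup table")
    p = target_mean_depth / table.mean_depth
    if p >= 1.0:
        if p > 1.0:
            warnings.warn(
                f"target mean depth {target_mean_depth} exceeds current mean "
                f"{table.mean_depth:.1f}; retention probability capped at 1"
            )
        return PileupTable(table.df.copy(), table.sample_id, dict(table.meta))
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    mat = df[COUNT_COLS].to_numpy()
    thinned = rng.binomial(mat, p)
    df[COUNT_COLS] = thinned
    df["depth"] = thinned.sum(axis=1)
    meta = dict(table.meta)
    meta["downsampled_to"] = target_mean_depth
    return PileupTable(df, table.sample_id, meta)
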