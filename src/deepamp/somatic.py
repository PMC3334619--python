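"""Somatic status assignment by tumor/germline comparison, and removal of
cross-species artifacts in xenograft samples.

A statistically significant tumor variant is labelled SOMATIC only when
the matched germline sample is informative and clean at that position:
covered by more than 10 reads, not itself called variant, and showing
less than a 20% alternative allelic ratio (the ratio criterion catches
obvious germline variants that failed the statistical assessment).
Xenograft samples additionally carry false positives from co-amplified
host (mouse) DNA; calls at known host/graft genome mismatch positions
are relabelled HOST_MISMATCH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .design import AmpliconDesign
from .pileup import BASE_INDEX, COUNT_COLS, PileupTable

log = logging.getLogger(__name__)

STATUS_SOMATIC = "SOMATIC"
STATUS_GERMLINE = "GERMLINE_EVIDENCE"
STATUS_UNASSESSABLE = "UNASSESSABLE"
STATUS_HOST_MISMATCH = "HOST_MISMATCH"


def call_somatic(
    tumor_calls: pd.DataFrame,
    germline_pileup: PileupTable,
    germline_calls: pd.DataFrame,
    min_germline_depth: int = 10,
    max_germline_ratio: float = 0.20,
) -> pd.DataFrame:
    """Label each tumor call SOMATIC / GERMLINE_EVIDENCE / UNASSESSABLE.

    The germline must be analysed with the same design and calibration
    artifacts as the tumor.  A call is UNASSESSABLE when the germline
    covers the position with ``min_germline_depth`` reads or fewer (or
    not at all); GERMLINE_EVIDENCE when the germline was itself called
    variant there or shows an alternative allelic ratio of at least
    ``max_germline_ratio``; otherwise SOMATIC.  The germline ratio is
    the candidate allele's pooled (forward + reverse) fraction.
    """
    gdf = germline_pileup.df
    depth_by_pos = gdf.groupby(["chrom", "pos"])["depth"].sum()
    alt_counts = {}
    mat = gdf[COUNT_COLS].to_numpy()
    for i, (chrom, pos) in enumerate(zip(gdf["chrom"], gdf["pos"])):
        acc = alt_counts.setdefault((chrom, pos), np.zeros(4, dtype=np.int64))
        acc += mat[i]

    germline_called = set(
        zip(germline_calls["chrom"], germline_calls["pos"], germline_calls["alt"])
    ) if len(germline_calls) else set()

    out = tumor_calls.copy()
    g_depth = np.zeros(len(out), dtype=np.int64)
    g_ratio = np.full(len(out), np.nan)
    g_called = np.zeros(len(out), dtype=bool)
    status = np.empty(len(out), dtype=object)
    for i, (chrom, pos, alt) in enumerate(zip(out["chrom"], out["pos"], out["alt"])):
        key = (chrom, pos)
        if key not in depth_by_pos.index:
            status[i] = STATUS_UNASSESSABLE
            continue
        depth = int(depth_by_pos.loc[key])
        g_depth[i] = depth
        if depth <= min_germline_depth:
            status[i] = STATUS_UNASSESSABLE
            continue
        ratio = alt_counts[key][BASE_INDEX[alt]] / depth
        g_ratio[i] = ratio
        g_called[i] = (chrom, pos, alt) in germline_called
        if g_called[i] or ratio >= max_germline_ratio:
            status[i] = STATUS_GERMLINE
        else:
            status[i] = STATUS_SOMATIC
    out["germline_depth"] = g_depth
    out["germline_alt_ratio"] = g_ratio
    out["germline_called"] = g_called
    out["status"] = status
    return out


# ---------------------------------------------------------------------------
# Cross-species mask
# ---------------------------------------------------------------------------

@dataclass
class CrossSpeciesMask:
    """Positions where host and graft reference genomes mismatch within
    the assayed amplicons (graft-genome coordinates)."""

    positions: set = field(default_factory=set)

    def __contains__(self, key) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def load_cross_species_mask(
    path: str | Path, designs: Iterable[AmpliconDesign]
) -> CrossSpeciesMask:
    """Load a (chrom, pos) TSV of host/graft mismatch positions, 1-based,
    restricted to the assayed amplicons; out-of-design rows are dropped
    with a warning and duplicates are collapsed."""
    designs = list(designs)
    positions: set[tuple[str, int]] = set()
    n_outside = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos_s = line.split("\t")[:2]
            pos = int(pos_s) - 1
            inside = any(
                d.chrom == chrom and d.amplicon_start <= pos < d.amplicon_end
                for d in designs
            )
            if inside:
                positions.add((chrom, pos))
            else:
                n_outside += 1
    if n_outside:
        log.warning(
            "cross-species mask: %d positions outside all amplicons dropped", n_outside
        )
    return CrossSpeciesMask(positions=positions)


def filter_cross_species(calls: pd.DataFrame, mask: CrossSpeciesMask) -> pd.DataFrame:
    """Relabel calls at host/graft mismatch positions as HOST_MISMATCH.

    Exact-position semantics: a call one base away from a masked position
    is untouched.
    """
    out = calls.copy()
    if len(out) == 0:
        return out
    hit = np.fromiter(
        ((c, p) in mask for c, p in zip(out["chrom"], out["pos"])),
        dtype=bool,
        count=len(out),
    )
    if "status" not in out.columns:
        out["status"] = STATUS_SOMATIC
    out.loc[hit, "status"] = STATUS_HOST_MISMATCH
    return out


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_STATUS_TO_FILTER = {
    STATUS_SOMATIC: "PASS",
    STATUS_GERMLINE: "GERMLINE",
    STATUS_UNASSESSABLE: "UNASSESSABLE",
    STATUS_HOST_MISMATCH: "HOST_MISMATCH",
}


def _vcf_header(designs: Iterable[AmpliconDesign]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chrom_max: dict[str, int] = {}
    for d in designs:
        chrom_max[d.chrom] = max(chrom_max.get(d.chrom, 0), d.amplicon_end + 1)
    for chrom, length in sorted(chrom_max.items()):
        header.contigs.add(chrom, length=length)
    header.filters.add("GERMLINE", None, None, "Germline evidence for the variant")
    header.filters.add("UNASSESSABLE", None, None, "Germline coverage 10 reads or fewer")
    header.filters.add("HOST_MISMATCH", None, None, "Host/graft genome mismatch position")
    header.filters.add("SUB_THRESHOLD_PREVALENCE", None, None,
                       "Prevalence below the reporting threshold")
    header.info.add("PREV", 1, "Float", "Estimated prevalence (pooled alt fraction)")
    header.info.add("PCOMB", 1, "Float", "Combined p-value (depth-weighted Stouffer)")
    header.info.add("DPF", 1, "Integer", "Forward-read depth")
    header.info.add("DPR", 1, "Integer", "Reverse-read depth")
    header.info.add("XF", 1, "Integer", "Forward-read alt count")
    header.info.add("XR", 1, "Integer", "Reverse-read alt count")
    header.info.add("GDP", 1, "Integer", "Germline depth")
    header.info.add("GAR", 1, "Float", "Germline alternative allelic ratio")
    return header


def write_vcf(
    calls: pd.DataFrame,
    path: str | Path,
    designs: Iterable[AmpliconDesign],
    min_prevalence: float = 0.0,
) -> None:
    """Write calls as VCF 4.2; rows are sorted by (chrom, pos).

    Rows with a ``status`` column are translated to FILTER values
    (SOMATIC -> PASS).  Rows without one are PASS when their prevalence
    meets ``min_prevalence`` and SUB_THRESHOLD_PREVALENCE otherwise.
    """
    designs = list(designs)
    header = _vcf_header(designs)
    df = calls.sort_values(["chrom", "pos"], kind="mergesort")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in df.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=int(row.pos),
                stop=int(row.pos) + 1,
                alleles=(row.ref, row.alt),
            )
            if hasattr(row, "status"):
                rec.filter.add(_STATUS_TO_FILTER[row.status])
            elif row.prevalence >= min_prevalence:
                rec.filter.add("PASS")
            else:
                rec.filter.add("SUB_THRESHOLD_PREVALENCE")
            rec.info["PREV"] = float(row.prevalence)
            if hasattr(row, "p") and np.isfinite(row.p):
                rec.info["PCOMB"] = float(row.p)
            rec.info["DPF"] = int(row.N_f)
            rec.info["DPR"] = int(row.N_r)
            rec.info["XF"] = int(row.X_f)
            rec.info["XR"] = int(row.X_r)
            if hasattr(row, "germline_depth"):
                rec.info["GDP"] = int(row.germline_depth)
                if np.isfinite(row.germline_alt_ratio):
                    rec.info["GAR"] = float(row.germline_alt_ratio)
            vcf.write(rec)
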