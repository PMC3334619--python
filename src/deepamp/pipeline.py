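"""Workflow orchestration: calibrate -> call -> evaluate.

These functions are thin compositions of the library modules.  Each can
persist its artifacts to an output directory so that calibration (error
model, threshold, coverage floor, noise mask) is reusable across runs of
the same sequencing batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import calling
from .calibration import (
    NoiseMask,
    ThresholdResult,
    coverage_floor,
    detect_systematic_noise,
    evaluate_performance,
    select_threshold,
)
from .calling import CallResult, call_variants
from .design import AmpliconDesign
from .error_model import ErrorModel, train_error_model
from .pileup import PileupTable, downsample_pileup
from .somatic import write_vcf
from .truth import TruthSet

log = logging.getLogger(__name__)

#: printed defaults for every tunable constant of the procedure
DEFAULTS = {
    "min_quality": 20,            # PHRED cutoff, strict >
    "trim_len": 122,              # sequencing cycles used per read
    "train_max_alt_frac": 0.05,   # invariant-site screen
    "train_min_depth": 10,        # invariant-site screen
    "min_alt_frac": 0.002,        # filter 2: pooled non-ref fraction floor
    "max_read_pos_single": 100,   # filter 3: single-direction read-end cut
    "coverage_floor_percentile": 5.0,   # filter 5
    "noise_window": 10,           # filter 7: flanking positions per side
    "noise_alpha": 5e-4,          # filter 7: corrected per-position level
    "noise_min_recurrence": 3,    # filter 7: controls required
    "min_prevalence_report": 0.05,  # VCF PASS reporting floor
}


def n_assayed_bases(designs: Iterable[AmpliconDesign], trim_len: int = 122) -> int:
    """Number of assessable target bases: non-primer positions reachable
    by at least one trimmed read, counted per amplicon (overlapping
    amplicons are kept separate)."""
    return sum(len(d.covered_target_positions(trim_len)) for d in designs)


@dataclass
class CalibrationArtifacts:
    model: ErrorModel
    threshold: ThresholdResult
    coverage_floor_depth: int
    noise_mask: NoiseMask | None = None
    n_assayed: int = 0

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.to_tsv(outdir / "error_model.tsv")
        payload = {
            "p_threshold": self.threshold.p_threshold,
            "mcc": self.threshold.mcc,
            "confusion": self.threshold.confusion(),
            "coverage_floor_depth": self.coverage_floor_depth,
            "n_assayed": self.n_assayed,
        }
        (outdir / "calibration.json").write_text(json.dumps(payload, indent=2) + "\n")
        if self.noise_mask is not None:
            self.noise_mask.to_tsv(outdir / "noise_mask.tsv")

    @classmethod
    def load(cls, outdir: str | Path) -> "CalibrationArtifacts":
        outdir = Path(outdir)
        model = ErrorModel.from_tsv(outdir / "error_model.tsv")
        payload = json.loads((outdir / "calibration.json").read_text())
        thr = ThresholdResult(
            p_threshold=payload["p_threshold"],
            mcc=payload["mcc"],
            **payload["confusion"],
        )
        mask = None
        mask_path = outdir / "noise_mask.tsv"
        if mask_path.exists():
            df = pd.read_csv(mask_path, sep="\t", dtype={"chrom": str})
            df["pos"] = df["pos"] - 1
            masked = df[df["masked"]] if "masked" in df else df
            mask = NoiseMask(set(zip(masked["chrom"], masked["pos"])), table=df)
        return cls(
            model=model,
            threshold=thr,
            coverage_floor_depth=payload["coverage_floor_depth"],
            noise_mask=mask,
            n_assayed=payload["n_assayed"],
        )


def run_calibrate(
    calibration: PileupTable,
    truth: TruthSet,
    designs: Sequence[AmpliconDesign],
    controls: Sequence[PileupTable] | None = None,
    outdir: str | Path | None = None,
    **params,
) -> CalibrationArtifacts:
    """Train the error model on the calibration sample, pick the MCC
    threshold from its known SNPs, derive the coverage floor, and (when
    control samples are given) the systematic-noise mask."""
    if len(truth) == 0:
        raise ValueError("calibration truth set is empty")
    p = {**DEFAULTS, **params}
    model = train_error_model(
        calibration,
        truth.masked_positions,
        max_alt_frac=p["train_max_alt_frac"],
        min_depth=p["train_min_depth"],
    )
    self_result = call_variants(
        calibration,
        designs,
        model,
        min_alt_frac=p["min_alt_frac"],
        max_read_pos_single=p["max_read_pos_single"],
    )
    n_assayed = n_assayed_bases(designs, p["trim_len"])
    threshold = select_threshold(self_result.best, truth, n_assayed)
    floor = coverage_floor(calibration, p["coverage_floor_percentile"])
    mask = None
    if controls:
        mask = detect_systematic_noise(
            controls,
            window=p["noise_window"],
            alpha=p["noise_alpha"],
            min_recurrence=p["noise_min_recurrence"],
        )
    log.info(
        "calibration: threshold=%.3g mcc=%.3f floor=%d filters=%s",
        threshold.p_threshold,
        threshold.mcc,
        floor,
        self_result.accounting,
    )
    artifacts = CalibrationArtifacts(
        model=model,
        threshold=threshold,
        coverage_floor_depth=floor,
        noise_mask=mask,
        n_assayed=n_assayed,
    )
    if outdir is not None:
        artifacts.save(outdir)
    return artifacts


def run_call(
    sample: PileupTable,
    designs: Sequence[AmpliconDesign],
    artifacts: CalibrationArtifacts,
    outdir: str | Path | None = None,
    min_prevalence_report: float | None = None,
    **params,
) -> CallResult:
    """Call variants in a tested sample using calibration artifacts.

    The returned ``calls`` contain every threshold-passing variant;
    ``min_prevalence_report`` only governs which records are PASS in the
    emitted VCF (sub-threshold-prevalence calls are written with a
    FILTER reason).
    """
    p = {**DEFAULTS, **params}
    if min_prevalence_report is None:
        min_prevalence_report = p["min_prevalence_report"]
    result = call_variants(
        sample,
        designs,
        artifacts.model,
        threshold=artifacts.threshold.p_threshold,
        coverage_floor_depth=artifacts.coverage_floor_depth,
        noise_mask=artifacts.noise_mask.positions if artifacts.noise_mask else None,
        min_alt_frac=p["min_alt_frac"],
        max_read_pos_single=p["max_read_pos_single"],
    )
    log.info("call: %s", result.accounting)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(
            result.calls, outdir / "calls.vcf", designs, min_prevalence=min_prevalence_report
        )
        dump = result.candidates.copy()
        dump["pos"] = dump["pos"] + 1
        dump.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        (outdir / "filter_accounting.json").write_text(
            json.dumps(result.accounting, indent=2) + "\n"
        )
    return result


def run_evaluate(
    designs: Sequence[AmpliconDesign],
    pools: Sequence[tuple[TruthSet, PileupTable]],
    ladder: Sequence[float] | None = None,
    seed: int = 0,
    include_self_pairs: bool = False,
    **params,
) -> pd.DataFrame:
    """Evaluate performance over ordered (calibration, tested) pool pairs.

    With a downsampling ``ladder``, both members of each pair are
    binomially thinned to every ladder depth and the calibration is
    re-trained at that depth, mimicking a lower multiplexed coverage.
    Returns one row per (pair, depth level) with the confusion metrics.
    """
    if len(pools) < 2 and not include_self_pairs:
        raise ValueError("need at least two pools (or include_self_pairs=True)")
    rows = []
    levels = [None] + list(ladder or [])
    for i, (truth_cal, table_cal) in enumerate(pools):
        for j, (truth_test, table_test) in enumerate(pools):
            if i == j and not include_self_pairs:
                continue
            for level in levels:
                if level is None:
                    cal, test = table_cal, table_test
                else:
                    cal = downsample_pileup(table_cal, level, seed=seed + 1000 * i + j)
                    test = downsample_pileup(
                        table_test, level, seed=seed + 1000 * i + j + 500
                    )
                artifacts = run_calibrate(cal, truth_cal, designs, **params)
                result = run_call(test, designs, artifacts, **params)
                metrics = evaluate_performance(
                    result.calls, truth_test, artifacts.n_assayed, pileup=test
                )
                row = {
                    "calibration": i,
                    "tested": j,
                    "depth_level": level if level is not None else test.mean_depth,
                    "full_depth": level is None,
                    "p_threshold": artifacts.threshold.p_threshold,
                    **{
                        k: v
                        for k, v in metrics.items()
                        if not isinstance(v, dict)
                    },
                }
                for prev, sens in metrics["sensitivity_by_prevalence"].items():
                    row[f"sens_{prev:g}"] = sens
                rows.append(row)
    return pd.DataFrame(rows)
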