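"""Truth sets: known-variant positions with expected prevalences.

A truth set serves two roles: it masks known polymorphic positions out
of error-model training, and it provides the labelled positives (with
expected prevalence) against which the significance threshold is chosen
and performance is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "prevalence"]


class TruthError(ValueError):
    pass


@dataclass
class TruthSet:
    """Mapping position -> (ref, alt, expected prevalence).

    ``df`` columns: chrom, pos (0-based internally), ref, alt,
    prevalence in (0, 1]; an optional boolean ``sub_detectable`` marks
    positions whose expected prevalence sits below the assay's design
    floor.  ``masked_positions`` holds every position to exclude from
    error-rate training — it is a superset of the truth positions
    (typically all positions polymorphic in any contributing donor).
    """

    df: pd.DataFrame
    masked_positions: set = field(default_factory=set)

    def __post_init__(self) -> None:
        prev = self.df["prevalence"]
        if len(self.df) and ((prev <= 0).any() or (prev > 1).any()):
            raise TruthError("expected prevalences must lie in (0, 1]")
        self.masked_positions = set(self.masked_positions) | set(self.positions())

    def positions(self) -> set[tuple[str, int]]:
        return set(zip(self.df["chrom"], self.df["pos"]))

    def alleles(self) -> set[tuple[str, int, str]]:
        return set(zip(self.df["chrom"], self.df["pos"], self.df["alt"]))

    def prevalence_of(self) -> dict[tuple[str, int, str], float]:
        return {
            (c, p, a): float(v)
            for c, p, a, v in zip(
                self.df["chrom"], self.df["pos"], self.df["alt"], self.df["prevalence"]
            )
        }

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["pos"] = out["pos"] + 1
        cols = [c for c in out.columns if c in TRUTH_COLUMNS + ["sub_detectable"]]
        out.to_csv(path, sep="\t", index=False, columns=cols)

    @classmethod
    def from_tsv(cls, path: str | Path, masked_positions=()) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
        if missing:
            raise TruthError(f"{path}: missing columns {missing}")
        df["pos"] = df["pos"].astype(int) - 1
        return cls(df, set(masked_positions))
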