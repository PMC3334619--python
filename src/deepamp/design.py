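"""Amplicon design table: parsing, validation and coordinate arithmetic.

An amplicon is a short PCR product (~200 bp including primers) sequenced
directly from both ends with single-end reads, so every genomic base of an
amplicon always falls at the same position of the sequencing read.  The
design table records, per amplicon, the target interval and the two primer
spans; the genomic coordinates at which forward and reverse sequencing
begin are derived from the primer spans (reads start at the outer primer
edge and run inward).

Coordinates are 0-based half-open internally and 1-based inclusive in
files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

DESIGN_COLUMNS = [
    "amplicon_id",
    "chrom",
    "target_start",
    "target_end",
    "fwd_primer_start",
    "fwd_primer_end",
    "rev_primer_start",
    "rev_primer_end",
]


class DesignError(ValueError):
    """Raised for malformed or geometrically inconsistent design rows."""


@dataclass(frozen=True)
class AmpliconDesign:
    """One amplicon: target interval plus flanking primer spans.

    All intervals are 0-based half-open.  ``fwd_primer_span`` must lie
    entirely left of the target, ``rev_primer_span`` entirely right of it;
    the two spans must not overlap each other.
    """

    amplicon_id: str
    chrom: str
    target_start: int
    target_end: int
    fwd_primer_span: tuple[int, int]
    rev_primer_span: tuple[int, int]
    overlapping: bool = False

    def __post_init__(self) -> None:
        f0, f1 = self.fwd_primer_span
        r0, r1 = self.rev_primer_span
        if not (f0 < f1 and r0 < r1):
            raise DesignError(f"{self.amplicon_id}: empty primer span")
        if not self.target_start < self.target_end:
            raise DesignError(f"{self.amplicon_id}: empty target interval")
        if f1 > self.target_start:
            raise DesignError(
                f"{self.amplicon_id}: forward primer span [{f0},{f1}) "
                f"overlaps or follows target start {self.target_start}"
            )
        if r0 < self.target_end:
            raise DesignError(
                f"{self.amplicon_id}: reverse primer span [{r0},{r1}) "
                f"overlaps or precedes target end {self.target_end}"
            )
        if f1 > r0:
            raise DesignError(f"{self.amplicon_id}: primer spans overlap")

    # -- derived coordinates -------------------------------------------------

    @property
    def amplicon_start(self) -> int:
        return self.fwd_primer_span[0]

    @property
    def amplicon_end(self) -> int:
        return self.rev_primer_span[1]

    @property
    def fwd_read_start(self) -> int:
        """Genomic coordinate of the first sequenced base of forward reads."""
        return self.amplicon_start

    @property
    def rev_read_start(self) -> int:
        """Genomic coordinate (0-based) of the first sequenced base of
        reverse reads, i.e. the rightmost base of the amplicon."""
        return self.amplicon_end - 1

    @property
    def target_length(self) -> int:
        return self.target_end - self.target_start

    def in_primer(self, pos: int) -> bool:
        f0, f1 = self.fwd_primer_span
        r0, r1 = self.rev_primer_span
        return f0 <= pos < f1 or r0 <= pos < r1

    def read_pos(self, pos: int, direction: str, trim_len: int = 122) -> int | None:
        """Read position (1-based, <= trim_len) of genomic ``pos`` in the
        given direction, or None if the trimmed read does not reach it."""
        if direction == "F":
            rp = pos - self.fwd_read_start + 1
        elif direction == "R":
            rp = self.rev_read_start - pos + 1
        else:
            raise ValueError(f"direction must be 'F' or 'R', got {direction!r}")
        return rp if 1 <= rp <= trim_len else None

    def covered_target_positions(self, trim_len: int = 122) -> list[int]:
        """Target positions reachable by at least one trimmed read."""
        return [
            p
            for p in range(self.target_start, self.target_end)
            if self.read_pos(p, "F", trim_len) is not None
            or self.read_pos(p, "R", trim_len) is not None
        ]


def flag_overlaps(designs: Iterable[AmpliconDesign]) -> list[AmpliconDesign]:
    """Mark amplicons whose target intervals overlap another amplicon's.

    Overlapping amplicons are legitimate and analysed separately; the flag
    exists for reporting only.
    """
    designs = list(designs)
    out = []
    for i, d in enumerate(designs):
        ov = any(
            j != i
            and e.chrom == d.chrom
            and e.target_start < d.target_end
            and d.target_start < e.target_end
            for j, e in enumerate(designs)
        )
        out.append(dataclasses.replace(d, overlapping=ov))
    return out


def load_design(path: str | Path) -> list[AmpliconDesign]:
    """Load a tab-separated amplicon design table.

    The file carries one '#'-prefixed header line followed by one row per
    amplicon with columns ``amplicon_id chrom target_start target_end
    fwd_primer_start fwd_primer_end rev_primer_start rev_primer_end``,
    coordinates 1-based inclusive.
    """
    designs: list[AmpliconDesign] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(DESIGN_COLUMNS):
                raise DesignError(
                    f"{path}:{lineno}: expected {len(DESIGN_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            amplicon_id, chrom = fields[0], fields[1]
            try:
                ts, te, f0, f1, r0, r1 = (int(x) for x in fields[2:])
            except ValueError as exc:
                raise DesignError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
            try:
                designs.append(
                    AmpliconDesign(
                        amplicon_id=amplicon_id,
                        chrom=chrom,
                        # 1-based inclusive -> 0-based half-open
                        target_start=ts - 1,
                        target_end=te,
                        fwd_primer_span=(f0 - 1, f1),
                        rev_primer_span=(r0 - 1, r1),
                    )
                )
            except DesignError as exc:
                raise DesignError(f"{path}:{lineno}: {exc}") from None
    return flag_overlaps(designs)


def write_design(designs: Iterable[AmpliconDesign], path: str | Path) -> None:
    """Write designs in the 1-based inclusive TSV dialect read by load_design."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DESIGN_COLUMNS) + "\n")
        for d in designs:
            f0, f1 = d.fwd_primer_span
            r0, r1 = d.rev_primer_span
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        d.amplicon_id,
                        d.chrom,
                        d.target_start + 1,
                        d.target_end,
                        f0 + 1,
                        f1,
                        r0 + 1,
                        r1,
                    )
                )
                + "\n"
            )
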