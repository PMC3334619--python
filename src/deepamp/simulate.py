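"""Synthetic amplicon pileups with known truth.

The generator emulates the data a multiplexed-amplicon ultra-deep
sequencing run produces, at the level the statistics consume: per
(amplicon, direction, genomic position) base-count columns.  It covers

* calibration pools — four donor genomes mixed at 1%/5%/20%/74%, each
  pool permuting which donor sits at which proportion, with ~200 known
  SNPs (homozygous-alternate in exactly one donor) spread across the
  amplicons so that every expected prevalence is represented at varied
  read positions;
* stratified error profiles — substitution-, direction- and
  read-position-dependent rates, with a GAII-like preset (rates rising
  along the read and inflating ~3x after cycle 100 for A/T reference
  bases) and a flatter MiSeq-like preset;
* coverage dispersion — per-amplicon lognormal efficiencies shared
  between samples of a run (amplicon PCR efficiency is a property of the
  primer pair, hence reproducible across samples) plus smaller
  per-sample noise; the default dispersion places ~82% of amplicons
  within 0.5-2x of the mean;
* optional host-DNA contamination at given positions and a whole-genome
  amplification (WGA) bias knob that attenuates low expected prevalences.

Pileups are simulated at column level (counts, not reads); read-position
semantics are preserved because every column carries its read position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import AmpliconDesign, flag_overlaps
from .pileup import BASES, BASE_INDEX, COUNT_COLS, PileupTable
from .truth import TruthSet

N_READ_POS = 122
DEFAULT_PROPORTIONS = (
    Fraction(1, 100),
    Fraction(5, 100),
    Fraction(20, 100),
    Fraction(74, 100),
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Error profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorProfile:
    """Per-(direction, read position, ref, alt) substitution rate field.

    ``rates`` is indexed [direction, read_pos, ref, alt] (direction
    0 = F, read_pos 1..122, bases ACGT; the diagonal is zero).  Presets
    are plausibility models of sequencing-by-synthesis error, not
    measurements of any particular instrument.
    """

    name: str
    rates: np.ndarray

    # baseline per-substitution rates: transitions above transversions,
    # oxidative-damage-like C>A / G>T slightly elevated
    _BASE = {
        ("A", "G"): 1.1e-3, ("G", "A"): 1.0e-3,
        ("C", "T"): 1.2e-3, ("T", "C"): 1.0e-3,
        ("C", "A"): 8e-4, ("G", "T"): 9e-4,
        ("A", "C"): 5e-4, ("A", "T"): 5e-4,
        ("C", "G"): 5e-4, ("G", "C"): 6e-4,
        ("T", "A"): 5e-4, ("T", "G"): 6e-4,
    }

    @classmethod
    def _build(
        cls,
        name: str,
        scale: float,
        slope: float,
        end_factor: float,
        end_onset: int,
        end_refs: str,
    ) -> "ErrorProfile":
        rates = np.zeros((2, N_READ_POS + 1, 4, 4))
        rp = np.arange(1, N_READ_POS + 1)
        trend = 1.0 + slope * (rp - 1) / (N_READ_POS - 1)
        for (ref, alt), base in cls._BASE.items():
            ri, ai = BASE_INDEX[ref], BASE_INDEX[alt]
            for di, dir_scale in enumerate((1.0, 1.15)):
                r = base * scale * dir_scale * trend
                if ref in end_refs and end_factor > 1:
                    r = np.where(rp > end_onset, r * end_factor, r)
                rates[di, 1:, ri, ai] = np.clip(r, 1e-6, 0.049)
        return cls(name=name, rates=rates)

    @classmethod
    def gaii(cls) -> "ErrorProfile":
        """GAII-like: rates rise along the read and inflate 3x after
        cycle 100 for A/T reference bases."""
        return cls._build("gaii", scale=1.0, slope=1.3, end_factor=3.0,
                          end_onset=100, end_refs="AT")

    @classmethod
    def miseq(cls) -> "ErrorProfile":
        """MiSeq-like: lower, flatter rates with no late-cycle inflation."""
        return cls._build("miseq", scale=0.55, slope=0.5, end_factor=1.0,
                          end_onset=100, end_refs="")

    @classmethod
    def flat(cls, rate: float) -> "ErrorProfile":
        """Uniform rate for every substitution, direction and position
        (diagnostic profile)."""
        rates = np.zeros((2, N_READ_POS + 1, 4, 4))
        for ri in range(4):
            for ai in range(4):
                if ai != ri:
                    rates[:, 1:, ri, ai] = rate
        return cls(name=f"flat({rate})", rates=rates)

    @classmethod
    def zero(cls) -> "ErrorProfile":
        return cls(name="zero", rates=np.zeros((2, N_READ_POS + 1, 4, 4)))


# ---------------------------------------------------------------------------
# Design, reference and calibration pools
# ---------------------------------------------------------------------------

def make_design(
    n_amplicons: int = 150,
    target_len: int = 160,
    primer_len: int = 20,
    gap: int = 50,
    chrom: str = "chrSim",
) -> list[AmpliconDesign]:
    """A synthetic tiling design: ``n_amplicons`` non-overlapping
    amplicons of ``target_len`` + 2 x ``primer_len`` bases (~200 bp).

    With 122-cycle reads every target base is reachable from at least
    one direction.
    """
    designs = []
    start = 1000
    amp_len = target_len + 2 * primer_len
    for i in range(n_amplicons):
        a0 = start + i * (amp_len + gap)
        designs.append(
            AmpliconDesign(
                amplicon_id=f"amp{i:04d}",
                chrom=chrom,
                target_start=a0 + primer_len,
                target_end=a0 + primer_len + target_len,
                fwd_primer_span=(a0, a0 + primer_len),
                rev_primer_span=(a0 + primer_len + target_len, a0 + amp_len),
            )
        )
    return flag_overlaps(designs)


def make_reference(designs: Iterable[AmpliconDesign], seed: int) -> dict[str, np.ndarray]:
    """Random reference base indices per chromosome covering all amplicons."""
    rng = np.random.default_rng(seed)
    ref: dict[str, np.ndarray] = {}
    for d in designs:
        length = d.amplicon_end + 10
        if d.chrom not in ref or len(ref[d.chrom]) < length:
            old = ref.get(d.chrom)
            arr = rng.integers(0, 4, size=length)
            if old is not None:
                arr[: len(old)] = old
            ref[d.chrom] = arr
    return ref


@dataclass
class PoolSpec:
    """Mixing specification for one calibration pool.

    ``genotypes`` has one row per candidate SNP with columns chrom, pos,
    ref, alt, and ``dosage_i`` (0/1/2 alternate-allele copies) for each
    donor i; ``proportions`` are the donors' mixing fractions and must
    sum to 1.
    """

    genotypes: pd.DataFrame
    proportions: Sequence[Fraction | float]

    @property
    def n_donors(self) -> int:
        return len(self.proportions)


def make_pool(spec: PoolSpec, detection_floor: float = 0.01) -> TruthSet:
    """Expected prevalence per position: sum_i proportion_i * dosage_i / 2,
    computed in exact rational arithmetic.

    Positions with prevalence 0 are dropped (non-truth); positions below
    ``detection_floor`` are retained but flagged ``sub_detectable``.
    All genotyped positions are masked for error-model training whether
    or not they are polymorphic in this particular pool.
    """
    props = [Fraction(p).limit_denominator(10**9) for p in spec.proportions]
    if sum(props) != 1:
        total = float(sum(props))
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"mixing proportions sum to {total}, not 1")
    rows = []
    for row in spec.genotypes.itertuples(index=False):
        prev = sum(
            props[i] * Fraction(int(getattr(row, f"dosage_{i}")), 2)
            for i in range(spec.n_donors)
        )
        if prev > 0:
            rows.append((row.chrom, row.pos, row.ref, row.alt, float(prev)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "prevalence"])
    df["sub_detectable"] = df["prevalence"] < detection_floor
    masked = set(zip(spec.genotypes["chrom"], spec.genotypes["pos"]))
    return TruthSet(df, masked_positions=masked)


def make_calibration_pools(
    designs: Sequence[AmpliconDesign],
    reference: Mapping[str, np.ndarray],
    n_snps: int = 200,
    proportions: Sequence[Fraction | float] = DEFAULT_PROPORTIONS,
    n_pools: int = 4,
    seed: int = 0,
) -> list[TruthSet]:
    """Four-donor calibration pools with rotated mixing proportions.

    ``n_snps`` positions are drawn uniformly from the read-coverable
    target bases; SNP j is homozygous-alternate in donor j mod 4 and
    homozygous-reference in the others, so each pool shows ~n_snps/4
    SNPs at each proportion.  Pool k assigns donor d the proportion at
    index (d + k) mod n_donors, mirroring a permuted mixing design.
    """
    rng = np.random.default_rng(seed)
    n_donors = len(proportions)
    coverable = [
        (d.chrom, p) for d in designs for p in d.covered_target_positions()
    ]
    if n_snps > len(coverable):
        raise SimulationError("more SNPs requested than coverable target bases")
    idx = rng.choice(len(coverable), size=n_snps, replace=False)
    geno_rows = []
    for j, i in enumerate(sorted(idx)):
        chrom, pos = coverable[i]
        ref = BASES[int(reference[chrom][pos])]
        alt = rng.choice([b for b in BASES if b != ref])
        dosages = [0] * n_donors
        dosages[j % n_donors] = 2
        geno_rows.append((chrom, pos, ref, alt, *dosages))
    genotypes = pd.DataFrame(
        geno_rows,
        columns=["chrom", "pos", "ref", "alt"] + [f"dosage_{i}" for i in range(n_donors)],
    )
    pools = []
    for k in range(n_pools):
        rotated = [proportions[(d + k) % n_donors] for d in range(n_donors)]
        pools.append(make_pool(PoolSpec(genotypes, rotated)))
    return pools


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

def amplicon_efficiencies(
    designs: Sequence[AmpliconDesign], dispersion: float = 0.52, seed: int = 0
) -> dict[str, float]:
    """Per-amplicon lognormal PCR efficiencies (mean 1), shared by every
    sample of a simulated run.  ``dispersion`` is the lognormal sigma;
    0.52 places roughly 82% of amplicons within 0.5-2x of the mean."""
    rng = np.random.default_rng(seed)
    effs = np.exp(rng.normal(0.0, dispersion, size=len(designs)) - dispersion**2 / 2)
    return {d.amplicon_id: float(e) for d, e in zip(designs, effs)}


def simulate_pileup(
    designs: Sequence[AmpliconDesign],
    reference: Mapping[str, np.ndarray],
    truth: TruthSet | None,
    profile: ErrorProfile,
    mean_depth: float,
    seed: int,
    efficiencies: Mapping[str, float] | None = None,
    dispersion: float = 0.52,
    sample_sigma: float = 0.15,
    sample_id: str = "sim",
) -> PileupTable:
    """Simulate one sample's per-direction pileup.

    Per (amplicon, direction) the depth is ``mean_depth`` times the
    amplicon's efficiency times per-sample and per-direction lognormal
    noise; each column's counts are a multinomial draw from the mixture
    (1 - prevalence) x error-row(ref) + prevalence x error-row(alt).
    Deterministic for a fixed seed.
    """
    if mean_depth <= 0:
        raise SimulationError("mean_depth must be positive")
    designs = list(designs)
    if efficiencies is None:
        efficiencies = amplicon_efficiencies(designs, dispersion, seed=seed + 7919)
    prev_map = truth.prevalence_of() if truth is not None else {}
    if truth is not None:
        covered = {
            (d.chrom, p) for d in designs
            for p in range(d.amplicon_start, d.amplicon_end)
        }
        outside = truth.positions() - covered
        if outside:
            raise SimulationError(
                f"{len(outside)} truth positions fall outside the design"
            )

    rng = np.random.default_rng(seed)
    amp_ids, dirs, chroms, poss, rps, ref_idx = [], [], [], [], [], []
    depths = []
    for d in designs:
        eff = efficiencies[d.amplicon_id]
        sample_f = np.exp(rng.normal(0, sample_sigma) - sample_sigma**2 / 2)
        for di, direction in enumerate("FR"):
            dir_f = np.exp(rng.normal(0, 0.05))
            depth = max(1, int(round(mean_depth * eff * sample_f * dir_f)))
            for rp in range(1, N_READ_POS + 1):
                pos = (
                    d.fwd_read_start + rp - 1
                    if direction == "F"
                    else d.rev_read_start - rp + 1
                )
                if not (d.amplicon_start <= pos < d.amplicon_end):
                    continue
                amp_ids.append(d.amplicon_id)
                dirs.append(direction)
                chroms.append(d.chrom)
                poss.append(pos)
                rps.append(rp)
                ref_idx.append(int(reference[d.chrom][pos]))
                depths.append(depth)

    n = len(poss)
    ref_idx = np.asarray(ref_idx)
    rps_a = np.asarray(rps)
    dir_idx = np.asarray([0 if x == "F" else 1 for x in dirs])
    depths = np.asarray(depths)

    err = profile.rates[dir_idx, rps_a, :, :]          # (n, 4, 4) rows by true base
    rows_ref = err[np.arange(n), ref_idx, :]           # (n, 4)
    probs = rows_ref.copy()
    probs[np.arange(n), ref_idx] = 0.0
    probs[np.arange(n), ref_idx] = 1.0 - probs.sum(axis=1)

    theta = np.zeros(n)
    alt_idx = np.zeros(n, dtype=int)
    has_var = np.zeros(n, dtype=bool)
    for i, (chrom, pos) in enumerate(zip(chroms, poss)):
        for ai, alt in enumerate(BASES):
            th = prev_map.get((chrom, pos, alt))
            if th:
                theta[i] = th
                alt_idx[i] = ai
                has_var[i] = True
                break
    if has_var.any():
        sel = np.nonzero(has_var)[0]
        rows_alt = err[sel, alt_idx[sel], :]
        rows_alt = rows_alt.copy()
        rows_alt[np.arange(len(sel)), alt_idx[sel]] = 0.0
        rows_alt[np.arange(len(sel)), alt_idx[sel]] = 1.0 - rows_alt.sum(axis=1)
        probs[sel] = (1 - theta[sel, None]) * probs[sel] + theta[sel, None] * rows_alt

    counts = rng.multinomial(depths, probs)

    df = pd.DataFrame(
        {
            "amplicon_id": amp_ids,
            "direction": dirs,
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "read_pos": rps_a.astype(np.int64),
            "ref": [BASES[i] for i in ref_idx],
            **{c: counts[:, i].astype(np.int64) for i, c in enumerate(COUNT_COLS)},
            "depth": counts.sum(axis=1).astype(np.int64),
        }
    )
    table = PileupTable(
        df, sample_id=sample_id, meta={"trim_len": N_READ_POS, "profile": profile.name}
    )
    return table.validate().sorted()


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def inject_host_contamination(
    table: PileupTable,
    mask_alleles: Mapping[tuple[str, int], str],
    contamination_fraction: float,
    seed: int = 0,
) -> PileupTable:
    """Shift a binomial share of each masked column's reference counts to
    the host allele, emulating co-amplified host DNA at known host/graft
    mismatch positions."""
    if not 0 <= contamination_fraction < 1:
        raise SimulationError("contamination fraction must lie in [0, 1)")
    if contamination_fraction == 0:
        return PileupTable(table.df.copy(), table.sample_id, dict(table.meta))
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    mat = df[COUNT_COLS].to_numpy().copy()
    for i, (chrom, pos, ref) in enumerate(zip(df["chrom"], df["pos"], df["ref"])):
        host = mask_alleles.get((chrom, pos))
        if host is None or host == ref:
            continue
        ri, hi = BASE_INDEX[ref], BASE_INDEX[host]
        k = min(rng.binomial(int(df["depth"].iloc[i]), contamination_fraction), mat[i, ri])
        mat[i, ri] -= k
        mat[i, hi] += k
    df[COUNT_COLS] = mat
    df["depth"] = mat.sum(axis=1)
    return PileupTable(df, table.sample_id, dict(table.meta))


def apply_wga_bias(truth: TruthSet, bias_strength: float, seed: int = 0) -> TruthSet:
    """Attenuate low expected prevalences, emulating allele-specific bias
    of whole-genome amplification.

    Each position's prevalence is multiplied by 1 - b*u*exp(-theta/0.05)
    with u ~ Uniform(0, 1): attenuation is random, averages below 1, is
    strongest below ~5% prevalence and negligible for high-prevalence
    variants.  A stress-test knob with no quantitative fidelity claimed.
    """
    if bias_strength < 0:
        raise SimulationError("bias_strength must be >= 0")
    if bias_strength == 0:
        return TruthSet(truth.df.copy(), set(truth.masked_positions))
    rng = np.random.default_rng(seed)
    df = truth.df.copy()
    theta = df["prevalence"].to_numpy()
    u = rng.uniform(0, 1, size=len(df))
    factor = 1.0 - bias_strength * u * np.exp(-theta / 0.05)
    df["prevalence"] = np.clip(theta * np.clip(factor, 0.02, 1.0), 1e-6, 1.0)
    return TruthSet(df, set(truth.masked_positions))
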