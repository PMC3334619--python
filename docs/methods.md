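# Methods

## Setting

`deepamp` detects low-prevalence single-nucleotide variants in ultra-deep
sequencing of multiplexed PCR amplicons (~200 bp including primers,
single-end reads from both amplicon ends). Because every genomic base of
an amplicon sits at a fixed cycle of the sequencing read, the dominant
covariates of sequencing-by-synthesis error — read position, read
direction, and substitution type — can be estimated empirically and used
as the null model of a per-allele significance test. Prevalence here
means the fraction of DNA molecules carrying the variant allele (e.g. a
subclonal somatic mutation), not a population allele frequency.

## Pileup construction

Aligned single-end reads are screened: any alignment containing an
insertion or deletion is discarded entirely (the statistics model
substitutions only), reads are trimmed to 122 sequencing cycles, and
each read is assigned to the amplicon whose derived sequencing start
matches its alignment start (forward reads by leftmost coordinate,
reverse reads by rightmost; exact match by default, ±tolerance
configurable because soft-clipped starts can shift the anchor). Base
calls with PHRED quality strictly greater than 20 are tallied into
per-(amplicon, direction, position) columns. Forward and reverse
observations of the same base are deliberately kept separate: they sit
at different read positions and therefore have different error rates.

## Error model (training)

Training uses the invariant bases of a calibration sample — a pool of
reference genomes mixed at known proportions. Known polymorphic
positions are masked; remaining columns are dropped if their
non-reference fraction exceeds 0.05 (likely unannotated variant or
upstream PCR error) or their depth is below 10 reads. Mismatch and depth
counts are pooled into 2 directions × 122 read positions × 12
substitution types (4 reference bases × 3 alternatives), and the raw
rate is e = mismatches / depth per bin.

Bins below the average bin depth (mean over the full 2×122×12 domain,
empty bins counting as zero) are smoothed within their
(direction, ref, alt) stratum by accumulating neighbouring read
positions symmetrically outward (k±1, k±2, …) until the summed depth
exceeds the average, then taking the weighted mean

    E_k = Σ_j e_j · n_j · r_j / Σ_j n_j · r_j ,   r_j = 1/(|j−k|+1),

so the bin itself has weight n·1, the first neighbours n/2, the second
n/3. The normalisation makes E a proper rate and a convex combination of
the contributing raw rates; boundary positions simply skip missing
neighbours. Strata with no data fall back to a floor rate — half the
smallest positive smoothed rate in the model — and every rate is bounded
below by that floor so the binomial test is never degenerate. The model
serialises to a TSV (direction, read_pos, ref, alt, mismatches, depth,
raw and smoothed rate) for audit and reuse.

## Candidate filtering

Four prefilters run before any statistics (a filtered position counts as
not mutated):

1. **Primer positions.** Bases inside primer spans are synthetic.
2. **Minimum alternative fraction.** Positions whose pooled (F+R)
   non-reference fraction is strictly below 0.2% are removed — five-fold
   below the assay's 1% design prevalence.
3. **Read-end, single direction.** Positions covered by one direction
   only are removed when they lie more than 100 cycles from the read
   start, where error rates climb steeply.
4. **Direction rejection.** At dual-covered positions whose two
   directions disagree (operationalised as: they disagree on whether the
   candidate allele's fraction exceeds 0.2%), a direction is rejected if
   its coverage is below a tenth of the other's, or if its base sits
   further from its read start. If both rules fire (one direction each),
   the candidate is uncallable.

Every non-reference allele at a surviving position becomes a candidate
and is tested against its own (direction, read position, ref→alt) rate.

## Statistics

Per accepted direction, the p-value is the upper binomial tail
P(B ≥ X), B ~ Binomial(N, E) — inclusive of X, so X = 0 gives p = 1.
P-values are clamped to [1e-300, 1] to keep quantile transforms finite.
When both directions carry accepted evidence they are combined with a
depth-weighted Stouffer Z:

    Z = (N_f Z_f + N_r Z_r) / √(N_f² + N_r²),   Z_i = Φ⁻¹(1 − p_i),

and p = 1 − Φ(Z); a single accepted direction passes its p through
unchanged. The weights use N literally ("weighted by read depth"); √N
weighting is a documented alternative, not the default. A position's
reported variant is the allele with the smallest combined p (ties: the
larger alt count, then alphabetical). Prevalence is estimated as the
pooled alt fraction over accepted directions.

## Threshold calibration and post-filters

Nominal p-values are not used for calling. The pipeline is run on the
calibration sample itself; with calibration SNPs as positives and
invariant assayed bases as negatives, every distinct candidate p-value
is scanned as a threshold (call iff p ≤ t) and the Matthews correlation
coefficient is computed from the resulting confusion counts; the
maximising t is kept, ties resolved toward the most stringent value.
MCC suits the extreme class imbalance (~200 positives vs tens of
thousands of negatives). Three post-filters then apply to tested
samples:

- **Coverage floor**: bases whose merged (F+R) coverage falls strictly
  below the calibration sample's 5th coverage percentile (nearest-rank,
  configurable) are not assessed.
- **Threshold**: candidates with p above the calibrated threshold.
- **Systematic-noise mask**: with ≥3 germline control samples, each
  position's mismatch count is tested binomially against the local error
  rate pooled from up to 10 flanking positions per side (truncated at
  amplicon edges; at least 5 per side or the position is unassessable)
  at the amplicon-corrected level α = 5×10⁻⁴; positions noisy in three
  or more controls are masked.

## Somatic assignment and xenografts

A statistically significant tumor variant is SOMATIC only when the
matched germline covers the position with more than 10 reads, was not
itself called variant there, and shows a pooled alternative allelic
ratio below 20% (the ratio rule catches obvious germline variants that
failed the statistical test). Shallower germline coverage yields
UNASSESSABLE; otherwise GERMLINE_EVIDENCE. In xenografts, primers can
co-amplify host (mouse) DNA, so calls at known host/graft reference
mismatch positions (supplied as a precomputed position list; deriving it
from a whole-genome alignment is out of scope) are relabelled
HOST_MISMATCH. Output is VCF 4.2 (INFO: PREV, PCOMB, DPF/DPR/XF/XR,
GDP, GAR; FILTER: PASS/GERMLINE/UNASSESSABLE/HOST_MISMATCH) plus a TSV
mirror.

## Synthetic data generator

The simulator produces the data structures the statistics consume —
per-direction count columns — without modelling individual reads (the
read-position semantics survive because each column carries its read
position). It emulates:

- **Calibration pools**: four donors mixed at 1/5/20/74%, 200 SNPs
  homozygous-alternate in exactly one donor, pools permuting which donor
  sits at which proportion; expected prevalences are exact rational
  arithmetic on dosages and proportions (50 SNPs per prevalence level
  per pool).
- **Error profiles**: substitution-specific base rates (transitions
  above transversions, 0.05–0.3% range), rising along the read; the
  GAII-like preset inflates rates 3× after cycle 100 for A/T reference
  bases, the MiSeq-like preset is lower and flat. These are plausibility
  presets, not measurements of either instrument.
- **Coverage dispersion**: per-amplicon lognormal PCR efficiencies
  (σ = 0.52, placing ~82% of amplicons within 0.5–2× of the mean) that
  are shared between samples of a run — amplification efficiency is a
  property of the primer pair and is reproducible across samples — plus
  smaller per-sample (σ = 0.15) and per-direction (σ = 0.05) noise.
- **Perturbations**: host-DNA contamination (binomial share of reference
  counts moved to the host allele at masked positions) and a
  whole-genome-amplification bias knob that randomly attenuates low
  expected prevalences (strongly below ~5%, negligibly at 74%) — a
  stress-test device with no quantitative fidelity claimed.

What the simulator does **not** emulate: PCR jackpot/recurrent artefact
noise, alignment errors, GC- or context-dependent systematic noise, and
overdispersion beyond binomial sampling. Passing tests therefore
demonstrate the statistical machinery under clean, correctly-specified
noise; real-data performance additionally depends on the systematic-
noise mask and on error structure the clean model lacks. One visible
consequence: at very low coverage (750×) the MCC threshold stretches to
capture marginal 1%-prevalence SNPs that real-world noise would have
made inseparable, so the simulated positive predictive value at 750×
(~0.90–0.99 across seeds) can fall below what was achievable on real
data, while simulated sensitivity is correspondingly higher.

## Numerical and design choices

- Internal coordinates are 0-based half-open; all files are 1-based
  inclusive.
- Downsampling thins every count with an independent Binomial(count, p)
  draw, p = target/current mean depth — distributionally equivalent to
  read sampling for column statistics and far cheaper. The multiplexing
  ladder thins the calibration pool too and retrains at each level, so
  threshold and coverage floor always match the tested sample's depth.
- The 5% minimum-prevalence reporting floor applies to VCF PASS
  labelling of clinical samples only; calibration experiments evaluate
  all threshold-passing calls (the pools contain 1% SNPs by design).
- The threshold scan is exactly equivalent to a brute-force cut-point
  scan (verified against one in the tests); sorting plus cumulative
  sums make it O(m log m).
- Seeds: all randomness flows through explicitly passed
  `numpy.random.default_rng` generators; fixed seed ⇒ byte-identical
  outputs end to end.
- Desk-scale problem sizes used throughout the test-suite experiments:
  150 amplicons × ~200 bp, 200 truth SNPs, 24,000× mean per-direction
  coverage, ladder at 12,000/6,000/3,000/1,500/750× — the full two-pool
  experiment plus ladder runs in well under a minute on one core.

## Known limitations

Indels are out of scope (gapped reads are excluded at pileup time).
Multi-allelic positions are reported by their best allele only. The
cross-species mask is consumed, not derived. Base-quality recalibration
and quality-conditioned error models are not implemented; the error
model conditions on read position, direction and substitution type
only.
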