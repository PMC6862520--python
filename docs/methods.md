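# Methods

## The measurement model

A digital PCR chip splits a reaction into `N ≈ 20,000` wells of volume
`Vp`. If a target is present at concentration `C` copies/µL in the loaded
reaction, molecules land in wells approximately independently, so the number
per well is Poisson with mean occupancy `λ = C·Vp/D` (`D` = dilution factor
applied during sample preparation) and a well amplifies (is "positive") iff
it received at least one molecule:

    p = P(positive) = 1 − e^(−λ)

Quantification inverts this at the observed positive fraction `p̂ = P/N`:

    λ̂ = −ln(1 − P/N),     T̂ = (D/Vp)·λ̂   [copies/µL]

Each chip is a duplex: two targets reported by different dyes (FAM, VIC),
called per well by the instrument, giving four well categories (FAM-only,
VIC-only, double-positive, negative) that must sum to `N`. Channel positives
are single + double positives; double positives are treated as independent
co-loading of the two targets, consistent with the independence assumption
of the Poisson model. The chromosomal dosage ratio of a chip is the ratio of
its two channel concentrations; `Vp` and `D` cancel, so ratios are
insensitive to both. A disomic:disomic duplex has expected ratio 1; a full
trisomy over a disomic reference has expected ratio 3/2.

The assay uses three panels: chr21(FAM)+chr13(VIC), chr18(FAM)+chr13(VIC)
and SRY(FAM)+X(VIC), with chromosome 13 doubling as the reference for both
autosomal panels.

### Saturation

`P = N` makes `λ̂` infinite. The protocol targets 200–2000 copies/µL
(λ ≈ 0.16–1.6 at the default well volume) precisely to avoid this, so
saturation is treated as a hard error advising dilution, never clamped.

### Uncertainty

No interval formula is inherited from the assay software, so the package
makes two standard, testable choices:

- **Concentration CI**: Wilson score interval on `p` at the configured level
  (default 95%), mapped through the strictly monotone transform
  `p ↦ −(D/Vp)·ln(1−p)`. Wilson remains well-behaved near `p = 0` and
  `p = 1`; monotonicity means the concentration endpoints are exactly the
  transformed proportion endpoints (a tested invariant). Monte-Carlo
  coverage at `C = 1000` copies/µL, `N = 20,000` sits in [93%, 97%].
- **Ratio CI**: delta method on the log-ratio with channels independent,
  `Var(λ̂) ≈ p/((1−p)·N)` per channel. Symmetric on the log scale, so the
  interval respects `ratio > 0`.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `partition_volume_ul` | 0.000809 µL | nominal well volume of the chip platform (809 pL); ratios are Vp-invariant |
| `n_wells_default` | 20 000 | wells per chip |
| `dilution_factor` | 1 | per-chip field; the protocol adjusts DNA input rather than recording D |
| `valid_conc_range` | (200, 2000) copies/µL | validated working range; QC warns (or fails in strict mode) outside it |
| `confidence_level` | 0.95 | all intervals |
| `genome_conc` | 250 genomes/µL | simulator default, placing disomic channels at ~500 copies/µL, mid-range |
| `conc_cv` | 0.02 | per-chip lognormal loading factor CV |
| `fp_rate`, `fn_rate` | 2·10⁻⁴, 10⁻³ | per-well miscall rates ("rain") |

## Classification

Bands on the sample-level mean ratio:

- [0.9, 1.1] → **euploid**;
- ≥ 1.15 → **trisomy**; if also < 1.35 the call is flagged
  `intermediate_possible_mosaic_or_contamination` and the implied aneuploid
  fraction `f̂ = 2(ratio − 1)` is reported (1.35 sits just below the
  smallest ratio observed among full trisomies, 1.382, so genuine full
  trisomies are not flagged);
- anything else → **inconclusive**. The gap (1.1, 1.15) is deliberately a
  third class: the validated bands define euploid and aneuploid but not the
  space between, and forcing a call there would hide exactly the mosaics
  and contaminated samples the flag exists for. Ratios below 0.9 are
  likewise inconclusive with a reference-anomaly flag — autosomal monosomy
  is not a supported call.

Replicates: the sample-level ratio is the mean over QC-passing chips,
classified as above; if any two replicates individually disagree
euploid-vs-trisomy, the sample is inconclusive with a repeat-test flag.

**Chromosome 13 ratios.** Chr13 is the shared reference channel, so a
trisomic chr13 depresses the chr21:13 and chr18:13 ratios of the same
sample to ≈ 2/3. The chr13 call therefore reads chr13 against whichever
duplex partner looks euploid: against chr18 if chr18 is euploid, else
against chr21 if chr21 is euploid, else (both partners depressed — the
pure-T13 signature) as the mean of the two inverted ratios, which lands at
≈ 3/2. This reconstruction is a package design choice; the clinical
procedure only states that the analyzed chromosome is divided by the
reference.

**Sex chromosomes.** The X(VIC) concentration is normalised against the
sample's mean chr13 concentration across its autosomal chips — a cross-chip
ratio that assumes equal DNA input per chip of a sample (same extraction and
adjustment); the simulator's per-chip lognormal factor deliberately
stresses this assumption. Bands: X:autosome in [0.4, 0.6] → one X,
[0.9, 1.1] → two X, ≥ 1.4 → three or more X. SRY is "detected" at
≥ 10 copies/µL **and** ≥ 20 positive FAM wells per chip (a noise floor
chosen because no limit-of-blank is specified; at default settings a true Y
yields ≈ 4000 positive wells, so the floor only suppresses rain).
Composition: one X + SRY → XY; one X, no SRY → monosomy X; two X, no SRY →
XX; ≥ 3 X + SRY → X-polysomy with Y; anything else inconclusive. The
per-chromosome detection-limit cutoffs (1.145 / 1.077 / 1.068 for
13/18/21) are kept as configurable defaults for the dilution analysis only;
clinical calling always uses the global 1.15 threshold.

## The simulator

`simulate_chip` draws the four well categories as one multinomial with cell
probabilities built from the two channels' noisy positive probabilities —
count conservation holds by construction. A sample is a karyotype profile:
integer copy numbers per chromosome, a mosaic fraction `f` of fetal genomes
carrying the aberration, and a maternal-contamination fraction `m` of
euploid female genomes. A channel's concentration is

    C = genome_conc · [(1−m)·(base·(1−f) + cn·f) + m·maternal_cn] · L

with `maternal_cn` = 2 for autosomes and X, 0 for Y, and `L` the per-chip
lognormal factor. This yields the closed-form expectations the analysis
relies on: a trisomy mixture has expected ratio `1 + f/2`, and a fully
trisomic fetus with contamination `m` has `1 + (1−m)/2` (e.g. `m = 0.614`
reproduces an intermediate ratio of 1.193).

What the simulator deliberately does **not** model: amplification-efficiency
differences between assays, partial-volume and dead-volume effects,
correlated well failures (chip-loading artifacts), fluorescence-threshold
misclassification structure beyond i.i.d. flips, and between-sample DNA
quality variation. Passing tests therefore demonstrate the statistical
machinery under the stated model — perfect cohort separation (AUROC 1.0)
says the binomial counting noise at ~500 copies/µL on 20,000 wells is far
smaller than the euploid/trisomy gap, not that real pre-analytical failure
modes cannot produce miscalls.

## Validation statistics

- **Mann–Whitney U**: exact enumeration when the smaller group has ≤ 8
  observations and no ties; otherwise the normal approximation with tie
  correction. Small-cohort p-values here are exact and will not match a
  software package that always uses the approximation.
- **AUROC**: pair-ordering estimator (equivalently `U/(n₁·n₂)`, an asserted
  identity), percentile bootstrap CI over samples, 2000 resamples, seeded.
  Degenerate single-class resamples are skipped.
- **Dilution regression**: technical replicates are averaged per fraction,
  then observed mean ratios are regressed on theoretical ratios `1 + f/2`
  by OLS; `r² = pearson_r²` by construction. With duplicate chips, r²
  typically lands at 0.99 ± 0.01 — the binomial counting noise per chip
  (sd ≈ 0.018 on a ratio near 1) is the floor.
- **Detection limit**: smallest grid fraction whose mean replicate ratio
  exceeds the per-chromosome cutoff with every larger fraction also
  exceeding it. The default compares the mean only; a stricter mode
  requires the 95% t-interval lower bound to clear the cutoff, which with
  duplicates is very conservative (the t-quantile at 1 degree of freedom is
  12.7). The default grid is 10% steps: a 5/10/30/50/70 design cannot
  distinguish a 15% from a 20% limit, a 10%-step grid can. On noiseless
  expectations the limits are 20% (cutoff 1.068, T21), 20% (1.077, T18) and
  30% (1.145, T13); the simulated limits reproduce these.

## Problem sizes

The shipped analyses use: 133-sample cohort × 3 panels × triplicates
(1197 chips); duplicate dilution series over 7 fractions; 50–100 replicate
chips per point on the 10%-step detection-limit grid; 1000 chips for CI
coverage; 150 chips for parameter-recovery bias; 2000 bootstrap resamples
for AUROC CIs. Each driver finishes in seconds on one core.

## Known limitations

- Absolute copies/µL depend on `Vp`, which is a platform nominal rather
  than a measured value; only ratios are calibration-free.
- The euploid-maxima cutoffs used for detection limits (1.068 for chr21,
  1.077 for chr18) are below the upper euploid band edge 1.1; they are kept
  as dilution-analysis defaults exactly as configured and are not used for
  clinical calls.
- The sex-chromosome logic is a documented reconstruction (see above), not
  a validated clinical procedure; X-dose bands assume comparable loading
  across a sample's chips.
- Exact Mann–Whitney p-values for very small groups (n = 3 trisomies) are
  bounded below by `2/C(n₁+n₂, n₁)` and cannot reach arbitrary published
  values; they are reported as computed.
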