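# chipdpcr

Analysis pipeline for rapid prenatal aneuploidy screening by chip-based
digital PCR: Poisson quantification of ~20,000-well duplex chips,
chromosomal dosage-ratio calling for chromosomes 13, 18, 21, X and Y, a
synthetic chip simulator, and the validation statistics used to
characterise the assay (group comparison, ROC, dilution-series regression,
mosaicism detection limits).

**Who it is for.** Labs and method developers who have per-chip called well
counts (total wells; FAM-only / VIC-only / double-positive / negative) from
duplex digital PCR aneuploidy assays and want absolute quantification,
sample-level karyotype calls and assay-performance statistics — plus a
generative simulator to study the design (wells, replicates, concentration,
noise) before committing samples.

## The model

Each chip partitions a reaction into `N` wells; with target concentration
`C` copies/µL, well occupancy is Poisson with mean `λ = C·Vp/D` and a well
is positive with probability `1 − e^(−λ)`. Quantification inverts the
observed positive fraction `P/N`:

    T = −(D/Vp) · ln(1 − P/N)

A duplex chip carries two targets (FAM and VIC dyes); the **chromosomal
ratio** divides the analysed chromosome's concentration by the reference
chromosome's (chr13 for the autosomal panels). Euploid samples sit near 1,
full trisomies near 1.5, and a mixture with trisomic fraction `f` at
`1 + f/2`. Calling uses bands validated on clinical material: ratio in
[0.9, 1.1] → euploid, ratio ≥ 1.15 → trisomy (flagged as possible
mosaicism/contamination below 1.35), anything else inconclusive. See
`docs/methods.md` for the full model, interval methods and design choices.

## Worked example

```python
import numpy as np
from chipdpcr import (
    PANELS, RunConfig, NoiseParams, ClassificationBands,
    trisomy_profile, simulate_sample, build_sample_report,
)

config = RunConfig()                     # 20,000 wells, Vp = 809 pL
rng = np.random.default_rng(1)

# a non-mosaic trisomy-21 male fetus, triplicate chips on all three panels
profile = trisomy_profile("case1", "21", sex="male")
chips = simulate_sample(profile, list(PANELS.values()), 3,
                        config, NoiseParams(), rng)
report = build_sample_report("case1", chips, config, ClassificationBands())
for chrom, call in sorted(report.autosome_calls.items()):
    print(f"chr{chrom}: ratio {call.ratio.ratio:.3f} -> {call.call}")
print(f"sex: X:autosome {report.sex_call.x_autosome_ratio:.2f}, "
      f"SRY {report.sex_call.sry_detected} -> {report.sex_call.call}")
```

prints

```
chr13: ratio 1.000 -> euploid
chr18: ratio 1.000 -> euploid
chr21: ratio 1.489 -> trisomy
sex: X:autosome 0.49, SRY True -> XY
```

The chr21:chr13 ratio of ~1.5 is the trisomy dosage signal; the X:autosome
ratio of ~0.5 plus a detected SRY gives the XY call.

## The analysis

Numbered drivers under `analysis/` reproduce the full study on simulated
data and write their tables under `results/`:

1. `01_simulate_cohort.py` — 133-sample screening cohort (17 T21, 9 T18,
   3 T13, monosomy X, XXXY, 102 euploid), triplicate duplex chips.
2. `02_quantify_and_call.py` — Poisson quantification of all 1197 chips and
   per-sample karyotype calls; checks calls against simulator truth.
3. `03_cohort_performance.py` — Mann–Whitney comparison, AUROC with
   bootstrap CI, sensitivity/specificity at the 1.15 threshold.
4. `04_dilution_limits.py` — trisomic/euploid mixture series: observed vs
   theoretical ratio regression and mosaicism detection limits.

Each takes `--seed`; run them in order from the repository root. A thin
`chipdpcr` CLI exposes the same stages (`simulate-cohort`, `quantify`,
`call`, `evaluate`, `simulate-dilution`, `run-all`, `show-config`) for use
on external chip CSVs.

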