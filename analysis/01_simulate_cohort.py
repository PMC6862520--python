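#!/usr/bin/env python
"""Simulate the screening cohort: 133 prenatal samples on duplex dPCR chips.

Emulates the validation cohort composition — 17 trisomy 21, 9 trisomy 18,
3 trisomy 13, one monosomy X, one XXXY and 102 euploid samples — with
triplicate 20,000-well chips per duplex panel per sample and default noise
(2% chip loading CV, rare well miscalls).  Writes the chip readout CSV and
the ground-truth karyotype table that the downstream steps consume.
"""

import argparse
from collections import Counter
from pathlib import Path

from chipdpcr import CohortSpec, PipelineConfig, simulate_cohort, write_chip_csv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    cohort = simulate_cohort(cfg.cohort, cfg.run, cfg.seed)
    chips = [c for _, _, sample_chips in cohort for c in sample_chips]

    args.out.mkdir(parents=True, exist_ok=True)
    write_chip_csv(chips, args.out / "chips.csv")
    with open(args.out / "truth.tsv", "w") as fh:
        fh.write("sample_id\tkaryotype\n")
        for profile, label, _ in cohort:
            fh.write(f"{profile.sample_id}\t{label}\n")

    counts = Counter(label for _, label, _ in cohort)
    print(f"Simulated {len(cohort)} samples ({len(chips)} chips) with seed {args.seed}:")
    for label, n in sorted(counts.items()):
        print(f"  {label:16s} {n:3d}")
    print(f"Wrote {args.out / 'chips.csv'} and {args.out / 'truth.tsv'}.")


if __name__ == "__main__":
    main()
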