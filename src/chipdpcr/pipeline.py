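"""End-to-end pipeline: simulate (or load) chips -> quantify -> call -> evaluate.

All randomness flows from explicit integer seeds, so a fixed configuration
and seed reproduce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .caller import ClassificationBands, SampleReport, build_sample_report
from .core import ChipReadout, QuantResult, RunConfig, SaturationError, poisson_concentration
from .evaluate import (
    CohortEvaluation,
    DilutionSeriesResult,
    analyze_dilution_series,
    cohort_summary,
)
from .io import (
    write_chip_csv,
    write_dilution_tsv,
    write_evaluation_json,
    write_quant_csv,
    write_report_tsv,
)
from .simulate import (
    CohortSpec,
    DilutionChip,
    MixtureSpec,
    NoiseParams,
    simulate_cohort,
    simulate_dilution_series,
)

logger = logging.getLogger("chipdpcr")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "quantify_chips",
    "sample_mean_ratios",
    "dilution_ratios",
    "run_dilution_analysis",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all tunables: platform, bands, simulator noise and seed."""

    run: RunConfig = field(default_factory=RunConfig)
    bands: ClassificationBands = field(default_factory=ClassificationBands)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        run_raw = dict(raw.get("run", {}))
        if "valid_conc_range" in run_raw:
            run_raw["valid_conc_range"] = tuple(run_raw["valid_conc_range"])
        run = RunConfig(**run_raw)
        bands_raw = dict(raw.get("bands", {}))
        for key in ("x_one_band", "x_two_band"):
            if key in bands_raw:
                bands_raw[key] = tuple(bands_raw[key])
        bands = ClassificationBands(**bands_raw)
        cohort_raw = dict(raw.get("cohort", {}))
        if "noise" in cohort_raw:
            cohort_raw["noise"] = NoiseParams(**cohort_raw["noise"])
        cohort = CohortSpec(**cohort_raw)
        return cls(run=run, bands=bands, cohort=cohort, seed=int(raw.get("seed", 0)))

    def to_yaml(self) -> str:
        data = {
            "run": {
                "partition_volume_ul": self.run.partition_volume_ul,
                "n_wells_default": self.run.n_wells_default,
                "confidence_level": self.run.confidence_level,
                "valid_conc_range": list(self.run.valid_conc_range),
            },
            "bands": {
                "euploid_low": self.bands.euploid_low,
                "euploid_high": self.bands.euploid_high,
                "aneuploid_threshold": self.bands.aneuploid_threshold,
                "per_chromosome_cutoffs": dict(self.bands.per_chromosome_cutoffs),
                "typical_trisomy_low": self.bands.typical_trisomy_low,
                "x_one_band": list(self.bands.x_one_band),
                "x_two_band": list(self.bands.x_two_band),
                "x_many_min": self.bands.x_many_min,
                "sry_min_conc": self.bands.sry_min_conc,
                "sry_min_wells": self.bands.sry_min_wells,
            },
            "cohort": {
                "n_t21": self.cohort.n_t21,
                "n_t18": self.cohort.n_t18,
                "n_t13": self.cohort.n_t13,
                "n_monosomy_x": self.cohort.n_monosomy_x,
                "n_xxxy": self.cohort.n_xxxy,
                "n_euploid_male": self.cohort.n_euploid_male,
                "n_euploid_female": self.cohort.n_euploid_female,
                "replicates_per_sample": self.cohort.replicates_per_sample,
                "noise": {
                    "conc_cv": self.cohort.noise.conc_cv,
                    "fp_rate": self.cohort.noise.fp_rate,
                    "fn_rate": self.cohort.noise.fn_rate,
                },
            },
            "seed": self.seed,
        }
        return yaml.safe_dump(data, sort_keys=False)


@dataclass(frozen=True)
class PipelineResult:
    chips: Tuple[ChipReadout, ...]
    reports: Tuple[SampleReport, ...]
    truth: Dict[str, str]
    evaluation: Optional[CohortEvaluation]


def quantify_chips(
    chips: Sequence[ChipReadout], config: RunConfig
) -> List[Tuple[ChipReadout, Dict[str, QuantResult]]]:
    """Quantify both channels of every chip; saturated chips are dropped with a log entry."""
    out = []
    for chip in chips:
        try:
            out.append(
                (
                    chip,
                    {
                        "FAM": poisson_concentration(chip, "FAM", config),
                        "VIC": poisson_concentration(chip, "VIC", config),
                    },
                )
            )
        except SaturationError as exc:
            logger.warning("chip %s: %s", chip.chip_id, exc)
    return out


def sample_mean_ratios(reports: Sequence[SampleReport]) -> Dict[str, Dict[str, float]]:
    """sample_id -> {chromosome -> mean dosage ratio} for cohort evaluation."""
    return {
        rep.sample_id: {
            chrom: call.ratio.ratio for chrom, call in rep.autosome_calls.items()
        }
        for rep in reports
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir: "str | Path",
    chips: Optional[Sequence[ChipReadout]] = None,
    truth: Optional[Mapping[str, str]] = None,
) -> PipelineResult:
    """Run simulate -> quantify -> call -> evaluate and write all output files.

    If ``chips`` is given the simulation stage is skipped and evaluation runs
    only when ``truth`` labels are supplied.  Writes ``chips.csv``,
    ``quantification.csv``, ``sample_reports.tsv`` and, when truth labels
    exist, ``evaluation.json`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_map: Dict[str, str] = dict(truth or {})
    if chips is None:
        cohort = simulate_cohort(config.cohort, config.run, config.seed)
        chips = [c for _, _, sample_chips in cohort for c in sample_chips]
        truth_map = {profile.sample_id: label for profile, label, _ in cohort}
        logger.info("simulated %d samples (%d chips)", len(cohort), len(chips))
    write_chip_csv(chips, out / "chips.csv")

    quants = quantify_chips(chips, config.run)
    write_quant_csv(quants, out / "quantification.csv")

    by_sample: Dict[str, List[ChipReadout]] = {}
    for chip in chips:
        by_sample.setdefault(chip.sample_id, []).append(chip)
    reports = [
        build_sample_report(sid, schips, config.run, config.bands)
        for sid, schips in by_sample.items()
    ]
    for rep in reports:
        failed = [c for c in rep.chip_qc if not c.passed]
        if failed:
            logger.warning("sample %s: %d chip(s) failed QC", rep.sample_id, len(failed))
        logger.info(
            "sample %s: calls %s flags %s",
            rep.sample_id,
            {c: a.call for c, a in rep.autosome_calls.items()},
            sorted(rep.flags) or "-",
        )
    write_report_tsv(reports, out / "sample_reports.tsv")

    evaluation = None
    if truth_map:
        evaluation = cohort_summary(
            sample_mean_ratios(reports),
            truth_map,
            threshold=config.bands.aneuploid_threshold,
            seed=config.seed,
        )
        write_evaluation_json(evaluation, out / "evaluation.json")
    return PipelineResult(
        chips=tuple(chips), reports=tuple(reports), truth=truth_map, evaluation=evaluation
    )


def dilution_ratios(
    chips: Sequence[DilutionChip], config: RunConfig, target_chrom: str | None = None
) -> Tuple[List[float], List[List[float]], List[float]]:
    """Per-chip target:reference ratios of a dilution series.

    Returns (sorted unique fractions, replicate-ratio lists aligned to them,
    per-chip ratios aligned to ``chips``).  The target chromosome's channel is
    FAM for chr21/chr18 panels and VIC (chr13) when chr13 is the trisomy.
    """
    per_chip: List[float] = []
    grouped: Dict[float, List[float]] = {}
    for item in chips:
        q = {
            "FAM": poisson_concentration(item.readout, "FAM", config),
            "VIC": poisson_concentration(item.readout, "VIC", config),
        }
        chrom = target_chrom or item.readout.sample_id.split("_")[1]
        target_is_vic = item.readout.panel.vic_target[0] == chrom
        num, den = ("VIC", "FAM") if target_is_vic else ("FAM", "VIC")
        ratio = q[num].concentration / q[den].concentration
        per_chip.append(ratio)
        grouped.setdefault(item.fraction, []).append(ratio)
    fractions = sorted(grouped)
    return fractions, [grouped[f] for f in fractions], per_chip


def run_dilution_analysis(
    trisomy_chrom: str,
    config: PipelineConfig,
    out_dir: "str | Path | None" = None,
    spec: Optional[MixtureSpec] = None,
    seed: Optional[int] = None,
) -> DilutionSeriesResult:
    """Simulate and analyse one trisomy dilution series; optionally write the TSV."""
    spec = spec or MixtureSpec(trisomy_chrom=trisomy_chrom)
    chips = simulate_dilution_series(
        spec, config.run, config.cohort.noise, config.seed if seed is None else seed
    )
    fractions, reps, per_chip = dilution_ratios(chips, config.run, spec.trisomy_chrom)
    cutoff = config.bands.per_chromosome_cutoffs.get(trisomy_chrom, config.bands.aneuploid_threshold)
    result = analyze_dilution_series(trisomy_chrom, fractions, reps, cutoff)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_dilution_tsv(chips, per_chip, out / f"dilution_T{trisomy_chrom}.tsv")
    return result
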