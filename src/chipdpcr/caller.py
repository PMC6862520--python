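"""Sample-level aneuploidy calling from replicate chromosomal ratios.

Calling bands follow the clinical validation: ratios in [0.9, 1.1] are
euploid, ratios at or above 1.15 are trisomic, and the uncovered gap
(1.1, 1.15) — as well as anything below the euploid band — is reported as
inconclusive rather than forced into a class.  A trisomy call whose ratio
falls below the typical non-mosaic range (default < 1.35) is flagged as a
possible mosaic or maternally contaminated sample, since a contaminated full
trisomy presents an intermediate ratio ``1 + (1-m)/2``.

Sex chromosomes are read from the X/SRY duplex: the X dose is normalised
against the same sample's chromosome-13 channels (cross-chip, which assumes
equal DNA input per chip of a sample), and SRY presence/absence separates XY
from monosomy X and XX from X-polysomy with Y.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import (
    ChipReadout,
    QuantResult,
    RatioEstimate,
    RunConfig,
    SaturationError,
    chromosome_ratio,
    poisson_concentration,
)

__all__ = [
    "ClassificationBands",
    "AutosomeCall",
    "SexCall",
    "ChipQC",
    "SampleReport",
    "classify_autosome",
    "estimate_aneuploid_fraction",
    "call_sex_chromosomes",
    "aggregate_replicates",
    "qc_chip",
    "build_sample_report",
]

FLAG_INTERMEDIATE = "intermediate_possible_mosaic_or_contamination"
FLAG_BELOW_EUPLOID = "below_euploid_range_possible_reference_anomaly"
FLAG_REPEAT = "discordant_replicates_repeat_test"


@dataclass(frozen=True)
class ClassificationBands:
    """Ratio bands for euploid/trisomy calling.

    The global aneuploid threshold (1.15) drives clinical calls; the
    per-chromosome cutoffs (the maxima observed among euploid samples in the
    dilution experiments) are used for detection-limit analysis only.
    """

    euploid_low: float = 0.9
    euploid_high: float = 1.1
    aneuploid_threshold: float = 1.15
    per_chromosome_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {"13": 1.145, "18": 1.077, "21": 1.068}
    )
    typical_trisomy_low: float = 1.35
    x_one_band: Tuple[float, float] = (0.4, 0.6)
    x_two_band: Tuple[float, float] = (0.9, 1.1)
    x_many_min: float = 1.4
    sry_min_conc: float = 10.0   # copies/uL noise floor for SRY detection
    sry_min_wells: int = 20      # minimum positive FAM wells for SRY detection

    def __post_init__(self) -> None:
        if not self.euploid_low < self.euploid_high <= self.aneuploid_threshold:
            raise ValueError(
                "bands must satisfy euploid_low < euploid_high <= aneuploid_threshold"
            )
        if self.typical_trisomy_low < self.aneuploid_threshold:
            raise ValueError("typical_trisomy_low must be >= aneuploid_threshold")


@dataclass(frozen=True)
class AutosomeCall:
    chromosome: str
    ratio: RatioEstimate
    call: str  # euploid | trisomy | inconclusive
    flags: frozenset = frozenset()


@dataclass(frozen=True)
class SexCall:
    x_autosome_ratio: float
    sry_detected: bool
    call: str  # XX | XY | monosomy_X | multiple_X_with_Y | inconclusive


@dataclass(frozen=True)
class ChipQC:
    chip_id: str
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class SampleReport:
    sample_id: str
    autosome_calls: Dict[str, AutosomeCall]
    sex_call: Optional[SexCall]
    replicate_ratios: Dict[str, Tuple[float, ...]]
    chip_qc: Tuple[ChipQC, ...]
    flags: frozenset = frozenset()
    aneuploid_fraction: Optional[float] = None


def _as_estimate(ratio: "RatioEstimate | float", chrom: str = "?") -> RatioEstimate:
    if isinstance(ratio, RatioEstimate):
        return ratio
    return RatioEstimate(chrom, "reference", float(ratio), float(ratio), float(ratio))


def classify_autosome(
    ratio: "RatioEstimate | float", bands: ClassificationBands, chromosome: str = "?"
) -> AutosomeCall:
    """Assign euploid / trisomy / inconclusive from a dosage ratio.

    Trisomy calls below ``typical_trisomy_low`` carry the mosaic-or-
    contamination flag; ratios below the euploid band carry a
    reference-anomaly flag (autosomal monosomy is never called).
    """
    est = _as_estimate(ratio, chromosome)
    r = est.ratio
    flags: set[str] = set()
    if bands.euploid_low <= r <= bands.euploid_high:
        call = "euploid"
    elif r >= bands.aneuploid_threshold:
        call = "trisomy"
        if r < bands.typical_trisomy_low:
            flags.add(FLAG_INTERMEDIATE)
    else:
        call = "inconclusive"
        if r < bands.euploid_low:
            flags.add(FLAG_BELOW_EUPLOID)
    return AutosomeCall(chromosome=chromosome, ratio=est, call=call, flags=frozenset(flags))


def estimate_aneuploid_fraction(ratio: float) -> float:
    """Invert the mixture relation ratio = 1 + f/2; clamped to [0, 1].

    Ratios below 1 have no mixture interpretation and return 0.
    """
    return min(max(2.0 * (ratio - 1.0), 0.0), 1.0)


def call_sex_chromosomes(
    x_quant: QuantResult,
    sry_quant: QuantResult,
    autosome_ref_conc: float,
    bands: ClassificationBands,
) -> SexCall:
    """Compose an X-dose band with SRY presence into a sex-chromosome call.

    The X:autosome ratio uses the sample's chromosome-13 concentration
    (averaged over its autosomal chips) as the disomic reference: ~0.5 means
    one X, ~1.0 two X, >=1.4 three or more X.
    """
    if autosome_ref_conc <= 0:
        raise ZeroDivisionError("missing or zero autosome reference concentration")
    x_ratio = x_quant.concentration / autosome_ref_conc
    sry = (
        sry_quant.concentration >= bands.sry_min_conc
        and sry_quant.n_positive >= bands.sry_min_wells
    )
    lo1, hi1 = bands.x_one_band
    lo2, hi2 = bands.x_two_band
    if lo1 <= x_ratio <= hi1:
        call = "XY" if sry else "monosomy_X"
    elif lo2 <= x_ratio <= hi2:
        call = "inconclusive" if sry else "XX"
    elif x_ratio >= bands.x_many_min and sry:
        call = "multiple_X_with_Y"
    else:
        call = "inconclusive"
    return SexCall(x_autosome_ratio=x_ratio, sry_detected=sry, call=call)


def aggregate_replicates(
    ratios: Sequence["RatioEstimate | float"],
    bands: ClassificationBands,
    chromosome: str = "?",
) -> AutosomeCall:
    """Sample-level call from QC-passing replicate ratios.

    The classification is applied to the mean replicate ratio; if any two
    replicates individually disagree euploid-vs-trisomy the sample is
    returned inconclusive with a repeat-test flag.
    """
    if not ratios:
        raise ValueError("no QC-passing replicate ratios to aggregate")
    values = [_as_estimate(r, chromosome).ratio for r in ratios]
    mean_ratio = statistics.fmean(values)
    per_rep = [classify_autosome(v, bands, chromosome).call for v in values]
    call = classify_autosome(mean_ratio, bands, chromosome)
    if "euploid" in per_rep and "trisomy" in per_rep:
        return AutosomeCall(
            chromosome=chromosome,
            ratio=call.ratio,
            call="inconclusive",
            flags=call.flags | {FLAG_REPEAT},
        )
    return call


def qc_chip(
    readout: ChipReadout,
    quants: Mapping[str, QuantResult],
    config: RunConfig,
    strict_range: bool = False,
) -> ChipQC:
    """Per-chip quality control.

    Fails on inconsistent counts (impossible here for validated readouts,
    kept for raw inputs), a saturated channel, or — when ``strict_range`` —
    a reference (VIC) concentration outside the validated working range.
    Out-of-range concentrations otherwise only annotate the verdict, since
    simulated data may legitimately scan other concentrations.
    """
    counts = (
        readout.n_fam_only + readout.n_vic_only + readout.n_double + readout.n_negative
    )
    if counts != readout.n_wells:
        return ChipQC(readout.chip_id, False, "count_mismatch")
    for ch in ("FAM", "VIC"):
        if readout.positives(ch) == readout.n_wells:
            return ChipQC(readout.chip_id, False, f"saturation_{ch}")
    vic = quants.get("VIC")
    if vic is not None:
        lo, hi = config.valid_conc_range
        if not lo <= vic.concentration <= hi:
            if strict_range:
                return ChipQC(readout.chip_id, False, "reference_out_of_range")
            return ChipQC(readout.chip_id, True, "warn_reference_out_of_range")
    return ChipQC(readout.chip_id, True)


def _quantify_chip(
    readout: ChipReadout, config: RunConfig
) -> Optional[Dict[str, QuantResult]]:
    try:
        return {
            "FAM": poisson_concentration(readout, "FAM", config),
            "VIC": poisson_concentration(readout, "VIC", config),
        }
    except SaturationError:
        return None


def build_sample_report(
    sample_id: str,
    chips: Sequence[ChipReadout],
    config: RunConfig,
    bands: ClassificationBands,
) -> SampleReport:
    """Quantify, QC and call one sample from all of its chips.

    Autosomal dosage ratios are taken per duplex chip: chr21 and chr18 are the
    FAM:VIC ratios of their panels; chr13 (the shared reference) is read
    against whichever partner chromosome the sample-level calls show to be
    euploid — against chr18 if chr18 is euploid, else against chr21 if chr21
    is euploid, else as the mean of both inverted ratios (the pure-T13 case,
    where both partners are depressed by the trisomic reference).
    """
    quants: Dict[str, Dict[str, QuantResult]] = {}
    qc: List[ChipQC] = []
    passing: Dict[str, List[Tuple[ChipReadout, Dict[str, QuantResult]]]] = {}
    for chip in chips:
        q = _quantify_chip(chip, config)
        if q is None:
            qc.append(ChipQC(chip.chip_id, False, "saturation"))
            continue
        verdict = qc_chip(chip, q, config)
        qc.append(verdict)
        if verdict.passed:
            passing.setdefault(chip.panel.panel_id, []).append((chip, q))

    replicate_ratios: Dict[str, Tuple[float, ...]] = {}
    autosome_calls: Dict[str, AutosomeCall] = {}

    def _panel_ratios(panel_id: str, invert: bool) -> List[RatioEstimate]:
        out = []
        for chip, q in passing.get(panel_id, []):
            num, den = ("VIC", "FAM") if invert else ("FAM", "VIC")
            out.append(
                chromosome_ratio(
                    q[num],
                    q[den],
                    numerator_chrom=chip.panel.chromosome(num),
                    denominator_chrom=chip.panel.chromosome(den),
                )
            )
        return out

    r21 = _panel_ratios("13_21", invert=False)
    r18 = _panel_ratios("13_18", invert=False)
    flags: set[str] = set()
    if r21:
        replicate_ratios["21"] = tuple(r.ratio for r in r21)
        autosome_calls["21"] = aggregate_replicates(r21, bands, "21")
    if r18:
        replicate_ratios["18"] = tuple(r.ratio for r in r18)
        autosome_calls["18"] = aggregate_replicates(r18, bands, "18")

    # chr13 against a partner believed disomic
    r13_vs_21 = _panel_ratios("13_21", invert=True)
    r13_vs_18 = _panel_ratios("13_18", invert=True)
    r13: List[RatioEstimate] = []
    if autosome_calls.get("18") and autosome_calls["18"].call == "euploid" and r13_vs_18:
        r13 = r13_vs_18
    elif autosome_calls.get("21") and autosome_calls["21"].call == "euploid" and r13_vs_21:
        r13 = r13_vs_21
    elif r13_vs_21 and r13_vs_18:
        r13 = [
            _as_estimate((a.ratio + b.ratio) / 2.0, "13")
            for a, b in zip(r13_vs_21, r13_vs_18)
        ]
    else:
        r13 = r13_vs_21 or r13_vs_18
    if r13:
        replicate_ratios["13"] = tuple(r.ratio for r in r13)
        autosome_calls["13"] = aggregate_replicates(r13, bands, "13")

    # sex chromosomes: mean X and SRY quantification over passing sex chips,
    # referenced to the mean chr13 (VIC) concentration of the autosomal chips
    sex_call: Optional[SexCall] = None
    sex_chips = passing.get("X_SRY", [])
    auto_ref_concs = [
        q["VIC"].concentration
        for pid in ("13_21", "13_18")
        for _, q in passing.get(pid, [])
    ]
    if sex_chips and auto_ref_concs:
        ref = statistics.fmean(auto_ref_concs)

        def _pool(channel: str) -> QuantResult:
            # replicate average: mean concentration, pooled well counts
            P = sum(q[channel].n_positive for _, q in sex_chips)
            N = sum(q[channel].n_wells for _, q in sex_chips)
            conc = statistics.fmean(q[channel].concentration for _, q in sex_chips)
            p = min(P / N, 1 - 1e-12)
            return QuantResult(
                channel, p, -math.log1p(-p), conc, conc, conc,
                N, round(P / len(sex_chips)),
            )

        sex_call = call_sex_chromosomes(_pool("VIC"), _pool("FAM"), ref, bands)
        replicate_ratios["X"] = tuple(
            q["VIC"].concentration / ref for _, q in sex_chips
        )

    for call in autosome_calls.values():
        flags |= call.flags

    # estimated aneuploid fraction for flagged intermediate trisomies
    aneuploid_fraction: Optional[float] = None
    for call in autosome_calls.values():
        if call.call == "trisomy" and FLAG_INTERMEDIATE in call.flags:
            aneuploid_fraction = estimate_aneuploid_fraction(call.ratio.ratio)

    return SampleReport(
        sample_id=sample_id,
        autosome_calls=autosome_calls,
        sex_call=sex_call,
        replicate_ratios=replicate_ratios,
        chip_qc=tuple(qc),
        flags=frozenset(flags),
        aneuploid_fraction=aneuploid_fraction,
    )
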