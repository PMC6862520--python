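"""Poisson statistics for chip-based digital PCR.

A digital PCR chip partitions a reaction into ~20,000 independent wells.
After endpoint PCR each well is called positive or negative per dye channel
(FAM, VIC).  If target molecules land in wells independently at mean
occupancy ``lambda`` per well, the positive fraction is ``p = 1 - exp(-lambda)``,
so the absolute target concentration in the original sample is

    T = (D / Vp) * (-ln(1 - P/N))        [copies/uL]

where ``P`` of ``N`` wells are positive, ``Vp`` is the well volume in uL and
``D`` the dilution factor applied during sample preparation.  A duplex chip
carries two assays (one per dye), so a single chip yields two absolute
concentrations whose quotient is the chromosomal dosage ratio used for
aneuploidy calling (about 1 for euploid, about 1.5 for a full trisomy
against a disomic reference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Tuple

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

Channel = Literal["FAM", "VIC"]

__all__ = [
    "Channel",
    "DuplexAssay",
    "ChipReadout",
    "QuantResult",
    "RatioEstimate",
    "RunConfig",
    "SaturationError",
    "PANELS",
    "occupancy_from_counts",
    "poisson_concentration",
    "concentration_ci",
    "chromosome_ratio",
]


class SaturationError(ValueError):
    """All wells positive: occupancy is unbounded; the sample must be diluted."""


@dataclass(frozen=True)
class DuplexAssay:
    """One two-dye panel: a VIC-labelled and a FAM-labelled target on different chromosomes."""

    panel_id: str
    vic_target: Tuple[str, str]  # (chromosome, locus name)
    fam_target: Tuple[str, str]

    def __post_init__(self) -> None:
        if self.vic_target[0] == self.fam_target[0]:
            raise ValueError(
                f"panel {self.panel_id!r}: VIC and FAM targets must sit on different chromosomes"
            )

    def chromosome(self, channel: Channel) -> str:
        return self.fam_target[0] if channel == "FAM" else self.vic_target[0]


#: The three duplex panels of the screening assay.  Chromosome 13 (VIC) serves
#: as the reference for both autosomal panels; the sex panel pairs a noncoding
#: X sequence (VIC) with the Y-specific SRY gene (FAM).
PANELS: dict[str, DuplexAssay] = {
    "13_21": DuplexAssay("13_21", vic_target=("13", "MBNL2"), fam_target=("21", "PRDM15")),
    "13_18": DuplexAssay("13_18", vic_target=("13", "MBNL2"), fam_target=("18", "EHZF")),
    "X_SRY": DuplexAssay("X_SRY", vic_target=("X", "ncX"), fam_target=("Y", "SRY")),
}


@dataclass(frozen=True)
class RunConfig:
    """Platform parameters shared by quantification and simulation.

    partition_volume_ul
        Volume of one well in microlitres.  Default 0.000809 uL (809 pL), the
        platform's nominal well volume.  Absolute concentrations scale with
        1/Vp, but chromosomal ratios are Vp-invariant.
    n_wells_default
        Wells per chip; the platform partitions into ~20,000.
    confidence_level
        Two-sided level for concentration and ratio intervals.
    valid_conc_range
        Validated reference-channel working range in copies/uL; chips outside
        it are flagged by QC.
    """

    partition_volume_ul: float = 0.000809
    n_wells_default: int = 20_000
    confidence_level: float = 0.95
    valid_conc_range: Tuple[float, float] = (200.0, 2000.0)

    def __post_init__(self) -> None:
        if self.partition_volume_ul <= 0:
            raise ValueError("partition_volume_ul must be positive")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0, 1)")
        if self.n_wells_default <= 0:
            raise ValueError("n_wells_default must be positive")
        lo, hi = self.valid_conc_range
        if lo < 0 or hi <= lo:
            raise ValueError("valid_conc_range must satisfy 0 <= low < high")


@dataclass(frozen=True)
class ChipReadout:
    """Called well counts for one duplex chip.

    The four categories partition the chip: FAM-only, VIC-only, double
    positive and negative wells must sum to ``n_wells``.  Channel positives
    combine single and double positives (a double-positive well received at
    least one molecule of each target).
    """

    sample_id: str
    chip_id: str
    panel: DuplexAssay
    n_wells: int
    n_fam_only: int
    n_vic_only: int
    n_double: int
    n_negative: int
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        counts = (self.n_fam_only, self.n_vic_only, self.n_double, self.n_negative)
        if self.n_wells <= 0:
            raise ValueError(f"chip {self.chip_id!r}: n_wells must be positive")
        if any(c < 0 for c in counts):
            raise ValueError(f"chip {self.chip_id!r}: negative well count")
        if sum(counts) != self.n_wells:
            raise ValueError(
                f"chip {self.chip_id!r}: well counts sum to {sum(counts)}, expected n_wells={self.n_wells}"
            )
        if self.dilution_factor < 1:
            raise ValueError(f"chip {self.chip_id!r}: dilution_factor must be >= 1")

    def positives(self, channel: Channel) -> int:
        """Positive wells in one dye channel (single + double positives)."""
        single = self.n_fam_only if channel == "FAM" else self.n_vic_only
        return single + self.n_double


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification of one dye channel of one chip."""

    channel: Channel
    p_hat: float                 # positive fraction P/N
    occupancy: float             # mean molecules per well, -ln(1 - p_hat)
    concentration: float         # copies/uL in the undiluted sample
    ci_low: float
    ci_high: float
    n_wells: int
    n_positive: int
    confidence_level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.concentration <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass(frozen=True)
class RatioEstimate:
    """Chromosomal dosage ratio: target concentration over reference concentration."""

    numerator_chrom: str
    denominator_chrom: str
    ratio: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if not self.ci_low <= self.ratio <= self.ci_high:
            raise ValueError("confidence interval must bracket the ratio")


def occupancy_from_counts(P: int, N: int) -> float:
    """Mean target molecules per well from positive/total partition counts.

    Inverts ``p = 1 - exp(-lambda)`` at the observed positive fraction:
    returns ``-ln(1 - P/N)``, strictly increasing in ``P``.

    Raises
    ------
    SaturationError
        If every well is positive (``P == N``): occupancy is undefined and
        the sample needs dilution.
    ValueError
        If ``N <= 0``, ``P < 0`` or ``P > N``.
    """
    if N <= 0:
        raise ValueError(f"total partition count must be positive, got N={N}")
    if P < 0 or P > N:
        raise ValueError(f"positive count P={P} outside [0, N={N}]")
    if P == N:
        raise SaturationError(
            f"all {N} partitions positive: occupancy undefined, dilute the sample"
        )
    # log1p for accuracy at small positive fractions
    return -math.log1p(-P / N)


def poisson_concentration(
    readout: ChipReadout, channel: Channel, config: RunConfig
) -> QuantResult:
    """Absolute concentration of one channel's target, with confidence interval.

    Applies ``T = (D / Vp) * (-ln(1 - P/N))`` with the chip's dilution factor
    and the configured partition volume; the interval comes from
    :func:`concentration_ci`.
    """
    P = readout.positives(channel)
    N = readout.n_wells
    lam = occupancy_from_counts(P, N)  # raises on saturation / bad counts
    scale = readout.dilution_factor / config.partition_volume_ul
    conc = scale * lam
    lo, hi = concentration_ci(
        P, N, config.partition_volume_ul, readout.dilution_factor, config.confidence_level
    )
    return QuantResult(
        channel=channel,
        p_hat=P / N,
        occupancy=lam,
        concentration=conc,
        ci_low=lo,
        ci_high=hi,
        n_wells=N,
        n_positive=P,
        confidence_level=config.confidence_level,
    )


def concentration_ci(
    P: int, N: int, Vp: float, D: float, level: float = 0.95
) -> Tuple[float, float]:
    """Two-sided confidence interval on concentration in copies/uL.

    A Wilson score interval on the positive fraction ``p = P/N`` is mapped
    through the strictly increasing transform ``p -> -(D/Vp) ln(1-p)``, so the
    endpoints on the concentration scale are the transformed endpoints on the
    proportion scale.  Wilson behaves well near p = 0 and p = 1, where the
    Wald interval degenerates.
    """
    if N <= 0 or P < 0 or P > N:
        raise ValueError(f"invalid counts P={P}, N={N}")
    if P == N:
        raise SaturationError("saturated channel: interval undefined, dilute the sample")
    p_lo, p_hi = proportion_confint(P, N, alpha=1.0 - level, method="wilson")
    scale = D / Vp
    lo = scale * -math.log1p(-min(p_lo, 1.0 - 1e-15))
    hi = scale * -math.log1p(-min(p_hi, 1.0 - 1e-15))
    return max(lo, 0.0), hi


def chromosome_ratio(
    target: QuantResult,
    reference: QuantResult,
    numerator_chrom: str = "target",
    denominator_chrom: str = "reference",
) -> RatioEstimate:
    """Dosage ratio of a target chromosome against the duplex reference channel.

    The point estimate divides the two absolute concentrations measured on the
    same chip (partition volume and dilution cancel, so the ratio equals the
    occupancy ratio).  The interval is a delta-method interval on the
    log-ratio treating the two channel occupancies as independent:
    ``Var(lambda_hat) ~= p / ((1-p) N)`` per channel, by propagating binomial
    sampling error through ``-ln(1-p)``.
    """
    if reference.concentration <= 0:
        raise ZeroDivisionError(
            "reference channel concentration is zero: chromosomal ratio undefined"
        )
    ratio = target.concentration / reference.concentration

    def _rel_var(q: QuantResult) -> float:
        if q.occupancy == 0:
            return math.inf
        var_lam = q.p_hat / ((1.0 - q.p_hat) * q.n_wells)
        return var_lam / q.occupancy**2

    var_log = _rel_var(target) + _rel_var(reference)
    z = stats.norm.ppf(0.5 + target.confidence_level / 2.0)
    if math.isfinite(var_log):
        half = z * math.sqrt(var_log)
        lo, hi = ratio * math.exp(-half), ratio * math.exp(half)
    else:
        lo, hi = 0.0, math.inf
    return RatioEstimate(
        numerator_chrom=numerator_chrom,
        denominator_chrom=denominator_chrom,
        ratio=ratio,
        ci_low=min(lo, ratio),
        ci_high=max(hi, ratio),
    )
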