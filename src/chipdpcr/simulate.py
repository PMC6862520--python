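"""Synthetic duplex-chip generator.

The study's clinical samples are not deposited, so validation runs on
simulated data whose generative model matches the assumptions of the
quantification: molecules load into wells independently (well positive with
probability ``1 - exp(-lambda)`` per channel, channels independent), plus two
realistic disturbances — a per-chip lognormal loading factor shared by both
channels (pipetting variability) and rare per-well miscalls ("rain").

Samples are described by a karyotype profile: integer copy numbers per
chromosome, a mosaic fraction ``f`` of genomes carrying the aberration, and a
maternal-contamination fraction ``m`` of euploid female genomes.  The
expected dosage ratio of a trisomy mixture over a disomic reference is
``1 + f/2``; maternal contamination of a fully trisomic fetus shifts it to
``1 + (1-m)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .core import PANELS, Channel, ChipReadout, DuplexAssay, RunConfig

__all__ = [
    "NoiseParams",
    "SampleProfile",
    "MixtureSpec",
    "CohortSpec",
    "DilutionChip",
    "effective_copy_number",
    "expected_ratio",
    "simulate_chip",
    "simulate_sample",
    "simulate_dilution_series",
    "simulate_cohort",
    "euploid_profile",
    "trisomy_profile",
]

AUTOSOMES = ("13", "18", "21")


@dataclass(frozen=True)
class NoiseParams:
    """Non-ideal behaviour of a real chip run.

    conc_cv
        Coefficient of variation of the per-chip lognormal loading factor
        (default 2%); the factor multiplies both channels of a chip, so it
        perturbs absolute concentrations and cross-chip comparisons but not
        within-chip ratios.
    fp_rate / fn_rate
        Per-well probability that a negative well is called positive
        (default 2e-4) or a positive well called negative (default 1e-3).
    """

    conc_cv: float = 0.02
    fp_rate: float = 2e-4
    fn_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.conc_cv < 0:
            raise ValueError("conc_cv must be >= 0")
        if not (0 <= self.fp_rate < 1 and 0 <= self.fn_rate < 1):
            raise ValueError("miscall rates must be in [0, 1)")

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(conc_cv=0.0, fp_rate=0.0, fn_rate=0.0)


@dataclass(frozen=True)
class SampleProfile:
    """Ground-truth karyotype and composition of one simulated sample.

    copy_numbers gives the aberrant karyotype (per-genome copies of 13, 18,
    21, X, Y); trisomic_fraction ``f`` is the fraction of fetal genomes
    carrying the aberration (1 = non-mosaic); contamination_fraction ``m`` is
    the fraction of admixed euploid female (maternal) genomes; genome_conc is
    diploid genome equivalents per uL of reaction, so a disomic channel sits
    at ``2 * genome_conc`` copies/uL.
    """

    sample_id: str
    copy_numbers: Mapping[str, int]
    trisomic_fraction: float = 1.0
    contamination_fraction: float = 0.0
    genome_conc: float = 250.0

    def __post_init__(self) -> None:
        for chrom, cn in self.copy_numbers.items():
            if int(cn) != cn or cn < 0:
                raise ValueError(f"copy number for chr{chrom} must be a non-negative integer")
        if not 0 <= self.trisomic_fraction <= 1:
            raise ValueError("trisomic_fraction must be in [0, 1]")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if self.genome_conc <= 0:
            raise ValueError("genome_conc must be positive")

    def _baseline(self, chrom: str) -> int:
        """Euploid copy number matched to the profile's sex (XX if no Y)."""
        if chrom in AUTOSOMES:
            return 2
        has_y = self.copy_numbers.get("Y", 0) > 0
        if chrom == "X":
            return 1 if has_y else 2
        if chrom == "Y":
            return 1 if has_y else 0
        raise KeyError(chrom)

    def effective_fetal_copies(self, chrom: str) -> float:
        """Mosaic-averaged fetal copy number: baseline and aberrant lines mixed at f."""
        cn = self.copy_numbers.get(chrom, self._baseline(chrom))
        base = self._baseline(chrom)
        f = self.trisomic_fraction
        return base * (1.0 - f) + cn * f

    def channel_concentration(self, chrom: str) -> float:
        """Expected copies/uL of a target on ``chrom`` in the final reaction.

        Blends fetal and contaminant genomes: the maternal contaminant is
        euploid female (2 copies of each autosome and of X, no Y).
        """
        m = self.contamination_fraction
        maternal = {"X": 2, "Y": 0}.get(chrom, 2)
        blended = (1.0 - m) * self.effective_fetal_copies(chrom) + m * maternal
        return self.genome_conc * blended


def euploid_profile(sample_id: str, sex: str = "female", genome_conc: float = 250.0) -> SampleProfile:
    cns = {"13": 2, "18": 2, "21": 2}
    cns.update({"X": 1, "Y": 1} if sex == "male" else {"X": 2, "Y": 0})
    return SampleProfile(sample_id, cns, trisomic_fraction=0.0, genome_conc=genome_conc)


def trisomy_profile(
    sample_id: str,
    chrom: str,
    f: float = 1.0,
    m: float = 0.0,
    sex: str = "female",
    genome_conc: float = 250.0,
) -> SampleProfile:
    """A (possibly mosaic / contaminated) autosomal trisomy profile."""
    if chrom not in AUTOSOMES:
        raise ValueError(f"trisomy chromosome must be one of {AUTOSOMES}")
    cns = {"13": 2, "18": 2, "21": 2, chrom: 3}
    cns.update({"X": 1, "Y": 1} if sex == "male" else {"X": 2, "Y": 0})
    return SampleProfile(
        sample_id, cns, trisomic_fraction=f, contamination_fraction=m, genome_conc=genome_conc
    )


@dataclass(frozen=True)
class MixtureSpec:
    """Design of a trisomic/euploid dilution series."""

    trisomy_chrom: str
    fractions: Tuple[float, ...] = (0.0, 0.05, 0.10, 0.30, 0.50, 0.70, 1.0)
    replicates_per_point: int = 2

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(not 0 <= x <= 1 for x in fr) or any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("fractions must be strictly increasing within [0, 1]")
        if self.replicates_per_point < 1:
            raise ValueError("replicates_per_point must be >= 1")
        if self.trisomy_chrom not in AUTOSOMES:
            raise ValueError(f"trisomy_chrom must be one of {AUTOSOMES}")


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated screening cohort.

    Default counts mirror the validation cohort: 133 samples with 17 trisomy
    21, 9 trisomy 18, 3 trisomy 13, one monosomy X, one XXXY, and the
    remaining 102 euploid (split evenly male/female); triplicate chips per
    panel per sample.
    """

    n_t21: int = 17
    n_t18: int = 9
    n_t13: int = 3
    n_monosomy_x: int = 1
    n_xxxy: int = 1
    n_euploid_male: int = 51
    n_euploid_female: int = 51
    replicates_per_sample: int = 3
    noise: NoiseParams = field(default_factory=NoiseParams)

    @property
    def n_total(self) -> int:
        return (
            self.n_t21 + self.n_t18 + self.n_t13 + self.n_monosomy_x
            + self.n_xxxy + self.n_euploid_male + self.n_euploid_female
        )


def effective_copy_number(base: int, extra_fraction: float) -> float:
    """Copies per genome when a fraction ``f`` of genomes carries one extra copy."""
    if base not in (0, 1, 2, 3):
        raise ValueError("base copy number must be in {0, 1, 2, 3}")
    if not 0 <= extra_fraction <= 1:
        raise ValueError("extra_fraction must be in [0, 1]")
    return base * (1.0 - extra_fraction) + (base + 1) * extra_fraction


def expected_ratio(f: float) -> float:
    """Theoretical trisomy:reference dosage ratio of a mixture with trisomic fraction f."""
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    return 1.0 + f / 2.0


def _noisy_positive_prob(lam: float, noise: NoiseParams) -> float:
    p = -np.expm1(-lam)
    return p * (1.0 - noise.fn_rate) + (1.0 - p) * noise.fp_rate


def simulate_chip(
    channel_concs: Mapping[Channel, float],
    config: RunConfig,
    noise: NoiseParams,
    rng: np.random.Generator,
    *,
    panel: DuplexAssay,
    sample_id: str = "sim",
    chip_id: str = "chip",
    dilution_factor: float = 1.0,
    n_wells: int | None = None,
) -> ChipReadout:
    """Draw called well counts for one duplex chip.

    Each channel's occupancy is ``lambda = C * Vp / D``; wells are positive
    independently per channel with probability ``1 - exp(-lambda)``, then
    per-well miscall rates are applied.  The four joint categories are drawn
    as a single multinomial, which guarantees count conservation.
    """
    N = config.n_wells_default if n_wells is None else n_wells
    for ch, conc in channel_concs.items():
        if conc < 0:
            raise ValueError(f"negative concentration for channel {ch}")
    lam_fam = channel_concs.get("FAM", 0.0) * config.partition_volume_ul / dilution_factor
    lam_vic = channel_concs.get("VIC", 0.0) * config.partition_volume_ul / dilution_factor
    p_fam = _noisy_positive_prob(lam_fam, noise)
    p_vic = _noisy_positive_prob(lam_vic, noise)
    probs = [
        p_fam * (1 - p_vic),       # FAM only
        (1 - p_fam) * p_vic,       # VIC only
        p_fam * p_vic,             # double positive
        (1 - p_fam) * (1 - p_vic), # negative
    ]
    n_fam_only, n_vic_only, n_double, n_negative = rng.multinomial(N, probs)
    return ChipReadout(
        sample_id=sample_id,
        chip_id=chip_id,
        panel=panel,
        n_wells=N,
        n_fam_only=int(n_fam_only),
        n_vic_only=int(n_vic_only),
        n_double=int(n_double),
        n_negative=int(n_negative),
        dilution_factor=dilution_factor,
    )


def simulate_sample(
    profile: SampleProfile,
    panels: Sequence[DuplexAssay],
    replicates: int,
    config: RunConfig,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> List[ChipReadout]:
    """Simulate ``replicates`` chips per panel for one sample.

    Each chip gets its own lognormal loading factor (mean 1, CV
    ``noise.conc_cv``) applied to the genome concentration of both channels;
    channel concentrations then follow from the profile's blended copy
    numbers.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    chips: List[ChipReadout] = []
    sigma = np.sqrt(np.log1p(noise.conc_cv**2))
    for rep in range(1, replicates + 1):
        for panel in panels:
            factor = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
            concs: Dict[Channel, float] = {
                "FAM": factor * profile.channel_concentration(panel.fam_target[0]),
                "VIC": factor * profile.channel_concentration(panel.vic_target[0]),
            }
            chips.append(
                simulate_chip(
                    concs,
                    config,
                    noise,
                    rng,
                    panel=panel,
                    sample_id=profile.sample_id,
                    chip_id=f"{profile.sample_id}:{panel.panel_id}:r{rep}",
                )
            )
    return chips


@dataclass(frozen=True)
class DilutionChip:
    """One chip of a dilution series with its ground-truth trisomic fraction."""

    fraction: float
    replicate: int
    readout: ChipReadout


def simulate_dilution_series(
    spec: MixtureSpec,
    config: RunConfig,
    noise: NoiseParams,
    seed: int | np.random.Generator,
) -> List[DilutionChip]:
    """Simulate trisomic/euploid mixtures across the fraction grid.

    Each point uses the duplex panel that interrogates the trisomy chromosome
    (13_21 for T21 and T13, 13_18 for T18); the mixture's effective copy
    number on the trisomy chromosome is ``2 + f``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panel = PANELS["13_18"] if spec.trisomy_chrom == "18" else PANELS["13_21"]
    out: List[DilutionChip] = []
    for f in spec.fractions:
        profile = trisomy_profile(
            f"mix_{spec.trisomy_chrom}_f{f:g}", spec.trisomy_chrom, f=f
        )
        chips = simulate_sample(
            profile, [panel], spec.replicates_per_point, config, noise, rng
        )
        for rep, chip in enumerate(chips, start=1):
            out.append(DilutionChip(fraction=f, replicate=rep, readout=chip))
    return out


def simulate_cohort(
    spec: CohortSpec,
    config: RunConfig,
    seed: int | np.random.Generator,
) -> List[Tuple[SampleProfile, str, List[ChipReadout]]]:
    """Simulate a labelled screening cohort.

    Returns one ``(profile, truth_label, chips)`` triple per sample, where
    chips cover all three duplex panels in ``replicates_per_sample``
    replicates and truth_label is one of ``T13/T18/T21/monosomy_X/XXXY/
    euploid_male/euploid_female``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    panels = list(PANELS.values())
    roster: List[Tuple[str, SampleProfile]] = []

    def add(label: str, profile: SampleProfile) -> None:
        roster.append((label, profile))

    i = 0
    for _ in range(spec.n_t21):
        i += 1
        add("T21", trisomy_profile(f"S{i:03d}", "21"))
    for _ in range(spec.n_t18):
        i += 1
        add("T18", trisomy_profile(f"S{i:03d}", "18"))
    for _ in range(spec.n_t13):
        i += 1
        add("T13", trisomy_profile(f"S{i:03d}", "13"))
    for _ in range(spec.n_monosomy_x):
        i += 1
        add("monosomy_X", SampleProfile(f"S{i:03d}", {"13": 2, "18": 2, "21": 2, "X": 1, "Y": 0}))
    for _ in range(spec.n_xxxy):
        i += 1
        add("XXXY", SampleProfile(f"S{i:03d}", {"13": 2, "18": 2, "21": 2, "X": 3, "Y": 1}))
    for _ in range(spec.n_euploid_male):
        i += 1
        add("euploid_male", euploid_profile(f"S{i:03d}", sex="male"))
    for _ in range(spec.n_euploid_female):
        i += 1
        add("euploid_female", euploid_profile(f"S{i:03d}", sex="female"))

    out = []
    for label, profile in roster:
        chips = simulate_sample(
            profile, panels, spec.replicates_per_sample, config, spec.noise, rng
        )
        out.append((profile, label, chips))
    return out
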