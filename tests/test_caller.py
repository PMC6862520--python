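"""Classification bands, replicate aggregation, sex calls, QC."""

import numpy as np
import pytest

from chipdpcr import (
    PANELS,
    ClassificationBands,
    NoiseParams,
    QuantResult,
    aggregate_replicates,
    build_sample_report,
    call_sex_chromosomes,
    classify_autosome,
    estimate_aneuploid_fraction,
    euploid_profile,
    expected_ratio,
    poisson_concentration,
    qc_chip,
    simulate_sample,
    trisomy_profile,
)
from chipdpcr.caller import FLAG_BELOW_EUPLOID, FLAG_INTERMEDIATE, FLAG_REPEAT
from tests.test_core import make_chip


@pytest.mark.parametrize(
    "ratio, expected_call, expected_flag",
    [
        (0.981, "euploid", None),        # cohort euploid mean
        (1.505, "trisomy", None),        # full trisomy 21 mean
        (1.12, "inconclusive", None),    # gap between bands
        (1.193, "trisomy", FLAG_INTERMEDIATE),  # contaminated trisomy
        (0.70, "inconclusive", FLAG_BELOW_EUPLOID),
        (0.9, "euploid", None),
        (1.15, "trisomy", FLAG_INTERMEDIATE),
    ],
)
def test_classify_autosome_bands(bands, ratio, expected_call, expected_flag):
    call = classify_autosome(ratio, bands, "21")
    assert call.call == expected_call
    if expected_flag:
        assert expected_flag in call.flags
    else:
        assert not call.flags


def test_band_exhaustiveness(bands):
    """Every positive ratio maps to exactly one class."""
    for r in np.linspace(0.05, 2.5, 491):
        assert classify_autosome(float(r), bands).call in {
            "euploid", "trisomy", "inconclusive"
        }


def test_bands_validation():
    with pytest.raises(ValueError):
        ClassificationBands(euploid_high=1.2, aneuploid_threshold=1.15)


@pytest.mark.parametrize(
    "ratio, expected",
    [(1.0, 0.0), (1.5, 1.0), (1.193, 0.386), (0.9, 0.0), (1.8, 1.0)],
)
def test_estimate_aneuploid_fraction(ratio, expected):
    assert estimate_aneuploid_fraction(ratio) == pytest.approx(expected)


def test_fraction_ratio_round_trip():
    for f in np.linspace(0, 1, 101):
        assert estimate_aneuploid_fraction(expected_ratio(float(f))) == pytest.approx(
            float(f), abs=1e-12
        )


def _quant(conc: float, n_positive: int = 5000) -> QuantResult:
    return QuantResult("VIC", 0.25, 0.29, conc, conc, conc, 20_000, n_positive)


@pytest.mark.parametrize(
    "x_conc, sry_conc, sry_wells, expected",
    [
        (250.0, 300.0, 4000, "XY"),              # one X + SRY
        (250.0, 0.0, 0, "monosomy_X"),           # one X, no SRY
        (500.0, 0.0, 0, "XX"),                   # two X, no SRY
        (750.0, 300.0, 4000, "multiple_X_with_Y"),  # three X + SRY
        (500.0, 300.0, 4000, "inconclusive"),    # two X with SRY: not interpretable
        (375.0, 0.0, 0, "inconclusive"),         # X dose between bands
        (250.0, 5.0, 4000, "monosomy_X"),        # SRY below concentration floor
        (250.0, 300.0, 10, "monosomy_X"),        # SRY below well-count floor
    ],
)
def test_call_sex_chromosomes(bands, x_conc, sry_conc, sry_wells, expected):
    call = call_sex_chromosomes(
        _quant(x_conc), _quant(sry_conc, n_positive=sry_wells), 500.0, bands
    )
    assert call.call == expected
    assert call.x_autosome_ratio == pytest.approx(x_conc / 500.0)


def test_call_sex_requires_reference(bands):
    with pytest.raises(ZeroDivisionError):
        call_sex_chromosomes(_quant(250.0), _quant(0.0), 0.0, bands)


@pytest.mark.parametrize(
    "ratios, expected_call, expected_flag",
    [
        ([1.49, 1.51, 1.50], "trisomy", None),
        ([0.98, 1.02], "euploid", None),
        ([0.98, 1.52], "inconclusive", FLAG_REPEAT),  # discordant replicates
        ([1.12, 1.13], "inconclusive", None),
    ],
)
def test_aggregate_replicates(bands, ratios, expected_call, expected_flag):
    call = aggregate_replicates(ratios, bands, "21")
    assert call.call == expected_call
    assert call.ratio.ratio == pytest.approx(float(np.mean(ratios)))
    if expected_flag:
        assert expected_flag in call.flags


def test_aggregate_requires_data(bands):
    with pytest.raises(ValueError):
        aggregate_replicates([], bands)


def test_qc_verdicts(config):
    chip = make_chip(n_fam_only=6000, n_vic_only=6000)
    quants = {
        "FAM": poisson_concentration(chip, "FAM", config),
        "VIC": poisson_concentration(chip, "VIC", config),
    }
    assert qc_chip(chip, quants, config).passed

    # reference concentration out of the validated range: warn by default, fail when strict
    low_chip = make_chip(n_fam_only=100, n_vic_only=100)
    low_q = {
        "FAM": poisson_concentration(low_chip, "FAM", config),
        "VIC": poisson_concentration(low_chip, "VIC", config),
    }
    verdict = qc_chip(low_chip, low_q, config)
    assert verdict.passed and "out_of_range" in verdict.reason
    assert not qc_chip(low_chip, low_q, config, strict_range=True).passed

    sat = make_chip(n_vic_only=20_000, n_wells=20_000)
    assert qc_chip(sat, {}, config).reason == "saturation_VIC"


def test_sample_report_trisomy_round_trip(config, noise_off):
    """classify(simulate(T21)) = trisomy on chr21, euploid elsewhere, for several seeds."""
    bands = ClassificationBands()
    for seed in range(5):
        rng = np.random.default_rng(seed)
        chips = simulate_sample(
            trisomy_profile("t", "21", sex="male"), list(PANELS.values()), 3,
            config, noise_off, rng,
        )
        rep = build_sample_report("t", chips, config, bands)
        assert rep.autosome_calls["21"].call == "trisomy"
        assert rep.autosome_calls["18"].call == "euploid"
        assert rep.autosome_calls["13"].call == "euploid"
        assert rep.sex_call.call == "XY"

        rng = np.random.default_rng(seed)
        chips = simulate_sample(
            euploid_profile("e"), list(PANELS.values()), 3, config, noise_off, rng
        )
        rep = build_sample_report("e", chips, config, bands)
        assert all(c.call == "euploid" for c in rep.autosome_calls.values())
        assert rep.sex_call.call == "XX"


def test_sample_report_t13_uses_partner_reference(config, noise_off, rng):
    """A trisomic chr13 reference depresses both panels; chr13 is still called trisomic."""
    chips = simulate_sample(
        trisomy_profile("t13", "13"), list(PANELS.values()), 3, config, noise_off, rng
    )
    rep = build_sample_report("t13", chips, config, ClassificationBands())
    assert rep.autosome_calls["13"].call == "trisomy"
    assert rep.autosome_calls["13"].ratio.ratio == pytest.approx(1.5, abs=0.05)
    # partner chromosomes read low against the trisomic reference, never trisomic
    assert rep.autosome_calls["21"].call == "inconclusive"
    assert FLAG_BELOW_EUPLOID in rep.autosome_calls["21"].flags


def test_contaminated_trisomy_flag_and_fraction(config, noise_off, rng):
    """A maternally contaminated full trisomy lands between bands with the mosaic flag."""
    profile = trisomy_profile("mcc", "21", f=1.0, m=0.614, sex="male")
    chips = simulate_sample(profile, list(PANELS.values()), 3, config, noise_off, rng)
    rep = build_sample_report("mcc", chips, config, ClassificationBands())
    call = rep.autosome_calls["21"]
    assert call.call == "trisomy"
    assert FLAG_INTERMEDIATE in call.flags
    assert call.ratio.ratio == pytest.approx(1.193, abs=0.03)
    # implied aneuploid fraction ~ 2 (ratio - 1)
    assert rep.aneuploid_fraction == pytest.approx(0.386, abs=0.06)
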