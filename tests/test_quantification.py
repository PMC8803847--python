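"""Culture and qPCR quantification: protocol arithmetic, standard-curve
fitting, run adjustment, censoring, and category bins."""

import math

import numpy as np
import pytest

from jejuquant.quantification import (
    CensoredValue,
    CultureProtocolParams,
    MolecularProtocolParams,
    NO_AMPLIFICATION,
    calibration_curve,
    calibration_dilution_series,
    cfu_per_ml,
    culture_category,
    fit_standard_curve,
    genome_bin,
    genomes_per_ml,
    genomes_per_ul_from_mass,
    loq_genomes_per_ml,
    run_adjustment,
)


class TestCultureArithmetic:
    def test_one_colony_is_160_cfu_per_ml(self):
        assert cfu_per_ml(1) == CensoredValue(160.0)

    def test_dilution_factor_is_8(self):
        assert CultureProtocolParams().dilution_factor == pytest.approx(8.0)

    def test_zero_colonies_left_censored(self):
        assert cfu_per_ml(0) == CensoredValue(160.0, "<")

    def test_uncountable_plate_right_censored(self):
        assert cfu_per_ml(">100") == CensoredValue(16000.0, ">")

    def test_25_colonies(self):
        v = cfu_per_ml(25)
        assert v.value == pytest.approx(4000.0)
        assert culture_category(v) == "sparse growth"

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cfu_per_ml(-1)

    def test_strictly_increasing_in_colony_count(self):
        values = [cfu_per_ml(n).value for n in range(1, 101)]
        assert all(b > a for a, b in zip(values, values[1:]))


@pytest.mark.parametrize(
    "cfu, expected",
    [
        (CensoredValue(160.0, "<"), "no growth"),
        (CensoredValue(159.0), "no growth"),
        (CensoredValue(160.0), "single colonies/broth only"),
        (CensoredValue(1599.0), "single colonies/broth only"),
        (CensoredValue(1600.0), "sparse growth"),
        (CensoredValue(7999.0), "sparse growth"),
        (CensoredValue(8000.0), "moderate growth"),
        (CensoredValue(16000.0), "moderate growth"),
        (CensoredValue(16000.0, ">"), "abundant growth"),
        (CensoredValue(16001.0), "abundant growth"),
    ],
)
def test_culture_category_bin_edges(cfu, expected):
    assert culture_category(cfu) == expected


class TestGenomeEquivalents:
    def test_fluorometry_to_genome_concentration(self):
        # 38.3 ng/ul of a 2,096,423 bp genome -> 1.69e7 genomes/ul (3 s.f.)
        v = genomes_per_ul_from_mass(38.3, 2_096_423)
        assert v == pytest.approx(1.69e7, rel=5e-3)

    def test_linearity_in_mass(self):
        one = genomes_per_ul_from_mass(10.0, 3e6)
        assert genomes_per_ul_from_mass(20.0, 3e6) == pytest.approx(2 * one)

    def test_single_genome_inverse(self):
        # the mass of one 2,096,423 bp genome in ng
        mass = 2_096_423 * 650 / 6.02214076e23 * 1e9
        assert genomes_per_ul_from_mass(mass, 2_096_423) == pytest.approx(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            genomes_per_ul_from_mass(0.0, 2e6)


class TestStandardCurve:
    def test_noiseless_series_recovers_ideal_slope(self):
        curve = fit_standard_curve(calibration_dilution_series())
        assert curve.slope == pytest.approx(-3.3219, abs=1e-4)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)

    def test_plateaued_low_steps_excluded_from_linear_range(self):
        series = calibration_dilution_series()
        curve = fit_standard_curve(series)
        copies = sorted(c for c, _ in series)
        # two most dilute steps plateau and must fall outside the range
        assert curve.linear_range[0] == pytest.approx(copies[2])

    def test_loq_ct_at_lowest_linear_step(self):
        curve = fit_standard_curve(calibration_dilution_series())
        assert curve.loq_ct == pytest.approx(34.17, abs=1e-6)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(1e4, [20.0]), (1e3, [23.3])])

    def test_run_adjustment_offset(self):
        curve = calibration_curve()
        obs = [31.25, 31.11, 30.93]
        adj = run_adjustment(obs, curve, 33.8 * 4)
        assert adj.run_offset == pytest.approx(np.mean(obs) - curve.predict_ct(33.8 * 4))

    def test_zero_offset_when_observed_equals_prediction(self):
        curve = calibration_curve()
        pred = curve.predict_ct(135.2)
        adj = run_adjustment([pred, pred], curve, 135.2)
        assert adj.run_offset == pytest.approx(0.0, abs=1e-12)

    def test_offset_shifts_estimates_by_offset_over_slope(self):
        curve = calibration_curve()
        shifted = run_adjustment([curve.predict_ct(1000.0) + 0.5], curve, 1000.0)
        ct = 30.0
        # a run reading 0.5 Ct high raises every copy estimate by 0.5/|slope| logs
        delta = math.log10(shifted.invert_ct(ct)) - math.log10(curve.invert_ct(ct))
        assert delta == pytest.approx(0.5 / abs(curve.slope))


class TestGenomesPerMl:
    def test_loq_ct_maps_to_2816_genomes_per_ml(self):
        v = genomes_per_ml(34.17, calibration_curve())
        assert v.is_point
        assert round(v.value) == 2816

    def test_one_log_step_above_loq(self):
        curve = calibration_curve()
        v = genomes_per_ml(curve.loq_ct + curve.slope, curve)  # slope < 0
        loq = loq_genomes_per_ml(curve, MolecularProtocolParams())
        assert v.value == pytest.approx(10 * loq, rel=1e-9)

    def test_ct_beyond_linear_range_censored(self):
        v = genomes_per_ml(40.0, calibration_curve())
        assert v.censor == "<"
        assert round(v.value) == 2816

    def test_no_amplification_censored(self):
        assert genomes_per_ml(NO_AMPLIFICATION, calibration_curve()).censor == "<"


@pytest.mark.parametrize(
    "value, expected",
    [
        (CensoredValue(2816.0), "<2.9e3"),
        (CensoredValue(2815.54, "<"), "<2.9e3"),
        (CensoredValue(2900.0), "2.9e3-<1e4"),
        (CensoredValue(9999.0), "2.9e3-<1e4"),
        (CensoredValue(1e4), "1e4-<1e5"),
        (CensoredValue(99999.0), "1e4-<1e5"),
        (CensoredValue(1e5), "1e5-<1e6"),
    ],
)
def test_genome_bin_edges(value, expected):
    assert genome_bin(value) == expected


def test_genome_bin_warns_above_reported_range():
    with pytest.warns(UserWarning):
        assert genome_bin(CensoredValue(2e6)) == "1e5-<1e6"
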