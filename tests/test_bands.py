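"""Marker-band quantification and derived macromolecular statistics."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import ftirmacro as fm
from ftirmacro.bands import BandAssignment, band_intensity
from ftirmacro.errors import NormalizationError, UndefinedRatioError

from conftest import make_spectrum, single_band_effect

WN = np.arange(4000.0, 649.0, -1.0)
GRID = fm.WavenumberGrid()


def quantified(effect, doses=(0.0, 1.5), seed=7, n_bio=1, n_tech=1,
               cell="HCT116_like"):
    design = fm.SampleDesign((cell,), doses, n_bio, n_tech, seed=seed)
    spectra, ref = fm.generate_experiment(design, effects={cell: effect})
    absorbance, second = fm.preprocess_set(spectra, ref)
    return fm.quantify_bands(absorbance, second)


class TestBandIntensity:
    def test_absorbance_peak_value_and_position(self):
        s = make_spectrum(WN, fm.evaluate_band(fm.Band("e", 1172, 12, 0.4),
                                               GRID))
        ba = BandAssignment("ester", 1172, (1168, 1176), "absorbance",
                            "lipid")
        peak, intensity = band_intensity(s, ba)
        assert peak == 1172
        assert intensity == pytest.approx(0.4, abs=1e-12)

    def test_second_derivative_matches_analytic_gaussian(self):
        # closed form: min of d²/dν² of A·exp(−4ln2(ν−c)²/w²) is at the
        # center with magnitude 8·ln2·A/w²
        A, w = 0.4, 12.0
        k = 4 * math.log(2) / w**2
        x = WN - 1172
        d2 = A * np.exp(-k * x**2) * (4 * k**2 * x**2 - 2 * k)
        s = make_spectrum(WN, d2, state=("raw", "second_derivative"))
        ba = BandAssignment("ester", 1172, (1168, 1176),
                            "second_derivative", "lipid")
        peak, intensity = band_intensity(s, ba)
        assert peak == 1172
        assert intensity == pytest.approx(8 * math.log(2) * A / w**2,
                                          rel=1e-12)

    def test_flat_spectrum_tie_breaks_toward_center(self):
        s = make_spectrum(WN, np.zeros_like(WN))
        ba = BandAssignment("ester", 1172, (1168, 1176), "absorbance",
                            "lipid")
        peak, intensity = band_intensity(s, ba)
        assert intensity == 0.0
        assert peak == 1172

    def test_window_outside_grid_rejected(self):
        s = make_spectrum(WN, np.zeros_like(WN))
        ba = BandAssignment("x", 5000, (4990, 5010), "absorbance", "lipid")
        with pytest.raises(ValueError):
            band_intensity(s, ba)

    def test_assignment_validation(self):
        with pytest.raises(ValueError, match="outside window"):
            BandAssignment("x", 1300, (1168, 1176), "absorbance", "lipid")
        with pytest.raises(ValueError, match="source"):
            BandAssignment("x", 1172, (1168, 1176), "fourth_derivative",
                           "lipid")


def _toy_table(ut_values, treated_values, band="po2_antisym"):
    rows = []
    for i, v in enumerate(ut_values):
        rows.append(dict(sample_id=f"u{i}", cell_line="X", dose=0.0,
                         bio_rep=1, tech_rep=i + 1, band=band,
                         macro_class="nucleic_acid", source="absorbance",
                         peak_wavenumber=1240.0, intensity=v))
    for i, v in enumerate(treated_values):
        rows.append(dict(sample_id=f"t{i}", cell_line="X", dose=1.5,
                         bio_rep=1, tech_rep=i + 1, band=band,
                         macro_class="nucleic_acid", source="absorbance",
                         peak_wavenumber=1240.0, intensity=v))
    return pd.DataFrame(rows)


class TestPercentOfUntreated:
    def test_simple_percent(self):
        out = fm.percent_of_untreated(_toy_table([2, 2, 2], [1]))
        treated = out[out.dose == 1.5]["percent"]
        assert treated.iloc[0] == pytest.approx(50.0)

    def test_untreated_mean_is_100(self):
        out = fm.percent_of_untreated(_toy_table([1.0, 2.0, 3.5], [1]))
        assert out[out.dose == 0.0]["percent"].mean() == pytest.approx(
            100.0, abs=1e-12)

    def test_scale_invariance(self):
        t = _toy_table([1.0, 2.0], [1.5])
        doubled = t.copy()
        doubled["intensity"] *= 2
        a = fm.percent_of_untreated(t)["percent"]
        b = fm.percent_of_untreated(doubled)["percent"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_missing_untreated_group_rejected(self):
        t = _toy_table([1.0], [2.0])
        t = t[t.dose != 0.0]
        with pytest.raises(NormalizationError):
            fm.percent_of_untreated(t)


def _ratio_table(z, a, b, dose, n=2):
    rows = []
    for band, val in [("zdna", z), ("adna", a), ("bdna", b)]:
        for i in range(n):
            rows.append(dict(sample_id=f"s{dose}_{i}", cell_line="X",
                             dose=dose, bio_rep=1, tech_rep=i + 1,
                             band=band, macro_class="dna_form",
                             source="second_derivative",
                             peak_wavenumber=0.0, intensity=val))
    return pd.DataFrame(rows)


class TestZdnaRatio:
    def test_untreated_fold_is_one(self):
        t = pd.concat([_ratio_table(1, 2, 3, 0.0),
                       _ratio_table(2, 2, 3, 1.5)])
        out = fm.zdna_enhancement_ratio(t)
        assert out.loc[out.dose == 0.0, "fold_change"].iloc[0] == 1.0
        assert out.loc[out.dose == 1.5, "fold_change"].iloc[0] == \
            pytest.approx(2.0)

    def test_generator_multiplier_recovered_noise_free(self):
        table = quantified(single_band_effect("zdna_1066", 1.5, 1.6))
        out = fm.zdna_enhancement_ratio(table)
        fold = out.loc[out.dose == 1.5, "fold_change"].iloc[0]
        assert fold == pytest.approx(1.6, rel=1e-6)

    def test_zero_denominator_rejected(self):
        t = _ratio_table(1, 0, 0, 0.0)
        with pytest.raises(UndefinedRatioError):
            fm.zdna_enhancement_ratio(t)

    def test_fold_monotone_in_multiplier(self):
        folds = []
        for f in (1.2, 1.6, 2.0):
            table = quantified(single_band_effect("zdna_1066", 1.5, f))
            out = fm.zdna_enhancement_ratio(table)
            folds.append(out.loc[out.dose == 1.5, "fold_change"].iloc[0])
        assert folds[0] < folds[1] < folds[2]


class TestLipidSummary:
    def test_equal_intensities_give_quarter(self):
        from ftirmacro.bands import LIPID_BANDS
        rows = []
        for dose in (0.0, 1.5):
            for band in LIPID_BANDS:
                for i in range(2):
                    rows.append(dict(sample_id=f"s{dose}_{i}", cell_line="X",
                                     dose=dose, bio_rep=1, tech_rep=i + 1,
                                     band=band, macro_class="lipid",
                                     source="second_derivative",
                                     peak_wavenumber=0.0, intensity=1.0))
        t = fm.percent_of_untreated(pd.DataFrame(rows))
        out = fm.lipid_unsaturation_summary(t)
        np.testing.assert_allclose(out["olefinic_over_total_mean"], 25.0)

    def test_ratio_invariant_under_global_scaling(self):
        table = quantified(fm.noise_free(
            fm.default_effect_model("HCT116_like")))
        t1 = fm.percent_of_untreated(table)
        scaled = table.copy()
        scaled["intensity"] *= 3.0
        t2 = fm.percent_of_untreated(scaled)
        a = fm.lipid_unsaturation_summary(t1)["olefinic_over_total_mean"]
        b = fm.lipid_unsaturation_summary(t2)["olefinic_over_total_mean"]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_generator_olefinic_increase_visible(self):
        table = fm.percent_of_untreated(
            quantified(single_band_effect("olefinic", 1.5, 1.2)))
        out = fm.lipid_unsaturation_summary(table)
        ut = out.loc[out.dose == 0.0, "olefinic_over_total_mean"].iloc[0]
        tr = out.loc[out.dose == 1.5, "olefinic_over_total_mean"].iloc[0]
        # olefinic percent rises to 120 while the other three stay at 100:
        # ratio rises by 1.2 / (1 + 0.2 * w) with w the olefinic weight
        assert tr > ut
        assert tr / ut == pytest.approx(1.2 / (1 + 0.2 * ut / 100), rel=1e-3)


class TestSecondaryStructure:
    def test_textbook_conversion_arithmetic(self):
        rows = []
        for dose, alpha, beta in [(0.0, 10.0, 4.0), (0.1, 8.5, 5.5)]:
            for band, val in [("alpha_1657", alpha * 0.6),
                              ("alpha_1649", alpha * 0.4),
                              ("beta_1636", beta * 0.5),
                              ("beta_1629", beta * 0.5)]:
                rows.append(dict(sample_id=f"s{dose}", cell_line="X",
                                 dose=dose, bio_rep=1, tech_rep=1,
                                 band=band, macro_class="protein",
                                 source="second_derivative",
                                 peak_wavenumber=0.0, intensity=val))
        out = fm.secondary_structure_summary(pd.DataFrame(rows))
        conv = out.loc[out.dose == 0.1, "conversion_percent"].iloc[0]
        assert conv == pytest.approx(15.0)
        assert out.loc[out.dose == 0.0, "conversion_percent"].iloc[0] == 0.0

    def test_generator_conversion_recovered_noise_free(self):
        eff = fm.noise_free(fm.default_effect_model("HCT116_like"))
        eff = dataclasses.replace(eff, multipliers={0.0: {}, 1.5: {}},
                                  conversion={0.0: 0.0, 1.5: 0.40})
        out = fm.secondary_structure_summary(quantified(eff))
        conv = out.loc[out.dose == 1.5, "conversion_percent"].iloc[0]
        assert conv == pytest.approx(40.0, abs=1.5)

    def test_conversion_monotone_in_generator_parameter(self):
        convs = []
        for c in (0.1, 0.25, 0.4):
            eff = fm.noise_free(fm.default_effect_model("HCT116_like"))
            eff = dataclasses.replace(eff, multipliers={0.0: {}, 1.5: {}},
                                      conversion={0.0: 0.0, 1.5: c})
            out = fm.secondary_structure_summary(quantified(eff))
            convs.append(out.loc[out.dose == 1.5,
                                 "conversion_percent"].iloc[0])
        assert convs[0] < convs[1] < convs[2]

    def test_beta_gain_reported_alongside(self):
        eff = fm.noise_free(fm.default_effect_model("HCT116_like"))
        out = fm.secondary_structure_summary(quantified(eff))
        gain = out.loc[out.dose == 1.5, "beta_gain_percent"].iloc[0]
        assert gain > 0

    def test_zero_alpha_untreated_rejected(self):
        rows = [dict(sample_id="s", cell_line="X", dose=0.0, bio_rep=1,
                     tech_rep=1, band=b, macro_class="protein",
                     source="second_derivative", peak_wavenumber=0.0,
                     intensity=0.0)
                for b in ("alpha_1657", "alpha_1649", "beta_1636",
                          "beta_1629")]
        with pytest.raises(UndefinedRatioError):
            fm.secondary_structure_summary(pd.DataFrame(rows))


class TestMultiplierRecovery:
    """Noise-free parameter recovery through the full pipeline."""

    @pytest.mark.parametrize("band,mult", [
        ("cholesteryl_ester", 0.8),
        ("ribose_915", 0.75),
    ])
    def test_percent_tracks_multiplier(self, band, mult):
        table = fm.percent_of_untreated(
            quantified(single_band_effect(band, 1.5, mult)))
        name = {"cholesteryl_ester": "cholesteryl_ester",
                "ribose_915": "ribose"}[band]
        sub = table[(table.band == name) & (table.dose == 1.5)]
        # full-spectrum vector normalization drifts slightly once a band
        # changes, so recovery is near-exact rather than exact
        assert sub["percent"].mean() == pytest.approx(100 * mult, rel=5e-3)

    def test_recovery_with_default_noise_within_3_sem(self):
        # isolate the ester multiplier so only measurement noise remains;
        # the standard error must include the noisy untreated-mean
        # denominator shared by all percent values
        eff = single_band_effect("cholesteryl_ester", 1.5, 0.8)
        eff = dataclasses.replace(
            eff, noise_sd=fm.default_effect_model("HCT116_like").noise_sd)
        table = fm.percent_of_untreated(
            quantified(eff, doses=(0.0, 1.5), n_bio=3, n_tech=3, seed=21))
        band = table[table.band == "cholesteryl_ester"]
        treated = band[band.dose == 1.5]["percent"]
        ut = band[band.dose == 0.0]["percent"]
        mean, sem_t = fm.mean_sem(treated)
        _, sem_u = fm.mean_sem(ut)
        se = math.hypot(sem_t, 0.8 * sem_u)
        assert abs(mean - 80.0) <= 3 * se
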