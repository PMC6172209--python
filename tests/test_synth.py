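"""Synthetic-spectrum generator: band shapes, effect models, experiments."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ftirmacro as fm
from ftirmacro.synth import build_profile


# ---------------------------------------------------------------------------
# evaluate_band
# ---------------------------------------------------------------------------

class TestEvaluateBand:
    def test_gaussian_peak_value_and_location(self, grid):
        band = fm.Band("z", center=1066, fwhm=10, amplitude=0.5)
        trace = fm.evaluate_band(band, grid)
        i = int(np.argmax(trace))
        assert grid.wavenumbers[i] == 1066
        assert trace[i] == pytest.approx(0.5, abs=1e-15)
        assert (trace >= 0).all()

    def test_zero_amplitude_gives_zero_trace(self, grid):
        band = fm.Band("z", 1066, 10, 0.0)
        assert not fm.evaluate_band(band, grid).any()

    @pytest.mark.parametrize("eta,pure", [(0.0, "gaussian"),
                                          (1.0, "lorentzian")])
    def test_pseudo_voigt_limits(self, grid, eta, pure):
        pv = fm.Band("b", 1500, 20, 0.3, shape="pseudo_voigt", eta=eta)
        ref = fm.Band("b", 1500, 20, 0.3, shape=pure)
        np.testing.assert_array_equal(fm.evaluate_band(pv, grid),
                                      fm.evaluate_band(ref, grid))

    def test_symmetry_about_center_on_symmetric_grid(self):
        g = fm.WavenumberGrid(1100, 1032, 1.0)  # symmetric around 1066
        trace = fm.evaluate_band(fm.Band("z", 1066, 12, 1.0), g)
        np.testing.assert_allclose(trace, trace[::-1], atol=1e-15)

    def test_center_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside grid"):
            fm.evaluate_band(fm.Band("x", 5000, 10, 1.0), grid)

    @pytest.mark.parametrize("bad", [
        dict(fwhm=0.0), dict(fwhm=-1.0), dict(amplitude=-0.1),
        dict(shape="voigt"), dict(eta=1.5),
    ])
    def test_invalid_band_fields_rejected(self, bad):
        kwargs = dict(name="b", center=1000.0, fwhm=10.0, amplitude=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            fm.Band(**kwargs)


# ---------------------------------------------------------------------------
# build_profile
# ---------------------------------------------------------------------------

def _mini_profile():
    return [
        fm.Band("amide_i_alpha_1657", 1657, 9, 0.30),
        fm.Band("amide_i_alpha_1649", 1649, 9, 0.20),
        fm.Band("amide_i_beta_1636", 1636, 9, 0.10),
        fm.Band("amide_i_beta_1629", 1629, 9, 0.05),
        fm.Band("zdna_1066", 1066, 10, 0.01),
    ]


def _effect(dose, mult=None, c=0.0):
    return fm.EffectModel(
        cell_line="HCT116_like",
        multipliers={0.0: {}, dose: mult or {}},
        conversion={0.0: 0.0, dose: c},
    )


class TestBuildProfile:
    def test_dose_zero_is_identity(self):
        base = _mini_profile()
        out = build_profile(base, _effect(1.5, {"zdna_1066": 1.6}, 0.3),
                            0.0, "HCT116_like")
        assert out == base

    def test_conversion_arithmetic(self):
        # c = 0.15 removes 15% of each alpha amplitude; betas gain the
        # removed total split equally
        out = build_profile(_mini_profile(), _effect(0.1, c=0.15),
                            0.1, "HCT116_like")
        amp = {b.name: b.amplitude for b in out}
        assert amp["amide_i_alpha_1657"] == pytest.approx(0.255)
        assert amp["amide_i_alpha_1649"] == pytest.approx(0.170)
        gain = (amp["amide_i_beta_1636"] - 0.10) + (amp["amide_i_beta_1629"]
                                                    - 0.05)
        assert gain == pytest.approx(0.075)

    def test_z_multiplier_exact(self):
        out = build_profile(_mini_profile(),
                            _effect(1.5, {"zdna_1066": 1.6}), 1.5,
                            "HCT116_like")
        amp = {b.name: b.amplitude for b in out}
        assert amp["zdna_1066"] == pytest.approx(0.016, rel=1e-15)

    def test_unknown_cell_line_rejected(self):
        with pytest.raises(ValueError, match="unknown cell line"):
            build_profile(_mini_profile(), _effect(1.5), 1.5, "HeLa")

    def test_dose_interpolation_linear(self):
        eff = fm.EffectModel("HCT116_like",
                             multipliers={0.0: {}, 1.0: {"zdna_1066": 2.0}},
                             conversion={0.0: 0.0, 1.0: 0.4})
        assert eff.multiplier("zdna_1066", 0.5) == pytest.approx(1.5)
        assert eff.conversion_at(0.25) == pytest.approx(0.1)
        with pytest.raises(ValueError, match="outside"):
            eff.multiplier("zdna_1066", 2.0)

    @given(c=st.floats(0.0, 1.0))
    def test_amide_amplitude_conserved_under_conversion(self, c):
        base = _mini_profile()
        out = build_profile(base, _effect(1.0, c=c), 1.0, "HCT116_like")
        names = ("amide_i_alpha_1657", "amide_i_alpha_1649",
                 "amide_i_beta_1636", "amide_i_beta_1629")
        before = sum(b.amplitude for b in base if b.name in names)
        after = sum(b.amplitude for b in out if b.name in names)
        assert after == pytest.approx(before, rel=1e-12)

    def test_effect_model_invariants_enforced(self):
        with pytest.raises(ValueError, match="dose 0"):
            fm.EffectModel("x", multipliers={0.5: {}},
                           conversion={0.0: 0.0, 0.5: 0.1})
        with pytest.raises(ValueError, match="equal 1.0"):
            fm.EffectModel("x", multipliers={0.0: {"a": 0.9}},
                           conversion={0.0: 0.0})
        with pytest.raises(ValueError, match="negative multiplier"):
            fm.EffectModel("x", multipliers={0.0: {}, 1.0: {"a": -0.1}},
                           conversion={0.0: 0.0, 1.0: 0.0})


# ---------------------------------------------------------------------------
# generate_experiment
# ---------------------------------------------------------------------------

class TestGenerateExperiment:
    def test_sample_count_and_grouping(self, noise_free_small_set):
        spectra, _ = noise_free_small_set
        assert len(spectra) == 27
        doses = [s.metadata["dose"] for s in spectra]
        for d in (0.0, 0.5, 1.5):
            assert doses.count(d) == 9

    def test_seed_determinism(self):
        design = fm.SampleDesign(("HCT116_like",), (0.0, 1.5), 2, 2, seed=7)
        a, ra = fm.generate_experiment(design)
        b, rb = fm.generate_experiment(design)
        np.testing.assert_array_equal(a.matrix(), b.matrix())
        np.testing.assert_array_equal(ra.values, rb.values)

    def test_different_seed_differs(self):
        d1 = fm.SampleDesign(("HCT116_like",), (0.0,), 1, 1, seed=1)
        d2 = fm.SampleDesign(("HCT116_like",), (0.0,), 1, 1, seed=2)
        a, _ = fm.generate_experiment(d1)
        b, _ = fm.generate_experiment(d2)
        assert not np.array_equal(a.matrix(), b.matrix())

    def test_noise_free_spectrum_is_exact_band_sum(self, grid, quiet_effect):
        design = fm.SampleDesign(("HCT116_like",), (0.0,), 1, 1, seed=3)
        spectra, ref = fm.generate_experiment(
            design, effects={"HCT116_like": quiet_effect})
        bands = fm.default_base_profile("HCT116_like")
        expected = sum(fm.evaluate_band(b, grid) for b in bands)
        expected = expected + quiet_effect.baseline.trace(grid)
        expected = expected + fm.evaluate_band(
            fm.Band("w", quiet_effect.water_center, quiet_effect.water_fwhm,
                    quiet_effect.water_amplitude), grid)
        np.testing.assert_allclose(spectra[0].values, expected, atol=1e-15)
        # reference is baseline + water only
        cellular = spectra[0].values - ref.values
        assert cellular.max() > 0.05

    def test_noise_free_spectra_non_negative(self, quiet_effect):
        eff = dataclasses.replace(quiet_effect, bio_jitter_sd=0.05,
                                  baseline_jitter_sd=0.2)
        design = fm.SampleDesign(("HCT116_like",), (0.0, 1.5), 2, 2, seed=11)
        spectra, _ = fm.generate_experiment(design,
                                            effects={"HCT116_like": eff})
        for s in spectra:
            assert (s.values >= 0).all()

    def test_bio_rep_jitter_shared_across_tech_reps(self, quiet_effect):
        eff = dataclasses.replace(quiet_effect, bio_jitter_sd=0.1)
        design = fm.SampleDesign(("HCT116_like",), (0.0,), 2, 2, seed=5)
        spectra, _ = fm.generate_experiment(design,
                                            effects={"HCT116_like": eff})
        by = {(s.metadata["bio_rep"], s.metadata["tech_rep"]): s.values
              for s in spectra}
        np.testing.assert_array_equal(by[(1, 1)], by[(1, 2)])
        assert not np.array_equal(by[(1, 1)], by[(2, 1)])

    def test_between_dose_distance_monotone_in_multiplier(self, quiet_effect):
        # stronger Z enhancement moves the treated mean spectrum further
        # from untreated
        dists = []
        for f in (1.2, 1.6, 2.0):
            eff = dataclasses.replace(
                quiet_effect,
                multipliers={0.0: {}, 1.5: {"zdna_1066": f}},
                conversion={0.0: 0.0, 1.5: 0.0})
            design = fm.SampleDesign(("HCT116_like",), (0.0, 1.5), 1, 1,
                                     seed=1)
            spectra, _ = fm.generate_experiment(
                design, effects={"HCT116_like": eff})
            ut = spectra.filter(dose=0.0).matrix().mean(axis=0)
            tr = spectra.filter(dose=1.5).matrix().mean(axis=0)
            dists.append(np.linalg.norm(tr - ut))
        assert dists[0] < dists[1] < dists[2]

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            fm.SampleDesign(("HCT116_like",), (0.0,), 0, 3)
        with pytest.raises(ValueError, match="unknown cell line"):
            fm.default_base_profile("HeLa")
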