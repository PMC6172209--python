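import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ftirmacro as fm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return fm.WavenumberGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_effect():
    """Default HCT-116-like effect model with noise and jitter off."""
    return fm.noise_free(fm.default_effect_model("HCT116_like"))


def make_spectrum(wavenumbers, values, state=("raw",), **meta):
    meta.setdefault("sample_id", "s")
    return fm.Spectrum(np.asarray(wavenumbers, dtype=float),
                       np.asarray(values, dtype=float), meta, tuple(state))


@pytest.fixture(scope="session")
def noise_free_small_set(quiet_effect):
    """27 noise-free spectra (UT / 0.5 / 1.5), plus the PBS reference."""
    design = fm.SampleDesign(("HCT116_like",), (0.0, 0.5, 1.5), 3, 3, seed=7)
    return fm.generate_experiment(design,
                                  effects={"HCT116_like": quiet_effect})


def single_band_effect(band_name, dose, multiplier, base="HCT116_like"):
    """Effect model that scales exactly one band at one dose."""
    eff = fm.noise_free(fm.default_effect_model(base))
    return dataclasses.replace(
        eff,
        multipliers={0.0: {}, dose: {band_name: multiplier}},
        conversion={0.0: 0.0, dose: 0.0},
    )
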