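"""Synthetic ATR-FTIR spectra of epithelial cell films.

The generator emulates the experiment the downstream analysis expects:
replicated cell samples (biological × technical replicates) measured at a
series of DMSO doses (% v/v), each spectrum a sum of macromolecular marker
bands on a smooth baseline with a residual free-water band near 2125 cm⁻¹
and i.i.d. gaussian detector noise.  Dose acts through an
:class:`EffectModel`: per-band amplitude multipliers (nucleic-acid decrease,
Z-DNA enhancement, cholesteryl-ester decrease, cell-line-specific olefinic
response) plus a compositional α-helix→β-sheet conversion that moves
amide-I amplitude from the 1657/1649 cm⁻¹ components to the 1636/1629 cm⁻¹
components while conserving their sum.

Everything is deterministic under the design seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .grid import WavenumberGrid
from .spectrum import Spectrum, SpectrumSet

__all__ = [
    "Band",
    "BaselineParams",
    "EffectModel",
    "SampleDesign",
    "evaluate_band",
    "build_profile",
    "generate_experiment",
    "default_base_profile",
    "default_effect_model",
    "DEFAULT_CELL_LINES",
]

_SHAPES = ("gaussian", "lorentzian", "pseudo_voigt")


@dataclass(frozen=True)
class Band:
    """One spectral band: ``name``, position ``center`` (cm⁻¹), ``fwhm``
    (cm⁻¹, > 0), peak ``amplitude`` (absorbance units, ≥ 0) and line
    ``shape`` (gaussian, lorentzian or pseudo_voigt with mixing ``eta``)."""

    name: str
    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"
    eta: float = 0.5  # pseudo-Voigt Lorentzian fraction

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown band shape {self.shape!r}")
        if self.fwhm <= 0:
            raise ValueError(f"band {self.name}: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band {self.name}: amplitude must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"band {self.name}: eta must lie in [0, 1]")


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-4.0 * math.log(2.0) * (x - center) ** 2 / fwhm**2)


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    h = fwhm / 2.0
    return h**2 / ((x - center) ** 2 + h**2)


def evaluate_band(band: Band, grid: WavenumberGrid) -> np.ndarray:
    """Evaluate one band on a grid; unit peak value at the band center.

    The trace is non-negative everywhere and attains its maximum at the
    grid point nearest ``band.center``.
    """
    if not grid.contains(band.center):
        raise ValueError(
            f"band {band.name!r} center {band.center} cm-1 outside grid "
            f"[{grid.end}, {grid.start}] cm-1"
        )
    x = grid.wavenumbers
    if band.shape == "gaussian":
        profile = _gaussian(x, band.center, band.fwhm)
    elif band.shape == "lorentzian":
        profile = _lorentzian(x, band.center, band.fwhm)
    else:  # pseudo-Voigt
        profile = (band.eta * _lorentzian(x, band.center, band.fwhm)
                   + (1.0 - band.eta) * _gaussian(x, band.center, band.fwhm))
    return band.amplitude * profile


@dataclass(frozen=True)
class BaselineParams:
    """Smooth additive baseline: offset + linear tilt + one broad hump
    (scattering / bound-water envelope).  All components non-negative so
    noise-free spectra stay non-negative."""

    offset: float = 0.002
    tilt: float = 0.001        # rise from low- to high-wavenumber end
    hump_amplitude: float = 0.004
    hump_center: float = 3350.0
    hump_fwhm: float = 500.0

    def trace(self, grid: WavenumberGrid) -> np.ndarray:
        wn = grid.wavenumbers
        frac = (wn - wn.min()) / max(wn.max() - wn.min(), 1.0)
        return (self.offset
                + self.tilt * frac
                + self.hump_amplitude * _gaussian(wn, self.hump_center,
                                                  self.hump_fwhm))


def _interp_dose(table: Mapping[float, float], dose: float, what: str) -> float:
    """Linear interpolation of a per-dose scalar; doses outside the table's
    range are rejected."""
    doses = np.array(sorted(table))
    vals = np.array([table[d] for d in doses])
    if dose < doses[0] or dose > doses[-1]:
        raise ValueError(
            f"dose {dose} outside {what} table range [{doses[0]}, {doses[-1]}]"
        )
    return float(np.interp(dose, doses, vals))


@dataclass(frozen=True)
class EffectModel:
    """Per-cell-line dose response.

    ``multipliers`` maps dose (% v/v) → {band name → amplitude multiplier};
    bands not listed keep multiplier 1.  ``conversion`` maps dose → fraction
    c ∈ [0, 1] of total α-helix amide-I amplitude transferred to the β-sheet
    components (split equally between them).  Doses absent from either table
    are linearly interpolated.  Replicate structure: one multiplicative
    log-normal amplitude jitter per band per biological replicate
    (``bio_jitter_sd`` = sd of log), per-sample log-normal scatter of the
    baseline and residual-water amplitudes, and i.i.d. gaussian noise of
    ``noise_sd`` absorbance units.
    """

    cell_line: str
    multipliers: Mapping[float, Mapping[str, float]]
    conversion: Mapping[float, float]
    alpha_bands: tuple[str, ...] = ("amide_i_alpha_1657", "amide_i_alpha_1649")
    beta_bands: tuple[str, ...] = ("amide_i_beta_1636", "amide_i_beta_1629")
    baseline: BaselineParams = field(default_factory=BaselineParams)
    noise_sd: float = 2e-4
    water_amplitude: float = 0.015
    water_center: float = 2125.0
    water_fwhm: float = 70.0
    bio_jitter_sd: float = 0.02
    baseline_jitter_sd: float = 0.10
    water_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if 0.0 not in self.multipliers or 0.0 not in self.conversion:
            raise ValueError("effect tables must include dose 0 (untreated)")
        if any(abs(m - 1.0) > 1e-12 for m in self.multipliers[0.0].values()):
            raise ValueError("all multipliers at dose 0 must equal 1.0")
        if abs(self.conversion[0.0]) > 1e-12:
            raise ValueError("conversion at dose 0 must be 0")
        for dose, table in self.multipliers.items():
            for name, m in table.items():
                if m < 0:
                    raise ValueError(
                        f"negative multiplier for {name!r} at dose {dose}")
        for dose, c in self.conversion.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"conversion at dose {dose} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def multiplier(self, band_name: str, dose: float) -> float:
        table = {d: m.get(band_name, 1.0) for d, m in self.multipliers.items()}
        return _interp_dose(table, dose, "multiplier")

    def conversion_at(self, dose: float) -> float:
        return _interp_dose(dict(self.conversion), dose, "conversion")


@dataclass(frozen=True)
class SampleDesign:
    """Which samples to generate: cell lines × doses × replicates."""

    cell_lines: tuple[str, ...] = ("HCT116_like",)
    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 1.5)
    n_bio: int = 3
    n_tech: int = 3
    seed: int = 0
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        if not self.cell_lines or not self.doses:
            raise ValueError("need at least one cell line and one dose")


def build_profile(base_bands: Sequence[Band], effect: EffectModel,
                  dose: float, cell_line: str) -> list[Band]:
    """Apply an effect model at one dose to a base band profile.

    Dose multipliers scale band amplitudes; the α→β conversion then removes
    fraction c of each α-component amplitude and distributes the removed
    total equally over the β components, conserving summed amide-I
    amplitude.
    """
    if cell_line != effect.cell_line:
        raise ValueError(
            f"unknown cell line {cell_line!r} for effect model of "
            f"{effect.cell_line!r}")
    scaled = [replace(b, amplitude=b.amplitude * effect.multiplier(b.name, dose))
              for b in base_bands]
    c = effect.conversion_at(dose)
    if c == 0.0:
        return scaled
    names = [b.name for b in scaled]
    alpha_idx = [names.index(n) for n in effect.alpha_bands if n in names]
    beta_idx = [names.index(n) for n in effect.beta_bands if n in names]
    if not alpha_idx or not beta_idx:
        return scaled
    removed = c * sum(scaled[i].amplitude for i in alpha_idx)
    gain = removed / len(beta_idx)
    out = list(scaled)
    for i in alpha_idx:
        out[i] = replace(out[i], amplitude=out[i].amplitude * (1.0 - c))
    for i in beta_idx:
        out[i] = replace(out[i], amplitude=out[i].amplitude + gain)
    if any(b.amplitude < 0 for b in out):  # conversion cannot produce this
        raise RuntimeError("internal error: negative band amplitude")
    return out


# ---------------------------------------------------------------------------
# default profiles and effect models
# ---------------------------------------------------------------------------

DEFAULT_CELL_LINES = ("HCT116_like", "SW480_like", "MCF10A_like")

# Common cellular band inventory.  Amplitudes are in absorbance units on the
# scale of a dried 5e5-cell film; amide-I secondary-structure components are
# kept narrow (8.5 cm-1) as effective second-derivative sub-bands.
_COMMON_BANDS: tuple[tuple[str, float, float, float], ...] = (
    # name, center, fwhm, amplitude
    ("amide_a",            3290.0, 120.0, 0.060),
    ("olefinic",           3009.0,  14.0, 0.010),
    ("ch3_antisym",        2958.0,  16.0, 0.020),
    ("ch2_antisym",        2921.0,  16.0, 0.045),
    ("ch3_sym",            2872.0,  14.0, 0.012),
    ("ch2_sym",            2852.0,  14.0, 0.030),
    ("amide_i_alpha_1657", 1657.0,   8.5, 0.080),
    ("amide_i_alpha_1649", 1649.0,   8.5, 0.055),
    ("amide_i_beta_1636",  1636.0,   8.5, 0.035),
    ("amide_i_beta_1629",  1629.0,   8.5, 0.025),
    ("amide_ii_1548",      1548.0,  12.0, 0.070),
    ("amide_ii_1516",      1516.0,  12.0, 0.030),
    ("ch2_bend",           1454.0,  18.0, 0.030),
    ("coo_sym",            1398.0,  20.0, 0.028),
    ("po2_antisym_a",      1240.0,  12.0, 0.025),
    ("po2_antisym_b",      1221.0,  12.0, 0.030),
    ("cholesteryl_ester",  1172.0,  12.0, 0.012),
    ("zdna_1066",          1066.0,  10.0, 0.008),
    ("carbohydrate_1025",  1025.0,  14.0, 0.020),
    ("ribose_915",          915.0,  12.0, 0.012),
)

# Cell-line-specific amplitude overrides, dominated by membrane-lipid
# differences (what separates the lines in the 3030-2830 cm-1 region).
_LINE_OVERRIDES: dict[str, dict[str, float]] = {
    "HCT116_like": {},
    "SW480_like": {
        "ch2_antisym": 0.054,
        "ch2_sym": 0.037,
        "ch3_antisym": 0.024,
        "olefinic": 0.007,
        "cholesteryl_ester": 0.015,
    },
    "MCF10A_like": {
        "ch2_antisym": 0.040,
        "ch2_sym": 0.026,
        "olefinic": 0.012,
        "cholesteryl_ester": 0.010,
    },
}

# Dose multiplier tables.  Magnitudes for bands the source experiments
# report only as significant increases/decreases are emulation defaults
# chosen to reproduce the qualitative dose pattern at n = 9; they are not
# measured values.  Dose 1.0 is deliberately absent and exercises linear
# interpolation.
def _dose_table(po2: float, ribose: float, z: float, ester: float,
                olefinic: float) -> dict[str, float]:
    return {
        "po2_antisym_a": po2,
        "po2_antisym_b": po2,
        "ribose_915": ribose,
        "zdna_1066": z,
        "cholesteryl_ester": ester,
        "olefinic": olefinic,
    }


_DEFAULT_MULTIPLIERS: dict[str, dict[float, dict[str, float]]] = {
    "HCT116_like": {
        0.0: _dose_table(1.00, 1.00, 1.00, 1.00, 1.00),
        0.1: _dose_table(0.99, 0.88, 1.20, 0.97, 1.15),
        0.5: _dose_table(0.97, 0.84, 1.40, 0.92, 1.20),
        1.5: _dose_table(0.80, 0.73, 1.70, 0.80, 1.00),
    },
    "SW480_like": {
        0.0: _dose_table(1.00, 1.00, 1.00, 1.00, 1.00),
        0.1: _dose_table(0.99, 0.89, 1.18, 0.97, 1.02),
        0.5: _dose_table(0.97, 0.85, 1.35, 0.93, 1.05),
        1.5: _dose_table(0.82, 0.75, 1.65, 0.82, 1.25),
    },
    "MCF10A_like": {
        0.0: _dose_table(1.00, 1.00, 1.00, 1.00, 1.00),
        0.1: _dose_table(0.95, 0.87, 1.22, 0.97, 1.10),
        0.5: _dose_table(0.90, 0.83, 1.42, 0.93, 1.12),
        1.5: _dose_table(0.72, 0.72, 1.75, 0.82, 1.05),
    },
}

_DEFAULT_CONVERSION: dict[float, float] = {0.0: 0.0, 0.1: 0.15, 0.5: 0.30,
                                           1.5: 0.40}


def default_base_profile(cell_line: str = "HCT116_like") -> list[Band]:
    """Default band inventory for one cell line (gaussian shapes)."""
    if cell_line not in _LINE_OVERRIDES:
        raise ValueError(f"unknown cell line {cell_line!r}; "
                         f"known: {sorted(_LINE_OVERRIDES)}")
    over = _LINE_OVERRIDES[cell_line]
    return [Band(name, center, fwhm, over.get(name, amp))
            for name, center, fwhm, amp in _COMMON_BANDS]


def default_effect_model(cell_line: str = "HCT116_like", **kwargs) -> EffectModel:
    """Default dose-response model for one cell line; keyword overrides
    pass through to :class:`EffectModel` (e.g. ``noise_sd=0`` for
    noise-free runs)."""
    if cell_line not in _DEFAULT_MULTIPLIERS:
        raise ValueError(f"unknown cell line {cell_line!r}; "
                         f"known: {sorted(_DEFAULT_MULTIPLIERS)}")
    return EffectModel(cell_line=cell_line,
                       multipliers=_DEFAULT_MULTIPLIERS[cell_line],
                       conversion=dict(_DEFAULT_CONVERSION),
                       **kwargs)


def noise_free(model: EffectModel) -> EffectModel:
    """Copy of an effect model with noise and all jitter switched off."""
    return replace(model, noise_sd=0.0, bio_jitter_sd=0.0,
                   baseline_jitter_sd=0.0, water_jitter_sd=0.0)


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------

def generate_experiment(
    design: SampleDesign,
    base_profiles: Mapping[str, Sequence[Band]] | None = None,
    effects: Mapping[str, EffectModel] | None = None,
) -> tuple[SpectrumSet, Spectrum]:
    """Generate one full experiment plus the PBS reference spectrum.

    Returns one spectrum per (cell line × dose × biological replicate ×
    technical replicate), in that nesting order, and a clean reference
    (baseline + residual water band, no cellular bands) for background
    subtraction.  Identical seeds give bit-identical output.
    """
    grid = design.grid
    if base_profiles is None:
        base_profiles = {cl: default_base_profile(cl)
                         for cl in design.cell_lines}
    if effects is None:
        effects = {cl: default_effect_model(cl) for cl in design.cell_lines}
    for cl in design.cell_lines:
        if cl not in base_profiles or cl not in effects:
            raise ValueError(f"no profile/effect model for cell line {cl!r}")

    rng = np.random.default_rng(design.seed)
    ref_effect = effects[design.cell_lines[0]]
    water = Band("residual_water", ref_effect.water_center,
                 ref_effect.water_fwhm, ref_effect.water_amplitude)
    water_trace = evaluate_band(water, grid)
    n = len(grid)

    spectra: list[Spectrum] = []
    for cell_line in design.cell_lines:
        eff = effects[cell_line]
        base = list(base_profiles[cell_line])
        baseline_trace = eff.baseline.trace(grid)
        for bio in range(1, design.n_bio + 1):
            # biological-replicate amplitude jitter, shared by all of this
            # replicate's technical replicates and doses
            jitter = np.exp(rng.normal(0.0, eff.bio_jitter_sd, len(base)))
            for dose in design.doses:
                bands = build_profile(base, eff, dose, cell_line)
                signal = np.zeros(n)
                for b, j in zip(bands, jitter):
                    signal += evaluate_band(
                        replace(b, amplitude=b.amplitude * j), grid)
                for tech in range(1, design.n_tech + 1):
                    base_scale = math.exp(
                        rng.normal(0.0, eff.baseline_jitter_sd))
                    water_scale = math.exp(
                        rng.normal(0.0, eff.water_jitter_sd))
                    noise = rng.normal(0.0, eff.noise_sd, n) \
                        if eff.noise_sd > 0 else np.zeros(n)
                    values = (signal
                              + base_scale * baseline_trace
                              + water_scale * water_trace
                              + noise)
                    meta = {
                        "sample_id": f"{cell_line}_d{dose:g}_b{bio}_t{tech}",
                        "cell_line": cell_line,
                        "dose": float(dose),
                        "bio_rep": bio,
                        "tech_rep": tech,
                    }
                    spectra.append(Spectrum(grid.wavenumbers.copy(),
                                            values, meta))

    reference = Spectrum(
        grid.wavenumbers.copy(),
        ref_effect.baseline.trace(grid) + water_trace,
        {"sample_id": "PBS_reference", "cell_line": "", "dose": np.nan,
         "bio_rep": 0, "tech_rep": 0},
    )
    return SpectrumSet(spectra), reference
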