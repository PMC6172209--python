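"""Spectral preprocessing.

The analysis uses two representations of each background-subtracted
spectrum: the vector-normalized absorbance spectrum (absolute band
intensities of the amide and phosphate bands) and the vector-normalized
second-derivative spectrum (band-position accuracy; all other marker
bands).  Order matters and is fixed here: background subtraction →
(optional Savitzky–Golay second derivative) → vector normalization.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateReferenceError, DegenerateSpectrumError
from .spectrum import Spectrum, SpectrumSet, window_mask

__all__ = [
    "subtract_reference",
    "savgol_derivative",
    "vector_normalize",
    "minmax_normalize",
    "extract_region",
    "mean_center",
]

#: default window (cm⁻¹) in which the residual free-water band is flattened
DEFAULT_FLATTEN_WINDOW = (2050.0, 2200.0)

#: default Savitzky–Golay parameters for 4 cm⁻¹-resolution data on a
#: 1 cm⁻¹ grid
DEFAULT_SG_WINDOW = 9
DEFAULT_SG_POLY = 3


def _project_out_line(values: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Residual of ``values`` after removing its least-squares straight line
    in ``wavenumbers``."""
    A = np.column_stack([np.ones_like(wavenumbers), wavenumbers])
    coef, *_ = np.linalg.lstsq(A, values, rcond=None)
    return values - A @ coef


def subtract_reference(
    sample: Spectrum,
    reference: Spectrum,
    flatten_window: tuple[float, float] = DEFAULT_FLATTEN_WINDOW,
) -> Spectrum:
    """Scaled background subtraction with free-water flattening.

    Returns ``sample − k·reference`` with the scale ``k`` chosen so that,
    inside ``flatten_window`` (default 2050–2200 cm⁻¹, bracketing the
    residual free-water band at ~2125 cm⁻¹), the difference is as close to
    a straight line as possible (least squares).  ``k`` is recorded in the
    output metadata as ``subtraction_scale``.
    """
    sample.require_same_grid(reference)
    mask = window_mask(sample.wavenumbers, *flatten_window)
    if not mask.any():
        raise ValueError("flatten window does not overlap the grid")
    wn = sample.wavenumbers[mask]
    r = _project_out_line(reference.values[mask], wn)
    denom = float(r @ r)
    if denom <= 1e-30:
        raise DegenerateReferenceError(
            "reference has no non-linear structure in the flatten window")
    s = _project_out_line(sample.values[mask], wn)
    k = float(s @ r) / denom
    out = sample.values - k * reference.values
    return sample.with_values(out, add_state="background_subtracted",
                              subtraction_scale=k)


def savgol_derivative(
    s: Spectrum,
    window_points: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_POLY,
    deriv: int = 2,
) -> Spectrum:
    """Savitzky–Golay smoothing (deriv=0) or second derivative (deriv=2).

    The derivative is taken with respect to wavenumber (d²A/dν², units
    absorbance·cm²); edge points come from the polynomial fitted on the
    truncated window.  The second derivative is invariant to the descending
    axis direction.
    """
    if deriv not in (0, 2):
        raise ValueError("deriv must be 0 or 2")
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points > s.values.size:
        raise ValueError("window_points exceeds trace length")
    if poly_order >= window_points:
        raise ValueError("poly_order must be smaller than window_points")
    if deriv > poly_order:
        raise ValueError("deriv must not exceed poly_order")
    out = savgol_filter(s.values, window_points, poly_order, deriv=deriv,
                        delta=s.step, mode="interp")
    state = "second_derivative" if deriv == 2 else None
    return s.with_values(out, add_state=state,
                         sg_window=window_points, sg_poly=poly_order)


def vector_normalize(s: Spectrum,
                     region: tuple[float, float] | None = None) -> Spectrum:
    """Divide by the Euclidean norm computed over ``region`` (default: the
    full grid).  The whole spectrum is rescaled; its norm over the region
    becomes exactly 1."""
    if region is None:
        seg = s.values
    else:
        seg = s.values[window_mask(s.wavenumbers, *region)]
    norm = float(np.linalg.norm(seg))
    if norm <= 1e-30:
        raise DegenerateSpectrumError("zero-norm spectrum cannot be normalized")
    return s.with_values(s.values / norm, add_state="vector_normalized")


def minmax_normalize(s: Spectrum,
                     anchor_window: tuple[float, float]) -> Spectrum:
    """Affine rescale: the global minimum maps to 0 and the maximum inside
    ``anchor_window`` (typically the amide I/II region) maps to 1."""
    mask = window_mask(s.wavenumbers, *anchor_window)
    if not mask.any():
        raise ValueError("anchor window does not overlap the grid")
    lo = float(s.values.min())
    hi = float(s.values[mask].max())
    if hi - lo <= 1e-30:
        raise DegenerateSpectrumError("flat spectrum cannot be min/max normalized")
    return s.with_values((s.values - lo) / (hi - lo),
                         add_state="minmax_normalized")


def extract_region(s: Spectrum, region: tuple[float, float]) -> Spectrum:
    """Closed-interval sub-spectrum; descending order preserved."""
    mask = window_mask(s.wavenumbers, *region)
    if not mask.any():
        raise ValueError(f"region {region} does not overlap the grid")
    return Spectrum(s.wavenumbers[mask], s.values[mask],
                    dict(s.metadata), s.state)


def mean_center(spectra: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    """Column-mean-center a spectrum set; returns (centered matrix, means)."""
    X = spectra.matrix()
    mu = X.mean(axis=0)
    return X - mu, mu
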