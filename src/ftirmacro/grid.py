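"""Wavenumber grids.

FTIR spectra are conventionally stored high-to-low in wavenumber; every grid
in this package is strictly monotone *descending*.  The instrument the
analysis emulates scans 4000–650 cm⁻¹ at a nominal 4 cm⁻¹ optical
resolution, exported on a 1 cm⁻¹ interpolated grid — hence the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class WavenumberGrid:
    """A descending, evenly spaced wavenumber axis in cm⁻¹.

    Parameters
    ----------
    start : float
        High-wavenumber end (default 4000 cm⁻¹).
    end : float
        Low-wavenumber end (default 650 cm⁻¹); must satisfy ``start > end``.
    step : float
        Grid spacing in cm⁻¹ (positive; default 1.0).
    """

    start: float = 4000.0
    end: float = 650.0
    step: float = 1.0
    wavenumbers: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.start > self.end:
            raise ValueError(f"start ({self.start}) must exceed end ({self.end})")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")
        n = int(np.floor((self.start - self.end) / self.step)) + 1
        wn = self.start - self.step * np.arange(n, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        self.wavenumbers.setflags(write=False)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def contains(self, wavenumber: float) -> bool:
        """Whether ``wavenumber`` lies within [end, start] (closed)."""
        return self.wavenumbers[-1] <= wavenumber <= self.wavenumbers[0]

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def window_mask(self, low: float, high: float) -> np.ndarray:
        """Boolean mask of grid points with ``low ≤ ν ≤ high`` (closed).

        A small tolerance absorbs floating-point representation of the grid
        so that on-grid endpoints are always included.
        """
        if low > high:
            low, high = high, low
        eps = 1e-9 * max(1.0, abs(high))
        wn = self.wavenumbers
        mask = (wn >= low - eps) & (wn <= high + eps)
        if not mask.any():
            raise ValueError(
                f"window [{low}, {high}] cm-1 does not overlap grid "
                f"[{self.end}, {self.start}] cm-1"
            )
        return mask

    @classmethod
    def from_wavenumbers(cls, wavenumbers: np.ndarray) -> "WavenumberGrid":
        """Reconstruct a grid object from an evenly spaced descending axis."""
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("need a 1-D axis with at least two points")
        steps = np.diff(wn)
        if not np.all(steps < 0):
            raise ValueError("axis must be strictly descending")
        step = -steps.mean()
        if not np.allclose(-steps, step, rtol=1e-6, atol=1e-9):
            raise ValueError("axis must be evenly spaced")
        return cls(start=float(wn[0]), end=float(wn[-1]), step=float(step))
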