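"""Spectrum containers.

A :class:`Spectrum` couples a descending wavenumber axis with an intensity
trace, per-sample metadata (cell line, dose, replicate ids) and an
append-only record of the processing steps applied.  A :class:`SpectrumSet`
is an ordered collection sharing one axis, convertible to/from tidy
long-format tables and to a samples × wavenumbers matrix for chemometrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError

#: processing states a spectrum can accumulate
STATES = (
    "raw",
    "background_subtracted",
    "second_derivative",
    "vector_normalized",
    "minmax_normalized",
    "mean_centered",
)


def window_mask(wavenumbers: np.ndarray, low: float, high: float) -> np.ndarray:
    """Closed-interval mask ``low ≤ ν ≤ high`` on a wavenumber axis.

    Endpoint ties resolve by inclusion (a small tolerance absorbs float
    representation of on-grid values).
    """
    if low > high:
        low, high = high, low
    eps = 1e-9 * max(1.0, abs(high))
    return (wavenumbers >= low - eps) & (wavenumbers <= high + eps)


def nearest_index(wavenumbers: np.ndarray, wavenumber: float) -> int:
    return int(np.argmin(np.abs(np.asarray(wavenumbers) - wavenumber)))


@dataclass
class Spectrum:
    wavenumbers: np.ndarray
    values: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)
    state: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavenumbers.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavenumbers and values must be 1-D")
        if self.wavenumbers.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers, "
                f"{self.values.size} values"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) < 0):
            raise ValueError("wavenumber axis must be strictly descending")

    # -- bookkeeping ---------------------------------------------------
    @property
    def sample_id(self) -> str:
        return str(self.metadata.get("sample_id", ""))

    def with_values(self, values: np.ndarray, add_state: str | None = None,
                    **meta: Any) -> "Spectrum":
        """Copy with new values; optionally append a processing state."""
        state = self.state + (add_state,) if add_state else self.state
        metadata = {**self.metadata, **meta}
        return Spectrum(self.wavenumbers, np.asarray(values, dtype=float),
                        metadata, state)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return (self.wavenumbers.size == other.wavenumbers.size
                and np.allclose(self.wavenumbers, other.wavenumbers, atol=atol))

    def require_same_grid(self, other: "Spectrum") -> None:
        if not self.same_grid(other):
            raise GridMismatchError("spectra are not on a common wavenumber grid")

    @property
    def step(self) -> float:
        return float(-np.diff(self.wavenumbers).mean())


@dataclass
class SpectrumSet:
    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if self.spectra:
            first = self.spectra[0]
            for s in self.spectra[1:]:
                first.require_same_grid(s)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def map(self, fn) -> "SpectrumSet":
        return SpectrumSet([fn(s) for s in self.spectra])

    def filter(self, **meta: Any) -> "SpectrumSet":
        out = [s for s in self.spectra
               if all(s.metadata.get(k) == v for k, v in meta.items())]
        return SpectrumSet(out)

    # -- tabular views -------------------------------------------------
    def matrix(self) -> np.ndarray:
        """samples × wavenumbers intensity matrix (row order preserved)."""
        return np.vstack([s.values for s in self.spectra])

    def meta_frame(self, keys: Sequence[str] | None = None) -> pd.DataFrame:
        if keys is None:
            keys = sorted({k for s in self.spectra for k in s.metadata})
        rows = [{k: s.metadata.get(k) for k in keys} for s in self.spectra]
        return pd.DataFrame(rows)

    def to_frame(self, value_name: str = "absorbance") -> pd.DataFrame:
        """Tidy long format: one row per (sample, wavenumber)."""
        meta_keys = ["sample_id", "cell_line", "dose", "bio_rep", "tech_rep"]
        frames = []
        for s in self.spectra:
            df = pd.DataFrame({
                "wavenumber": s.wavenumbers,
                value_name: s.values,
            })
            for k in reversed(meta_keys):
                df.insert(0, k, s.metadata.get(k))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   value_name: str = "absorbance") -> "SpectrumSet":
        return cls(spectra_from_frame(df, value_name))


def spectra_from_frame(df: pd.DataFrame,
                       value_name: str = "absorbance") -> list[Spectrum]:
    """Parse a tidy long-format table into spectra (grids may differ)."""
    meta_keys = [c for c in ("cell_line", "dose", "bio_rep", "tech_rep")
                 if c in df.columns]
    spectra = []
    for sid, g in df.groupby("sample_id", sort=False):
        g = g.sort_values("wavenumber", ascending=False)
        meta: dict[str, Any] = {"sample_id": sid}
        for k in meta_keys:
            meta[k] = g[k].iloc[0]
        spectra.append(Spectrum(g["wavenumber"].to_numpy(),
                                g[value_name].to_numpy(), meta))
    return spectra
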