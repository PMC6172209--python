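"""File formats.

Canonical interchange is long-format CSV with columns ``sample_id,
cell_line, dose, bio_rep, tech_rep, wavenumber, absorbance``.  A minimal
JCAMP-DX subset (``##XYDATA=(X++(Y..Y))`` with AFFN values, and
``##XYPOINTS=(XY..XY)``) is supported for interoperability with instrument
exports; one spectrum per file.  Ascending axes are reordered to the
package's descending convention; spectra on differing grids are resampled
onto the first spectrum's grid by linear interpolation.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .spectrum import Spectrum, SpectrumSet, spectra_from_frame

log = logging.getLogger("ftirmacro")

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "read_spectra",
    "write_jcamp",
    "read_jcamp",
]

_CSV_COLUMNS = ("sample_id", "cell_line", "dose", "bio_rep", "tech_rep",
                "wavenumber", "absorbance")


def write_spectra_csv(spectra: SpectrumSet, path: str | Path) -> Path:
    """Write a spectrum set as long-format CSV at full float precision."""
    path = Path(path)
    df = spectra.to_frame()
    # pandas' default float repr is shortest-round-trip, so read-back is
    # bit-identical
    df.to_csv(path, index=False)
    return path


def read_spectra_csv(path: str | Path) -> SpectrumSet:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty spectra file") from exc
    missing = [c for c in ("sample_id", "wavenumber", "absorbance")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no spectra records")
    bad = df[df["wavenumber"].isna() | df["absorbance"].isna()]
    if not bad.empty:
        # +2: header line and 1-based numbering
        raise ValueError(
            f"{path}: malformed record at line {int(bad.index[0]) + 2}")
    return _common_grid(spectra_from_frame(df))


def _common_grid(spectra: list[Spectrum]) -> SpectrumSet:
    """Resample everything onto the first spectrum's grid if grids differ."""
    if len(spectra) <= 1:
        return SpectrumSet(list(spectra))
    first = spectra[0]
    out = [first]
    for s in spectra[1:]:
        if s.same_grid(first):
            out.append(s)
        else:
            log.warning("resampling %s onto common grid by linear "
                        "interpolation", s.sample_id)
            # np.interp wants ascending abscissae
            vals = np.interp(first.wavenumbers[::-1], s.wavenumbers[::-1],
                             s.values[::-1])[::-1]
            out.append(Spectrum(first.wavenumbers.copy(), vals,
                                dict(s.metadata), s.state))
    return SpectrumSet(out)


# ---------------------------------------------------------------------------
# JCAMP-DX subset
# ---------------------------------------------------------------------------

def write_jcamp(s: Spectrum, path: str | Path, title: str | None = None) -> Path:
    """Write one spectrum as a minimal JCAMP-DX 4.24 file (AFFN XYDATA)."""
    path = Path(path)
    wn, y = s.wavenumbers, s.values
    lines = [
        f"##TITLE={title or s.sample_id or 'spectrum'}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={wn[0]:.8g}",
        f"##LASTX={wn[-1]:.8g}",
        f"##NPOINTS={wn.size}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    step = (wn[-1] - wn[0]) / max(wn.size - 1, 1)
    per_line = 6
    for i in range(0, wn.size, per_line):
        x = wn[0] + i * step
        ys = " ".join(f"{v:.10g}" for v in y[i:i + per_line])
        lines.append(f"{x:.8g} {ys}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_jcamp(path: str | Path) -> Spectrum:
    """Read one spectrum from a JCAMP-DX file (AFFN XYDATA or XYPOINTS)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty JCAMP file")
    headers: dict[str, str] = {}
    mode = None
    xs: list[float] = []
    ys: list[float] = []
    data_header: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("$$")[0].strip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
                data_header = dict(headers)
            elif key == "XYPOINTS":
                mode = "xypoints"
                data_header = dict(headers)
            elif key == "END":
                break
            else:
                headers[key] = value
                mode = None
            continue
        if mode is None:
            continue
        try:
            nums = [float(tok) for tok in line.replace(",", " ").split()]
        except ValueError as exc:
            raise ValueError(f"{path}: malformed data at line {lineno}") from exc
        if mode == "xydata":
            if len(nums) < 2:
                raise ValueError(f"{path}: malformed data at line {lineno}")
            yfac = float(data_header.get("YFACTOR", 1.0))
            x0 = nums[0] * float(data_header.get("XFACTOR", 1.0))
            n_prev = len(ys)
            ys.extend(v * yfac for v in nums[1:])
            # x positions filled in afterwards from FIRSTX/LASTX; record
            # the line-leading x to sanity-check monotonicity
            xs.append(x0)
            del n_prev
        else:
            if len(nums) % 2:
                raise ValueError(f"{path}: malformed data at line {lineno}")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
    if not ys:
        raise ValueError(f"{path}: no spectral data found")
    xunits = headers.get("XUNITS", "1/CM").upper()
    if xunits not in ("1/CM", "CM-1", "CM^-1"):
        raise ValueError(f"{path}: unsupported x units {xunits!r}")
    if mode == "xydata" or (mode is None and "FIRSTX" in headers):
        firstx = float(data_header.get("FIRSTX", headers.get("FIRSTX")))
        lastx = float(data_header.get("LASTX", headers.get("LASTX")))
        npoints = int(data_header.get("NPOINTS", headers.get("NPOINTS",
                                                             len(ys))))
        if npoints != len(ys):
            raise ValueError(
                f"{path}: NPOINTS={npoints} but {len(ys)} values read")
        wn = np.linspace(firstx, lastx, npoints)
    else:
        wn = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    if wn.size >= 2 and wn[0] < wn[-1]:
        log.warning("%s: ascending wavenumber axis reordered to descending",
                    path)
        wn, y = wn[::-1].copy(), y[::-1].copy()
    title = headers.get("TITLE", path.stem)
    return Spectrum(wn, y, {"sample_id": title})


def read_spectra(paths: str | Path | list[str | Path],
                 fmt: str = "csv") -> SpectrumSet:
    """Read spectra from CSV (one file, many samples) or JCAMP-DX (one
    file per sample)."""
    if fmt == "csv":
        if isinstance(paths, (list, tuple)):
            if len(paths) != 1:
                raise ValueError("CSV input takes a single file")
            paths = paths[0]
        return read_spectra_csv(paths)
    if fmt == "jcamp":
        if not isinstance(paths, (list, tuple)):
            paths = [paths]
        return _common_grid([read_jcamp(p) for p in paths])
    raise ValueError(f"unknown format {fmt!r}")
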