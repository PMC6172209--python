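"""Marker-band quantification and derived macromolecular statistics.

Each marker band is read from one of the two preprocessed representations:
absorbance bands (total nucleic-acid phosphate, optionally the symmetric
phosphate stretch) as the window maximum of the vector-normalized
absorbance spectrum, and second-derivative bands as the magnitude of the
negative lobe (absorbance maxima are second-derivative minima) of the
vector-normalized second-derivative spectrum.

Derived statistics follow the study conventions of DMSO-dose FTIR
profiling: percent-of-untreated band intensities, the Z-DNA enhancement
ratio I(1066)/(I(1240)+I(1221)) reported as fold change versus untreated,
lipid unsaturation summaries built on the olefinic/total-lipid ratio, and
protein secondary-structure change expressed as the relative loss of total
α-helix amide-I intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, UndefinedRatioError
from .spectrum import Spectrum, SpectrumSet, window_mask

__all__ = [
    "BandAssignment",
    "DEFAULT_BAND_TABLE",
    "band_intensity",
    "quantify_bands",
    "percent_of_untreated",
    "zdna_enhancement_ratio",
    "lipid_unsaturation_summary",
    "secondary_structure_summary",
]

SOURCES = ("absorbance", "second_derivative")
CLASSES = ("nucleic_acid", "dna_form", "protein", "lipid")


@dataclass(frozen=True)
class BandAssignment:
    """A named marker band: literature center, peak-search window (closed,
    cm⁻¹), source representation and macromolecule class."""

    name: str
    center: float
    window: tuple[float, float]
    source: str
    macro_class: str
    enabled: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo <= self.center <= hi:
            raise ValueError(
                f"band {self.name}: center {self.center} outside window "
                f"{self.window}")
        if self.source not in SOURCES:
            raise ValueError(f"band {self.name}: unknown source {self.source!r}")
        if self.macro_class not in CLASSES:
            raise ValueError(
                f"band {self.name}: unknown class {self.macro_class!r}")


def _pm4(center: float) -> tuple[float, float]:
    # default search window: center ± instrument resolution (4 cm-1)
    return (center - 4.0, center + 4.0)


#: Default marker-band table.  Windows are center ± 4 cm⁻¹ except the
#: Z-DNA band (1071–1061) and the phosphate antisymmetric envelope
#: (1242–1238).  The symmetric phosphate band at ~1080 cm⁻¹ is included
#: but disabled by default.
DEFAULT_BAND_TABLE: tuple[BandAssignment, ...] = (
    BandAssignment("po2_antisym", 1240.0, (1238.0, 1242.0), "absorbance",
                   "nucleic_acid"),
    BandAssignment("po2_sym", 1080.0, _pm4(1080.0), "absorbance",
                   "nucleic_acid", enabled=False),
    BandAssignment("ribose", 915.0, _pm4(915.0), "second_derivative",
                   "nucleic_acid"),
    BandAssignment("adna", 1240.0, _pm4(1240.0), "second_derivative",
                   "dna_form"),
    BandAssignment("bdna", 1221.0, _pm4(1221.0), "second_derivative",
                   "dna_form"),
    BandAssignment("zdna", 1066.0, (1061.0, 1071.0), "second_derivative",
                   "dna_form"),
    BandAssignment("alpha_1657", 1657.0, _pm4(1657.0), "second_derivative",
                   "protein"),
    BandAssignment("alpha_1649", 1649.0, _pm4(1649.0), "second_derivative",
                   "protein"),
    BandAssignment("beta_1636", 1636.0, _pm4(1636.0), "second_derivative",
                   "protein"),
    BandAssignment("beta_1629", 1629.0, _pm4(1629.0), "second_derivative",
                   "protein"),
    BandAssignment("olefinic", 3009.0, _pm4(3009.0), "second_derivative",
                   "lipid"),
    BandAssignment("ch2_antisym", 2921.0, _pm4(2921.0), "second_derivative",
                   "lipid"),
    BandAssignment("ch2_sym", 2852.0, _pm4(2852.0), "second_derivative",
                   "lipid"),
    BandAssignment("cholesteryl_ester", 1172.0, _pm4(1172.0),
                   "second_derivative", "lipid"),
)

ALPHA_BANDS = ("alpha_1657", "alpha_1649")
BETA_BANDS = ("beta_1636", "beta_1629")
LIPID_BANDS = ("olefinic", "ch2_antisym", "ch2_sym", "cholesteryl_ester")


def band_intensity(s: Spectrum, b: BandAssignment) -> tuple[float, float]:
    """Locate one band; returns (peak wavenumber, intensity).

    Absorbance source: intensity is the window maximum.  Second-derivative
    source: intensity is the magnitude of the window minimum (negative
    lobe).  Ties in the extremum break toward the literature band center.
    The spectrum must already be in the band's source representation and
    vector-normalized.
    """
    mask = window_mask(s.wavenumbers, *b.window)
    if not mask.any():
        raise ValueError(
            f"band {b.name}: window {b.window} outside spectral grid")
    wn = s.wavenumbers[mask]
    seg = s.values[mask]
    if b.source == "absorbance":
        extremum = seg.max()
    else:
        extremum = seg.min()
    ties = np.flatnonzero(seg == extremum)
    pick = ties[np.argmin(np.abs(wn[ties] - b.center))]
    intensity = float(extremum if b.source == "absorbance" else abs(extremum))
    return float(wn[pick]), intensity


_META_COLS = ("sample_id", "cell_line", "dose", "bio_rep", "tech_rep")


def quantify_bands(
    absorbance: SpectrumSet,
    second_derivative: SpectrumSet,
    assignments: Iterable[BandAssignment] = DEFAULT_BAND_TABLE,
) -> pd.DataFrame:
    """Quantify every enabled band for every sample.

    ``absorbance`` and ``second_derivative`` must hold the same samples (by
    ``sample_id``) in their respective preprocessed representations.
    Returns a tidy table with one row per sample × band.
    """
    sd_by_id = {s.sample_id: s for s in second_derivative}
    rows = []
    for s_abs in absorbance:
        sid = s_abs.sample_id
        if sid not in sd_by_id:
            raise ValueError(f"sample {sid!r} missing from the "
                             "second-derivative set")
        reps = {"absorbance": s_abs, "second_derivative": sd_by_id[sid]}
        for b in assignments:
            if not b.enabled:
                continue
            s = reps[b.source]
            peak, intensity = band_intensity(s, b)
            row = {k: s.metadata.get(k) for k in _META_COLS}
            row.update(band=b.name, macro_class=b.macro_class,
                       source=b.source, peak_wavenumber=peak,
                       intensity=intensity)
            rows.append(row)
    return pd.DataFrame(rows)


def percent_of_untreated(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("cell_line",),
) -> pd.DataFrame:
    """Express intensities as percent of the untreated (dose 0) group mean.

    Normalization is carried out per band within each ``group_keys`` stratum
    (by default per cell line), so the untreated mean is 100 for every band.
    """
    keys = [k for k in group_keys if k in table.columns] + ["band"]
    out = table.copy()
    out["percent"] = np.nan
    for _, idx in out.groupby(keys, sort=False).groups.items():
        sub = out.loc[idx]
        ut = sub[sub["dose"] == 0.0]["intensity"]
        if ut.empty:
            raise NormalizationError(
                "no untreated (dose 0) samples for group "
                f"{sub[keys].iloc[0].to_dict()}")
        ut_mean = float(ut.mean())
        if ut_mean <= 0:
            raise NormalizationError(
                "untreated mean intensity is not positive for group "
                f"{sub[keys].iloc[0].to_dict()}")
        out.loc[idx, "percent"] = 100.0 * sub["intensity"] / ut_mean
    return out


def _pivot(table: pd.DataFrame, bands: Sequence[str],
           value: str = "intensity") -> pd.DataFrame:
    """sample × band matrix of one value column, metadata preserved."""
    missing = [b for b in bands if b not in set(table["band"])]
    if missing:
        raise ValueError(f"bands missing from the table: {missing}")
    sub = table[table["band"].isin(bands)]
    wide = sub.pivot_table(index=list(_META_COLS), columns="band",
                           values=value, aggfunc="first").reset_index()
    return wide


def _group_stats(df: pd.DataFrame, value: str,
                 keys: Sequence[str]) -> pd.DataFrame:
    g = df.groupby(list(keys), sort=True)[value]
    out = g.agg(n="count", mean="mean", sem="sem").reset_index()
    return out


def zdna_enhancement_ratio(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("cell_line",),
) -> pd.DataFrame:
    """Z-DNA enhancement: r = I(Z 1066) / (I(A 1240) + I(B 1221)) per
    sample, summarized per dose as fold change of the group mean ratio
    versus untreated (fold = 1 at dose 0 by construction)."""
    wide = _pivot(table, ["zdna", "adna", "bdna"])
    denom = wide["adna"] + wide["bdna"]
    if (denom <= 0).any():
        raise UndefinedRatioError("I(A-DNA) + I(B-DNA) is zero for some sample")
    wide["ratio"] = wide["zdna"] / denom
    keys = [k for k in group_keys if k in wide.columns] + ["dose"]
    out = _group_stats(wide, "ratio", keys)
    out = out.rename(columns={"mean": "ratio_mean", "sem": "ratio_sem"})
    strata = [k for k in group_keys if k in out.columns]
    def _fold(g: pd.DataFrame) -> pd.DataFrame:
        ut = g.loc[g["dose"] == 0.0, "ratio_mean"]
        if ut.empty or float(ut.iloc[0]) <= 0:
            raise UndefinedRatioError("no positive untreated mean ratio")
        g = g.copy()
        g["fold_change"] = g["ratio_mean"] / float(ut.iloc[0])
        return g
    if strata:
        out = pd.concat([_fold(g) for _, g in out.groupby(strata, sort=False)],
                        ignore_index=True)
    else:
        out = _fold(out)
    return out


def lipid_unsaturation_summary(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("cell_line",),
) -> pd.DataFrame:
    """Olefinic and olefinic/total-lipid summaries per dose.

    Total lipid is the per-sample sum of the percent intensities of the
    olefinic (3009), CH₂ antisymmetric (2921), CH₂ symmetric (2852) and
    cholesteryl-ester (1172 cm⁻¹) bands; the unsaturation index is
    100 × olefinic / total lipid.  Requires a ``percent`` column (run
    :func:`percent_of_untreated` first).
    """
    if "percent" not in table.columns:
        raise ValueError("run percent_of_untreated first: no 'percent' column")
    wide = _pivot(table, list(LIPID_BANDS), value="percent")
    total = wide[list(LIPID_BANDS)].sum(axis=1)
    if (total <= 0).any():
        raise UndefinedRatioError("total lipid intensity is zero for some sample")
    wide["olefinic_percent"] = wide["olefinic"]
    wide["olefinic_over_total"] = 100.0 * wide["olefinic"] / total
    keys = [k for k in group_keys if k in wide.columns] + ["dose"]
    ole = _group_stats(wide, "olefinic_percent", keys).rename(
        columns={"mean": "olefinic_mean", "sem": "olefinic_sem"})
    rat = _group_stats(wide, "olefinic_over_total", keys).rename(
        columns={"mean": "olefinic_over_total_mean",
                 "sem": "olefinic_over_total_sem"})
    return ole.merge(rat.drop(columns="n"), on=keys)


def secondary_structure_summary(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("cell_line",),
) -> pd.DataFrame:
    """Amide-I secondary-structure change per dose.

    Per sample, total α = I(1657) + I(1649) and total β = I(1636) +
    I(1629) from second-derivative intensities.  The α→β conversion at a
    dose is the relative loss of mean α versus untreated,
    ``100 × (1 − mean α(dose) / mean α(UT))``; the β gain
    ``100 × (mean β(dose)/mean β(UT) − 1)`` is reported alongside as a
    conservation diagnostic.
    """
    wide = _pivot(table, list(ALPHA_BANDS + BETA_BANDS))
    wide["alpha_total"] = wide[list(ALPHA_BANDS)].sum(axis=1)
    wide["beta_total"] = wide[list(BETA_BANDS)].sum(axis=1)
    keys = [k for k in group_keys if k in wide.columns] + ["dose"]
    a = _group_stats(wide, "alpha_total", keys).rename(
        columns={"mean": "alpha_mean", "sem": "alpha_sem"})
    b = _group_stats(wide, "beta_total", keys).rename(
        columns={"mean": "beta_mean", "sem": "beta_sem"})
    out = a.merge(b.drop(columns="n"), on=keys)
    strata = [k for k in group_keys if k in out.columns]

    def _conv(g: pd.DataFrame) -> pd.DataFrame:
        ut = g[g["dose"] == 0.0]
        if ut.empty or float(ut["alpha_mean"].iloc[0]) <= 0:
            raise UndefinedRatioError(
                "untreated mean alpha intensity is not positive")
        a0 = float(ut["alpha_mean"].iloc[0])
        b0 = float(ut["beta_mean"].iloc[0])
        g = g.copy()
        g["conversion_percent"] = 100.0 * (1.0 - g["alpha_mean"] / a0)
        g["beta_gain_percent"] = (100.0 * (g["beta_mean"] / b0 - 1.0)
                                  if b0 > 0 else np.nan)
        return g

    if strata:
        out = pd.concat([_conv(g) for _, g in out.groupby(strata, sort=False)],
                        ignore_index=True)
    else:
        out = _conv(out)
    return out
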