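"""End-to-end orchestration.

``run_pipeline`` executes simulate (optional) → preprocess → band
quantification → chemometrics → group statistics, writes tidy CSV outputs
plus a run manifest, and is bit-reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import (DEFAULT_BAND_TABLE, lipid_unsaturation_summary,
                    percent_of_untreated, quantify_bands,
                    secondary_structure_summary, zdna_enhancement_ratio)
from .chemometrics import DiscriminationReport, discriminate_groups
from .errors import ConfigError
from .grid import WavenumberGrid
from .io import write_spectra_csv
from .preprocess import (DEFAULT_FLATTEN_WINDOW, DEFAULT_SG_POLY,
                         DEFAULT_SG_WINDOW, savgol_derivative,
                         subtract_reference, vector_normalize)
from .spectrum import Spectrum, SpectrumSet
from .stats import group_summary
from .synth import (EffectModel, SampleDesign, default_effect_model,
                    generate_experiment)

log = logging.getLogger("ftirmacro")

__all__ = ["PipelineConfig", "preprocess_set", "run_pipeline", "RunResult"]

#: spectral regions of interest (low, high) in cm⁻¹
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "whole": (650.0, 4000.0),
    "lipid": (2830.0, 3030.0),
    "nucleic": (1200.0, 1250.0),
}


def _check_unknown(d: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} keys: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated, serializable description of one full run."""

    # grid
    grid_start: float = 4000.0
    grid_end: float = 650.0
    grid_step: float = 1.0
    # design
    cell_lines: tuple[str, ...] = ("HCT116_like",)
    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 1.5)
    n_bio: int = 3
    n_tech: int = 3
    # preprocessing
    sg_window: int = DEFAULT_SG_WINDOW
    sg_poly: int = DEFAULT_SG_POLY
    flatten_window: tuple[float, float] = DEFAULT_FLATTEN_WINDOW
    # regions
    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))
    # chemometrics
    pca_k: int | None = None
    lda_m: int | None = None
    lda_kind: str = "linear"
    lda_split: float = 2 / 3
    # statistics
    t_variant: str = "student"
    stat_unit: str = "biological"
    # generator overrides (passed to default_effect_model) and optional
    # full effect tables per cell line:
    # effects: {cell_line: {multipliers: {dose: {band: mult}},
    #                       conversion: {dose: c}}}
    noise_sd: float | None = None
    bio_jitter_sd: float | None = None
    effects: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_lines = tuple(self.cell_lines)
        self.doses = tuple(float(d) for d in self.doses)
        self.flatten_window = tuple(self.flatten_window)  # type: ignore
        self.regions = {k: tuple(v) for k, v in self.regions.items()}
        if self.grid_start <= self.grid_end:
            raise ConfigError("grid_start must exceed grid_end")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_poly:
            raise ConfigError("sg_window must be odd and exceed sg_poly")
        for name, (lo, hi) in self.regions.items():
            if lo >= hi:
                raise ConfigError(
                    f"region {name!r}: contradictory bounds ({lo}, {hi})")
        lo, hi = self.flatten_window
        if lo >= hi:
            raise ConfigError("flatten_window bounds are contradictory")
        if not 0 < self.lda_split < 1:
            raise ConfigError("lda_split must lie in (0, 1)")
        if self.lda_kind not in ("linear", "mahalanobis"):
            raise ConfigError(f"unknown lda_kind {self.lda_kind!r}")
        if self.t_variant not in ("student", "welch"):
            raise ConfigError(f"unknown t_variant {self.t_variant!r}")
        if self.stat_unit not in ("biological", "technical"):
            raise ConfigError(f"unknown stat_unit {self.stat_unit!r}")

    # -- (de)serialization --------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        _check_unknown(d, {f.name for f in dc_fields(cls)}, "config")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        d["doses"] = list(self.doses)
        d["flatten_window"] = list(self.flatten_window)
        d["regions"] = {k: list(v) for k, v in self.regions.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def make_grid(self) -> WavenumberGrid:
        return WavenumberGrid(self.grid_start, self.grid_end, self.grid_step)

    def make_design(self) -> SampleDesign:
        return SampleDesign(self.cell_lines, self.doses, self.n_bio,
                            self.n_tech, self.seed, self.make_grid())

    def make_effects(self) -> dict[str, Any]:
        over: dict[str, Any] = {}
        if self.noise_sd is not None:
            over["noise_sd"] = self.noise_sd
        if self.bio_jitter_sd is not None:
            over["bio_jitter_sd"] = self.bio_jitter_sd
        out: dict[str, Any] = {}
        for cl in self.cell_lines:
            custom = (self.effects or {}).get(cl)
            if custom is None:
                out[cl] = default_effect_model(cl, **over)
                continue
            _check_unknown(custom, {"multipliers", "conversion"},
                           f"effects[{cl}]")
            try:
                out[cl] = EffectModel(
                    cell_line=cl,
                    multipliers={float(d): dict(t) for d, t in
                                 custom.get("multipliers", {0.0: {}}).items()},
                    conversion={float(d): float(c) for d, c in
                                custom.get("conversion", {0.0: 0.0}).items()},
                    **over)
            except ValueError as exc:
                raise ConfigError(f"effects[{cl}]: {exc}") from exc
        return out


def preprocess_set(
    spectra: SpectrumSet,
    reference: Spectrum,
    sg_window: int = DEFAULT_SG_WINDOW,
    sg_poly: int = DEFAULT_SG_POLY,
    flatten_window: tuple[float, float] = DEFAULT_FLATTEN_WINDOW,
) -> tuple[SpectrumSet, SpectrumSet]:
    """Background-subtract every spectrum, then build both analysis
    representations: vector-normalized absorbance and vector-normalized
    second derivative."""
    subtracted = spectra.map(
        lambda s: subtract_reference(s, reference, flatten_window))
    absorbance = subtracted.map(vector_normalize)
    second = subtracted.map(
        lambda s: vector_normalize(
            savgol_derivative(s, sg_window, sg_poly, deriv=2)))
    return absorbance, second


@dataclass
class RunResult:
    config: PipelineConfig
    band_table: pd.DataFrame
    zdna: pd.DataFrame
    lipids: pd.DataFrame
    secondary_structure: pd.DataFrame
    group_stats: pd.DataFrame
    discriminations: dict[tuple[str, ...], DiscriminationReport]
    manifest: dict[str, Any]
    out_dir: Path | None = None


def _write(df: pd.DataFrame, path: Path, outputs: dict[str, str]) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
    outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    spectra: SpectrumSet | None = None,
    reference: Spectrum | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute the full analysis; simulate input if none is given.

    Writes CSV outputs and ``manifest.json`` under ``out_dir`` when given.
    Identical (config, seed) produce identical outputs.
    """
    simulated = spectra is None
    if simulated:
        log.info("simulating experiment (seed=%d)", config.seed)
        spectra, reference = generate_experiment(
            config.make_design(), effects=config.make_effects())
    if reference is None:
        raise ValueError("a PBS reference spectrum is required for "
                         "background subtraction")

    log.info("preprocessing %d spectra", len(spectra))
    absorbance, second = preprocess_set(
        spectra, reference, config.sg_window, config.sg_poly,
        config.flatten_window)

    log.info("quantifying marker bands")
    band_table = percent_of_untreated(
        quantify_bands(absorbance, second, DEFAULT_BAND_TABLE))
    zdna = zdna_enhancement_ratio(band_table)
    lipids = lipid_unsaturation_summary(band_table)
    secondary = secondary_structure_summary(band_table)

    log.info("group statistics (%s replicates)", config.stat_unit)
    stats_rows = []
    for (cl, band), sub in band_table.groupby(["cell_line", "band"],
                                              sort=True):
        if sub["dose"].nunique() < 2:
            continue
        summary = group_summary(sub, value="percent", variant=config.t_variant,
                                unit=config.stat_unit)
        summary.insert(0, "band", band)
        summary.insert(0, "cell_line", cl)
        stats_rows.append(summary)
    group_stats = (pd.concat(stats_rows, ignore_index=True)
                   if stats_rows else pd.DataFrame())

    log.info("chemometrics")
    discriminations: dict[tuple[str, ...], DiscriminationReport] = {}
    meta = spectra.meta_frame(["cell_line", "dose"])
    for cl in meta["cell_line"].unique():
        sub = spectra.filter(cell_line=cl)
        if pd.Series([s.metadata["dose"] for s in sub]).nunique() < 2:
            continue
        for rname, region in config.regions.items():
            discriminations[(str(cl), rname)] = discriminate_groups(
                sub, region=region, label_key="dose", k=config.pca_k,
                m=config.lda_m, kind=config.lda_kind,
                split=config.lda_split, seed=config.seed)
    if meta["cell_line"].nunique() >= 2:
        for rname, region in config.regions.items():
            discriminations[("all", rname)] = discriminate_groups(
                spectra, region=region, label_key="cell_line",
                k=config.pca_k, m=config.lda_m, kind=config.lda_kind,
                split=config.lda_split, seed=config.seed)

    outputs: dict[str, str] = {}
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        if simulated:
            write_spectra_csv(spectra, out_path / "spectra.csv")
            outputs["spectra.csv"] = hashlib.sha256(
                (out_path / "spectra.csv").read_bytes()).hexdigest()
        _write(band_table, out_path / "band_intensities.csv", outputs)
        _write(zdna, out_path / "zdna_ratio.csv", outputs)
        _write(lipids, out_path / "lipid_summary.csv", outputs)
        _write(secondary, out_path / "secondary_structure.csv", outputs)
        _write(group_stats, out_path / "group_stats.csv", outputs)
        acc_rows, conf_rows, ev_rows = [], [], []
        for key, rep in discriminations.items():
            tag = "/".join(key)
            acc_rows.append({
                "model": tag,
                "holdout_accuracy": rep.holdout_accuracy,
                "training_accuracy": rep.training_accuracy,
                "overall_accuracy": rep.overall_accuracy,
            })
            cm = rep.confusion_holdout
            for i, ct in enumerate(cm.classes):
                for j, cp in enumerate(cm.classes):
                    conf_rows.append({"model": tag, "true": ct,
                                      "predicted": cp,
                                      "count": int(cm.counts[i, j])})
            for i, ev in enumerate(rep.pca.explained_variance):
                ev_rows.append({"model": tag, "component": i + 1,
                                "explained_variance": float(ev)})
        _write(pd.DataFrame(acc_rows), out_path / "lda_accuracy.csv", outputs)
        _write(pd.DataFrame(conf_rows), out_path / "confusion.csv", outputs)
        _write(pd.DataFrame(ev_rows), out_path / "explained_variance.csv",
               outputs)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "simulated": simulated,
        "n_spectra": len(spectra),
        "versions": {
            "ftirmacro": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": outputs,
    }
    if out_path is not None:
        (out_path / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RunResult(config, band_table, zdna, lipids, secondary,
                     group_stats, discriminations, manifest, out_path)
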