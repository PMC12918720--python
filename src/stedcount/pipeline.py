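"""Pipeline orchestration: configuration, presets, reports and logging.

Ties the stages together (simulate -> detect -> fit -> calibrate ->
quantify) for the two study designs the package ships presets for:

* ``origami``: fields of single-class DNA origami with N in a set of
  strand counts, fitted one Gaussian each, then calibrated (center vs N
  line, width vs sqrt(N)).
* ``egfr``: a resting receptor field (monomers only; two-Gaussian fit;
  labeling efficiency) plus a stimulated field (three-Gaussian fit with
  the second width fixed from the resting fit and the third linked by
  sqrt(2); dimer-fraction inversion under both conventions).

Every run directory contains the fully resolved config (with a content
hash), per-stage CSV/JSON outputs and a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .calibrate import CalibrationPoint, fit_linear_calibration, fit_width_scaling
from .detect import build_spot_table
from .fitting import MixtureFit, build_histogram, component_fractions, fit_gaussians
from .quantify import (dimer_peak_width, estimate_labeling_efficiency,
                       invert_dimer_fraction)
from .simulate import (SimulationConfig, make_origami_mixture,
                       make_receptor_field, write_tiff)

logger = logging.getLogger("stedcount")

__all__ = [
    "PipelineConfig",
    "SimulateSettings",
    "DetectSettings",
    "FitSettings",
    "QuantifySettings",
    "run_pipeline",
    "config_hash",
]


class SimulateSettings(BaseModel):
    field_size: tuple[int, int] = (320, 320)
    pixel_size_nm: float = Field(30.0, gt=0)
    psf_fwhm_ref_nm: float = Field(70.0, gt=0)
    psf_fwhm_quant_nm: float = Field(70.0, gt=0)
    brightness_per_fluorophore: float = Field(30.0, ge=0)
    brightness_cv: float = Field(0.2, ge=0)
    occupancy_p: float = Field(0.9, ge=0.0, le=1.0)
    background: float = Field(2.0, ge=0)
    noise: Literal["poisson", "poisson+gaussian", "none"] = "poisson"
    read_noise_sd: float = Field(0.0, ge=0)
    # origami preset
    strand_counts: list[int] = [1, 2, 3, 4, 5, 7]
    n_per_class: int = Field(300, ge=1)
    corner_distance_nm: float = Field(30.0, gt=0)
    # receptor preset: cell-sized field at ~5.5 units/um^2
    receptor_field_size: tuple[int, int] = (448, 448)
    n_units: int = Field(1000, ge=1)
    dimer_fraction: float = Field(0.55, ge=0.0, le=1.0)
    labeling_efficiency: float = Field(0.59, gt=0.0, lt=1.0)
    dimer_separation_nm: float = Field(11.0, ge=0)

    def to_simulation_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            seed=seed,
            field_size=tuple(self.field_size),
            pixel_size_nm=self.pixel_size_nm,
            psf_fwhm_ref_nm=self.psf_fwhm_ref_nm,
            psf_fwhm_quant_nm=self.psf_fwhm_quant_nm,
            brightness_per_fluorophore=self.brightness_per_fluorophore,
            brightness_cv=self.brightness_cv,
            occupancy_p=self.occupancy_p,
            background=self.background,
            noise=self.noise,
            read_noise_sd=self.read_noise_sd,
        )


class DetectSettings(BaseModel):
    prominence_origami: float = Field(15.0, gt=0)
    prominence_receptor: float = Field(10.0, gt=0)
    readout: Literal["single", "mean3x3"] = "single"
    exclude_border: bool = False


class FitSettings(BaseModel):
    bin_size_origami: float = Field(2.0, gt=0)
    bin_size_receptor: float = Field(1.0, gt=0)
    exclusion_threshold_origami: float = Field(2.0, ge=0)
    # cell data keep the background peak as the first fitted component;
    # bins start at -0.5 so integer pixel counts (including 0) sit at bin
    # centers and the unlabeled-spot peak is not truncated
    exclusion_threshold_receptor: float = -0.5


class QuantifySettings(BaseModel):
    convention: Literal["factor2", "as_printed"] = "factor2"


class PipelineConfig(BaseModel):
    """Fully resolved parameters of one pipeline run."""

    preset: Literal["origami", "egfr"] = "origami"
    seed: int
    simulate: SimulateSettings = SimulateSettings()
    detect: DetectSettings = DetectSettings()
    fit: FitSettings = FitSettings()
    quantify: QuantifySettings = QuantifySettings()
    write_images: bool = False

    @model_validator(mode="after")
    def _check(self):
        if not self.simulate.strand_counts:
            raise ValueError("strand_counts must be non-empty")
        if any(not 1 <= s <= 7 for s in self.simulate.strand_counts):
            raise ValueError("strand_counts must lie in 1..7")
        return self

    def to_json(self) -> str:
        """Canonical serialization (stable key order, fixed separators)."""
        return json.dumps(self.model_dump(mode="json"), sort_keys=True,
                          separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.model_validate(json.loads(text))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "tool": "stedcount",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": config_hash(config),
        "seed": config.seed,
    }


def _fit_to_dict(fit: MixtureFit) -> dict:
    return {
        "y0": fit.y0,
        "y0_se": fit.y0_se,
        "rss": fit.rss,
        "converged": fit.converged,
        "n_bins": fit.n_bins,
        "components": [dataclasses.asdict(c) for c in fit.components],
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def analyze_origami_class(
    n_strands: int,
    config: PipelineConfig,
    seed: int,
) -> tuple[CalibrationPoint, MixtureFit, pd.DataFrame]:
    """Simulate a single-class origami field and fit its intensity peak."""
    sim_cfg = config.simulate.to_simulation_config(seed)
    image, _ = make_origami_mixture(
        [n_strands], config.simulate.n_per_class, sim_cfg,
        corner_distance_nm=config.simulate.corner_distance_nm,
    )
    spots = build_spot_table(image, config.detect.prominence_origami,
                             config.detect.readout, config.detect.exclude_border)
    hist = build_histogram(spots["I_quant_au"], config.fit.bin_size_origami,
                           config.fit.exclusion_threshold_origami)
    fit = fit_gaussians(hist, k=1)
    comp = fit.components[0]
    point = CalibrationPoint(
        N=n_strands, xc=comp.xc,
        xc_se=comp.xc_se if comp.xc_se is not None else float("nan"),
        fwhm=comp.fwhm,
        fwhm_se=comp.fwhm_se if comp.fwhm_se is not None else float("nan"),
    )
    logger.info("origami N=%d: %d spots, xc=%.2f au fwhm=%.2f au",
                n_strands, len(spots), comp.xc, comp.fwhm)
    return point, fit, spots


def analyze_origami_mixture(
    strand_counts: Sequence[int],
    config: PipelineConfig,
    seed: int,
    fixed_fwhm: Sequence[float] | None = None,
    init_centers: Sequence[float] | None = None,
):
    """Simulate a mixed-origami field and unmix its intensity histogram.

    Fits one Gaussian per class; widths are typically fixed to the values
    obtained from the corresponding unmixed calibration samples.  Returns
    the mixture fit, its class fractions and the spot table.
    """
    sim_cfg = config.simulate.to_simulation_config(seed)
    image, truth = make_origami_mixture(
        list(strand_counts), config.simulate.n_per_class, sim_cfg,
        corner_distance_nm=config.simulate.corner_distance_nm,
    )
    spots = build_spot_table(image, config.detect.prominence_origami,
                             config.detect.readout, config.detect.exclude_border)
    hist = build_histogram(spots["I_quant_au"], config.fit.bin_size_origami,
                           config.fit.exclusion_threshold_origami)
    fit = fit_gaussians(hist, k=len(strand_counts),
                        init_centers=init_centers, fixed_fwhm=fixed_fwhm,
                        poisson_weights=True, fixed_y0=0.0)
    fractions = component_fractions(fit)
    return fit, fractions, spots, truth


def run_origami_preset(config: PipelineConfig, out_dir: Path) -> dict:
    points = []
    for i, n_strands in enumerate(config.simulate.strand_counts):
        point, fit, spots = analyze_origami_class(
            n_strands, config, seed=config.seed + 1000 * i)
        points.append(point)
        spots.to_csv(out_dir / f"spots_{n_strands}x.csv", index=False)
        _write_json(out_dir / f"fit_{n_strands}x.json", _fit_to_dict(fit))
    curve = fit_linear_calibration(points)
    width = fit_width_scaling(points)
    width_off = fit_width_scaling(points, with_offset=True)
    report = {
        "points": [dataclasses.asdict(p) for p in points],
        "linear": dataclasses.asdict(curve),
        "width_sqrt": dataclasses.asdict(width),
        "width_sqrt_offset": dataclasses.asdict(width_off),
    }
    pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(
        out_dir / "calibration_points.csv", index=False)
    _write_json(out_dir / "calibration.json", report)
    return report


def analyze_receptor_field(
    config: PipelineConfig,
    seed: int,
    stimulated: bool,
    fixed_fwhm2: float | None = None,
):
    """Simulate one receptor field and fit its intensity histogram.

    Resting fields (``stimulated=False``) use a two-component fit
    (background + single label).  Stimulated fields use three components
    with fwhm2 frozen (typically to the resting value) and
    fwhm3 = fwhm2 * sqrt(2).
    """
    sim_cfg = config.simulate.to_simulation_config(seed)
    sim_cfg = dataclasses.replace(
        sim_cfg, field_size=tuple(config.simulate.receptor_field_size))
    f_dimer = config.simulate.dimer_fraction if stimulated else 0.0
    image, truth = make_receptor_field(
        config.simulate.n_units, f_dimer,
        config.simulate.labeling_efficiency, sim_cfg,
        dimer_separation_nm=config.simulate.dimer_separation_nm,
    )
    spots = build_spot_table(image, config.detect.prominence_receptor,
                             config.detect.readout, config.detect.exclude_border)
    hist = build_histogram(spots["I_quant_au"], config.fit.bin_size_receptor,
                           config.fit.exclusion_threshold_receptor)
    # Poisson weighting: bin counts are Poisson, and weighted fits give
    # calibrated parameter uncertainties for the downstream inference
    # Poisson (Pearson) weighting and a pinned zero baseline: bin counts
    # are Poisson and a spot-intensity histogram has no pedestal, so this
    # gives calibrated uncertainties for the downstream inference
    if not stimulated:
        fit = fit_gaussians(hist, k=2, poisson_weights=True, fixed_y0=0.0)
    else:
        fixed = [None, fixed_fwhm2,
                 dimer_peak_width(fixed_fwhm2) if fixed_fwhm2 else None]
        if fixed_fwhm2 is not None:
            fit = fit_gaussians(hist, k=3, fixed_fwhm=fixed,
                                poisson_weights=True, fixed_y0=0.0)
        else:
            fit = fit_gaussians(hist, k=3, link_fwhm3_sqrt2=True,
                                poisson_weights=True, fixed_y0=0.0)
    return fit, spots, hist, truth


def run_egfr_preset(config: PipelineConfig, out_dir: Path) -> dict:
    # resting field: two peaks -> labeling efficiency
    rest_fit, rest_spots, _, _ = analyze_receptor_field(
        config, seed=config.seed, stimulated=False)
    rest_frac = component_fractions(rest_fit)
    le = estimate_labeling_efficiency(
        rest_frac.fractions[0], rest_frac.fractions[1],
        rest_frac.ses[0], rest_frac.ses[1])
    fwhm2 = rest_fit.components[1].fwhm

    # stimulated field: three peaks -> dimer fraction under both conventions
    stim_fit, stim_spots, _, _ = analyze_receptor_field(
        config, seed=config.seed + 1, stimulated=True, fixed_fwhm2=fwhm2)
    stim_frac = component_fractions(stim_fit)
    estimates = {}
    for convention in ("factor2", "as_printed"):
        est = invert_dimer_fraction(
            stim_frac.fractions[0], stim_frac.fractions[1],
            stim_frac.fractions[2], le.le, convention=convention,
            fraction_ses=tuple(stim_frac.ses), le_se=le.se)
        estimates[convention] = {
            "per_peak": list(est.per_peak),
            "per_peak_se": list(est.per_peak_se),
            "clipped": list(est.clipped),
            "mean": est.mean,
            "mean_se": est.mean_se,
        }
    report = {
        "labeling_efficiency": {"value": le.le, "se": le.se},
        "resting_fit": _fit_to_dict(rest_fit),
        "resting_fractions": list(rest_frac.fractions),
        "stimulated_fit": _fit_to_dict(stim_fit),
        "stimulated_fractions": list(stim_frac.fractions),
        "dimer_fraction": estimates,
        "convention_default": config.quantify.convention,
    }
    rest_spots.to_csv(out_dir / "spots_resting.csv", index=False)
    stim_spots.to_csv(out_dir / "spots_stimulated.csv", index=False)
    _write_json(out_dir / "quantification.json", report)
    logger.info("LE=%.3f±%.3f, F(%s)=%.3f±%.3f", le.le, le.se,
                config.quantify.convention,
                estimates[config.quantify.convention]["mean"],
                estimates[config.quantify.convention]["mean_se"])
    return report


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run a preset end to end, writing reports into ``out_dir``.

    Returns the summary dictionary that is also written as
    ``summary.json``; raises on any stage failure (the CLI maps that to a
    nonzero exit status).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run %s preset, seed=%d, config=%s", config.preset,
                config.seed, config_hash(config))
    (out_dir / "config.json").write_text(config.to_json())
    if config.preset == "origami":
        report = run_origami_preset(config, out_dir)
    else:
        report = run_egfr_preset(config, out_dir)
    summary = {"provenance": _provenance(config), "preset": config.preset,
               "report": report}
    _write_json(out_dir / "summary.json", summary)
    return summary
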