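"""Synthetic two-channel STED image generation with known ground truth.

Emulates the two experiment families the analysis pipeline is built for:

* DNA-origami calibration samples: a triangular three-site marker in the
  reference channel identifies each origami, and a central target docking
  strand in the quantification channel carries 1-7 copies of a 4x-repeat
  label (up to 4 fluorophores per strand, Bernoulli site occupancy).
* Receptor fields: membrane-receptor units that are monomeric or dimeric,
  each receptor carrying a reference label and, with probability equal to
  the labeling efficiency, a single 4x docking strand in the
  quantification channel.

Every emitter is rendered as an isotropic 2D Gaussian of the channel's
effective PSF width, integrated analytically over pixel areas so that the
rendered flux equals the realized brightness exactly.  Poisson shot noise
(optionally plus Gaussian read noise) is applied last.  Intensities are in
"au", the raw pixel-count scale of the detector image; the simulator's au
scale is arbitrary and only meaningful relative to the thresholds and bin
sizes applied downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

__all__ = [
    "Channel",
    "EmitterDesign",
    "SimulationConfig",
    "TwoChannelImage",
    "GroundTruth",
    "simulate_field",
    "make_origami_mixture",
    "make_receptor_field",
    "psf_peak_factor",
    "write_tiff",
    "read_tiff",
]

#: fwhm = SIGMA_TO_FWHM * sigma for a Gaussian profile
SIGMA_TO_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class Channel(str, Enum):
    """Spectral channel of an emitter."""

    REFERENCE = "reference"  # identifier label (e.g. STAR 635P)
    QUANTIFICATION = "quantification"  # counting label (e.g. STAR 580)


@dataclass(frozen=True)
class EmitterDesign:
    """A point-like labeled site at a sub-pixel position.

    Parameters
    ----------
    x_nm, y_nm:
        Position in nm.  Pixel ``i`` is centered at ``i * pixel_size`` nm,
        so the field spans ``[-pixel_size/2, (n - 1/2) * pixel_size)``.
    n_docking_strands:
        Number of docking strands at this site (1-7 for origami targets,
        1 per receptor unit).
    sites_per_strand:
        Fluorophore binding sites per docking strand (4 for the 4x label,
        2 for the 22 nt corner strands).
    channel:
        Which spectral channel the emitter is rendered into.
    """

    x_nm: float
    y_nm: float
    n_docking_strands: int = 1
    sites_per_strand: int = 4
    channel: Channel = Channel.QUANTIFICATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel(self.channel))
        if self.n_docking_strands < 1:
            raise ValueError("n_docking_strands must be >= 1")
        if self.sites_per_strand < 1:
            raise ValueError("sites_per_strand must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.n_docking_strands * self.sites_per_strand


@dataclass(frozen=True)
class SimulationConfig:
    """Imaging and labeling parameters for a synthetic field.

    ``brightness_per_fluorophore`` is the expected integrated signal (au)
    one fluorophore contributes to the image over the acquisition;
    ``brightness_cv`` is the coefficient of variation of a multiplicative
    lognormal per-fluorophore brightness factor.  ``occupancy_p`` is the
    Bernoulli probability that a fluorophore binding site is occupied.
    """

    seed: int
    field_size: tuple[int, int] = (256, 256)  # (rows, cols) pixels
    pixel_size_nm: float = 30.0
    psf_fwhm_ref_nm: float = 70.0
    psf_fwhm_quant_nm: float = 70.0
    brightness_per_fluorophore: float = 30.0
    brightness_cv: float = 0.2
    occupancy_p: float = 0.9
    background: float = 2.0
    noise: str = "poisson"  # "poisson" | "poisson+gaussian" | "none"
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy_p <= 1.0):
            raise ValueError("occupancy_p must be in [0, 1]")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        for name in ("psf_fwhm_ref_nm", "psf_fwhm_quant_nm",
                     "brightness_per_fluorophore", "brightness_cv",
                     "background", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise not in ("poisson", "poisson+gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if min(self.field_size) < 1:
            raise ValueError("field_size must be positive")

    def psf_fwhm_nm(self, channel: Channel) -> float:
        return (self.psf_fwhm_ref_nm if channel is Channel.REFERENCE
                else self.psf_fwhm_quant_nm)


@dataclass
class TwoChannelImage:
    """A reference/quantification raster pair with physical pixel size."""

    reference: np.ndarray
    quantification: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        if self.reference.shape != self.quantification.shape:
            raise ValueError("channel shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape

    def channel(self, which: Channel) -> np.ndarray:
        return (self.reference if which is Channel.REFERENCE
                else self.quantification)


#: Ground-truth table columns, one row per emitter design.
GROUND_TRUTH_COLUMNS = [
    "emitter_id", "x_nm", "y_nm", "channel", "n_strands",
    "realized_fluorophores", "realized_brightness",
]

GroundTruth = pd.DataFrame  # alias for readability of signatures


def psf_peak_factor(psf_fwhm_nm: float, pixel_size_nm: float) -> float:
    """Fraction of an emitter's total flux landing in its central pixel.

    For the analytic pixel-integrated Gaussian used here, an emitter at a
    pixel center deposits ``erf(p / (2*sigma*sqrt(2)))**2`` of its flux in
    that pixel (p = pixel size, sigma = PSF standard deviation).
    """
    sigma = psf_fwhm_nm / SIGMA_TO_FWHM
    a = pixel_size_nm / (2.0 * sigma * math.sqrt(2.0))
    return float(erf(a) ** 2)


def _field_bounds_nm(config: SimulationConfig) -> tuple[float, float, float, float]:
    p = config.pixel_size_nm
    rows, cols = config.field_size
    return (-0.5 * p, (cols - 0.5) * p, -0.5 * p, (rows - 0.5) * p)


def _render_emitter(canvas: np.ndarray, x_nm: float, y_nm: float,
                    brightness: float, sigma_nm: float,
                    pixel_size_nm: float) -> None:
    """Add a pixel-integrated Gaussian spot to ``canvas`` in place."""
    rows, cols = canvas.shape
    p = pixel_size_nm
    half = max(3, int(math.ceil(5.0 * sigma_nm / p)))
    c0 = int(round(x_nm / p))
    r0 = int(round(y_nm / p))
    clo, chi = max(0, c0 - half), min(cols, c0 + half + 1)
    rlo, rhi = max(0, r0 - half), min(rows, r0 + half + 1)
    if clo >= chi or rlo >= rhi:
        return
    denom = sigma_nm * math.sqrt(2.0)
    # pixel i spans [(i - 0.5) p, (i + 0.5) p)
    cedges = (np.arange(clo, chi + 1) - 0.5) * p
    redges = (np.arange(rlo, rhi + 1) - 0.5) * p
    fx = 0.5 * np.diff(erf((cedges - x_nm) / denom))
    fy = 0.5 * np.diff(erf((redges - y_nm) / denom))
    canvas[rlo:rhi, clo:chi] += brightness * np.outer(fy, fx)


def simulate_field(
    designs: Sequence[EmitterDesign],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TwoChannelImage, GroundTruth]:
    """Render a two-channel field from emitter designs.

    Per emitter, the realized fluorophore count is drawn as
    ``Binomial(n_docking_strands * sites_per_strand, occupancy_p)`` and each
    occupied fluorophore contributes ``brightness_per_fluorophore`` times a
    lognormal factor with mean 1 and the configured CV.  Noise is applied
    last.  Identical seed and inputs give bit-identical output.

    Returns the image pair and a ground-truth table with one row per
    design (realized counts and brightness included).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    xlo, xhi, ylo, yhi = _field_bounds_nm(config)
    for i, d in enumerate(designs):
        if not (xlo <= d.x_nm < xhi and ylo <= d.y_nm < yhi):
            raise ValueError(
                f"emitter {i} at ({d.x_nm:.1f}, {d.y_nm:.1f}) nm lies outside "
                f"the field x=[{xlo:.1f}, {xhi:.1f}) nm, y=[{ylo:.1f}, {yhi:.1f}) nm"
            )

    expected = {
        Channel.REFERENCE: np.full(config.field_size, float(config.background)),
        Channel.QUANTIFICATION: np.full(config.field_size, float(config.background)),
    }
    records = []
    if config.brightness_cv > 0:
        ln_sigma2 = math.log(1.0 + config.brightness_cv ** 2)
        ln_mu = -0.5 * ln_sigma2
        ln_sigma = math.sqrt(ln_sigma2)
    for i, d in enumerate(designs):
        k = int(rng.binomial(d.n_sites, config.occupancy_p))
        if config.brightness_cv > 0 and k > 0:
            factors = rng.lognormal(ln_mu, ln_sigma, size=k)
            brightness = config.brightness_per_fluorophore * float(factors.sum())
        else:
            brightness = config.brightness_per_fluorophore * k
        sigma = config.psf_fwhm_nm(d.channel) / SIGMA_TO_FWHM
        if brightness > 0:
            _render_emitter(expected[d.channel], d.x_nm, d.y_nm, brightness,
                            sigma, config.pixel_size_nm)
        records.append((i, d.x_nm, d.y_nm, d.channel.value,
                        d.n_docking_strands, k, brightness))

    out = {}
    for ch in (Channel.REFERENCE, Channel.QUANTIFICATION):
        img = expected[ch]
        if config.noise in ("poisson", "poisson+gaussian"):
            img = rng.poisson(img).astype(float)
        if config.noise == "poisson+gaussian" and config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        out[ch] = img

    truth = pd.DataFrame.from_records(records, columns=GROUND_TRUTH_COLUMNS)
    image = TwoChannelImage(out[Channel.REFERENCE],
                            out[Channel.QUANTIFICATION],
                            config.pixel_size_nm)
    return image, truth


# ---------------------------------------------------------------------------
# Field layouts


def _grid_positions(config: SimulationConfig, n: int, spacing_nm: float,
                    jitter_nm: float, margin_nm: float,
                    rng: np.random.Generator) -> np.ndarray:
    """n random cells of a jittered grid; guarantees min separation.

    Grid placement (rather than rejection sampling) keeps dense fields
    feasible: cells are ``spacing_nm`` apart, positions jittered by up to
    ``jitter_nm`` per axis within the cell.
    """
    xlo, xhi, ylo, yhi = _field_bounds_nm(config)
    xlo += margin_nm
    ylo += margin_nm
    xhi -= margin_nm
    yhi -= margin_nm
    nx = int((xhi - xlo) // spacing_nm)
    ny = int((yhi - ylo) // spacing_nm)
    if nx * ny < n:
        area_um2 = ((xhi - xlo) * (yhi - ylo)) * 1e-6
        raise ValueError(
            f"field too small: {n} sites at >= {spacing_nm:.0f} nm separation "
            f"need more than the {nx * ny} available grid cells "
            f"({n / max(area_um2, 1e-9):.1f} sites/um^2 requested)"
        )
    cells = rng.choice(nx * ny, size=n, replace=False)
    cx = xlo + (cells % nx + 0.5) * spacing_nm
    cy = ylo + (cells // nx + 0.5) * spacing_nm
    pos = np.stack([cx, cy], axis=1)
    if jitter_nm > 0:
        pos += rng.uniform(-jitter_nm, jitter_nm, size=pos.shape)
    return pos


def make_origami_mixture(
    strand_counts: Sequence[int],
    n_per_class: int,
    config: SimulationConfig,
    corner_distance_nm: float = 30.0,
    corner_strands: int = 7,
    corner_sites_per_strand: int = 2,
    min_separation_nm: float | None = None,
) -> tuple[TwoChannelImage, GroundTruth]:
    """Simulate a field of DNA origami, mixing classes in equal numbers.

    Each origami carries a triangular marker of three reference-channel
    corner sites (``corner_strands`` docking strands each, two imager
    sites per strand) at ``corner_distance_nm`` from its center, and one
    quantification-channel target site at the center whose strand count is
    the origami's class (1-7).  Classes are placed in exactly equal
    numbers at random, non-overlapping positions and random orientations.
    """
    strand_counts = list(strand_counts)
    if not strand_counts:
        raise ValueError("strand_counts must be non-empty")
    if any(not (1 <= s <= 7) for s in strand_counts):
        raise ValueError("strand_counts must lie in 1..7")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")

    rng = np.random.default_rng(config.seed)
    n_total = len(strand_counts) * n_per_class
    psf = max(config.psf_fwhm_ref_nm, config.psf_fwhm_quant_nm)
    sep = 5.0 * psf if min_separation_nm is None else min_separation_nm
    spacing = sep + 50.0
    margin = corner_distance_nm + 2.0 * psf
    centers = _grid_positions(config, n_total, spacing,
                              jitter_nm=25.0, margin_nm=margin, rng=rng)

    classes = np.repeat(strand_counts, n_per_class)
    rng.shuffle(classes)
    angles0 = rng.uniform(0.0, 2.0 * math.pi, size=n_total)

    designs: list[EmitterDesign] = []
    origami_ids: list[int] = []
    for i in range(n_total):
        x, y = centers[i]
        for corner in range(3):
            a = angles0[i] + corner * (2.0 * math.pi / 3.0)
            designs.append(EmitterDesign(
                x_nm=x + corner_distance_nm * math.cos(a),
                y_nm=y + corner_distance_nm * math.sin(a),
                n_docking_strands=corner_strands,
                sites_per_strand=corner_sites_per_strand,
                channel=Channel.REFERENCE,
            ))
            origami_ids.append(i)
        designs.append(EmitterDesign(
            x_nm=x, y_nm=y, n_docking_strands=int(classes[i]),
            sites_per_strand=4, channel=Channel.QUANTIFICATION,
        ))
        origami_ids.append(i)

    image, truth = simulate_field(designs, config, rng=rng)
    truth = truth.assign(origami_id=origami_ids)
    return image, truth


def make_receptor_field(
    n_units: int,
    dimer_fraction: float,
    labeling_efficiency: float,
    config: SimulationConfig,
    dimer_separation_nm: float = 11.0,
    reference_brightness_au: float = 250.0,
    min_separation_nm: float | None = None,
) -> tuple[TwoChannelImage, GroundTruth]:
    """Simulate a resting/stimulated receptor field.

    Each of ``n_units`` receptor units is a dimer with probability
    ``dimer_fraction`` (two receptors ``dimer_separation_nm`` apart, below
    the PSF width) or a monomer.  Every receptor contributes a fixed
    reference-channel signal of ``reference_brightness_au`` (the
    identifier label, assumed fully labeled) and, independently with
    probability ``labeling_efficiency``, one 4x docking strand in the
    quantification channel.  A resting field is ``dimer_fraction=0``.

    The ground-truth table carries one row per emitter plus columns
    ``unit_id``, ``is_dimer`` and per-unit ``n_labeled``.
    """
    if not (0.0 <= dimer_fraction <= 1.0):
        raise ValueError("dimer_fraction must be in [0, 1]")
    if not (0.0 <= labeling_efficiency <= 1.0):
        raise ValueError("labeling_efficiency must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    psf = max(config.psf_fwhm_ref_nm, config.psf_fwhm_quant_nm)
    sep = 5.0 * psf if min_separation_nm is None else min_separation_nm
    spacing = sep + 50.0
    centers = _grid_positions(config, n_units, spacing,
                              jitter_nm=25.0, margin_nm=psf, rng=rng)

    is_dimer = rng.random(n_units) < dimer_fraction
    designs: list[EmitterDesign] = []
    unit_ids: list[int] = []
    dimer_flags: list[bool] = []
    half = 0.5 * dimer_separation_nm
    for i in range(n_units):
        x, y = centers[i]
        if is_dimer[i]:
            a = rng.uniform(0.0, 2.0 * math.pi)
            offsets = [(half * math.cos(a), half * math.sin(a)),
                       (-half * math.cos(a), -half * math.sin(a))]
        else:
            offsets = [(0.0, 0.0)]
        for dx, dy in offsets:
            designs.append(EmitterDesign(
                x_nm=x + dx, y_nm=y + dy, n_docking_strands=1,
                sites_per_strand=1, channel=Channel.REFERENCE,
            ))
            unit_ids.append(i)
            dimer_flags.append(bool(is_dimer[i]))
        for dx, dy in offsets:
            if rng.random() < labeling_efficiency:
                designs.append(EmitterDesign(
                    x_nm=x + dx, y_nm=y + dy, n_docking_strands=1,
                    sites_per_strand=4, channel=Channel.QUANTIFICATION,
                ))
                unit_ids.append(i)
                dimer_flags.append(bool(is_dimer[i]))
    
    # reference emitters carry a fixed brightness (the dye-labeled
    # identifier nanobody): render noise-free under a dedicated config
    # (occupancy 1, no brightness variation), then apply noise once to
    # the combined expected images
    ref_cfg = replace(config, brightness_per_fluorophore=reference_brightness_au,
                      brightness_cv=0.0, occupancy_p=1.0, noise="none")
    ref_designs = [d for d in designs if d.channel is Channel.REFERENCE]
    q_designs = [d for d in designs if d.channel is Channel.QUANTIFICATION]
    ref_img, ref_truth = simulate_field(ref_designs, ref_cfg, rng=rng)
    q_img, q_truth = simulate_field(q_designs, replace(config, noise="none"),
                                    rng=rng)
    expected_ref = ref_img.reference
    expected_q = q_img.quantification
    if config.noise in ("poisson", "poisson+gaussian"):
        expected_ref = rng.poisson(expected_ref).astype(float)
        expected_q = rng.poisson(expected_q).astype(float)
    if config.noise == "poisson+gaussian" and config.read_noise_sd > 0:
        expected_ref = expected_ref + rng.normal(
            0.0, config.read_noise_sd, size=expected_ref.shape)
        expected_q = expected_q + rng.normal(
            0.0, config.read_noise_sd, size=expected_q.shape)

    image = TwoChannelImage(expected_ref, expected_q, config.pixel_size_nm)
    truth = pd.concat([ref_truth, q_truth], ignore_index=True)
    truth["emitter_id"] = np.arange(len(truth))
    order = [u for u, d in zip(unit_ids, designs) if d.channel is Channel.REFERENCE]
    order += [u for u, d in zip(unit_ids, designs) if d.channel is Channel.QUANTIFICATION]
    flags = [f for f, d in zip(dimer_flags, designs) if d.channel is Channel.REFERENCE]
    flags += [f for f, d in zip(dimer_flags, designs) if d.channel is Channel.QUANTIFICATION]
    truth["unit_id"] = order
    truth["is_dimer"] = flags
    labeled_per_unit = (
        truth[truth.channel == Channel.QUANTIFICATION.value]
        .groupby("unit_id").size()
    )
    truth["n_labeled"] = truth["unit_id"].map(labeled_per_unit).fillna(0).astype(int)
    return image, truth


# ---------------------------------------------------------------------------
# IO


def write_tiff(path, image: TwoChannelImage, dtype: str = "float32") -> None:
    """Write the pair as a 2-page TIFF (page 0 = reference, 1 = quantification)."""
    if dtype not in ("float32", "uint16"):
        raise ValueError("dtype must be 'float32' or 'uint16'")
    stack = np.stack([image.reference, image.quantification])
    if dtype == "uint16":
        stack = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max)
    data = stack.astype(dtype)
    tifffile.imwrite(
        path, data,
        metadata={"pixel_size_nm": image.pixel_size_nm},
    )


def read_tiff(path, pixel_size_nm: float | None = None) -> TwoChannelImage:
    """Read a 2-page TIFF written by :func:`write_tiff` (or equivalent)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        if pixel_size_nm is None:
            meta = tif.shaped_metadata or tif.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            pixel_size_nm = float(meta.get("pixel_size_nm", 0.0)) or None
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("expected a multi-page TIFF with >= 2 channel pages")
    if pixel_size_nm is None:
        raise ValueError("pixel size not found in TIFF metadata; pass pixel_size_nm")
    return TwoChannelImage(data[0], data[1], pixel_size_nm)


def write_ground_truth(path, truth: GroundTruth) -> None:
    truth.to_csv(path, index=False)
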