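"""Biological inference from fitted peak fractions.

The labeling model treats every receptor as carrying a functional label
with probability LE (the labeling efficiency).  In a resting sample
(monomers only) the histogram splits into a background peak (unlabeled,
fraction f1) and a single-label peak (f2), giving LE = f2 / (f1 + f2).
In a stimulated sample containing a fraction F of dimers, the three peak
fractions follow a binomial labeling model:

    f3 = F * LE^2                                   (dual-labeled dimer)
    f2 = 2 * F * LE * (1 - LE) + (1 - F) * LE       (single label)
    f1 = F * (1 - LE)^2 + (1 - F) * (1 - LE)        (no label)

Two conventions are provided.  ``factor2`` (default) carries the binomial
multiplicity 2 on the single-labeled-dimer term, so the three fractions
sum to 1 for any (F, LE).  ``as_printed`` drops that factor (f2 = F * LE
* (1 - LE) + (1 - F) * LE), in which case the fractions sum to
1 - F * LE * (1 - LE); it is retained for literal reproduction of that
variant of the model.  Every report states the convention used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONVENTIONS",
    "LabelingEfficiency",
    "DimerEstimate",
    "DensityReport",
    "estimate_labeling_efficiency",
    "dimer_peak_width",
    "forward_fractions",
    "invert_dimer_fraction",
    "cluster_density",
]

CONVENTIONS = ("factor2", "as_printed")

#: below this, |1 - 2 LE| makes the factor2 second-peak inversion degenerate
_DEGENERATE_TOL = 1e-9


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")


@dataclass
class LabelingEfficiency:
    le: float
    se: float


def estimate_labeling_efficiency(
    f1: float, f2: float, f1_se: float = 0.0, f2_se: float = 0.0,
) -> LabelingEfficiency:
    """LE = f2 / (f1 + f2) from the resting-sample peak fractions.

    f1 is the background (unlabeled) peak fraction, f2 the single-label
    peak fraction.  The SE is propagated to first order from the fraction
    SEs (assumed uncorrelated).
    """
    if f1 < 0 or f2 < 0:
        raise ValueError("fractions must be >= 0")
    total = f1 + f2
    if total == 0:
        raise ValueError("f1 + f2 must be > 0")
    le = f2 / total
    d1 = -f2 / total ** 2
    d2 = f1 / total ** 2
    se = math.hypot(d1 * f1_se, d2 * f2_se)
    return LabelingEfficiency(le=float(le), se=float(se))


def dimer_peak_width(fwhm2: float) -> float:
    """Width of the dual-label peak: fwhm3 = fwhm2 * sqrt(2).

    The dual-label intensity is the sum of two independent single-label
    intensities, so its spread grows by sqrt(2).
    """
    if fwhm2 <= 0:
        raise ValueError("fwhm2 must be > 0")
    return fwhm2 * math.sqrt(2.0)


def forward_fractions(
    f_dimer: float, le: float, convention: str = "factor2",
) -> tuple[float, float, float]:
    """Peak fractions (f1, f2, f3) predicted from (F_dimer, LE)."""
    _check_convention(convention)
    if not (0.0 <= f_dimer <= 1.0 and 0.0 <= le <= 1.0):
        raise ValueError("f_dimer and le must lie in [0, 1]")
    F, p = f_dimer, le
    f3 = F * p ** 2
    f1 = F * (1.0 - p) ** 2 + (1.0 - F) * (1.0 - p)
    if convention == "factor2":
        f2 = 2.0 * F * p * (1.0 - p) + (1.0 - F) * p
    else:
        f2 = F * p * (1.0 - p) + (1.0 - F) * p
    return (f1, f2, f3)


def _invert_one(peak: int, f: float, le: float, convention: str) -> float:
    """Closed-form F from a single observed peak fraction at known LE."""
    p = le
    if peak == 3:
        return f / p ** 2
    if peak == 1:
        return (1.0 - f / (1.0 - p)) / p
    if convention == "factor2":
        denom = 1.0 - 2.0 * p
        if abs(denom) < _DEGENERATE_TOL:
            return math.nan  # f2 = 1/2 regardless of F: uninformative
        return (f / p - 1.0) / denom
    return (p - f) / p ** 2


@dataclass
class DimerEstimate:
    """Per-peak and aggregate dimer-fraction estimates at a given LE."""

    per_peak: tuple[float, float, float]  # via f1, f2, f3 (clipped to [0,1])
    per_peak_raw: tuple[float, float, float]
    per_peak_se: tuple[float, float, float]
    clipped: tuple[bool, bool, bool]
    degenerate: tuple[bool, bool, bool]
    mean: float
    mean_se: float
    convention: str
    le: float


def invert_dimer_fraction(
    f1: float,
    f2: float,
    f3: float,
    le: float,
    convention: str = "factor2",
    fraction_ses: tuple[float, float, float] | None = None,
    le_se: float = 0.0,
    weighted: bool = False,
) -> DimerEstimate:
    """Estimate the dimer fraction F from observed peak fractions.

    Each peak equation is inverted in closed form for F given LE; the
    three estimates are clipped to [0, 1] (flagged when clipping occurs)
    and combined as an unweighted mean (``weighted=True`` uses
    inverse-variance weights instead).  SEs are propagated to first order
    from the fraction SEs and, when given, the LE SE, combined across
    peaks without correlation — a conservative simplification.

    Under the factor2 convention the second-peak equation carries no
    information about F at LE = 1/2; that estimate is then NaN, flagged
    ``degenerate`` and excluded from the aggregate.
    """
    _check_convention(convention)
    if not (0.0 < le < 1.0):
        raise ValueError("LE must lie strictly inside (0, 1); the model is "
                         "unidentifiable at LE = 0 or 1")
    fracs = (f1, f2, f3)
    if any(f < 0 for f in fracs):
        raise ValueError("fractions must be >= 0")
    ses = fraction_ses if fraction_ses is not None else (0.0, 0.0, 0.0)

    raw, clipped, flags, se_out = [], [], [], []
    h = 1e-7
    for peak, f, sf in zip((1, 2, 3), fracs, ses):
        est = _invert_one(peak, f, le, convention)
        degen = math.isnan(est)
        flags.append(degen)
        raw.append(est)
        if degen:
            clipped.append(False)
            se_out.append(math.nan)
            continue
        dfd = (_invert_one(peak, f + h, le, convention)
               - _invert_one(peak, f - h, le, convention)) / (2 * h)
        dle = (_invert_one(peak, f, min(le + h, 1 - h), convention)
               - _invert_one(peak, f, max(le - h, h), convention)) / (2 * h)
        se_out.append(math.hypot(dfd * sf, dle * le_se))
        clipped.append(not (0.0 <= est <= 1.0))

    per_peak = tuple(
        math.nan if math.isnan(r) else min(max(r, 0.0), 1.0) for r in raw
    )
    valid = [i for i in range(3) if not flags[i]]
    if not valid:
        raise ValueError("no identifiable peak equations at this LE")
    vals = np.array([per_peak[i] for i in valid])
    errs = np.array([se_out[i] for i in valid])
    if weighted and np.all(errs > 0):
        wgt = 1.0 / errs ** 2
        mean = float(np.sum(wgt * vals) / np.sum(wgt))
        mean_se = float(1.0 / math.sqrt(np.sum(wgt)))
    else:
        mean = float(vals.mean())
        mean_se = float(np.sqrt(np.sum(errs ** 2)) / len(valid))
    return DimerEstimate(
        per_peak=per_peak,
        per_peak_raw=tuple(raw),
        per_peak_se=tuple(se_out),
        clipped=tuple(clipped),
        degenerate=tuple(flags),
        mean=mean,
        mean_se=mean_se,
        convention=convention,
        le=le,
    )


@dataclass
class DensityReport:
    n_spots: int
    area_um2: float
    density_per_um2: float


def cluster_density(
    spot_table: pd.DataFrame,
    mask: np.ndarray,
    pixel_size_nm: float,
) -> DensityReport:
    """Spots per um^2 inside a boolean mask.

    Counts spot-table rows whose (row, col) pixel lies inside the mask and
    divides by the mask area converted with the pixel size.
    """
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise ValueError("mask area must be > 0")
    area_um2 = n_pixels * (pixel_size_nm * 1e-3) ** 2
    if len(spot_table):
        r = spot_table["row"].to_numpy(dtype=int)
        c = spot_table["col"].to_numpy(dtype=int)
        inside = mask[r, c]
        n = int(inside.sum())
    else:
        n = 0
    return DensityReport(n_spots=n, area_um2=float(area_um2),
                         density_per_um2=n / area_um2)
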