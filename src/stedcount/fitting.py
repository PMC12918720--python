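"""Intensity histograms and constrained multi-Gaussian peak fitting.

Histogram peaks are modeled as

    y(x) = y0 + A / (fwhm * sqrt(pi / (2 ln 2))) * exp(-4 ln 2 ((x - xc)/fwhm)^2)

with a single shared baseline y0 across components.  ``A`` is the peak's
area parameter on this parameterization; component fractions are
f_i = A_i / sum_j A_j and are invariant to the normalization constant.
Widths (and centers) can be frozen per component -- the calibration
workflow fixes fwhm values obtained from unmixed samples -- and the third
peak of the dual-label model can be linked to fwhm2 * sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "IntensityHistogram",
    "GaussianComponent",
    "MixtureFit",
    "FractionResult",
    "gaussian_peak",
    "build_histogram",
    "fit_gaussians",
    "component_fractions",
]

_LN2 = math.log(2.0)
#: multiplies A/fwhm to give the peak height above baseline
HEIGHT_FACTOR = 1.0 / math.sqrt(math.pi / (2.0 * _LN2))


def gaussian_peak(x, y0, xc, A, fwhm):
    """Single Gaussian peak with offset, center, area parameter and fwhm."""
    x = np.asarray(x, dtype=float)
    amp = A / fwhm * HEIGHT_FACTOR
    return y0 + amp * np.exp(-4.0 * _LN2 * ((x - xc) / fwhm) ** 2)


@dataclass
class IntensityHistogram:
    """Binned intensities with uniform bins starting at the exclusion threshold."""

    bin_size: float
    edges: np.ndarray
    counts: np.ndarray
    exclusion_threshold: float
    n_total: int
    n_retained: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def retained_fraction(self) -> float:
        """Share of input values surviving the exclusion threshold."""
        return self.n_retained / self.n_total if self.n_total else math.nan


def build_histogram(
    intensities,
    bin_size: float,
    exclusion_threshold: float = 0.0,
) -> IntensityHistogram:
    """Bin intensities, dropping values <= the exclusion threshold.

    The first bin edge sits at the threshold and bins of width
    ``bin_size`` extend to cover the maximum retained value.  The retained
    fraction is recorded so the share of signal analyzed can be reported.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    values = np.asarray(intensities, dtype=float).ravel()
    kept = values[values > exclusion_threshold]
    if kept.size == 0:
        raise ValueError("no intensities above the exclusion threshold")
    span = kept.max() - exclusion_threshold
    n_bins = max(1, int(math.ceil(span / bin_size)))
    edges = exclusion_threshold + bin_size * np.arange(n_bins + 1)
    if edges[-1] < kept.max():  # guard against float round-off at the top edge
        edges = np.append(edges, edges[-1] + bin_size)
    counts, _ = np.histogram(kept, bins=edges)
    return IntensityHistogram(
        bin_size=float(bin_size),
        edges=edges,
        counts=counts.astype(int),
        exclusion_threshold=float(exclusion_threshold),
        n_total=int(values.size),
        n_retained=int(kept.size),
    )


@dataclass
class GaussianComponent:
    xc: float
    A: float
    fwhm: float
    xc_se: float | None = None
    A_se: float | None = None
    fwhm_se: float | None = None
    xc_fixed: bool = False
    fwhm_fixed: bool = False


@dataclass
class MixtureFit:
    """Result of a shared-baseline multi-Gaussian histogram fit."""

    components: list[GaussianComponent]
    y0: float
    y0_se: float | None
    rss: float
    converged: bool
    n_bins: int
    area_cov: np.ndarray | None = None  # covariance of the free A_i
    message: str = ""

    @property
    def k(self) -> int:
        return len(self.components)

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.y0)
        for comp in self.components:
            y = y + gaussian_peak(x, 0.0, comp.xc, comp.A, comp.fwhm)
        return y


def _initial_centers(hist: IntensityHistogram, k: int) -> np.ndarray:
    """k initial centers from the most prominent histogram peaks."""
    from scipy.signal import find_peaks

    counts = hist.counts.astype(float)
    centers = hist.centers
    peaks, props = find_peaks(counts, prominence=0.0)
    if len(peaks):
        order = np.argsort(props["prominences"])[::-1]
        best = np.sort(peaks[order[:k]])
        init = list(centers[best])
    else:
        init = []
    while len(init) < k:  # fall back to mass quantiles
        total = counts.sum()
        if total <= 0:
            init.append(float(centers[len(init) % len(centers)]))
            continue
        q = (len(init) + 0.5) / k
        cdf = np.cumsum(counts) / total
        init.append(float(centers[np.searchsorted(cdf, q)]))
    return np.sort(np.asarray(init[:k], dtype=float))


def fit_gaussians(
    hist: IntensityHistogram,
    k: int,
    init_centers=None,
    fixed_fwhm=None,
    fixed_centers=None,
    link_fwhm3_sqrt2: bool = False,
    poisson_weights: bool = False,
    fixed_y0: float | None = None,
) -> MixtureFit:
    """Least-squares fit of k shared-baseline Gaussian peaks to a histogram.

    Parameters with entries in ``fixed_fwhm`` / ``fixed_centers`` (length-k
    sequences; ``None`` entries stay free) are frozen at the given values.
    ``link_fwhm3_sqrt2`` constrains the last component's width to
    ``sqrt(2)`` times the second's (the dual-label peak of the dimer
    model).  The default objective is unweighted least squares on the bin
    counts; ``poisson_weights`` switches to 1/sqrt(max(count, 1)) weights.

    Returns a :class:`MixtureFit`; non-convergence is flagged, never
    silently replaced.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    non_empty = int((hist.counts > 0).sum())
    if non_empty < 4 * k:
        raise ValueError(
            f"histogram has {non_empty} non-empty bins; need >= {4 * k} for k={k}"
        )
    for name, seq in (("fixed_fwhm", fixed_fwhm), ("fixed_centers", fixed_centers),
                      ("init_centers", init_centers)):
        if seq is not None and len(seq) != k:
            raise ValueError(f"{name} must have length k={k}")
    if link_fwhm3_sqrt2 and k < 2:
        raise ValueError("link_fwhm3_sqrt2 requires k >= 2")

    x = hist.centers
    y = hist.counts.astype(float)
    centers0 = (np.asarray(init_centers, dtype=float) if init_centers is not None
                else _initial_centers(hist, k))
    if fixed_centers is not None:
        centers0 = np.array([
            fc if fc is not None else c0
            for fc, c0 in zip(fixed_centers, centers0)
        ])
    fwhm0 = 4.0 * hist.bin_size
    span = x[-1] - x[0] + hist.bin_size

    params = lmfit.Parameters()
    if fixed_y0 is not None:
        # a spot-intensity histogram has no pedestal: every count belongs
        # to some component, so pipelines may pin the baseline
        params.add("y0", value=float(fixed_y0), vary=False)
    else:
        params.add("y0", value=float(y.min()))  # unconstrained baseline offset
    for i in range(k):
        c0 = float(centers0[i])
        # local mass around the initial center as the starting area
        sel = np.abs(x - c0) <= 2.0 * fwhm0
        a0 = max(float(y[sel].sum() * hist.bin_size), hist.bin_size)
        params.add(f"xc{i}", value=c0, min=x[0] - span, max=x[-1] + span)
        params.add(f"A{i}", value=a0, min=0.0)
        if fixed_fwhm is not None and fixed_fwhm[i] is not None:
            params.add(f"fwhm{i}", value=float(fixed_fwhm[i]), vary=False)
        elif link_fwhm3_sqrt2 and i == k - 1:
            params.add(f"fwhm{i}", expr=f"fwhm{k - 2} * sqrt(2)")
        else:
            params.add(f"fwhm{i}", value=fwhm0, min=hist.bin_size / 20.0)
        if fixed_centers is not None and fixed_centers[i] is not None:
            params[f"xc{i}"].set(value=float(fixed_centers[i]), vary=False)

    def model(p) -> np.ndarray:
        out = np.full_like(x, p["y0"].value)
        for i in range(k):
            out = out + gaussian_peak(x, 0.0, p[f"xc{i}"].value,
                                      p[f"A{i}"].value, p[f"fwhm{i}"].value)
        return out

    def residual(p):
        r = model(p) - y
        if poisson_weights:
            # Pearson residuals: variance taken from the model, not the
            # observed counts (observed-count weights bias low-count fits)
            return r / np.sqrt(np.maximum(model(p), 1.0))
        return r

    result = lmfit.minimize(residual, params, method="leastsq",
                            nan_policy="raise", max_nfev=20000)
    p = result.params
    comps = []
    for i in range(k):
        comps.append(GaussianComponent(
            xc=float(p[f"xc{i}"].value),
            A=float(p[f"A{i}"].value),
            fwhm=float(p[f"fwhm{i}"].value),
            xc_se=_se(p[f"xc{i}"]),
            A_se=_se(p[f"A{i}"]),
            fwhm_se=_se(p[f"fwhm{i}"]),
            xc_fixed=not p[f"xc{i}"].vary,
            fwhm_fixed=not p[f"fwhm{i}"].vary,
        ))
    order = np.argsort([c.xc for c in comps])
    comps = [comps[i] for i in order]

    area_cov = None
    if result.covar is not None:
        names = [nm for nm in result.var_names]
        a_idx = []
        ok = True
        for i in order:
            nm = f"A{i}"
            if nm in names:
                a_idx.append(names.index(nm))
            else:
                ok = False
        if ok:
            area_cov = np.asarray(result.covar)[np.ix_(a_idx, a_idx)]

    resid = model(p) - y
    return MixtureFit(
        components=comps,
        y0=float(p["y0"].value),
        y0_se=_se(p["y0"]),
        rss=float(np.sum(resid ** 2)),
        converged=bool(result.success),
        n_bins=len(x),
        area_cov=area_cov,
        message=str(result.message),
    )


def _se(param) -> float | None:
    se = getattr(param, "stderr", None)
    return float(se) if se is not None and np.isfinite(se) else None


@dataclass
class FractionResult:
    """Component fractions f_i = A_i / sum(A_j) with propagated SEs."""

    fractions: np.ndarray
    ses: np.ndarray
    included: list[int]


def component_fractions(fit: MixtureFit, exclude=()) -> FractionResult:
    """Fractions of the included components' areas (sum exactly 1).

    SEs are propagated to first order from the area covariance when the
    fit provides one, otherwise from the per-area SEs assuming
    independence.
    """
    if not fit.converged:
        raise ValueError("cannot compute fractions from a non-converged fit")
    included = [i for i in range(fit.k) if i not in set(exclude)]
    if not included:
        raise ValueError("all components excluded")
    areas = np.array([fit.components[i].A for i in included], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all component areas are zero")
    fractions = areas / total

    m = len(included)
    if fit.area_cov is not None and fit.area_cov.shape == (fit.k, fit.k):
        cov = fit.area_cov[np.ix_(included, included)]
    else:
        ses = np.array([
            fit.components[i].A_se if fit.components[i].A_se is not None else 0.0
            for i in included
        ])
        cov = np.diag(ses ** 2)
    # d f_i / d A_j = (delta_ij * total - A_i) / total^2
    jac = (np.eye(m) * total - areas[:, None]) / total ** 2
    var = np.einsum("ij,jk,ik->i", jac, cov, jac)
    return FractionResult(fractions=fractions, ses=np.sqrt(np.maximum(var, 0.0)),
                          included=included)
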