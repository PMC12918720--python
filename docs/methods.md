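# Methods

This note documents the models, algorithms and numerical choices behind
`stedcount`, and what the synthetic-data generator does and does not
emulate.

## Counting by intensity

The workflow assumes two spectrally separated labels on the same target:
an *identifier* label imaged in the reference channel, used only to find
spots, and a *counting* label with defined stoichiometry (a DNA docking
strand binding up to four fluorophore-labeled imager strands) imaged in
the quantification channel.  Detection in one channel and readout in the
other keeps unspecific signal out of the intensity statistics: a spot is
only analyzed if the identifier is present, and its quantification-channel
intensity is an unbiased sample (the two channels' noise is independent,
so reading at the reference-channel maximum does not select for upward
fluctuations in the counting channel).

### Spot detection

`find_maxima` accepts a local maximum when its **prominence** — the
maximum's value minus the highest saddle level connecting it to any
strictly higher region — reaches a threshold.  The implementation sorts
equal-value plateaus in descending value order and merges components with
a union-find (peak persistence); the saddle level of a peak is the value
at which its component first merges with a component holding a strictly
higher peak.  Properties fixed here, since "find maxima by prominence"
alone does not pin them down:

* 8-connectivity;
* plateaus of equal value count as one maximum, reported at the plateau
  centroid rounded half-up (row, then column);
* peaks of exactly equal height do not kill each other: both survive
  until strictly higher ground appears (or to the end, taking
  `value − min(image)` like the global maximum);
* border maxima are retained by default (`exclude_border` exists);
* output is deterministically ordered by (row, column).

These semantics are regression-tested against an independent brute-force
oracle that, for every local-maximum plateau, lowers a water level from
the peak until the flooded region touches a strictly higher pixel
(scipy.ndimage-based, sharing no code with the detector).

The default readout is the single pixel value at the detected coordinate.
A `mean3x3` readout (average over the 3×3 neighborhood) is provided as an
explicit alternative; see "Width law" below for when it matters.

### Histogramming and peak fitting

Intensities are binned with a fixed bin size (2 au for origami data, 1 au
for receptor data), after discarding values at or below an exclusion
threshold; bins start at the threshold and the retained fraction is
reported.  For origami samples a threshold of 2 au isolates the
target-specific signal.  For receptor data no positive threshold is used
— the background peak is kept and modeled as the first Gaussian
component — and the pipeline default threshold of −0.5 au makes integer
pixel counts (including 0) fall at bin centers.

Histogram peaks are fitted by nonlinear least squares as a sum of
Gaussians

    y(x) = y0 + A / (fwhm · sqrt(π/(2 ln 2))) · exp(−4 ln 2 ((x − xc)/fwhm)²)

with one shared baseline `y0` (k independent offsets would be
degenerate).  On this parameterization the height at `xc` is
`y0 + A/(fwhm·sqrt(π/(2 ln 2)))` and the true integral of a component is
`A/√2`; since the normalization constant is common to all components, the
fractions `f_i = A_i / Σ A_j` are unaffected, and `A` is reported as
given by the fit.  Per-component widths and centers can be frozen, and
the last width can be linked as `fwhm₃ = fwhm₂·√2`.

Numerical choices:

* optimizer: Levenberg–Marquardt via lmfit, which also provides the
  parameter covariance; convergence is reported honestly (no fallback);
* initialization: the k most prominent histogram peaks as centers
  (falling back to mass quantiles), initial width 4 bins, initial area
  from the local mass, baseline at the minimum count;
* components are sorted by center in the output;
* the default objective is **unweighted** least squares on bin counts.
  A `poisson_weights` option divides residuals by `sqrt(max(model, 1))`
  (Pearson residuals).  Model-based weights matter twice: observed-count
  weights bias low-count fits (bins fluctuating low get overweighted),
  and unweighted fits understate the uncertainty of parameters dominated
  by high-count bins.  The pipeline presets use Pearson weighting, and
  additionally pin `y0 = 0` (`fixed_y0`), because a spot-intensity
  histogram has no pedestal — every count belongs to some component, and
  a free baseline can absorb peak tails and destabilize area ratios.
  The free-baseline, unweighted fit remains the library default.

Fraction uncertainties are propagated to first order from the area
covariance of the fit (falling back to independent SEs when the
covariance is unavailable).

### Calibration

With origami standards carrying N ∈ {1…7} target docking strands, the
fitted centers follow `xc(N) = slope·N + intercept` (ordinary least
squares; the intercept estimates the background readout level), and the
widths follow `fwhm(N) = a·√N`, because independent per-strand
contributions add in variance.  The square-root fit is pure by default
(`a = Σ√N·fwhm / ΣN` in closed form); an additive-offset variant is
reported with a flag.  An SE-weighted regression option exists; the
default is unweighted.  `predict_count` inverts the line for unknown
samples, clipping negative estimates to zero with a flag.

**Width law and readout.**  The √N law holds when per-spot intensity
variance grows linearly with N (per-strand brightness, site occupancy,
shot noise).  The single-pixel readout adds a *multiplicative* spread —
the read pixel sits a variable sub-pixel offset from the emitter center,
scaling the whole signal — whose standard deviation grows like N, not
√N.  The width-law verification therefore uses the neighborhood-mean
readout, which integrates enough flux to make the offset factor nearly
constant, together with a noise-free detector so per-fluorophore
brightness variation dominates.  Under the default single-pixel/Poisson
conditions the measured `fwhm(4)/fwhm(1)` ratio is still ≈ 2 but with a
small upward bias.

A related, smaller effect: single-Gaussian fits of slightly skewed peaks
(the occupancy mixture over 2–4 occupied sites is left-skewed) displace
fitted centers by a few tenths of an au in an N-dependent way.  The
calibration is linear to R² > 0.999, but a χ² lack-of-fit test at
α = 0.01 against the per-class center SEs — which are only ~0.1–0.7 au —
can occasionally reject on this systematic; the corresponding test is
seeded and the effect documented here rather than hidden.

### Labeling efficiency and dimer fraction

Resting receptor samples are assumed purely monomeric, so their histogram
has a background peak (unlabeled receptors, fraction f1) and a
single-label peak (f2), giving `LE = f2/(f1+f2)` with first-order SE
propagation.  Stimulated samples are modeled as monomer/dimer mixtures;
the three-peak fractions follow the binomial model given in the README.

Two conventions are implemented for the single-labeled-dimer term.  The
`factor2` convention carries the binomial multiplicity 2 (two ways to
label one of two protomers) and normalizes exactly to 1 for all (F, LE);
it is the default.  The `as_printed` convention drops that factor, so the
fractions sum to `1 − F·LE·(1−LE)`; it is retained for literal
reproduction of that variant and every report states which convention was
used.  Each peak equation is inverted in closed form; under `factor2`
the second-peak equation, `f2 = LE·(1 + F(1−2LE))`, carries no
information about F at LE = 1/2, where that estimate is returned as NaN
with a `degenerate` flag and excluded from the aggregate.

The headline dimer fraction is the unweighted mean of the per-peak
estimates (an inverse-variance-weighted alternative exists).  Its SE
combines the per-peak SEs — each propagated from the fraction SEs and,
when supplied, the LE SE — without correlation terms.  The per-peak
estimates derive from one fit and are in fact negatively correlated
through the fraction constraint, so the no-correlation combination is
conservative.

Cluster density is the count of detected spots inside a boolean mask
divided by the mask area in μm².

## The synthetic-data generator

`simulate` renders point emitters as isotropic 2D Gaussians (the
effective STED PSF) integrated analytically over pixel areas, so the
rendered flux equals the realized brightness exactly (flux conservation
is asserted by pixel sums in the tests).  Per emitter, the number of
occupied fluorophore sites is Binomial(strands × sites, occupancy), and
each occupied fluorophore contributes a lognormal brightness factor of
mean 1.  Poisson shot noise (optionally plus Gaussian read noise) is
applied last.  All randomness flows from a single integer seed;
identical seed and inputs give bit-identical images.

Defaults, chosen once as a realistic operating point:

| parameter | default | rationale |
|---|---|---|
| pixel size | 30 nm | typical STED sampling for this kind of imaging |
| PSF fwhm (both channels) | 70 nm | a routine effective STED resolution |
| occupancy p | 0.9 | high-affinity (LNA-stabilized) imagers near saturation |
| brightness / fluorophore | 30 au | places spot peaks well above shot noise, giving the clearly bimodal / multi-modal histograms the method needs; the "au" scale is arbitrary and only defined relative to the thresholds and bin sizes |
| brightness CV | 0.2 | moderate per-fluorophore emission variability |
| background | 2 au/pixel | weak uniform background |
| noise | Poisson | shot-noise-limited photon counting |
| identifier brightness (receptors) | 250 au | the identifier channel is imaged brightly; detection there must not limit the analysis |
| dimer separation | 11 nm | protomer spacing well below the PSF, so dimers appear as single spots |

Origami fields place each origami's three reference corner sites at a
configurable design distance (default 30 nm) from the center and a single
central target site with the class's strand count (7 strands × 2 imager
sites per corner).  Mixtures contain exactly equal class counts.
Receptor fields hold monomers/dimers at ~5.5 units/μm² on a cell-sized
field; every receptor carries the identifier label, and independently
with probability LE one 4x docking strand.

Emitters are placed on a jittered grid guaranteeing ≥ 5 PSF-fwhm
separation.  Rejection sampling would jam at these densities; the grid
keeps spots resolvable, which is also the regime the real experiments are
designed for (sparse fields / moderate receptor densities).  Positional
regularity does not enter any intensity statistic.

**What the generator does not emulate**, and hence what passing tests do
not certify about real data: photobleaching, blinking and imager exchange
kinetics; unspecific binding and autofluorescence structure; sample drift
and chromatic misregistration (the package *measures* channel offsets
rather than correcting them); spatially varying background or PSF;
spot overlap and clustering beyond the dimer geometry; detector
afterpulsing or saturation; 3D effects.  Estimator behavior on real
images additionally depends on how well two Gaussians describe truly
skewed peak shapes.

## Problem sizes

The test-suite and acceptance-script runs use: 300 origami per class on
320² px fields (480² px for the three-class mixture, ~900 spots), and
1000 receptor units on 448² px fields (~181 μm², ~5.5 units/μm²);
parameter-recovery coverage uses 100 seeded resting/stimulated pairs.
These sizes give per-run fraction SEs of a few percent, comparable to a
pooled multi-cell experiment.

## Known limitations

* The aggregate dimer fraction recovered from the default synthetic
  stimulated fields is biased upward by a few percentage points (peak
  shape mismatch between the skewed dual-label peak and the √2-linked
  Gaussian); the bias is well inside the reported SE, and the coverage
  tests confirm the intervals remain honest.
* Closed-form per-peak inversion can leave [0, 1]; estimates are clipped
  with flags rather than re-solved under constraints.
* The fit covariance understates center uncertainty for unweighted fits
  of count histograms; use Pearson weighting (as the pipeline does) when
  the SEs are consumed downstream.
* No model selection across component counts k is provided; k comes from
  the experimental design.
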