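# Methods

This note documents the models, parameter choices and numerical decisions
behind `dermaflim`, and what the synthetic cohorts do and do not
establish about real clinical data.

## Decay model and fitter

Per-pixel TCSPC histograms are modelled as
`f(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2)` with the instrument response
treated as an ideal delta: no IRF convolution, no background term.  This
keeps the fitted model identical to the two-component description the
analysis is built on; real instruments would add an IRF and an
afterpulsing background, which this package deliberately does not model.
Skin autofluorescence in the 405–600 nm band is a mixture of NAD(P)H,
keratin, flavins and melanin; at realistic signal-to-noise only two
components are identifiable, hence exactly two are fitted.

The default time axis is 256 bins over 12.5 ns (the 80 MHz
repetition-rate equivalent; 48.8 ps bins).  Before fitting, each pixel's
trace is replaced by the sum over a (2n+1)×(2n+1) moving window with
n = 4 (81 pixels, clipped at frame edges), implemented with integer
integral images so photon conservation is exact.

Fitting is iteratively reweighted Poisson least squares, solved by a
projected Levenberg–Marquardt loop vectorised over all pixels of a frame
simultaneously (per-pixel 4×4 normal equations, per-pixel damping, box
projection to bounds).  The first pass weights by `1/max(count, 1)`; the
weights are then recomputed from the fitted model, `1/max(model, 1)`,
and a second pass refines the estimate.  The refinement matters: data
counts appearing in their own weights correlate noise with weight and
bias lifetimes low by several percent at typical photon budgets, which
model-derived weights remove.  A single-exponential model is fitted
alongside, and the two-component fit is reported only when it beats the
single fit by a Poisson-deviance margin of 9 (roughly a 1 % χ² test on
the two extra parameters); otherwise the trace is reported as a single
component with `a2 = 0` — for one-component data the bi-exponential
surface is a flat ridge and an unguarded fit lands at an arbitrary,
noise-chosen split.  The
initialiser is deterministic: a count-weighted log-linear regression on
the last 40 % of bins gives the long-lifetime start, the short lifetime
starts at a fifth of it, and the amplitudes come from a weighted linear
solve — no random restarts, so identical inputs give identical fits.
Bounds are τ ∈ [0.01, 10] ns and a ≥ 0.  Components are reported in
ascending lifetime order; fits whose two lifetimes agree within 2 % are
collapsed to a single-component report (p2 = 0).  Pixels with fewer than
`min_photons = 100` photons in the binned trace are masked (below this a
two-component fit is not identifiable); non-converged pixels are masked
with a sentinel χ².  Frame statistics (mean and population-N standard
deviation of τ1, τ2, and the amplitude percentages) are computed over
valid pixels only.

"Percentage of fluorescence from a component" uses the amplitude
convention `p_i = 100·a_i/(a1+a2)` by default — the convention of the
commercial fitting software this pipeline's feature set mirrors — with
the intensity-weighted alternative `a_iτ_i/Σaτ` available as an option.

`fit_frame` accepts a `stride`: fitting every stride-th pixel of the
binned frame.  Because binning already correlates neighbours over a
9-pixel window, frame-level statistics from a strided grid are nearly as
precise as from the full grid; stride is a pure compute knob.

## Texture features

**Fourier parameter.**  2-D FFT of the time-summed intensity frame,
magnitude averaged over two centred annuli — medium r ∈ [14, 24) px and
high r ∈ [24, 36) px for a 512 px frame — and reported as high/medium.
Inner radii are inclusive, outer exclusive, so the two zones partition
[14, 36) without double counting.  DC and low frequencies (illumination)
and very high frequencies (noise) are excluded by construction.  The
radii are defined in FFT pixels at a 512 px reference and scale
proportionally with frame size, i.e. the bands sit at a fixed fraction
of the Nyquist frequency.  The direction high/medium (rising with
sub-cellular clutter such as mitochondrial clustering) is the package's
standard; an `invert` flag gives the reciprocal.  The radial average
uses raw |F|, not log magnitude.

**Local entropy.**  The frame is min–max quantized to 256 gray levels;
each pixel's Shannon entropy (base 2) is computed over the gray-level
histogram in a radius-2 px disk (13 pixels, neighbourhoods clipped at
edges) and averaged over the frame.  Computing entropy locally first
suppresses slow illumination gradients.  The implementation is the
rank-filter entropy of scikit-image, verified bit-exact against a
brute-force per-pixel histogram computation; min–max quantization makes
the measure invariant to positive affine intensity changes.

## Layers and feature vectors

SG and SB frames are selected by depth metadata (nearest recorded depth
to the configured target), never by image content.  "Optical distance"
SG→SB is the raw stage-depth difference with no refractive-index
correction.  The 8-feature condition vector (per site) and 5-feature
PASI vector (per psoriasis subject, with three inflamed/pseudo-control
ratios) have fixed, versioned schemas; any site with a missing or
non-finite constituent is excluded and logged, not imputed.

## Severity model

Features are individually scaled to zero mean and unit variance
(population divisor), so the subsequent PCA is correlation-matrix PCA.
It is computed via SVD of the centred scaled table (numerically stabler
than forming the covariance; the test suite checks agreement with a
brute-force eigendecomposition to 1e−8).  PC1 is oriented as the
severity axis:

* condition model — sign chosen so the highest-severity group present
  (ordinal order control < pseudo-control < eczema < psoriasis) has the
  larger mean PC1 than the lowest; ties resolve to +1; absent labels
  leave the sign at +1 with a warning;
* PASI model — sign chosen so the inflamed-site SG→SB distance loads
  positively (epidermal thickening = more severe).  Orienting by
  correlation with PASI itself would bias the reported correlation
  positive, so it is deliberately not done.

Group separation is summarised by the mean silhouette in the PC1–PC2
plane plus pairwise group-mean gaps along PC1.  PASI banding uses
low = [1, 9] and high = [10, 29]; a combined PASI+LIS banding is not
canonically defined, so it is provided as a separate configurable
predicate (`combined_band`, default: high if PASI ≥ 10 or LIS ≥ 7) and
marked non-canonical, never baked into the model.  PASI totals use the
standard body-surface weights (head 0.1,
upper limbs 0.2, trunk 0.3, lower limbs 0.4), which are not part of the
region-score arithmetic itself and are configurable.

The row unit is one imaging site for the condition analysis (a psoriasis
subject contributes a lesional and a pseudo-control row) and one subject
for the PASI analysis.

## Synthetic cohorts

The generator emulates the acquisition protocol the pipeline targets:
200 µm × 200 µm fields recorded as 40 optical sections in 5 µm steps
(depths 0–195 µm), 512 px frames, 256 time bins over 12.5 ns.  All of
these are configurable; `PipelineConfig.reduced()` is the documented
desk-scale setting (128 px, 64 bins, only the SG/SB sections
materialised, fit stride 8) used by the test suite and the acceptance
script — statistically equivalent per-feature, with slightly larger
sampling noise.

Per-pixel expected decays are
`A(x,y)·[(1−q)e^(−t/τ1) + q e^(−t/τ2)]`, normalised so the expected
total per pixel is `photons_per_pixel·A`, with Poisson counts per bin.
The amplitude field A is a cellular texture: a smooth low-frequency
background, bright cytoplasm rings around dark nuclei with spacing a
fixed fraction (1/18) of the frame so cell-scale power lands in the
medium Fourier annulus, and `puncta_density` bright 1–2 px puncta
(mitochondrial-cluster analogue) whose broad spectrum raises the high
annulus.  The long-component fraction q tracks the texture weakly
(factor 0.15), mimicking structure-correlated metabolic signal.

Group defaults (simulation choices, not measurements — directions follow
the qualitative biology: longer τ2, thicker epidermis, more puncta and a
larger long-component fraction in inflamed skin):

| group          | τ1 (ns) | τ2 (ns) | a2 frac | SG (µm) | SB (µm) | puncta |
|----------------|---------|---------|---------|---------|---------|--------|
| control        | 0.30    | 2.0     | 0.30    | 25      | 55      | 30     |
| pseudo-control | 0.32    | 2.2     | 0.34    | 25      | 60      | 45     |
| eczema         | 0.33    | 2.3     | 0.37    | 27.5    | 70      | 52     |
| psoriasis      | 0.35    | 2.4     | 0.40    | 30      | 90      | 60     |

Eczema sits between pseudo-control and psoriasis, matching its expected
cluster placement.  Subject-level jitter (τ2 SD 0.05 ns, depth SD 2.5 µm
snapped to the 5 µm grid, puncta SD 5, a2 SD 0.02) creates within-group
spread.  Each psoriasis subject draws a latent severity z ~ N(0, 1) that
shifts its lesional-site parameters along the disease direction
(+0.08 ns τ2, +8 µm SB depth, +10 puncta, +0.03 a2 per unit z) and
generates PASI = clip(round(12 + 6·(r·z + √(1−r²)·ε)), 1, 29) with
coupling r = 0.5 by default, so the measured PC1–PASI correlation has a
known target; LIS is generated analogously (mean 5, SD 2, weaker
coupling).  Depth targets for layer selection come from the stored
ground-truth metadata.

What the synthetic cohorts do **not** emulate: anatomical realism
(texture is statistical, not histological), depth-dependent scattering
and signal attenuation, motion artefacts, IRF and detector effects, age/
skin-type covariates, and any empirically calibrated effect magnitudes.
Passing tests therefore demonstrate that the pipeline recovers the
statistical structure it assumes — not that real psoriatic skin carries
effects of these sizes.

## Numerical choices and degenerate inputs

* Binning uses exact integer arithmetic; the n = 0 window is the
  identity and edge windows are clipped, not padded.
* Constant frames: entropy 0 (defined), Fourier ratio undefined
  (degenerate-spectrum error), standardization undefined
  (degenerate-feature error naming the column).
* Correlation requires n ≥ 3 and non-constant inputs.
* Frame statistics require ≥ 2 valid pixels; an all-masked frame is an
  empty-map error that excludes the site.
* Silhouette excludes singleton groups with a warning.
* All simulation is driven by `numpy` `SeedSequence` spawning, so every
  artefact is a pure function of (parameters, seed).

## Known limitations

* The delta-IRF assumption makes fitted τ1 optimistic relative to real
  instruments at short lifetimes.
* The Fourier-parameter annuli scale with frame size (fixed fraction of
  Nyquist); for fixed physical field of view this means the probed
  physical length scales change with pixel count, so ratios are
  comparable only within a fixed acquisition geometry.
* PC1 orientation needs either ≥ 2 groups or a designated feature; a
  fully unsupervised run leaves the sign arbitrary.
* The silhouette on PC1–PC2 understates separation when clusters are
  elongated along PC2.
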