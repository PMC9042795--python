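# Methods

This note documents the models and procedures granulekit implements, the
defaults it ships with and why, what the synthetic-data generator does and
does not emulate, and the numerical choices that were genuinely open.

## The measurement problem

RNP granules are mesoscale condensates of mRNA and RNA-binding proteins.
In fluorescence microscopy they appear as bright, near-diffraction-sized
spots whose population statistics — size distribution, shape, molecular
content, exchange kinetics, spatial organization — report on the physics
of their assembly (liquid-liquid phase separation, arrest, aging) and on
their transport. granulekit turns multi-channel image stacks and FRAP
recordings into those statistics, and ships a generator that produces all
of its input types with exact ground truth so each estimator's bias and
variance can be measured rather than assumed.

## Synthetic-microscopy generator

Granules are rendered as hard ellipsoids of the sampled diameter filled at
uniform density and then optionally convolved with a Gaussian PSF. The
hard-ellipsoid-then-blur decomposition keeps true size separate from
optics, so morphometrics can be validated with and without blur.
Per-voxel fill fractions come from 3× sub-voxel supersampling of the
ellipsoid indicator and are renormalized so each granule's integrated
signal equals `copies × unit_intensity` exactly before PSF and noise
(photon conservation). Noise is applied in physical order: PSF blur →
Poisson resampling → additive Gaussian read noise.

Defaults follow the study conditions the package targets: granule
diameters Gaussian with mean 400 nm and SD 129 nm (the in-vivo granule
population), truncated by rejection at twice the largest voxel extent
(sub-voxel spots are unmeasurable; real granules are ≳200 nm); intensity
populations dominated by 1–2 copy particles (weights 0.7/0.3 in the
calibration scenario); FRAP acquisitions with 3 pre-bleach frames, 0.35 s
frame interval and ~55 s of recovery. Copy counts can be fixed, drawn
from a categorical or zero-truncated Poisson law, or tied to volume at
constant internal concentration (`("constant_concentration", c_per_µm³)`)
— the regime in which RNA content grows with granule volume at unchanged
concentration, and the right fixture for testing segmentation, since
constant-copies granules have brightness density ∝ 1/d³.

Placement is uniform with an optional hard-core separation constraint,
by bounded rejection sampling (1000 attempts per granule; exhaustion
raises a "field too crowded" error). Coordinates are 0-based `(z, y, x)`
voxels; all ground truth is physical nm from the corner of voxel
(0, 0, 0). One root seed feeds deterministically derived, CRC-labelled
child streams per component, so stages re-run in isolation reproduce
bit-identically.

Not emulated: vectorial/anisotropic PSF physics, STED depletion effects,
ooplasmic flow or transport, spot motion, detector nonlinearity, spatially
structured background. Passing tests therefore demonstrate estimator
correctness under the stated image-formation model, not robustness to
every artifact of real acquisitions. The noise model and SNR of real
recordings are not constrained by the study this emulates; Poisson +
Gaussian read noise is a modeling choice and fully configurable.

## Segmentation

The Intermodes threshold uses the classical formulation: a 256-bin
equal-width histogram over [min, max] is smoothed with an iterated
3-point moving mean (zero-padded ends) until exactly two strict local
maxima remain; the threshold is the midpoint of the two mode bins,
mapped back to intensity units at the centre of the fractional bin.
Histograms that never become bimodal within 10,000 iterations raise an
error. Counts are first canonicalized by exact rational division by
their total, which makes the threshold exactly invariant to positive
scaling of the counts (a pure float pipeline can flip near-tied peak
comparisons between scaled inputs). Foreground is strictly
`intensity > threshold`, so ties fall to background and a constant image
thresholded at its own value is empty.

Labeling defaults to full connectivity (face+edge+vertex in 3D,
8-connectivity in 2D) because small blurred spots fragment under
face-only connectivity. No watershed splitting of touching granules is
attempted; in synthetic work the `min_separation` parameter controls
contact. Per-object measurements define volume as voxel count × voxel
volume, equivalent diameter as that of the equal-volume sphere (circle in
2D), centroids intensity-weighted, and `integrated = mean × n_voxels`
exactly.

## Morphometrics

Axis lengths are measured as the FWHM of the background-subtracted line
profile through the intensity-weighted centroid along each principal
axis of the second-moment tensor, with linear interpolation between
voxels; the aspect ratio is the major/minor FWHM ratio. FWHM was chosen
as the endpoint criterion because it is robust to background and is the
optics convention; the background is the median intensity of the 1-voxel
shell around the object's bounding box. A profile that never drops below
half maximum inside the field raises an "unbounded profile" error rather
than silently truncating.

The partition coefficient is the mean intensity inside the condensate
mask over the mean of the dilute phase, the complement of the mask
dilated by an exclusion halo (default 1 voxel, reported in the output):
blurred condensate edges otherwise contaminate the dilute estimate. The
volume–intensity relation reports the least-squares slope (± SE) of
integrated intensity/volume against volume, so "concentration does not
increase with volume" is a quantitative slope-consistent-with-zero
statement rather than a binary claim. Polygon-ROI integrated density
sums voxels whose centres fall inside the polygon under the even-odd
rule, per slice in 3D.

## FRAP

The recovery model is `FRAP(t) = I₀ + I₁·[1 − e^−(t−t_bleach)/τ]` fitted
by least squares over post-bleach frames, with `t_bleach` the timestamp
of the first post-bleach frame (the bleach event itself is not sampled)
and the pre-bleach plateau the mean of all pre-bleach frames. Derived
quantities: immobile fraction `(1 − I₀ − I₁)/(1 − I₀)`, half-time
`τ·ln 2`.

Normalization is the double-normalization scheme: background subtraction,
frame-wise division by the reference ROI (cancelling acquisition
bleaching exactly), then division by the pre-bleach mean so the plateau
sits at 1. On noiseless model traces this recovers the generating curve
to machine precision, which is what makes grid-wise parameter recovery a
meaningful test. Full dynamic-range scaling (pinning the first
post-bleach frame to 0 as well) is available as `full_scale=True`; it is
an affine reparametrization under which τ and the immobile fraction are
invariant (`I₀ → 0`, `I₁ → I₁/(1−I₀)`), so either convention yields the
same derived kinetics — but the default keeps fitted `(I₀, I₁)` on the
generating scale. Both anchors are carried in the trace so the choice is
transparent.

Fit initialization is deterministic and seed-free: `I₀` from the first
post-bleach value, `I₁` from the final value, `τ` from a linear scan for
the time the trace first reaches `I₀ + (1 − 1/e)·I₁`; non-convergence
triggers bounded τ-scaled restarts and finally an error carrying the
best residual. Whether a background ROI is subtracted is optional and
recorded; traces without a reference ROI fall back to single
normalization with a warning.

## Abundance calibration

smFISH spot intensities are fitted with a 1D Gaussian mixture by EM,
written here because the procedure's contract is specific: quantile-
spaced initial means, pooled SD, uniform weights; convergence at
relative log-likelihood change < 1e-8 or 1000 iterations with the
log-likelihood asserted non-decreasing every iteration; degenerate
components restart with ±10% jittered means from the seeded stream
(error after 10 restarts); the component count is chosen by BIC over
K ∈ {1..4} by default. The unit intensity — the signal of one mRNA — is
the mean of the largest-weight component, ties broken toward the smaller
mean; this encodes the prior that nurse-cell particles are predominantly
single transcripts. Copy number is intensity/unit (raw and rounded,
floored at 0); molar concentration is `copies/(N_A·V)` with per-granule
volumes when available, else the cohort mean (which was used is
recorded). The protein route fits ordinary least squares of intensity on
known concentration and inverts it; predictions outside the fitted range
are flagged as extrapolated.

## Colocalization

A reference object is observed-colocalized when its nearest target
centroid lies within the window (default 250 nm, the confocal resolution
limit; centroid distance, not overlap, because the window is a
resolution criterion). The null re-places only the target channel —
reference positions stay fixed — uniformly over the confinement mask (a
uniformly chosen foreground voxel plus sub-voxel jitter), with no
exclusion between randomized objects, R = 100 iterations by default.
The colocalization frequency is observed − null mean; the full null
vector, its SD, and a one-sided exceedance proportion are reported. In
crowded fields the chance term is large and the frequency underestimates
the true bound fraction — a documented property of the statistic. In the
sparse regime the null mean matches the Poisson void probability
`1 − exp(−λ·V_window)`, which the tests use as a closed-form calibration.

## Polarity

The AP statistic is the intensity-weighted centre of mass over the cell
mask minus the mask's unweighted (geometric) centre, along an explicitly
supplied AP axis — images carry no intrinsic polarity, so orientation is
a required input, posterior positive. Both the raw displacement (nm) and
the displacement normalized by the mask's AP bounding extent (range
[−0.5, +0.5]) are reported. Background is subtracted from the weights
with negatives clipped at 0. Group comparisons use the standard unpaired
two-tailed t-test as a thin reporting wrapper; exact zero-variance
separation is refused rather than reported as an infinite statistic.

## Problem sizes and tolerances

The test suite and the acceptance script run entirely on synthetic data
at desk scale, chosen to make each check statistically decisive: 50-sphere
3D fields (40×300×300 voxels at 100/50/50 nm), 100 FRAP traces at noise
SD 0.02, n = 5000 intensity populations, colocalization with up to 500
reference objects in 80×80 µm fields and R up to 500 null iterations,
4000-granule polarity fields. Noiseless model fits are required to
recover parameters to ≤1e-6 relative error; stochastic recoveries are
tested against closed-form expectations within explicit Monte-Carlo
standard-error bands (3 SE unless stated). For the independent-channel
colocalization check the comparison scale is the null SD itself (the
observed fraction is one draw from the null under independence), not the
null mean's SE.

## Known limitations

* Equivalence with the commercial segmenters used on real data (Imaris,
  Lightning) is not claimed — only with the stated Intermodes/threshold
  procedures.
* The aspect-ratio estimator reports apparent (PSF-convolved) shape; no
  deconvolution to "true" size is attempted. An anisotropic `psf_sigma`
  in the generator permits exploring depletion-power-like trends, but no
  quantitative target is claimed.
* FRAP fitting is single-exponential only; diffusion-reaction models,
  bleach-profile corrections and model selection are out of scope.
* The randomization null assumes targets can occupy any mask voxel
  independently; hard-core placement between randomized objects is not
  implemented (and was not used in the procedure this follows).
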