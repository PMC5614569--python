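# Methods

This note records the models, conventions, and numerical choices behind
`dsaflow`, and what the synthetic phantoms do and do not establish about
behavior on clinical data.

## Acquisition model

Frame times follow a multi-rate schedule: an ordered list of
(frame rate, duration) segments, by default (7.5 fps, 5 s), (4, 3),
(3, 2), (2, 2) — a 12-second base acquisition, optionally prolonged at
2 fps for slow venous opacification. Each segment is **half-open**
[start, start + duration): a frame lands exactly on a segment start,
never on its end. This convention is forced by the first segment —
7.5 fps × 5 s = 37.5 is not an integer — and yields 38 + 12 + 6 + 4 = 60
frames for the default schedule, with the last frame at 11.5 s. The true
vendor frame placement is not documented anywhere we know of; the
half-open rule avoids double-placing frames at segment joints.

Canonical frames hold positive contrast density: larger value = more
iodine, frame at t = 0 ≈ 0 everywhere. Readers expose `invert` (sources
that render contrast dark) and `subtract_baseline` (subtract frame 0 on
load, default on). Pixel indices are 0-based row-major; ROI polygons use
(x, y) pixel coordinates and are rasterized with matplotlib's point-in-
polygon test (boundary-inclusive via a tiny positive radius).

## Motion correction

Head motion during a cranial run is approximately rigid in projection, so
the transform family is rotation + translation — fewer parameters are
robust with few matches. Frames are normalized by their own peak before
SIFT detection; the difference-of-Gaussian contrast threshold is set very
low (`c_dog = 0.001`) because once contrast fills the vessels, the only
texture shared with the pre-contrast reference is the faint
subtraction-residual anatomy at a few percent of peak. Matches pass a
Lowe ratio test at 0.75 with cross-checking, then RANSAC with a 1-px
inlier tolerance (500 trials, fixed internal seed — the whole stage is
deterministic) fits the rigid transform mapping reference coordinates to
moving-frame coordinates. Resampling is bilinear with out-of-bounds
pixels set to 0.

Degenerate inputs degrade rather than fail:

- a frame with fewer than `min_matches` (default 8) ratio-test survivors
  gets the transform of the nearest **later** frame that registered
  (contrast-free early frames share the pose of the frames just after
  them), else identity — always with a warning;
- if the t = 0 reference itself is featureless (exact baseline
  subtraction produces an identically zero frame), the earliest
  feature-rich frame serves as a surrogate reference. Pre-bolus frames
  share the reference pose because motion accumulates over the 12-s run,
  so this preserves the reference geometry to first order.

On the motion phantom (≤ 5 px translation, ≤ 2° rotation, smooth random
pose path) the estimated transforms agree with the injected motion to
< 0.1 px mean displacement.

## Independent component decomposition

Frames are flattened to a (T × H·W) matrix and decomposed into exactly
three components; the component count is fixed by the three-phase
physiology (arterial / capillary / venous), not selected from data.

The decomposition is **spatial** ICA: the spatial maps are the
independent sources (one sample per pixel) and the time courses are the
paired mixing columns. Vascular territories overlap little in
projection, so their pixel supports are close to statistically
independent and strongly super-Gaussian — exactly ICA's working regime.
The alternative orientation (time courses as sources) fails on this
problem: bolus curves through successive compartments overlap heavily in
time and are far from independent, and in our experiments temporal ICA
recovered phantom courses only to |r| ≈ 0.8–0.95 where spatial ICA
exceeds 0.998.

Whitening is performed explicitly — center each frame over pixels,
project onto the top three principal directions, scale to unit variance —
and FastICA (scikit-learn, log-cosh contrast, parallel updates,
tol 1e-4, max 500 iterations, seeded) runs on the whitened coordinates
with its internal whitening disabled. The explicit step matters:
exactly rank-deficient input (noiseless synthetic data) sends sklearn's
built-in whitening into a numerically degenerate state, while a truncated
SVD with a singular-value floor degrades cleanly; input of rank < 3 is
flagged non-converged and warned about, never raised.

Sign ambiguity is resolved per component so the time course's maximum
exceeds |minimum| (a bolus passes in the positive direction); the map
flips with the course, leaving the reconstruction unchanged. Phases are
assigned by time of the course maximum — earliest arterial, middle
capillary, latest venous — with TTP ties broken by larger spatial-map
energy taking the earlier phase, then by component index (warned).

A two-peak detector (scipy `find_peaks`, peaks above 30% of maximum with
20% prominence) runs on the capillary TDC and warns when a second bump
suggests arterial leakage into the capillary component, the known failure
mode at severe stenosis where stagnant arterial flow mimics capillary
kinetics. No remedial unmixing is attempted.

## Segmentation and TDC extraction

Component maps are clipped at zero (only positive loading indicates
contrast arrival under the sign convention), histogrammed into 256
equal-width bins, and cut at the interior bin edge maximizing
between-class variance; ties take the lowest edge, and a constant clipped
map yields a degenerate (all-off, flagged) mask rather than an error.
The implementation is verified against exhaustive search over all
candidate edges on every random instance tested.

The TDC is the **mean** density over masked pixels per frame (not the
sum): FWHM is invariant to vertical scale either way, but the mean keeps
curves comparable across views and mask sizes. Densities come from the
registered original series, not from the ICA time course — the component
course is a whitened-space object, while the masked mean retains density
units and any mixture actually present in those pixels.

## Gamma-variate fitting and markers

Model: C(t) = baseline + K(t−t₀)^α e^{−(t−t₀)/β} for t > t₀, else
baseline; α, β > 0. This is the standard indicator-dilution form, and
TTP = t₀ + αβ and FWHM = β·w(α) follow analytically. w(α) solves
x^α e^{−x} = α^α e^{−α}/2 on either side of the mode, in log space;
w(3) ≈ 4.1312, hence the 5.0-s phantom blush uses β = 5/w(3) ≈ 1.2103.

Fitting is nonlinear least squares (scipy trust-region-reflective,
bounded) on the non-uniform grid with uniform weights — each frame is one
measurement regardless of local frame rate. Initialization scans t₀
candidates over [0, argmax time); at each, log-linearizing
ln(C − baseline) = ln K + α ln(t−t₀) − (t−t₀)/β gives (α, β, K) by
ordinary least squares, and the candidate with the smallest SSE seeds the
refinement. Baseline is a free parameter (it absorbs residual offsets in
baseline-subtracted data). Preconditions: ≥ 8 samples, a peak at least 3×
a robust noise floor (1.4826·median |successive differences| / √2) above
baseline, and an interior argmax; flat or monotone curves raise a fit
error with a diagnostic. r² < 0.8 warns. On exact curves sampled on the
default grid, parameters return within far less than 1%; with 5%-of-peak
Gaussian noise the median FWHM error over 100 seeds is ≈ 1%.

FWHM is computed on the **fitted analytic curve**, not raw samples — the
2-fps tail makes raw half-crossings coarse. Crossings are bracketed
around the mode and solved by scipy `brentq` to 1e-9 s; for very small α
the left crossing collapses numerically onto t₀ and is treated as the
arrival time itself.

TTP offers two estimators: `argmax` (timestamp of the maximum sample,
ties to the earliest with a warning) mirrors the manual clinical
workflow and is the CCT default; `fitted` (t₀ + αβ) serves phantom
validation. CCT = TTP(parietal vein) − TTP(cavernous ICA) from manual
ROIs on a lateral series; an AP series warns but computes. Marker
correlations are pairwise Pearson r with raw two-sided p-values flagged
at p < 0.05, no multiplicity correction, and pairs with < 3 complete
cases or zero variance reported as missing. No strength labels
("moderate"/"strong") are attached to r values.

## Synthetic phantom

Each compartment is a unit-coordinate geometry (polyline vessel tree with
width, or elliptical blush) rasterized onto the frame — phantoms are
resolution-independent — times a gamma-variate course. Compartments add
(projection physics: densities along a ray sum), which is what makes
overlapping anatomy complicate TDCs in the first place. Per-pixel
lognormal amplitude jitter (σ = 0.25 in the standard phantoms) gives the
Otsu step realistic non-binary maps. A static "subtraction-residual"
background (smoothed noise at 4% of peak) plays the role of the
imperfectly-cancelled anatomy that real registration locks onto. Noise
is Gaussian with σ a stated fraction of the noiseless global peak
(optionally Poisson); a contrast-free corner of the stack reproduces the
nominal σ within 10%. Motion, when scheduled, warps each frame by the
inverse of its pose so that a perfect registration restores the
reference geometry. Everything is deterministic given the seed.

Standard configurations:

- `easy` — disjoint compartments; TTPs 2 / 4.5 / 7 s; arterial kinetics
  (t₀ 0.8, α 4, β 0.3), capillary (α 3, β 5/w(3), TTP 4.5 s, FWHM
  exactly 5.0 s), venous (t₀ 4, α 3, β 1); peak densities 1.0 / 0.6 /
  0.8 — the blush is fainter than vessels, as in projection angiography.
- `overlap` — the blush shifted under the arterial tree so ~20% of its
  pixels overlap.
- `severe_stenosis_like` — stagnant arterial flow (t₀ 1, α 3, β 1.2)
  whose course correlates ≥ 0.99 with the blush, plus the overlap
  geometry. The pipeline degrades gracefully here (aMTT biased high by
  ~5–10%, no crash); notably the spatial decomposition still separates
  the compartments, so neither the two-peak warning nor a low-r² flag
  fires on this phantom — the warning machinery is exercised by direct
  unit tests instead.
- `motion` — `easy` plus a smooth random rigid pose path, ≤ 5 px and
  ≤ 2°, identity at frame 0.

Biplane views are two independent geometry layouts sharing kinetics —
sufficient to test aMTT_AP vs aMTT_Lat without 3-D ray casting.

**What the phantoms do not show.** Real subtraction runs have structured
artifacts (swallowing, table motion, bone edges), vessel-overlap patterns
from true 3-D anatomy, autoregulation-dependent kinetics, and detector
physics none of which the generator models. Passing phantom tests
establishes internal correctness of each stage and of their composition
under known conditions — not clinical accuracy. The aMTT's agreement
with MR-perfusion transit times on patients is outside what desk-scale
synthetic data can address.

## Problem sizes and validation conditions

The validation suite and `scripts/acceptance.py` use 128×128 frames on
the full 60-frame default schedule. Monte-Carlo studies use 100 noise
realizations at σ = 5% of peak; these run on motionless phantoms with
the registration stage bypassed (it is exercised separately by the
motion phantom, where it recovers injected poses to < 0.1 px mean and
reduces the aMTT error relative to the unregistered series). Measured
outcomes on these conditions: noiseless aMTT error < 0.01 s against the
5.00-s ground truth; median noisy aMTT error ≈ 0.01 s; worst matched
course correlation ≥ 0.998 noiseless, median ≥ 0.997 at 5% noise;
capillary-mask Dice ≈ 0.99; CCT within one local frame interval (0.25 s)
of the 4.87-s ground-truth difference.

## Known limitations

- Rigid registration only; no deformable or gantry-motion model.
- Component count fixed at three; a fourth physiologic phase (e.g.,
  delayed collateral filling) would fold into the nearest component.
- Phase labelling assumes distinct TTPs; pathologies that invert venous
  and capillary timing would be mislabelled (the TDC and fit are still
  reported for inspection).
- The two-peak warning detects, but does not correct, arterial leakage
  into the capillary component.
- No morphological cleanup of masks — isolated supra-threshold pixels
  stay in the mask, which is faithful to the thresholding step but can
  admit noise pixels at very low SNR.
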