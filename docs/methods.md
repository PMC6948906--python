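# Methods

## Kinetic model

Tissue contrast concentration follows the extended Tofts model

    Ct(t) = vp Cp(t - d) + Ktrans * Int_0^t Cp(u - d) exp(-kep (t - u)) du

with Ktrans (1/min) the plasma-to-interstitium transfer constant, kep
(1/min) the efflux rate, vp the fractional plasma volume, and d a bolus lag
between arterial input and tissue enhancement.  ve = Ktrans/kep is reported
as the derived ratio rather than fitted independently: the extended model
has exactly three free kinetic parameters, and an independently fitted ve
would be redundant.  The convolution is evaluated by trapezoidal quadrature
directly on the acquisition grid (7.6 s frames by default); against the
analytic closed form for an exponential input the discrete operator is
accurate to ~0.2 % of the curve maximum at this sampling, so no upsampling
is performed by default.

The model assumes a linear relationship between signal enhancement and
concentration (valid for the low-dose 0.1 mmol/kg protocol) and bidirectional
exchange with a well-mixed interstitium; it ignores water-exchange effects
and intravoxel dispersion.

## Arterial input function

Whole-blood concentration after a compact bolus is modelled by the
Weinmann biexponential, Cb(t) = scale * dose * (a1 e^(-m1 t') + a2 e^(-m2 t'))
with t' = t - onset, using the literature constants a1 = 3.99, a2 = 4.78
kg/L, m1 = 0.144, m2 = 0.0111 /min (shipped in `data/aif_weinmann.json`,
overridable).  Plasma concentration is Cp = (1 - HCT) Cb with HCT 0.45.
Because signal units are arbitrary, the population curve is calibrated to
measured arterial curves: the frame-wise mean of the measured curves
determines a single least-squares amplitude factor and the bolus arrival.
Arrival is detected per curve as the first frame exceeding baseline mean +
3 SD — a detection that can only be late, by up to one frame — and is then
refined within the preceding frame interval to the onset minimising the
calibration residual.  Concentrations are therefore *relative*: fitted
Ktrans and vp are comparable within a protocol but not absolute, which is
why absolute kinetic magnitudes are not an evaluation surface here.

## Lag selection and fitting

The data cannot resolve sub-frame lags, so d is restricted to whole-frame
shifts (default grid 0–5 frames) and chosen by exhaustive search: for each
candidate lag a bounded trust-region least-squares problem in (Ktrans, kep,
vp) is solved (bounds [0, 5] /min, [0, 50] /min, [0, 1]; start (0.05, 1.0,
0.1); three jittered restarts from a fixed seed on non-convergence) and the
lag with the smallest residual sum of squares wins.  All-zero curves
short-circuit to zero parameters with a `zero-signal` flag; voxels that
fail outright are flagged, never silently zeroed.

**Identifiability.**  With a biexponential AIF there is no first-pass peak,
so the vascular term vp·Cp and the leakage term are nearly collinear
(parameter correlations ≈ 0.9–0.95).  The Cramér–Rao floor for Ktrans at
5 %-of-peak curve noise, 7.6 s sampling and typical adnexal values
(Ktrans 0.05, kep 2.0, vp 0.15) is a relative SD of ~80 %, and for
kep ≳ 8 /min the exponential kernel decays within a frame interval and
(Ktrans, kep) degenerate into their ratio ve.  Individual noisy fits
therefore scatter widely — occasionally to the bounds — although the
estimator is median-unbiased (the median recovered Ktrans over replicates
stays within a few percent of truth) and noiseless recovery is exact to
<0.01 %.  The bounds are deliberately left wide: tightening them to
physiological ranges would clip genuinely fast-exchange lesions and bias
noiseless fits.  vp, by contrast, is estimated with ~2–6 % precision and is
the better-behaved quantitative marker under this AIF.  In practice this
imprecision is mitigated by averaging Ktrans over multi-voxel hot-spot
ROIs, which is exactly what `roi_analysis` implements.

## Semi-quantitative descriptors

SI0 is the mean of the pre-injection frames; SI_max the maximum raw
post-injection signal; TTP the time from injection to that frame (the 10 s
pre-injection lead therefore does not bias it); SI_rel, WIR and WOR follow
their standard definitions; iAUC60 integrates the baseline-subtracted
signal over the 60 s after injection with interpolated window edges.
SI_peak is not given a formula in the study this package models, but its
reported values sit ~10 % below SI_max; it is implemented as the maximum of
the 3-point moving-average-smoothed curve — a noise-robust peak — and
documented as an interpretation.  SI_end is the final dynamic frame
(380 s), not a delayed post-contrast acquisition.  Flat curves yield
TTP = WIR = WOR = 0 with a flag; a zero baseline makes SI_rel undefined and
raises.

## Hot-spot ROIs

Reader-placed "few-pixel" ROIs on the most-enhancing part of the lesion are
automated as a greedy search: every lesion voxel seeds a candidate region
grown by repeatedly absorbing the highest-valued available face-neighbour
until the target size (default 9 voxels), and the best-mean candidate is
kept; removing it and repeating yields the default three disjoint ROIs in
descending order of mean Ktrans.  On smooth or plateau-like fields — the
intended regime — this matches exhaustive search over all connected
regions, verified by brute force on 200-voxel masks; on adversarial fields
greedy growth is a heuristic.  Per-lesion values are the unweighted mean
over the ROI means (the source study does not state its aggregation rule);
descriptors are recomputed from each ROI's mean signal curve, keeping
kinetic and semi-quantitative outputs internally consistent.

## Statistics

Per parameter: one-way ANOVA across benign/borderline/malignant; pairwise
benign-vs-malignant and benign-vs-(borderline+malignant) by two-tailed
t-test when both groups pass Shapiro–Wilk at alpha 0.05, otherwise
Mann–Whitney U (groups with n < 2 are reported absent; all-tied samples get
p = 1).  No multiple-testing correction is applied, matching the analysis
being reproduced.  ROC AUC uses the rank (Mann–Whitney) statistic with tie
correction, counting borderline with malignant as positive; its p-value
comes from the tie-corrected normal approximation.  The "optimal" cutoff
maximises Youden's J over midpoints between consecutive distinct values
(plus sentinels), ties resolved toward the lower cutoff, with a
greater-than-cutoff-is-positive orientation (every discriminative
parameter is higher in malignancy).  Confusion-matrix percentages are
rounded to one decimal in reports; undefined predictive values (empty
predicted class) are reported absent rather than zero.

## Synthetic cohort

The generator emulates the reference study's statistical structure, not its
images: 27/3/19 lesions in 43 patients with six bilateral (malignant)
patients; per-class Ktrans, kep, vp and age drawn from zero-truncated
normals with the published group means/SDs (a moment-matched lognormal
family is available by flag — note the malignant kep SD of 11.81 at mean
5.38 cannot be matched by any zero-truncated normal, so the printed moments
parameterise the pre-truncation normal); bolus lag uniform on {0, 1, 2}
frames.  Curves are built through the forward model and converted to
signal as SI = SI0 (1 + g·Ct), where the single gain g (≈ 19) collapses
relaxivity and T1 weighting and is set so the benign class-mean template
enhances ~97 % over baseline, anchoring descriptor magnitudes to the
published benign group mean.  The same gain scales the simulated arterial
curves, so AIF calibration recovers it and fitted parameters come out on
the true scale.  Noise is additive Gaussian at 0.2 % of the noiseless peak
signal by default: each lesion curve represents the mean over ~27 hot-spot
ROI voxels of data with voxel-level baseline SNR ≈ 20, and ROI averaging
suppresses voxel noise by ≈ √27.  Everything is drawn from one generator
seeded by the cohort seed, so outputs are bit-reproducible given (spec,
seed).

What the generator does *not* model: pelvic anatomy, motion, Rician
magnitude-noise bias, partial-volume mixtures, or any correlation structure
beyond the class-conditional marginals.  Consequences worth knowing:

* Only the published per-class moments constrain the simulation — the real
  cohort's joint distribution is unknown — so cohort-level AUCs and cutoffs
  match the study qualitatively, not numerically.  In particular, the
  Ktrans class moments (benign 0.03 ± 0.02, borderline 0.03 ± 0.01,
  malignant 0.05 ± 0.01) imply a *population* ground-truth AUC of ≈ 0.75
  for benign vs borderline/malignant; single 49-lesion draws scatter around
  it with SE ≈ 0.07, and estimation noise pushes the fitted-Ktrans AUC
  lower still.  A high observed Ktrans AUC is therefore not reproducible
  from the published moments alone.
* Because descriptor differences are induced through the kinetics, the
  faster exchange of malignant lesions also produces earlier peaks and a
  *class-dependent* wash-out rate, whereas the study observed no
  significant TTP/WOR differences; these two descriptors should be read as
  "not designed to discriminate" rather than "guaranteed null".

Passing tests on this cohort therefore demonstrate correctness of the
pipeline and qualitative transfer of the published group structure, not
clinical performance.

## Numerical and design choices

* Signal-to-concentration: relative enhancement (SI − SI0)/SI0 with the
  proportionality constant absorbed into the calibrated AIF scale.
* Trapezoidal quadrature weights are precomputed per grid; the exponential
  kernel matrix is rebuilt per candidate kep (the dominant fit cost).
* Bolus-arrival threshold 3 SD above baseline: conventional; a flat or
  zero-variance curve with no excursion falls back to the configured
  injection time with a warning.
* The ten measured arterial curves are combined by frame-wise mean before
  calibration (per-patient fits would add a dispersion model the data
  cannot support).
* Protocol defaults (7.6 s × 50 frames, 10 s lead, 0.1 mmol/kg) and class
  counts are the study's; ROI size default 9 voxels ("a few pixels");
  simulation sizes in the test suite (tens of voxels per phantom, ≤ 100
  fit replicates) are chosen so the full suite completes in well under a
  minute of fitting time while keeping Monte-Carlo standard errors below
  the asserted tolerances.

## Known limitations

* No T1 mapping or nonlinear signal-to-concentration conversion; results
  are in relative concentration units.
* No alternative kinetic models (2CXM, four-parameter models,
  reference-region) and no motion/registration handling.
* The greedy hot-spot search is exact only on well-separated/smooth
  enhancement fields; its optimality is verified on such instances.
* Ktrans point estimates from a single low-SNR curve are unreliable under
  a first-pass-free population AIF (see Identifiability above); use ROI
  aggregation or report vp alongside.
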