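# adnexal-dce

Quantitative and semi-quantitative analysis of dynamic contrast-enhanced MRI
(DCE-MRI) for differentiating benign from malignant adnexal masses.

Adnexal (ovarian/tubal) lesions that remain indeterminate on ultrasound and
conventional MRI are often triaged with DCE-MRI: a T1-weighted series is
acquired every few seconds while a gadolinium bolus passes through the
lesion, and the enhancement kinetics of the solid component carry
information about tumour neo-angiogenesis.  This package implements the two
standard analysis routes on a common, tested code base:

* **Pharmacokinetic (quantitative) analysis.**  The extended Tofts
  two-compartment model

  &nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>t</sub>(*t*) = *v*<sub>p</sub>
  *C*<sub>p</sub>(*t* − δ) + *K*<sup>trans</sup> ∫₀<sup>*t*</sup>
  *C*<sub>p</sub>(τ − δ) e<sup>−*k*<sub>ep</sub>(*t* − τ)</sup> dτ

  is fitted per curve (or per voxel) by bounded nonlinear least squares,
  with the bolus lag δ selected by exhaustive search over whole-frame
  shifts.  The arterial plasma input *C*<sub>p</sub> = (1 − HCT)
  *C*<sub>b</sub> comes from a biexponential population model of blood
  concentration (Weinmann constants, HCT 0.45), calibrated to measured
  arterial curves by a least-squares amplitude factor and a bolus-arrival
  shift.  Outputs: K<sup>trans</sup>, k<sub>ep</sub>, v<sub>e</sub> =
  K<sup>trans</sup>/k<sub>ep</sub>, v<sub>p</sub>, δ, and fit quality.

* **Semi-quantitative analysis.**  Model-free descriptors of the
  signal-time curve: SI<sub>0</sub>, SI<sub>max</sub>, SI<sub>peak</sub>,
  SI<sub>end</sub>, relative enhancement SI<sub>rel</sub> =
  (SI<sub>max</sub> − SI<sub>0</sub>)/SI<sub>0</sub> × 100, time-to-peak
  (TTP), wash-in rate (SI<sub>max</sub> − SI<sub>0</sub>)/TTP, wash-out
  rate (SI<sub>max</sub> − SI<sub>end</sub>)/(SI<sub>max</sub> −
  SI<sub>0</sub>), and the initial area under the curve over 60 s
  (iAUC<sub>60</sub>).

On top sit hot-spot ROI selection on K<sup>trans</sup> maps (three small
connected regions of maximal mean K<sup>trans</sup> per lesion), three-group
statistics (ANOVA; Shapiro–Wilk-gated t-test / Mann–Whitney U), and ROC
analysis with Youden-optimal cutoffs treating borderline tumours as
positive together with malignant ones.  A synthetic cohort generator
reproduces the reference study's structure — 49 lesions in 43 patients
(27 benign / 3 borderline / 19 malignant, six bilateral patients), with
per-class kinetic distributions anchored to the published group means — so
the entire pipeline runs end-to-end with known ground truth and no data
download.

## Worked example

```bash
adnexal-dce run-all --seed 0 --outdir results/demo
```

generates the default synthetic cohort, calibrates the population AIF to
ten simulated arterial curves, fits every lesion, computes the descriptors
and writes the result tables.  It prints:

```
study complete: results/demo
best parameter by AUC: si_peak (AUC=0.818)
```

`results/demo/diagnostic_performance.csv` then contains one row per
evaluated parameter (excerpt, seed 0):

```
parameter   auc  p_auc  cutoff  accuracy  sensitivity  specificity
   ktrans 0.534  0.688   0.034      57.1         63.6         51.9
       vp 0.798  0.000   0.175      79.6         68.2         88.9
   si_max 0.816  0.000 249.967      79.6         77.3         81.5
   si_rel 0.813  0.000 147.113      77.6         77.3         77.8
      ttp 0.318  0.029 275.000      55.1          4.5         96.3
   iauc60 0.801  0.000 9161.836     81.6         63.6         96.3
```

Reading: on this synthetic draw the strong discriminators are the
enhancement-amplitude parameters (SI<sub>max</sub>/SI<sub>rel</sub>/
iAUC<sub>60</sub>, AUC ≈ 0.80–0.82) and the plasma fraction v<sub>p</sub>,
while TTP carries almost no usable signal — the qualitative pattern the
method is designed to expose.  An `auc` is the probability that a randomly
chosen borderline/malignant lesion scores above a randomly chosen benign
one; `cutoff` is the Youden-optimal threshold, and the percent columns are
the confusion-matrix metrics at that threshold.
`group_comparison.csv` holds the per-class means/SDs with ANOVA and
pairwise p-values, and `lesions.csv` the per-lesion fits, descriptors and
ground truth.  Note that per-lesion K<sup>trans</sup> estimates are
intrinsically imprecise under a first-pass-free biexponential AIF (see
`docs/methods.md`), so its single-cohort AUC is unstable even though the
noiseless fit is exact.

The same stages are available separately (`simulate`, `fit`, `describe`,
`evaluate`) and as library calls; voxelwise fitting
(`pk_model.fit_voxelwise`), hot-spot ROI search
(`roi_analysis.find_hotspots`) and NIfTI/PNG map export (`io`) operate on
4-D series such as those from `synthetic_cohort.generate_phantom_volume`.

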