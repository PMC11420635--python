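# dceauc

Model-free DCE-MRI perfusion mapping (AUC60) and cutpoint-based survival
analysis for radiotherapy cohorts.

Poorly perfused head-and-neck tumors tend to be hypoxic, radio-resistant and
metastatic, so pretreatment perfusion is a candidate prognostic biomarker.
`dceauc` implements the full quantitative chain from raw dynamic
contrast-enhanced MR signal to survival stratification, for researchers who
want a tested, reproducible reference implementation of this workflow — plus
a synthetic phantom/cohort generator with exact ground truth, so every stage
can be validated without any patient data.

## What it computes

1. **T1 mapping.** Two pre-contrast spoiled gradient echo (SPGR) scans at
   flip angles of 6° and 16° give the native T1 per voxel through the exact
   two-point inversion of S = M0 sin α (1−E1)/(1−E1 cos α), E1 = exp(−TR/T1).
2. **Concentration.** Dynamic SPGR signal is inverted frame by frame to
   R1(t), and C(t) = (R1(t) − R1,pre)/r1 with relaxivity
   r1 = 4.5 L·mmol⁻¹·s⁻¹ (gadobutrol at 3 T).
3. **AUC60.** The arterial input function peak is detected in an artery ROI;
   the area under each tumor voxel's concentration curve is integrated over
   60 s starting one frame (≈5 s) before that peak. Voxels outside the
   per-frame 2nd/98th concentration percentiles at any time point, and
   voxels with negative AUC60, are removed; the tumor is summarised by
   AUC60_median and AUC60_p95 (mmol·s/L) over retained voxels.
4. **Survival.** Continuous markers are dichotomised at the maximally
   selected standardized log-rank cutpoint; Kaplan–Meier curves, log-rank
   tests with a Bonferroni threshold, Cox proportional-hazards models with
   backward elimination, and GVIF multicollinearity screening follow, for
   local control / disease control / overall survival endpoints.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

The synthetic end-to-end run generates a DCE phantom (SPGR forward model,
gamma-variate arterial input, heterogeneous tumor curves) and an 89-patient
survival cohort with a known protective perfusion effect, then runs every
stage:

```bash
$ dceauc -v run-all --seed 5 --out demo
dceauc.pipeline INFO phantom: grid=(24, 24, 12) frames=24 tumor_voxels=520
dceauc.pipeline INFO perfusion: window=[24.75, 84.75]s retained=0.958 median=16.496 p95=24.213
dceauc.pipeline INFO cohort: input=89 analysis=89
done: AUC60median=16.50 mmol.s/L, learned cutoff=32.82 -> demo/report.json
```

Reading `demo/report.json`:

- the AIF peaks at frame 6 (29.7 s), so the 60 s window is anchored one
  frame earlier at 24.75 s and ends at 84.75 s;
- the recovered tumor `AUC60median` of 16.50 mmol·s/L equals the phantom's
  ground truth (16.496137…) to ~1e-15 relative — the noiseless inversion
  chain is exact — while the percentile filter retains 95.8% of the 520
  tumor voxels (on heterogeneous tumors it always trims the extreme ~4%);
- the cutpoint scan over 72 admissible splits learns a cutoff of
  32.82 mmol·s/L against a true change-point of 31.7;
- in the overall-survival analysis the high-perfusion group has hazard
  ratio 0.19 (95% CI 0.08–0.48, log-rank p = 6.8e-05): high AUC60 is
  protective, the effect structure the cohort was simulated with.

The same stages are available piecewise (`dceauc simulate`, `t1map`,
`concentration`, `auc60`, `survival`) on NIfTI volumes, tumor/artery masks
and clinical CSV tables you supply, and programmatically:

```python
from dceauc import PhantomSpec, generate_dce_phantom, VFAT1Mapper, \
    SignalToConcentration, AUC60Extractor

series, pair, truth = generate_dce_phantom(PhantomSpec(seed=5))
t1 = VFAT1Mapper().fit(pair).t1_map_
conc = SignalToConcentration(flip_deg=16.0, tr_s=0.005,
                             baseline_frames=range(4)).transform(series, t1)
ex = AUC60Extractor().fit(conc, truth.tumor_mask,
                          conc.conc[truth.aif_mask].mean(axis=0))
print(ex.summary_.auc60_median, ex.summary_.auc60_p95)
```

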