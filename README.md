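# gaitscreen

Automatic locomotor diagnostics for walking quadrupeds from 2-D
pose-estimation trajectories: quality-filtered stride extraction, Fourier
coordination analysis, and probabilistic inference of subject
characteristics, with an out-of-sample screen for developmental delay.

## The problem

Locomotion is a highly variable behavior shaped by the animal's mass,
size, age and sex. A screening tool that wants to say "this individual
moves abnormally" must first account for all of that. `gaitscreen`
implements an inverse-modeling strategy for this problem, developed for
neonate piglets walking past a lateral camera: instead of modeling
kinematics as the output of subject characteristics, it asks what subject
the kinematics look like. A probabilistic reference model is trained on
normal-birth-weight (NBW) animals; out-of-sample low-birth-weight (LBW)
individuals whose **age** is consistently inferred *below* their actual
age are flagged as developmentally delayed.

## The pipeline

1. **Landmark I/O** (`landmarks`) — reads DeepLabCut-dialect CSVs
   (scorer / bodyparts / coords headers) of 17 landmarks (head, back line,
   fore- and hindlimb chains), calibrates pixels to meters, normalizes the
   y axis and optionally mirrors leftward walks.
2. **Stride segmentation** (`segmentation`) — extracts usable episodes
   (likelihood, noise and bone-length filters), detects footfalls with a
   kinematic contact proxy, cuts strides from forelimb touchdown to the
   next ipsilateral touchdown, and checks cyclicality by Procrustes
   superimposition of the start and end landmark configurations.
3. **Kinematics** (`kinematics`) — six joint-angle profiles (shoulder,
   elbow, carpal, hip, stifle, tarsal) plus the total forelimb reference
   angle; nine gait variables (stride distance / frequency / speed, duty
   factors, clearances, head angle, hindlimb phase) with dynamic-similarity
   dimensionless scaling: `d/h`, `f*sqrt(h/g)`, `v/sqrt(g*h)`.
4. **FCAS** (`fourier`) — Fourier Series decomposition (8 harmonics) with
   Fourier Coefficient Affine Superimposition: per-joint mean and
   amplitude (eROM) form the 12 **dynamic posture** variables; after mean
   removal, amplitude normalization and phase alignment on the forelimb
   reference, the residual 96 coefficients (6 joints x 8 harmonics x
   Re/Im) are **coordination** sensu stricto. Phase-preserving averaging
   avoids the destructive-interference artifact of pointwise means.
5. **Multivariate** (`multivariate`) — PCA of the coordination space
   (first 12 components used) and the body-size score (first PC of
   skeleton segment lengths).
6. **Subject model** (`model`) — for an outcome theta in {mass, size, age}:

   ```
   theta ~ v1*alpha + vs*beta_s + sum_G vg*beta_g + sum_P vp*beta_p + sum_C vc*beta_c + v1*eps
   ```

   36 free parameters (intercept, sex, 9 gait, 12 posture, 12 coordination
   slopes, residual scale), Student-t likelihood with Gamma-distributed
   degrees of freedom, Normal slope priors, Half-Cauchy residual prior;
   sampled by a blocked Gibbs sampler on the Student-t scale-mixture
   representation. `SubjectModel.fit()` returns a results object with
   `summary()`, R-hat/ESS diagnostics and per-stride posterior-predictive
   `predict()`.
7. **Screening** (`screening`) — per-subject verdicts: a subject is
   *consistently underestimated* when more than 75% of pooled predictive
   samples fall below the actual value and the majority of its strides
   have negative mean Delta (Delta = predicted - actual).
8. **Synthetic data** (`synthetic`) — a full generator for subjects,
   stride features, harmonic profiles and planar-walker landmark
   recordings with known ground truth, so the entire pipeline is testable
   without any recordings.

## Worked example

```python
from gaitscreen import generate_cohort, SubjectModel, split_dataset
from gaitscreen.screening import verdict_table

cohort = generate_cohort(seed=1)          # 58 piglets, first 10 life hours
train, validation, test = split_dataset(cohort.strides, seed=1)
results = SubjectModel.from_dataframe(train, outcome="age").fit(
    draws=1000, tune=500, seed=1)
print(results.summary().loc[["alpha", "b_clearance_fore", "epsilon", "nu"]])
print(verdict_table(results.predict(test, seed=2)))
```

prints (abridged):

```
                    mean      sd  hdi_2.5%  hdi_97.5%   rhat       ess
alpha             -0.005   0.046    -0.093      0.088  1.001  3492.503
b_clearance_fore   0.228   0.048     0.134      0.325  1.000  3543.201
epsilon            0.732   0.037     0.661      0.808  1.002  2468.093
nu                28.618  14.786     9.294     66.083  1.001  2746.564

subject_id  actual  strides  underestimation_count  underestimation_ratio  pred_mean_delta  pred_sd  consistent_underestimation
      s009    3.73        6                      1                   0.28             1.57     2.77                       False
      s031    3.59        8                      1                   0.30             1.36     2.59                       False
      s036    5.86        7                      7                   0.93            -3.46     2.42                        True
      s039    6.50        8                      8                   0.77            -1.87     2.51                        True
      s055    5.83        6                      5                   0.79            -2.10     2.64                        True
```

Slopes are on standardized predictor / standardized outcome scale; forelimb
clearance carries age signal in this cohort (`b_clearance_fore` well away
from zero). The verdict table reads like a screening report: the three
older LBW subjects carry the generator's injected 5 h developmental delay
and are consistently underestimated (ratio > 0.75, stride majority,
mean Delta of -2 to -3.5 h at ~2.5 h predictive sd); the two young LBW
subjects walk age-appropriately and are, if anything, overestimated.

The same workflow is available from the shell:

```bash
gaitscreen pipeline --out runs/demo --seed 1 --outcome age
gaitscreen simulate --out runs/sim --seed 2 --landmarks   # DLC-dialect CSVs
gaitscreen segment runs/sim/landmarks/*.csv --out runs/sim/strides.csv --scale 0.001
```

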