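# crtopt

Model-guided selection of the left-ventricular (LV) pacing site for cardiac
resynchronization therapy (CRT).

About 30% of heart-failure patients implanted with a biventricular (BiV)
pacemaker do not improve. Both the decision to implant and the placement of
the LV lead are plausible levers. `crtopt` implements a hybrid
modelling + machine-learning workflow for both questions:

1. **Simulate ventricular activation.** On a biventricular tetrahedral mesh
   with rule-based fibers, an anisotropic eikonal model computes activation
   times `T(x)` solving `|∇T|_M = 1`, with conduction velocity `v_f·√κ`
   along the fiber and a 4:1 along:across velocity ratio. Baseline left
   bundle branch block (LBBB) is driven by a fractal right-bundle Purkinje
   tree (3 mm/ms, left bundle absent); BiV pacing by point stimuli at the RV
   and LV sites. Scar does not conduct; fibrosis conductivity is halved. A
   pseudo-12-lead ECG gives the QRS duration, and the global conductivity
   multiplier `κ ∈ [0.2, 1.5]` can be fitted to a target QRSd.
2. **Score the probability of CRT response.** Dyssynchrony indices (TAT95,
   AD_RVLV, AD_STLV, scar/late-activation distances, RV–LV delay, …) are
   joined with clinical covariates (LVEF, BMI, EDD). A logistic-regression
   classifier — preprocessing with standardization and an |r| > 0.85
   correlation filter, leave-one-out cross-validation with in-fold feature
   selection — outputs an *ML-score*, the estimated response probability;
   scores above the 0.51 cutoff predict a responder.
3. **Optimize the pacing site.** Over the candidate LV epicardial surface
   (septal AHA segments and scar excluded), Gaussian-process Bayesian
   optimization maximizes the ML-score: evaluate the 12 eligible AHA segment
   centers, then iterate `fit GP → argmax L(μ,σ) = μ + 2σ → simulate that
   site` until two iterations propose the same node. The result is an
   ML-score map over the LV surface, the optimal site (ML-PS), and its
   distance D_PS to a reference site. The same machinery minimizes TAT95
   (TAT-PS) and locates the latest-activated site (LAT-PS).

No clinical data are required: a synthetic-cohort module generates anatomies,
scar patterns, covariates and ground-truth response labels, at a
statistical tier (features drawn from distributions, for classifier tests)
and a physics tier (features simulated end to end).

## Worked example

```sh
cat > config.yaml <<'YAML'
geometry:
  spacing: 6.0        # mesh node spacing, mm (coarse demo)
cohort:
  n: 12
  seed: 2
YAML
crtopt --config config.yaml --out-dir run synth
crtopt --config config.yaml --out-dir run features
crtopt --config config.yaml --out-dir run train
crtopt --config config.yaml --out-dir run optimize --patient-id 3
```

which prints, for the demo patient:

```
wrote 12 patient models to run
feature table: 12 patients x 27 columns
ML-PS node 64, max ML-score 0.690, D_PS 19.6 mm
```

Reading: the best LV pacing site found for this patient carries an ML-score
of 0.690 — above the 0.51 cutoff, so the model predicts a positive response
when pacing there — and lies 19.6 mm from the reference (lateral-wall) lead
position. `run/patient_003_optimization.yaml` records the full iteration
trace (19 model evaluations to convergence), and
`run/patient_003_aha_summary.csv` summarizes the predicted score map per AHA
segment, e.g.

```
aha_segment,mean,max,count
1,0.587,0.666,11
4,0.052,0.095,17
6,0.408,0.586,17
```

— anterior/anterolateral sites score high for this patient, inferior sites
low. On a 12-patient toy cohort the LOO-CV report is noise (the demo prints
its AUC for completeness); meaningful cross-validation needs a realistic
cohort size.

Everything the CLI does is also available as a library
(`crtopt.anatomy`, `.purkinje`, `.eikonal`, `.ecg`, `.features`,
`.classifier`, `.optimizer`, `.cohort`, `.io`).

## Scope

The geometry is a parametric two-ellipsoid idealization, the ECG forward
model an infinite-homogeneous-medium pseudo-ECG, and the action potential a
fixed depolarization template; image segmentation, personalized torso lead
fields, ionic-model integration, repolarization and electromechanics are out
of scope. See `docs/methods.md` for the model details, numerical choices and
limitations.
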