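# Methods

This note documents the models, parameters, numerical choices and known
limitations of `crtopt`. Units are mm, ms and mm/ms throughout.

## Synthetic anatomy

The biventricular geometry is an idealized stand-in for image-derived
patient meshes: the LV is a thick-walled truncated prolate ellipsoid (cavity
semi-axes 22/22/40 mm, wall 10 mm), the RV a thinner crescent shell (wall
4 mm) attached on the +x side, both truncated by a basal plane at z = 10 mm.
Nodes are placed on a jittered regular grid (default spacing 3 mm; the
jitter, 5% of the spacing, breaks Delaunay degeneracies and is drawn from
the seeded generator, so meshes are bit-reproducible), tetrahedralized with
Delaunay, and filtered to the implicit solid. Boundary facets are tagged
LV-endocardium / RV-endocardium / epicardium / base by the closest implicit
surface; elements are tagged LV free wall, septum (LV wall inside the RV
epicardial ellipsoid) or RV free wall.

**Fibers.** The rule-based field rotates the helix angle linearly across the
wall, +60° at the endocardium to −60° at the epicardium (the common
convention). The transmural coordinate is solved per element by bisection on
the interpolated family of ellipsoids; fibers lie in the local wall-tangent
plane. Near the apex, where the long axis is normal to the wall, the
longitudinal reference falls back to a fixed in-plane direction.

**AHA parcellation.** Standard 17-segment rule: basal and mid thirds of the
long axis in six 60° sectors, apical third in four 90° sectors, apex cap
(17) below the cavity tip. The circumferential origin is the direction of
the RV free-wall centroid, so segment ids are invariant under rigid motion
of the mesh. Septal segments are {2, 3, 8, 9, 14}; the thirds are measured
from the cavity apex to the base.

**Tissue labels.** Scar and fibrosis are applied at whole-AHA-segment
granularity and transmurally, mirroring segment-level expert annotation;
scar takes precedence on overlap.

## Conduction system

A fractal binary tree grows from the His node over the RV endocardial
surface (tangent-plane projection at each step): initial branch 20 mm,
length decay 0.8, branching angle 30° ± 5° seeded jitter, 7 generations
(128 terminals), chosen to cover the RV endocardium of the default anatomy.
Only the right bundle exists — total LBBB is the modeled baseline. Each
terminal couples to its nearest RV endocardial node (PMJ) with no junction
delay; there is no retrograde coupling. Tree conduction velocity is 3 mm/ms,
so a terminal's activation time is exactly its root-path length over 3.

## Activation model

The anisotropic eikonal equation `|∇T|_M = 1` is solved on the tetrahedral
mesh by a label-correcting fast-iterative scheme: per-element metrics are
reduced to unit speed by mapping vertices through the metric square root,
and each local update takes the minimum of plane-wave face updates (with
characteristic-foot and causality checks), two-point edge updates and
one-point vertex updates. Convergence tolerance is 1e-6 ms; ties break by
node index.

Speeds: `v_along = v_f·√κ` and `v_across = v_along/ρ`, with ρ = 4 (the 4:1
along:across velocity ratio), further scaled by `√0.5` in fibrosis (velocity
scales as the square root of conductivity under the monodomain reduction —
this mapping is a single policy in `ConductionModel`). Scar elements are
removed from the update graph: nodes connected only to scar remain at the
unreached sentinel (+inf in memory, −1 in exported files). The default
`v_f = 0.65 mm/ms` was calibrated once so the scar-free default anatomy
paced by the right-bundle tree yields an LBBB-range QRS duration
(150–190 ms) with κ = 1, then frozen.

**Accuracy.** On structured slabs the solver reproduces closed-form travel
times and the 4:1 speed ratio to well under 1%. Like all first-order local
solvers, it overestimates in oblique cross-fiber directions when the
anisotropy is strong (up to ~10% at 4:1 on coarse meshes — a stencil
visibility effect, not a convergence failure). The graph-oracle test
therefore compares against densified-graph Dijkstra at mild anisotropy,
where both routes are accurate; strong anisotropy is validated against the
closed forms. The systematic overestimate affects absolute activation times
far from sources but largely cancels in the BiV-vs-LBBB contrasts the
classifier consumes.

Geodesic distances (site-to-scar, site-to-late-activation, D_PS) reuse the
same solver with unit isotropic speed over all tissue including scar — they
are geometric distances, not activation times. D_PS is therefore a
through-wall geodesic; for epicardial site pairs it can slightly undercut a
strictly surface-bound path.

## ECG and conductivity personalization

Electrode potentials follow the infinite-homogeneous-medium pseudo-ECG:
`φ_e = Σ_k V_k ∇V_m,k · ∇(1/r_k)` over elements, with element gradients
from linear shape functions and a fixed 9-electrode torso-scale layout.
Personalized torso/lung lead fields are deliberately not modeled; amplitudes
are in arbitrary units and only timing quantities are used downstream. The
action potential is a fixed template — rest −84 mV, 1 ms linear upstroke to
+26 mV, depolarized plateau — because only depolarization shapes the QRS;
repolarization is absent by design, so traces carry no T-wave.

Limb and augmented leads use the standard combinations (II − I − III = 0
holds to machine precision by construction); precordial leads reference the
Wilson terminal. Sampling step 1 ms.

**QRS delineation.** Onset/offset are the first/last sustained excursion of
the across-lead RMS derivative above 2% of its global maximum, with a 5 ms
debounce; the window covers all 12 leads, matching a "maximum QRSd across
leads" convention. Threshold and debounce are configuration entries.

**Conductivity fit.** QRSd(κ) is monotone non-increasing (all speeds scale
by √κ), so the fit brackets the target on κ ∈ [0.2, 1.5] and runs a Brent
root-find (κ tolerance 2e-3, QRSd tolerance 2 ms; QRSd is quantized at the
1 ms sampling step). An unattainable target returns the nearest bound with a
`boundary_hit` flag rather than raising.

## Dyssynchrony indices

All statistics are volume-weighted over non-scar elements; an element is
reached when all four vertices are. TAT95 is the volume percentile of
activation time at 95% (denominator: reached non-scar volume, so TAT at
p=100 is the latest reached time even if isolated nodes are unreached).
AD_RVLV = max LV time − max RV time, with the septum counted as LV (the
per-ventricle "total activation time" is the maximum; a percentile variant
would be a one-line change). AD_STLV = (volume-mean LV-free-wall time −
volume-mean septal time) / TAT, with TAT at 100% (not TAT95) as the
denominator. The late-activation (LAT) region is the top 10% of LV
epicardial activation times in baseline — the fraction is a configuration
entry since no quantified convention exists. RV–LV distance is Euclidean
between the pacing sites; the scar and LAT distances are isotropic-eikonal
geodesics. A scar-free model reports the scar distance as missing; the
classifier imputes the training-set maximum ("as far from scar as
possible"), falling back to a 120 mm ceiling when the whole cohort is
scar-free — never silently zero.

## Response classifier

Non-categorical columns are standardized (population SD); zero-variance
columns are dropped with a logged warning; of every pair with |Pearson r| >
0.85 the later column in the documented order is dropped. The classifier is
plain maximum-likelihood logistic regression (no hyperparameter search); a
weak ridge (C = 100) is substituted only when separation drives
coefficients beyond ±50, with a warning. The default seven-feature model
uses LVEF, BMI, EDD, scar distance, baseline TAT95, and AD_RVLV at baseline
and under BiV pacing; the decision cutoff is 0.51 (the score-map coloring
threshold is separately 0.5 — both appear in the configuration because both
conventions are in use).

Leave-one-out cross-validation refits *everything* — normalization,
correlation filter, feature selection, coefficients — on each fold's n−1
rows; the three selectable selection methods are univariate ranking
(F-score), the l1-regularization path (features ranked by the penalty at
which they first activate), and recursive feature elimination. These three
are this package's concrete choices; they are exposed by name. Held-out
scores from LOO on null data sit slightly *below* chance (the known
class-imbalance-flip artifact: removing a row tilts the training prevalence
against its own class), so chance-level behavior is asserted on
Monte-Carlo means over permutations, not single draws.

## Pacing-site optimization

Candidate sites are LV epicardial nodes outside septal segments and scar
(scar excludes both its own nodes and any whole segment containing scar).
The initial design evaluates the candidate node nearest each eligible
segment's epicardial centroid — 12 sites on a scar-free model, fewer with
scar. The surrogate is a Gaussian process with constant × RBF kernel on 3D
Euclidean coordinates (length scale bounded to [5, 100] mm, hyperparameters
by marginal likelihood, noise floor 1e-6); Euclidean rather than
surface-geodesic distances are a deliberate simplification — the candidate
shell is smooth at these length scales, and a geodesic kernel is a noted
extension. The acquisition is the upper confidence bound L(μ,σ) = μ + 2σ,
maximized over candidate nodes (not continuously).

Convergence follows the repeated-proposal rule — two successive iterations
proposing the same node — with one safeguard added by this package: when
the proposal repeats, the posterior-mean argmax is evaluated first if it has
not been simulated yet, preventing convergence on an overconfident
surrogate. An optional distance tolerance (e.g. < 2 mm) can replace exact
node identity. Each iteration adds at most one expensive simulation;
re-proposals of evaluated sites are served from cache. A failed evaluation
(e.g. a rejected site) scores 0 with a log entry, steering the search away
without aborting. The score map is the clipped GP posterior mean over
candidates.

Because the stopping rule certifies optimality only up to the GP's
between-node interpolation error, agreement with exhaustive search is exact
in most cases and within ~1e-3 on the unit score scale otherwise; optima
pinned to the candidate-surface boundary are the hardest case. TAT95
minimization reuses the loop with acquisition μ − 2σ.

## Synthetic cohorts

Ground truth is a logistic model over the seven classifier features with
coefficients on the standardized scale (defaults: LVEF +0.5, BMI −0.7, EDD
−0.5, scar distance +0.8, TAT95 +0.6, AD_RVLV(LBBB) +0.5, AD_RVLV(BiV)
−0.6) and an intercept solved by bisection to hit the target prevalence
(default 0.4). Covariate scales — LVEF 26 ± 6%, BMI 29 ± 5, EDD 66 ± 9 mm,
truncated — emulate a dilated-cardiomyopathy CRT cohort and are plausible
defaults only, never test targets. The statistical tier draws the simulated
features directly from distributions (TAT95 151 ± 20 ms etc.) and supports
exact parameter-recovery tests; the physics tier samples geometry (±8%
scale), non-septal scar/fibrosis segments, and an LV lead segment placed in
the lateral wall for 88% of patients, then simulates every feature. What
the physics tier does *not* emulate: realistic scar geometry (sub-segment,
non-transmural), patient-specific fiber disarray, torso variability, or any
correlation structure between covariates and anatomy — so green end-to-end
tests demonstrate internal consistency of the pipeline, not clinical
validity.

## Problem sizes and runtimes

Defaults were chosen so every check runs on one CPU: validation slabs at
1–2 mm spacing (≈5k nodes), anatomy tests at 4 mm (≈3.7k nodes, 18k tets),
end-to-end runs at 5–6 mm. A full single-patient workflow — baseline LBBB,
BiV from all eligible segment centers, Bayesian optimization to
convergence — takes seconds to a few minutes depending on resolution. The
test suite finishes in about a minute; `scripts/acceptance.py` in a few
seconds.

## Known limitations

* Idealized geometry; no coronary-vein constraints on LV lead placement, no
  atria, no endocardial/His/multisite pacing, VV delay fixed at 0 by default.
* First-order eikonal accuracy degrades in oblique directions at strong
  anisotropy (see above).
* The pseudo-ECG ignores torso inhomogeneity; QRSd trends survive, absolute
  morphology does not.
* Scar is segment-granular and transmural; fibrosis is a uniform
  conductivity factor.
* The cohort generator's labels come from its own logistic ground truth;
  classifier performance on it says nothing about real patients.
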