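"""Synthetic patient cohorts.

Two generation tiers share one ground-truth logistic response model over the
seven classifier features:

* the *statistical tier* draws the features directly from plausible
  distributions (fast; isolates the statistical machinery and supports
  parameter-recovery tests with a known coefficient vector), and
* the *physics tier* samples per-patient geometry, scar burden and pacing
  sites, runs the full simulation pipeline, and joins the simulated indices
  with the clinical covariates.

Default covariate scales (LVEF 26 +- 6 %, BMI 29 +- 5, EDD 66 +- 9 mm)
emulate a dilated-cardiomyopathy CRT cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anatomy import (
    SEPTAL_SEGMENTS,
    SURF_RV_ENDO,
    GeometryParams,
    assign_fibers,
    generate_biventricular_mesh,
    label_tissue,
    parcellate_aha,
)
from .classifier import DEFAULT_FEATURES
from .ecg import compute_ecg
from .eikonal import ConductionModel, simulate_biv, simulate_lbbb
from .features import extract_features
from .purkinje import generate_purkinje_tree

log = logging.getLogger(__name__)

LATERAL_SEGMENTS = (5, 6, 11, 12, 16)

#: feature scales for the statistical tier: (mean, sd, low, high)
FEATURE_SCALES = {
    "lvef": (26.0, 6.0, 10.0, 45.0),
    "bmi": (29.0, 5.0, 16.0, 45.0),
    "edd": (66.0, 9.0, 45.0, 95.0),
    "scar_lvps": (40.0, 25.0, 0.0, 120.0),
    "tat95_LBBB": (151.0, 20.0, 90.0, 220.0),
    "ad_rvlv_LBBB": (60.0, 20.0, 0.0, 130.0),
    "ad_rvlv_BiV": (10.0, 15.0, -40.0, 60.0),
}

#: ground-truth coefficients on the standardized feature scale
DEFAULT_BETA = {
    "lvef": 0.5,
    "bmi": -0.7,
    "edd": -0.5,
    "scar_lvps": 0.8,
    "tat95_LBBB": 0.6,
    "ad_rvlv_LBBB": 0.5,
    "ad_rvlv_BiV": -0.6,
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n: int = 60
    seed: int = 0
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    prevalence: float = 0.4
    scar_probability: float = 0.5
    fibrosis_probability: float = 0.3
    lateral_lead_fraction: float = 0.88
    feature_scales: dict = field(default_factory=lambda: dict(FEATURE_SCALES))

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort needs at least two patients")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _draw_labels(rng, X_std: pd.DataFrame, beta: dict, prevalence: float):
    """Bernoulli labels from the ground-truth logistic model.

    The intercept is solved by bisection so the mean response probability on
    the drawn covariates equals the target prevalence.
    """
    z = sum(beta[k] * X_std[k].values for k in beta)
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(z + mid)))).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(-(z + b0)))
    return rng.random(len(p)) < p, b0, z + b0


def statistical_dataset(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Statistical-tier dataset: features drawn directly from distributions.

    Returns (feature table, labels, truth) where ``truth`` records the
    standardized-scale coefficients, intercept and latent linear predictor
    actually used — the targets for parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(20):
        cols = {}
        for name, (mean, sd, lo, hi) in spec.feature_scales.items():
            cols[name] = _truncated_normal(rng, mean, sd, lo, hi, spec.n)
        df = pd.DataFrame(cols)
        X_std = (df - df.mean()) / df.std(ddof=0)
        y, b0, z = _draw_labels(rng, X_std, spec.beta, spec.prevalence)
        if 0 < y.sum() < spec.n:
            return df, y.astype(int), {
                "beta": dict(spec.beta), "intercept": b0, "linear_predictor": z,
            }
        log.warning("single-class draw (attempt %d); resampling", attempt)
    raise RuntimeError("could not draw a two-class cohort")


@dataclass
class SyntheticPatient:
    patient_id: int
    geometry: GeometryParams
    scar_segments: tuple[int, ...]
    fibrosis_segments: tuple[int, ...]
    lv_lead_segment: int
    lvef: float
    bmi: float
    edd: float
    seed: int


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    patients: list[SyntheticPatient]

    def covariates(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"patient_id": p.patient_id, "lvef": p.lvef, "bmi": p.bmi,
              "edd": p.edd} for p in self.patients]
        ).set_index("patient_id")


def sample_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Physics-tier cohort: geometry, scar burden and lead positions.

    The LV lead segment is drawn preferentially from the lateral wall
    (default 88% of patients), emulating transvenous lead placement; scar
    and fibrosis are whole AHA segments outside the septum.
    """
    rng = np.random.default_rng(spec.seed)
    sc = spec.feature_scales
    nonseptal = sorted(set(range(1, 17)) - SEPTAL_SEGMENTS)
    patients = []
    for i in range(spec.n):
        scale = rng.uniform(0.92, 1.08)
        geom = GeometryParams(
            lv_endo_radius=22.0 * scale,
            lv_endo_length=40.0 * scale,
            lv_wall=10.0 * scale,
        )
        scar: tuple[int, ...] = ()
        fib: tuple[int, ...] = ()
        if rng.random() < spec.scar_probability:
            k = int(1 + rng.poisson(1.0))
            scar = tuple(int(s) for s in
                         sorted(rng.choice(nonseptal, size=min(k, 4), replace=False)))
        if rng.random() < spec.fibrosis_probability:
            fib = (int(rng.choice(nonseptal)),)
        if rng.random() < spec.lateral_lead_fraction:
            pool = [s for s in LATERAL_SEGMENTS if s not in scar]
        else:
            pool = [s for s in nonseptal if s not in scar and s not in LATERAL_SEGMENTS]
        pool = pool or [s for s in nonseptal if s not in scar] or list(nonseptal)
        lead = int(rng.choice(pool))
        patients.append(SyntheticPatient(
            patient_id=i,
            geometry=geom,
            scar_segments=scar,
            fibrosis_segments=fib,
            lv_lead_segment=lead,
            lvef=float(_truncated_normal(rng, *sc["lvef"], 1)[0]),
            bmi=float(_truncated_normal(rng, *sc["bmi"], 1)[0]),
            edd=float(_truncated_normal(rng, *sc["edd"], 1)[0]),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return SyntheticCohort(spec=spec, patients=patients)


@dataclass(frozen=True)
class SimSettings:
    """Problem sizes for the physics tier (coarse by default)."""

    spacing: float = 5.0
    conduction: ConductionModel = field(default_factory=ConductionModel)
    compute_ecg: bool = True


def simulate_patient(patient: SyntheticPatient, sim: SimSettings) -> dict:
    """Run the full physics pipeline for one patient at the reference sites."""
    geom = replace(patient.geometry, spacing=sim.spacing)
    mesh = generate_biventricular_mesh(geom, seed=patient.seed)
    fibers = assign_fibers(mesh)
    parc = parcellate_aha(mesh)
    labels = label_tissue(mesh, parc, patient.scar_segments, patient.fibrosis_segments)
    tree = generate_purkinje_tree(mesh, seed=patient.seed)

    lbbb = simulate_lbbb(mesh, fibers, sim.conduction, tree, labels)
    rv_nodes = mesh.surface_nodes(SURF_RV_ENDO)
    rv_site = mesh.nodes[rv_nodes[np.argmin(mesh.nodes[rv_nodes][:, 2])]]
    lv_site = parc.epi_centroids[patient.lv_lead_segment]
    biv = simulate_biv(mesh, fibers, sim.conduction, rv_site, lv_site, labels)

    lbbb_ecg = compute_ecg(mesh, lbbb) if sim.compute_ecg else None
    biv_ecg = compute_ecg(mesh, biv) if sim.compute_ecg else None
    feats = extract_features(
        lbbb, biv, lbbb_ecg, biv_ecg, mesh, labels, parc, rv_site, lv_site
    )
    return feats.to_row()


def make_dataset(
    cohort: SyntheticCohort, sim: SimSettings | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Physics-tier dataset: one row per patient at the reference sites.

    Per-patient simulation failures drop the row with a log entry.  Labels
    are drawn from the ground-truth logistic model applied to the seven
    classifier features of the *simulated* table.
    """
    sim = sim or SimSettings()
    rows, ids = [], []
    for p in cohort.patients:
        try:
            row = simulate_patient(p, sim)
        except Exception as exc:  # noqa: BLE001 — contract: drop and log
            log.warning("patient %d dropped: %s", p.patient_id, exc)
            continue
        row.update({"lvef": p.lvef, "bmi": p.bmi, "edd": p.edd})
        rows.append(row)
        ids.append(p.patient_id)
    if not rows:
        raise RuntimeError("all patient simulations failed")
    df = pd.DataFrame(rows, index=ids)

    spec = cohort.spec
    rng = np.random.default_rng(spec.seed + 1)
    from .classifier import SCAR_DISTANCE_CEILING, impute_missing

    sub = impute_missing(  # scar-free patients: farthest-from-scar imputation
        df[list(DEFAULT_FEATURES)], fallbacks={"scar_lvps": SCAR_DISTANCE_CEILING}
    )
    sd = sub.std(ddof=0).replace(0.0, 1.0)
    X_std = (sub - sub.mean()) / sd
    for _ in range(20):
        y, _, _ = _draw_labels(rng, X_std, spec.beta, spec.prevalence)
        if 0 < y.sum() < len(y):
            break
        log.warning("single-class label draw; resampling")
    return df, y.astype(int)
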