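"""Bayesian optimization of the LV pacing site on the epicardial surface.

The search space is the set of LV epicardial mesh nodes outside septal AHA
segments and outside scar.  A Gaussian-process surrogate (RBF kernel on 3D
coordinates) is fitted to the ML-scores observed so far; the next site is
the node maximizing the upper-confidence acquisition L(mu, sigma) = mu +
2*sigma.  The loop starts from the eligible AHA segment centers and stops
when two successive iterations propose the same node (or after ``max_iter``
iterations, flagged unconverged).  The same machinery minimizes TAT95 for
the alternative activation-time-based strategy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .anatomy import (
    SEPTAL_SEGMENTS,
    AHAParcellation,
    BiventricularMesh,
    TissueLabelMap,
)
from .eikonal import ActivationMap, isotropic_distance_field

log = logging.getLogger(__name__)


@dataclass
class CandidateSurface:
    """Eligible LV epicardial pacing nodes."""

    node_ids: np.ndarray          # mesh node indices
    coords: np.ndarray            # (K, 3) mm
    segments: np.ndarray          # AHA segment id per node
    mesh: BiventricularMesh

    def index_of(self, node_id: int) -> int:
        pos = np.searchsorted(self.node_ids, node_id)
        if pos >= len(self.node_ids) or self.node_ids[pos] != node_id:
            raise ValueError(f"node {node_id} is not on the candidate surface")
        return int(pos)


def candidate_surface(
    mesh: BiventricularMesh,
    parcellation: AHAParcellation,
    labels: TissueLabelMap | None = None,
) -> CandidateSurface:
    """LV epicardium minus septal segments minus scar."""
    ids, segs = [], []
    scar_nodes: set[int] = set()
    scar_segments: set[int] = set()
    if labels is not None and labels.scar_mask.any():
        scar_nodes = set(np.unique(mesh.tets[labels.scar_mask]).tolist())
        scar_segments = set(
            np.unique(parcellation.element_segment[labels.scar_mask]).tolist()
        )
    for n, s in parcellation.node_segment.items():
        if s in SEPTAL_SEGMENTS or s in scar_segments or n in scar_nodes:
            continue
        ids.append(n)
        segs.append(s)
    if not ids:
        raise ValueError("no eligible pacing surface")
    order = np.argsort(ids)
    return CandidateSurface(
        node_ids=np.asarray(ids, dtype=np.int64)[order],
        coords=mesh.nodes[np.asarray(ids, dtype=np.int64)[order]],
        segments=np.asarray(segs, dtype=np.int64)[order],
        mesh=mesh,
    )


def initial_design(
    surface: CandidateSurface, parcellation: AHAParcellation | None = None
) -> list[int]:
    """One site per eligible segment: the node nearest the segment center.

    Segment membership is carried by the surface itself; ``parcellation`` is
    accepted for interface symmetry and not otherwise needed.
    """
    sites = []
    for seg in np.unique(surface.segments):
        mask = surface.segments == seg
        center = surface.coords[mask].mean(axis=0)
        d = np.linalg.norm(surface.coords[mask] - center, axis=1)
        sites.append(int(surface.node_ids[mask][np.argmin(d)]))
    return sites


class GPSurrogate:
    """Gaussian-process regression of scores over surface coordinates."""

    def __init__(
        self,
        length_scale: float = 20.0,
        length_scale_bounds: tuple[float, float] = (5.0, 100.0),
        noise_variance: float = 1e-6,
        seed: int = 0,
        optimize_hyperparams: bool = True,
    ):
        self.noise_variance = noise_variance
        if not optimize_hyperparams:
            length_scale_bounds = "fixed"
        kernel = ConstantKernel(1.0, "fixed" if not optimize_hyperparams else (1e-4, 1e3)) * RBF(
            length_scale=length_scale, length_scale_bounds=length_scale_bounds
        )
        self._gpr = GaussianProcessRegressor(
            kernel=kernel,
            alpha=noise_variance,
            normalize_y=True,
            n_restarts_optimizer=2,
            random_state=seed,
        )
        self.X: np.ndarray | None = None
        self.y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPSurrogate":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < 2:
            raise ValueError("GP surrogate needs at least two training points")
        if np.std(y) == 0:
            # degenerate constant-target case: marginal-likelihood optimization
            # is ill-posed; pin the kernel instead
            self._gpr.optimizer = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gpr.fit(X, y)
        self.X, self.y = X, y
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and standard deviation at coordinates ``X``."""
        mu, sd = self._gpr.predict(np.atleast_2d(X), return_std=True)
        return mu, sd


def gp_fit(X, y, **kwargs) -> GPSurrogate:
    """Fit the GP surrogate to observed (coordinates, score) pairs."""
    return GPSurrogate(**kwargs).fit(X, y)


def acquisition(surrogate: GPSurrogate, coords, coef: float = 2.0) -> float:
    """Upper-confidence acquisition L(mu, sigma) = mu + coef * sigma."""
    mu, sd = surrogate.predict(np.atleast_2d(coords))
    return float(mu[0] + coef * sd[0])


@dataclass
class ScoreMap:
    """GP-predicted ML-score over the candidate surface."""

    node_ids: np.ndarray
    values: np.ndarray            # clipped to [0, 1]
    positive: np.ndarray          # values > map threshold
    threshold: float = 0.5


@dataclass
class OptimizationResult:
    best_node: int
    best_coords: np.ndarray
    best_score: float
    trace: list[tuple[int, float]]        # evaluated (node, score)
    converged: bool
    positive_response: bool | None        # max score vs classifier cutoff
    d_ps: float | None = None             # mm to a reference site, if given
    n_evaluations: int = 0


def _bayes_opt(
    surface: CandidateSurface,
    evaluator,
    maximize: bool,
    max_iter: int,
    seed: int,
    acq_coef: float = 2.0,
    noise_variance: float = 1e-6,
    site_tol_mm: float = 0.0,
) -> tuple[list[tuple[int, float]], bool, GPSurrogate]:
    """Shared BO loop; returns (trace, converged, fitted surrogate)."""
    sign = 1.0 if maximize else -1.0
    cache: dict[int, float] = {}

    def safe_eval(node: int) -> float:
        if node in cache:
            return cache[node]
        try:
            val = float(evaluator(node))
        except Exception as exc:  # noqa: BLE001 — site failures must not abort
            log.warning("evaluation failed at node %d: %s; scoring 0", node, exc)
            val = 0.0
        cache[node] = val
        return val

    design = initial_design(surface)
    trace = [(n, safe_eval(n)) for n in design]

    converged = False
    prev_proposal: int | None = None
    surrogate = None
    for _ in range(max_iter):
        X = surface.mesh.nodes[[n for n, _ in trace]]
        y = np.array([sign * s for _, s in trace])
        surrogate = GPSurrogate(noise_variance=noise_variance, seed=seed).fit(X, y)
        mu, sd = surrogate.predict(surface.coords)
        proposal = int(surface.node_ids[np.argmax(mu + acq_coef * sd)])
        same = proposal == prev_proposal
        if not same and site_tol_mm > 0 and prev_proposal is not None:
            d = np.linalg.norm(
                surface.mesh.nodes[proposal] - surface.mesh.nodes[prev_proposal]
            )
            same = d < site_tol_mm
        if same:
            # before declaring convergence, exploit the posterior mean: if
            # its argmax has not been simulated yet, spend the iteration
            # there instead of stopping on a possibly overconfident GP
            exploit = int(surface.node_ids[np.argmax(mu)])
            if exploit not in cache:
                trace.append((exploit, safe_eval(exploit)))
                prev_proposal = exploit
                continue
            converged = True
            break
        if proposal not in cache:
            trace.append((proposal, safe_eval(proposal)))
        prev_proposal = proposal
    if surrogate is None:
        X = surface.mesh.nodes[[n for n, _ in trace]]
        y = np.array([sign * s for _, s in trace])
        surrogate = GPSurrogate(noise_variance=noise_variance, seed=seed).fit(X, y)
    return trace, converged, surrogate


def optimize_pacing_site(
    surface: CandidateSurface,
    evaluator,
    max_iter: int = 30,
    seed: int = 0,
    cutoff: float = 0.51,
    map_threshold: float = 0.5,
    reference_site=None,
    site_tol_mm: float = 0.0,
) -> tuple[OptimizationResult, ScoreMap]:
    """Maximize the ML-score over the candidate surface.

    ``evaluator(node_id) -> ML-score`` runs the full pipeline (BiV
    simulation, feature extraction, classifier) at one LV site; failures at
    a site score 0 and are logged, steering the search elsewhere.
    """
    trace, converged, surrogate = _bayes_opt(
        surface, evaluator, maximize=True, max_iter=max_iter, seed=seed,
        site_tol_mm=site_tol_mm,
    )
    best_node, best_score = max(trace, key=lambda t: (t[1], -t[0]))
    mu, _ = surrogate.predict(surface.coords)
    values = np.clip(mu, 0.0, 1.0)
    score_map = ScoreMap(
        node_ids=surface.node_ids.copy(),
        values=values,
        positive=values > map_threshold,
        threshold=map_threshold,
    )
    d = None
    if reference_site is not None:
        d = d_ps(surface, reference_site, surface.mesh.nodes[best_node])
    result = OptimizationResult(
        best_node=int(best_node),
        best_coords=surface.mesh.nodes[best_node].copy(),
        best_score=float(best_score),
        trace=trace,
        converged=converged,
        positive_response=best_score > cutoff,
        d_ps=d,
        n_evaluations=len(trace),
    )
    return result, score_map


def optimize_tat(
    surface: CandidateSurface,
    evaluator_tat,
    max_iter: int = 30,
    seed: int = 0,
    site_tol_mm: float = 0.0,
) -> OptimizationResult:
    """Minimize TAT95 over the candidate surface (acquisition mu − 2*sigma)."""
    trace, converged, _ = _bayes_opt(
        surface, evaluator_tat, maximize=False, max_iter=max_iter, seed=seed,
        site_tol_mm=site_tol_mm,
    )
    best_node, best_val = min(trace, key=lambda t: (t[1], t[0]))
    return OptimizationResult(
        best_node=int(best_node),
        best_coords=surface.mesh.nodes[best_node].copy(),
        best_score=float(best_val),
        trace=trace,
        converged=converged,
        positive_response=None,
        n_evaluations=len(trace),
    )


def lat_site(lbbb_map: ActivationMap, surface: CandidateSurface) -> int:
    """Candidate node with the latest baseline activation (LAT-PS)."""
    t = lbbb_map.times[surface.node_ids]
    fin = np.isfinite(t)
    if not fin.any():
        raise ValueError("baseline map unreached on the candidate surface")
    t = np.where(fin, t, -np.inf)
    # ties break to the lowest node index; node_ids are sorted and argmax
    # returns the first maximal entry
    return int(surface.node_ids[np.argmax(t)])


def d_ps(surface: CandidateSurface, site_a, site_b) -> float:
    """Geodesic distance (mm) between two epicardial sites.

    Computed with the unit-speed isotropic eikonal solve through the
    myocardial wall, the same convention as the other model distances.
    """
    mesh = surface.mesh
    a = mesh.nearest_node(site_a)
    b = mesh.nearest_node(site_b)
    if a == b:
        return 0.0
    field_vals = isotropic_distance_field(mesh, np.array([b]))
    return float(field_vals[a])
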