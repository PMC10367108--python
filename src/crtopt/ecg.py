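"""Pseudo-12-lead ECG synthesis, QRS delineation, and conductivity fitting.

The forward model is an infinite-homogeneous-medium pseudo-ECG: each
electrode potential is the volume sum of element dipoles, phi_e(t) =
sum_k V_k grad(Vm_k(t)) . grad(1/r_k), where Vm is a fixed template action
potential shifted by the local activation time.  Torso and lung
inhomogeneities are deliberately not modeled; QRS duration and gross
morphology trends are preserved.  Only depolarization is represented in the
template — repolarization does not shape the QRS, which is the quantity
fitted against clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .anatomy import BiventricularMesh, FiberField, TissueLabelMap
from .eikonal import ActivationMap, ConductionModel, simulate_biv, simulate_lbbb

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class APTemplate:
    """Sampled transmembrane action-potential waveform (mV)."""

    samples: np.ndarray
    dt: float
    upstroke_index: int

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) * self.dt

    def at(self, t: np.ndarray) -> np.ndarray:
        """Waveform value at times ``t`` (ms) relative to local activation."""
        return np.interp(
            t, np.arange(len(self.samples)) * self.dt, self.samples,
            left=self.samples[0], right=self.samples[-1],
        )


def default_ap_template(
    dt: float = 0.1,
    rest_mv: float = -84.0,
    peak_mv: float = 26.0,
    upstroke_ms: float = 1.0,
    plateau_ms: float = 40.0,
) -> APTemplate:
    """Resting plateau, 1 ms monotone upstroke, depolarized plateau."""
    pre = int(round(5.0 / dt))
    up = int(round(upstroke_ms / dt))
    post = int(round(plateau_ms / dt))
    samples = np.concatenate([
        np.full(pre, rest_mv),
        np.linspace(rest_mv, peak_mv, up + 1),
        np.full(post, peak_mv),
    ])
    return APTemplate(samples=samples, dt=dt, upstroke_index=pre)


@dataclass
class ElectrodeSet:
    """Nine body-surface electrodes on a parametric shell around the heart."""

    positions: dict[str, np.ndarray]

    def __post_init__(self):
        required = {"RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6"}
        missing = required - set(self.positions)
        if missing:
            raise ValueError(f"missing electrodes: {sorted(missing)}")


def default_electrodes() -> ElectrodeSet:
    """Plausible torso-scale electrode layout (mm, heart near the origin).

    The chest (anterior) direction is -y and the patient's left is -x in the
    anatomic frame of the synthetic mesh (the RV sits at +x, anterior-right).
    """
    return ElectrodeSet(positions={
        "RA": np.array([140.0, 60.0, 150.0]),
        "LA": np.array([-140.0, 60.0, 150.0]),
        "LL": np.array([-100.0, 60.0, -350.0]),
        "V1": np.array([60.0, -90.0, 30.0]),
        "V2": np.array([20.0, -100.0, 20.0]),
        "V3": np.array([-20.0, -105.0, 0.0]),
        "V4": np.array([-60.0, -100.0, -20.0]),
        "V5": np.array([-95.0, -75.0, -25.0]),
        "V6": np.array([-115.0, -40.0, -30.0]),
    })


@dataclass
class ECG12:
    """Twelve named lead traces on a common time base."""

    time: np.ndarray              # (T,) ms
    leads: dict[str, np.ndarray]  # name -> (T,) mV (arbitrary common scale)
    dt: float

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.leads[n] for n in LEAD_NAMES])


@dataclass
class QRSWindow:
    onset: float
    offset: float

    @property
    def qrsd(self) -> float:
        return self.offset - self.onset


def _gradient_operators(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Per-tet linear shape-function gradient operator G (M, 3, 4)."""
    p = nodes[tets]
    E = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))   # (M, 3, 3)
    Einv = np.linalg.inv(E)                            # rows: grad of lam1..3
    G = np.empty((len(tets), 3, 4))
    G[:, :, 1:] = np.transpose(Einv, (0, 2, 1))
    G[:, :, 0] = -G[:, :, 1:].sum(axis=2)
    return G


def lead_field_matrix(
    mesh_nodes: np.ndarray, tets: np.ndarray, electrodes: ElectrodeSet
) -> tuple[np.ndarray, list[str]]:
    """Dense electrode-by-node transfer matrix for the pseudo-ECG sum."""
    G = _gradient_operators(mesh_nodes, tets)
    p = mesh_nodes[tets]
    vol = np.abs(np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0)
    cent = p.mean(axis=1)
    names = sorted(electrodes.positions)
    A = np.zeros((len(names), len(mesh_nodes)))
    for e, name in enumerate(names):
        r = electrodes.positions[name] - cent                  # (M, 3)
        w = r / (np.linalg.norm(r, axis=1) ** 3)[:, None]      # grad(1/r)
        contrib = vol[:, None] * np.einsum("mi,mij->mj", w, G)  # (M, 4)
        np.add.at(A[e], tets.ravel(), contrib.ravel())
    return A, names


def compute_ecg(
    mesh: BiventricularMesh,
    activation: ActivationMap,
    electrodes: ElectrodeSet | None = None,
    template: APTemplate | None = None,
    dt: float = 1.0,
) -> ECG12:
    """Pseudo-ECG from an activation map via the template action potential."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not activation.reached.any():
        raise ValueError("activation map has no reached nodes")
    electrodes = electrodes or default_electrodes()
    template = template or default_ap_template()

    act = activation.times
    finite = activation.reached
    t_max = float(act[finite].max()) + template.upstroke_index * template.dt + 10.0
    time = np.arange(0.0, t_max + dt, dt)

    # node voltages: template shifted by activation time; unreached stays at rest
    offset = template.upstroke_index * template.dt
    shifted = time[None, :] - np.where(finite, act, np.inf)[:, None] + offset
    V = template.at(shifted)
    V[~finite] = template.samples[0]

    A, names = lead_field_matrix(mesh.nodes, mesh.tets, electrodes)
    phi = {n: row @ V for n, row in zip(names, A)}

    I = phi["LA"] - phi["RA"]
    III = phi["LL"] - phi["LA"]
    II = I + III                      # Einthoven identity exact by construction
    wct = (phi["RA"] + phi["LA"] + phi["LL"]) / 3.0
    leads = {
        "I": I, "II": II, "III": III,
        "aVR": phi["RA"] - (phi["LA"] + phi["LL"]) / 2.0,
        "aVL": phi["LA"] - (phi["RA"] + phi["LL"]) / 2.0,
        "aVF": phi["LL"] - (phi["RA"] + phi["LA"]) / 2.0,
    }
    for v in ("V1", "V2", "V3", "V4", "V5", "V6"):
        leads[v] = phi[v] - wct
    return ECG12(time=time, leads=leads, dt=dt)


def detect_qrs(
    ecg: ECG12, threshold_frac: float = 0.02, debounce_ms: float = 5.0
) -> QRSWindow:
    """QRS onset/offset from the across-lead RMS derivative.

    Onset (offset) is the start (end) of the first (last) run of samples
    whose RMS across-lead derivative exceeds ``threshold_frac`` of its global
    maximum and that lasts at least ``debounce_ms``.
    """
    M = ecg.as_matrix()
    D = np.gradient(M, ecg.dt, axis=1)
    r = np.sqrt((D**2).mean(axis=0))
    peak = r.max()
    if peak <= 0 or not np.isfinite(peak):
        raise ValueError("no QRS detected: flat signal")
    above = r >= threshold_frac * peak
    min_run = max(1, int(round(debounce_ms / ecg.dt)))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= min_run
    if not keep.any():
        raise ValueError("no QRS detected: no sustained deflection")
    onset = ecg.time[starts[keep][0]]
    offset = ecg.time[ends[keep][-1] - 1]
    return QRSWindow(onset=float(onset), offset=float(offset))


@dataclass
class ConductivityFit:
    kappa: float
    qrsd: float
    boundary_hit: bool
    n_evaluations: int


def fit_conductivity(
    mesh: BiventricularMesh,
    fibers: FiberField,
    labels: TissueLabelMap | None,
    protocol,
    target_qrsd: float,
    conduction: ConductionModel | None = None,
    bounds: tuple[float, float] | None = None,
    tol_ms: float = 2.0,
    dt: float = 1.0,
) -> ConductivityFit:
    """Fit the global conductivity multiplier kappa to a target QRS duration.

    ``protocol`` is ``("lbbb", tree)`` or ``("biv", rv_site, lv_site)``.
    QRSd(kappa) decreases monotonically in kappa (all speeds scale by
    sqrt(kappa)), so the fit is a bounded bracketing root-find.  If the
    target lies outside the attainable range the nearest bound is returned
    with ``boundary_hit`` set, not raised.
    """
    if target_qrsd <= 0:
        raise ValueError("target QRS duration must be positive")
    conduction = conduction or ConductionModel()
    lo, hi = bounds or conduction.kappa_bounds
    if not (0 < lo < hi):
        raise ValueError("invalid kappa bounds")

    evals = {"n": 0}

    def qrsd(kappa: float) -> float:
        evals["n"] += 1
        cm = ConductionModel(
            v_f=conduction.v_f, rho=conduction.rho, kappa=float(kappa),
            fibrosis_factor=conduction.fibrosis_factor, kappa_bounds=(lo, hi),
        )
        if protocol[0] == "lbbb":
            amap = simulate_lbbb(mesh, fibers, cm, protocol[1], labels)
        elif protocol[0] == "biv":
            amap = simulate_biv(mesh, fibers, cm, protocol[1], protocol[2], labels)
        else:
            raise ValueError(f"unknown protocol {protocol[0]!r}")
        return detect_qrs(compute_ecg(mesh, amap, dt=dt)).qrsd

    q_lo = qrsd(lo)   # slowest tissue -> longest QRS
    if target_qrsd >= q_lo:
        return ConductivityFit(lo, q_lo, boundary_hit=target_qrsd > q_lo + tol_ms,
                               n_evaluations=evals["n"])
    q_hi = qrsd(hi)
    if target_qrsd <= q_hi:
        return ConductivityFit(hi, q_hi, boundary_hit=target_qrsd < q_hi - tol_ms,
                               n_evaluations=evals["n"])

    kappa = brentq(lambda k: qrsd(k) - target_qrsd, lo, hi, xtol=2e-3, rtol=1e-3)
    return ConductivityFit(float(kappa), qrsd(kappa), boundary_hit=False,
                           n_evaluations=evals["n"])
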