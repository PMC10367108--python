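"""Model-derived dyssynchrony indices.

All volume statistics are volume-weighted over non-scar elements; an element
counts as reached when all four of its vertices are reached.  Element
activation time is the mean of its vertex times.

Index conventions:

* TAT95 — earliest time by which 95% of the (reached, non-scar) myocardial
  volume is activated; TAT is the 100% figure.
* AD_RVLV — LV total activation time minus RV total activation time
  (inter-ventricular uncoupling); totals are per-ventricle maxima, with the
  septum counted as LV.
* AD_STLV — (volume-mean LV-free-wall time − volume-mean septal time) / TAT
  (intra-ventricular dyssynchrony, dimensionless, in [-1, 1]).
* Scar-LVPS / LAT-LVPS — isotropic-eikonal distances from the LV pacing
  site to the scar region and to the late-activation region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import (
    LV_FREE_WALL,
    RV_FREE_WALL,
    SEPTUM,
    AHAParcellation,
    BiventricularMesh,
    TissueLabelMap,
)
from .ecg import ECG12, detect_qrs
from .eikonal import ActivationMap, isotropic_distance_field


def _element_times(activation: ActivationMap, mesh: BiventricularMesh) -> np.ndarray:
    """Mean vertex time per element; inf where any vertex is unreached."""
    vt = activation.times[mesh.tets]
    out = vt.mean(axis=1)
    out[~np.isfinite(vt).all(axis=1)] = np.inf
    return out


def _valid_mask(
    elem_times: np.ndarray, mesh: BiventricularMesh, labels: TissueLabelMap | None
) -> np.ndarray:
    ok = np.isfinite(elem_times)
    if labels is not None:
        ok &= ~labels.scar_mask
    return ok


def tat_percentile(
    activation: ActivationMap,
    mesh: BiventricularMesh,
    labels: TissueLabelMap | None = None,
    p: float = 95.0,
) -> float:
    """Volume-weighted activation-time percentile over non-scar tissue."""
    if not (0.0 < p <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    et = _element_times(activation, mesh)
    ok = _valid_mask(et, mesh, labels)
    if not ok.any():
        raise ValueError("no reached elements")
    t = et[ok]
    v = mesh.tet_volumes[ok]
    order = np.argsort(t, kind="stable")
    cum = np.cumsum(v[order])
    idx = np.searchsorted(cum, p / 100.0 * cum[-1], side="left")
    return float(t[order][min(idx, len(t) - 1)])


def ad_rvlv(
    activation: ActivationMap,
    mesh: BiventricularMesh,
    labels: TissueLabelMap | None = None,
) -> float:
    """LV total activation time minus RV total activation time (ms)."""
    et = _element_times(activation, mesh)
    ok = _valid_mask(et, mesh, labels)
    lv = ok & np.isin(mesh.ventricle_tag, (LV_FREE_WALL, SEPTUM))
    rv = ok & (mesh.ventricle_tag == RV_FREE_WALL)
    if not lv.any() or not rv.any():
        raise ValueError("a ventricle is fully unreached")
    return float(et[lv].max() - et[rv].max())


def ad_stlv(
    activation: ActivationMap,
    mesh: BiventricularMesh,
    labels: TissueLabelMap | None = None,
) -> float:
    """(mean LV-free-wall time − mean septal time) / total activation time."""
    et = _element_times(activation, mesh)
    ok = _valid_mask(et, mesh, labels)
    lat = ok & (mesh.ventricle_tag == LV_FREE_WALL)
    sep = ok & (mesh.ventricle_tag == SEPTUM)
    if not lat.any() or not sep.any():
        raise ValueError("LV free wall or septum fully unreached")
    v = mesh.tet_volumes
    tat = float(et[ok].max())
    if tat <= 0:
        return 0.0
    m_lat = float(np.average(et[lat], weights=v[lat]))
    m_sep = float(np.average(et[sep], weights=v[sep]))
    return (m_lat - m_sep) / tat


def lat_region(
    lbbb_map: ActivationMap,
    mesh: BiventricularMesh,
    fraction: float = 0.10,
) -> np.ndarray:
    """LV epicardial nodes in the latest-activated ``fraction`` of the LBBB map."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    nodes = mesh.lv_epi_nodes
    t = lbbb_map.times[nodes]
    fin = np.isfinite(t)
    if not fin.any():
        raise ValueError("LBBB map unreached on the LV epicardium")
    thr = np.quantile(t[fin], 1.0 - fraction)
    return nodes[fin & (t >= thr)]


def rv_lv_delay(
    lbbb_map: ActivationMap, mesh: BiventricularMesh, rv_site, lv_site
) -> float:
    """Baseline delay: LBBB activation time at the LV site minus the RV site."""
    t_lv = lbbb_map.times[mesh.nearest_node(lv_site)]
    t_rv = lbbb_map.times[mesh.nearest_node(rv_site)]
    if not (np.isfinite(t_lv) and np.isfinite(t_rv)):
        raise ValueError("pacing site unreached in the baseline map")
    return float(t_lv - t_rv)


_DELTA_KEYS = ("tat95", "tat", "qrsd", "ad_rvlv", "ad_stlv")


@dataclass
class SimFeatures:
    """Model-derived indices for one (patient, LV-pacing-site) configuration."""

    lbbb: dict[str, float]
    biv: dict[str, float]
    delta: dict[str, float]          # BiV − LBBB
    delta_rel: dict[str, float]      # (BiV − LBBB) / LBBB
    scar_lvps: float | None          # mm; None when the model has no scar
    lat_lvps: float                  # mm
    rv_lv_distance: float            # mm (Euclidean between pacing sites)
    rv_lv_delay: float               # ms, from the LBBB map

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for proto, vals in (("LBBB", self.lbbb), ("BiV", self.biv)):
            for k, v in vals.items():
                row[f"{k}_{proto}"] = v
        for k in _DELTA_KEYS:
            row[f"d_{k}"] = self.delta[k]
            row[f"d_{k}_rel"] = self.delta_rel[k]
        row["scar_lvps"] = np.nan if self.scar_lvps is None else self.scar_lvps
        row["lat_lvps"] = self.lat_lvps
        row["rv_lv_distance"] = self.rv_lv_distance
        row["rv_lv_delay"] = self.rv_lv_delay
        return row


def _protocol_indices(
    activation: ActivationMap,
    ecg: ECG12 | None,
    mesh: BiventricularMesh,
    labels: TissueLabelMap | None,
) -> dict[str, float]:
    out = {
        "tat95": tat_percentile(activation, mesh, labels, 95.0),
        "tat": tat_percentile(activation, mesh, labels, 100.0),
        "ad_rvlv": ad_rvlv(activation, mesh, labels),
        "ad_stlv": ad_stlv(activation, mesh, labels),
    }
    out["qrsd"] = detect_qrs(ecg).qrsd if ecg is not None else np.nan
    return out


def extract_features(
    lbbb_map: ActivationMap,
    biv_map: ActivationMap,
    lbbb_ecg: ECG12 | None,
    biv_ecg: ECG12 | None,
    mesh: BiventricularMesh,
    labels: TissueLabelMap | None,
    parcellation: AHAParcellation,
    rv_site,
    lv_site,
    lat_fraction: float = 0.10,
) -> SimFeatures:
    """Assemble all indices for one pacing configuration."""
    lbbb = _protocol_indices(lbbb_map, lbbb_ecg, mesh, labels)
    biv = _protocol_indices(biv_map, biv_ecg, mesh, labels)
    delta = {k: biv[k] - lbbb[k] for k in _DELTA_KEYS}
    delta_rel = {
        k: (delta[k] / lbbb[k] if lbbb[k] != 0 else np.nan) for k in _DELTA_KEYS
    }

    scar_lvps: float | None = None
    if labels is not None and labels.scar_mask.any():
        scar_nodes = np.unique(mesh.tets[labels.scar_mask])
        dist = isotropic_distance_field(mesh, scar_nodes)
        scar_lvps = float(dist[mesh.nearest_node(lv_site)])

    lat_nodes = lat_region(lbbb_map, mesh, lat_fraction)
    lat_dist = isotropic_distance_field(mesh, lat_nodes)
    lat_lvps = float(lat_dist[mesh.nearest_node(lv_site)])

    rvlv_dist = float(np.linalg.norm(np.asarray(lv_site, float) - np.asarray(rv_site, float)))
    delay = rv_lv_delay(lbbb_map, mesh, rv_site, lv_site)

    return SimFeatures(
        lbbb=lbbb,
        biv=biv,
        delta=delta,
        delta_rel=delta_rel,
        scar_lvps=scar_lvps,
        lat_lvps=lat_lvps,
        rv_lv_distance=rvlv_dist,
        rv_lv_delay=delay,
    )
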