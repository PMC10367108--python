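"""Synthetic biventricular anatomy.

Parametric stand-in for image-derived patient geometries: the left ventricle
is a thick-walled truncated prolate ellipsoid, the right ventricle a thinner
crescent-shaped shell attached on the +x side.  The long axis is +z with the
apex at the bottom and the truncation (base) plane at the top.  On top of the
tetrahedral mesh the module provides rule-based transmural fiber rotation,
the standard AHA 17-segment parcellation of the LV, and segment-granular
scar/fibrosis labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
from scipy.spatial import Delaunay, cKDTree

# ventricle tags (per element)
LV_FREE_WALL = 0
SEPTUM = 1
RV_FREE_WALL = 2

# surface tags (per boundary facet)
SURF_LV_ENDO = 0
SURF_RV_ENDO = 1
SURF_EPI = 2
SURF_BASE = 3

# tissue classes (per element)
HEALTHY = 0
FIBROSIS = 1
SCAR = 2

#: septal segments of the AHA 17-segment model
SEPTAL_SEGMENTS = frozenset({2, 3, 8, 9, 14})


class ParameterError(ValueError):
    """Non-physical geometry parameters."""


@dataclass(frozen=True)
class GeometryParams:
    """Geometry of the two truncated ellipsoids (all lengths in mm)."""

    lv_endo_radius: float = 22.0      # LV cavity short-axis semi-axis
    lv_endo_length: float = 40.0      # LV cavity long-axis semi-axis
    lv_wall: float = 10.0             # LV wall thickness
    rv_center: tuple[float, float, float] = (25.0, 0.0, 5.0)
    rv_endo_radii: tuple[float, float, float] = (26.0, 20.0, 36.0)
    rv_wall: float = 4.0              # RV free-wall thickness
    base_z: float = 10.0              # truncation plane
    spacing: float = 3.0              # target node spacing (resolution)
    jitter: float = 0.05              # node jitter as a fraction of spacing

    def validate(self) -> None:
        if self.lv_endo_radius <= 0 or self.lv_endo_length <= 0:
            raise ParameterError("LV cavity radii must be positive")
        if self.lv_wall <= 0 or self.rv_wall <= 0:
            raise ParameterError("wall thicknesses must be positive")
        if self.lv_wall >= self.lv_endo_radius:
            raise ParameterError("LV wall thickness must be smaller than the cavity radius")
        if self.rv_wall >= min(self.rv_endo_radii):
            raise ParameterError("RV wall thickness must be smaller than the cavity radii")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        if self.spacing > min(self.lv_wall, self.rv_wall) * 2:
            raise ParameterError(
                "spacing too coarse: fewer than ~2 elements across the thinnest wall"
            )

    @property
    def lv_endo_axes(self) -> np.ndarray:
        return np.array([self.lv_endo_radius, self.lv_endo_radius, self.lv_endo_length])

    @property
    def lv_epi_axes(self) -> np.ndarray:
        return self.lv_endo_axes + self.lv_wall

    @property
    def rv_endo_axes(self) -> np.ndarray:
        return np.asarray(self.rv_endo_radii, dtype=float)

    @property
    def rv_epi_axes(self) -> np.ndarray:
        return self.rv_endo_axes + self.rv_wall


def _ellipsoid(points: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Implicit ellipsoid function: <1 inside, 1 on the surface, >1 outside."""
    q = (points - center) / axes
    return np.einsum("...i,...i->...", q, q)


@dataclass
class BiventricularMesh:
    """Tetrahedral biventricular geometry with region and surface labels."""

    nodes: np.ndarray                 # (N, 3) mm
    tets: np.ndarray                  # (M, 4) int, positively oriented
    ventricle_tag: np.ndarray         # (M,) int in {LV_FREE_WALL, SEPTUM, RV_FREE_WALL}
    boundary_faces: np.ndarray        # (F, 3) int
    surface_tag: np.ndarray           # (F,) int
    long_axis: np.ndarray             # unit vector apex -> base
    apex: np.ndarray                  # (3,) mm
    base_center: np.ndarray           # (3,) mm
    params: GeometryParams = field(default_factory=GeometryParams)

    @cached_property
    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    @cached_property
    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @cached_property
    def node_tree(self) -> cKDTree:
        return cKDTree(self.nodes)

    def surface_nodes(self, tag: int) -> np.ndarray:
        """Sorted unique node indices of boundary facets carrying ``tag``."""
        return np.unique(self.boundary_faces[self.surface_tag == tag])

    @cached_property
    def lv_element_mask(self) -> np.ndarray:
        return np.isin(self.ventricle_tag, (LV_FREE_WALL, SEPTUM))

    @cached_property
    def lv_epi_nodes(self) -> np.ndarray:
        """Nodes on epicardial facets of LV (free wall or septal) elements."""
        lv_nodes = np.unique(self.tets[self.lv_element_mask])
        epi = self.surface_nodes(SURF_EPI)
        return np.intersect1d(epi, lv_nodes)

    @cached_property
    def node_to_tets(self) -> list[np.ndarray]:
        adj: list[list[int]] = [[] for _ in range(len(self.nodes))]
        for t, quad in enumerate(self.tets):
            for n in quad:
                adj[n].append(t)
        return [np.asarray(a, dtype=np.int64) for a in adj]

    def nearest_node(self, point) -> int:
        return int(self.node_tree.query(np.asarray(point, dtype=float))[1])


def generate_biventricular_mesh(
    params: GeometryParams | None = None, seed: int = 0
) -> BiventricularMesh:
    """Build a watertight two-cavity truncated-ellipsoid tetrahedral mesh.

    Nodes are placed on a jittered regular grid, kept where the implicit
    two-ventricle solid holds, and tetrahedralized by Delaunay; tetrahedra
    whose centroid leaves the solid (or that span a cavity) are discarded.
    Deterministic for fixed ``params`` and ``seed``.
    """
    params = params or GeometryParams()
    params.validate()
    rng = np.random.default_rng(seed)
    h = params.spacing

    lo = np.minimum(-params.lv_epi_axes, np.asarray(params.rv_center) - params.rv_epi_axes) - h
    hi = np.maximum(params.lv_epi_axes, np.asarray(params.rv_center) + params.rv_epi_axes) + h
    hi[2] = params.base_z
    grids = [np.arange(lo[i], hi[i] + 0.5 * h, h) for i in range(3)]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = pts + rng.uniform(-params.jitter * h, params.jitter * h, size=pts.shape)
    pts[:, 2] = np.minimum(pts[:, 2], params.base_z)

    inside = _myocardium_mask(pts, params)
    pts = pts[inside]
    if len(pts) < 20:
        raise ParameterError("resolution too coarse for the requested geometry")

    tri = Delaunay(pts)
    tets = tri.simplices
    cent = pts[tets].mean(axis=1)
    keep = _myocardium_mask(cent, params)
    edges = pts[tets]
    # drop cavity-/exterior-spanning slivers: any edge much longer than the grid
    emax = np.zeros(len(tets))
    for i in range(4):
        for j in range(i + 1, 4):
            d = np.linalg.norm(edges[:, i] - edges[:, j], axis=1)
            emax = np.maximum(emax, d)
    keep &= emax < 2.0 * h
    tets = tets[keep]

    vol = np.linalg.det(pts[tets][:, 1:] - pts[tets][:, :1]) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vol = np.abs(vol)
    tets = tets[vol > 1e-9 * h**3]

    used = np.unique(tets)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = pts[used]
    tets = remap[tets]

    faces, face_tag = _boundary_faces(nodes, tets, params)
    vent = _ventricle_tags(nodes, tets, params)

    apex = np.array([0.0, 0.0, -(params.lv_endo_length + params.lv_wall)])
    base_center = np.array([0.0, 0.0, params.base_z])
    return BiventricularMesh(
        nodes=nodes,
        tets=tets,
        ventricle_tag=vent,
        boundary_faces=faces,
        surface_tag=face_tag,
        long_axis=np.array([0.0, 0.0, 1.0]),
        apex=apex,
        base_center=base_center,
        params=params,
    )


def _myocardium_mask(points: np.ndarray, p: GeometryParams) -> np.ndarray:
    zero = np.zeros(3)
    rvc = np.asarray(p.rv_center, dtype=float)
    f_lv_endo = _ellipsoid(points, zero, p.lv_endo_axes)
    f_lv_epi = _ellipsoid(points, zero, p.lv_epi_axes)
    f_rv_endo = _ellipsoid(points, rvc, p.rv_endo_axes)
    f_rv_epi = _ellipsoid(points, rvc, p.rv_epi_axes)
    below_base = points[:, 2] <= p.base_z + 1e-9
    lv_wall = (f_lv_epi < 1.0) & (f_lv_endo >= 1.0)
    rv_wall = (f_rv_epi < 1.0) & (f_rv_endo >= 1.0) & (f_lv_epi >= 1.0)
    return below_base & (lv_wall | rv_wall)


def _ventricle_tags(nodes: np.ndarray, tets: np.ndarray, p: GeometryParams) -> np.ndarray:
    cent = nodes[tets].mean(axis=1)
    zero = np.zeros(3)
    rvc = np.asarray(p.rv_center, dtype=float)
    f_lv_epi = _ellipsoid(cent, zero, p.lv_epi_axes)
    f_rv_epi = _ellipsoid(cent, rvc, p.rv_epi_axes)
    tags = np.full(len(tets), RV_FREE_WALL, dtype=np.int64)
    in_lv = f_lv_epi < 1.0
    tags[in_lv & (f_rv_epi < 1.0)] = SEPTUM
    tags[in_lv & (f_rv_epi >= 1.0)] = LV_FREE_WALL
    return tags


def _boundary_faces(
    nodes: np.ndarray, tets: np.ndarray, p: GeometryParams
) -> tuple[np.ndarray, np.ndarray]:
    local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    all_faces = np.concatenate([tets[:, idx] for idx in local])
    key = np.sort(all_faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    faces = all_faces[first[counts == 1]]

    cent = nodes[faces].mean(axis=1)
    zero = np.zeros(3)
    rvc = np.asarray(p.rv_center, dtype=float)
    d_lv_endo = np.abs(_ellipsoid(cent, zero, p.lv_endo_axes) - 1.0)
    d_rv_endo = np.abs(_ellipsoid(cent, rvc, p.rv_endo_axes) - 1.0)
    f_lv_epi = _ellipsoid(cent, zero, p.lv_epi_axes)
    f_rv_epi = _ellipsoid(cent, rvc, p.rv_epi_axes)
    d_epi = np.abs(np.minimum(f_lv_epi, f_rv_epi) - 1.0)
    # RV endocardium exists only outside the LV epicardial ellipsoid
    d_rv_endo = np.where(f_lv_epi > 1.0, d_rv_endo, np.inf)

    tag = np.full(len(faces), SURF_EPI, dtype=np.int64)
    is_base = cent[:, 2] > p.base_z - 0.35 * p.spacing
    stacked = np.stack([d_lv_endo, d_rv_endo, d_epi])
    tag = np.array([SURF_LV_ENDO, SURF_RV_ENDO, SURF_EPI])[np.argmin(stacked, axis=0)]
    tag[is_base] = SURF_BASE
    return faces, tag


# ---------------------------------------------------------------------------
# fibers


@dataclass
class FiberField:
    """Per-element myocardial fiber direction (unit vectors)."""

    directions: np.ndarray  # (M, 3)


def transmural_depth(mesh: BiventricularMesh, points: np.ndarray) -> np.ndarray:
    """Normalized wall depth at ``points``: 0 at endocardium, 1 at epicardium.

    Solved per point by bisection on the interpolated family of ellipsoids
    between the endocardial and epicardial surfaces of the ventricle that
    owns the point.
    """
    p = mesh.params
    zero = np.zeros(3)
    rvc = np.asarray(p.rv_center, dtype=float)
    in_lv = _ellipsoid(points, zero, p.lv_epi_axes) < 1.0

    depth = np.empty(len(points))
    for mask, center, a_endo, a_epi in (
        (in_lv, zero, p.lv_endo_axes, p.lv_epi_axes),
        (~in_lv, rvc, p.rv_endo_axes, p.rv_epi_axes),
    ):
        if not mask.any():
            continue
        q = points[mask]
        lo = np.full(len(q), -1.0)
        hi = np.full(len(q), 2.0)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            axes = a_endo + mid[:, None] * (a_epi - a_endo)
            f = np.einsum("ij,ij->i", (q - center) / axes, (q - center) / axes)
            outside = f > 1.0  # interpolated ellipsoid still too small
            lo = np.where(outside, mid, lo)
            hi = np.where(outside, hi, mid)
        depth[mask] = np.clip(0.5 * (lo + hi), 0.0, 1.0)
    return depth


def assign_fibers(
    mesh: BiventricularMesh, endo_angle: float = 60.0, epi_angle: float = -60.0
) -> FiberField:
    """Rule-based fibers: the helix angle rotates linearly across the wall.

    The angle is ``endo_angle`` on the endocardium and ``epi_angle`` on the
    epicardium (degrees from the circumferential direction, positive toward
    the base).  Vectors are tangent to the local wall surface.
    """
    if not (-90.0 <= endo_angle <= 90.0) or not (-90.0 <= epi_angle <= 90.0):
        raise ValueError("helix angles must lie in [-90, 90] degrees")
    p = mesh.params
    cent = mesh.tet_centroids
    depth = transmural_depth(mesh, cent)

    zero = np.zeros(3)
    rvc = np.asarray(p.rv_center, dtype=float)
    in_lv = _ellipsoid(cent, zero, p.lv_epi_axes) < 1.0
    center = np.where(in_lv[:, None], zero, rvc)
    a_endo = np.where(in_lv[:, None], p.lv_endo_axes, p.rv_endo_axes)
    a_epi = np.where(in_lv[:, None], p.lv_epi_axes, p.rv_epi_axes)
    axes = a_endo + depth[:, None] * (a_epi - a_endo)

    normal = 2.0 * (cent - center) / axes**2  # gradient of the implicit surface
    nn = np.linalg.norm(normal, axis=1, keepdims=True)
    bad = ~np.isfinite(nn[:, 0]) | (nn[:, 0] < 1e-12)
    if bad.any():
        raise ValueError(f"undefined transmural coordinate for elements {np.where(bad)[0][:5]}")
    normal /= nn

    z = mesh.long_axis
    e_l = z - normal * (normal @ z)[:, None]
    ln = np.linalg.norm(e_l, axis=1, keepdims=True)
    # near the apex the long axis is normal to the wall; fall back to a fixed
    # in-plane reference to keep the frame defined
    degen = ln[:, 0] < 1e-6
    if degen.any():
        alt = np.array([1.0, 0.0, 0.0]) - normal[degen] * normal[degen, 0:1]
        e_l[degen] = alt
        ln[degen] = np.linalg.norm(alt, axis=1, keepdims=True)
    e_l /= ln
    e_c = np.cross(normal, e_l)
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)

    alpha = np.deg2rad(endo_angle + (epi_angle - endo_angle) * depth)
    fibers = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    return FiberField(directions=fibers)


# ---------------------------------------------------------------------------
# AHA parcellation


@dataclass
class AHAParcellation:
    """AHA 17-segment labels over the LV (elements and epicardial nodes)."""

    element_segment: np.ndarray       # (M,) 1..17 for LV elements, 0 elsewhere
    node_segment: dict[int, int]      # LV epicardial node -> segment id
    centroids: dict[int, np.ndarray]  # segment -> element-centroid mean (mm)
    epi_centroids: dict[int, np.ndarray]  # segment -> epicardial-node mean (mm)
    septal_segments: frozenset = SEPTAL_SEGMENTS

    @property
    def segment_ids(self) -> np.ndarray:
        return np.unique(self.element_segment[self.element_segment > 0])


def _aha_segment_of(zeta: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Map normalized long-axis position and circumferential angle to 1..17.

    ``zeta`` runs 0 at the cavity apex to 1 at the base (negative below the
    cavity apex = apical cap); ``theta_deg`` is measured from the septum
    center (direction of the RV), increasing toward the anterior wall.
    """
    seg = np.zeros(len(zeta), dtype=np.int64)
    th = np.mod(theta_deg, 360.0)
    basal = np.array([2, 1, 6, 5, 4, 3])    # 60-degree sectors from theta=0
    mid = basal + 6
    sector6 = (th // 60).astype(np.int64)
    sector4 = (np.mod(th + 45.0, 360.0) // 90).astype(np.int64)
    apical = np.array([14, 13, 16, 15])

    cap = zeta < 0.0
    ap = (zeta >= 0.0) & (zeta < 1.0 / 3.0)
    md = (zeta >= 1.0 / 3.0) & (zeta < 2.0 / 3.0)
    ba = zeta >= 2.0 / 3.0
    seg[cap] = 17
    seg[ap] = apical[sector4[ap]]
    seg[md] = mid[sector6[md]]
    seg[ba] = basal[sector6[ba]]
    return seg


def parcellate_aha(mesh: BiventricularMesh) -> AHAParcellation:
    """Standard AHA rule: 6+6 basal/mid sectors, 4 apical, apex cap (17)."""
    z = np.asarray(mesh.long_axis, dtype=float)
    if np.linalg.norm(z) < 1e-12:
        raise ValueError("degenerate long axis")
    z = z / np.linalg.norm(z)
    apex = np.asarray(mesh.apex, dtype=float)
    length = (mesh.base_center - apex) @ z
    cavity_apex_s = mesh.params.lv_wall  # wall thickness below the cavity tip

    rv_cent = mesh.tet_centroids[mesh.ventricle_tag == RV_FREE_WALL].mean(axis=0)
    rv_dir = rv_cent - apex
    rv_dir -= z * (rv_dir @ z)
    rv_dir /= np.linalg.norm(rv_dir)
    anterior = np.cross(z, rv_dir)

    def classify(points: np.ndarray) -> np.ndarray:
        rel = points - apex
        s = rel @ z
        zeta = (s - cavity_apex_s) / (length - cavity_apex_s)
        x_c = rel @ rv_dir
        y_c = rel @ anterior
        theta = np.degrees(np.arctan2(y_c, x_c))
        return _aha_segment_of(zeta, theta)

    elem_seg = np.zeros(len(mesh.tets), dtype=np.int64)
    lv = mesh.lv_element_mask
    elem_seg[lv] = classify(mesh.tet_centroids[lv])

    epi_nodes = mesh.lv_epi_nodes
    node_seg_arr = classify(mesh.nodes[epi_nodes])
    node_segment = {int(n): int(s) for n, s in zip(epi_nodes, node_seg_arr)}

    centroids: dict[int, np.ndarray] = {}
    epi_centroids: dict[int, np.ndarray] = {}
    for s in np.unique(elem_seg[lv]):
        centroids[int(s)] = mesh.tet_centroids[elem_seg == s].mean(axis=0)
    for s in np.unique(node_seg_arr):
        epi_centroids[int(s)] = mesh.nodes[epi_nodes[node_seg_arr == s]].mean(axis=0)

    return AHAParcellation(
        element_segment=elem_seg,
        node_segment=node_segment,
        centroids=centroids,
        epi_centroids=epi_centroids,
    )


# ---------------------------------------------------------------------------
# tissue labels


@dataclass
class TissueLabelMap:
    """Per-element tissue class: healthy, fibrosis, or scar."""

    labels: np.ndarray  # (M,) int

    @property
    def scar_mask(self) -> np.ndarray:
        return self.labels == SCAR

    @property
    def fibrosis_mask(self) -> np.ndarray:
        return self.labels == FIBROSIS


def label_tissue(
    mesh: BiventricularMesh,
    parcellation: AHAParcellation,
    scar_segments=(),
    fibrosis_segments=(),
) -> TissueLabelMap:
    """Label whole AHA segments as scar or fibrosis (scar wins on overlap)."""
    for s in list(scar_segments) + list(fibrosis_segments):
        if not 1 <= int(s) <= 17:
            raise ValueError(f"unknown AHA segment id {s}")
    labels = np.full(len(mesh.tets), HEALTHY, dtype=np.int64)
    if fibrosis_segments:
        labels[np.isin(parcellation.element_segment, list(fibrosis_segments))] = FIBROSIS
    if scar_segments:
        labels[np.isin(parcellation.element_segment, list(scar_segments))] = SCAR
    return TissueLabelMap(labels=labels)


def tissue_volume_fractions(
    mesh: BiventricularMesh, labels: TissueLabelMap
) -> dict[str, float]:
    """Volume-weighted scar and fibrosis fractions of the myocardium."""
    vol = mesh.tet_volumes
    total = vol.sum()
    return {
        "scar_fraction": float(vol[labels.scar_mask].sum() / total),
        "fibrosis_fraction": float(vol[labels.fibrosis_mask].sum() / total),
    }


# ---------------------------------------------------------------------------
# simple structured meshes (calibration and validation geometries)


def slab_mesh(
    size=(40.0, 10.0, 10.0), spacing: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Structured tetrahedral slab: returns (nodes, tets).

    Each grid cell is split into six positively oriented tetrahedra; used for
    wave-speed validation against closed-form travel times.
    """
    nx, ny, nz = (max(1, int(round(s / spacing))) for s in size)
    xs = np.linspace(0, size[0], nx + 1)
    ys = np.linspace(0, size[1], ny + 1)
    zs = np.linspace(0, size[2], nz + 1)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    nodes = grid.reshape(-1, 3)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # six-tet Kuhn subdivision of the cube
    kuhn = [
        (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
        (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
    ]
    corners = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                        (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)])
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + c[0], j + c[1], k + c[2]) for c in corners]
                for t in kuhn:
                    tets.append([ids[t[0]], ids[t[1]], ids[t[2]], ids[t[3]]])
    tets = np.asarray(tets, dtype=np.int64)
    p = nodes[tets]
    vol = np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0
    flip = vol < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return nodes, tets
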