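"""Right-bundle Purkinje network for total left bundle branch block.

A fractal binary tree grows from the His node over the RV endocardial
surface; every leaf couples to the nearest RV endocardial mesh node (a
Purkinje-myocardial junction, PMJ).  The tree is electrically isolated from
the working myocardium except at the PMJs, and conducts at a fixed velocity
(default 3 mm/ms).  Growth is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .anatomy import SURF_RV_ENDO, BiventricularMesh


@dataclass(frozen=True)
class GrowthParams:
    """Fractal-tree growth settings (lengths in mm, angles in degrees)."""

    initial_length: float = 20.0
    length_decay: float = 0.8
    branch_angle: float = 30.0
    generations: int = 7
    angle_jitter: float = 5.0
    min_length: float = 2.0


@dataclass
class PurkinjeTree:
    """Directed conduction tree rooted at the His node."""

    nodes: np.ndarray                # (K, 3) mm
    edges: np.ndarray                # (E, 2) parent -> child
    edge_lengths: np.ndarray         # (E,) mm
    root: int
    terminals: np.ndarray            # leaf tree-node ids
    pmj_nodes: np.ndarray            # coupled mesh node per terminal
    v_purkinje: float = 3.0

    def parent_map(self) -> dict[int, tuple[int, float]]:
        return {int(c): (int(p), float(l))
                for (p, c), l in zip(self.edges, self.edge_lengths)}


@dataclass
class TreeActivation:
    """Activation time (ms) per tree node, zero at the His root."""

    times: np.ndarray


class _Surface:
    """Tangent-plane projection onto the RV endocardial surface."""

    def __init__(self, mesh: BiventricularMesh):
        self.node_ids = mesh.surface_nodes(SURF_RV_ENDO)
        if len(self.node_ids) == 0:
            raise ValueError("RV endocardial surface is empty")
        self.points = mesh.nodes[self.node_ids]
        self.tree = cKDTree(self.points)
        faces = mesh.boundary_faces[mesh.surface_tag == SURF_RV_ENDO]
        normals = np.zeros((len(mesh.nodes), 3))
        fp = mesh.nodes[faces]
        fn = np.cross(fp[:, 1] - fp[:, 0], fp[:, 2] - fp[:, 0])
        for i in range(3):
            np.add.at(normals, faces[:, i], fn)
        nrm = np.linalg.norm(normals[self.node_ids], axis=1, keepdims=True)
        nrm[nrm < 1e-12] = 1.0
        self.normals = normals[self.node_ids] / nrm

    def project(self, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project onto the tangent plane at the nearest surface node."""
        _, i = self.tree.query(point)
        q, n = self.points[i], self.normals[i]
        return point - n * ((point - q) @ n), n

    def nearest_mesh_node(self, point: np.ndarray) -> int:
        return int(self.node_ids[self.tree.query(point)[1]])


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    return (v * np.cos(a) + np.cross(axis, v) * np.sin(a)
            + axis * (axis @ v) * (1 - np.cos(a)))


def generate_purkinje_tree(
    mesh: BiventricularMesh,
    side: str = "right_only",
    growth: GrowthParams | None = None,
    seed: int = 0,
    v_purkinje: float = 3.0,
) -> PurkinjeTree:
    """Grow the fractal conduction tree on the RV endocardium.

    ``side='right_only'`` models total LBBB: no branch reaches the LV
    endocardium.  (``'both'`` is reserved and not implemented: the package
    models complete block only.)
    """
    if side != "right_only":
        raise NotImplementedError("only the right-bundle tree (total LBBB) is modeled")
    growth = growth or GrowthParams()
    if growth.generations < 1 or growth.initial_length <= 0:
        raise ValueError("growth parameters yield no terminals")
    rng = np.random.default_rng(seed)
    surf = _Surface(mesh)

    # His node: top of the septal RV endocardium, near the base
    septal_x = 0.6 * mesh.params.lv_epi_axes[0]
    his_seed = np.array([septal_x, 0.0, mesh.params.base_z])
    root_pt, _ = surf.project(his_seed)
    down = -mesh.long_axis  # initial bundle direction: toward the apex

    pts: list[np.ndarray] = [root_pt]
    edges: list[tuple[int, int]] = []
    frontier = [(0, down / np.linalg.norm(down), growth.initial_length)]
    for gen in range(growth.generations):
        nxt = []
        for start_id, direction, length in frontier:
            start = pts[start_id]
            raw_end = start + direction * length
            end, normal = surf.project(raw_end)
            if np.linalg.norm(end - start) < 1e-6:
                end = start + direction * max(growth.min_length, 0.5 * length)
                end, normal = surf.project(end + normal * 0.0)
                if np.linalg.norm(end - start) < 1e-6:
                    end = start + direction * growth.min_length
            pts.append(end)
            cid = len(pts) - 1
            edges.append((start_id, cid))
            if gen == growth.generations - 1:
                continue
            new_dir = end - start
            nd = np.linalg.norm(new_dir)
            new_dir = direction if nd < 1e-9 else new_dir / nd
            child_len = max(length * growth.length_decay, growth.min_length)
            for sgn in (1.0, -1.0):
                ang = sgn * (growth.branch_angle
                             + rng.uniform(-growth.angle_jitter, growth.angle_jitter))
                d = _rotate(new_dir, normal, ang)
                d -= normal * (d @ normal)  # keep in the tangent plane
                nn = np.linalg.norm(d)
                d = new_dir if nn < 1e-9 else d / nn
                nxt.append((cid, d, child_len))
        frontier = nxt

    nodes = np.asarray(pts)
    edges_arr = np.asarray(edges, dtype=np.int64)
    lengths = np.linalg.norm(nodes[edges_arr[:, 1]] - nodes[edges_arr[:, 0]], axis=1)
    has_child = np.zeros(len(nodes), dtype=bool)
    has_child[edges_arr[:, 0]] = True
    terminals = np.where(~has_child)[0]
    if len(terminals) == 0:
        raise ValueError("growth parameters yield no terminals")
    pmj = np.array([surf.nearest_mesh_node(nodes[t]) for t in terminals], dtype=np.int64)
    return PurkinjeTree(
        nodes=nodes,
        edges=edges_arr,
        edge_lengths=lengths,
        root=0,
        terminals=terminals,
        pmj_nodes=pmj,
        v_purkinje=v_purkinje,
    )


def activate_tree(tree: PurkinjeTree) -> TreeActivation:
    """Propagate activation from the His root at the tree velocity.

    Each node's time is its root-path length divided by ``v_purkinje``.
    """
    if tree.v_purkinje <= 0:
        raise ValueError("Purkinje conduction velocity must be positive")
    times = np.full(len(tree.nodes), np.nan)
    times[tree.root] = 0.0
    # edges are emitted parent-before-child by construction
    for (p, c), l in zip(tree.edges, tree.edge_lengths):
        times[c] = times[p] + l / tree.v_purkinje
    if np.isnan(times).any():
        raise ValueError("tree contains nodes unreachable from the root")
    return TreeActivation(times=times)


def pmj_sources(tree: PurkinjeTree, activation: TreeActivation) -> list[tuple[int, float]]:
    """Myocardial sources: (mesh node, onset ms) for every PMJ.

    The junction adds no transmission delay; the myocardial node inherits the
    terminal's time.
    """
    if len(tree.terminals) == 0:
        raise ValueError("tree has no terminals")
    return [
        (int(m), float(activation.times[t]))
        for t, m in zip(tree.terminals, tree.pmj_nodes)
    ]


def root_path_length(tree: PurkinjeTree, node: int) -> float:
    """Summed edge length from the His root to ``node``."""
    parents = tree.parent_map()
    total = 0.0
    while node != tree.root:
        node, l = parents[node]
        total += l
    return total
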