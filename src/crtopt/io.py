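"""File I/O: legacy-VTK unstructured grids, tree edge lists, model files.

Meshes and scalar fields travel as legacy ASCII VTK unstructured grids
(readable by ParaView and most mesh toolchains); tabular artifacts as CSV;
trained models and configuration as YAML.  The writer/reader pair here
covers exactly the subset of the VTK format this package emits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomy import BiventricularMesh, GeometryParams
from .classifier import LRModel

#: sentinel written for unreached nodes in exported activation fields
UNREACHED_SENTINEL = -1.0

VTK_TET = 10


def write_vtk(
    path,
    nodes: np.ndarray,
    tets: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    comment: str = "crtopt unstructured grid",
) -> None:
    """Write a tetrahedral mesh with optional data arrays (legacy ASCII VTK).

    Non-finite values in point data are replaced by ``UNREACHED_SENTINEL``
    (documented in the header comment line).
    """
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0",
             f"{comment}; unreached sentinel {UNREACHED_SENTINEL}",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in nodes]
    lines.append(f"CELLS {len(tets)} {5 * len(tets)}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += [str(VTK_TET)] * len(tets)

    def data_block(kind, count, arrays):
        out = [f"{kind} {count}"]
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                arr = np.where(np.isfinite(arr), arr, UNREACHED_SENTINEL)
                out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                out += [f"{v:.10g}" for v in arr]
            else:
                out.append(f"VECTORS {name} double")
                out += [" ".join(f"{v:.10g}" for v in row) for row in arr]
        return out

    if point_data:
        lines += data_block("POINT_DATA", len(nodes), point_data)
    if cell_data:
        lines += data_block("CELL_DATA", len(tets), cell_data)
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> tuple[np.ndarray, np.ndarray, dict, dict]:
    """Read a file written by :func:`write_vtk`.

    Returns (nodes, tets, point_data, cell_data).
    """
    tok = Path(path).read_text().split("\n")
    i = 0
    nodes = tets = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    target = None
    while i < len(tok):
        line = tok[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            nodes = np.array([[float(v) for v in tok[i + 1 + k].split()]
                              for k in range(n)])
            i += n
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            tets = np.array([[int(v) for v in tok[i + 1 + k].split()[1:]]
                             for k in range(m)], dtype=np.int64)
            i += m
        elif line.startswith("POINT_DATA"):
            target = point_data
        elif line.startswith("CELL_DATA"):
            target = cell_data
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            count = len(nodes) if target is point_data else len(tets)
            vals = np.array([float(tok[i + 2 + k]) for k in range(count)])
            target[name] = vals
            i += count + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            count = len(nodes) if target is point_data else len(tets)
            vals = np.array([[float(v) for v in tok[i + 1 + k].split()]
                             for k in range(count)])
            target[name] = vals
            i += count
        i += 1
    if nodes is None or tets is None:
        raise ValueError(f"{path}: not a crtopt VTK unstructured grid")
    return nodes, tets, point_data, cell_data


def write_patient_model(path, mesh: BiventricularMesh, parcellation=None,
                        labels=None, fibers=None, extra_cell=None,
                        extra_point=None) -> None:
    """One-file-per-patient export: mesh + aha/tissue/fiber element arrays."""
    cell = {"ventricle": mesh.ventricle_tag.astype(float)}
    if parcellation is not None:
        cell["aha"] = parcellation.element_segment.astype(float)
    if labels is not None:
        cell["tissue"] = labels.labels.astype(float)
    if fibers is not None:
        cell["fiber"] = fibers.directions
    if extra_cell:
        cell.update(extra_cell)
    write_vtk(path, mesh.nodes, mesh.tets, point_data=extra_point, cell_data=cell)


def write_tree(path, tree) -> None:
    """Serialize a conduction tree as an edge-list text file."""
    payload = {
        "v_purkinje": tree.v_purkinje,
        "root": int(tree.root),
        "nodes": tree.nodes.tolist(),
        "edges": tree.edges.tolist(),
        "terminals": tree.terminals.tolist(),
        "pmj_nodes": tree.pmj_nodes.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_tree(path):
    from .purkinje import PurkinjeTree

    d = json.loads(Path(path).read_text())
    nodes = np.asarray(d["nodes"])
    edges = np.asarray(d["edges"], dtype=np.int64)
    lengths = np.linalg.norm(nodes[edges[:, 1]] - nodes[edges[:, 0]], axis=1)
    return PurkinjeTree(
        nodes=nodes, edges=edges, edge_lengths=lengths, root=d["root"],
        terminals=np.asarray(d["terminals"], dtype=np.int64),
        pmj_nodes=np.asarray(d["pmj_nodes"], dtype=np.int64),
        v_purkinje=d["v_purkinje"],
    )


def write_ecg_csv(path, ecg) -> None:
    """Twelve-lead trace as CSV: time column plus one column per lead."""
    from .ecg import LEAD_NAMES

    df = pd.DataFrame({"time_ms": ecg.time})
    for n in LEAD_NAMES:
        df[n] = ecg.leads[n]
    df.to_csv(path, index=False)


def write_model(path, model: LRModel) -> None:
    """Trained classifier as structured text (YAML)."""
    payload = {
        "features": list(model.features),
        "coef": [float(c) for c in model.coef],
        "intercept": float(model.intercept),
        "means": {k: float(v) for k, v in model.means.items()},
        "sds": {k: float(v) for k, v in model.sds.items()},
        "cutoff": float(model.cutoff),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_model(path) -> LRModel:
    d = yaml.safe_load(Path(path).read_text())
    return LRModel(
        features=d["features"],
        coef=np.asarray(d["coef"], dtype=float),
        intercept=d["intercept"],
        means=pd.Series(d["means"]),
        sds=pd.Series(d["sds"]),
        cutoff=d["cutoff"],
    )


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping, for provenance stamps."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
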