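"""Shared fixtures.

Simulation fixtures are session-scoped and deliberately coarse (5-6 mm node
spacing) so the whole suite runs in minutes on one CPU; accuracy-sensitive
checks build their own structured slab meshes instead.
"""

import numpy as np
import pytest

from crtopt.anatomy import (
    GeometryParams,
    assign_fibers,
    generate_biventricular_mesh,
    label_tissue,
    parcellate_aha,
)
from crtopt.eikonal import ConductionModel, simulate_lbbb
from crtopt.purkinje import generate_purkinje_tree


@pytest.fixture(scope="session")
def mesh():
    """Default-geometry mesh at moderate resolution."""
    return generate_biventricular_mesh(GeometryParams(spacing=4.0), seed=0)


@pytest.fixture(scope="session")
def coarse_mesh():
    return generate_biventricular_mesh(GeometryParams(spacing=6.0), seed=0)


@pytest.fixture(scope="session")
def fibers(mesh):
    return assign_fibers(mesh)


@pytest.fixture(scope="session")
def parcellation(mesh):
    return parcellate_aha(mesh)


@pytest.fixture(scope="session")
def healthy_labels(mesh, parcellation):
    return label_tissue(mesh, parcellation)


@pytest.fixture(scope="session")
def conduction():
    return ConductionModel()


@pytest.fixture(scope="session")
def tree(mesh):
    return generate_purkinje_tree(mesh, seed=3)


@pytest.fixture(scope="session")
def lbbb_map(mesh, fibers, conduction, tree):
    return simulate_lbbb(mesh, fibers, conduction, tree)


@pytest.fixture(scope="session")
def rv_apex_site(mesh):
    from crtopt.anatomy import SURF_RV_ENDO

    rv = mesh.surface_nodes(SURF_RV_ENDO)
    return mesh.nodes[rv[np.argmin(mesh.nodes[rv][:, 2])]]


@pytest.fixture(scope="session")
def lateral_site(parcellation):
    return parcellation.epi_centroids[12]
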