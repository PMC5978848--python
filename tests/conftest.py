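"""Shared fixtures: geometries and BEM operators are expensive, so the
cheap single-chamber shell bundle and the default study context are built
once per session."""

from __future__ import annotations

import numpy as np
import pytest

from edlimaging import (
    BEMSolver,
    StudyConfig,
    VolumeConductorModel,
    build_study_context,
    build_torso,
    build_ventricle,
    fra_candidates,
    geodesic_graph,
    surface_laplacian,
    transmural_pairs,
)
from edlimaging.geometry import _ellipsoid_mesh


@pytest.fixture(scope="session")
def shell_ventricle():
    return build_ventricle(kind="shell", resolution=6.0)


@pytest.fixture(scope="session")
def shell_vcm(shell_ventricle):
    return build_torso(shell_ventricle)


@pytest.fixture(scope="session")
def shell_solver(shell_vcm):
    return BEMSolver(shell_vcm)


@pytest.fixture(scope="session")
def shell_transfer(shell_solver):
    return shell_solver.edl_transfer()


@pytest.fixture(scope="session")
def shell_graph(shell_vcm):
    vent = shell_vcm.ventricle
    return geodesic_graph(vent.surface,
                          transmural_pairs(vent.surface, vent.sampling))


@pytest.fixture(scope="session")
def shell_laplacian(shell_vcm):
    return surface_laplacian(shell_vcm.ventricle.surface)


@pytest.fixture(scope="session")
def shell_maps(shell_graph):
    return fra_candidates(shell_graph)


@pytest.fixture(scope="session")
def shell_leadfield(shell_solver, shell_vcm):
    return shell_solver.dipole_leadfield(shell_vcm.ventricle.sampling.points)


@pytest.fixture(scope="session")
def default_ctx():
    """Study context at the default ~1500-node biventricular geometry."""
    return build_study_context(StudyConfig())


def sphere_vcm(subdivisions: int, radius: float = 1.0,
               sigma: float = 1.0) -> VolumeConductorModel:
    """Homogeneous sphere conductor with every vertex an electrode."""
    s = _ellipsoid_mesh((radius,) * 3, (0, 0, 0), subdivisions, "thorax")
    nodes = np.arange(s.n_vertices)
    return VolumeConductorModel([(s, sigma, 0.0)], s.vertices[nodes],
                                nodes, 0)


@pytest.fixture(scope="session")
def unit_sphere_solver():
    return BEMSolver(sphere_vcm(3))
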