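"""Shared fixtures: meshes, assembled systems and one default strike run.

The default 10 ms explicit run (~970-element orbit, ~40k steps) costs a few
seconds, so it is computed once per session and shared by the analysis,
pipeline and acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import orbishock as ob


@pytest.fixture(scope="session")
def material() -> ob.Material:
    return ob.Material()


@pytest.fixture(scope="session")
def default_mesh() -> ob.ShellMesh:
    return ob.generate_orbit()


@pytest.fixture(scope="session")
def coarse_mesh() -> ob.ShellMesh:
    return ob.generate_orbit(
        dataclasses.replace(ob.OrbitParams(), target_elements=200)
    )


@pytest.fixture(scope="session")
def coarse_system(coarse_mesh, material) -> ob.GlobalSystem:
    return ob.assemble(coarse_mesh, material)


@pytest.fixture(scope="session")
def default_system(default_mesh, material) -> ob.GlobalSystem:
    return ob.assemble(default_mesh, material)


@pytest.fixture(scope="session")
def default_history(default_system, default_mesh) -> ob.DisplacementHistory:
    case = ob.default_strike_load(default_mesh)
    return ob.integrate(default_system, case, ob.TimeIntegrationConfig())


@pytest.fixture(scope="session")
def default_report(default_history, default_mesh, material) -> ob.WaveReport:
    return ob.wave_report(default_history, default_mesh, material)


def rigid_body_modes(points: np.ndarray) -> list[np.ndarray]:
    """Six generalized rigid-body motions of a node set (6 dofs per node)."""
    modes = []
    for ax in range(3):
        m = np.zeros((len(points), 6))
        m[:, ax] = 1.0
        modes.append(m.ravel())
    for ax in range(3):
        axis = np.zeros(3)
        axis[ax] = 1.0
        m = np.zeros((len(points), 6))
        for i, p in enumerate(points):
            m[i, :3] = np.cross(axis, p)
            m[i, 3:] = axis
        modes.append(m.ravel())
    return modes
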