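"""Shared fixtures: small analytic meshes generated at test time."""

import numpy as np
import pytest

from planktomesh import TriangleMesh, make_icosphere


def unit_cube() -> TriangleMesh:
    """Unit cube with outward-oriented faces: SA = 6, V = 1."""
    v = np.array([
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ], dtype=float)
    f = np.array([
        [0, 2, 1], [0, 3, 2],  # bottom (z=0), normal -z
        [4, 5, 6], [4, 6, 7],  # top (z=1), normal +z
        [0, 1, 5], [0, 5, 4],  # y=0, normal -y
        [1, 2, 6], [1, 6, 5],  # x=1, normal +x
        [2, 3, 7], [2, 7, 6],  # y=1, normal +y
        [3, 0, 4], [3, 4, 7],  # x=0, normal -x
    ])
    return TriangleMesh(v, f, name="unit_cube")


@pytest.fixture
def cube() -> TriangleMesh:
    return unit_cube()


@pytest.fixture(scope="session")
def icosphere_r5():
    """Radius-5 icosphere at 4 subdivisions (5120 faces), built once."""
    return make_icosphere(5.0, 4)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
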