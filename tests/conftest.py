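"""Shared fixtures and independent oracles.

Expensive pathway builds are session-scoped; the quaternion superposition
oracle (Horn's closed form, a different algorithm family from the SVD-based
implementation under test) lives here so several test modules can use it.
"""

from __future__ import annotations

import numpy as np
import pytest

from tanm import (
    HingeSpec,
    TanmConfig,
    build_transition_path,
    default_test_system,
    make_two_state_hinge,
    map_common_residues,
)


@pytest.fixture(scope="session")
def hinge_system():
    """Canonical two-state hinge: 30 residues/arm, 60° vs 140°, no noise."""
    return default_test_system()


@pytest.fixture(scope="session")
def hinge_path(hinge_system):
    a, b, mapping = hinge_system
    return build_transition_path(a, b, mapping)


@pytest.fixture(scope="session")
def small_system():
    """Cheaper hinge for tests that rebuild pathways repeatedly."""
    a, b = make_two_state_hinge(
        HingeSpec(n_per_arm=10, hinge_angle_a=70.0, hinge_angle_b=130.0)
    )
    return a, b, map_common_residues(a, b)


@pytest.fixture(scope="session")
def small_path(small_system):
    a, b, mapping = small_system
    return build_transition_path(a, b, mapping)


def quaternion_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Minimal RMSD by Horn's quaternion method (closed form, no SVD)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    K = np.array(
        [
            [M[0, 0] + M[1, 1] + M[2, 2], M[1, 2] - M[2, 1], M[2, 0] - M[0, 2], M[0, 1] - M[1, 0]],
            [M[1, 2] - M[2, 1], M[0, 0] - M[1, 1] - M[2, 2], M[0, 1] + M[1, 0], M[0, 2] + M[2, 0]],
            [M[2, 0] - M[0, 2], M[0, 1] + M[1, 0], -M[0, 0] + M[1, 1] - M[2, 2], M[1, 2] + M[2, 1]],
            [M[0, 1] - M[1, 0], M[0, 2] + M[2, 0], M[1, 2] + M[2, 1], -M[0, 0] - M[1, 1] + M[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    resid = np.sum(P0 * P0) + np.sum(Q0 * Q0) - 2.0 * lam
    return float(np.sqrt(max(resid, 0.0) / P.shape[0]))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
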