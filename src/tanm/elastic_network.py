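"""Per-state anisotropic network model (ANM).

Each end state defines an elastic network over the common Cα index set: every
residue pair within a cutoff distance r_c of the reference conformation R⁰ is
joined by a Hookean spring of uniform force constant γ, giving the energy

    U(R) = (γ/2) Σ_{contacts (i,j)} (R_ij − R⁰_ij)²

with R_ij the instantaneous i–j distance.  The contact set is fixed once from
the reference structure and never recomputed for intermediate conformers, so
the two end-state surfaces genuinely differ in both topology and reference
distances.  With γ in kcal/(mol·Å²) and distances in Å, energies are kcal/mol.

Defaults follow common practice for Cα networks of large membrane proteins:
r_c = 13 Å, γ = 0.1 kcal/(mol·Å²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from .errors import DegenerateSpringError, DisconnectedNetworkError

__all__ = [
    "AnmModel",
    "ModeSet",
    "build_anm",
    "anm_energy",
    "anm_force",
    "anm_hessian",
    "compute_modes",
    "DEFAULT_CUTOFF",
    "DEFAULT_FORCE_CONSTANT",
]

DEFAULT_CUTOFF = 13.0  # Å
DEFAULT_FORCE_CONSTANT = 0.1  # kcal/(mol·Å²)

_MIN_SPRING_LENGTH = 1e-8  # Å; below this a spring direction is undefined


@dataclass(frozen=True)
class AnmModel:
    """One end state's elastic network.

    Attributes
    ----------
    ref_coords:
        n×3 reference conformation R⁰, Å.
    contacts:
        m×2 integer array of contact pairs, stored with i < j.
    cutoff:
        Contact cutoff r_c, Å.
    force_constant:
        Uniform spring constant γ, kcal/(mol·Å²).
    ref_distances:
        Per-contact reference distances R⁰_ij, Å.
    """

    ref_coords: np.ndarray
    contacts: np.ndarray
    cutoff: float
    force_constant: float
    ref_distances: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.ref_coords.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]


@dataclass(frozen=True)
class ModeSet:
    """Low-frequency normal modes of an ANM Hessian.

    ``eigenvalues`` are the ascending non-rigid eigenvalues, ``eigenvectors``
    the matching orthonormal 3n-component columns; the ``n_zero`` rigid-body
    modes (six for a connected 3-D network) are excluded.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int


def build_anm(
    structure_coords: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> AnmModel:
    """Build an ANM around a reference conformation.

    A pair (i, j) is a contact iff its reference distance satisfies
    R⁰_ij ≤ cutoff (boundary inclusive).  Coincident nodes are rejected:
    a zero-length spring has no direction.
    """
    coords = np.asarray(structure_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise ValueError("structure_coords must be n×3 with n ≥ 2")
    if cutoff <= 0 or force_constant <= 0:
        raise ValueError("cutoff and force_constant must be positive")
    d = pdist(coords)
    iu, ju = np.triu_indices(coords.shape[0], k=1)
    if d.min() < _MIN_SPRING_LENGTH:
        k = int(np.argmin(d))
        raise DegenerateSpringError(
            f"nodes {iu[k]} and {ju[k]} coincide (distance {d[k]:.2e} Å)"
        )
    mask = d <= cutoff
    contacts = np.column_stack([iu[mask], ju[mask]])
    return AnmModel(
        ref_coords=coords.copy(),
        contacts=contacts,
        cutoff=float(cutoff),
        force_constant=float(force_constant),
        ref_distances=d[mask].copy(),
    )


def _contact_vectors(model: AnmModel, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i, j = model.contacts[:, 0], model.contacts[:, 1]
    diff = coords[i] - coords[j]
    return diff, np.linalg.norm(diff, axis=1)


def anm_energy(model: AnmModel, coords: np.ndarray) -> float:
    """Evaluate U(R) = (γ/2) Σ (R_ij − R⁰_ij)² in kcal/mol."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != model.ref_coords.shape:
        raise ValueError(f"coords shape {coords.shape} != {model.ref_coords.shape}")
    _, r = _contact_vectors(model, coords)
    dev = r - model.ref_distances
    return 0.5 * model.force_constant * float(dev @ dev)


def anm_force(model: AnmModel, coords: np.ndarray) -> np.ndarray:
    """Analytic force −∂U/∂R, kcal/(mol·Å), shape n×3.

    The contribution of contact (i, j) to node i is
    −γ (R_ij − R⁰_ij)(R_i − R_j)/R_ij.  Because U is invariant under rigid
    motions the total force and the net torque about the centroid vanish.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != model.ref_coords.shape:
        raise ValueError(f"coords shape {coords.shape} != {model.ref_coords.shape}")
    diff, r = _contact_vectors(model, coords)
    if r.min() < _MIN_SPRING_LENGTH:
        k = int(np.argmin(r))
        i, j = model.contacts[k]
        raise DegenerateSpringError(
            f"contacting nodes {i} and {j} nearly coincide (distance {r[k]:.2e} Å)"
        )
    coef = -model.force_constant * (r - model.ref_distances) / r
    contrib = coef[:, None] * diff
    force = np.zeros_like(coords)
    np.add.at(force, model.contacts[:, 0], contrib)
    np.add.at(force, model.contacts[:, 1], -contrib)
    return force


def anm_hessian(model: AnmModel) -> np.ndarray:
    """Second derivative of U at the reference conformation (3n×3n).

    At R = R⁰ each contact contributes the rank-one block γ êêᵀ along its
    unit bond vector ê, accumulated with the usual network sign pattern.  The
    result is symmetric, positive semi-definite, and annihilates uniform
    translations (3×3 superblock row sums vanish).
    """
    n = model.n_nodes
    H = np.zeros((3 * n, 3 * n))
    i, j = model.contacts[:, 0], model.contacts[:, 1]
    e = (model.ref_coords[i] - model.ref_coords[j]) / model.ref_distances[:, None]
    blocks = model.force_constant * np.einsum("ka,kb->kab", e, e)
    for k in range(model.n_contacts):
        bi, bj = 3 * i[k], 3 * j[k]
        B = blocks[k]
        H[bi : bi + 3, bi : bi + 3] += B
        H[bj : bj + 3, bj : bj + 3] += B
        H[bi : bi + 3, bj : bj + 3] -= B
        H[bj : bj + 3, bi : bi + 3] -= B
    return H


def _assert_connected(model: AnmModel) -> None:
    n = model.n_nodes
    i, j = model.contacts[:, 0], model.contacts[:, 1]
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise DisconnectedNetworkError(
            f"contact graph has {n_comp} components (sizes {sizes.tolist()})"
        )


def compute_modes(model: AnmModel, n_modes: int | None = None) -> ModeSet:
    """Normal modes of the ANM Hessian, rigid-body modes excluded.

    Eigenvalues below 1e-8 × the largest eigenvalue are flagged as rigid-body
    (zero) modes; for a connected three-dimensional network there are exactly
    six.  The returned modes are the ``n_modes`` lowest non-rigid eigenpairs
    (all of them when ``n_modes`` is None), ascending by eigenvalue.
    """
    _assert_connected(model)
    H = anm_hessian(model)
    evals, evecs = np.linalg.eigh(H)
    threshold = 1e-8 * float(np.max(np.abs(evals)))
    n_zero = int(np.sum(evals < threshold))
    lo = n_zero
    hi = len(evals) if n_modes is None else min(len(evals), lo + n_modes)
    return ModeSet(
        eigenvalues=evals[lo:hi].copy(),
        eigenvectors=evecs[:, lo:hi].copy(),
        n_zero=n_zero,
    )
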