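"""Cusp two-state potential built from the two end-state ANMs.

The two surfaces U_A(R) and U_B(R) are mixed with the cusp rule

    U(R) = ½ (U_A + U_B − √((U_A − U_B)²)) = min(U_A, U_B),

where the square root of the squared gap is implemented as an absolute value
to avoid cancellation noise.  The set of configurations with U_A = U_B is the
cusp hypersurface; the transition state is the minimum of U restricted to it.
Both end-state references are zero-energy minima of U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic_network import AnmModel, anm_energy

__all__ = [
    "TwoStatePotential",
    "EnergyTriple",
    "two_state_energy",
    "energy_gap",
    "on_cusp",
    "active_surface",
    "DEFAULT_EPS_CUSP",
]

DEFAULT_EPS_CUSP = 5e-5  # kcal/mol; |U_A − U_B| below this counts as "on the cusp"


@dataclass(frozen=True)
class TwoStatePotential:
    """Paired end-state ANMs over the same common residue index set.

    ``model_b`` is expected to be built from B's coordinates after rigid
    superposition onto A's frame, so both surfaces live in one frame.
    """

    model_a: AnmModel
    model_b: AnmModel

    def __post_init__(self) -> None:
        if self.model_a.n_nodes != self.model_b.n_nodes:
            raise ValueError(
                f"node count mismatch: {self.model_a.n_nodes} vs {self.model_b.n_nodes}"
            )

    @property
    def n_nodes(self) -> int:
        return self.model_a.n_nodes


@dataclass(frozen=True)
class EnergyTriple:
    """Energies of one conformation on both surfaces, kcal/mol.

    ``u`` is the mixed two-state energy min(u_a, u_b); ``gap`` = u_a − u_b.
    """

    u_a: float
    u_b: float
    u: float
    gap: float


def two_state_energy(potential: TwoStatePotential, coords: np.ndarray) -> EnergyTriple:
    """Evaluate both surfaces and the cusp-mixed energy at ``coords``."""
    u_a = anm_energy(potential.model_a, coords)
    u_b = anm_energy(potential.model_b, coords)
    u = 0.5 * (u_a + u_b - abs(u_a - u_b))
    return EnergyTriple(u_a=u_a, u_b=u_b, u=u, gap=u_a - u_b)


def energy_gap(potential: TwoStatePotential, coords: np.ndarray) -> float:
    """U_A − U_B at ``coords``; its sign selects the lower surface."""
    return anm_energy(potential.model_a, coords) - anm_energy(potential.model_b, coords)


def on_cusp(
    potential: TwoStatePotential, coords: np.ndarray, eps_cusp: float = DEFAULT_EPS_CUSP
) -> bool:
    """True iff |U_A − U_B| ≤ eps_cusp (absolute tolerance, kcal/mol)."""
    if eps_cusp <= 0:
        raise ValueError("eps_cusp must be positive")
    return abs(energy_gap(potential, coords)) <= eps_cusp


def active_surface(
    potential: TwoStatePotential, coords: np.ndarray, eps_cusp: float = DEFAULT_EPS_CUSP
) -> str:
    """Which surface drives a descent step: 'CUSP', 'A' or 'B'."""
    if eps_cusp <= 0:
        raise ValueError("eps_cusp must be positive")
    gap = energy_gap(potential, coords)
    if abs(gap) <= eps_cusp:
        return "CUSP"
    return "A" if gap < 0 else "B"
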