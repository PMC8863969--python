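"""Synthetic two-state structures.

The pathway machinery assumes two well-defined minima separated by a large
hinge/closure motion — the geometry of transporters that alternate between
inward- and outward-facing states.  These generators emulate exactly that at
desk scale: two internally rigid helical Cα arms sharing a vertex, opened at
a different hinge angle in each state, with realistic consecutive-Cα spacing
(3.8 Å) so the default 13 Å cutoff produces protein-like contact densities
and the two states genuinely differ in contact topology near the hinge.

The arms are ideal α-helix traces (2.3 Å radius, 1.5 Å rise, ≈99.1° twist
per residue, uniformly rescaled so consecutive Cα sit ``spacing`` apart)
rather than straight lines for a physical reason: a collinear bead chain has
zero quadratic bending stiffness in a distance-based elastic network, which
would make each end state's minimum degenerate along the hinge coordinate —
local bending near the vertex could satisfy every cross-arm contact without
moving the arms.  The helical trace triangulates its own contacts, so each
arm is genuinely stiff and each end state is an isolated minimum of its own
network, as for a real protein fold.

All generators are pure functions of their spec, including the seed; the
draw order (state A jitter first, then state B jitter) is part of the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PlacementError
from .structure_io import CaStructure, ResidueId, ResidueMapping, map_common_residues

__all__ = [
    "HingeSpec",
    "make_two_state_hinge",
    "make_random_two_state",
    "default_test_system",
]

CA_SPACING = 3.8  # Å, consecutive Cα distance in real protein chains
_MIN_SEPARATION = 3.0  # Å, excluded-volume floor for the random chain


@dataclass(frozen=True)
class HingeSpec:
    """Geometry of a two-arm hinge in its two states.

    ``hinge_angle_a``/``hinge_angle_b`` are the opening angles (degrees)
    between the arms in states A and B; ``noise_sigma`` adds independent
    isotropic Gaussian jitter (Å) to each state.
    """

    n_per_arm: int = 30
    spacing: float = CA_SPACING
    hinge_angle_a: float = 60.0
    hinge_angle_b: float = 140.0
    noise_sigma: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_per_arm < 5:
            raise ValueError("n_per_arm must be ≥ 5")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        for angle in (self.hinge_angle_a, self.hinge_angle_b):
            if not (0.0 <= angle <= 180.0):
                raise ValueError("hinge angles must lie in [0°, 180°]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")


# canonical α-helix Cα geometry, rescaled so the Cα–Cα chord equals `spacing`
_HELIX_RADIUS = 2.3  # Å
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = np.radians(99.1)  # per residue


def _helix_arm(n: int, spacing: float, axis: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Ideal helical Cα trace of ``n`` residues starting at the origin.

    The helix winds about ``axis`` with first radial direction ``p1``;
    point k=0 (the shared vertex) is subtracted out so every consecutive
    pair, including vertex→first arm residue, sits exactly one Cα chord
    apart.
    """
    chord = np.hypot(2.0 * _HELIX_RADIUS * np.sin(_HELIX_TWIST / 2.0), _HELIX_RISE)
    scale = spacing / chord
    radius = _HELIX_RADIUS * scale
    rise = _HELIX_RISE * scale
    p2 = np.cross(axis, p1)
    k = np.arange(n + 1)
    pts = (
        np.outer(k * rise, axis)
        + radius * np.outer(np.cos(k * _HELIX_TWIST), p1)
        + radius * np.outer(np.sin(k * _HELIX_TWIST), p2)
    )
    return (pts - pts[0])[1:]


def _hinge_coords(n_per_arm: int, spacing: float, angle_deg: float) -> np.ndarray:
    """Two helical arms meeting at the origin, axes opened by ``angle_deg``."""
    half = np.radians(angle_deg) / 2.0
    d1 = np.array([np.cos(half), np.sin(half), 0.0])
    d2 = np.array([np.cos(half), -np.sin(half), 0.0])
    p1 = np.array([np.sin(half), -np.cos(half), 0.0])  # ⊥ d1, rotates with it
    p2 = np.array([-np.sin(half), -np.cos(half), 0.0])  # ⊥ d2, mirror frame
    arm1 = _helix_arm(n_per_arm, spacing, d1, p1)
    arm2 = _helix_arm(n_per_arm, spacing, d2, p2)
    coords = np.empty((2 * n_per_arm + 1, 3))
    coords[:n_per_arm] = arm1[::-1]  # chain runs tip → vertex → tip
    coords[n_per_arm] = 0.0
    coords[n_per_arm + 1 :] = arm2
    return coords


def _as_structure(coords: np.ndarray) -> CaStructure:
    residues = [ResidueId("A", i + 1, "", "GLY") for i in range(coords.shape[0])]
    return CaStructure(residues, coords)


def make_two_state_hinge(spec: HingeSpec) -> tuple[CaStructure, CaStructure]:
    """Generate the two end states of a hinge system.

    Both states share residue numbering (chain A, 1..2·n_per_arm+1).  When
    ``noise_sigma`` > 0, each state receives an independent jitter draw from
    one generator seeded with ``spec.seed`` (state A drawn first).
    """
    coords_a = _hinge_coords(spec.n_per_arm, spec.spacing, spec.hinge_angle_a)
    coords_b = _hinge_coords(spec.n_per_arm, spec.spacing, spec.hinge_angle_b)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords_a = coords_a + rng.normal(0.0, spec.noise_sigma, coords_a.shape)
        coords_b = coords_b + rng.normal(0.0, spec.noise_sigma, coords_b.shape)
    return _as_structure(coords_a), _as_structure(coords_b)


def make_random_two_state(
    n: int, displacement_scale: float, seed: int
) -> tuple[CaStructure, CaStructure]:
    """Self-avoiding random chain plus a smooth low-frequency deformation.

    State A is grown step by step with consecutive spacing 3.8 Å and a hard
    3.0 Å floor on all other inter-residue distances.  State B adds a smooth
    displacement field — three low-order cosine modes along the chain with
    random amplitudes and phases — rescaled to an exact RMS amplitude of
    ``displacement_scale`` Å.
    """
    if n < 4:
        raise ValueError("n must be ≥ 4")
    if displacement_scale < 0:
        raise ValueError("displacement_scale must be ≥ 0")
    rng = np.random.default_rng(seed)
    for _ in range(50):  # whole-chain restarts
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(100):
                vec = rng.normal(size=3)
                vec /= np.linalg.norm(vec)
                cand = coords[i - 1] + CA_SPACING * vec
                if i > 1:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if d.min() < _MIN_SEPARATION:
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise PlacementError("self-avoiding chain placement failed after 50 restarts")
    field = np.zeros((n, 3))
    t = (np.arange(n) + 0.5) / n
    for mode in (1, 2, 3):
        amp = rng.normal(size=3)
        phase = rng.uniform(0, 2 * np.pi)
        field += np.outer(np.cos(np.pi * mode * t + phase), amp)
    if displacement_scale > 0:
        rms = np.sqrt(np.mean(np.sum(field**2, axis=1)))
        field *= displacement_scale / rms
    else:
        field[:] = 0.0
    return _as_structure(coords), _as_structure(coords + field)


def default_test_system() -> tuple[CaStructure, CaStructure, ResidueMapping]:
    """Canonical hinge fixture: 30 residues per arm, 60° vs 140°, no noise."""
    a, b = make_two_state_hinge(HingeSpec())
    return a, b, map_common_residues(a, b)
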