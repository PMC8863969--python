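"""Minimum-energy transition pathway on the two-state cusp potential.

The pathway construction runs in five stages:

1. rigid-body (Kabsch) superposition of end state B onto A over the common
   residue set;
2. linear interpolation of M images between the superposed ends;
3. location of the image (or bisected point between two images) where the two
   surface energies cross — the seed on the cusp hypersurface;
4. iterative refinement of the transition state: one steepest-descent step on
   each surface from the current cusp point, then bisection along the segment
   between the two stepped points back onto the cusp; step sizes shrink when
   the segment fails to bracket the cusp or the cusp energy rises;
5. two independent steepest descents from the transition state, one per
   surface, collecting conformers spaced by a user RMSD; the reversed A
   descent, the transition state, and the B descent form the path.

The algorithm is deterministic: given the same inputs and configuration it
produces bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .elastic_network import (
    DEFAULT_CUTOFF,
    DEFAULT_FORCE_CONSTANT,
    AnmModel,
    anm_energy,
    anm_force,
    build_anm,
)
from .errors import (
    ConfigError,
    CuspNotFoundError,
    EndpointRecoveryError,
    MaxIterationsError,
    StepUnderflowError,
    TanmError,
)
from .structure_io import CaStructure, ResidueId, ResidueMapping, map_common_residues
from .two_state_potential import (
    DEFAULT_EPS_CUSP,
    EnergyTriple,
    TwoStatePotential,
    two_state_energy,
)

__all__ = [
    "BRANCH_A",
    "BRANCH_TS",
    "BRANCH_B",
    "BRANCH_LINEAR",
    "TanmConfig",
    "Conformer",
    "TransitionPath",
    "kabsch",
    "superpose",
    "rmsd_no_superposition",
    "interpolate_images",
    "locate_cusp_image",
    "refine_transition_state",
    "descend_to_minimum",
    "build_transition_path",
    "linear_path",
]

BRANCH_A = "A_DESCENT"
BRANCH_TS = "TRANSITION_STATE"
BRANCH_B = "B_DESCENT"
BRANCH_LINEAR = "LINEAR"

_STEP_FLOOR = 1e-12
_MAX_BISECTIONS = 200


@dataclass(frozen=True)
class TanmConfig:
    """Run configuration.

    Parameters
    ----------
    cutoff, force_constant:
        ANM parameters shared by both surfaces (Å; kcal/(mol·Å²)).
    n_images:
        Number M of linearly interpolated images, end states included.  Only
        the cusp-crossing seed depends on M, so the refined transition state
        is insensitive to it.
    eps_cusp:
        ε†, kcal/mol — energy-gap tolerance defining "on the cusp".
    eps_conv:
        ε_conv, kcal/mol — convergence tolerance on the cusp energy between
        successive transition-state iterations.
    step_a, step_b:
        Initial steepest-descent step sizes on surfaces A and B.
    step_shrink:
        Multiplicative step reduction applied when a trial step fails.
    collect_rmsd:
        Conformer collection spacing along each descent, Å.
    max_ts_iterations, max_descent_iterations:
        Iteration budgets for the transition-state search and each descent.
    descent_force_tol:
        Descent stops when the force max-norm falls below this,
        kcal/(mol·Å).
    random_seed:
        Recorded for provenance; the core algorithm draws no random numbers.
    """

    cutoff: float = DEFAULT_CUTOFF
    force_constant: float = DEFAULT_FORCE_CONSTANT
    n_images: int = 50
    eps_cusp: float = DEFAULT_EPS_CUSP
    eps_conv: float = 1e-4
    step_a: float = 1.0
    step_b: float = 1.0
    step_shrink: float = 0.5
    collect_rmsd: float = 0.1
    max_ts_iterations: int = 10000
    max_descent_iterations: int = 200000
    descent_force_tol: float = 1e-6
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cutoff", "force_constant", "eps_cusp", "eps_conv",
                     "step_a", "step_b", "collect_rmsd", "descent_force_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_images < 3:
            raise ConfigError("n_images must be ≥ 3")
        if not (0 < self.step_shrink < 1):
            raise ConfigError("step_shrink must lie in (0, 1)")
        if self.max_ts_iterations < 1 or self.max_descent_iterations < 1:
            raise ConfigError("iteration budgets must be ≥ 1")

    @classmethod
    def from_dict(cls, data: dict) -> "TanmConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TanmConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Conformer:
    """One point along a pathway: coordinates, energies, branch label."""

    coords: np.ndarray
    energies: EnergyTriple
    branch: str
    index: int


@dataclass
class TransitionPath:
    """Ordered conformers from end A through the transition state to end B.

    ``coords_a`` / ``coords_b`` are the end-state coordinates over the common
    residue set, with B already superposed onto A's frame; ``residues`` are
    the matching identifiers taken from structure A.  ``potential`` allows all
    cached energies to be re-evaluated from coordinates.
    """

    conformers: list[Conformer]
    ts_index: int
    config: TanmConfig
    iterations_used: int
    rotation: np.ndarray
    translation: np.ndarray
    initial_rmsd: float
    coords_a: np.ndarray
    coords_b: np.ndarray
    residues: list[ResidueId]
    potential: TwoStatePotential
    endpoint_rmsd_a: float = 0.0
    endpoint_rmsd_b: float = 0.0

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def ts(self) -> Conformer:
        return self.conformers[self.ts_index]

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.conformers])

    def as_structure(self, k: int) -> CaStructure:
        return CaStructure(list(self.residues), self.conformers[k].coords.copy())


def rmsd_no_superposition(x: np.ndarray, y: np.ndarray) -> float:
    """Plain coordinate RMSD in a shared frame (no refitting), Å."""
    d = np.asarray(x, float) - np.asarray(y, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix with det +1, translation, minimized RMSD) such
    that ``mobile @ R.T + t`` best fits ``target``.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share an n×3 shape")
    if P.shape[0] < 3:
        raise TanmError("superposition needs at least 3 mapped residues")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if (
        np.linalg.matrix_rank(P0, tol=1e-9) < 2
        or np.linalg.matrix_rank(Q0, tol=1e-9) < 2
    ):
        raise TanmError("degenerate (collinear or coincident) point sets")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = qc - R @ pc
    # residuals computed directly: the rssd shortcut loses ~1e-7 Å to
    # cancellation on near-exact rigid matches
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    return R, t, rmsd


def superpose(
    mobile: CaStructure,
    target: CaStructure,
    mapping: ResidueMapping | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Superpose a structure onto a target over mapped residues.

    ``mapping`` must pair ``mobile`` (first column) with ``target`` (second
    column); by default residues with identical identifiers are paired.  The
    rigid transform is fitted on the mapped subset and applied to all mobile
    coordinates.  Returns (transformed coords, rotation, translation, rmsd).
    """
    if mapping is None:
        mapping = map_common_residues(mobile, target)
    R, t, rmsd = kabsch(
        mobile.coords[mapping.a_indices], target.coords[mapping.b_indices]
    )
    return mobile.coords @ R.T + t, R, t, rmsd


def interpolate_images(
    coords_a: np.ndarray, coords_b: np.ndarray, m: int
) -> list[np.ndarray]:
    """M images along the straight line from A to B, ends included."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("end-state coordinate shapes differ")
    if m < 3:
        raise ValueError("need at least 3 images")
    return [a + (k / (m - 1)) * (b - a) for k in range(m)]


def _bisect_gap(
    x0: np.ndarray,
    x1: np.ndarray,
    g0: float,
    g1: float,
    potential: TwoStatePotential,
    eps_cusp: float,
) -> np.ndarray:
    """Bisect the straight segment [x0, x1] for |U_A − U_B| ≤ eps_cusp.

    Assumes the gap changes sign across the segment (or an endpoint is
    already within tolerance).  Returns the bisection point after at most
    200 halvings.
    """
    if abs(g0) <= eps_cusp:
        return x0
    if abs(g1) <= eps_cusp:
        return x1
    lo, hi = x0, x1
    glo = g0
    mid = 0.5 * (lo + hi)
    for _ in range(_MAX_BISECTIONS):
        mid = 0.5 * (lo + hi)
        gm = two_state_energy(potential, mid).gap
        if abs(gm) <= eps_cusp:
            return mid
        if (gm < 0) == (glo < 0):
            lo, glo = mid, gm
        else:
            hi = mid
    return mid


def locate_cusp_image(
    images: Sequence[np.ndarray],
    potential: TwoStatePotential,
    eps_cusp: float = DEFAULT_EPS_CUSP,
) -> np.ndarray:
    """Find the cusp seed R†(0) along an interpolated image series.

    If some image already has |gap| ≤ ε† the one with the smallest |gap| is
    returned (ties go to the lowest index); otherwise the consecutive image
    pair bracketing the sign change is bisected.  If the gap never changes
    sign the two end states order the surfaces identically everywhere along
    the line and no cusp crossing exists.
    """
    if len(images) < 3:
        raise ValueError("need at least 3 images")
    gaps = np.array([two_state_energy(potential, x).gap for x in images])
    within = np.abs(gaps) <= eps_cusp
    if within.any():
        best = int(np.argmin(np.where(within, np.abs(gaps), np.inf)))
        return np.asarray(images[best], float).copy()
    signs = np.sign(gaps)
    crossings = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    if len(crossings) == 0:
        raise CuspNotFoundError(
            "energy gap never changes sign along the image series "
            f"(endpoint gaps {gaps[0]:.6g} and {gaps[-1]:.6g} kcal/mol)"
        )
    k = int(crossings[0])
    return _bisect_gap(
        np.asarray(images[k], float),
        np.asarray(images[k + 1], float),
        gaps[k],
        gaps[k + 1],
        potential,
        eps_cusp,
    )


def refine_transition_state(
    start: np.ndarray,
    potential: TwoStatePotential,
    config: TanmConfig,
) -> tuple[np.ndarray, EnergyTriple, int]:
    """Minimize the two-state energy restricted to the cusp hypersurface.

    From the current cusp point R†(n), one steepest-descent step is taken on
    each surface — R^A = R† + s_A f_A, R^B = R† + s_B f_B — and the point on
    the segment [R^A, R^B] with |U_A − U_B| ≤ ε† becomes R†(n+1): each
    endpoint moved downhill on its own surface, so the segment brackets the
    cusp.  Iteration stops when the cusp energy changes by less than ε_conv.
    If the segment fails to bracket a sign change, or the energy rises by
    ε_conv or more, both step sizes shrink and the step is retried from the
    current point.
    """
    R = np.asarray(start, float).copy()
    e = two_state_energy(potential, R)
    if abs(e.gap) > config.eps_cusp:
        raise TanmError(
            f"start is off the cusp: |gap| = {abs(e.gap):.3g} > ε† = {config.eps_cusp:.3g}"
        )
    s_a, s_b = config.step_a, config.step_b
    for it in range(1, config.max_ts_iterations + 1):
        f_a = anm_force(potential.model_a, R)
        f_b = anm_force(potential.model_b, R)
        ra = R + s_a * f_a
        rb = R + s_b * f_b
        ga = two_state_energy(potential, ra).gap
        gb = two_state_energy(potential, rb).gap
        bracketed = (
            abs(ga) <= config.eps_cusp
            or abs(gb) <= config.eps_cusp
            or (ga < 0) != (gb < 0)
        )
        if bracketed:
            r_new = _bisect_gap(ra, rb, ga, gb, potential, config.eps_cusp)
            e_new = two_state_energy(potential, r_new)
            delta = e_new.u - e.u
            if abs(delta) < config.eps_conv:
                return r_new, e_new, it
            if delta < 0:
                R, e = r_new, e_new
                continue
        # spanned the saddle: shrink and retry from the breakpoint
        s_a *= config.step_shrink
        s_b *= config.step_shrink
        if s_a < _STEP_FLOOR or s_b < _STEP_FLOOR:
            raise StepUnderflowError(
                f"transition-state step size underflow at iteration {it}"
            )
    raise MaxIterationsError(
        f"transition-state search did not converge in {config.max_ts_iterations} iterations"
    )


def descend_to_minimum(
    start: np.ndarray,
    model: AnmModel,
    potential: TwoStatePotential,
    config: TanmConfig,
    branch: str = BRANCH_A,
    step_init: float | None = None,
) -> list[Conformer]:
    """Steepest descent on a single surface with RMSD-spaced collection.

    A trial step R + s·f is accepted only if the surface energy does not
    increase; otherwise s shrinks by ``step_shrink`` and the step is retried
    (after an accepted step s recovers towards its initial value, so an early
    shrink does not slow the whole descent).  Descent stops when the force
    max-norm drops below ``descent_force_tol``.  A per-step energy-decrement
    test is deliberately not used: on the soft collective modes that dominate
    large hinge motions it becomes tiny long before the minimum is reached.
    Collected conformers are the start, every iterate at least
    ``collect_rmsd`` from the previously collected one, and the final
    minimum; their single-surface energies are non-increasing.
    """
    R = np.asarray(start, float).copy()
    u = anm_energy(model, R)
    s_init = config.step_a if step_init is None else step_init
    s = s_init
    collected_coords: list[np.ndarray] = [R.copy()]
    last = R
    for _ in range(config.max_descent_iterations):
        f = anm_force(model, R)
        if np.max(np.abs(f)) < config.descent_force_tol:
            break
        while True:
            r_try = R + s * f
            u_try = anm_energy(model, r_try)
            if not np.isfinite(u_try):
                raise TanmError("non-finite energy during descent")
            if u_try <= u:
                break
            s *= config.step_shrink
            if s < _STEP_FLOOR:
                raise StepUnderflowError("descent step size underflow")
        R, u = r_try, u_try
        s = min(s / config.step_shrink, s_init)
        if rmsd_no_superposition(R, last) >= config.collect_rmsd:
            collected_coords.append(R.copy())
            last = R
    else:
        raise MaxIterationsError(
            f"descent did not converge in {config.max_descent_iterations} iterations"
        )
    if not np.array_equal(R, collected_coords[-1]):
        collected_coords.append(R.copy())
    return [
        Conformer(
            coords=x,
            energies=two_state_energy(potential, x),
            branch=branch,
            index=i,
        )
        for i, x in enumerate(collected_coords)
    ]


def build_transition_path(
    a: CaStructure,
    b: CaStructure,
    mapping: ResidueMapping | None = None,
    config: TanmConfig | None = None,
) -> TransitionPath:
    """Run the full pipeline from two end-state structures.

    Superposes B onto A over the mapped residues, builds both ANMs,
    interpolates images, locates and refines the transition state on the
    cusp, descends on each surface, and assembles the path as
    reverse(A descent) + [TS] + B descent.  Identical end states yield a
    single-conformer path with zero energy.
    """
    if config is None:
        config = TanmConfig()
    if mapping is None:
        mapping = map_common_residues(a, b)
    residues = [a.residues[i] for i in mapping.a_indices]
    coords_a = a.coords[mapping.a_indices].copy()
    mobile_b = b.coords[mapping.b_indices]
    R, t, initial_rmsd = kabsch(mobile_b, coords_a)
    coords_b = mobile_b @ R.T + t

    model_a = build_anm(coords_a, config.cutoff, config.force_constant)
    model_b = build_anm(coords_b, config.cutoff, config.force_constant)
    potential = TwoStatePotential(model_a, model_b)

    if initial_rmsd < 1e-9:
        conf = Conformer(
            coords=coords_a.copy(),
            energies=two_state_energy(potential, coords_a),
            branch=BRANCH_TS,
            index=0,
        )
        return TransitionPath(
            conformers=[conf], ts_index=0, config=config, iterations_used=0,
            rotation=R, translation=t, initial_rmsd=initial_rmsd,
            coords_a=coords_a, coords_b=coords_b, residues=residues,
            potential=potential,
        )

    images = interpolate_images(coords_a, coords_b, config.n_images)
    seed = locate_cusp_image(images, potential, config.eps_cusp)
    ts_coords, ts_energy, iterations = refine_transition_state(seed, potential, config)

    desc_a = descend_to_minimum(
        ts_coords, model_a, potential, config, BRANCH_A, config.step_a
    )
    desc_b = descend_to_minimum(
        ts_coords, model_b, potential, config, BRANCH_B, config.step_b
    )

    conformers: list[Conformer] = []
    for c in reversed(desc_a[1:]):  # minimum-A first, TS-adjacent last
        conformers.append(c)
    ts_index = len(conformers)
    conformers.append(
        Conformer(coords=ts_coords, energies=ts_energy, branch=BRANCH_TS, index=0)
    )
    conformers.extend(desc_b[1:])
    for i, c in enumerate(conformers):
        c.index = i

    # finite descent steps are torque-free individually but accumulate a tiny
    # net rigid rotation along a curved path (a geometric phase); the endpoint
    # test therefore compares best-fit RMSD, the frame-free measure.
    _, _, end_rmsd_a = kabsch(conformers[0].coords, coords_a)
    _, _, end_rmsd_b = kabsch(conformers[-1].coords, coords_b)
    if end_rmsd_a > config.collect_rmsd or end_rmsd_b > config.collect_rmsd:
        raise EndpointRecoveryError(
            "descents did not return to the end-state basins "
            f"(RMSD to A: {end_rmsd_a:.4f} Å, to superposed B: {end_rmsd_b:.4f} Å, "
            f"allowed {config.collect_rmsd} Å)"
        )
    return TransitionPath(
        conformers=conformers, ts_index=ts_index, config=config,
        iterations_used=iterations, rotation=R, translation=t,
        initial_rmsd=initial_rmsd, coords_a=coords_a, coords_b=coords_b,
        residues=residues, potential=potential,
        endpoint_rmsd_a=end_rmsd_a, endpoint_rmsd_b=end_rmsd_b,
    )


def linear_path(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    m: int,
    potential: TwoStatePotential,
) -> list[Conformer]:
    """Rigid linear-interpolation baseline with two-state energies.

    M straight-line images between the (already superposed) end states,
    evaluated on the cusp potential.  Its barrier is never lower than the
    refined transition-state energy on the same inputs.
    """
    if m < 2:
        raise ValueError("need at least 2 images")
    if m == 2:
        images = [np.asarray(coords_a, float), np.asarray(coords_b, float)]
    else:
        images = interpolate_images(coords_a, coords_b, m)
    return [
        Conformer(
            coords=np.asarray(x, float),
            energies=two_state_energy(potential, x),
            branch=BRANCH_LINEAR,
            index=i,
        )
        for i, x in enumerate(images)
    ]
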