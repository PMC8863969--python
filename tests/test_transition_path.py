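"""Superposition, image interpolation, transition-state search and descents."""

import numpy as np
import pytest

from tanm import (
    AnmModel,
    TanmConfig,
    TwoStatePotential,
    anm_energy,
    build_anm,
    build_transition_path,
    descend_to_minimum,
    interpolate_images,
    kabsch,
    linear_path,
    locate_cusp_image,
    refine_transition_state,
    rmsd_no_superposition,
    superpose,
    two_state_energy,
)
from tanm.errors import ConfigError, CuspNotFoundError, TanmError
from tanm.transition_path import BRANCH_TS

from conftest import quaternion_rmsd, random_rotation


# ---------------------------------------------------------------- superposition

def test_superpose_identity():
    rng = np.random.default_rng(31)
    coords = rng.uniform(0, 10, (7, 3))
    R, t, rmsd = kabsch(coords, coords)
    assert rmsd <= 1e-9
    np.testing.assert_allclose(R, np.eye(3), atol=1e-9)


def test_superpose_recovers_rigid_transform():
    rng = np.random.default_rng(32)
    target = rng.uniform(0, 10, (9, 3))
    for _ in range(5):
        Q = random_rotation(rng)
        moved = target @ Q.T + rng.uniform(-20, 20, 3)
        R, t, rmsd = kabsch(moved, target)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(moved @ R.T + t, target, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_superpose_matches_quaternion_oracle():
    rng = np.random.default_rng(33)
    for _ in range(20):
        P = rng.uniform(0, 10, (5, 3))
        Q = rng.uniform(0, 10, (5, 3))
        _, _, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-3)


def test_superpose_never_increases_rmsd():
    rng = np.random.default_rng(34)
    for _ in range(10):
        P = rng.uniform(0, 10, (6, 3))
        Q = P + rng.normal(0, 1.0, P.shape)
        _, _, rmsd = kabsch(P, Q)
        assert rmsd <= rmsd_no_superposition(P, Q) + 1e-12


def test_superpose_degenerate_inputs_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    cloud = np.random.default_rng(35).uniform(0, 5, (5, 3))
    with pytest.raises(TanmError, match="degenerate"):
        kabsch(line, cloud)
    with pytest.raises(TanmError, match="3 mapped"):
        kabsch(cloud[:2], cloud[:2])


def test_superpose_structure_wrapper(small_system):
    a, b, mapping = small_system
    moved, R, t, rmsd = superpose(b, a, mapping.swapped())
    assert rmsd <= rmsd_no_superposition(b.coords, a.coords)
    np.testing.assert_allclose(moved, b.coords @ R.T + t)


# ---------------------------------------------------------------- interpolation

def test_interpolation_endpoints_midpoint_and_linearity():
    rng = np.random.default_rng(36)
    a = rng.uniform(0, 10, (6, 3))
    b = a + rng.normal(0, 3.0, a.shape)
    images = interpolate_images(a, b, 3)
    np.testing.assert_array_equal(images[0], a)
    np.testing.assert_array_equal(images[-1], b)
    np.testing.assert_allclose(images[1], 0.5 * (a + b), atol=1e-12)
    images = interpolate_images(a, b, 11)
    per_res = np.linalg.norm(b - a, axis=1)
    for k, img in enumerate(images):
        np.testing.assert_allclose(
            np.linalg.norm(img - a, axis=1), (k / 10) * per_res, atol=1e-9
        )


# ------------------------------------------------------------------- toy models

def _two_node_potential(ref_a: float = 0.0, ref_b: float = 4.0):
    """Single spring with reference lengths ref_a / ref_b, γ = 0.1."""
    contacts = np.array([[0, 1]])
    model_a = AnmModel(
        ref_coords=np.array([[0.0, 0, 0], [ref_a, 0, 0]]),
        contacts=contacts, cutoff=13.0, force_constant=0.1,
        ref_distances=np.array([ref_a]),
    )
    model_b = AnmModel(
        ref_coords=np.array([[0.0, 0, 0], [ref_b, 0, 0]]),
        contacts=contacts, cutoff=13.0, force_constant=0.1,
        ref_distances=np.array([ref_b]),
    )
    return TwoStatePotential(model_a, model_b)


def _bond_conf(length: float) -> np.ndarray:
    return np.array([[0.0, 0, 0], [length, 0, 0]])


def test_cusp_seed_matches_dense_line_scan():
    # gap(r) = ½γ[(r−1)² − (r−3)²] = γ(2r−4): root exactly at r = 2
    pot = _two_node_potential(1.0, 3.0)
    images = interpolate_images(_bond_conf(1.0), _bond_conf(3.0), 7)
    seed = locate_cusp_image(images, pot, eps_cusp=5e-5)
    r_seed = np.linalg.norm(seed[1] - seed[0])
    ts = np.linspace(1.0, 3.0, 10**6)
    gaps = np.abs(0.1 * (2 * ts - 4))
    r_scan = ts[np.argmin(gaps)]
    assert r_seed == pytest.approx(r_scan, abs=2e-6)
    # symmetric toy: odd image count puts an image exactly on the cusp
    images = interpolate_images(_bond_conf(1.0), _bond_conf(3.0), 5)
    seed = locate_cusp_image(images, pot, eps_cusp=5e-5)
    assert np.linalg.norm(seed[1] - seed[0]) == pytest.approx(2.0, abs=1e-12)


def test_cusp_seed_postcondition_and_failure():
    pot = _two_node_potential(1.0, 3.0)
    images = interpolate_images(_bond_conf(1.2), _bond_conf(2.9), 9)
    seed = locate_cusp_image(images, pot, eps_cusp=5e-5)
    assert abs(two_state_energy(pot, seed).gap) <= 5e-5
    # both ends on the same side of the cusp: no crossing to find
    with pytest.raises(CuspNotFoundError):
        locate_cusp_image(
            interpolate_images(_bond_conf(0.2), _bond_conf(0.8), 9), pot, 5e-5
        )


def test_transition_state_of_single_spring_toy():
    """Cusp minimum of the 0 Å / 4 Å spring pair: bond d/2, energy ½γ(d/2)²."""
    pot = _two_node_potential(0.0, 4.0)
    cfg = TanmConfig()
    images = interpolate_images(_bond_conf(0.5), _bond_conf(4.0), 21)
    seed = locate_cusp_image(images, pot, cfg.eps_cusp)
    ts, energy, iterations = refine_transition_state(seed, pot, cfg)
    assert np.linalg.norm(ts[1] - ts[0]) == pytest.approx(2.0, abs=1e-3)
    assert energy.u == pytest.approx(0.2, abs=10 * cfg.eps_conv)
    # restarting from the converged point terminates immediately
    ts2, energy2, it2 = refine_transition_state(ts, pot, cfg)
    assert it2 <= 2
    assert energy2.u == pytest.approx(energy.u, abs=10 * cfg.eps_conv)


def test_refine_rejects_off_cusp_start():
    pot = _two_node_potential(0.0, 4.0)
    with pytest.raises(TanmError, match="off the cusp"):
        refine_transition_state(_bond_conf(0.5), pot, TanmConfig())


def _tri_coords(d12, d13, d23):
    x3 = (d12**2 + d13**2 - d23**2) / (2 * d12)
    y3 = np.sqrt(d13**2 - x3**2)
    return np.array([[0.0, 0, 0], [d12, 0, 0], [x3, y3, 0]])


def _triangle_grid_oracle(a_ref, b_ref, gamma=0.1):
    """Minimize U_A over the cusp in distance space (U_A = U_B is linear in
    d23 for equal spring constants, so the constraint solves in closed form).
    """
    def cusp_energy(d12, d13):
        rhs = -(
            (d12 - a_ref[0]) ** 2 - (d12 - b_ref[0]) ** 2
            + (d13 - a_ref[1]) ** 2 - (d13 - b_ref[1]) ** 2
        )
        d23 = (rhs / (b_ref[2] - a_ref[2]) + a_ref[2] + b_ref[2]) / 2
        u = 0.5 * gamma * (
            (d12 - a_ref[0]) ** 2 + (d13 - a_ref[1]) ** 2 + (d23 - a_ref[2]) ** 2
        )
        triangle = (d23 > 0) & (d23 < d12 + d13) & (d12 < d13 + d23) & (d13 < d12 + d23)
        return np.where(triangle, u, np.inf)

    g12, g13 = np.meshgrid(np.linspace(4, 7, 601), np.linspace(4, 7, 601))
    u = cusp_energy(g12, g13)
    k = np.unravel_index(np.argmin(u), u.shape)
    c12, c13 = g12[k], g13[k]
    g12, g13 = np.meshgrid(
        np.linspace(c12 - 0.01, c12 + 0.01, 201),
        np.linspace(c13 - 0.01, c13 + 0.01, 201),
    )
    return float(np.min(cusp_energy(g12, g13)))


def test_transition_state_of_triangle_matches_grid_search():
    a_ref = (4.0, 4.5, 5.0)
    b_ref = (6.0, 5.5, 6.5)
    A = _tri_coords(*a_ref)
    B = _tri_coords(*b_ref)
    R, t, _ = kabsch(B, A)
    pot = TwoStatePotential(build_anm(A, 20.0), build_anm(B @ R.T + t, 20.0))
    cfg = TanmConfig()
    seed = locate_cusp_image(
        interpolate_images(A, B @ R.T + t, 50), pot, cfg.eps_cusp
    )
    ts, energy, _ = refine_transition_state(seed, pot, cfg)
    oracle = _triangle_grid_oracle(np.array(a_ref), np.array(b_ref))
    assert energy.u == pytest.approx(oracle, abs=10 * cfg.eps_conv)


# --------------------------------------------------------------------- descents

def test_descent_from_reference_returns_single_conformer():
    model = build_anm(_bond_conf(3.0))
    pot = _two_node_potential(3.0, 4.0)
    out = descend_to_minimum(_bond_conf(3.0), model, pot, TanmConfig())
    assert len(out) == 1
    np.testing.assert_array_equal(out[0].coords, _bond_conf(3.0))


def test_descent_relaxes_stretched_spring():
    model = build_anm(_bond_conf(3.0))
    pot = _two_node_potential(3.0, 6.0)
    cfg = TanmConfig()
    out = descend_to_minimum(_bond_conf(4.0), model, pot, cfg)
    final = out[-1].coords
    assert np.linalg.norm(final[1] - final[0]) == pytest.approx(3.0, abs=1e-4)
    on_surface = [anm_energy(model, c.coords) for c in out]
    assert all(x >= y - 1e-12 for x, y in zip(on_surface, on_surface[1:]))


def test_descent_collection_spacing(hinge_path):
    """Consecutive collected conformers are at least collect_rmsd apart,
    except where each descent appends its final minimum (the two path ends)."""
    cfg = hinge_path.config
    coords = hinge_path.coords_array()
    inner = range(1, len(coords) - 2)
    for k in inner:
        assert rmsd_no_superposition(coords[k], coords[k + 1]) >= cfg.collect_rmsd - 1e-9


# ------------------------------------------------------------------ full builds

def test_identical_end_states_give_single_conformer(small_system):
    a, _, mapping = small_system
    path = build_transition_path(a, a, config=TanmConfig())
    assert len(path) == 1
    assert path.ts_index == 0
    assert path.conformers[0].branch == BRANCH_TS
    assert path.conformers[0].energies.u == 0.0


def test_hinge_path_structure(hinge_path):
    path = hinge_path
    assert path.conformers[path.ts_index].branch == BRANCH_TS
    us = [c.energies.u for c in path.conformers]
    assert np.argmax(us) == path.ts_index
    assert us[0] <= 1e-3 and us[-1] <= 1e-3
    # path continuity: consecutive conformers exceed the collection spacing
    # by at most one descent step (s · |f| in RMSD terms) — largest right at
    # the transition state, where the descending surface is steepest
    from tanm import anm_force

    coords = path.coords_array()
    n = coords.shape[1]
    s = max(path.config.step_a, path.config.step_b)

    def step_rmsd(k):
        branch = path.conformers[k].branch
        out = 0.0
        if branch != "B_DESCENT":
            out = max(out, s * np.linalg.norm(
                anm_force(path.potential.model_a, coords[k])) / np.sqrt(n))
        if branch != "A_DESCENT":
            out = max(out, s * np.linalg.norm(
                anm_force(path.potential.model_b, coords[k])) / np.sqrt(n))
        return out

    for k in range(len(coords) - 1):
        step = rmsd_no_superposition(coords[k], coords[k + 1])
        bound = 2 * path.config.collect_rmsd + max(step_rmsd(k), step_rmsd(k + 1))
        assert step <= bound + 1e-9
    assert path.iterations_used >= 1
    assert path.initial_rmsd > 5.0


def test_path_is_deterministic(small_system):
    a, b, mapping = small_system
    p1 = build_transition_path(a, b, mapping)
    p2 = build_transition_path(a, b, mapping)
    assert len(p1) == len(p2)
    for c1, c2 in zip(p1.conformers, p2.conformers):
        assert np.array_equal(c1.coords, c2.coords)
        assert c1.energies == c2.energies


def test_transition_state_insensitive_to_image_count(small_system):
    a, b, mapping = small_system
    u_ts = [
        build_transition_path(a, b, mapping, TanmConfig(n_images=m)).ts.energies.u
        for m in (20, 50)
    ]
    assert u_ts[0] == pytest.approx(u_ts[1], rel=1e-3)


# ---------------------------------------------------------------------- LI path

def test_linear_path_endpoints_and_barrier(small_path):
    path = small_path
    li = linear_path(path.coords_a, path.coords_b, 50, path.potential)
    assert li[0].energies.u_a == 0.0
    assert li[-1].energies.u_b == 0.0
    assert max(c.energies.u for c in li) >= path.ts.energies.u
    two = linear_path(path.coords_a, path.coords_b, 2, path.potential)
    assert len(two) == 2
    np.testing.assert_array_equal(two[0].coords, path.coords_a)
    np.testing.assert_array_equal(two[1].coords, path.coords_b)


# ----------------------------------------------------------------------- config

def test_config_validation_and_yaml(tmp_path):
    with pytest.raises(ConfigError):
        TanmConfig(n_images=2)
    with pytest.raises(ConfigError):
        TanmConfig(step_shrink=1.0)
    with pytest.raises(ConfigError):
        TanmConfig(eps_cusp=-1.0)
    f = tmp_path / "run.yaml"
    f.write_text("cutoff: 12.0\nn_images: 30\n")
    cfg = TanmConfig.from_yaml(f)
    assert cfg.cutoff == 12.0 and cfg.n_images == 30
    f.write_text("cutof: 12.0\n")
    with pytest.raises(ConfigError, match="unknown config keys"):
        TanmConfig.from_yaml(f)
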