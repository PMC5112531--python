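"""Explicit relaxation solver: oracles, invariants, and symmetry checks."""

import dataclasses

import numpy as np
import pytest

from gyrogen.mechanics import SimConfig, run_simulation
from gyrogen.mechanics._kernels import OK, relax2d, relax3d
from gyrogen.mechanics.mesh import build_bilayer_mesh
from gyrogen.mechanics.solver import (Discretization, GrowthField, SolverState,
                                      evaluate_state, internal_forces,
                                      step_explicit, total_energy)

MU = 330.0
BULK = 100.0 * MU


def _relax_free(mesh, g_max, ramp, total, bulk=BULK, gmul=None, dt_safety=0.5,
                damping=0.8):
    """Relax a fully unconstrained mesh under ramped growth via the kernels."""
    disc = Discretization(mesh)
    d = mesh.dim
    ne = mesh.n_elements
    gmul = np.ones(ne) if gmul is None else gmul
    mu0 = np.full(ne, MU)
    smul = np.ones(ne)
    x = mesh.nodes.copy()
    v = np.zeros_like(x)
    h_min = np.sqrt(disc.element_volume.min()) if d == 2 \
        else disc.element_volume.min() ** (1 / 3)
    dt = dt_safety * h_min / np.sqrt((bulk + 2 * MU) / 1.0)
    n_steps = int(total / dt)
    free = np.ones_like(x, dtype=bool)
    if d == 2:
        rc = relax2d(x, v, mesh.elements, disc.gradN0, disc.wdet, gmul, mu0,
                     smul, bulk, disc.unit_mass, damping, dt, 0.0, n_steps,
                     ramp, ramp, g_max, free[:, 0], free[:, 1])
    else:
        rc = relax3d(x, v, mesh.elements, disc.gradN0, disc.wdet, gmul, mu0,
                     smul, bulk, disc.unit_mass, damping, dt, 0.0, n_steps,
                     ramp, ramp, g_max, free)
    assert rc == OK
    g_elem = 1.0 + gmul * (g_max - 1.0)
    return disc, x, v, g_elem, mu0


@pytest.mark.parametrize("dim", [2, 3])
def test_unconstrained_homogeneous_growth_is_stress_free(dim):
    """Free growth: the mesh rescales by g with max |sigma| << mu."""
    g = 1.3
    if dim == 2:
        mesh = build_bilayer_mesh(length=4, depth=4, cortex_thickness=2,
                                  dx_cortex=2.0)
    else:
        mesh = build_bilayer_mesh(length=4, depth=4, width=4,
                                  cortex_thickness=2, dx_cortex=2.0)
    disc, x, v, g_elem, mu0 = _relax_free(mesh, g_max=g, ramp=30, total=150)
    state = evaluate_state(disc, x, g_elem, mu0, BULK)
    assert np.abs(state.sigma).max() < 1e-6 * MU
    # node pairs scale by g
    span0 = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
    span = x.max(axis=0) - x.min(axis=0)
    np.testing.assert_allclose(span, g * span0, rtol=1e-6)


def test_zero_growth_is_an_equilibrium_fixed_point():
    """With g = 1 everywhere the perturbed reference state does not move."""
    cfg = SimConfig(seed=4, g_max=1.0, ramp_time=5.0, settle_time=5.0)
    res = run_simulation(cfg)
    assert res.status == "no_instability"
    assert res.fold_amplitude() <= 2 * cfg.perturb_amplitude + 1e-12
    # surface never drifts from the (perturbed) reference heights
    np.testing.assert_allclose(res.top_h[-1], res.top_h[0], atol=1e-12)


def test_no_folding_without_growth_differential(default_run):
    """Differential growth drives folding; without it nothing folds (and
    with it, at the same settings, folds do appear)."""
    flat = run_simulation(SimConfig(seed=1, g_max=1.0, ramp_time=5.0,
                                    settle_time=5.0))
    assert flat.status == "no_instability"
    assert default_run.folded  # same seed, growth on


def test_kernel_matches_numpy_reference_step():
    """The production numba loop and the readable numpy step agree."""
    mesh = build_bilayer_mesh(length=20, depth=8, cortex_thickness=2,
                              dx_cortex=2.0, patch_width=6.0)
    disc = Discretization(mesh)
    ne = mesh.n_elements
    gmul = np.where(mesh.layer == 1, 1.0, 0.0)
    gmul[mesh.special] = 1.2
    smul = np.where(mesh.special, 2.0, 1.0)
    mu0 = np.full(ne, MU)
    growth = GrowthField(rate_multiplier=gmul, g_max=1.3, ramp_time=2.0)
    free = np.ones((mesh.n_nodes, 2), dtype=bool)
    free[mesh.bottom_nodes(), 1] = False
    dt, damping, n = 1e-3, 0.7, 40

    xk = mesh.nodes.copy()
    vk = np.zeros_like(xk)
    rc = relax2d(xk, vk, mesh.elements, disc.gradN0, disc.wdet, gmul, mu0,
                 smul, BULK, disc.unit_mass, damping, dt, 0.0, n,
                 2.0, 2.0, 1.3, np.ascontiguousarray(free[:, 0]),
                 np.ascontiguousarray(free[:, 1]))
    assert rc == OK

    state = SolverState(x=mesh.nodes.copy(), v=np.zeros_like(xk), t=0.0)
    for _ in range(n):
        state = step_explicit(state, disc, mu0, BULK, growth, dt, damping,
                              free, stiffness_multiplier=smul)
    np.testing.assert_allclose(xk, state.x, rtol=0, atol=1e-9)
    np.testing.assert_allclose(vk, state.v, rtol=0, atol=1e-9)


def test_internal_forces_are_energy_gradient(rng):
    """Nodal forces equal -dE/dx by central finite differences."""
    mesh = build_bilayer_mesh(length=6, depth=4, cortex_thickness=2,
                              dx_cortex=2.0)
    disc = Discretization(mesh)
    x = mesh.nodes + 0.05 * rng.standard_normal(mesh.nodes.shape)
    g = np.where(mesh.layer == 1, 1.1, 1.0)
    mu = np.full(mesh.n_elements, MU)
    f = internal_forces(disc, x, g, mu, BULK)
    h = 1e-6
    for n in rng.choice(mesh.n_nodes, size=6, replace=False):
        for i in range(2):
            xp, xm = x.copy(), x.copy()
            xp[n, i] += h
            xm[n, i] -= h
            fd = -(total_energy(disc, xp, g, mu, BULK)
                   - total_energy(disc, xm, g, mu, BULK)) / (2 * h)
            assert abs(f[n, i] - fd) < 1e-4 * max(1.0, abs(fd))


def test_kinetic_energy_drains_after_growth_stops():
    cfg = SimConfig(seed=2, g_max=1.05, ramp_time=10.0, settle_time=60.0)
    res = run_simulation(cfg)
    after = res.kinetic[res.times > 15.0]
    assert after[-1] < 1e-3 * res.kinetic.max()


def test_objectivity_rotated_mesh_gives_rotated_equilibrium():
    """Rigidly rotating the initial mesh rotates the relaxed state."""
    mesh = build_bilayer_mesh(length=20, depth=8, cortex_thickness=2,
                              dx_cortex=2.0)
    gmul = np.where(mesh.layer == 1, 1.0, 0.0)
    disc, x, v, g_elem, mu0 = _relax_free(mesh, g_max=1.05, ramp=20,
                                          total=120, gmul=gmul)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rmesh = dataclasses.replace(mesh, nodes=mesh.nodes @ R.T,
                                special=mesh.special)
    _, xr, _, _, _ = _relax_free(rmesh, g_max=1.05, ramp=20, total=120,
                                 gmul=gmul)
    np.testing.assert_allclose(xr, x @ R.T, atol=1e-6)


def test_mirror_symmetric_perturbation_mirrors_the_profile():
    """Below the folding threshold the response mirrors exactly."""
    kw = dict(seed=9, g_max=1.5, ramp_time=60.0, settle_time=30.0, length=60.0)
    a = run_simulation(SimConfig(**kw))
    b = run_simulation(SimConfig(mirror_perturbation=True, **kw))
    np.testing.assert_allclose(b.top_h[-1], a.top_h[-1][::-1], atol=1e-8)
    assert np.isclose(b.fold_amplitude(), a.fold_amplitude(), rtol=1e-6,
                      atol=1e-9)


def test_run_determinism(default_run):
    again = run_simulation(SimConfig(seed=1))
    np.testing.assert_array_equal(again.top_h[-1], default_run.top_h[-1])
    assert again.status == default_run.status


def test_folded_run_kinematic_invariants(default_run):
    """F = A G to machine tolerance and |det A - 1| <= 0.02 throughout."""
    st = default_run.final_state
    assert st.reconstruction_error() < 1e-10
    assert default_run.max_det_err.max() <= 0.02
    assert np.isfinite(default_run.kinetic).all()
    assert np.isfinite(default_run.strain).all()


def test_small_3d_run_completes():
    cfg = SimConfig(seed=5, width=16.0, length=16.0, depth=8.0,
                    dx_cortex=2.0, g_max=1.3, ramp_time=8.0,
                    settle_time=4.0, steps_per_frame=1000, patch_width=0.0)
    res = run_simulation(cfg)
    assert res.status in ("no_instability", "grown", "folded", "contact")
    assert np.isfinite(res.top_h).all()
    assert res.max_det_err.max() <= 0.02


def test_mode_validation():
    with pytest.raises(ValueError):
        SimConfig(mode="bogus")
    with pytest.raises(ValueError):
        SimConfig(ramp_time=-1.0)
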