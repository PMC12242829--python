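"""Time integration: Euler-Maruyama statistics, determinism, stability."""

import math

import numpy as np
import pytest

from spherofiber.config import SimulationConfig
from spherofiber.dynamics import (DynamicsParams, advance, build_state,
                                  euler_maruyama_update, run,
                                  stability_dt_bound, step)
from spherofiber.fiber import site_count_for_half_extent


def tiny_config(**over):
    kw = dict(N_c=27, N_LS=8, N_f=site_count_for_half_extent(5),
              t_f=4.0, t_on=1.0, contraction_interval=2.0, s0=5.4,
              K_S=10.0, K_B=2.25e-3, K_LS=22.5)
    kw.update(over)
    return SimulationConfig(**kw).validate()


def test_overdamped_harmonic_relaxation_matches_closed_form():
    """x(t) = x0 exp(-mu k t) up to O(dt) Euler error."""
    k, mu, dt = 2.0, 1.0, 1e-3
    pos = np.array([[1.0, 0.0, 0.0]])
    rng = np.random.default_rng(0)
    n = 500
    for _ in range(n):
        f = -k * pos
        euler_maruyama_update(pos, f, mu, dt, 0.0, rng)
    exact = math.exp(-mu * k * n * dt)
    assert pos[0, 0] == pytest.approx(exact, rel=5e-3)


def test_noise_variance_is_2_mu_kT_dt():
    """Sampled per-component displacement variance within 5%."""
    mu, dt, kT = 1.0, 0.005, 1e-3
    n_particles, n_steps = 300, 400
    pos = np.zeros((n_particles, 3))
    rng = np.random.default_rng(1)
    samples = []
    for _ in range(n_steps):
        before = pos.copy()
        euler_maruyama_update(pos, np.zeros_like(pos), mu, dt, kT, rng)
        samples.append(pos - before)
    var = np.concatenate(samples).ravel().var()
    assert var == pytest.approx(2 * mu * kT * dt, rel=0.05)


def test_zero_forces_zero_temperature_is_static(cube):
    cfg = tiny_config()
    state = build_state(cfg, seed=3)
    params = DynamicsParams.from_config(cfg, kT_eff=0.0)
    # a cube at its exact target is force-free; reuse the machinery on the
    # real state instead: positions move only where forces act
    p0 = state.net.positions.copy()
    step(state, params)
    assert np.array_equal(state.net.positions[state.net.pinned],
                          p0[state.net.pinned])


def test_fused_block_matches_single_steps_exactly_at_zero_temperature():
    cfg = tiny_config()
    a = build_state(cfg, seed=5)
    b = build_state(cfg, seed=5)
    params = DynamicsParams.from_config(cfg, kT_eff=0.0)
    for _ in range(20):
        step(a, params)
    advance(b, params, 20)
    np.testing.assert_allclose(a.cc.positions, b.cc.positions,
                               rtol=1e-12, atol=1e-12)
    np.testing.assert_allclose(a.net.positions, b.net.positions,
                               rtol=1e-12, atol=1e-12)
    assert a.t == pytest.approx(b.t)
    assert [lk.rest for lk in a.linkers.linkers] == \
        pytest.approx([lk.rest for lk in b.linkers.linkers])


def test_total_energy_nonincreasing_at_zero_temperature():
    """Pure gradient flow (no noise, constant linker rest lengths)."""
    cfg = tiny_config(Gamma=0.25, t_on=10.0, t_f=11.0)
    state = build_state(cfg, seed=7)
    params = DynamicsParams.from_config(cfg, kT_eff=0.0)
    energies = [state.energy()["total"]]
    for _ in range(300):       # all before t_on: the schedule is constant
        step(state, params)
        energies.append(state.energy()["total"])
    diffs = np.diff(energies)
    assert (diffs <= 1e-9).all()


def test_pinned_fiber_nodes_never_move():
    cfg = tiny_config()
    state = build_state(cfg, seed=2)
    params = DynamicsParams.from_config(cfg)
    pinned0 = state.net.positions[state.net.pinned].copy()
    advance(state, params, 200)
    np.testing.assert_array_equal(state.net.positions[state.net.pinned],
                                  pinned0)


def test_dt_stability_bound_is_enforced():
    cfg = tiny_config(dt=1.0)
    with pytest.raises(ValueError, match="stability"):
        run(cfg, seed=0)
    assert stability_dt_bound(tiny_config()) > 0.005


def test_smoke_run_completes_with_valid_state_and_series():
    cfg = tiny_config()
    params = DynamicsParams.from_config(cfg, observe_every=100)
    traj = run(cfg, seed=11, params=params)
    assert traj.aborted is None
    assert traj.state.cc.audit() == []
    assert traj.times[-1] == pytest.approx(cfg.t_f)
    qn = traj.series["qn"]
    assert qn[0] == 1.0
    assert all(0.0 <= q <= 1.0 for q in qn)
    # linker rest lengths completed their ramp
    assert all(lk.rest == pytest.approx(cfg.l0_final)
               for lk in traj.state.linkers.linkers)
    # occupied-bond count is conserved by the dynamics
    assert traj.state.net.occ.sum() == traj.state.net.occ.sum()


def test_same_seed_gives_identical_observable_series():
    cfg = tiny_config()
    params = DynamicsParams.from_config(cfg, observe_every=200)
    t1 = run(cfg, seed=9, params=params)
    t2 = run(cfg, seed=9, params=params)
    for k in t1.series:
        assert t1.series[k] == t2.series[k], k
    assert [e[:2] for e in t1.event_log] == [e[:2] for e in t2.event_log]
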