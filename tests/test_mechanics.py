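"""Vertex-model energy and analytic forces."""

import numpy as np
import pytest

from spherofiber.mechanics import (EnergyBreakdown, VertexModelParams,
                                   vm_energy, vm_forces)


def params(**kw):
    base = dict(K_V=1.0, K_A=0.01, V0=1.0, A0=6.0, Gamma=1.0)
    base.update(kw)
    return VertexModelParams(**base)


def test_cell_at_target_with_no_interface_is_a_global_minimum(cube):
    eb = vm_energy(cube, params())
    assert eb.total == 0.0
    assert np.abs(vm_forces(cube, params())).max() < 1e-10


def test_single_interface_face_contributes_gamma_times_area(cube):
    eb = vm_energy(cube, params(), interface_faces={0})
    assert eb.volume_term == 0.0 and eb.area_term == 0.0
    assert eb.tension_term == pytest.approx(1.0)   # unit face, Gamma = 1
    doubled = vm_energy(cube, params(Gamma=2.0), interface_faces={0})
    assert doubled.tension_term == pytest.approx(2 * eb.tension_term)
    assert doubled.volume_term == eb.volume_term
    assert doubled.area_term == eb.area_term


def test_energy_terms_sum_and_are_nonnegative(two_cell, rng):
    cc = two_cell.copy()
    cc.positions = cc.positions + 0.05 * rng.standard_normal(cc.positions.shape)
    eb = vm_energy(cc, params(A0=5.5), interface_faces={0, 1})
    assert eb.total == pytest.approx(eb.volume_term + eb.area_term
                                     + eb.tension_term)
    assert eb.volume_term >= 0 and eb.area_term >= 0 and eb.tension_term >= 0


@pytest.mark.parametrize("seed", range(5))
def test_analytic_forces_match_central_finite_differences(two_cell, seed):
    """Gradient consistency on randomly perturbed configurations."""
    rng = np.random.default_rng(seed)
    cc = two_cell.copy()
    cc.positions = cc.positions + 0.08 * rng.standard_normal(cc.positions.shape)
    p = params(A0=5.4, Gamma=0.6)
    iface = {0, 3}
    f = vm_forces(cc, p, interface_faces=iface)
    h = 1e-6
    for v in range(len(cc.positions)):
        for d in range(3):
            cc.positions[v, d] += h
            ep = vm_energy(cc, p, interface_faces=iface).total
            cc.positions[v, d] -= 2 * h
            em = vm_energy(cc, p, interface_faces=iface).total
            cc.positions[v, d] += h
            fd = -(ep - em) / (2 * h)
            assert f[v, d] == pytest.approx(fd, rel=1e-5, abs=1e-9)


def test_energy_invariant_under_translation_and_rotation(two_cell, rng):
    cc = two_cell.copy()
    cc.positions = cc.positions + 0.05 * rng.standard_normal(cc.positions.shape)
    p = params(A0=5.5)
    e0 = vm_energy(cc, p).total
    cc.positions = cc.positions + np.array([3.0, -2.0, 7.0])
    assert vm_energy(cc, p).total == pytest.approx(e0, rel=1e-12)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    cc.positions = cc.positions @ R.T
    assert vm_energy(cc, p).total == pytest.approx(e0, rel=1e-12)


def test_net_force_vanishes_without_interface_tension(two_cell, rng):
    """Translation invariance implies zero total force at Gamma = 0."""
    cc = two_cell.copy()
    cc.positions = cc.positions + 0.05 * rng.standard_normal(cc.positions.shape)
    f = vm_forces(cc, params(Gamma=0.0, A0=5.4))
    assert np.abs(f.sum(axis=0)).max() < 1e-10


def test_gradient_descent_monotonically_relaxes_a_single_cell(cube):
    cc = cube.copy()
    rng = np.random.default_rng(3)
    cc.positions = cc.positions + 0.15 * rng.standard_normal(cc.positions.shape)
    p = params(A0=5.6, Gamma=0.0)
    energies = [vm_energy(cc, p).total]
    for _ in range(200):
        f = vm_forces(cc, p)
        cc.positions = cc.positions + 0.005 * f
        energies.append(vm_energy(cc, p).total)
    diffs = np.diff(energies)
    assert (diffs <= 1e-12).all()
    assert energies[-1] < energies[0]
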