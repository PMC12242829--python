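"""Diluted FCC fiber network: construction, energies, forces, stiffness."""

import numpy as np
import pytest

from spherofiber.fiber import (build_fcc_network, carve_cavity, fiber_energy,
                               fiber_forces, shear_stiffness,
                               site_count_for_half_extent)
from spherofiber.fixtures import make_fixture


def _site_degrees(net):
    deg = np.zeros(net.n_lattice_sites, dtype=int)
    for a, b in net.bonds[net.occ]:
        deg[net.sites[a]] += 1
        deg[net.sites[b]] += 1
    return deg


def test_full_lattice_interior_coordination_and_phantom_split():
    net = make_fixture("fcc_patch", p=1.0, half_extent=4)
    deg = _site_degrees(net)
    interior = deg == 12
    assert interior.sum() > 100
    # 3 phantom nodes per site, each hosting at most 4 bonds (2 fiber directions)
    assert net.n_nodes == 3 * net.n_lattice_sites
    node_deg = np.zeros(net.n_nodes, dtype=int)
    for a, b in net.bonds[net.occ]:
        node_deg[a] += 1
        node_deg[b] += 1
    assert node_deg.max() <= 4
    # 6 collinear bending pairs per interior site
    per_site = np.zeros(net.n_lattice_sites, dtype=int)
    for j in net.triples[:, 1]:
        per_site[net.sites[j]] += 1
    assert (per_site[interior] == 6).all()


def test_dilution_fraction_matches_p():
    net = build_fcc_network(8, 1.5, 0.8, np.random.default_rng(1))
    assert len(net.occ) >= 10_000
    assert net.occ.mean() == pytest.approx(0.80, abs=0.01)


def test_build_determinism():
    a = build_fcc_network(3, 1.5, 0.7, np.random.default_rng(4))
    b = build_fcc_network(3, 1.5, 0.7, np.random.default_rng(4))
    np.testing.assert_array_equal(a.positions, b.positions)
    np.testing.assert_array_equal(a.occ, b.occ)
    np.testing.assert_array_equal(a.triples, b.triples)


def test_phantom_nodes_are_independent():
    """Displacing one phantom node exerts no force on its co-located siblings
    unless they share a bond."""
    net = make_fixture("fcc_patch", p=1.0, half_extent=3)
    center_site = int(net.sites[np.argmin(np.linalg.norm(net.positions, axis=1))])
    nodes = [3 * center_site + m for m in range(3)]
    net.positions[nodes[0]] += np.array([0.08, 0.05, -0.03])
    f = fiber_forces(net)
    assert np.abs(f[nodes[1]]).max() < 1e-12
    assert np.abs(f[nodes[2]]).max() < 1e-12
    assert np.abs(f[nodes[0]]).max() > 1e-3


def test_single_bond_hooke_energy():
    chain = make_fixture("collinear_chain")
    chain.positions[2, 0] = 2.1   # outer bond stretched to 1.1 l0
    chain.triples = chain.triples[:0]
    es, eb = fiber_energy(chain, K_S=1.0, K_B=0.0)
    assert es == pytest.approx(0.5 * 0.1 ** 2, rel=1e-12)
    assert eb == 0.0


def test_collinear_chain_small_angle_bending():
    chain = make_fixture("collinear_chain")
    es0, eb0 = fiber_energy(chain, K_S=1.0, K_B=0.02)
    assert es0 == pytest.approx(0.0, abs=1e-20)
    assert eb0 == pytest.approx(0.0, abs=1e-20)
    delta = 1e-3
    chain.positions[1, 1] = delta   # middle node transverse: angle pi - 2*delta
    _, eb = fiber_energy(chain, K_S=1.0, K_B=0.02)
    assert eb == pytest.approx(0.5 * 0.02 * (2 * delta) ** 2, rel=1e-4)


def test_undeformed_lattice_is_at_rest():
    net = make_fixture("fcc_patch", p=0.9, half_extent=3)
    es, eb = fiber_energy(net)
    assert es == pytest.approx(0.0, abs=1e-20)
    assert eb == pytest.approx(0.0, abs=1e-20)
    assert np.abs(fiber_forces(net)).max() < 1e-10


@pytest.mark.parametrize("seed", range(3))
def test_fiber_forces_match_finite_differences(seed):
    rng = np.random.default_rng(seed)
    net = build_fcc_network(3, 1.5, 0.85, rng, K_S=1.3, K_B=0.02)
    net.positions = net.positions + 0.08 * rng.standard_normal(net.positions.shape)
    f = fiber_forces(net)
    h = 1e-6
    for v in range(0, net.n_nodes, 11):
        for d in range(3):
            net.positions[v, d] += h
            ep = sum(fiber_energy(net))
            net.positions[v, d] -= 2 * h
            em = sum(fiber_energy(net))
            net.positions[v, d] += h
            fd = -(ep - em) / (2 * h)
            assert f[v, d] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_energy_invariant_under_rigid_motion_and_zero_net_force():
    rng = np.random.default_rng(2)
    net = build_fcc_network(3, 1.5, 0.8, rng, pin_boundary=False)
    net.positions = net.positions + 0.05 * rng.standard_normal(net.positions.shape)
    e0 = sum(fiber_energy(net))
    f = fiber_forces(net)
    assert np.abs(f.sum(axis=0)).max() < 1e-10
    net.positions = net.positions + np.array([1.0, -2.0, 0.5])
    assert sum(fiber_energy(net)) == pytest.approx(e0, rel=1e-12)
    th = 0.4
    R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                  [-np.sin(th), 0, np.cos(th)]])
    net.positions = net.positions @ R.T
    assert sum(fiber_energy(net)) == pytest.approx(e0, rel=1e-10)


def test_carve_cavity_removes_exactly_the_inner_bonds():
    rng = np.random.default_rng(3)
    net = build_fcc_network(5, 1.5, 0.8, rng)
    unchanged = carve_cavity(net, 0.0)
    assert unchanged.occ.sum() == net.occ.sum()
    radius = 3.0
    carved = carve_cavity(net, radius)
    # brute-force oracle: occupied bonds with both endpoints outside survive
    r = np.linalg.norm(net.positions, axis=1)
    expect = 0
    for (a, b), occ in zip(net.bonds, net.occ):
        if occ and r[a] >= radius and r[b] >= radius:
            expect += 1
    assert carved.occ.sum() == expect
    bi, bj, _ = carved.occupied_arrays()
    rr = np.linalg.norm(carved.positions, axis=1)
    assert min(rr[bi].min(), rr[bj].min()) >= radius
    with pytest.raises(ValueError, match="swallows"):
        carve_cavity(net, 100.0)


def test_shear_stiffness_positive_and_linear_at_full_occupation():
    net = build_fcc_network(4, 1.5, 1.0, np.random.default_rng(5),
                            pin_boundary=False)
    g = shear_stiffness(net, [5e-5, 2e-4])
    assert (g > 0).all()
    assert g[0] == pytest.approx(g[1], rel=0.01)   # linear response


def test_shear_stiffness_monotone_in_occupation_probability():
    """Median stiffness nondecreasing over p in {0.75, 0.8, 0.85, 0.9}."""
    ps = [0.75, 0.8, 0.85, 0.9]
    med = []
    for p in ps:
        vals = []
        for seed in range(5):
            net = build_fcc_network(3, 1.5, p, np.random.default_rng(100 + seed),
                                    pin_boundary=False)
            vals.append(shear_stiffness(net, [1e-2])[0])
        med.append(np.median(vals))
    assert all(med[i] <= med[i + 1] + 1e-12 for i in range(len(med) - 1))


def test_site_count_formula_matches_construction():
    for h in (2, 3, 4):
        net = build_fcc_network(h, 1.0, 1.0, np.random.default_rng(0))
        assert net.n_lattice_sites == site_count_for_half_extent(h)
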