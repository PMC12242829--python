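"""Measurements: Q_n, displacements, radial profiles, orientation tensors,
spheroid shape, histograms."""

import numpy as np
import pytest

from spherofiber.fiber import FiberNetwork, build_fcc_network
from spherofiber.fixtures import make_fixture
from spherofiber.observables import (RadialProfile, default_shell_edges,
                                     density_profile, displacement,
                                     histograms, orientation_profile,
                                     qn_fraction, spheroid_shape)


def test_qn_is_one_initially_and_counts_losses(small_spheroid):
    nm = small_spheroid.neighbor_map()
    init = {c: set(v) for c, v in nm.items()}
    assert qn_fraction(small_spheroid, init) == 1.0
    # every cell "loses" two neighbors -> 0
    stripped = {c: v | {10 ** 6, 10 ** 6 + 1} for c, v in init.items()}
    assert qn_fraction(small_spheroid, stripped) == 0.0


def test_qn_counts_partial_losses_exactly(small_spheroid):
    nm = {c: set(v) for c, v in small_spheroid.neighbor_map().items()}
    cells = sorted(nm)
    # one cell records 2 extra initial neighbors it has since "lost",
    # another only 1 (which does not count)
    nm[cells[0]] = nm[cells[0]] | {10 ** 6, 10 ** 6 + 1}
    nm[cells[1]] = nm[cells[1]] | {10 ** 6 + 2}
    expect = (len(cells) - 1) / len(cells)
    assert qn_fraction(small_spheroid, nm) == pytest.approx(expect)


def test_displacement_zero_for_static_and_exact_for_translation():
    c0 = np.zeros((7, 3))
    static = [c0, c0, c0]
    out = displacement(static, window=1, R_s=2.0)
    assert np.allclose(out, 0.0)
    d = np.array([0.3, -0.4, 0.0])   # |d| = 0.5
    moved = [c0, c0 + d, c0 + 2 * d]
    out = displacement(moved, window=1, R_s=2.0)
    assert out[1] == pytest.approx(0.25)
    assert out[2] == pytest.approx(0.25)


def _uniform_net(rng, half=4, p=0.8):
    return build_fcc_network(half, 1.5, p, rng, pin_boundary=False)


def test_density_ratio_is_one_for_identical_states(rng):
    net = _uniform_net(rng)
    edges = default_shell_edges(2.0, 5.0)
    prof = density_profile(net.positions.copy(), net, np.zeros(3), edges=edges)
    assert np.allclose(prof.values[~prof.masked], 1.0)


def test_density_profile_against_segment_clipping_oracle(rng):
    """Uniform radial contraction r -> 0.9 r raises inner-shell density."""
    net = _uniform_net(rng)
    initial = net.positions.copy()
    net.positions = 0.9 * net.positions
    edges = np.array([0.0, 1.5, 3.0, 4.5])
    prof = density_profile(initial, net, np.zeros(3), edges=edges)
    assert prof.values[0] > 1.0
    # oracle: dense sampling of each bond, counting sampled length per shell
    bi, bj, _ = net.occupied_arrays()
    t = np.linspace(0, 1, 2001)
    mids = 0.5 * (t[:-1] + t[1:])
    expect = np.zeros(len(edges) - 1)
    for a, b in zip(bi, bj):
        p1, p2 = net.positions[a], net.positions[b]
        seg = np.linalg.norm(p2 - p1) / (len(t) - 1)
        r = np.linalg.norm(p1[None, :] + mids[:, None] * (p2 - p1), axis=1)
        idx = np.searchsorted(edges, r, side="right") - 1
        for sh in range(len(expect)):
            expect[sh] += seg * (idx == sh).sum()
    length_f = prof.values * prof.counts
    assert length_f[~prof.masked] == pytest.approx(expect[~prof.masked],
                                                   rel=2e-3)


def test_density_total_length_is_conserved_across_shells(rng):
    net = _uniform_net(rng)
    r_max = np.linalg.norm(net.positions, axis=1).max() + net.spacing
    edges = np.linspace(0, r_max + 1.0, 9)
    prof = density_profile(net.positions.copy(), net, np.zeros(3), edges=edges)
    total = prof.counts.sum()      # initial clipped length over all shells
    assert total == pytest.approx(net.bond_lengths().sum(), rel=1e-9)


def test_orientation_single_axis_bonds():
    pos = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    net = FiberNetwork(positions=pos, sites=np.arange(4),
                       bonds=np.array([[0, 1], [1, 2], [2, 3]]),
                       occ=np.ones(3, dtype=bool), l0=np.ones(3),
                       triples=np.zeros((0, 3), dtype=np.int64),
                       pinned=np.zeros(4, dtype=bool), spacing=1.0,
                       n_lattice_sites=4)
    prof = orientation_profile(net, center=np.zeros(3))
    T = prof.tensors[0]
    assert T[0, 0] == pytest.approx(1.0)
    assert abs(T[1, 1]) < 1e-12 and abs(T[2, 2]) < 1e-12


def test_undiluted_fcc_orientation_is_isotropic(rng):
    """Full FCC lattice in a single bin: all Cartesian diagonals are 1/3."""
    net = build_fcc_network(5, 1.5, 1.0, rng, pin_boundary=False)
    prof = orientation_profile(net, center=np.zeros(3))
    diag = np.diag(prof.tensors[0])
    assert diag == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-12)


def test_orientation_trace_is_one_per_shell(rng):
    net = _uniform_net(rng, p=0.7)
    net.positions = net.positions + 0.1 * rng.standard_normal(net.positions.shape)
    edges = default_shell_edges(1.5, 6.0)
    prof = orientation_profile(net, center=np.zeros(3), edges=edges)
    for s in range(len(edges) - 1):
        if not prof.masked[s]:
            assert np.trace(prof.tensors[s]) == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(prof.tensors[s], prof.tensors[s].T)


def test_orientation_strain_filter_raises_on_empty_set(rng):
    net = _uniform_net(rng)
    with pytest.raises(ValueError, match="strain filter"):
        orientation_profile(net, center=np.zeros(3), strain_threshold=10.0)


def test_spheroid_shape_of_cut_out(small_spheroid):
    A, V, idx, dev = spheroid_shape(small_spheroid, R_s=2.43)
    assert V > 0
    assert idx >= (36 * np.pi) ** (1 / 3)
    assert len(dev) == len(small_spheroid.interface_faces())
    # the cut-out is roughly spherical: most face centers near R_s
    assert np.median(np.abs(dev)) < 1.0


def test_histograms_normalized_and_point_masses(cube, rng):
    net = _uniform_net(rng)
    out = histograms(cube, net, bins=30)
    edges, dens = out["shape_index"]
    assert (dens * np.diff(edges)).sum() == pytest.approx(1.0)
    # a single cube is a point mass at s = 6
    nz = np.nonzero(dens)[0]
    assert len(nz) == 1
    assert edges[nz[0]] <= 6.0 <= edges[nz[0] + 1]
    # unstrained network: strain histogram is a point mass at 0 (all the
    # histogram's support sits within float noise of zero strain)
    edges, dens = out["bond_strain"]
    assert (dens * np.diff(edges)).sum() == pytest.approx(1.0)
    assert max(abs(edges[0]), abs(edges[-1])) < 1e-12
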