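"""Active linker springs: attachment, schedule, forces, lifecycle."""

import numpy as np
import pytest

from spherofiber.builder import spheroid_complex
from spherofiber.fiber import build_fcc_network, carve_cavity
from spherofiber.geometry import face_geometry
from spherofiber.linkers import (Linker, LinkerSchedule, LinkerSet,
                                 attach_linkers, face_center_is_interior,
                                 linker_energy_forces, rest_length,
                                 update_linker_population)


SCHED = LinkerSchedule(t_on=500.0, l0_init=1.5, l0_final=0.2, interval=5000.0)


@pytest.fixture(scope="module")
def embedded():
    rng = np.random.default_rng(12)
    cc = spheroid_complex(60, rng)
    net = build_fcc_network(7, 1.5, 0.8, rng)
    net = carve_cavity(net, 2.43 + 1.5)
    return cc, net


def test_rest_length_schedule_values():
    assert rest_length(0.0, SCHED) == 1.5
    assert rest_length(500.0, SCHED) == 1.5
    assert rest_length(500.0 + 2500.0, SCHED) == pytest.approx(0.85)  # midpoint
    assert rest_length(5500.0, SCHED) == pytest.approx(0.2)
    assert rest_length(25000.0, SCHED) == pytest.approx(0.2)
    # monotone nonincreasing
    ts = np.linspace(0, 7000, 200)
    vals = [rest_length(t, SCHED) for t in ts]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_attach_respects_boundary_and_uniqueness(embedded):
    cc, net = embedded
    rng = np.random.default_rng(0)
    boundary = cc.boundary_cells()
    n_ls = len(boundary) // 2
    lset = attach_linkers(cc, net, n_ls, rng, schedule=SCHED)
    assert len(lset) == n_ls
    cells = [lk.cell for lk in lset.linkers]
    assert len(set(cells)) == n_ls            # at most one linker per cell
    assert set(cells) <= boundary
    iface = cc.interface_faces()
    for lk in lset.linkers:
        assert lk.face in iface
        assert lk.rest == 1.5


def test_attached_node_is_the_true_nearest_phantom_node(embedded):
    cc, net = embedded
    lset = attach_linkers(cc, net, 10, np.random.default_rng(3), schedule=SCHED)
    for lk in lset.linkers:
        _, center, _ = face_geometry(cc.faces[lk.face], cc.positions)
        d = np.linalg.norm(net.positions - center, axis=1)
        assert d[lk.node] == pytest.approx(d.min())


def test_attach_zero_and_too_many(embedded):
    cc, net = embedded
    assert len(attach_linkers(cc, net, 0, np.random.default_rng(0),
                              schedule=SCHED)) == 0
    with pytest.raises(ValueError, match="boundary cells"):
        attach_linkers(cc, net, 10_000, np.random.default_rng(0),
                       schedule=SCHED)


def test_linker_hooke_force_and_momentum_balance(embedded):
    cc, net = embedded
    lset = attach_linkers(cc, net, 1, np.random.default_rng(4), schedule=SCHED)
    lk = lset.linkers[0]
    _, center, _ = face_geometry(cc.faces[lk.face], cc.positions)
    l = np.linalg.norm(net.positions[lk.node] - center)
    # zero energy/forces at rest
    lk.rest = float(l)
    e, fc_, fn = linker_energy_forces(lset, cc, net, K_LS=2.25)
    assert e == pytest.approx(0.0, abs=1e-20)
    assert np.abs(fn).max() < 1e-12 and np.abs(fc_).max() < 1e-12
    # stretched by delta: |force| = K_LS*delta on each side, opposite
    delta = 0.3
    lk.rest = float(l - delta)
    e, fc_, fn = linker_energy_forces(lset, cc, net, K_LS=2.25)
    assert e == pytest.approx(0.5 * 2.25 * delta ** 2)
    assert np.linalg.norm(fn[lk.node]) == pytest.approx(2.25 * delta)
    total = fn.sum(axis=0) + fc_.sum(axis=0)
    assert np.abs(total).max() < 1e-12


def test_population_update_noop_when_nothing_degenerates(embedded):
    cc, net = embedded
    rng = np.random.default_rng(5)
    lset = attach_linkers(cc, net, 12, rng, schedule=SCHED)
    before = [(lk.cell, lk.face, lk.node) for lk in lset.linkers]
    removed, created = update_linker_population(lset, cc, net, rng, 0.0, SCHED)
    assert (removed, created) == (0, 0)
    assert [(lk.cell, lk.face, lk.node) for lk in lset.linkers] == before


def test_small_face_triggers_replacement(embedded):
    cc, net = embedded
    rng = np.random.default_rng(6)
    lset = attach_linkers(cc, net, 12, rng, schedule=SCHED)
    lk = lset.linkers[0]
    victim_cell = lk.cell
    # shrink the linker's polygon to area < 0.1 about its center
    cc2 = cc.copy()
    verts = np.asarray(cc2.faces[lk.face])
    center = cc2.positions[verts].mean(axis=0)
    cc2.positions[verts] = center + 0.05 * (cc2.positions[verts] - center)
    removed, created = update_linker_population(lset, cc2, net, rng, 600.0, SCHED)
    assert removed == 1 and created == 1
    assert len(lset) == 12                       # count conserved
    cells = {l.cell for l in lset.linkers}
    assert victim_cell not in cells
    # the replacement starts at the current schedule value, not the initial one
    reborn = max(lset.linkers, key=lambda l: l.birth_time)
    assert reborn.rest == pytest.approx(rest_length(600.0, SCHED))


def test_face_center_interior_test():
    from spherofiber.cellcomplex import CellComplex
    cc = CellComplex()
    cc.add_vertices(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                             dtype=float))
    f = cc.new_face([0, 1, 2, 3])
    assert face_center_is_interior(cc, f)
    # a chevron whose vertex-mean lies outside the polygon
    cc2 = CellComplex()
    cc2.add_vertices(np.array([[0, 0, 0], [2, 0, 0], [1, 0.2, 0],
                               [2, 4, 0], [0, 4, 0]], dtype=float))
    # strongly concave: mean pulled above the notch
    cc2.positions[3] = [2, 0.4, 0]
    cc2.positions[4] = [0, 0.4, 0]
    g = cc2.new_face([0, 1, 3, 2, 4])
    assert not face_center_is_interior(cc2, g)


def test_rest_lengths_nonincreasing_under_schedule(embedded):
    cc, net = embedded
    rng = np.random.default_rng(8)
    lset = attach_linkers(cc, net, 5, rng, schedule=SCHED)
    prev = [lk.rest for lk in lset.linkers]
    for t in (100.0, 600.0, 1500.0, 3000.0, 6000.0):
        lset.set_rest_lengths(t, SCHED)
        cur = [lk.rest for lk in lset.linkers]
        assert all(c <= p + 1e-12 for c, p in zip(cur, prev))
        prev = cur
    assert all(lk.rest == pytest.approx(0.2) for lk in lset.linkers)
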