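"""Reconnection events: candidates, admissibility, reversibility, audits."""

import numpy as np
import pytest

from spherofiber.cellcomplex import EMPTY, REAL, edge_key
from spherofiber.reconnection import (ReconnectionEvent, RejectedMove,
                                      apply_reconnection, edge_candidates,
                                      find_candidates, sweep,
                                      triangle_candidates)


def _central_edge(cc):
    """The interior edge shared by three real cells with tetravalent ends."""
    ve = cc.vertex_edges()
    fc = cc.face_cells()
    best = None
    for key, fl in cc.edge_faces().items():
        if len(fl) != 3:
            continue
        a, b = key >> 32, key & 0xFFFFFFFF
        if len(ve[a]) != 4 or len(ve[b]) != 4:
            continue
        cells = {c for f in fl for c, _ in fc[f]}
        if all(cc.cell_label[c] == REAL for c in cells):
            d = np.linalg.norm(cc.positions[a] - cc.positions[b])
            if best is None or d < best[1]:
                best = ((int(a), int(b)), d)
    assert best is not None
    return best


def _topo_signature(cc):
    """Incidence invariants: per-cell face-size multisets and neighbor pairs."""
    fc = cc.face_cells()
    pairs = set()
    for inc in fc.values():
        if len(inc) == 2:
            pairs.add(tuple(sorted((inc[0][0], inc[1][0]))))
    sizes = {c: sorted(len(cc.faces[f]) for f in fo)
             for c, fo in cc.cells.items()}
    return pairs, sizes, len(cc.faces)


def test_no_candidates_when_all_edges_are_long(five_cell):
    assert find_candidates(five_cell, 1e-6) == []


def test_short_edge_is_listed(five_cell):
    (v1, v2), d = _central_edge(five_cell)
    cands = edge_candidates(five_cell, d * 1.01)
    assert (min(v1, v2), max(v1, v2)) in {(min(a, b), max(a, b))
                                          for a, b in cands}


def test_fresh_spheroid_has_few_candidates(small_spheroid):
    """Short edges are a small fraction of the tessellation's edge set."""
    n_edges = len(small_spheroid.real_edge_array())
    n_cand = len(find_candidates(small_spheroid, 0.02))
    assert n_cand / n_edges < 0.03


def test_edge_to_triangle_and_back_restores_topology(five_cell):
    cc = five_cell.copy()
    sig0 = _topo_signature(cc)
    (v1, v2), d = _central_edge(cc)
    ev = apply_reconnection(cc, ("edge", (v1, v2)), l_th=d * 1.05)
    assert isinstance(ev, ReconnectionEvent)
    assert cc.audit(confluent=True) == []
    # exactly one neighbor pair gained (the two polar cells), none lost
    pairs0, _, nfaces0 = sig0
    pairs1, _, nfaces1 = _topo_signature(cc)
    assert pairs1 - pairs0 == {tuple(sorted(ev.cells[:2]))}
    assert pairs0 - pairs1 == set()
    assert nfaces1 == nfaces0 + 1
    # the new triangle sits above threshold (hysteresis guard)
    tri = cc.positions[np.asarray(cc.faces[ev.new_face])]
    lengths = np.linalg.norm(tri - np.roll(tri, -1, axis=0), axis=1)
    assert (lengths >= d * 1.05).all()
    # reverse restores an incidence-isomorphic complex
    rev = apply_reconnection(cc, ("triangle", (ev.new_face,)), l_th=10.0)
    assert isinstance(rev, ReconnectionEvent)
    assert cc.audit(confluent=True) == []
    assert _topo_signature(cc) == sig0


def test_triangle_collapse_loses_exactly_one_neighbor_pair(five_cell):
    cc = five_cell.copy()
    (v1, v2), d = _central_edge(cc)
    ev = apply_reconnection(cc, ("edge", (v1, v2)), l_th=d * 1.05)
    pairs_before, _, _ = _topo_signature(cc)
    rev = apply_reconnection(cc, ("triangle", (ev.new_face,)), l_th=10.0)
    pairs_after, _, _ = _topo_signature(cc)
    assert pairs_before - pairs_after == {tuple(sorted(rev.cells[:2]))}
    assert pairs_after - pairs_before == set()


def test_move_rejected_if_polar_cells_already_share_a_face(five_cell):
    cc = five_cell.copy()
    (v1, v2), d = _central_edge(cc)
    ev = apply_reconnection(cc, ("edge", (v1, v2)), l_th=d * 1.05)
    # the polar pair now shares the new triangle; a second edge between the
    # same pair may not flip (no two cells may share two or more faces)
    top, bot = ev.cells[:2]
    ve = cc.vertex_edges()
    fc = cc.face_cells()
    rejected = None
    for key, fl in cc.edge_faces().items():
        if len(fl) != 3:
            continue
        a, b = key >> 32, key & 0xFFFFFFFF
        if len(ve.get(a, ())) != 4 or len(ve.get(b, ())) != 4:
            continue
        cells = {c for f in fl for c, _ in fc[f]}
        vf = cc.vertex_faces()
        at_a = {c for f in vf[a] for c, _ in fc[f]}
        at_b = {c for f in vf[b] for c, _ in fc[f]}
        pol_a, pol_b = at_a - cells, at_b - cells
        if pol_a == {top} and pol_b == {bot} or pol_a == {bot} and pol_b == {top}:
            rejected = apply_reconnection(cc, ("edge", (int(a), int(b))), l_th=10.0)
            break
    if rejected is not None:
        assert isinstance(rejected, RejectedMove)
        assert "doubly-shared" in rejected.reason or "share" in rejected.reason


def test_rejection_leaves_complex_untouched(five_cell):
    cc = five_cell.copy()
    sig0 = _topo_signature(cc)
    pos0 = cc.positions.copy()
    # a hull edge of the empty padding is not a generic interior edge
    results = []
    for key, fl in list(cc.edge_faces().items())[:200]:
        a, b = key >> 32, key & 0xFFFFFFFF
        r = apply_reconnection(cc, ("edge", (int(a), int(b))), l_th=1e-9)
        results.append(r)
    assert any(isinstance(r, RejectedMove) for r in results)
    assert _topo_signature(cc) == sig0
    np.testing.assert_array_equal(cc.positions[cc.vertex_active],
                                  pos0[cc.vertex_active])


def test_energetic_admissibility_rejects_shrinking_elements(five_cell):
    """With tissue parameters favouring the edge, the flip is rejected."""
    from spherofiber.mechanics import VertexModelParams
    cc = five_cell.copy()
    (v1, v2), d = _central_edge(cc)
    # enormous area stiffness with tiny target area: every face wants to
    # shrink, so the newly created triangle cannot expand
    params = VertexModelParams(K_V=0.0, K_A=50.0, V0=1.0, A0=4.84, Gamma=0.0)
    res = apply_reconnection(cc, ("edge", (v1, v2)), l_th=d * 1.05,
                             vm_params=params)
    assert isinstance(res, RejectedMove)
    assert "energetically" in res.reason
    assert cc.audit(confluent=True) == []


def test_sweep_is_deterministic_and_keeps_validity(five_cell):
    (v1, v2), d = _central_edge(five_cell)
    logs = []
    for _ in range(2):
        cc = five_cell.copy()
        ev = sweep(cc, l_th=d * 1.05, rng=np.random.default_rng(9))
        assert cc.audit(confluent=True) == []
        logs.append([(e.kind, e.cells) for e in ev])
    assert logs[0] == logs[1]
    assert len(logs[0]) >= 1


def test_sweep_without_candidates_is_a_noop(five_cell):
    cc = five_cell.copy()
    sig0 = _topo_signature(cc)
    assert sweep(cc, 1e-9, np.random.default_rng(0)) == []
    assert _topo_signature(cc) == sig0


def test_boundary_cell_can_become_interior_and_back(five_cell):
    """Empty cells take part: flipping an interface element moves a real cell
    between the boundary and the interior."""
    cc = five_cell.copy()
    ve = cc.vertex_edges()
    fc = cc.face_cells()
    vf = cc.vertex_faces()
    applied = None
    for key, fl in cc.edge_faces().items():
        if len(fl) != 3:
            continue
        a, b = key >> 32, key & 0xFFFFFFFF
        if len(ve[a]) != 4 or len(ve[b]) != 4:
            continue
        side = {c for f in fl for c, _ in fc[f]}
        at_a = {c for f in vf[a] for c, _ in fc[f]}
        at_b = {c for f in vf[b] for c, _ in fc[f]}
        if len(at_a) != 4 or len(at_b) != 4:
            continue
        polar = (at_a | at_b) - side
        if len(polar) != 2:
            continue
        labs = sorted(cc.cell_label[c] for c in polar)
        if labs == [EMPTY, REAL]:
            before = set(cc.boundary_cells())
            res = apply_reconnection(cc, ("edge", (int(a), int(b))), l_th=10.0)
            if isinstance(res, ReconnectionEvent):
                after = set(cc.boundary_cells())
                real_polar = next(c for c in polar if cc.cell_label[c] == REAL)
                # the real polar cell gained an interface face -> now boundary
                assert real_polar in after
                applied = (res, before, after, real_polar)
                break
            continue
    assert applied is not None, "no interface edge admitted a flip"
    res, before, after, real_polar = applied
    assert cc.audit(confluent=True) == []
    # reverse: collapsing the interface triangle removes that contact again
    rev = apply_reconnection(cc, ("triangle", (res.new_face,)), l_th=10.0)
    assert isinstance(rev, ReconnectionEvent)
    assert set(cc.boundary_cells()) == before
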