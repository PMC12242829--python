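"""Reconnection events: the 3D analogue of T1 transitions.

A short interior edge (shared by exactly three faces, with tetravalent
endpoints — the generic situation in a random Voronoi tessellation) is
replaced by a small triangular face, making the two "polar" cells at the
edge's ends face-sharing neighbors; the reverse move collapses a small
triangle back to an edge, destroying that neighbor pair.  A move is attempted
only when every edge it removes is shorter than the threshold ``l_th``, and is
rejected unless it is geometrically, topologically, and energetically
reversible:

* topologically — no two cells may end up sharing two or more polygons, all
  cells stay closed oriented surfaces, and the configuration produced is
  exactly the one the reverse move requires;
* energetically — the new element is created slightly *above* threshold
  (size ``l_th * (1 + eps)``), a hysteresis guard so a move cannot
  immediately re-trigger its own reverse.

Empty cells participate on equal footing, which is how boundary cells migrate
into the interior and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import _kernels
from .cellcomplex import REAL, CellComplex, edge_key

__all__ = ["ReconnectionEvent", "RejectedMove", "find_candidates",
           "apply_reconnection", "sweep", "edge_candidates", "triangle_candidates"]

HYSTERESIS_EPS = 0.05


@dataclass
class ReconnectionEvent:
    kind: str                     # "edge_to_triangle" | "triangle_to_edge"
    time: float
    cells: Tuple[int, ...]        # (top, bottom, side1, side2, side3)
    vertices_before: Tuple[int, ...]
    vertices_after: Tuple[int, ...]
    faces_changed: Tuple[int, ...]
    new_face: Optional[int] = None        # triangle created (edge_to_triangle)
    removed_face: Optional[int] = None    # triangle removed (triangle_to_edge)


@dataclass
class RejectedMove:
    kind: str
    reason: str
    element: Tuple


def edge_candidates(cc: CellComplex, l_th: float) -> List[Tuple[int, int]]:
    """Edges shorter than ``l_th`` (edge -> triangle candidates)."""
    edges = cc.real_edge_array()
    if len(edges) == 0:
        return []
    e1 = np.ascontiguousarray(edges[:, 0])
    e2 = np.ascontiguousarray(edges[:, 1])
    flags = np.zeros(len(e1), dtype=bool)
    n = _kernels.min_edge_scan(cc.positions, e1, e2, l_th, flags)
    if n == 0:
        return []
    return [(int(a), int(b)) for a, b in zip(e1[flags], e2[flags])]


def triangle_candidates(cc: CellComplex, l_th: float) -> List[int]:
    """Triangular faces all of whose edges are shorter than ``l_th``."""
    tris = cc.real_triangle_faces()
    if len(tris) == 0:
        return []
    p = cc.positions[tris[:, 1:]]
    lengths = np.linalg.norm(p - np.roll(p, -1, axis=1), axis=2)
    sel = lengths.max(axis=1) < l_th
    return [int(f) for f in tris[sel, 0]]


def find_candidates(cc: CellComplex, l_th: float
                    ) -> List[Tuple[str, Tuple]]:
    """All admissible-length candidates, as ("edge", (v1, v2)) or ("triangle", (fid,))."""
    if l_th <= 0:
        raise ValueError("l_th must be positive")
    cands: List[Tuple[str, Tuple]] = [("edge", e) for e in edge_candidates(cc, l_th)]
    cands += [("triangle", (f,)) for f in triangle_candidates(cc, l_th)]
    return cands


# --------------------------------------------------------------------------- #
# edge -> triangle


def _replace_subseq(cycle: List[int], old: Sequence[int], new: Sequence[int]
                    ) -> Optional[List[int]]:
    """Replace consecutive (cyclic) subsequence ``old`` (or its reverse) by ``new``."""
    n = len(cycle)
    m = len(old)
    for start in range(n):
        seg = [cycle[(start + k) % n] for k in range(m)]
        if seg == list(old):
            rep = list(new)
        elif seg == list(old)[::-1]:
            rep = list(new)[::-1]
        else:
            continue
        rest = [cycle[(start + m + k) % n] for k in range(n - m)]
        return rep + rest
    return None


def _perp_direction(vec: np.ndarray, axis: np.ndarray) -> Optional[np.ndarray]:
    perp = vec - (vec @ axis) * axis
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        return None
    return perp / norm


def apply_reconnection(cc: CellComplex, candidate: Tuple[str, Tuple],
                       l_th: float, time: float = 0.0,
                       eps: float = HYSTERESIS_EPS,
                       vm_params=None):
    """Apply one reconnection move; returns ReconnectionEvent or RejectedMove.

    The complex is mutated only when the move is admissible; on any failed
    check the complex is left untouched and the rejection reason is returned.
    With ``vm_params`` (a :class:`~spherofiber.mechanics.VertexModelParams`),
    energetic reversibility is additionally enforced: the created element must
    expand under the local tissue force field, otherwise it would immediately
    re-collapse and re-trigger its own reverse.
    """
    kind, elem = candidate
    if kind == "edge":
        return _edge_to_triangle(cc, elem[0], elem[1], l_th, time, eps,
                                 vm_params)
    if kind == "triangle":
        return _triangle_to_edge(cc, elem[0], l_th, time, eps, vm_params)
    raise ValueError(f"unknown candidate kind {kind!r}")


def _local_vm_forces(cc: CellComplex, cells, iface_local, vm_params,
                     vids) -> np.ndarray:
    """Tissue forces on selected vertices from the energy of a few cells."""
    fids: List[int] = []
    seen: Set[int] = set()
    real_cells = [c for c in cells if cc.cell_label[c] == REAL]
    for c in real_cells:
        for f in cc.cells[c]:
            if f not in seen:
                seen.add(f)
                fids.append(f)
    loc = {f: i for i, f in enumerate(fids)}
    off = [0]
    idx: List[int] = []
    for f in fids:
        idx.extend(cc.faces[f])
        off.append(len(idx))
    tension = np.array([vm_params.Gamma if f in iface_local else 0.0
                        for f in fids])
    c_off = [0]
    c_face: List[int] = []
    c_orient: List[float] = []
    for c in real_cells:
        for f, o in cc.cells[c].items():
            c_face.append(loc[f])
            c_orient.append(o)
        c_off.append(len(c_face))
    forces = np.zeros_like(cc.positions)
    _kernels.vm_eval(cc.positions,
                     np.asarray(off, dtype=np.int64),
                     np.asarray(idx, dtype=np.int64), tension,
                     np.asarray(c_off, dtype=np.int64),
                     np.asarray(c_face, dtype=np.int64),
                     np.asarray(c_orient, dtype=np.float64),
                     vm_params.K_V, vm_params.K_A, vm_params.V0, vm_params.A0,
                     True, forces, np.zeros(len(real_cells)),
                     np.zeros(len(real_cells)))
    return forces[np.asarray(vids)]


def _element_expands(cc: CellComplex, cells, iface_local, vm_params,
                     vids) -> bool:
    """Whether the element spanned by ``vids`` grows under local forces."""
    f = _local_vm_forces(cc, cells, iface_local, vm_params, vids)
    r = cc.positions[np.asarray(vids)]
    rel = r - r.mean(axis=0)
    return float(np.einsum("ij,ij->", f, rel)) > 0.0


def _edge_to_triangle(cc: CellComplex, v1: int, v2: int, l_th: float,
                      time: float, eps: float, vm_params=None):
    def reject(reason: str) -> RejectedMove:
        return RejectedMove("edge_to_triangle", reason, (v1, v2))

    ef = cc.edge_faces()
    fids = ef.get(edge_key(v1, v2))
    if not fids:
        return reject("edge no longer exists")
    if len(fids) != 3:
        return reject(f"edge has {len(fids)} incident faces (need 3)")
    ve = cc.vertex_edges()
    if len(ve[v1]) != 4 or len(ve[v2]) != 4:
        return reject("endpoint is not tetravalent")
    for f in fids:
        if len(cc.faces[f]) < 4:
            return reject("a side face is a triangle and would degenerate")
    fc = cc.face_cells()
    side_cells: Set[int] = set()
    for f in fids:
        inc = fc[f]
        if len(inc) != 2:
            return reject("side face is not shared by two cells (hull)")
        side_cells.update(c for c, _ in inc)
    if len(side_cells) != 3:
        return reject(f"{len(side_cells)} side cells around edge (need 3)")
    vf = cc.vertex_faces()
    cells_at = {}
    for v in (v1, v2):
        cs: Set[int] = set()
        for f in vf[v]:
            cs.update(c for c, _ in fc[f])
        cells_at[v] = cs
    top_set = cells_at[v1] - side_cells
    bot_set = cells_at[v2] - side_cells
    if len(top_set) != 1 or len(bot_set) != 1:
        return reject("polar cells not uniquely defined")
    top, bot = top_set.pop(), bot_set.pop()
    if top == bot:
        return reject("polar cells coincide")
    shared = set(cc.cells[top]) & set(cc.cells[bot])
    if shared:
        return reject("polar cells already share a face "
                      "(move would create a doubly-shared pair)")
    # a-vertices (v1 side) and b-vertices (v2 side) per side face
    a_of: Dict[int, int] = {}
    b_of: Dict[int, int] = {}
    for f in fids:
        cyc = cc.faces[f]
        n = len(cyc)
        i1, i2 = cyc.index(v1), cyc.index(v2)
        nb1 = {cyc[(i1 - 1) % n], cyc[(i1 + 1) % n]} - {v2}
        nb2 = {cyc[(i2 - 1) % n], cyc[(i2 + 1) % n]} - {v1}
        if len(nb1) != 1 or len(nb2) != 1:
            return reject("side face cycle malformed around the edge")
        a_of[f], b_of[f] = nb1.pop(), nb2.pop()
    avs, bvs = set(a_of.values()), set(b_of.values())
    if len(avs) != 3 or len(bvs) != 3 or (avs & bvs):
        return reject("wing vertices collide (geometric self-intersection proxy)")
    # top/bottom wing faces
    top_faces = [f for f in vf[v1] if f not in fids]
    bot_faces = [f for f in vf[v2] if f not in fids]
    if len(top_faces) != 3 or len(bot_faces) != 3:
        return reject("wrong wing-face count at an endpoint")
    # geometry of the new triangle
    r1, r2 = cc.positions[v1], cc.positions[v2]
    mid = 0.5 * (r1 + r2)
    axis = r2 - r1
    nrm = np.linalg.norm(axis)
    if nrm < 1e-14:
        return reject("edge has zero length")
    axis = axis / nrm
    f_list = sorted(fids)
    dirs = []
    for f in f_list:
        fcentroid = cc.positions[np.asarray(cc.faces[f])].mean(axis=0)
        d = _perp_direction(fcentroid - mid, axis)
        if d is None:
            return reject("degenerate side-face direction")
        dirs.append(d)
    l_new = l_th * (1.0 + eps)
    rho = l_new / np.sqrt(3.0)
    w_pos = [mid + rho * d for d in dirs]
    tri = np.asarray(w_pos)
    tnormal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    if np.linalg.norm(tnormal) < 1e-14:
        return reject("new triangle is degenerate")

    # ---- all checks passed; mutate (with rollback on local audit failure)
    touched_cells = set(side_cells) | {top, bot}
    pre_open = {c for c in touched_cells if not _cell_is_closed(cc, c)}
    pre_iface = cc.interface_faces() if vm_params is not None else set()
    saved_faces = {f: list(cc.faces[f]) for f in set(fids) | set(top_faces) | set(bot_faces)}
    saved_cells = {c: dict(cc.cells[c]) for c in (top, bot)}
    saved_cache = dict(cc._cache)
    saved_nfid = cc._next_fid
    w_ids = [cc.add_vertex(p) for p in w_pos]
    w_of = {f: w for f, w in zip(f_list, w_ids)}

    def rollback():
        for w in w_ids:
            cc.free_vertex(w)
        for f, cyc in saved_faces.items():
            cc.faces[f] = cyc
        for c, fo in saved_cells.items():
            cc.cells[c] = fo
        if tri_fid in cc.faces:
            cc.drop_face(tri_fid)
        cc._next_fid = saved_nfid
        # the rollback restores the exact pre-move topology, so the derived
        # maps built before the move are valid again
        cc._cache = dict(saved_cache)

    # triangle face
    tri_cycle = list(w_ids)
    tn = tnormal / np.linalg.norm(tnormal)
    if tn @ axis < 0:
        tri_cycle = tri_cycle[::-1]
    tri_fid = cc.new_face(tri_cycle)    # outward from top is along +axis
    cc.cells[top] = dict(cc.cells[top])
    cc.cells[bot] = dict(cc.cells[bot])
    cc.cells[top][tri_fid] = 1
    cc.cells[bot][tri_fid] = -1
    ok = True
    for f in f_list:
        newcyc = _replace_subseq(cc.faces[f], [v1, v2], [w_of[f]])
        if newcyc is None:
            ok = False
            break
        cc.faces[f] = newcyc
    if ok:
        for f in top_faces:
            cyc = cc.faces[f]
            n = len(cyc)
            i = cyc.index(v1)
            prev_v, next_v = cyc[(i - 1) % n], cyc[(i + 1) % n]
            f_prev = next((g for g, a in a_of.items() if a == prev_v), None)
            f_next = next((g for g, a in a_of.items() if a == next_v), None)
            if f_prev is None or f_next is None:
                ok = False
                break
            newcyc = _replace_subseq(cyc, [prev_v, v1, next_v],
                                     [prev_v, w_of[f_prev], w_of[f_next], next_v])
            if newcyc is None:
                ok = False
                break
            cc.faces[f] = newcyc
    if ok:
        for f in bot_faces:
            cyc = cc.faces[f]
            n = len(cyc)
            i = cyc.index(v2)
            prev_v, next_v = cyc[(i - 1) % n], cyc[(i + 1) % n]
            f_prev = next((g for g, b in b_of.items() if b == prev_v), None)
            f_next = next((g for g, b in b_of.items() if b == next_v), None)
            if f_prev is None or f_next is None:
                ok = False
                break
            newcyc = _replace_subseq(cyc, [prev_v, v2, next_v],
                                     [prev_v, w_of[f_prev], w_of[f_next], next_v])
            if newcyc is None:
                ok = False
                break
            cc.faces[f] = newcyc
    cc._touch()
    reason = "rewiring failed local validity audit"
    if ok:
        ok = not _local_audit(cc, touched_cells, tolerate=pre_open)
    if ok and vm_params is not None:
        labs = {cc.cell_label[top], cc.cell_label[bot]}
        iface_local = (pre_iface | {tri_fid}) if len(labs) == 2 else pre_iface
        if not _element_expands(cc, list(side_cells) + [top, bot],
                                iface_local, vm_params, w_ids):
            ok = False
            reason = ("energetically irreversible: the new triangle would "
                      "immediately shrink")
    if not ok:
        rollback()
        return RejectedMove("edge_to_triangle", reason, (v1, v2))
    cc.free_vertex(v1)
    cc.free_vertex(v2)
    return ReconnectionEvent(
        kind="edge_to_triangle", time=time,
        cells=(top, bot, *sorted(side_cells)),
        vertices_before=(v1, v2), vertices_after=tuple(w_ids),
        faces_changed=tuple(f_list + top_faces + bot_faces),
        new_face=tri_fid)


def _triangle_to_edge(cc: CellComplex, tri_fid: int, l_th: float,
                      time: float, eps: float, vm_params=None):
    def reject(reason: str) -> RejectedMove:
        return RejectedMove("triangle_to_edge", reason, (tri_fid,))

    if tri_fid not in cc.faces:
        return reject("triangle no longer exists")
    ws = list(cc.faces[tri_fid])
    if len(ws) != 3:
        return reject("face is not a triangle")
    fc = cc.face_cells()
    inc = fc[tri_fid]
    if len(inc) != 2:
        return reject("triangle not shared by two cells")
    # top = the cell for which the stored cycle is outward (+1)
    top = next(c for c, o in inc if o == 1)
    bot = next(c for c, o in inc if o == -1)
    shared = set(cc.cells[top]) & set(cc.cells[bot])
    if shared != {tri_fid}:
        return reject("polar cells share more than the triangle")
    ve = cc.vertex_edges()
    vf = cc.vertex_faces()
    for w in ws:
        if len(ve[w]) != 4:
            return reject("triangle corner is not tetravalent")
        if len(vf[w]) != 6:
            return reject("triangle corner has wrong face count")
    top_fids = set(cc.cells[top])
    bot_fids = set(cc.cells[bot])
    a_of: Dict[int, int] = {}
    b_of: Dict[int, int] = {}
    side_face: Dict[int, int] = {}
    for w in ws:
        others = ve[w] - set(ws)
        if len(others) != 2:
            return reject("triangle corner wiring malformed")
        a = b = None
        for x in others:
            faces_of_edge = set(cc.edge_faces()[edge_key(w, x)])
            in_top = bool(faces_of_edge & top_fids)
            in_bot = bool(faces_of_edge & bot_fids)
            if in_top and not in_bot:
                a = x
            elif in_bot and not in_top:
                b = x
        if a is None or b is None:
            return reject("cannot split corner neighbors into polar sides")
        a_of[w], b_of[w] = a, b
        sf = [f for f in vf[w] if f not in top_fids and f not in bot_fids]
        if len(sf) != 1:
            return reject("side face not unique at a corner")
        side_face[w] = sf[0]
    if len(set(side_face.values())) != 3:
        return reject("side faces not distinct")
    if len(set(a_of.values())) != 3 or len(set(b_of.values())) != 3 \
            or set(a_of.values()) & set(b_of.values()):
        return reject("wing vertices collide")
    side_cells: Set[int] = set()
    for f in side_face.values():
        side_cells.update(c for c, _ in fc[f])
    if len(side_cells) != 3 or top in side_cells or bot in side_cells:
        return reject("side cells malformed")
    top_wings = [f for f in vf[ws[0]] + vf[ws[1]] + vf[ws[2]]
                 if f in top_fids and f != tri_fid]
    bot_wings = [f for f in vf[ws[0]] + vf[ws[1]] + vf[ws[2]]
                 if f in bot_fids and f != tri_fid]
    top_wings = sorted(set(top_wings))
    bot_wings = sorted(set(bot_wings))
    if len(top_wings) != 3 or len(bot_wings) != 3:
        return reject("wrong wing-face count")
    for f in top_wings + bot_wings:
        if len(cc.faces[f]) < 4:
            return reject("a wing face is a triangle and would degenerate")
    # geometry
    tri = cc.positions[np.asarray(ws)]
    c = tri.mean(axis=0)
    normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    nn = np.linalg.norm(normal)
    if nn < 1e-14:
        return reject("triangle degenerate")
    normal /= nn                      # outward from top by orientation
    l_new = l_th * (1.0 + eps)
    p1 = c - 0.5 * l_new * normal     # v1 on the top side
    p2 = c + 0.5 * l_new * normal

    touched_cells = set(side_cells) | {top, bot}
    pre_open = {c for c in touched_cells if not _cell_is_closed(cc, c)}
    pre_iface = cc.interface_faces() if vm_params is not None else set()
    saved_faces = {f: list(cc.faces[f])
                   for f in set(side_face.values()) | set(top_wings) | set(bot_wings)}
    saved_faces[tri_fid] = list(cc.faces[tri_fid])
    saved_cells = {cid: dict(cc.cells[cid]) for cid in (top, bot)}
    saved_cache = dict(cc._cache)
    v1 = cc.add_vertex(p1)
    v2 = cc.add_vertex(p2)

    def rollback():
        cc.free_vertex(v1)
        cc.free_vertex(v2)
        for f, cyc in saved_faces.items():
            cc.faces[f] = cyc
        for cid, fo in saved_cells.items():
            cc.cells[cid] = fo
        cc._cache = dict(saved_cache)

    cc.cells[top] = dict(cc.cells[top])
    cc.cells[bot] = dict(cc.cells[bot])
    del cc.cells[top][tri_fid]
    del cc.cells[bot][tri_fid]
    cc.drop_face(tri_fid)
    ok = True
    for w in ws:
        f = side_face[w]
        newcyc = _replace_subseq(cc.faces[f], [a_of[w], w, b_of[w]],
                                 [a_of[w], v1, v2, b_of[w]])
        if newcyc is None:
            ok = False
            break
        cc.faces[f] = newcyc
    if ok:
        for f in top_wings:
            cyc = cc.faces[f]
            pair = [w for w in ws if w in cyc]
            if len(pair) != 2:
                ok = False
                break
            newcyc = _replace_subseq(cyc, pair, [v1])
            if newcyc is None:
                newcyc = _replace_subseq(cyc, pair[::-1], [v1])
            if newcyc is None:
                ok = False
                break
            cc.faces[f] = newcyc
    if ok:
        for f in bot_wings:
            cyc = cc.faces[f]
            pair = [w for w in ws if w in cyc]
            if len(pair) != 2:
                ok = False
                break
            newcyc = _replace_subseq(cyc, pair, [v2])
            if newcyc is None:
                newcyc = _replace_subseq(cyc, pair[::-1], [v2])
            if newcyc is None:
                ok = False
                break
            cc.faces[f] = newcyc
    cc._touch()
    reason = "rewiring failed local validity audit"
    if ok:
        ok = not _local_audit(cc, touched_cells, tolerate=pre_open)
    if ok and vm_params is not None:
        iface_local = pre_iface - {tri_fid}
        if not _element_expands(cc, list(side_cells) + [top, bot],
                                iface_local, vm_params, (v1, v2)):
            ok = False
            reason = ("energetically irreversible: the new edge would "
                      "immediately shrink")
    if not ok:
        rollback()
        return RejectedMove("triangle_to_edge", reason, (tri_fid,))
    for w in ws:
        cc.free_vertex(w)
    return ReconnectionEvent(
        kind="triangle_to_edge", time=time,
        cells=(top, bot, *sorted(side_cells)),
        vertices_before=tuple(ws), vertices_after=(v1, v2),
        faces_changed=tuple(sorted(set(side_face.values()))
                            + top_wings + bot_wings),
        removed_face=tri_fid)


def _cell_is_closed(cc: CellComplex, cid: int) -> bool:
    directed: Dict[Tuple[int, int], int] = {}
    for fid, o in cc.cells[cid].items():
        if fid not in cc.faces:
            return False
        cyc = cc.faces[fid] if o == 1 else cc.faces[fid][::-1]
        n = len(cyc)
        for k in range(n):
            e = (cyc[k], cyc[(k + 1) % n])
            directed[e] = directed.get(e, 0) + 1
    for (a, b), cnt in directed.items():
        if cnt != 1 or directed.get((b, a), 0) != 1:
            return False
    return True


def _local_audit(cc: CellComplex, cells: Set[int],
                 tolerate: Optional[Set[int]] = None) -> List[str]:
    """Closed-surface check restricted to the touched cells.

    ``tolerate`` lists cells that were already open before the move (hull
    cells of the empty padding); those are exempt from the closure check.
    """
    problems = []
    tolerate = tolerate or set()
    for cid in cells:
        if cid in tolerate:
            continue
        directed: Dict[Tuple[int, int], int] = {}
        for fid, o in cc.cells[cid].items():
            if fid not in cc.faces:
                problems.append(f"cell {cid} references dropped face {fid}")
                continue
            cyc = cc.faces[fid] if o == 1 else cc.faces[fid][::-1]
            if len(set(cyc)) != len(cyc):
                problems.append(f"face {fid} degenerate after rewiring")
            n = len(cyc)
            for k in range(n):
                e = (cyc[k], cyc[(k + 1) % n])
                directed[e] = directed.get(e, 0) + 1
        for (a, b), cnt in directed.items():
            if cnt != 1 or directed.get((b, a), 0) != 1:
                problems.append(f"cell {cid} not closed at edge ({a},{b})")
                break
    return problems


REJECT_COOLDOWN = 20.0  # t0; how long a rejected candidate rests before retry


def sweep(cc: CellComplex, l_th: float, rng: np.random.Generator,
          time: float = 0.0, eps: float = HYSTERESIS_EPS,
          vm_params=None, cooldown: Optional[Dict[Tuple, float]] = None
          ) -> List[ReconnectionEvent]:
    """Attempt all current candidates in random order, each at most once.

    The candidate list is frozen at entry; candidates invalidated by earlier
    events in the same sweep are skipped via the admissibility checks.
    ``cooldown`` (mutated in place) suppresses re-attempts of recently
    rejected candidates for ``REJECT_COOLDOWN`` time units.
    """
    cands = find_candidates(cc, l_th)
    if not cands:
        return []
    order = rng.permutation(len(cands))
    events: List[ReconnectionEvent] = []
    for k in order:
        kind, elem = cands[int(k)]
        ckey = (kind, elem)
        if cooldown is not None:
            until = cooldown.get(ckey)
            if until is not None and time < until:
                continue
        if kind == "edge":
            v1, v2 = elem
            if not (cc.vertex_active[v1] and cc.vertex_active[v2]):
                continue
            d = np.linalg.norm(cc.positions[v2] - cc.positions[v1])
            if d >= l_th:
                continue
        else:
            fid = elem[0]
            if fid not in cc.faces or len(cc.faces[fid]) != 3:
                continue
            p = cc.positions[np.asarray(cc.faces[fid])]
            if np.linalg.norm(p - np.roll(p, -1, axis=0), axis=1).max() >= l_th:
                continue
        result = apply_reconnection(cc, (kind, elem), l_th, time, eps,
                                    vm_params=vm_params)
        if isinstance(result, ReconnectionEvent):
            events.append(result)
        elif cooldown is not None:
            cooldown[ckey] = time + REJECT_COOLDOWN
    return events
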