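"""Active linker springs coupling boundary-cell faces to fiber nodes.

Each linker is a Hookean spring between the center of one interface polygon of
a boundary cell and one phantom node of the fiber network.  Its rest length
follows a global schedule: constant at ``l0_init`` until ``t_on``, then a
linear ramp down to ``l0_final`` over ``contraction_interval``, then constant.
The schedule is monotone nonincreasing, so linkers born mid-ramp simply adopt
the current value and never see earlier (longer) rest lengths.  This encodes
focal-adhesion / molecular-clutch contractility as a shrinking target length.

At most one linker per boundary cell.  Linkers are removed when their cell
leaves the boundary through a reconnection event, or when their polygon
degenerates (area below 0.1 V0^{2/3}, or concave with the center on/outside an
edge); every removal is immediately followed by a creation on a random
linker-free boundary cell so the linker count is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .cellcomplex import CellComplex
from .fiber import FiberNetwork
from .geometry import face_geometry

__all__ = ["Linker", "LinkerSchedule", "LinkerSet", "rest_length",
           "attach_linkers", "linker_energy_forces", "update_linker_population",
           "face_center_is_interior", "MIN_LINKER_FACE_AREA"]

MIN_LINKER_FACE_AREA = 0.1     # in units V0^{2/3}


@dataclass(frozen=True)
class LinkerSchedule:
    t_on: float = 500.0
    l0_init: float = 1.5
    l0_final: float = 0.2
    interval: float = 5000.0

    def __post_init__(self) -> None:
        if self.interval <= 0 or self.t_on < 0:
            raise ValueError("interval must be > 0 and t_on >= 0")
        if self.l0_final >= self.l0_init:
            raise ValueError("l0_final must be below l0_init")


def rest_length(t: float, schedule: LinkerSchedule) -> float:
    """Piecewise-linear contraction schedule, constant outside the ramp."""
    if t <= schedule.t_on:
        return schedule.l0_init
    frac = (t - schedule.t_on) / schedule.interval
    if frac >= 1.0:
        return schedule.l0_final
    return schedule.l0_init + frac * (schedule.l0_final - schedule.l0_init)


@dataclass
class Linker:
    cell: int
    face: int
    node: int
    rest: float          # current rest length
    birth_time: float


@dataclass
class LinkerSet:
    linkers: List[Linker] = field(default_factory=list)
    starvation_log: List[Tuple[float, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.linkers)

    def cells(self) -> Set[int]:
        return {lk.cell for lk in self.linkers}

    def set_rest_lengths(self, t: float, schedule: LinkerSchedule) -> None:
        r = rest_length(t, schedule)
        for lk in self.linkers:
            # the schedule is monotone; never revisit an earlier (longer) value
            lk.rest = min(lk.rest, r)


def _interface_faces_of_cell(cc: CellComplex, cid: int) -> List[int]:
    iface = cc.interface_faces()
    return [f for f in cc.cells[cid] if f in iface]


def _largest_interface_face(cc: CellComplex, cid: int,
                            min_area: float = MIN_LINKER_FACE_AREA
                            ) -> Optional[int]:
    """Largest admissible interface polygon of a boundary cell.

    Polygons below the removal area threshold or with a non-interior center
    are not offered for attachment (a linker there would be removed at the
    next population update anyway).
    """
    best, best_area = None, -1.0
    for f in _interface_faces_of_cell(cc, cid):
        area, _, _ = face_geometry(cc.faces[f], cc.positions)
        if area > best_area and area >= min_area \
                and face_center_is_interior(cc, f):
            best, best_area = f, area
    return best


def _load_bearing_nodes(net: FiberNetwork) -> np.ndarray:
    """Nodes with at least two occupied bonds (able to transmit force)."""
    deg = np.zeros(net.n_nodes, dtype=np.int64)
    bi, bj, _ = net.occupied_arrays()
    np.add.at(deg, bi, 1)
    np.add.at(deg, bj, 1)
    return np.nonzero(deg >= 2)[0]


def _nearest_phantom_node(net: FiberNetwork, point: np.ndarray) -> int:
    """Nearest load-bearing phantom node; ties broken by lowest index."""
    cand = _load_bearing_nodes(net)
    rel = net.positions[cand] - point
    d2 = np.einsum("ij,ij->i", rel, rel)
    return int(cand[np.argmin(d2)])


def attach_linkers(cc: CellComplex, net: FiberNetwork, n_ls: int,
                   rng: np.random.Generator, t: float = 0.0,
                   schedule: Optional[LinkerSchedule] = None) -> LinkerSet:
    """Attach ``n_ls`` linkers to distinct random boundary cells.

    Each selected cell contributes its largest interface polygon; the fiber
    end is the phantom node nearest that polygon's center.
    """
    schedule = schedule or LinkerSchedule()
    boundary = sorted(cc.boundary_cells())
    eligible = [c for c in boundary if _largest_interface_face(cc, c) is not None]
    if n_ls > len(eligible):
        raise ValueError(
            f"requested {n_ls} linkers but only {len(eligible)} boundary cells "
            "have an interface face")
    chosen = rng.choice(len(eligible), size=n_ls, replace=False) if n_ls else []
    out = LinkerSet()
    r = rest_length(t, schedule)
    for k in sorted(int(i) for i in np.atleast_1d(chosen)):
        cid = eligible[k]
        fid = _largest_interface_face(cc, cid)
        _, center, _ = face_geometry(cc.faces[fid], cc.positions)
        node = _nearest_phantom_node(net, center)
        out.linkers.append(Linker(cell=cid, face=fid, node=node,
                                  rest=r, birth_time=t))
    return out


def linker_energy_forces(lset: LinkerSet, cc: CellComplex, net: FiberNetwork,
                         K_LS: float,
                         cell_forces: Optional[np.ndarray] = None,
                         fiber_forces: Optional[np.ndarray] = None
                         ) -> Tuple[float, np.ndarray, np.ndarray]:
    """Energy and forces of all linker springs.

    The spring acts between the polygon center (mean of the face's vertices)
    and the phantom node; the reaction on the center is redistributed equally
    over the face's vertices (chain rule through the mean), so each linker
    imparts zero net momentum.
    """
    if cell_forces is None:
        cell_forces = np.zeros_like(cc.positions)
    if fiber_forces is None:
        fiber_forces = np.zeros_like(net.positions)
    energy = 0.0
    for lk in lset.linkers:
        cyc = cc.faces.get(lk.face)
        if cyc is None:
            raise KeyError(f"linker references missing face {lk.face}")
        verts = np.asarray(cyc)
        center = cc.positions[verts].mean(axis=0)
        d = net.positions[lk.node] - center
        l = float(np.linalg.norm(d))
        if l < 1e-12:
            continue
        stretch = l - lk.rest
        energy += 0.5 * K_LS * stretch ** 2
        f_node = -K_LS * stretch * d / l        # pulls node toward center if stretched
        fiber_forces[lk.node] += f_node
        cell_forces[verts] += (-f_node) / len(verts)
    return energy, cell_forces, fiber_forces


def linker_lengths_tensions(lset: LinkerSet, cc: CellComplex,
                            net: FiberNetwork, K_LS: float
                            ) -> Tuple[np.ndarray, np.ndarray]:
    ls, taus = [], []
    for lk in lset.linkers:
        verts = np.asarray(cc.faces[lk.face])
        center = cc.positions[verts].mean(axis=0)
        l = float(np.linalg.norm(net.positions[lk.node] - center))
        ls.append(l)
        taus.append(K_LS * (l - lk.rest))
    return np.asarray(ls), np.asarray(taus)


def face_center_is_interior(cc: CellComplex, fid: int, tol: float = 1e-9) -> bool:
    """Whether the polygon center lies strictly inside the polygon.

    The polygon is projected on its best-fit plane; a winding-number test
    plus a minimum distance to every edge decides strict interiority.  A
    concave polygon whose center has drifted onto or beyond an edge fails.
    """
    pts = cc.positions[np.asarray(cc.faces[fid])]
    center = pts.mean(axis=0)
    rel = pts - center
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    e1, e2 = vt[0], vt[1]
    xy = np.stack([rel @ e1, rel @ e2], axis=1)
    n = len(xy)
    winding = 0.0
    for k in range(n):
        a, b = xy[k], xy[(k + 1) % n]
        seg = b - a
        seg_len2 = seg @ seg
        if seg_len2 < tol ** 2:
            return False
        # distance from origin (the center) to segment ab
        tproj = np.clip(-(a @ seg) / seg_len2, 0.0, 1.0)
        closest = a + tproj * seg
        if np.linalg.norm(closest) <= tol:
            return False
        winding += np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b)
    return abs(winding) > np.pi   # ~ +-2*pi when the center is enclosed


def update_linker_population(lset: LinkerSet, cc: CellComplex,
                             net: FiberNetwork, rng: np.random.Generator,
                             t: float, schedule: LinkerSchedule,
                             min_area: float = MIN_LINKER_FACE_AREA
                             ) -> Tuple[int, int]:
    """Remove degenerate linkers and refill to conserve the linker count.

    Removal triggers: the cell is no longer a boundary cell; the linker's
    polygon no longer exists or is no longer an interface polygon of that
    cell; the polygon area fell below ``min_area``; or the polygon became
    concave with its center on/outside an edge.  Each removal is followed by a
    creation on a random linker-free boundary cell at the current schedule
    value.  Returns (removed, created); created < removed only when no
    linker-free boundary cell was available (logged starvation).
    """
    boundary = cc.boundary_cells()
    iface = cc.interface_faces()
    keep: List[Linker] = []
    removed = 0
    for lk in lset.linkers:
        ok = (lk.cell in boundary
              and lk.face in cc.faces
              and lk.face in iface
              and lk.face in cc.cells[lk.cell])
        if ok:
            area, _, _ = face_geometry(cc.faces[lk.face], cc.positions)
            ok = area >= min_area and face_center_is_interior(cc, lk.face)
        if ok:
            keep.append(lk)
        else:
            removed += 1
    created = 0
    if removed:
        occupied = {lk.cell for lk in keep}
        free_cells = sorted(c for c in boundary if c not in occupied
                            and _largest_interface_face(cc, c) is not None)
        r = rest_length(t, schedule)
        for _ in range(removed):
            if not free_cells:
                lset.starvation_log.append((t, removed - created))
                break
            k = int(rng.integers(len(free_cells)))
            cid = free_cells.pop(k)
            fid = _largest_interface_face(cc, cid)
            _, center, _ = face_geometry(cc.faces[fid], cc.positions)
            node = _nearest_phantom_node(net, center)
            keep.append(Linker(cell=cid, face=fid, node=node,
                               rest=r, birth_time=t))
            created += 1
    lset.linkers = keep
    return removed, created
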