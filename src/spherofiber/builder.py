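"""Construct the initial confluent spheroid from a bulk random Voronoi tessellation.

Seed points are sampled uniformly in a periodic cube at unit number density
(mean Voronoi volume = V0), optionally regularized by a few Lloyd sweeps, and
tessellated with qhull using image points so the tessellation is
bulk-periodic.  The spheroid is the set of Voronoi cells whose generator sits
within a cut radius of the box center; two concentric layers of the discarded
cells are kept, relabeled *empty*, and everything beyond is dropped.  Real
cells that share a polygon with an empty cell are boundary cells, and those
shared polygons are the interface faces that carry the surface tension.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import Voronoi

from .cellcomplex import EMPTY, REAL, CellComplex

__all__ = ["sample_seed_points", "build_spheroid", "radius_for_count",
           "spheroid_complex", "box_edge_for", "spheroid_radius"]

_IMAGE_MARGIN = 2.5   # how far outside the box periodic images are kept


def spheroid_radius(n_real: int, V0: float = 1.0) -> float:
    """Radius of the sphere holding ``n_real`` cells of volume V0."""
    return (3.0 * n_real * V0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def box_edge_for(n_points: int) -> float:
    """Periodic box edge giving mean Voronoi volume exactly 1."""
    return float(n_points) ** (1.0 / 3.0)


def _with_images(points: np.ndarray, box: float,
                 margin: float = _IMAGE_MARGIN
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Append periodic images within ``margin`` of the box.

    Returns (all_points, original_index) where the first ``len(points)``
    entries are the central copies.
    """
    n = len(points)
    all_pts = [points]
    orig = [np.arange(n)]
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                img = points + np.array([dx, dy, dz]) * box
                keep = np.all((img > -margin) & (img < box + margin), axis=1)
                if keep.any():
                    all_pts.append(img[keep])
                    orig.append(np.nonzero(keep)[0])
    return np.vstack(all_pts), np.concatenate(orig)


def _cell_triangles(vor: Voronoi, ridges_of: Dict[int, List[int]],
                    idx: int) -> Tuple[np.ndarray, np.ndarray]:
    """Fan triangles (apex = generator) of one bounded Voronoi cell."""
    x0 = vor.points[idx]
    tris = []
    for r in ridges_of.get(idx, []):
        rv = vor.ridge_vertices[r]
        if -1 in rv:
            return np.zeros((0, 3, 3)), x0
        poly = vor.vertices[rv]
        cf = poly.mean(axis=0)
        for k in range(len(poly)):
            tris.append((cf, poly[k], poly[(k + 1) % len(poly)]))
    return np.asarray(tris), x0


def _lloyd_sweep(points: np.ndarray, box: float,
                 relax_mask: np.ndarray) -> np.ndarray:
    """One Lloyd sweep: move selected points to their Voronoi cell centroid."""
    all_pts, _ = _with_images(points, box)
    vor = Voronoi(all_pts)
    ridges_of: Dict[int, List[int]] = {}
    for r, (a, b) in enumerate(vor.ridge_points):
        ridges_of.setdefault(int(a), []).append(r)
        ridges_of.setdefault(int(b), []).append(r)
    new_pts = points.copy()
    for i in np.nonzero(relax_mask)[0]:
        tris, x0 = _cell_triangles(vor, ridges_of, int(i))
        if len(tris) == 0:
            continue
        cf, p1, p2 = tris[:, 0], tris[:, 1], tris[:, 2]
        vols = np.abs(np.einsum("ij,ij->i",
                                np.cross(cf - x0, p1 - x0), p2 - x0)) / 6.0
        total = vols.sum()
        if total <= 0:
            continue
        centers = (x0 + cf + p1 + p2) / 4.0
        new_pts[i] = (vols[:, None] * centers).sum(axis=0) / total
    return np.mod(new_pts, box)


def sample_seed_points(n: int, box: float, rng: np.random.Generator,
                       lloyd_sweeps: int = 2,
                       focus_radius: Optional[float] = None) -> np.ndarray:
    """Uniform seed points in a periodic cube, with optional Lloyd relaxation.

    ``focus_radius`` restricts the (costly) relaxation to points within that
    distance of the box center; points outside keep their sampled positions.
    With ``box = n**(1/3)`` the mean Voronoi volume is exactly V0 = 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if box ** 3 < n * 0.1:
        raise ValueError(f"{n} points will not fit box edge {box} at unit density")
    pts = rng.uniform(0.0, box, size=(n, 3))
    if lloyd_sweeps > 0:
        center = np.full(3, box / 2.0)
        if focus_radius is None:
            mask = np.ones(n, dtype=bool)
        else:
            mask = np.linalg.norm(pts - center, axis=1) < focus_radius
        for _ in range(lloyd_sweeps):
            pts = _lloyd_sweep(pts, box, mask)
    return pts


def radius_for_count(points: np.ndarray, box: float, n_real: int) -> float:
    """Cut radius such that exactly ``n_real`` generators fall inside.

    The midpoint between the n-th and (n+1)-th order statistics of the
    center distances — the fixed point any bisection on the count converges to.
    """
    center = np.full(3, box / 2.0)
    d = np.sort(np.linalg.norm(points - center, axis=1))
    if n_real >= len(points):
        raise ValueError(f"cannot cut {n_real} cells from {len(points)} points")
    return 0.5 * (d[n_real - 1] + d[n_real])


def _order_ridge(vor: Voronoi, rv: List[int], axis: np.ndarray) -> List[int]:
    """Order ridge vertices into a cycle around the ridge's own axis."""
    pts = vor.vertices[rv]
    c = pts.mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rel = pts - c
    ang = np.arctan2(rel @ e2, rel @ e1)
    order = np.argsort(ang)
    return [rv[k] for k in order]


def build_spheroid(points: np.ndarray, radius: float, box: float,
                   rng: Optional[np.random.Generator] = None) -> CellComplex:
    """Cut a spheroid out of the periodic tessellation of ``points``.

    Real cells: generators within ``radius`` of the box center.  Two layers of
    the discarded cells (by face adjacency) are kept as empty padding; deeper
    discarded cells vanish.  Vertex positions are recentered so the box center
    is at the origin.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    center = np.full(3, box / 2.0)
    dist = np.linalg.norm(points - center, axis=1)
    real: Set[int] = set(np.nonzero(dist < radius)[0].tolist())
    if not real:
        raise ValueError(f"no generator lies within radius {radius}")
    all_pts, orig = _with_images(points, box)
    vor = Voronoi(all_pts)
    # adjacency over original indices
    adj: Dict[int, Set[int]] = {i: set() for i in range(n)}
    for a, b in vor.ridge_points:
        oa, ob = int(orig[a]), int(orig[b])
        if oa != ob:
            adj[oa].add(ob)
            adj[ob].add(oa)
    layer1 = set().union(*(adj[i] for i in real)) - real
    layer2 = set().union(*(adj[i] for i in layer1)) - real - layer1
    kept = real | layer1 | layer2

    cc = CellComplex()
    vmap: Dict[int, int] = {}

    def local_vertex(gv: int) -> int:
        if gv not in vmap:
            vmap[gv] = cc.add_vertex(vor.vertices[gv] - center)
        return vmap[gv]

    cell_faces: Dict[int, Dict[int, int]] = {i: {} for i in kept}
    for r, (a, b) in enumerate(vor.ridge_points):
        a, b = int(a), int(b)
        oa, ob = int(orig[a]), int(orig[b])
        if oa not in kept or ob not in kept:
            continue
        if a >= n or b >= n:
            # duplicate of a central-central ridge, shifted by the box; the
            # central copy carries the face (closure is verified below)
            continue
        rv = vor.ridge_vertices[r]
        if -1 in rv:
            raise ValueError("unbounded ridge inside the kept region")
        axis = points[b] - points[a]
        cyc_global = _order_ridge(vor, rv, axis)
        cyc = [local_vertex(g) for g in cyc_global]
        # orient the stored cycle outward from cell a
        poly = cc.positions[cyc]
        cf = poly.mean(axis=0)
        normal = np.cross(poly - cf, np.roll(poly, -1, axis=0) - cf).sum(axis=0)
        fid = cc.new_face(cyc if normal @ axis > 0 else cyc[::-1])
        cell_faces[a][fid] = 1
        cell_faces[b][fid] = -1
    for i in sorted(kept):
        cc.new_cell(cell_faces[i], REAL if i in real else EMPTY)
    # every real cell must be a closed oriented surface
    for msg in cc.audit(confluent=True):
        if "cell" in msg and "closed" in msg:
            raise ValueError(f"cut-out produced an open real cell: {msg}; "
                             "increase the box margin")
    return cc


def spheroid_complex(n_real: int, rng: np.random.Generator,
                     lloyd_sweeps: int = 2, layer_pad: float = 2.8,
                     margin: float = 2.6) -> CellComplex:
    """End-to-end construction: sample, relax, cut out ``n_real`` cells.

    ``layer_pad`` is the radial allowance for the two empty layers and
    ``margin`` the further distance kept between the padding and the periodic
    box, both in cell diameters (V0^{1/3}).
    """
    R = spheroid_radius(n_real)
    box_min = 2.0 * (R + layer_pad + margin)
    n_pts = int(math.ceil(box_min ** 3))
    box = box_edge_for(n_pts)
    pts = sample_seed_points(n_pts, box, rng, lloyd_sweeps=lloyd_sweeps,
                             focus_radius=R + layer_pad + 1.0)
    radius = radius_for_count(pts, box, n_real)
    return build_spheroid(pts, radius, box)
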