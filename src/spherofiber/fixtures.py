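"""Deterministic toy states for tests, demos and validation.

Available fixtures: ``single_cube_cell``, ``two_cell``,
``five_cell_short_edge`` (the generic interior-edge configuration: two polar
cells and three side cells meeting along one short axial edge),
``fcc_patch``, ``collinear_chain`` and ``monopole`` (a fiber network
contracted by springs anchored at a single central point — the idealized
radially-contractile monopole a solid-like spheroid approximates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import Voronoi

from .cellcomplex import EMPTY, REAL, CellComplex
from .fiber import FiberNetwork, build_fcc_network, carve_cavity

__all__ = ["make_fixture", "FIXTURE_NAMES", "MonopoleFixture",
           "relax_monopole", "complex_from_points", "regular_tetrahedron_cell"]

FIXTURE_NAMES = ("single_cube_cell", "two_cell", "five_cell_short_edge",
                 "fcc_patch", "collinear_chain", "monopole")

_CUBE_VERTS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)
# outward-oriented quads
_CUBE_FACES = [
    [0, 3, 2, 1],   # z = 0
    [4, 5, 6, 7],   # z = 1
    [0, 1, 5, 4],   # y = 0
    [2, 3, 7, 6],   # y = 1
    [0, 4, 7, 3],   # x = 0
    [1, 2, 6, 5],   # x = 1
]


def _single_cube() -> CellComplex:
    cc = CellComplex()
    cc.add_vertices(_CUBE_VERTS)
    fo = {cc.new_face(cyc): 1 for cyc in _CUBE_FACES}
    cc.new_cell(fo, REAL)
    return cc


def _two_cell() -> CellComplex:
    cc = CellComplex()
    extra = np.array([[2, 0, 0], [2, 1, 0], [2, 1, 1], [2, 0, 1]], dtype=float)
    cc.add_vertices(np.vstack([_CUBE_VERTS, extra]))
    fids = [cc.new_face(cyc) for cyc in _CUBE_FACES]
    cc.new_cell({f: 1 for f in fids}, REAL)
    shared = fids[5]                     # the x = 1 quad
    right = [
        [8, 9, 10, 11],                  # x = 2
        [1, 2, 9, 8],                    # z = 0
        [5, 11, 10, 6],                  # z = 1
        [1, 8, 11, 5],                   # y = 0
        [2, 6, 10, 9],                   # y = 1
    ]
    fo2 = {cc.new_face(cyc): 1 for cyc in right}
    fo2[shared] = -1
    cc.new_cell(fo2, REAL)
    return cc


def regular_tetrahedron_cell(edge: float = 1.0) -> CellComplex:
    """One real cell shaped as a regular tetrahedron with given edge length."""
    verts = edge * np.array([
        [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
    ], dtype=float) / (2.0 * math.sqrt(2.0))
    cc = CellComplex()
    cc.add_vertices(verts)
    faces = [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]]
    fo = {}
    centroid = verts.mean(axis=0)
    for cyc in faces:
        p = verts[cyc]
        normal = np.cross(p[1] - p[0], p[2] - p[0])
        outward = (p.mean(axis=0) - centroid) @ normal > 0
        fo[cc.new_face(cyc if outward else cyc[::-1])] = 1
    cc.new_cell(fo, REAL)
    return cc


def complex_from_points(points: np.ndarray, real: Set[int],
                        empty: Set[int]) -> CellComplex:
    """Cell complex from an open (non-periodic) Voronoi tessellation.

    Real cells must be interior (bounded, all their ridges among kept cells);
    empty cells on the hull may be open, which the confluent audit permits.
    """
    points = np.asarray(points, dtype=np.float64)
    vor = Voronoi(points)
    kept = real | empty
    cc = CellComplex()
    vmap: Dict[int, int] = {}

    def lv(gv: int) -> int:
        if gv not in vmap:
            vmap[gv] = cc.add_vertex(vor.vertices[gv])
        return vmap[gv]

    cell_faces: Dict[int, Dict[int, int]] = {i: {} for i in kept}
    for r, (a, b) in enumerate(vor.ridge_points):
        a, b = int(a), int(b)
        if a not in kept or b not in kept:
            continue
        rv = vor.ridge_vertices[r]
        if -1 in rv:
            if a in real or b in real:
                raise ValueError("a real cell is unbounded; add more padding")
            continue
        axis = points[b] - points[a]
        pts = vor.vertices[rv]
        c = pts.mean(axis=0)
        u = axis / np.linalg.norm(axis)
        ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        ang = np.arctan2((pts - c) @ e2, (pts - c) @ e1)
        cyc_global = [rv[k] for k in np.argsort(ang)]
        cyc = [lv(g) for g in cyc_global]
        poly = cc.positions[cyc]
        cf = poly.mean(axis=0)
        normal = np.cross(poly - cf, np.roll(poly, -1, axis=0) - cf).sum(axis=0)
        fid = cc.new_face(cyc if normal @ axis > 0 else cyc[::-1])
        cell_faces[a][fid] = 1
        cell_faces[b][fid] = -1
    for i in sorted(kept):
        cc.new_cell(cell_faces[i], REAL if i in real else EMPTY)
    return cc


def _five_cell() -> CellComplex:
    """Two polar cells + three side cells meeting along one interior edge.

    The polar generators sit farther from the origin than the equatorial
    ones, so the three side cells meet along a short axial edge whose
    endpoints are shared with the polar cells — exactly the generic
    edge-to-triangle configuration.  Slight symmetry breaking keeps qhull in
    general position.
    """
    h, r = 1.3, 1.0
    angles = np.array([0.07, 2 * np.pi / 3 + 0.13, 4 * np.pi / 3 + 0.19])
    core = [(0.011, -0.013, h), (0.017, 0.008, -h)]
    core += [(r * np.cos(a), r * np.sin(a), 0.021 * (i - 1))
             for i, a in enumerate(angles)]
    # deterministic padding shell (Fibonacci sphere)
    n_shell = 40
    k = np.arange(n_shell)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_shell
    rho = np.sqrt(1.0 - z * z)
    shell = 3.6 * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    pts = np.vstack([np.asarray(core), shell])
    return complex_from_points(pts, real=set(range(5)),
                               empty=set(range(5, 5 + n_shell)))


def _collinear_chain() -> FiberNetwork:
    positions = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    bonds = np.array([[0, 1], [1, 2]], dtype=np.int64)
    net = FiberNetwork(positions=positions, sites=np.arange(3),
                       bonds=bonds, occ=np.ones(2, dtype=bool),
                       l0=np.ones(2), triples=np.array([[0, 1, 2]], dtype=np.int64),
                       pinned=np.zeros(3, dtype=bool), spacing=1.0,
                       n_lattice_sites=3)
    net.K_S = 1.0
    net.K_B = 2.25e-4
    return net


@dataclass
class MonopoleFixture:
    net: FiberNetwork
    anchor_nodes: np.ndarray     # nodes pulled toward the origin
    anchor_rest: float           # contracted rest length of the anchor springs
    K_anchor: float


def _monopole(p: float = 0.8, seed: int = 7) -> MonopoleFixture:
    rng = np.random.default_rng(seed)
    net = build_fcc_network(6, 1.5, p, rng, pin_boundary=True)
    net = carve_cavity(net, 2.2)
    r = np.linalg.norm(net.positions, axis=1)
    anchors = np.nonzero((r < 2.2 + 1.6) & ~net.pinned)[0]
    return MonopoleFixture(net=net, anchor_nodes=anchors,
                           anchor_rest=0.3, K_anchor=2.25)


def relax_monopole(fx: MonopoleFixture, gtol: float = 1e-8,
                   maxiter: int = 4000) -> FiberNetwork:
    """Relax the monopole to mechanical equilibrium (zero temperature)."""
    from scipy.optimize import minimize

    from . import _kernels

    net = fx.net
    bi, bj, l0 = net.occupied_arrays()
    t0, t1, t2 = net.triples[:, 0], net.triples[:, 1], net.triples[:, 2]
    free = ~net.pinned
    base = net.positions.copy()
    K_S = getattr(net, "K_S", 1.0)
    K_B = getattr(net, "K_B", 2.25e-4)

    def fun(x):
        p = base.copy()
        p[free] = x.reshape(-1, 3)
        g = np.zeros_like(p)
        es, eb, status = _kernels.fiber_eval(p, bi, bj, l0, K_S,
                                             t0, t1, t2, K_B, True, g)
        if status:
            raise FloatingPointError("degenerate bond")
        ra = np.linalg.norm(p[fx.anchor_nodes], axis=1)
        stretch = ra - fx.anchor_rest
        e_anchor = 0.5 * fx.K_anchor * (stretch ** 2).sum()
        g[fx.anchor_nodes] -= (fx.K_anchor * stretch / np.maximum(ra, 1e-12)
                               )[:, None] * p[fx.anchor_nodes]
        return es + eb + e_anchor, -g[free].ravel()

    res = minimize(fun, base[free].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-15})
    out_pos = base.copy()
    out_pos[free] = res.x.reshape(-1, 3)
    relaxed = FiberNetwork(positions=out_pos, sites=net.sites.copy(),
                           bonds=net.bonds.copy(), occ=net.occ.copy(),
                           l0=net.l0.copy(), triples=net.triples.copy(),
                           pinned=net.pinned.copy(), spacing=net.spacing,
                           n_lattice_sites=net.n_lattice_sites)
    relaxed.K_S = K_S
    relaxed.K_B = K_B
    return relaxed


def make_fixture(name: str, **kwargs):
    """Build one of the named deterministic toy states."""
    builders = {
        "single_cube_cell": _single_cube,
        "two_cell": _two_cell,
        "five_cell_short_edge": _five_cell,
        "fcc_patch": lambda p=1.0, half_extent=4, seed=3: build_fcc_network(
            half_extent, 1.5, p, np.random.default_rng(seed)),
        "collinear_chain": _collinear_chain,
        "monopole": _monopole,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return builders[name](**kwargs)
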