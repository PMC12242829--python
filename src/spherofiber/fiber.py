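"""Diluted FCC fiber network with phantom-node crosslinks.

Bonds occupy a face-centered-cubic lattice and are independently removed with
probability ``1 - p``, which sets the network stiffness.  Each lattice site
hosts six fiber directions (twelve nearest neighbors); to keep crosslinks
freely rotating and at most two fibers stiffly connected per junction, every
site is split into three co-located *phantom nodes*, each hosting a random
pairing of two of the six directions.  Bending stiffness acts only on pairs of
occupied collinear bonds meeting at the same phantom node (rest angle pi);
there is no twist energy and no cross-fiber bending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _kernels

__all__ = ["FiberNetwork", "build_fcc_network", "carve_cavity",
           "fiber_energy", "fiber_forces", "shear_stiffness",
           "half_extent_for_sites", "site_count_for_half_extent",
           "FCC_SITE_DENSITY"]

# the 6 unsigned fiber directions of the FCC lattice (integer half-spacing coords)
_DIRECTIONS = np.array([
    [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1],
], dtype=np.int64)

#: lattice sites per unit volume at nearest-neighbor spacing 1
FCC_SITE_DENSITY = math.sqrt(2.0)


def site_count_for_half_extent(half_extent: int) -> int:
    """Number of FCC sites in the cube of integer half-width ``half_extent``."""
    span = np.arange(-half_extent, half_extent + 1)
    par = (span % 2 == 0)
    n_even = int(par.sum())
    n_odd = len(span) - n_even
    # i+j+k even: all-even, or exactly two odd
    return n_even ** 3 + 3 * n_even * n_odd ** 2


def half_extent_for_sites(n_sites: int) -> int:
    """Smallest integer half-extent whose cube holds at least ``n_sites``."""
    h = 1
    while site_count_for_half_extent(h) < n_sites:
        h += 1
    return h


@dataclass
class FiberNetwork:
    """Phantom-node fiber network state.

    ``positions`` holds the phantom nodes (3 per surviving site);
    ``bonds`` is (B, 2) into positions with occupancy flags ``occ``; rest
    lengths ``l0`` equal the lattice spacing.  ``triples`` (T, 3) are the
    collinear bending triples (i, j, k) with the shared phantom node in the
    middle.  Pinned nodes feel forces but are never moved by integrators.
    """

    positions: np.ndarray
    sites: np.ndarray            # (M,) lattice-site index per phantom node
    bonds: np.ndarray            # (B, 2) int
    occ: np.ndarray              # (B,) bool
    l0: np.ndarray               # (B,) float
    triples: np.ndarray          # (T, 3) int, over occupied bonds only
    pinned: np.ndarray           # (M,) bool
    spacing: float
    n_lattice_sites: int         # sites before carving (diagnostic)

    def __post_init__(self) -> None:
        self._occ_cache: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None

    # occupied-bond arrays for the compiled kernel
    def occupied_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._occ_cache is None:
            sel = np.nonzero(self.occ)[0]
            self._occ_cache = (
                np.ascontiguousarray(self.bonds[sel, 0]),
                np.ascontiguousarray(self.bonds[sel, 1]),
                np.ascontiguousarray(self.l0[sel]),
            )
        return self._occ_cache

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def bond_lengths(self, occupied_only: bool = True) -> np.ndarray:
        if occupied_only:
            bi, bj, _ = self.occupied_arrays()
        else:
            bi, bj = self.bonds[:, 0], self.bonds[:, 1]
        return np.linalg.norm(self.positions[bj] - self.positions[bi], axis=1)

    def bond_strains(self) -> np.ndarray:
        """(l - l0)/l0 per occupied bond; negative = compression."""
        bi, bj, l0 = self.occupied_arrays()
        l = np.linalg.norm(self.positions[bj] - self.positions[bi], axis=1)
        return (l - l0) / l0

    def bond_tensions(self, K_S: float) -> np.ndarray:
        bi, bj, l0 = self.occupied_arrays()
        l = np.linalg.norm(self.positions[bj] - self.positions[bi], axis=1)
        return K_S * (l - l0)


def build_fcc_network(half_extent: int, spacing: float, p: float,
                      rng: np.random.Generator,
                      K_S: float = 1.0, K_B: float = 2.25e-4,
                      pin_boundary: bool = True) -> FiberNetwork:
    """Build the diluted FCC network in a cube of integer half-width.

    Lattice sites live at ``(i, j, k) * spacing / sqrt(2)`` with ``i+j+k``
    even and ``max(|i|,|j|,|k|) <= half_extent``; nearest-neighbor distance is
    ``spacing``.  Bonds are occupied independently with probability ``p``.
    If ``pin_boundary`` the outermost shell of sites (within one spacing of
    the cube surface) is pinned as a far-field anchor.
    """
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if half_extent < 2:
        raise ValueError("half_extent must be >= 2 (at least two shells)")
    h = half_extent
    rngspan = np.arange(-h, h + 1)
    ii, jj, kk = np.meshgrid(rngspan, rngspan, rngspan, indexing="ij")
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    coords = coords[(coords.sum(axis=1) % 2) == 0]
    n_sites = len(coords)
    site_index: Dict[Tuple[int, int, int], int] = {
        tuple(c): s for s, c in enumerate(coords)}
    scale = spacing / math.sqrt(2.0)

    # phantom split: random pairing of the 6 directions into 3 pairs per site
    # dir_node[s, d] = which of the site's 3 phantom nodes hosts direction d
    perms = np.argsort(rng.random((n_sites, 6)), axis=1)
    dir_node = np.empty((n_sites, 6), dtype=np.int64)
    for m in range(3):
        dir_node[np.arange(n_sites)[:, None], perms[:, 2 * m:2 * m + 2]] = m

    positions = np.repeat(coords.astype(np.float64) * scale, 3, axis=0)
    sites = np.repeat(np.arange(n_sites), 3)

    bonds: List[Tuple[int, int]] = []
    bond_site_dir: List[Tuple[int, int, int]] = []   # (site_u, site_v, dir)
    for s, c in enumerate(coords):
        for d in range(6):
            nb = tuple(c + _DIRECTIONS[d])
            v = site_index.get(nb)
            if v is None:
                continue
            bonds.append((3 * s + dir_node[s, d], 3 * v + dir_node[v, d]))
            bond_site_dir.append((s, v, d))
    bonds_arr = np.asarray(bonds, dtype=np.int64)
    occ = rng.random(len(bonds_arr)) < p
    l0 = np.full(len(bonds_arr), spacing)

    # bending triples: occupied collinear pairs sharing a phantom node
    occ_lookup: Dict[Tuple[int, int], bool] = {}
    for n_, (s, v, d) in enumerate(bond_site_dir):
        occ_lookup[(min(s, v) * 6 + d, max(s, v))] = bool(occ[n_])
    triples: List[Tuple[int, int, int]] = []
    for s, c in enumerate(coords):
        for d in range(6):
            up = site_index.get(tuple(c + _DIRECTIONS[d]))
            dn = site_index.get(tuple(c - _DIRECTIONS[d]))
            if up is None or dn is None:
                continue
            k_up = (min(s, up) * 6 + d, max(s, up))
            k_dn = (min(s, dn) * 6 + d, max(s, dn))
            if occ_lookup.get(k_up) and occ_lookup.get(k_dn):
                triples.append((3 * dn + dir_node[dn, d],
                                3 * s + dir_node[s, d],
                                3 * up + dir_node[up, d]))
    triples_arr = (np.asarray(triples, dtype=np.int64)
                   if triples else np.zeros((0, 3), dtype=np.int64))

    half_phys = h * scale
    if pin_boundary:
        pinned = np.max(np.abs(positions), axis=1) >= half_phys - spacing
    else:
        pinned = np.zeros(len(positions), dtype=bool)

    net = FiberNetwork(positions=positions, sites=sites, bonds=bonds_arr,
                       occ=occ, l0=l0, triples=triples_arr, pinned=pinned,
                       spacing=spacing, n_lattice_sites=n_sites)
    net.K_S = K_S
    net.K_B = K_B
    return net


def carve_cavity(net: FiberNetwork, cavity_radius: float) -> FiberNetwork:
    """Remove bonds with an endpoint inside the cavity; drop isolated nodes.

    Returns a new network with phantom nodes reindexed; bending triples that
    referenced removed bonds are dropped.
    """
    if cavity_radius < 0:
        raise ValueError("cavity_radius must be >= 0")
    r = np.linalg.norm(net.positions, axis=1)
    inside = r < cavity_radius
    kill = inside[net.bonds[:, 0]] | inside[net.bonds[:, 1]]
    occ = net.occ & ~kill
    keep_bond = ~kill
    used = np.zeros(net.n_nodes, dtype=bool)
    used[net.bonds[keep_bond].ravel()] = True
    if not used.any():
        raise ValueError("cavity swallows the entire lattice")
    new_id = -np.ones(net.n_nodes, dtype=np.int64)
    new_id[used] = np.arange(used.sum())
    bonds = new_id[net.bonds[keep_bond]]
    occ2 = occ[keep_bond]
    l0 = net.l0[keep_bond]
    # rebuild triples over surviving occupied bonds
    occ_pairs = set()
    for a, b in bonds[occ2]:
        occ_pairs.add((min(a, b), max(a, b)))
    triples = []
    for i, j, k in net.triples:
        if used[i] and used[j] and used[k]:
            ni, nj, nk = new_id[i], new_id[j], new_id[k]
            if ((min(ni, nj), max(ni, nj)) in occ_pairs
                    and (min(nj, nk), max(nj, nk)) in occ_pairs):
                triples.append((ni, nj, nk))
    triples_arr = (np.asarray(triples, dtype=np.int64)
                   if triples else np.zeros((0, 3), dtype=np.int64))
    out = FiberNetwork(positions=net.positions[used].copy(),
                       sites=net.sites[used].copy(),
                       bonds=bonds, occ=occ2, l0=l0, triples=triples_arr,
                       pinned=net.pinned[used].copy(), spacing=net.spacing,
                       n_lattice_sites=net.n_lattice_sites)
    out.K_S = getattr(net, "K_S", 1.0)
    out.K_B = getattr(net, "K_B", 2.25e-4)
    return out


def fiber_energy(net: FiberNetwork, K_S: Optional[float] = None,
                 K_B: Optional[float] = None) -> Tuple[float, float]:
    """(stretch_term, bend_term) of the network energy."""
    K_S = getattr(net, "K_S", 1.0) if K_S is None else K_S
    K_B = getattr(net, "K_B", 2.25e-4) if K_B is None else K_B
    bi, bj, l0 = net.occupied_arrays()
    es, eb, status = _kernels.fiber_eval(
        net.positions, bi, bj, l0, K_S,
        net.triples[:, 0], net.triples[:, 1], net.triples[:, 2], K_B,
        False, np.zeros((0, 3)))
    if status:
        raise FloatingPointError("degenerate (zero-length) bond in fiber network")
    return float(es), float(eb)


def fiber_forces(net: FiberNetwork, K_S: Optional[float] = None,
                 K_B: Optional[float] = None,
                 out: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic force on every phantom node (pinned nodes included)."""
    K_S = getattr(net, "K_S", 1.0) if K_S is None else K_S
    K_B = getattr(net, "K_B", 2.25e-4) if K_B is None else K_B
    bi, bj, l0 = net.occupied_arrays()
    forces = out if out is not None else np.zeros_like(net.positions)
    _, _, status = _kernels.fiber_eval(
        net.positions, bi, bj, l0, K_S,
        net.triples[:, 0], net.triples[:, 1], net.triples[:, 2], K_B,
        True, forces)
    if status:
        raise FloatingPointError("degenerate (zero-length) bond in fiber network")
    return forces


def shear_stiffness(net: FiberNetwork, strains, slab_fraction: float = 0.15,
                    gtol: float = 1e-10, maxiter: int = 5000) -> np.ndarray:
    """Shear modulus probe: clamp top/bottom slabs, shear, relax, read energy.

    For each strain ``gamma`` the slabs beyond ``(1 - slab_fraction)`` of the
    vertical half-height are displaced affinely (``x += gamma * z``), the free
    nodes are relaxed to mechanical equilibrium, and the stiffness
    ``2 E / (gamma^2 V)`` is reported with V the sheared volume.
    """
    from scipy.optimize import minimize

    K_S = getattr(net, "K_S", 1.0)
    K_B = getattr(net, "K_B", 2.25e-4)
    z = net.positions[:, 2]
    zmax = np.abs(z).max()
    clamped = np.abs(z) > (1.0 - slab_fraction) * zmax
    free = ~clamped
    if not free.any():
        raise ValueError("slab_fraction leaves no free nodes")
    span = net.positions.max(axis=0) - net.positions.min(axis=0)
    volume = float(np.prod(span))
    bi, bj, l0 = net.occupied_arrays()
    t0, t1, t2 = net.triples[:, 0], net.triples[:, 1], net.triples[:, 2]
    out = np.empty(len(np.atleast_1d(strains)))
    for si, gamma in enumerate(np.atleast_1d(strains)):
        pos = net.positions.copy()
        pos[:, 0] += gamma * pos[:, 2]     # affine initial guess

        def fun(x):
            p = pos.copy()
            p[free] = x.reshape(-1, 3)
            g = np.zeros_like(p)
            es, eb, status = _kernels.fiber_eval(
                p, bi, bj, l0, K_S, t0, t1, t2, K_B, True, g)
            if status:
                raise FloatingPointError("degenerate bond during relaxation")
            return es + eb, -g[free].ravel()

        res = minimize(fun, pos[free].ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "gtol": gtol,
                                "ftol": 1e-16})
        energy = float(res.fun)
        out[si] = 2.0 * energy / (gamma ** 2 * volume)
    return out
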