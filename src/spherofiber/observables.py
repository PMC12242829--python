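"""Measurements: rearrangement fraction, displacements, radial remodeling
profiles, fiber orientation tensors, spheroid shape and histograms.

Radial profiles are computed in concentric spherical shells about the spheroid
center of mass.  Fiber *density* assigns bond length to shells by exact
segment-sphere clipping (so total length is conserved across shells), while
the *orientation* tensor bins whole bonds by their midpoint; the tensor is the
length-weighted second moment of the bond unit vectors, normalized per shell
so its trace is one.  A radial-radial component above 1/3 indicates radial
alignment of the fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .cellcomplex import REAL, CellComplex
from .fiber import FiberNetwork
from .geometry import face_geometry, polygon_fan_geometry

__all__ = ["RadialProfile", "OrientationTensorProfile", "qn_fraction",
           "displacement", "density_profile", "orientation_profile",
           "spheroid_shape", "histograms", "default_shell_edges"]


@dataclass
class RadialProfile:
    edges: np.ndarray            # (n+1,) shell edges (absolute radii)
    values: np.ndarray           # (n,) per-shell quantity
    counts: np.ndarray           # (n,) contributing bonds (or length) per shell
    masked: np.ndarray           # (n,) True where the shell was empty


@dataclass
class OrientationTensorProfile:
    edges: np.ndarray
    tensors: np.ndarray          # (n, 3, 3) Cartesian, trace 1 where defined
    omega_rr: np.ndarray         # (n,) radial-radial component
    lengths: np.ndarray          # (n,) total (filtered) fiber length per shell
    masked: np.ndarray


def default_shell_edges(R_s: float, r_max: float,
                        width_factor: float = 0.25) -> np.ndarray:
    """Contiguous shells of width ``width_factor * R_s`` from 0 to ``r_max``."""
    w = width_factor * R_s
    n = max(1, int(np.ceil(r_max / w)))
    return np.arange(n + 1) * w


def qn_fraction(cc: CellComplex, initial_neighbors: Dict[int, Set[int]]
                ) -> float:
    """Fraction of real cells that have lost fewer than two initial neighbors."""
    current = cc.neighbor_map()
    cells = list(initial_neighbors)
    if set(cells) != set(current):
        raise ValueError("real-cell set changed since the initial snapshot")
    ok = sum(1 for c in cells
             if len(initial_neighbors[c] - current[c]) < 2)
    return ok / len(cells)


def displacement(centroid_samples: Sequence[np.ndarray], window: int,
                 R_s: float) -> np.ndarray:
    """Mean |cell-center displacement|/R_s over a trailing sample window."""
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    out = np.empty(len(centroid_samples))
    for k, c in enumerate(centroid_samples):
        ref = centroid_samples[max(0, k - window)]
        out[k] = np.linalg.norm(c - ref, axis=1).mean() / R_s
    return out


def _segment_shell_lengths(p1: np.ndarray, p2: np.ndarray, center: np.ndarray,
                           edges: np.ndarray) -> np.ndarray:
    """Length of each segment inside each shell (exact clipping).

    Vectorized over segments: for every segment the breakpoints where it
    crosses a shell sphere are found from the quadratic |p1 + t d - c|^2 = R^2
    and the inter-breakpoint pieces are assigned by the radius of their
    midpoint.
    """
    d = p2 - p1
    rel = p1 - center
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", rel, d)
    c0 = np.einsum("ij,ij->i", rel, rel)
    lengths = np.sqrt(a)
    n_seg = len(p1)
    n_shell = len(edges) - 1
    out = np.zeros((n_seg, n_shell))
    for s in range(n_seg):
        if lengths[s] < 1e-15:
            continue
        ts = [0.0, 1.0]
        for R in edges:
            disc = b[s] * b[s] - 4.0 * a[s] * (c0[s] - R * R)
            if disc <= 0:
                continue
            sq = np.sqrt(disc)
            for t in ((-b[s] - sq) / (2 * a[s]), (-b[s] + sq) / (2 * a[s])):
                if 0.0 < t < 1.0:
                    ts.append(t)
        ts = np.array(sorted(ts))
        mids = 0.5 * (ts[:-1] + ts[1:])
        pieces = (ts[1:] - ts[:-1]) * lengths[s]
        r_mid = np.sqrt(a[s] * mids * mids + b[s] * mids + c0[s])
        shells = np.searchsorted(edges, r_mid, side="right") - 1
        for piece, sh in zip(pieces, shells):
            if 0 <= sh < n_shell:
                out[s, sh] += piece
    return out


def density_profile(initial_positions: np.ndarray, net: FiberNetwork,
                    center: np.ndarray,
                    edges: Optional[np.ndarray] = None,
                    R_s: Optional[float] = None) -> RadialProfile:
    """Final/initial fiber density ratio per shell (shells fixed in the
    initial frame, centered on the initial spheroid center of mass).

    Requires the same occupied-bond set in both states (bonds never break).
    """
    if len(initial_positions) != net.n_nodes:
        raise ValueError("initial and final states have different bond sets")
    bi, bj, _ = net.occupied_arrays()
    if edges is None:
        if R_s is None:
            raise ValueError("provide either shell edges or R_s")
        r_max = float(np.linalg.norm(net.positions - center, axis=1).max())
        edges = default_shell_edges(R_s, r_max)
    li = _segment_shell_lengths(initial_positions[bi], initial_positions[bj],
                                center, edges)
    lf = _segment_shell_lengths(net.positions[bi], net.positions[bj],
                                center, edges)
    length_i = li.sum(axis=0)
    length_f = lf.sum(axis=0)
    masked = length_i <= 0
    values = np.divide(length_f, length_i,
                       out=np.full(len(length_i), np.nan), where=~masked)
    return RadialProfile(edges=np.asarray(edges), values=values,
                         counts=length_i, masked=masked)


def orientation_profile(net: FiberNetwork, center: np.ndarray,
                        edges: Optional[np.ndarray] = None,
                        strain_threshold: Optional[float] = None,
                        R_s: Optional[float] = None
                        ) -> OrientationTensorProfile:
    """Length-weighted fiber orientation tensor per shell (bond midpoints).

    ``strain_threshold`` keeps only bonds strained beyond it (e.g. 0.001 for
    the high-tension subpopulation).  Raises if the filter empties the set.
    """
    bi, bj, l0 = net.occupied_arrays()
    p1 = net.positions[bi]
    p2 = net.positions[bj]
    vec = p2 - p1
    length = np.linalg.norm(vec, axis=1)
    good = length > 1e-15
    if strain_threshold is not None:
        good &= (length - l0) / l0 > strain_threshold
    if not good.any():
        raise ValueError("no bonds pass the strain filter")
    p1, p2, vec, length = p1[good], p2[good], vec[good], length[good]
    mid = 0.5 * (p1 + p2) - center
    r = np.linalg.norm(mid, axis=1)
    if edges is None:
        if R_s is None:
            edges = np.array([0.0, max(r.max(), 1e-9) * (1 + 1e-12)])
        else:
            edges = default_shell_edges(R_s, float(r.max()) * (1 + 1e-12))
    edges = np.asarray(edges)
    n_shell = len(edges) - 1
    shell = np.searchsorted(edges, r, side="right") - 1
    nhat = vec / length[:, None]
    rhat = np.divide(mid, np.maximum(r, 1e-15)[:, None])
    tensors = np.zeros((n_shell, 3, 3))
    omega_rr = np.full(n_shell, np.nan)
    lengths = np.zeros(n_shell)
    for s in range(n_shell):
        sel = shell == s
        if not sel.any():
            continue
        L = length[sel]
        lengths[s] = L.sum()
        outer = np.einsum("k,ki,kj->ij", L, nhat[sel], nhat[sel])
        tensors[s] = outer / lengths[s]
        proj = np.einsum("ki,ki->k", nhat[sel], rhat[sel])
        omega_rr[s] = float((L * proj ** 2).sum() / lengths[s])
    masked = lengths <= 0
    return OrientationTensorProfile(edges=edges, tensors=tensors,
                                    omega_rr=omega_rr, lengths=lengths,
                                    masked=masked)


def spheroid_shape(cc: CellComplex, R_s: Optional[float] = None
                   ) -> Tuple[float, float, float, np.ndarray]:
    """(A_sp, V_sp, A_sp/V_sp^(2/3), per-face surface deviation).

    The spheroid surface is the set of interface faces, oriented outward from
    the real region; its volume follows from the divergence theorem.  The
    deviation of face alpha is ``|center_alpha - com| - R_s`` (NaN entries if
    R_s is not given).
    """
    iface = sorted(cc.interface_faces())
    if not iface:
        raise ValueError("no interface faces (no empty padding?)")
    if cc.interface_surface_components() != 1:
        raise ValueError("interface surface is not a single closed component")
    fc = cc.face_cells()
    A = 0.0
    V = 0.0
    centers = np.empty((len(iface), 3))
    for k, fid in enumerate(iface):
        orient = next(o for c, o in fc[fid] if cc.cell_label[c] == REAL)
        area, center, vol = face_geometry(cc.faces[fid], cc.positions)
        A += area
        V += orient * vol
        centers[k] = center
    if V <= 0:
        raise ValueError("non-positive spheroid volume")
    # center of mass of the enclosed region ~ area-weighted face centers
    com = centers.mean(axis=0)
    dev = np.linalg.norm(centers - com, axis=1) - (R_s if R_s else np.nan)
    return A, V, A / V ** (2.0 / 3.0), dev


def histograms(cc: Optional[CellComplex] = None,
               net: Optional[FiberNetwork] = None,
               bins: int = 40) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Normalized histograms: shape index s_i, V_i/V0 and bond strain.

    Returns ``{name: (bin_edges, density)}``; densities integrate to one.
    """
    from .mechanics import cell_volumes_areas

    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    if cc is not None:
        _, V, A = cell_volumes_areas(cc)
        if np.any(V <= 0):
            raise ValueError("non-positive cell volume")
        s = A / V ** (2.0 / 3.0)
        dens, edges = np.histogram(s, bins=bins, density=True)
        out["shape_index"] = (edges, dens)
        dens, edges = np.histogram(V, bins=bins, density=True)
        out["volume_ratio"] = (edges, dens)
    if net is not None:
        strain = net.bond_strains()
        dens, edges = np.histogram(strain, bins=bins, density=True)
        out["bond_strain"] = (edges, dens)
    return out
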