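"""Polyhedral geometry: face areas/centroids, cell volumes and shape indices.

A polygonal face (possibly nonplanar) is triangulated as a fan from the
arithmetic mean of its vertices; its area is the sum of triangle areas and its
signed volume contribution is the divergence-theorem cone volume of the
oriented fan.  The centroid is a *dependent* point, not a degree of freedom:
force evaluation (see :mod:`spherofiber.mechanics`) applies the chain rule
through it.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .cellcomplex import CellComplex

__all__ = ["face_geometry", "cell_geometry", "shape_index", "polygon_fan_geometry"]


def polygon_fan_geometry(poly: np.ndarray) -> Tuple[float, np.ndarray, float]:
    """Area, centroid, and signed cone volume of an ordered 3D polygon.

    The signed volume is the divergence-theorem contribution of the oriented
    fan triangulation: one sixth of ``sum det[c, p_k, p_{k+1}]``.
    """
    poly = np.asarray(poly, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 3:
        raise ValueError("polygon must be an (n>=3, 3) array")
    c = poly.mean(axis=0)
    p1 = poly
    p2 = np.roll(poly, -1, axis=0)
    cross = np.cross(p1 - c, p2 - c)
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    vol = np.einsum("i,ki->", c, np.cross(p1, p2)).item() / 6.0
    return float(area), c, float(vol)


def face_geometry(face: Sequence[int], positions: np.ndarray
                  ) -> Tuple[float, np.ndarray, float]:
    """Area, centroid and signed volume contribution of a face vertex cycle."""
    face = list(face)
    if len(face) < 3:
        raise ValueError("face needs at least 3 vertices")
    if len(set(face)) != len(face):
        raise ValueError(f"face has repeated vertex indices: {face}")
    return polygon_fan_geometry(np.asarray(positions)[face])


def cell_geometry(complex_or_faces, cid_or_orients, positions=None
                  ) -> Tuple[float, float]:
    """Volume and surface area of a closed polyhedral cell.

    Either ``cell_geometry(complex, cid)`` or
    ``cell_geometry(face_cycles, orientations, positions)`` with parallel
    sequences of vertex cycles and +-1 orientations.
    """
    if isinstance(complex_or_faces, CellComplex):
        cc: CellComplex = complex_or_faces
        cid = cid_or_orients
        cycles = [cc.faces[f] for f in cc.cells[cid]]
        orients = [cc.cells[cid][f] for f in cc.cells[cid]]
        positions = cc.positions
    else:
        cycles = list(complex_or_faces)
        orients = list(cid_or_orients)
    V = 0.0
    A = 0.0
    for cyc, o in zip(cycles, orients):
        a, _, v = face_geometry(cyc, positions)
        A += a
        V += o * v
    return float(V), float(A)


def shape_index(complex_or_faces, cid_or_orients, positions=None) -> float:
    """Dimensionless shape index ``A / V**(2/3)`` of a single cell.

    Bounded below by ``(36*pi)**(1/3) ~ 4.836`` (the sphere), about 5.345 for
    a regular dodecahedron, 6 for a cube and about 7.21 for a regular
    tetrahedron.
    """
    V, A = cell_geometry(complex_or_faces, cid_or_orients, positions)
    if V <= 0:
        raise ValueError(f"cell volume must be positive, got {V}")
    return A / V ** (2.0 / 3.0)
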