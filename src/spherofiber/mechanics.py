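"""Vertex-model energy and analytic forces over a cell complex.

The tissue energy is

    E_VM = K_V sum_j (V_j - V0)^2 + K_A sum_j (A_j - A0)^2
           + Gamma sum_{interface faces} S_alpha

summed over *real* cells only; empty padding cells carry no energy.  The
interfacial tension acts on the faces separating real cells from empty cells.
Forces are the exact negative gradient with respect to every vertex, with the
fan-centroid treated as a dependent point (chain rule), and are checked
against central finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set

import numpy as np

from . import _kernels
from .cellcomplex import CellComplex
from .config import SPHERE_SHAPE_INDEX, SimulationConfig

__all__ = ["VertexModelParams", "EnergyBreakdown", "MechCache",
           "vm_energy", "vm_forces", "cell_volumes_areas"]


@dataclass(frozen=True)
class VertexModelParams:
    K_V: float = 1.0
    K_A: float = 0.01
    V0: float = 1.0
    A0: float = 5.2
    Gamma: float = 1.0

    def __post_init__(self) -> None:
        if min(self.K_V, self.K_A, self.Gamma) < 0:
            raise ValueError("stiffnesses must be nonnegative")
        if self.A0 < SPHERE_SHAPE_INDEX * self.V0 ** (2.0 / 3.0) - 1e-12:
            raise ValueError("A0 below the isoperimetric sphere bound")

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "VertexModelParams":
        return cls(K_V=cfg.K_V, K_A=cfg.K_A, V0=cfg.V0, A0=cfg.A0,
                   Gamma=cfg.Gamma)


@dataclass
class EnergyBreakdown:
    volume_term: float
    area_term: float
    tension_term: float

    @property
    def total(self) -> float:
        return self.volume_term + self.area_term + self.tension_term


class MechCache:
    """Flattened index arrays for the compiled vertex-model kernel.

    Built once per topology; reused every step until a reconnection event
    invalidates it.  Only faces belonging to at least one real cell enter the
    arrays (empty-empty faces carry no energy).
    """

    def __init__(self, cc: CellComplex, gamma: float,
                 interface_faces: Optional[Set[int]] = None) -> None:
        fids = cc.faces_of_real_cells()
        self.fid_to_local: Dict[int, int] = {f: i for i, f in enumerate(fids)}
        self.fids = fids
        off = [0]
        idx: list = []
        for f in fids:
            idx.extend(cc.faces[f])
            off.append(len(idx))
        self.f_off = np.asarray(off, dtype=np.int64)
        self.f_idx = np.asarray(idx, dtype=np.int64)
        iface = cc.interface_faces() if interface_faces is None else interface_faces
        self.f_tension = np.array(
            [gamma if f in iface else 0.0 for f in fids], dtype=np.float64)
        self.cell_ids = list(cc.real_cells())
        c_off = [0]
        c_face: list = []
        c_orient: list = []
        for cid in self.cell_ids:
            for f, o in cc.cells[cid].items():
                c_face.append(self.fid_to_local[f])
                c_orient.append(o)
            c_off.append(len(c_face))
        self.c_f_off = np.asarray(c_off, dtype=np.int64)
        self.c_f_face = np.asarray(c_face, dtype=np.int64)
        self.c_f_orient = np.asarray(c_orient, dtype=np.float64)
        # vertices that feel tissue forces (any vertex of a real cell's face)
        self.mobile_vertices = np.unique(self.f_idx)
        self.cellV = np.zeros(len(self.cell_ids))
        self.cellA = np.zeros(len(self.cell_ids))

    def evaluate(self, positions: np.ndarray, params: VertexModelParams,
                 forces: Optional[np.ndarray] = None) -> EnergyBreakdown:
        want = forces is not None
        if not want:
            forces = np.zeros((0, 3))
        ev, ea, et = _kernels.vm_eval(
            positions, self.f_off, self.f_idx, self.f_tension,
            self.c_f_off, self.c_f_face, self.c_f_orient,
            params.K_V, params.K_A, params.V0, params.A0,
            want, forces, self.cellV, self.cellA)
        return EnergyBreakdown(ev, ea, et)


def _require_labels(cc: CellComplex) -> None:
    missing = [c for c in cc.cells if c not in cc.cell_label]
    if missing:
        raise ValueError(f"cells without labels: {missing}")


def vm_energy(cc: CellComplex, params: VertexModelParams,
              interface_faces: Optional[Set[int]] = None) -> EnergyBreakdown:
    """Energy breakdown of the complex (real cells only).

    ``interface_faces`` overrides the label-derived interface set; this is
    how standalone toy cells (no empty padding) can be given a tension patch.
    """
    _require_labels(cc)
    cache = MechCache(cc, params.Gamma, interface_faces)
    return cache.evaluate(cc.positions, params)


def vm_forces(cc: CellComplex, params: VertexModelParams,
              interface_faces: Optional[Set[int]] = None) -> np.ndarray:
    """Per-vertex force field, exactly ``-grad E_VM`` (full-size array)."""
    _require_labels(cc)
    cache = MechCache(cc, params.Gamma, interface_faces)
    forces = np.zeros_like(cc.positions)
    cache.evaluate(cc.positions, params, forces)
    return forces


def cell_volumes_areas(cc: CellComplex, params: Optional[VertexModelParams] = None):
    """(cell ids, volumes, areas) for all real cells via the compiled kernel."""
    params = params or VertexModelParams(A0=SPHERE_SHAPE_INDEX)
    cache = MechCache(cc, 0.0, set())
    cache.evaluate(cc.positions, params)
    return list(cache.cell_ids), cache.cellV.copy(), cache.cellA.copy()
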