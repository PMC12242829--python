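"""Polyhedral cell complex: vertices, polygonal faces, polyhedral cells.

Cells are stored as ``{face_id: orientation}`` maps where orientation ``+1``
means the stored vertex cycle of the face, traversed in order, has an outward
normal for that cell (and ``-1`` the reverse).  Interior faces are shared by
exactly two cells with opposite orientations.  Cells carry a ``real`` or
``empty`` label: empty cells pad the spheroid so that its surface has a
well-defined topology, carry no mechanical energy, but participate fully in
reconnection events.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = ["CellComplex", "edge_key", "edge_key_verts"]

REAL = "real"
EMPTY = "empty"


def edge_key(a: int, b: int) -> int:
    """Order-free integer key of an undirected edge (cheap dict key)."""
    return (a << 32) | b if a < b else (b << 32) | a


def edge_key_verts(key: int) -> Tuple[int, int]:
    return key >> 32, key & 0xFFFFFFFF


class CellComplex:
    def __init__(self) -> None:
        self.positions = np.zeros((0, 3), dtype=np.float64)
        self.vertex_active = np.zeros(0, dtype=bool)
        self.faces: Dict[int, List[int]] = {}
        self.cells: Dict[int, Dict[int, int]] = {}
        self.cell_label: Dict[int, str] = {}
        self._vfree: List[int] = []
        self._next_fid = 0
        self._next_cid = 0
        self._topo_version = 0
        self._cache: Dict[str, object] = {}

    # ------------------------------------------------------------------ build
    def add_vertices(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        n0 = self.positions.shape[0]
        self.positions = np.vstack([self.positions, xyz])
        self.vertex_active = np.concatenate(
            [self.vertex_active, np.ones(len(xyz), dtype=bool)])
        self._touch()
        return np.arange(n0, n0 + len(xyz))

    def add_vertex(self, xyz) -> int:
        if self._vfree:
            v = self._vfree.pop()
            self.positions[v] = np.asarray(xyz, dtype=np.float64)
            self.vertex_active[v] = True
            self._touch()
            return v
        return int(self.add_vertices(np.asarray(xyz)[None, :])[0])

    def free_vertex(self, v: int) -> None:
        self.vertex_active[v] = False
        self._vfree.append(int(v))
        self._touch()

    def new_face(self, cycle: Sequence[int]) -> int:
        cycle = [int(v) for v in cycle]
        if len(cycle) < 3 or len(set(cycle)) != len(cycle):
            raise ValueError(f"face cycle must be >=3 distinct vertices, got {cycle}")
        fid = self._next_fid
        self._next_fid += 1
        self.faces[fid] = cycle
        self._touch()
        return fid

    def drop_face(self, fid: int) -> None:
        del self.faces[fid]
        self._touch()

    def new_cell(self, face_orients: Dict[int, int], label: str = REAL) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.cells[cid] = dict(face_orients)
        self.cell_label[cid] = label
        self._touch()
        return cid

    def _touch(self) -> None:
        self._topo_version += 1
        self._cache.clear()

    def copy(self) -> "CellComplex":
        other = CellComplex()
        other.positions = self.positions.copy()
        other.vertex_active = self.vertex_active.copy()
        other.faces = {f: list(c) for f, c in self.faces.items()}
        other.cells = {c: dict(fo) for c, fo in self.cells.items()}
        other.cell_label = dict(self.cell_label)
        other._vfree = list(self._vfree)
        other._next_fid = self._next_fid
        other._next_cid = self._next_cid
        return other

    # ------------------------------------------------------------ derived maps
    def _cached(self, key: str, builder):
        if key not in self._cache:
            self._cache[key] = builder()
        return self._cache[key]

    def real_cells(self) -> List[int]:
        return self._cached(
            "real_cells",
            lambda: [c for c, lab in self.cell_label.items() if lab == REAL])

    def face_cells(self) -> Dict[int, List[Tuple[int, int]]]:
        """face id -> list of (cell id, orientation) incidences."""
        def build():
            fc: Dict[int, List[Tuple[int, int]]] = {f: [] for f in self.faces}
            for cid, fo in self.cells.items():
                for fid, o in fo.items():
                    fc[fid].append((cid, o))
            return fc
        return self._cached("face_cells", build)

    def interface_faces(self) -> Set[int]:
        """Faces separating a real cell from an empty cell."""
        def build():
            out = set()
            for fid, inc in self.face_cells().items():
                if len(inc) == 2:
                    labs = {self.cell_label[c] for c, _ in inc}
                    if labs == {REAL, EMPTY}:
                        out.add(fid)
            return out
        return self._cached("interface_faces", build)

    def boundary_cells(self) -> Set[int]:
        """Real cells sharing at least one face with an empty cell."""
        def build():
            out = set()
            for fid in self.interface_faces():
                for c, _ in self.face_cells()[fid]:
                    if self.cell_label[c] == REAL:
                        out.add(c)
            return out
        return self._cached("boundary_cells", build)

    def neighbor_map(self) -> Dict[int, Set[int]]:
        """Real cell -> set of face-sharing real cells (symmetric)."""
        def build():
            nm: Dict[int, Set[int]] = {c: set() for c in self.real_cells()}
            for inc in self.face_cells().values():
                if len(inc) == 2:
                    (c1, _), (c2, _) = inc
                    if self.cell_label[c1] == REAL and self.cell_label[c2] == REAL:
                        nm[c1].add(c2)
                        nm[c2].add(c1)
            return nm
        return self._cached("neighbor_map", build)

    def edge_faces(self) -> Dict[int, List[int]]:
        """Undirected edge (see :func:`edge_key`) -> incident face ids."""
        def build():
            ef: Dict[int, List[int]] = {}
            for fid, cyc in self.faces.items():
                prev = cyc[-1]
                for v in cyc:
                    e = edge_key(prev, v)
                    lst = ef.get(e)
                    if lst is None:
                        ef[e] = [fid]
                    else:
                        lst.append(fid)
                    prev = v
            return ef
        return self._cached("edge_faces", build)

    def vertex_faces(self) -> Dict[int, List[int]]:
        def build():
            vf: Dict[int, List[int]] = {}
            for fid, cyc in self.faces.items():
                for v in cyc:
                    lst = vf.get(v)
                    if lst is None:
                        vf[v] = [fid]
                    else:
                        lst.append(fid)
            return vf
        return self._cached("vertex_faces", build)

    def vertex_edges(self) -> Dict[int, Set[int]]:
        """Vertex -> set of adjacent vertices (over all face edges)."""
        def build():
            ve: Dict[int, Set[int]] = {}
            for key in self.edge_faces():
                a, b = key >> 32, key & 0xFFFFFFFF
                sa = ve.get(a)
                if sa is None:
                    ve[a] = {b}
                else:
                    sa.add(b)
                sb = ve.get(b)
                if sb is None:
                    ve[b] = {a}
                else:
                    sb.add(a)
            return ve
        return self._cached("vertex_edges", build)

    def cell_vertices(self, cid: int) -> List[int]:
        seen: Set[int] = set()
        for fid in self.cells[cid]:
            seen.update(self.faces[fid])
        return sorted(seen)

    def real_edge_array(self) -> np.ndarray:
        """(E, 2) array of edges on faces of real cells (for candidate scans)."""
        def build():
            seen: Set[int] = set()
            for fid in self.faces_of_real_cells():
                cyc = self.faces[fid]
                prev = cyc[-1]
                for v in cyc:
                    seen.add(edge_key(prev, v))
                    prev = v
            if not seen:
                return np.zeros((0, 2), dtype=np.int64)
            keys = np.fromiter(seen, dtype=np.int64, count=len(seen))
            keys.sort()
            return np.stack([keys >> 32, keys & 0xFFFFFFFF], axis=1)
        return self._cached("real_edge_array", build)

    def real_triangle_faces(self) -> np.ndarray:
        """(T, 4) array [fid, v0, v1, v2] of triangular faces of real cells."""
        def build():
            rows = [(fid, *self.faces[fid]) for fid in self.faces_of_real_cells()
                    if len(self.faces[fid]) == 3]
            return (np.asarray(rows, dtype=np.int64) if rows
                    else np.zeros((0, 4), dtype=np.int64))
        return self._cached("real_triangle_faces", build)

    def faces_of_real_cells(self) -> List[int]:
        def build():
            out: Set[int] = set()
            for c in self.real_cells():
                out.update(self.cells[c])
            return sorted(out)
        return self._cached("faces_of_real_cells", build)

    # ------------------------------------------------------------------ audit
    def audit(self, confluent: bool = True) -> List[str]:
        """Validity audit.  Returns a list of human-readable violations.

        ``confluent=True`` additionally requires that every face of a real
        cell is shared by exactly two cells (real spheroids are padded by
        empty cells); the outermost hull faces of the empty padding are the
        only faces allowed a single incidence.
        """
        problems: List[str] = []
        fc = self.face_cells()
        for fid, cyc in self.faces.items():
            if len(cyc) < 3 or len(set(cyc)) != len(cyc):
                problems.append(f"face {fid} has a degenerate cycle {cyc}")
            if not all(self.vertex_active[v] for v in cyc):
                problems.append(f"face {fid} references an inactive vertex")
            inc = fc[fid]
            if len(inc) == 0 or len(inc) > 2:
                problems.append(f"face {fid} has {len(inc)} incident cells")
            if len(inc) == 2 and inc[0][1] * inc[1][1] != -1:
                problems.append(f"face {fid} has inconsistent orientations")
            if confluent and len(inc) == 1 and self.cell_label[inc[0][0]] == REAL:
                problems.append(f"face {fid} of real cell {inc[0][0]} is unshared")
        # closed, orientable cells
        for cid, fo in self.cells.items():
            directed: Dict[Tuple[int, int], int] = {}
            verts: Set[int] = set()
            for fid, o in fo.items():
                cyc = self.faces[fid] if o == 1 else self.faces[fid][::-1]
                n = len(cyc)
                verts.update(cyc)
                for k in range(n):
                    e = (cyc[k], cyc[(k + 1) % n])
                    directed[e] = directed.get(e, 0) + 1
            open_cell = False
            for (a, b), cnt in directed.items():
                if cnt != 1 or directed.get((b, a), 0) != 1:
                    open_cell = True
            if open_cell:
                if self.cell_label[cid] == REAL or not confluent:
                    problems.append(f"cell {cid} is not a closed oriented surface")
                continue
            V, E, F = len(verts), len(directed) // 2, len(fo)
            if V - E + F != 2:
                problems.append(f"cell {cid} Euler characteristic {V - E + F} != 2")
        # no two cells share two or more faces
        pair_count: Dict[Tuple[int, int], int] = {}
        for inc in fc.values():
            if len(inc) == 2:
                key = tuple(sorted((inc[0][0], inc[1][0])))
                pair_count[key] = pair_count.get(key, 0) + 1
        for pair, cnt in pair_count.items():
            if cnt > 1:
                problems.append(f"cells {pair} share {cnt} faces")
        if confluent:
            for fid in self.interface_faces():
                labs = sorted(self.cell_label[c] for c, _ in fc[fid])
                if labs != [EMPTY, REAL]:
                    problems.append(f"interface face {fid} has labels {labs}")
        return problems

    def interface_surface_components(self) -> int:
        """Number of connected components of the interface-face surface."""
        ifaces = list(self.interface_faces())
        if not ifaces:
            return 0
        edge_to_faces: Dict[FrozenSet[int], List[int]] = {}
        for fid in ifaces:
            cyc = self.faces[fid]
            n = len(cyc)
            for k in range(n):
                e = frozenset((cyc[k], cyc[(k + 1) % n]))
                edge_to_faces.setdefault(e, []).append(fid)
        adj: Dict[int, Set[int]] = {f: set() for f in ifaces}
        for flist in edge_to_faces.values():
            for i in range(len(flist)):
                for j in range(i + 1, len(flist)):
                    adj[flist[i]].add(flist[j])
                    adj[flist[j]].add(flist[i])
        seen: Set[int] = set()
        comps = 0
        for f in ifaces:
            if f in seen:
                continue
            comps += 1
            stack = [f]
            while stack:
                g = stack.pop()
                if g in seen:
                    continue
                seen.add(g)
                stack.extend(adj[g] - seen)
        return comps
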