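"""Persistence: HDF5 states/trajectories, legacy-ASCII VTK exports, CSV
observables and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .cellcomplex import CellComplex
from .config import SimulationConfig, dumps_config, loads_config
from .dynamics import SimulationState, Trajectory
from .fiber import FiberNetwork
from .linkers import Linker, LinkerSchedule, LinkerSet

__all__ = ["save_state", "load_state", "save_trajectory", "load_trajectory",
           "write_vtk_cells", "write_vtk_fibers", "write_vtk_linkers",
           "write_observables_csv", "RunManifest"]

_H5 = dict(track_times=False)


# --------------------------------------------------------------------- states
def _complex_to_group(cc: CellComplex, g: h5py.Group) -> None:
    g.create_dataset("positions", data=cc.positions, **_H5)
    g.create_dataset("vertex_active", data=cc.vertex_active, **_H5)
    fids = sorted(cc.faces)
    idx, off = [], [0]
    for f in fids:
        idx.extend(cc.faces[f])
        off.append(len(idx))
    g.create_dataset("face_ids", data=np.asarray(fids, dtype=np.int64), **_H5)
    g.create_dataset("face_idx", data=np.asarray(idx, dtype=np.int64), **_H5)
    g.create_dataset("face_off", data=np.asarray(off, dtype=np.int64), **_H5)
    cids = sorted(cc.cells)
    cf, co, coff = [], [], [0]
    for c in cids:
        for f, o in sorted(cc.cells[c].items()):
            cf.append(f)
            co.append(o)
        coff.append(len(cf))
    g.create_dataset("cell_ids", data=np.asarray(cids, dtype=np.int64), **_H5)
    g.create_dataset("cell_face", data=np.asarray(cf, dtype=np.int64), **_H5)
    g.create_dataset("cell_orient", data=np.asarray(co, dtype=np.int8), **_H5)
    g.create_dataset("cell_off", data=np.asarray(coff, dtype=np.int64), **_H5)
    labels = np.asarray([1 if cc.cell_label[c] == "real" else 0 for c in cids],
                        dtype=np.int8)
    g.create_dataset("cell_real", data=labels, **_H5)


def _complex_from_group(g: h5py.Group) -> CellComplex:
    cc = CellComplex()
    cc.positions = g["positions"][...]
    cc.vertex_active = g["vertex_active"][...].astype(bool)
    cc._vfree = [int(v) for v in np.nonzero(~cc.vertex_active)[0]]
    fids = g["face_ids"][...]
    idx = g["face_idx"][...]
    off = g["face_off"][...]
    for k, f in enumerate(fids):
        cc.faces[int(f)] = [int(v) for v in idx[off[k]:off[k + 1]]]
    cc._next_fid = int(fids.max()) + 1 if len(fids) else 0
    cids = g["cell_ids"][...]
    cf = g["cell_face"][...]
    co = g["cell_orient"][...]
    coff = g["cell_off"][...]
    real = g["cell_real"][...]
    for k, c in enumerate(cids):
        fo = {int(cf[j]): int(co[j]) for j in range(coff[k], coff[k + 1])}
        cc.cells[int(c)] = fo
        cc.cell_label[int(c)] = "real" if real[k] else "empty"
    cc._next_cid = int(cids.max()) + 1 if len(cids) else 0
    cc._touch()
    return cc


def _network_to_group(net: FiberNetwork, g: h5py.Group) -> None:
    g.create_dataset("positions", data=net.positions, **_H5)
    g.create_dataset("sites", data=net.sites, **_H5)
    g.create_dataset("bonds", data=net.bonds, **_H5)
    g.create_dataset("occ", data=net.occ, **_H5)
    g.create_dataset("l0", data=net.l0, **_H5)
    g.create_dataset("triples", data=net.triples, **_H5)
    g.create_dataset("pinned", data=net.pinned, **_H5)
    g.attrs["spacing"] = net.spacing
    g.attrs["n_lattice_sites"] = net.n_lattice_sites
    g.attrs["K_S"] = getattr(net, "K_S", 1.0)
    g.attrs["K_B"] = getattr(net, "K_B", 2.25e-4)


def _network_from_group(g: h5py.Group) -> FiberNetwork:
    net = FiberNetwork(
        positions=g["positions"][...], sites=g["sites"][...],
        bonds=g["bonds"][...], occ=g["occ"][...].astype(bool),
        l0=g["l0"][...], triples=g["triples"][...],
        pinned=g["pinned"][...].astype(bool),
        spacing=float(g.attrs["spacing"]),
        n_lattice_sites=int(g.attrs["n_lattice_sites"]))
    net.K_S = float(g.attrs["K_S"])
    net.K_B = float(g.attrs["K_B"])
    return net


def _linkers_to_group(lset: LinkerSet, g: h5py.Group) -> None:
    rows = np.asarray([[lk.cell, lk.face, lk.node] for lk in lset.linkers],
                      dtype=np.int64).reshape(-1, 3)
    g.create_dataset("ids", data=rows, **_H5)
    g.create_dataset("rest", data=np.asarray([lk.rest for lk in lset.linkers]),
                     **_H5)
    g.create_dataset("birth", data=np.asarray(
        [lk.birth_time for lk in lset.linkers]), **_H5)


def _linkers_from_group(g: h5py.Group) -> LinkerSet:
    ids = g["ids"][...]
    rest = g["rest"][...]
    birth = g["birth"][...]
    out = LinkerSet()
    for k in range(len(ids)):
        out.linkers.append(Linker(cell=int(ids[k, 0]), face=int(ids[k, 1]),
                                  node=int(ids[k, 2]), rest=float(rest[k]),
                                  birth_time=float(birth[k])))
    return out


def save_state(state: SimulationState, path) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["t"] = state.t
        h.attrs["config"] = dumps_config(state.cfg)
        _complex_to_group(state.cc, h.create_group("complex"))
        _network_to_group(state.net, h.create_group("network"))
        _linkers_to_group(state.linkers, h.create_group("linkers"))


def load_state(path) -> SimulationState:
    with h5py.File(path, "r") as h:
        cfg = loads_config(h.attrs["config"])
        cc = _complex_from_group(h["complex"])
        net = _network_from_group(h["network"])
        lset = _linkers_from_group(h["linkers"])
        t = float(h.attrs["t"])
    schedule = LinkerSchedule(t_on=cfg.t_on, l0_init=cfg.l0_init,
                              l0_final=cfg.l0_final,
                              interval=cfg.contraction_interval)
    return SimulationState(cc=cc, net=net, linkers=lset, schedule=schedule,
                           cfg=cfg, rng=np.random.default_rng(cfg.seed), t=t)


# ----------------------------------------------------------------- trajectory
def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["config"] = dumps_config(traj.cfg)
        h.attrs["seed"] = traj.seed
        h.attrs["R_s"] = traj.R_s
        if traj.aborted:
            h.attrs["aborted"] = traj.aborted
        h.create_dataset("times", data=np.asarray(traj.times), **_H5)
        g = h.create_group("series")
        for k, v in traj.series.items():
            g.create_dataset(k, data=np.asarray(v), **_H5)
        if traj.centroids:
            h.create_dataset("centroids", data=np.stack(traj.centroids), **_H5)
        if traj.initial_fiber_positions is not None:
            h.create_dataset("initial_fiber_positions",
                             data=traj.initial_fiber_positions, **_H5)
        if traj.initial_com is not None:
            h.create_dataset("initial_com", data=traj.initial_com, **_H5)
        if traj.event_log:
            ev = np.asarray([[t, 0 if kind == "edge_to_triangle" else 1]
                             for t, kind, _ in traj.event_log])
            h.create_dataset("event_log", data=ev, **_H5)
        if traj.state is not None:
            st = h.create_group("final_state")
            st.attrs["t"] = traj.state.t
            _complex_to_group(traj.state.cc, st.create_group("complex"))
            _network_to_group(traj.state.net, st.create_group("network"))
            _linkers_to_group(traj.state.linkers, st.create_group("linkers"))


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as h:
        cfg = loads_config(h.attrs["config"])
        traj = Trajectory(cfg=cfg, seed=int(h.attrs["seed"]),
                          R_s=float(h.attrs["R_s"]))
        traj.aborted = h.attrs.get("aborted")
        traj.times = [float(t) for t in h["times"][...]]
        for k in h["series"]:
            traj.series[k] = [float(x) for x in h["series"][k][...]]
        if "centroids" in h:
            traj.centroids = [c for c in h["centroids"][...]]
        if "initial_fiber_positions" in h:
            traj.initial_fiber_positions = h["initial_fiber_positions"][...]
        if "initial_com" in h:
            traj.initial_com = h["initial_com"][...]
        if "final_state" in h:
            st = h["final_state"]
            cc = _complex_from_group(st["complex"])
            net = _network_from_group(st["network"])
            lset = _linkers_from_group(st["linkers"])
            schedule = LinkerSchedule(t_on=cfg.t_on, l0_init=cfg.l0_init,
                                      l0_final=cfg.l0_final,
                                      interval=cfg.contraction_interval)
            traj.state = SimulationState(
                cc=cc, net=net, linkers=lset, schedule=schedule, cfg=cfg,
                rng=np.random.default_rng(cfg.seed), t=float(st.attrs["t"]))
    return traj


# ------------------------------------------------------------------------ VTK
def _compact_vertices(cc: CellComplex, fids) -> Tuple[np.ndarray, Dict[int, int]]:
    used = sorted({v for f in fids for v in cc.faces[f]})
    vmap = {v: i for i, v in enumerate(used)}
    return cc.positions[used], vmap


def write_vtk_cells(cc: CellComplex, path, real_only: bool = True) -> None:
    """Legacy-ASCII VTK polydata: the polygons of the (real) cells."""
    fids = cc.faces_of_real_cells() if real_only else sorted(cc.faces)
    pts, vmap = _compact_vertices(cc, fids)
    iface = cc.interface_faces()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspherofiber cells\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        size = sum(len(cc.faces[f]) + 1 for f in fids)
        fh.write(f"POLYGONS {len(fids)} {size}\n")
        for f in fids:
            cyc = cc.faces[f]
            fh.write(str(len(cyc)) + " " + " ".join(str(vmap[v]) for v in cyc)
                     + "\n")
        fh.write(f"CELL_DATA {len(fids)}\nSCALARS interface int 1\n"
                 "LOOKUP_TABLE default\n")
        for f in fids:
            fh.write(f"{1 if f in iface else 0}\n")


def write_vtk_fibers(net: FiberNetwork, path) -> None:
    """Legacy-ASCII VTK polydata lines with per-bond strain and occupancy."""
    bi, bj, l0 = net.occupied_arrays()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspherofiber network\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {net.n_nodes} float\n")
        for p in net.positions:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"LINES {len(bi)} {3 * len(bi)}\n")
        for a, b in zip(bi, bj):
            fh.write(f"2 {a} {b}\n")
        strain = net.bond_strains()
        fh.write(f"CELL_DATA {len(bi)}\nSCALARS strain float 1\n"
                 "LOOKUP_TABLE default\n")
        for s in strain:
            fh.write(f"{s:.6g}\n")


def write_vtk_linkers(state: SimulationState, path) -> None:
    rows = []
    for lk in state.linkers.linkers:
        center = state.cc.positions[np.asarray(state.cc.faces[lk.face])].mean(axis=0)
        rows.append((center, state.net.positions[lk.node]))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspherofiber linkers\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {2 * len(rows)} float\n")
        for a, b in rows:
            fh.write(f"{a[0]:.6g} {a[1]:.6g} {a[2]:.6g}\n")
            fh.write(f"{b[0]:.6g} {b[1]:.6g} {b[2]:.6g}\n")
        fh.write(f"LINES {len(rows)} {3 * len(rows)}\n")
        for k in range(len(rows)):
            fh.write(f"2 {2 * k} {2 * k + 1}\n")


# ------------------------------------------------------------------------ CSV
def write_observables_csv(traj: Trajectory, out_dir) -> List[Path]:
    """Tidy CSVs: the time series, and (if a final state is present) the
    radial remodeling profiles and final-state histograms."""
    from . import observables as obs

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    df = pd.DataFrame({"t": traj.times, **{k: v for k, v in traj.series.items()}})
    p = out_dir / "series.csv"
    df.to_csv(p, index=False)
    paths.append(p)
    if traj.state is not None and traj.initial_fiber_positions is not None:
        prof = obs.density_profile(traj.initial_fiber_positions,
                                   traj.state.net, traj.initial_com,
                                   R_s=traj.R_s)
        orient = obs.orientation_profile(traj.state.net, traj.initial_com,
                                         edges=prof.edges)
        rows = pd.DataFrame({
            "r_lo": prof.edges[:-1], "r_hi": prof.edges[1:],
            "density_ratio": prof.values, "omega_rr": orient.omega_rr,
            "fiber_length": orient.lengths,
        })
        p = out_dir / "radial_profiles.csv"
        rows.to_csv(p, index=False)
        paths.append(p)
        hists = obs.histograms(traj.state.cc, traj.state.net)
        for name, (edges, dens) in hists.items():
            hp = out_dir / f"hist_{name}.csv"
            pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                          "density": dens}).to_csv(hp, index=False)
            paths.append(hp)
    return paths


# ------------------------------------------------------------------- manifest
@dataclass
class RunManifest:
    config_hash: str
    seed: int
    code_version: str
    started: float
    finished: Optional[float] = None
    event_counts: Dict[str, int] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)

    @classmethod
    def start(cls, cfg: SimulationConfig, seed: int) -> "RunManifest":
        from . import __version__
        digest = hashlib.sha256(dumps_config(cfg).encode()).hexdigest()[:16]
        return cls(config_hash=digest, seed=seed, code_version=__version__,
                   started=_time.time())

    def finalize(self, traj: Trajectory, outputs: List[str]) -> "RunManifest":
        self.finished = _time.time()
        kinds: Dict[str, int] = {}
        for _, kind, _ in traj.event_log:
            kinds[kind] = kinds.get(kind, 0) + 1
        self.event_counts = kinds
        self.outputs = outputs
        return self

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
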