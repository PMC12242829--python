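"""Time integration of the coupled spheroid / fiber-network / linker system.

Cell vertices follow overdamped Brownian dynamics integrated with the
Euler-Maruyama scheme: ``r <- r + mu F dt + xi`` with i.i.d. Gaussian noise of
per-component variance ``2 mu kT_eff dt`` encoding active force fluctuations.
Fiber phantom nodes follow plain overdamped Euler updates with no noise, and
pinned nodes never move.  All forces derive from the total energy
``E = E_VM + E_FB + E_LS`` evaluated at the pre-step configuration.

The interleaving per step is fixed: forces -> integrate -> (on cadence)
reconnection sweep -> linker population update -> observables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from . import fiber as fiber_mod
from . import linkers as linkers_mod
from .builder import spheroid_complex, spheroid_radius
from .cellcomplex import CellComplex
from .config import SimulationConfig
from .fiber import FiberNetwork, build_fcc_network, carve_cavity
from .linkers import LinkerSchedule, LinkerSet, attach_linkers
from .mechanics import MechCache, VertexModelParams
from .reconnection import ReconnectionEvent, sweep

__all__ = ["DynamicsParams", "SimulationState", "Trajectory",
           "build_state", "step", "run", "euler_maruyama_update",
           "stability_dt_bound", "fiber_half_extent"]


@dataclass
class DynamicsParams:
    mu: float = 1.0
    mu_f: float = 1.0              # fiber-node mobility (same damping scale)
    kT_eff: float = 1.0e-4
    dt: float = 0.005
    reconnect_every: int = 10      # steps between reconnection sweeps
    observe_every: int = 1000      # steps between observable samples

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.mu_f <= 0:
            raise ValueError("mobilities must be positive")
        if self.reconnect_every < 1 or self.observe_every < 1:
            raise ValueError("cadences must be >= 1")

    @classmethod
    def from_config(cls, cfg: SimulationConfig, **over) -> "DynamicsParams":
        kw = dict(mu=cfg.mu, mu_f=cfg.mu, kT_eff=cfg.kT_eff, dt=cfg.dt)
        kw.update(over)
        return cls(**kw)


def stability_dt_bound(cfg: SimulationConfig) -> float:
    """Heuristic explicit-Euler stability bound from the stiffest local mode.

    The stiffest tissue mode is volume elasticity (curvature ~ 2 K_V A_f^2
    for a face of area A_f ~ V0^{2/3}), the stiffest network modes are bond
    stretching (~2 K_S) and the linker spring.  A conservative factor of ~10
    per-vertex incidences is folded in.
    """
    k_cell = 2.0 * cfg.K_V * cfg.V0 ** (4.0 / 3.0) * 10.0 \
        + 2.0 * cfg.K_A * cfg.A0 * 10.0 + cfg.Gamma
    k_fib = 2.0 * cfg.K_S * 4.0 + cfg.K_LS
    return 1.0 / (max(cfg.mu * k_cell, cfg.mu * k_fib))


def euler_maruyama_update(positions: np.ndarray, forces: np.ndarray,
                          mobility: float, dt: float, kT: float,
                          rng: np.random.Generator,
                          mask: Optional[np.ndarray] = None) -> None:
    """In-place overdamped update with optional Gaussian active noise."""
    if mask is None:
        sel = slice(None)
        n = len(positions)
    else:
        sel = mask
        n = int(mask.sum()) if mask.dtype == bool else len(mask)
    positions[sel] += mobility * dt * forces[sel]
    if kT > 0:
        sigma = math.sqrt(2.0 * mobility * kT * dt)
        positions[sel] += sigma * rng.standard_normal((n, 3))


@dataclass
class SimulationState:
    cc: CellComplex
    net: FiberNetwork
    linkers: LinkerSet
    schedule: LinkerSchedule
    cfg: SimulationConfig
    rng: np.random.Generator
    t: float = 0.0
    events: List[ReconnectionEvent] = field(default_factory=list)
    steps_done: int = 0
    _cache: Optional[MechCache] = None
    _linker_flat: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray,
                                 np.ndarray, np.ndarray]] = None
    _buffers: Optional[Tuple[np.ndarray, np.ndarray]] = None
    _vm_params: Optional[VertexModelParams] = None

    def buffers(self) -> Tuple[np.ndarray, np.ndarray]:
        if self._buffers is None:
            self._buffers = (np.zeros_like(self.cc.positions),
                             np.zeros_like(self.net.positions))
            self._free_nodes = np.nonzero(~self.net.pinned)[0]
        return self._buffers

    def vm_params(self) -> VertexModelParams:
        if self._vm_params is None:
            self._vm_params = VertexModelParams.from_config(self.cfg)
        return self._vm_params

    def invalidate(self) -> None:
        self._cache = None
        self._linker_flat = None
        self._buffers = None

    def mech_cache(self) -> MechCache:
        if self._cache is None:
            self._cache = MechCache(self.cc, self.cfg.Gamma)
        return self._cache

    def linker_flat(self):
        """Flattened linker arrays: (node, rest, face-vertex idx, offsets, counts)."""
        if self._linker_flat is None:
            nodes, rests, idx, off = [], [], [], [0]
            for lk in self.linkers.linkers:
                nodes.append(lk.node)
                rests.append(lk.rest)
                idx.extend(self.cc.faces[lk.face])
                off.append(len(idx))
            self._linker_flat = (
                np.asarray(nodes, dtype=np.int64),
                np.asarray(rests, dtype=np.float64),
                np.asarray(idx, dtype=np.int64),
                np.asarray(off, dtype=np.int64),
                np.diff(np.asarray(off, dtype=np.int64)).astype(np.float64),
            )
        return self._linker_flat

    def refresh_linker_rests(self) -> None:
        self.linkers.set_rest_lengths(self.t, self.schedule)
        if self._linker_flat is not None:
            nodes, rests, idx, off, cnt = self._linker_flat
            for i, lk in enumerate(self.linkers.linkers):
                rests[i] = lk.rest

    def energy(self) -> Dict[str, float]:
        params = VertexModelParams.from_config(self.cfg)
        eb = self.mech_cache().evaluate(self.cc.positions, params)
        es, ebend = fiber_mod.fiber_energy(self.net, self.cfg.K_S, self.cfg.K_B)
        el, _, _ = linkers_mod.linker_energy_forces(
            self.linkers, self.cc, self.net, self.cfg.K_LS)
        return {"volume": eb.volume_term, "area": eb.area_term,
                "tension": eb.tension_term, "stretch": es, "bend": ebend,
                "linker": el,
                "total": eb.total + es + ebend + el}


def _linker_forces_fast(state: SimulationState, cell_forces: np.ndarray,
                        fib_forces: np.ndarray) -> None:
    nodes, rests, idx, off, cnt = state.linker_flat()
    if len(nodes) == 0:
        return
    pos = state.cc.positions
    sums = np.add.reduceat(pos[idx], off[:-1], axis=0)
    centers = sums / cnt[:, None]
    d = state.net.positions[nodes] - centers
    l = np.linalg.norm(d, axis=1)
    safe = l > 1e-12
    stretch = np.where(safe, l - rests, 0.0)
    coef = np.where(safe, -state.cfg.K_LS * stretch / np.maximum(l, 1e-12), 0.0)
    f_node = coef[:, None] * d
    np.add.at(fib_forces, nodes, f_node)
    per_vertex = np.repeat(-f_node / cnt[:, None], np.diff(off), axis=0)
    np.add.at(cell_forces, idx, per_vertex)


def advance(state: SimulationState, params: DynamicsParams,
            n_steps: int) -> None:
    """Advance ``n_steps`` steps through the fused compiled kernel.

    Statistically identical to ``n_steps`` calls of :func:`step` (same update
    rule and noise law; the Gaussian block is drawn from the same generator).
    Topology must not change inside the block, so callers interleave this
    with reconnection sweeps.
    """
    from . import _kernels

    cache = state.mech_cache()
    cell_F, fib_F = state.buffers()
    nodes, rests, idx, off, cnt = state.linker_flat()
    cfg = state.cfg
    p = state.vm_params()
    mobile = cache.mobile_vertices
    noise = state.rng.standard_normal((n_steps, len(mobile), 3)) \
        if params.kT_eff > 0 else np.zeros((n_steps, len(mobile), 3))
    sigma = math.sqrt(2.0 * params.mu * params.kT_eff * params.dt)
    bi, bj, bl0 = state.net.occupied_arrays()
    tr = state.net.triples
    t_new = _kernels.advance_block(
        state.cc.positions, state.net.positions,
        cache.f_off, cache.f_idx, cache.f_tension,
        cache.c_f_off, cache.c_f_face, cache.c_f_orient,
        p.K_V, p.K_A, p.V0, p.A0,
        bi, bj, bl0, cfg.K_S, tr[:, 0], tr[:, 1], tr[:, 2], cfg.K_B,
        nodes, rests, idx, off, cfg.K_LS,
        mobile, state._free_nodes,
        noise, params.mu * params.dt, params.mu_f * params.dt, sigma,
        state.t, params.dt, state.schedule.t_on, state.schedule.l0_init,
        state.schedule.l0_final, state.schedule.interval,
        cell_F, fib_F, cache.cellV, cache.cellA)
    state.t = float(t_new)
    state.steps_done += n_steps
    for i, lk in enumerate(state.linkers.linkers):
        lk.rest = float(rests[i])
    if not (np.isfinite(state.cc.positions).all()
            and np.isfinite(state.net.positions).all()):
        raise FloatingPointError(
            f"non-finite position at t={state.t:.3f}; aborting")


_FINITE_CHECK_EVERY = 50


def step(state: SimulationState, params: DynamicsParams) -> None:
    """Advance one time step (both subsystems from the pre-step forces)."""
    cache = state.mech_cache()
    cell_forces, fib_forces = state.buffers()
    cell_forces[:] = 0.0
    fib_forces[:] = 0.0
    cache.evaluate(state.cc.positions, state.vm_params(), cell_forces)
    fiber_mod.fiber_forces(state.net, state.cfg.K_S, state.cfg.K_B,
                           out=fib_forces)
    _linker_forces_fast(state, cell_forces, fib_forces)
    euler_maruyama_update(state.cc.positions, cell_forces, params.mu,
                          params.dt, params.kT_eff, state.rng,
                          mask=cache.mobile_vertices)
    free = state._free_nodes
    state.net.positions[free] += params.mu_f * params.dt * fib_forces[free]
    state.t += params.dt
    state.steps_done += 1
    state.refresh_linker_rests()
    if state.steps_done % _FINITE_CHECK_EVERY == 0:
        if not (np.isfinite(state.cc.positions).all()
                and np.isfinite(state.net.positions).all()):
            raise FloatingPointError(
                f"non-finite position at t={state.t:.3f}; aborting")


def fiber_half_extent(cfg: SimulationConfig) -> int:
    """Integer lattice half-width implied by the configured site count N_f."""
    h = fiber_mod.half_extent_for_sites(cfg.N_f)
    return max(h, 2)


def build_state(cfg: SimulationConfig, seed: Optional[int] = None,
                lloyd_sweeps: int = 2, pin_boundary: bool = True,
                cavity_pad: float = 1.0) -> SimulationState:
    """Assemble the embedded-spheroid initial condition.

    Pipeline: random Voronoi spheroid cut-out; diluted FCC lattice (dilute
    first, carve second) with a cavity of radius ``R_s + cavity_pad * spacing``
    so the initial linker lengths sit near their initial rest length; linkers
    on a random half. . . on ``N_LS`` random boundary cells.
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    cc = spheroid_complex(cfg.N_c, rng, lloyd_sweeps=lloyd_sweeps)
    R_s = spheroid_radius(cfg.N_c, cfg.V0)
    cavity = R_s + cavity_pad * cfg.fcc_spacing
    h = fiber_half_extent(cfg)
    phys_half = h * cfg.fcc_spacing / math.sqrt(2.0)
    if phys_half < cavity + cfg.fcc_spacing:
        raise ValueError(
            f"N_f={cfg.N_f} gives a lattice half-width {phys_half:.2f} smaller "
            f"than the cavity {cavity:.2f} plus one spacing")
    net = build_fcc_network(h, cfg.fcc_spacing, cfg.p, rng,
                            K_S=cfg.K_S, K_B=cfg.K_B,
                            pin_boundary=pin_boundary)
    net = carve_cavity(net, cavity)
    schedule = LinkerSchedule(t_on=cfg.t_on, l0_init=cfg.l0_init,
                              l0_final=cfg.l0_final,
                              interval=cfg.contraction_interval)
    lset = attach_linkers(cc, net, cfg.N_LS, rng, t=0.0, schedule=schedule)
    return SimulationState(cc=cc, net=net, linkers=lset, schedule=schedule,
                           cfg=cfg, rng=rng)


@dataclass
class Trajectory:
    cfg: SimulationConfig
    seed: int
    R_s: float
    times: List[float] = field(default_factory=list)
    series: Dict[str, List[float]] = field(default_factory=dict)
    centroids: List[np.ndarray] = field(default_factory=list)  # per sample (N_c,3)
    initial_fiber_positions: Optional[np.ndarray] = None
    initial_neighbors: Optional[Dict[int, Set[int]]] = None
    initial_com: Optional[np.ndarray] = None
    event_log: List[Tuple[float, str, Tuple[int, ...]]] = field(default_factory=list)
    state: Optional[SimulationState] = None
    aborted: Optional[str] = None

    def record(self, key: str, value: float) -> None:
        self.series.setdefault(key, []).append(float(value))


def _real_cell_centroids(cc: CellComplex, cell_ids: List[int]) -> np.ndarray:
    out = np.empty((len(cell_ids), 3))
    for i, cid in enumerate(cell_ids):
        vs = cc.cell_vertices(cid)
        out[i] = cc.positions[vs].mean(axis=0)
    return out


def _spheroid_com(cc: CellComplex, cache: MechCache,
                  centroids: np.ndarray) -> np.ndarray:
    w = np.maximum(cache.cellV, 1e-12)
    return (w[:, None] * centroids).sum(axis=0) / w.sum()


def run(cfg: SimulationConfig, seed: Optional[int] = None,
        params: Optional[DynamicsParams] = None,
        lloyd_sweeps: int = 2, pin_boundary: bool = True,
        displacement_window: Optional[float] = None,
        enforce_dt_bound: bool = True,
        state: Optional[SimulationState] = None) -> Trajectory:
    """Run a full simulation and collect the observable series.

    ``displacement_window`` is the trailing window (in t0) for cell-center
    displacement; default is 5 observable samples.
    """
    from . import observables as obs

    if params is None:
        params = DynamicsParams.from_config(cfg)
    if enforce_dt_bound and params.dt > stability_dt_bound(cfg):
        raise ValueError(
            f"dt={params.dt} exceeds the estimated stability bound "
            f"{stability_dt_bound(cfg):.4g}; pass enforce_dt_bound=False to override")
    if state is None:
        state = build_state(cfg, seed=seed, lloyd_sweeps=lloyd_sweeps,
                            pin_boundary=pin_boundary)
    traj = Trajectory(cfg=cfg, seed=cfg.seed if seed is None else seed,
                      R_s=spheroid_radius(cfg.N_c, cfg.V0), state=state)
    cell_ids = list(state.cc.real_cells())
    traj.initial_neighbors = {c: set(v) for c, v in state.cc.neighbor_map().items()}
    traj.initial_fiber_positions = state.net.positions.copy()
    cache = state.mech_cache()
    params0 = VertexModelParams.from_config(cfg)
    cache.evaluate(state.cc.positions, params0)
    cent0 = _real_cell_centroids(state.cc, cell_ids)
    traj.initial_com = _spheroid_com(state.cc, cache, cent0)

    n_steps = int(round(cfg.t_f / params.dt))
    window_samples = 5
    if displacement_window is not None:
        window_samples = max(1, int(round(
            displacement_window / (params.dt * params.observe_every))))
    ramp_end = cfg.t_on + cfg.contraction_interval
    ref_force: Optional[float] = None

    def sample() -> None:
        nonlocal ref_force
        cachev = state.mech_cache()
        eb = cachev.evaluate(state.cc.positions,
                             VertexModelParams.from_config(cfg))
        traj.times.append(state.t)
        cents = _real_cell_centroids(state.cc, cell_ids)
        traj.centroids.append(cents)
        qn = obs.qn_fraction(state.cc, traj.initial_neighbors)
        traj.record("qn", qn)
        k = len(traj.centroids) - 1
        ref = traj.centroids[max(0, k - window_samples)]
        disp = np.linalg.norm(cents - ref, axis=1).mean() / traj.R_s
        traj.record("mean_disp", disp)
        _, taus = linkers_mod.linker_lengths_tensions(
            state.linkers, state.cc, state.net, cfg.K_LS)
        mean_f = float(np.abs(taus).mean()) if len(taus) else 0.0
        traj.record("mean_linker_force", mean_f)
        if ref_force is None and state.t >= ramp_end:
            ref_force = mean_f if mean_f > 0 else None
        traj.record("mean_linker_force_norm",
                    mean_f / ref_force if ref_force else np.nan)
        try:
            A_sp, V_sp, sp_idx, _ = obs.spheroid_shape(state.cc)
        except ValueError:
            A_sp = V_sp = sp_idx = np.nan
        traj.record("spheroid_shape", sp_idx)
        traj.record("mean_volume_ratio", float(cachev.cellV.mean() / cfg.V0))
        traj.record("energy_total", state.energy()["total"])
        traj.record("n_events", float(len(state.events)))

    sample()
    cooldown: Dict = {}
    try:
        istep = 0
        while istep < n_steps:
            block = min(params.reconnect_every, n_steps - istep)
            advance(state, params, block)
            istep += block
            if istep % params.reconnect_every == 0 or istep == n_steps:
                events = sweep(state.cc, cfg.l_th, state.rng, time=state.t,
                               vm_params=state.vm_params(), cooldown=cooldown)
                if events:
                    state.events.extend(events)
                    for ev in events:
                        traj.event_log.append((ev.time, ev.kind, ev.cells))
                    state.invalidate()
                    removed, created = linkers_mod.update_linker_population(
                        state.linkers, state.cc, state.net, state.rng,
                        state.t, state.schedule)
                    if removed or created:
                        state.invalidate()
            if istep % params.observe_every == 0:
                # degenerate-polygon linker triggers are checked on the
                # observable cadence even without reconnection events
                removed, created = linkers_mod.update_linker_population(
                    state.linkers, state.cc, state.net, state.rng,
                    state.t, state.schedule)
                if removed or created:
                    state.invalidate()
                sample()
    except FloatingPointError as exc:   # keep the partial trajectory
        traj.aborted = str(exc)
    return traj
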