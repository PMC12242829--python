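"""Prepackaged computational studies at the reduced scale.

`solid_fluid_sweep` runs the target-shape-index ensemble (3 seeds per s0 on
the reduced conditions of :mod:`spherofiber.presets`) and classifies each s0
as fluid-like when the ensemble-mean neighbor-retention fraction <Q_n> keeps
decreasing after the contraction ramp ends (negative least-squares slope
beyond two standard errors, after a short post-ramp dead time that excludes
ramp-release transients).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .dynamics import DynamicsParams, Trajectory, run
from .presets import REDUCED_RAMP, REDUCED_T_ON, reduced_config

__all__ = ["solid_fluid_sweep", "S0_GRID", "POST_RAMP_DEAD_TIME"]

S0_GRID = (5.2, 5.4, 5.6, 5.7, 5.8)
POST_RAMP_DEAD_TIME = 25.0   # t0


def _run_seed(seed: int, k: int, s0: float) -> int:
    return (seed + 7919 * (k + 1) + int(s0 * 10)) % (2 ** 31)


def solid_fluid_sweep(seed: int, s0_grid: Sequence[float] = S0_GRID,
                      n_seeds: int = 3, keep_trajectories: bool = False,
                      **config_over) -> Dict[float, dict]:
    """Run the sweep; per-s0 summary of the post-ramp <Q_n> trend.

    Returns ``{s0: {"slope", "stderr", "fluid", "mean_volume_ratio",
    "qn_end", "trajectories"?}}``.
    """
    ramp_end = REDUCED_T_ON + REDUCED_RAMP
    out: Dict[float, dict] = {}
    for s0 in s0_grid:
        qn_runs: List[np.ndarray] = []
        vols: List[float] = []
        trajs: List[Trajectory] = []
        for k in range(n_seeds):
            rs = _run_seed(seed, k, s0)
            cfg = reduced_config(s0=s0, seed=rs, **config_over)
            traj = run(cfg, seed=rs,
                       params=DynamicsParams.from_config(cfg,
                                                         observe_every=500))
            t = np.asarray(traj.times)
            qn_runs.append(np.asarray(traj.series["qn"]))
            vols.append(traj.series["mean_volume_ratio"][-1])
            if keep_trajectories:
                trajs.append(traj)
        qbar = np.mean(qn_runs, axis=0)
        post = t >= ramp_end + POST_RAMP_DEAD_TIME
        fit = stats.linregress(t[post], qbar[post])
        entry = {
            "slope": float(fit.slope),
            "stderr": float(fit.stderr),
            "fluid": bool(fit.slope + 2.0 * fit.stderr < 0.0),
            "mean_volume_ratio": float(np.mean(vols)),
            "qn_end": float(qbar[-1]),
        }
        if keep_trajectories:
            entry["trajectories"] = trajs
        out[s0] = entry
    return out


def smallest_fluid_s0(sweep: Dict[float, dict]) -> Optional[float]:
    fluid = [s0 for s0, v in sweep.items() if v["fluid"]]
    return min(fluid) if fluid else None
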