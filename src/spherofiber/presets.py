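"""Canonical parameter sets.

``reference_config`` is the full-scale operating point (400 cells, 25000 t0).
``reduced_config`` is the scaled-down ensemble used for desk-scale studies and
the test suite: about 100 cells with the linker coverage of the boundary kept
at the full-scale value, a proportionally larger cavity allowance, and a
contraction ramp compressed to 100 t0 followed by an equally long post-ramp
window.  Both subsystems relax much
faster than either ramp (bond and volume relaxation times are O(1) t0), so
the contraction remains quasi-static at the reduced duration; problem sizes
are a package choice documented in docs/methods.md.
"""

from __future__ import annotations

import math

from .config import SimulationConfig
from .fiber import FCC_SITE_DENSITY, site_count_for_half_extent
from .builder import spheroid_radius

__all__ = ["reference_config", "reduced_config", "REDUCED_T_ON",
           "REDUCED_RAMP", "REDUCED_T_F"]

REDUCED_T_ON = 25.0
REDUCED_RAMP = 100.0
REDUCED_T_F = 225.0   # onset + ramp + an equally long post-ramp window


def reference_config(**over) -> SimulationConfig:
    """The default full-scale parameter table."""
    return SimulationConfig(**over).validate()


def _fiber_sites_for(n_cells: int, spacing: float, cavity_pad: float = 1.0,
                     shell_spacings: float = 2.0) -> int:
    """Lattice sites so the cube reaches ``shell_spacings`` beyond the cavity."""
    cavity = spheroid_radius(n_cells) + cavity_pad * spacing
    half_phys = cavity + shell_spacings * spacing
    h = max(2, math.ceil(half_phys / (spacing / math.sqrt(2.0))))
    return site_count_for_half_extent(h)


def reduced_config(s0: float, seed: int, n_cells: int = 100, p: float = 0.8,
                   gamma: float = 1.0, t_f: float = REDUCED_T_F,
                   n_linkers: int = 40, **over) -> SimulationConfig:
    """Scaled-down embedded-spheroid run (same physics, smaller and shorter).

    ``n_linkers`` keeps the linker-bearing fraction of boundary cells near the
    full-scale coverage (the boundary-cell count scales like N_c^{2/3}).
    """
    kw = dict(N_c=n_cells, N_LS=n_linkers,
              N_f=_fiber_sites_for(n_cells, 1.5),
              s0=s0, p=p, Gamma=gamma, seed=seed,
              t_on=REDUCED_T_ON, contraction_interval=REDUCED_RAMP, t_f=t_f)
    kw.update(over)
    return SimulationConfig(**kw).validate()
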