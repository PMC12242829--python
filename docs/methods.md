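# Model and methods

`spherofiber` simulates a confluent cell spheroid, resolved at the level of
deformable polyhedral cells, mechanically embedded in a crosslinked fiber
network through actively contracting linker springs.  This note records the
model equations, the numerical choices, the parameters that matter and why,
and what the scaled-down study conditions used by the test suite do and do
not establish.

## 1. The three energy terms

The total energy is `E = E_VM + E_FB + E_LS`.

**Tissue (3D vertex model).**  Cells are polyhedra sharing faces; the degrees
of freedom are the vertices:

    E_VM = K_V * sum_j (V_j - V0)^2  +  K_A * sum_j (A_j - A0)^2
           + Gamma * sum_alpha S_alpha          (interface polygons only)

`V_j`, `A_j` are cell volume and surface area; `V0` the target volume (the
length unit is `V0^(1/3)`); `A0 = s0 * V0^(2/3)` encodes the target shape
index `s0`, the isotropic cortical contractility knob that tunes tissue
rheology (solid-like at low `s0`, fluid-like at high `s0`).  The interfacial
tension `Gamma` acts on the polygons separating real cells from the *empty*
padding cells that surround the spheroid.  Empty cells carry no energy but
are full topological citizens (they participate in reconnection events, which
is how cells enter and leave the boundary).  A face (possibly nonplanar) is
fan-triangulated about the arithmetic mean of its vertices; the mean is a
dependent point, and all forces apply the chain rule through it.  Volumes
come from the divergence theorem over the oriented fans.

**Fiber network.**  Bonds on an FCC lattice (nearest-neighbor spacing 1.5
length units), each independently occupied with probability `p`:

    E_FB = K_S/2 * sum_bonds f_ij (l_ij - l_0)^2
         + K_B/2 * sum_collinear-pairs f_ij f_jk (theta_ijk - pi)^2

Each lattice site hosts six fiber directions; it is split into three
co-located *phantom nodes*, each holding a random pair of directions, so at
most two fibers are rigidly crosslinked anywhere and crosslinks otherwise
rotate freely.  Bending acts only on collinear occupied pairs meeting at the
same phantom node (rest angle pi); there is no twist energy.  Dilution is
applied first, then a spherical cavity is carved (every bond with an endpoint
inside it is removed, isolated phantom nodes dropped) so the spheroid fits.

**Active linkers.**  `N_LS` springs join the center of an interface polygon of
a boundary cell (at most one per cell) to the nearest *load-bearing* phantom
node (at least two occupied bonds — a dangling node cannot transmit force):

    E_LS = K_LS/2 * sum_i (l'_i - l'_0i(t))^2

The rest length is constant at 1.5 until `t_on`, ramps linearly to 0.2 over
the contraction interval, then stays; the schedule is monotone, so linkers
created mid-ramp adopt the current value and never revisit longer ones.  This
is a molecular-clutch caricature of focal-adhesion contractility.  A linker is
removed when its cell leaves the boundary, or its polygon shrinks below area
0.1 or turns concave with the center on an edge; every removal is followed by
a creation on a random linker-free boundary cell, conserving `N_LS` (logged
starvation aside).

## 2. Parameters and units

Lengths in `V0^(1/3)` (about 10 um), times in `t0` (about 0.144 s, fixed by
the damping relation `K_V V0^(4/3) t0 / mu = 1`), forces in `K_V V0^(5/3)`
(about 1 nN).  Defaults: `dt = 0.005`, `t_f = 25000`, `t_on = 500`,
contraction interval 5000, `K_A = 0.01`, `s0 = 5.2-5.8`,
`Gamma in {0.25, 1.0}`, `l_th = 0.02`, `kT_eff = 1e-4`, `p = 0.75-0.95`
(default 0.8), `N_c = 400`, `N_LS = 100`.  The fiber diameter and pore size
are metadata (they enter no energy).

**The fiber stiffness scale `K_S`.**  Only the *ratios*
`K_B/(K_S l'_0(0)^2) = 1e-4` and `K_LS/(K_S l'_0(0)^2) = 1` are fixed by the
dimensionless table; the spheroid-to-network stiffness ratio is a free
physical choice.  It controls everything about the coupled statics: a
Laplace-type estimate gives a *free* spheroid a fractional volume deficit of
`(Gamma/Gamma0) * V0^(1/3)/R_s` (about 22% for 400 cells), and only linker
anchoring into a sufficiently stiff network can hold the surface out against
that.  We set `K_S = 10` (units `K_V V0^(4/3)`), the scale at which the
network shear modulus at `p ~ 0.8` is comparable to the spheroid's surface
stiffness `Gamma/R_s` — the mechanical-reciprocity regime the model is built
to probe — hence `K_B = 2.25e-3` and `K_LS = 22.5`.  Much larger values are
excluded by the explicit-Euler stability bound at `dt = 0.005` (a fiber node
with four bonds has curvature ~ `8 K_S`).  Even so, the carved network edge
responds to radial point loads through geometric (strain-stiffening) rather
than linear elasticity, so at reduced scale the embedded spheroid
equilibrates substantially below its target volume, and the outcome is
insensitive to `K_S` across the whole stable range (probed 1-20) and to the
cavity allowance (probed 0.33-1.0 spacings); only unphysical rigid anchoring
changes the regime.  See §6.

## 3. Construction of the initial state

Seed points are sampled uniformly at unit number density in a periodic cube
(`n = box^3`), optionally regularized by Lloyd sweeps (default 2, restricted
to the region of interest), and tessellated by qhull with periodic image
points.  The spheroid keeps every Voronoi cell whose generator lies within
the exact order-statistic radius that yields `N_c` cells; two face-adjacency
layers of discarded cells are kept as empty padding, everything deeper is
dropped (the outermost padding layer is therefore open, which the audits
tolerate for empty cells only).  The cavity radius is `R_s + 1` lattice
spacing with `R_s = (3 N_c V0 / 4 pi)^(1/3)`, so initial linker lengths sit
near the initial rest length 1.5.  The fiber lattice half-width follows from
the configured site count `N_f`; the outermost shell of sites (one spacing)
is pinned as a far-field anchor (a documented choice — the far boundary
condition is otherwise unconstrained — with a free-boundary switch).

## 4. Dynamics

Cell vertices follow overdamped Brownian dynamics (Euler-Maruyama):
`r += mu F dt + xi`, `Var(xi) = 2 mu kT_eff dt` per component, the noise
modeling active intracellular force fluctuations.  Fiber nodes follow plain
Euler with no noise; pinned nodes never move.  Both subsystems use forces
from the same pre-step configuration.  The interleaving is fixed: forces ->
integrate -> (every 10 steps) reconnection sweep -> linker population update
-> observables.  Inner blocks between sweeps run in a fused compiled kernel;
it is exactly equivalent to single steps (the test suite checks bitwise
agreement at zero temperature).  A heuristic stability bound on `dt` from
the stiffest local mode is enforced unless overridden.

**Reconnection events.**  The 3D analogue of T1 transitions: an interior edge
shared by exactly three faces with tetravalent endpoints (the generic Voronoi
situation) becomes a small triangle, making the two polar cells neighbors;
the reverse collapses a small triangle back to an edge.  A move triggers when
every edge it removes is shorter than `l_th`, and must be reversible:
topologically (no two cells may share two or more faces; all touched cells
remain closed oriented surfaces — cells that were already open, i.e. the
padding hull, are exempt), geometrically (new elements are built from the
centroid of the vanished element, the triangle perpendicular to the vanished
edge), and energetically.  Energetic admissibility required a design
decision: creating the new element slightly above threshold
(`l_th * (1 + 0.05)`) is necessary but *not* sufficient — under local stress
the element re-collapses within a few steps and the pair of moves cycles
indefinitely.  We therefore also require the created element to *expand*
under the instantaneous tissue force field, evaluated from the local
five-cell energy gradient; rejected candidates rest for 20 t0 before being
reconsidered.  Accepted moves are applied without a Metropolis test.

## 5. Observables

* `<Q_n>`: fraction of real cells that have lost fewer than two of their
  initial neighbors (1 = no rearrangement).
* Cell-center displacement over a trailing window, normalized by `R_s`.
* Radial profiles in spherical shells (default width `0.25 R_s`) about the
  initial volume-weighted spheroid center: fiber density ratio
  `rho_f/rho_i` with bond length assigned to shells by exact segment-sphere
  clipping (total length is conserved across shells), and the fiber
  orientation tensor `Omega = sum L_f n n^T / sum L_f` with whole bonds
  binned by midpoint.  Per shell `tr Omega = 1`; the radial component
  `Omega_rr > 1/3` means radial alignment.  An optional strain filter keeps
  bonds strained beyond a threshold (0.001 for the high-tension population).
  The normalization is the total (filtered) fiber length per shell.
* Spheroid shape `A_sp / V_sp^(2/3)` over the closed interface surface, with
  per-polygon surface deviations; histograms of cell shape index, `V_i/V0`
  and bond strain; mean linker force, normalized by its value at the first
  sample after the ramp completes.

## 6. Scaled-down study conditions, and what they show

The full-scale operating point (400 cells, 5e6 steps, 20 realizations) is far
beyond a test suite.  The packaged study conditions (`presets.reduced_config`)
use ~100 cells (`N_LS = 40` keeps the linker coverage of boundary cells at
the full-scale ~45-50%), a fiber cube reaching 2 spacings beyond the cavity,
`t_on = 25`, a 100 t0 ramp and an equally long post-ramp window
(`t_f = 225`), with 3 seeds per condition; the
problem sizes and durations are package choices so the whole suite runs on a
laptop.  Consequences to keep in mind:

* The contraction is 50x faster than full scale but still quasi-static with
  respect to bond and cell-volume relaxation (both O(1) t0).
* Rearrangement statistics are *slow* physics: at full scale `<Q_n>` falls by
  order 0.5 over 25000 t0.  A 100 t0 post-ramp window sees only a handful of
  neighbor losses, so the solid/fluid classification from the post-ramp
  `<Q_n>` slope is statistically marginal at this scale.
* At ~100 cells the surface-tension pressure `2 Gamma / R_s` is 1.6x the
  full-scale value, and the carved network fringe anchors the linkers only
  through geometric stiffening; the embedded spheroid therefore equilibrates
  with a mean cell-volume deficit of order tens of percent — the free
  Laplace value for this energy functional — rather than the few percent a
  stiffly anchored full-scale system would show.  The package reports what
  the model produces; no parameter was adjusted to a desired output.
* The synthetic tessellation is the model's own initial condition, not real
  tissue: it contains a ~1% population of very short edges that reconnect
  away in the first few t0 (an initialization transient excluded from
  post-ramp trend fits by a 25 t0 dead time).

## 7. Numerical details and degenerate inputs

* Forces are exact analytic gradients; the suite checks them against central
  finite differences (relative tolerance 1e-5) for all three energy terms.
* The bending angle near pi uses an arcsin series (error < 1e-9 within 20
  degrees of pi) with the exact arccos fallback elsewhere; the
  `(theta - pi)/sin(theta)` force factor takes its analytic limit -1 at
  collinearity.
* Zero-length bonds and non-finite positions abort a run with a diagnostic;
  partial trajectories are kept.
* Degenerate faces (repeated vertices), open real cells, doubly-shared cell
  pairs and orientation mismatches are caught by the validity audit, which
  runs after every reconnection sweep in the tests and on demand via the CLI.
* Ties in nearest-node attachment break to the lowest node index; candidate
  order within a reconnection sweep is a seeded random permutation; all
  randomness flows from a single `numpy` generator per run, so equal seeds
  give bit-identical trajectories.

## 8. Known limitations

* Reconnections handle the generic (tetravalent) topology only; non-generic
  candidates are rejected, never force-resolved.
* No viscoelastic or force-sensitive crosslinks, no fiber plasticity, no
  cell invasion/breakout, no anisotropic contractility.
* The `N_f = 1000` default describes a thin network shell; radial profiles
  beyond ~2.5 R_s need a larger lattice (pass a larger `N_f`).
* The linker-bearing fraction of boundary cells at `N_c = 400` measures
  39-41% here (the construction counts every real cell sharing any polygon
  with an empty cell, including sliver contacts), somewhat below the ~50%
  coverage quoted for the reference parameter set.
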