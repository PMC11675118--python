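# Methods

## Model

`dll2d` simulates an athermal, coarse-grained two-dimensional colloidal
mixture on a fully occupied triangular lattice with periodic boundary
conditions.  Three species share the lattice:

* **solvent** — monomers occupying one site;
* **dimers** — two mers joined by a rigid bond that must connect
  nearest-neighbour sites at all times;
* **obstacles** — immobile, impenetrable single-site objects.

The only interaction is excluded volume (no double occupancy), so no
Boltzmann acceptance criterion exists; dynamics is purely athermal.
Concentrations are site fractions: `c = n/L²` for `n` obstacles and
`d = 2m/L²` for `m` dimers; solvent fills the remainder.  Lattice constant
and Monte Carlo step are the units of length and time.

## Dynamic lattice liquid step

Because every site is occupied, single-particle hops are impossible and
motion is strictly cooperative.  One MC step:

1. **Direction field.**  Every non-obstacle site draws an independent
   uniform direction toward one of its six neighbours.  Obstacle sites get
   no vector and terminate any chain that points at them.
2. **Loop detection.**  The field is a successor map; its cycles are the
   candidate cooperative loops.  Cycles are vertex-disjoint by
   construction.  Two-site cycles (mutual exchange) are tallied and always
   rejected; loops must contain at least three sites.  Objects outside a
   loop are immobile this step.
3. **Constraint validation**, iterated to a fixed point (Gauss–Seidel in
   ascending smallest-site order, so runs are reproducible):
   * *bond break* — a loop is rejected if executing it (given the currently
     accepted set) would leave any dimer's mers at non-nearest-neighbour
     separation.  A single mer may pivot around its stationary partner as
     long as adjacency is preserved.
   * *bond cross* — a loop is rejected if any of its objects, moving by
     simultaneous linear interpolation, passes through a *moving* dimer
     bond.  The signed area of (bond, moving point) is quadratic in the
     interpolation parameter `s`; a crossing is a root in `(0, 1]` whose
     point projects strictly inside the bond segment.  Endpoint contact
     (an object entering the site a mer vacates) is not a crossing.  A
     static bond is a lattice edge and cannot be crossed by another lattice
     edge, so only moving bonds are tested.  Candidate bonds are gathered
     from the 42 sites within Cartesian distance √12 of the moving object
     (a rigorous bound: the nearer endpoint of any crossable bond lies
     within 0.5 + 3s ≤ 3.5).  On very small boxes each periodic image is
     tested separately.
   Rejections shrink the accepted set monotonically, so the sweep
   terminates.  The crossing rule is kept behind a single predicate
   (`engine.crossing_test` / `engine._cross`) so alternative geometric
   readings can be swapped in and compared.
4. **Synchronous execution.**  Every object in an accepted loop replaces
   its successor; unwrapped displacement accumulators advance by the unit
   vector of each hop; `t` increases by one.

A topologically winding loop (length ≥ L, wrapping the torus) carries a
net hop sum of one lattice period; for all shorter loops the hop vectors
sum to zero and the centre of mass of the mobile objects is invariant.
Winding loops are astronomically rare at production sizes but are exercised
deliberately by the L = 4 uniform-field fixture.

The cycle detection, validation and execution path is compiled with numba
and runs at ≈0.1–0.5 ms per step for L = 64 on one core, which is what
makes the 10⁵–3×10⁵-step desk-scale runs practical.

## Initialization

Obstacles are placed first, uniformly at random, so the obstacle ensemble
is independent of the dimer concentration; several trajectories can share
one obstacle matrix.  Dimers are then placed by random sequential
adsorption (RSA) on edges with both endpoints free.  RSA alone jams below
~90% coverage of the available sites, which cannot reach compositions such
as (c, d) = (0.28, 0.70) where dimers must cover ~97% of the non-obstacle
sites.  A vacancy-diffusion repair phase therefore follows: an exposed free
site exchanges with a neighbouring dimer (the dimer re-orients onto the
vacancy) so vacancies random-walk, and whenever two vacancies meet on
adjacent sites they become a new dimer.  The phase is capped
(2000·m + 10⁵ iterations) and raises an infeasible-packing error if the
cap is hit, e.g. when the remaining vacancies are walled in by obstacles.
Remaining sites become solvent.  All randomness flows through a seeded
`numpy` generator; runs are bit-reproducible.

## Observables

Computed over ensembles of independent trajectories sampled on a shared
log-spaced schedule (default 20 points per decade), single time origin at
t = 0 — matching the many-trajectories protocol this kind of study uses.
A multi-origin mode exists for desk-scale variance reduction; it averages
over exact sample-time differences, which with a log schedule reduces to
nearly single-origin, and outputs are flagged accordingly.

* **MSD** `⟨Δr²(t)⟩` from unwrapped coordinates; dimer centre of mass is
  the mean of the two mer positions (it may sit at an edge midpoint and is
  treated in continuous coordinates).
* **Non-Gaussian parameter** `α₂(t) = ⟨Δr⁴⟩ / (2⟨Δr²⟩²) − 1` (the
  two-dimensional coefficient); `α₂(0) := 0` by convention, and any later
  zero-MSD point is reported as 0 with a degenerate flag.
* **End-to-end autocorrelation** `⟨cos φ⟩(t) = ⟨R(0)·R(t)/R²(0)⟩` with the
  sign of each dimer's end-to-end vector fixed at t = 0.  Since bonds are
  rigid, |R| ≡ 1.
* **Position autocorrelation** `ρ(t)`: fraction of objects found at their
  t = 0 lattice site, using wrapped site identity — an object that wanders
  away and returns counts again, so ρ is not monotone in principle.
  Implemented for solvent by default with a species switch (mers
  selectable).
* **Trapped fraction**: objects whose wrapped site never differs from the
  initial site at any sample in a window; the complement-filtered ρ(t) is
  returned alongside.  The trapped fraction lower-bounds ρ at every time.
* **Loop statistics**: accepted-loop length distribution, mean length,
  mobile fraction of sites per step, and rejection rates by reason.

## Diffusion fits

`MSD ~ t^α` is fitted as the least-squares slope of log MSD vs log t
(unweighted — log-spaced samples are near-uniform in log t); `d_w = 2/α`.
Diffusion coefficients use the 2-D Einstein relation `⟨Δr²⟩ = 4Dt`:
D is the linear slope over a window divided by 4, and is *defined* only
when α on the same window passes the normal-diffusion gate.  The default
gate is symmetric, 0.9 < α ≤ 1.1, because finite sampling scatters α
slightly above 1 in the Fickian limit; the strict one-sided gate
0.9 < α < 1 is selectable.  Default windows: short-time t ∈ [1, 10²];
long-time the last decade of the data (at desk scale there is no t > 10⁷).
The short-time coefficient follows `D_SH = D₀ exp(−a c)`; a log-linear fit
returns D₀ and a.  The solvent/dimer ratio propagates the two slope
standard errors.

## Percolation

Obstacle matrices are Bernoulli site configurations; the spanning
criterion is a **wrapping** cluster on the torus, detected by union-find
with per-site offsets to the component root (an inconsistent offset when
joining two sites already in one component reveals a winding).  The torus
criterion avoids the boundary ambiguity of side-to-side spanning on a
periodic box.  The threshold estimate interpolates, for each lattice size,
the open-site probability at which the wrapping probability crosses one
half, and averages over sizes with a bootstrap standard error.  The
wrapping probability at the true threshold of 2-D percolation is ≈0.69,
not 0.5, so the 0.5-crossing sits slightly below the threshold at finite
size (measured ≈0.490 at L = 64 and ≈0.495 at L = 128, i.e. within 0.01
of the infinite-lattice value 1/2).

## Study conditions and problem sizes

The package targets the production protocol of this system (L = 256, 10⁹
steps, >40,000 trajectories per obstacle matrix, ~30 matrices; d ∈ {0.10,
0.50, 0.70}, c ∈ [0, 0.36]); such configurations parse and run but are
flagged `cluster_scale` in the manifest.  The bundled analyses use desk
scale: L = 64 (loop statistics are size-independent above L = 64), 10⁵
steps for the Fickian-limit exponent (8 trajectories), 3×10⁵ steps and 10
obstacle matrices for the crowded-system analyses, and 500 realizations
per grid point at L ∈ {64, 128} for percolation.

## What the generator does and does not emulate

Synthetic systems reproduce the full composition range of the study,
including extreme crowding (2% solvent).  They do not include
polydispersity, longer chains, thermal interactions, or continuum
hydrodynamics — cooperative loops are the only transport mechanism, which
is exactly the model's premise.  Passing tests therefore validate the
lattice model, not any off-lattice system.

## Known limitations

* The geometric reading of the "jump over a bond" rejection is
  reconstructed from a pictorial description.  Under this reading (and
  under a stricter no-pivot variant that was implemented and measured
  during development) the dimer matrix at the extreme composition
  c = 0.28, d = 0.70 remains fluid at long times: the solvent position
  autocorrelation relaxes to ≈0.1 rather than plateauing near 0.5, and the
  never-moved solvent fraction shrinks slowly with the observation window
  (≈9.5% over 10⁴ steps, ≈6.5% over 3×10⁵) as dimer rearrangements
  dissolve cages, even though all free-liquid benchmarks agree with the
  reference behaviour.  The plateau level at
  extreme crowding should be treated as sensitive to the exact rejection
  geometry; `engine._cross` is the single place to swap alternatives.
* Multi-origin averaging is only useful with schedules whose pairwise
  time differences recur (linear schedules).
* The percolation estimator reports the 0.5-crossing without finite-size
  extrapolation; its small systematic offset is documented above.
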