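# dll2d — cooperative-motion Monte Carlo for crowded 2D lattice liquids

`dll2d` simulates a dense two-dimensional mixture of solvent monomers,
rigid dimers and immobile obstacles on a fully occupied triangular lattice,
using the dynamic lattice liquid (DLL) algorithm: because every site is
occupied, objects can move only through closed cooperative displacement
loops of at least three sites, which keeps the continuity equation
satisfied at liquid density.  The package is for researchers studying
anomalous diffusion and dynamical heterogeneity in crowded media — e.g.
how immobile obstacles and slow macromolecules reshape tracer transport.

Each MC step assigns every non-obstacle site a random unit vector toward a
neighbour, finds the closed loops those vectors form, rejects loops that
would break a rigid dimer bond or carry an object across a moving bond,
and executes all surviving loops synchronously.  From trajectory ensembles
the package computes:

* mean square displacement ⟨Δr²(t)⟩ and the anomalous exponent α in
  ⟨Δr²(t)⟩ ~ t^α (walk dimension d_w = 2/α),
* short- and long-time diffusion coefficients from ⟨Δr²⟩ = 4Dt, gated on
  normal diffusion (0.9 < α ≤ 1.1), and the decay law D_SH = D₀ exp(−a c),
* the non-Gaussian parameter α₂(t) = ⟨Δr⁴⟩/(2⟨Δr²⟩²) − 1,
* the dimer end-to-end autocorrelation ⟨cos φ⟩(t) and the solvent position
  autocorrelation ρ(t), with trapped-molecule bookkeeping,
* cooperative-loop statistics, and
* the site-percolation threshold of obstacle matrices (wrapping clusters
  on the torus via union-find).

## Worked example

```python
import dll2d
from dll2d import observables as obs, fits

# obstacle-free liquid at dimer coverage 0.5 in a 64 x 64 box
stores = []
for k in range(2):
    state = dll2d.initialize_system(L=64, c=0.0, d=0.5, seed=100 + k)
    stores.append(dll2d.run_trajectory(state, n_steps=20_000))

msd = obs.msd(stores, "solvent")
alpha = fits.fit_alpha(msd, fits.last_decade_window(msd))
d_solv = fits.fit_diffusion_coefficient(msd, window=(1, 100))
d_dim = fits.fit_diffusion_coefficient(obs.msd(stores, "dimer_com"), (1, 100))
tau = fits.efolding_time(obs.end_to_end_acf(stores))

print(f"alpha (last decade)   = {alpha.alpha:.3f}")
print(f"D_SH solvent          = {d_solv.D:.5f}")
print(f"D_SH dimer            = {d_dim.D:.5f}")
print(f"solvent/dimer ratio   = {d_solv.D / d_dim.D:.2f}")
print(f"cos(phi) e-fold time  = {tau:.1f}")
```

Output:

```
alpha (last decade)   = 1.007
D_SH solvent          = 0.00969
D_SH dimer            = 0.00228
solvent/dimer ratio   = 4.24
cos(phi) e-fold time  = 33.3
```

The solvent diffuses normally (α ≈ 1); dimers are about 4× slower at short
times; dimers forget their orientation within a few tens of steps.  Adding
obstacles (`c > 0`) suppresses both coefficients exponentially and drives
the long-time exponent below 1 as the obstacle matrix approaches its
percolation threshold (0.5 for triangular-lattice sites).

A command-line interface wraps the same pipeline:

```bash
dll2d init --out run.yaml          # write a template configuration
dll2d run run.yaml                 # run the configured sweep
dll2d percolation --sizes 64,128   # estimate the percolation threshold
```

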