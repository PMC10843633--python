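# rclpsd

Langevin dynamics and single-particle-trajectory analysis of chromatin
**phase-separated nanodomains** built from a **random cross-linker (RCL)
polymer model**.

Heterochromatin-like nanodomains can arise when a chromatin fiber is
stitched together by cross-linking proteins (HP1, cohesin, CTCF…): enough
random internal springs collapse a swollen chain into a condensed globule
that excludes diffusing molecules (transcription factors, remodelers)
without any membrane. `rclpsd` is for polymer physicists and computational
biologists who want to simulate that transition and quantify, from
trajectories, how porous the resulting domain is.

The model is a Kremer–Grest bead–spring chain (WCA excluded volume, FENE
backbone, bending stiffness κ_θ = 5 k_BT) with N_c harmonic cross-links
between random non-adjacent monomer pairs (k_rc = 0.5 ε/σ², quenched per
realization), N_mol diffusing molecules of the same size σ, optional
attractive binding sites (5 k_BT wells), and underdamped Langevin dynamics
(γ = 0.5/τ_MD, velocity-Verlet with a Grønbech-Jensen–Farago thermostat,
Δt = 5·10⁻³ τ_MD) in a periodic box at density ρ = (N_mon + N_mol)/V. One
bead is 3 kbp ≈ 30 nm; τ_MD ≈ 0.02 s.

On top of the simulator sits the analysis stack:

- **structure** — gyration radius R_g; the domain Ω = ball of radius ⟨R_g⟩
  around the chain center of mass; radial distributions g_mol, g_mon and
  pair correlations; the pore-size distribution inside Ω and the mesh size
  ζ = ⟨s⟩; power-law-with-offset fits y = k·N_c^∓e + c;
- **kinetics** — residence times τ_in and penetration lengths L_in of
  molecule visits, binding times τ_b, local density at binding sites,
  escape times τ_e from the domain center, the radially-conditioned MSD
  ⟨|x(t+τ)−x(t)|² | x(t)∈A_r⟩ and the anomalous-exponent spectrum α(r);
- **wellfield** — coarse-grained drift field a(x_k) from trajectories, the
  attraction coefficient A of a truncated parabolic well with semi-axes
  R_g, and the parabolic index S ∈ [0, 1] (S = 0: perfect radial well,
  S → 1: random field) that tests whether the domain is an attractor;
- **escape theory** — narrow-escape mean time τ̄ = |Ω|/(2πκN_w a²) and the
  number of escape windows N_w(N_c) implied by the fitted scaling laws;
- **fixtures** — ideal gases, Brownian and Ornstein–Uhlenbeck tracks and
  scripted tracks with analytic ground truth, used to validate every
  estimator independently of the polymer.

## Worked example

Condense a 200-monomer chain with 30 cross-links among 400 molecules at
ρ = 0.05 σ⁻³ and measure the domain:

```python
import numpy as np
from rclpsd import (SimulationParameters, SimulationProtocol, make_topology,
                    run, mean_gyration_radius, molecule_coords_rel_cm,
                    pore_size_distribution)

topo = make_topology(n_mon=200, n_mol=400, n_c=30, rng=1)
params = SimulationParameters.from_density(topo.n_particles, rho=0.05)
proto = SimulationProtocol(n_equil_steps=50_000, n_prod_steps=150_000,
                           frame_interval=200, seed=3)
ens = run(params, topo, proto)          # ~15 s, 750 frames

rg = mean_gyration_radius(ens)
rel = molecule_coords_rel_cm(ens)       # molecule positions about the CM
inside = np.linalg.norm(rel, axis=-1) < rg
occupancy = inside.mean() / (4/3 * np.pi * rg**3 / ens.box**3)
mon = ens.monomer_frames()[-1] - ens.center_of_mass()[-1]
zeta = pore_size_distribution(mon, rg, n_probes=300, rng=0).mesh_size
print(f"Rg = {rg:.2f} sigma, occupancy = {occupancy:.2f}, zeta = {zeta:.2f} sigma")
```

```
Rg = 4.77 sigma, occupancy = 0.42, zeta = 0.77 sigma
```

The cross-linked chain has collapsed (an uncross-linked chain of this
length has ⟨R_g⟩ ≈ 13 σ): molecules inside the domain sit at 42% of the
uniform expectation — the condensed polymer excludes them — and the mean
cavity radius available between monomers is under one molecule diameter. Repeating over N_c ∈ {0, 10, 30, 60} (see `rclpsd.study`) gives
the full trend: R_g and ζ fall with N_c while the exclusion sharpens.

A command-line interface mirrors the library
(`rclpsd simulate|fixtures|analyze-structure|analyze-kinetics|wellfield|escape-theory|fit-scaling`),
reading YAML configs and writing extended-XYZ or HDF5 trajectories plus
tidy CSV tables.

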