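# Methods

## Model

`rclpsd` simulates a coarse-grained chromatin fiber as a Kremer–Grest
bead–spring chain with quenched random cross-links, embedded among freely
diffusing molecules of the same size. One bead maps to 3 kbp of 30-nm fiber
(σ = 30 nm); energies are in units of ε = k_BT (T = 300 K) and time in
τ_MD = σ√(m/ε) ≈ 0.02 s. The Hamiltonian is

- **WCA repulsion** between every bead pair (monomer–monomer,
  monomer–molecule, molecule–molecule, bonded pairs included):
  truncated-shifted Lennard-Jones, cutoff 2^(1/6) σ. Including bonded pairs
  follows the Kremer–Grest convention; together with the FENE term it puts
  the backbone bond minimum at ≈ 0.96 σ (FENE alone would have its minimum
  at zero extension).
- **FENE backbone**, κ = 30 ε/σ², R₀ = 1.5 σ, divergent at R₀.
- **Bending**, κ_θ (1 − cos θ) with κ_θ = 5 k_BT on consecutive bonds
  (Kuhn length ≈ 10 beads of 30-nm fiber).
- **Cross-links**: N_c zero-rest-length harmonic springs, k_rc = 0.5 ε/σ²,
  between uniformly drawn monomer pairs with |i − j| ≥ 2, fixed for a
  realization (quenched disorder). The spring constant is read as an
  energy/length² quantity; the inverse orientation has no meaning for a
  spring energy.
- **Binding sites** (optional): N_bs monomers attract molecules through a
  full truncated Lennard-Jones well of depth 5 k_BT and cutoff 2.5 σ. A free
  molecule within the capture distance 2·2^(1/6) σ of a site attaches to the
  nearest one (ties to the lowest index); a bound molecule releases beyond
  the same distance (no hysteresis — the simplest rule that makes the bound
  time the contiguous time below the capture radius). One site per molecule;
  a site can hold several molecules. While bound, the pair's generic WCA
  term is replaced by the attractive well (its own repulsive core prevents
  double counting).

Dynamics follow the underdamped Langevin equation with friction
γ = 0.5/τ_MD and noise satisfying fluctuation–dissipation in three
dimensions (D = k_BT/mγ = 2 σ²/τ_MD). Integration uses the
Grønbech-Jensen–Farago discretization of Langevin velocity Verlet at
Δt = 5·10⁻³ τ_MD, which samples the configurational Boltzmann distribution
correctly at finite Δt and reduces to plain velocity Verlet when γ = 0 (the
NVE limit used to test energy conservation). Pair interactions use a
Verlet/cell list with a 0.4 σ skin rebuilt on half-skin displacement; pair
enumeration is exact within the cutoff. Intramolecular terms (FENE,
bending, cross-link springs) act on unwrapped coordinates — the chain is a
contiguous object, and a fresh cross-link can legitimately span more than
half the periodic box; non-bonded terms use the minimum image.

Initial states lay the chain out as a self-avoiding random walk at the bond
minimum (self-avoidance checked against periodic images as well), insert
molecules by rejection sampling at pair distance ≥ σ, and draw
Maxwell–Boltzmann velocities. Runs equilibrate (no frames kept) and then
record production frames every 200 steps (1 τ_MD) by default. A run is
bit-reproducible from (seed, parameters, topology): all noise comes from a
single seeded PCG64 stream.

## Observables

**PSD region.** The phase-separated domain Ω is the ball of radius ⟨R_g⟩
(frame-averaged gyration radius of the realization) around the
instantaneous polymer center of mass. All radial statistics are taken in
that moving frame.

**Radial distributions.** g_mol, g_mon (center-of-mass referenced) and the
pair correlations g_mol,mon, g_mol,mol, g_mon,mon are shell histograms
normalized so a uniform ideal system gives 1; exact shell volumes are used
rather than 4πr²Δr (identical in the small-bin limit, unbiased for finite
bins). Default bin width 0.1 σ; bins below σ/2 are shell-volume-noisy.

**Pore sizes and mesh size.** The pore size s(p) of a probe point p ∈ Ω is
the radius of the largest sphere that contains p, lies in Ω, and avoids
every monomer hard core (radius σ/2) — the covering pore-size function of
void statistics. It is computed by SLSQP over sphere centers (vectorized
constraints, two starts) and validated against an exhaustive lattice
oracle; the mesh size ζ is the mean of s over uniform probes. Adding an
obstacle can only shrink pores, and an empty region returns s ≡ R_Ω.

**Kinetics.** Boundary crossings are dated at the first frame on the new
side (no sub-frame interpolation; bias O(frame interval)). Residence
episodes record τ_in and the penetration depth L_in = max(⟨R_g⟩ − r);
episodes truncated by either end of the run are censored and excluded from
means (flagging only, no survival correction). Binding intervals are
contiguous bound frames per molecule; escape times are first exits of
trajectories started inside Ω, censored at run end. The conditional MSD
averages |x(t+τ) − x(t)|² over all (trajectory, t) pairs whose folded
CM-distance at time t falls in the annulus (r, r + δr), δr = ⟨R_g⟩/10;
displacements are taken on unwrapped coordinates so long lags are exact.
The anomalous exponent α(r) is the log–log slope of MSD(τ|r) over a lag
window, by default [5, 50] τ_MD: the lower edge sits past the thermostat's
velocity relaxation 1/γ = 2 τ_MD, so α measures configurational diffusion
rather than the ballistic crossover.

**Drift field and well test.** The drift a(x_k) is the per-bin mean
displacement per frame interval on a cubic lattice (default Δx = ⟨R_g⟩/5,
bins with ≥ 20 points). The attraction coefficient of a truncated parabolic
well with semi-axes R_g is A = (R_g²/2)|Σ a·x|/Σ|x|² over bins with
|x_k| ≤ R_g, reported with an attract/repel orientation flag (the
regression formula alone fixes only the magnitude). The parabolic index is
the cosine-similarity form S = 1 − (Σ a·x)²/(Σ|x|²·Σ‖a‖²) ∈ [0, 1] by
Cauchy–Schwarz, 0 iff the field is exactly radial-linear and → 1 for an
uncorrelated field; a rendering with an extra 1/2 would give S = 1/2 for a
perfect well and is not used. In condition sweeps the drift samples of all
realizations are pooled before computing S, mirroring ensemble averaging
and keeping bins populated when the condensed domain excludes most
molecules.

**Narrow escape.** The mean escape time through N_w partially absorbing
windows of size a on a sphere is τ̄ = |Ω|/(2πκ N_w a²); κ is not fixed by
the simulations and is carried as a free parameter (default 1), so N_w is
reported up to 1/κ. Combining the fitted scalings R_g(N_c) = k_rg N_c^−ν +
rg∞, ζ(N_c) = k_ζ N_c^−γ + ζ∞ (window size a ∼ ζ) and τ_e(N_c) = k_τ N_c^η
+ τ⁰ gives N_w(N_c) as an exact ratio and as the three-term large-N_c
expansion N_c^−η + 3(k_rg/rg∞) N_c^−(ν+η) − 2(k_ζ/ζ∞) N_c^−(η+γ). The last
coefficient is the first-order expansion of the (1 + k_ζ/ζ∞ N_c^−γ)^−2
factor; with the reference fitted constants the expansion agrees with the
exact ratio to better than 2% at N_c = 10³ and converges at rate
N_c^−min(2ν, 2γ, …). Below N_c ≈ (τ⁰/k_τ)^(1/η) ≈ 3·10² the constant τ⁰
dominates the escape time and N_w is not monotone; the expansion is only
meaningful past that crossover.

**Scaling fits** use Levenberg–Marquardt least squares of
y = k x^(∓e) + c with log–log-slope initialization and Jacobian-based
standard errors; a flat input is flagged exponent-unidentifiable rather
than fitted.

## Synthetic fixtures

The fixture generators provide analytically known inputs: uniform ideal
gases (g ≡ 1), free Brownian tracks (MSD = 6Dτ, α = 1, ⟨τ_e⟩ = R²/6D from
a sphere center), Ornstein–Uhlenbeck wells with exact discretization
(drift −λx, stationary variance D/λ, well coefficient A = R_g²λ/2), and
piecewise-linear scripted tracks for episode logic. They emulate the null
and known-well cases only — no fixture reproduces polymer-induced
subdiffusion or the exclusion physics of the chain, so passing fixture
tests validates the estimators, not the polymer model; the simulator
itself is validated by its closed-form limits (NVE drift, equipartition,
free-particle diffusion) and by the condensation trends below.

## Desk-scale condition sweeps and their limits

The reference ensembles (2000-monomer chains, 8000 molecules, 5·10⁶ steps,
100 realizations × 100 runs) are far beyond a workstation budget. The
package's `study` module runs the same pipeline at desk scale — 200
monomers, 400 molecules, ρ = 0.05 σ⁻³ (the density of the reference radial
distribution figures), N_c ∈ {0, 10, 30, 60}, 5·10⁴ equilibration +
1.5·10⁵ production steps, 10 quenched realizations — chosen to finish in
minutes while keeping the condensation transition inside the N_c range.

At this scale the collapse and exclusion trends are robust: ⟨R_g⟩ falls
monotonically with N_c, the interior molecule occupancy and the mesh size
fall with it. Two observables do **not** transfer from the cluster scale,
for physical reasons worth stating:

- the condensed domain has R_g ≈ 4 σ, so a molecule traverses it in about
  R_g²/6D ≈ 1.3 τ_MD — below the thermostat relaxation 2 τ_MD. Interior
  molecules are superdiffusively expelled rather than caged, so the mean
  α inside Ω *rises* with N_c at desk scale (expulsion superdiffusion is
  also seen at moderate condensation in the full-scale study; the
  subdiffusive interior needs domains many molecule diameters wide).
- the exclusion gradient is compressed into a boundary layer that the
  pooled drift estimator resolves: the radial drift profile peaks right at
  the Ω boundary, pointing outward. The parabolic index penalizes any
  radial field regardless of sign, so S drops well below 1 at N_c = 60
  even though the fitted well orientation is *repelling* — the
  no-attracting-well conclusion itself stands in every condition.

## Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| σ, ε, m | 1 | reduced | bead size (30 nm), k_BT, bead mass |
| r_cut | 2^(1/6) σ | σ | WCA cutoff |
| R₀, κ_fene | 1.5, 30 | σ, ε/σ² | FENE extension cap, stiffness |
| κ_θ | 5 | k_BT | bending stiffness |
| k_rc | 0.5 | ε/σ² | cross-link spring constant |
| ε_bind, r_bind | 5, 2.5 | k_BT, σ | binding well depth, cutoff |
| d_capture | 2·2^(1/6) | σ | capture/release distance |
| γ | 0.5 | 1/τ_MD | Langevin friction (D = 2 σ²/τ_MD) |
| Δt | 5·10⁻³ | τ_MD | integration step |
| ρ | 0.05–0.5 | σ⁻³ | total number density (N_mon+N_mol)/V |
| frame interval | 200 steps = 1 τ_MD | | trajectory sampling |
| δr (MSD annuli) | ⟨R_g⟩/10 | σ | conditional-MSD binning |
| α window | [5, 50] | τ_MD | log–log fit range |
| Δx (drift grid) | ⟨R_g⟩/5 | σ | drift binning, min 20 points/bin |
| pore exclusion | σ/2 | σ | monomer hard-core radius |

## Known limitations

- Fixed connectivity: no binding/unbinding or sliding of cross-linkers, no
  loop extrusion, fixed volume (no barostat), implicit solvent only.
- Censored episodes are flagged and excluded, not survival-corrected;
  frame-resolution crossing times bias short episodes by up to one frame.
- The parabolic index depends on the sampling power of the drift
  estimator: with few points per bin, noise drives S toward 1 regardless
  of the field. Compare S only between grids of comparable occupancy.
- κ in the narrow-escape formula is undetermined; all N_w values are
  relative (N_w·κ).
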