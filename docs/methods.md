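# Methods

`chainexpand` simulates and analyzes the free expansion of a single
coarse-grained polymer released from a spherical cavity, the minimal model
of genome release from a ruptured viral capsid.  This note records the
model, the numerical choices, and what the package's scaled-down ensembles
can and cannot say about the published-scale phenomenology.

## Model

The chain is a bead-spring polymer of N beads (diameter sigma, mass m).
All bead pairs repel through the WCA potential

    U_ex(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 + 1/4 ],   r <= 2^(1/6) sigma,

with eps = 1.2 kBT (good solvent, effective hard-sphere diameter ~ sigma),
and consecutive beads are bonded by U_bd(b) = (k/2)(b - b0)^2 with
b0 = 1.0 sigma and k = 6000 kBT/sigma^2.  At this stiffness the RMS bond
fluctuation is sqrt(kBT/k_eff) ~ 1.2% of b0 (the WCA curvature adds ~10%
to k), so strand crossing is impossible and the chain topology is
conserved.  The confining cavity of diameter D = sigma (N/phi0)^(1/3)
acts on bead centers by specular reflection at radius D/2 - 0.5 sigma
(the wall "sees" beads of radius 0.5 sigma); reflection conserves speed
and adds no potential energy.

Dynamics are Langevin (free-draining Rouse friction, no hydrodynamics)
with friction eta = 20 sqrt(m kBT)/sigma per bead — an aqueous-like
damping — and time step dt = 0.005 tu, where tu = sigma sqrt(m/kBT).
With the single-stranded DNA/RNA mapping sigma = 3.4 A, m = 320 g/mol,
kBT = 4.14e-21 J, the time unit evaluates to tu = 3.85 ps.

## Integrator

Velocity Verlet with a BAOAB splitting: half kick, half drift, exact
Ornstein-Uhlenbeck friction/noise update

    v -> c v + sqrt((1 - c^2) kBT/m) xi,   c = exp(-eta dt/m),

half drift, wall reflection (when confined), half kick.  The O-step is
exact, so a free bead reproduces the Maxwell-Boltzmann distribution and
the Einstein diffusivity D = kBT/eta = 0.05 sigma^2/tu at any stable dt;
both are asserted by the test suite.  Wall reflection is applied after
the position update of each step rather than by in-step event detection:
at dt = 0.005 a thermal bead travels ~0.009 sigma per step, far below the
cavity radius, so the mirror approximation is excellent.

Nonbonded forces use a Verlet pair list (cutoff + 0.5 sigma skin) rebuilt
by a counting-sort cell grid whenever any bead has moved half a skin.
The grid edge never drops below the list radius and the cell count is
capped near 4N, so the same code path serves the dense confined state and
the dilute expanded coil; systems below 72 beads use the O(N^2) loop
directly, which is faster there.  Both paths are validated against an
all-pairs brute-force oracle.

## Preparing the ensembles

**Confined states.** A fixed-bond random walk is grown inside the wall
radius (overlaps allowed), then relaxed in four short Langevin stages with
the pair force capped at 5, 20, 100, 1000 kBT/sigma (velocities redrawn
from Maxwell-Boltzmann after each stage).  The cap is an
initialization-only device; production dynamics never cap forces.  The
state is then equilibrated with the wall active (default budgets:
60,000 steps for N <= 256, 100,000 for N = 512, both checked by a
block-averaged zero-trend test on Rg^2(t)); production averages follow.
The confined chain relaxes on blob scales, orders of magnitude faster
than a free coil, which is what makes the reduced budget sufficient —
the equilibrated N = 512, phi0 = 0.4 cavity gives Rg = 4.05 sigma,
matching the uniform-sphere estimate sqrt(3/5) D/2 = 4.2 to within the
expected near-wall depletion.

**Free coils.** The global modes of a free coil relax on the coil
expansion time (~0.18 N^2.36 tu, i.e. ~5e7 steps at N = 256), which is
cluster-scale.  Relaxed-coil ensembles are therefore sampled exactly from
the hard-core self-avoiding ensemble by the dimerization method (two
recursively sampled half-chains, joined at a random orientation, with the
pair rejected and fully regenerated on any overlap below 0.9 sigma), then
thermalized by a short Langevin run (100 tu discarded) and averaged over
a 500 tu production window.  Dimerization is exact for the hard-core
chain; the short MD run equilibrates bond lengths and local structure at
the WCA potential.  Replicas, not production length, carry the statistics
for global shape observables, because conformations decorrelate on the
Rouse time.

**Seeding.** A master seed spawns per-replica seeds through
`numpy.random.SeedSequence`; every run is bit-reproducible from its
manifest on a fixed platform.

## Observables

Size: Rg^2 per snapshot; the ensemble size is R(t) = <Rg^2(t)>^(1/2)
(mean of Rg^2 across replicas, then the root — the order matters and the
mean-then-root convention is asserted in tests).  Shape: the gyration
tensor's descending eigenvalues (their sum equals Rg^2 identically at
every sampled frame), asphericity A, rescaled prolateness P in [-1, 1]
and conventional prolateness Pc in [-1/4, 2].  Averaged shape curves use
the per-snapshot convention (compute A, P, Pc per frame, then average);
the mean-eigenvalue convention is also exposed since the two differ —
e.g. A evaluated on mean relaxed-coil eigenvalues is ~0.47 while the
averaged A is ~0.44.  Expansion speed: three-point differentiation of
each run's Rg(t) on a uniform grid, then ensemble averaging; the t = 0
value is pinned to zero because the confined chain starts at rest
(one-sided stencils would report the post-release surge instead).

## Two-stage kinetics and estimation

Stage 1 (spherical expansion): R(t) = R0 (1 + t/tau_s)^alpha with
alpha = (3 nu_b - 1)/(6 nu_b + 1); a melt-like blob interior (nu_b = 1/2)
gives alpha = 1/8.  Stage 2 (coil expansion): R(t) = RF (1 - bc
e^(-t/tau_c))^(1/5) with bc = 1 for release from strong confinement.
The expansion time is defined as tau = 3 tau_c, where the normalized size
reaches (1 - e^-3)^(1/5) = 0.9898.

Estimation follows the diagnostics-then-fit pattern.  F(t, beta) =
-t/ln(1 - R~^(1/beta)) is constant (= tau_c) exactly when beta is right;
G and H play the same role for 1/beta and alpha.  tau_c comes from a
single-parameter least-squares fit of the normalized master curve
restricted to t > 0.3 tau_c; because the window depends on the estimate
it is recomputed until tau_c moves < 0.1%.  (tau_s, alpha) come from a
two-parameter Levenberg-Marquardt fit on [0, 10 tau_s], iterated the same
way with a 0.5% tolerance and seeded from the early knee of the curve
(first sample with R' > 1.05) so the window latches onto the first-stage
regime even when the input spans the whole expansion.  Exponents are
weighted log-log regressions with 1-sigma errors from the scaled
covariance.  The master-curve collapse factor (theta for stage 2, omega
for stage 1, applied as factor^(g_ref - g) with N = 2^g) minimizes the
across-curve variance of the rescaled curves interpolated onto a shared
logarithmic grid over their common support, scanned at 0.01 resolution;
ties prefer the factor nearest 1.  This "minimum integrated variance"
objective is the package's formalization of picking the finest neck of
the curve bundle.

## Synthetic fixtures

`fixtures.synth_ensemble` emulates the engine's output without dynamics:
the generating curve is max(stage1, stage2) — the first stage rides on
top of the principal coil curve and joins it where they meet — and each
replica multiplies it by log-normal noise exp(s z_t - s^2) with an
optional AR(1) correlation (default coefficient 0.8 between successive
samples, mimicking the time-correlated zigzag of single trajectories).
The -s^2 offset makes E[noise^2] = 1, so R = <Rg^2>^(1/2) is an unbiased
probe of the generating law.  Defaults reflect the N = 512, phi0 = 0.4
release (R0 = 4.05, RF = 18.6, tau_c = 4e5, tau_s = 2.5, alpha = 0.098,
5% noise).  Fitted standard errors are calibrated for white noise;
with AR(1) correlation the naive errors understate the truth, which the
recovery tests therefore probe at ar1_corr = 0.

## Problem sizes, and what the tests do and do not show

The package's default study conditions are desk-scale: chain lengths 32 -
512, tens to hundreds of replicas, 1e4 - 1e5 equilibration steps with a
stationarity check, releases out to ~2.5 tau_c.  At these sizes the
pipelines reproduce the equilibrium scaling laws (RF ~ N^0.60, R0 ~
N^0.36 at phi0 = 0.4, confined N = 512 size 4.05 sigma), the relaxed-coil
shape factors (A ~ 0.44, Pc ~ 0.56, both carrying a known positive
finite-size offset relative to the long-chain values 0.438/0.551), and
characteristic-time exponents with visible finite-size curvature: the
tau_c exponent measured on N = 32 - 96 comes out near 2.6 (the N = 32
point sits below the asymptotic law), and the tau_s exponent on N = 32 -
256 near 0.5 - 0.55 against the published-scale 0.61.  Passing tests
therefore demonstrate correctness of the machinery and consistency with
the scaling picture at reduced size, not a high-precision determination
of the asymptotic exponents.  The synthetic fixtures prove the estimators
recover known parameters; they say nothing about the force field.

## Known limitations

- Rouse (free-draining) dynamics only; no hydrodynamic interactions.
- No bending stiffness, attraction or electrostatics; chain topology is
  trivial (release from reflective confinement does not generate the
  tight entanglements of aged or collapsed globules).
- The loading pathway into the cavity is not simulated; confined states
  are constructed directly, which matches any protocol whose end point is
  the equilibrated confined ensemble.
- The wall reflects bead centers at D/2 - 0.5 sigma; defining it at D/2
  would shift confined sizes by a few percent at small N.
- XYZ trajectories record positions only; velocities are not persisted.
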