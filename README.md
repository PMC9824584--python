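# chainexpand

Expansion kinetics of a single polymer released from a spherical cavity —
a coarse-grained model of genome release from a ruptured viral capsid,
for polymer physicists and structural modellers who want a reproducible,
desk-scale version of the confined-chain release experiment.

A bead-spring chain (WCA excluded volume, stiff harmonic bonds) is
equilibrated inside a reflecting sphere of diameter
D = σ(N/ϕ₀)^(1/3) and released at t = 0 under Langevin (Rouse) dynamics.
The ensemble size R(t) = ⟨R_g²(t)⟩^(1/2) then follows a two-stage law:

* **Stage 1 — spherical expansion.**  R(t) = R₀ (1 + t/τ_s)^α with
  α = (3ν_b − 1)/(6ν_b + 1); a melt-like blob interior (ν_b ≈ 1/2) gives
  α ≈ 1/8, and τ_s ∼ N^x_s with x_s ≈ 0.6–0.85 depending on ϕ₀.
* **Stage 2 — coil expansion.**  R(t) = R_F (1 − e^(−t/τ_c))^(1/5), the
  exact solution of the free-energy/dissipation balance with the Flory
  free energy.  τ_c ∼ N^2.36 empirically, the total expansion time is
  τ = 3τ_c, and curves for different N collapse onto a master curve when
  time is rescaled by θ^(9−g) with N = 2^g, θ = 2^2.36 ≈ 5.13.

The package provides the Langevin engine (numba-accelerated), the
size/shape observables (gyration tensor eigenvalues, asphericity,
prolateness, expansion velocity), the closed-form theory, the fitting and
master-curve-collapse machinery, a synthetic-ensemble generator for
testing the estimators without dynamics, and a thin `chainexpand` CLI.

## Worked example

Fit both stage laws on a synthetic 100-replica ensemble with known
parameters (`examples/02_fit_two_stage_laws.py`):

```
truth: tau_c = 400000, tau_s = 2.5, alpha = 0.098
F(t, beta=1/5) level: 4e+05 (flat => beta right)
stage 2: tau_c = 399938 +- 2354 (window t > 119981, 3 iterations)
stage 1: tau_s = 2.37 +- 0.10, alpha = 0.0964 +- 0.0021
```

The F diagnostic is constant in time exactly when the stage-2 exponent
β = 1/5 is right, and its level previews τ_c; the windowed fits then
recover both characteristic times within their standard errors.

Release an actual chain (`examples/01_release_single_chain.py`, N = 64,
ϕ₀ = 0.4, ~1 minute):

```
cavity diameter D = 5.429 sigma (wall at 2.214 sigma for bead centers)
t =      0.0 tu   Rg =  1.927 sigma   A = 0.003
t =     28.3 tu   Rg =  2.690 sigma   A = 0.021
t =   2489.6 tu   Rg =  5.990 sigma   A = 0.450
```

The chain grows from the cavity-set size to the self-avoiding coil value
while its shape turns from spherical (A ≈ 0) to coil-like (A ≈ 0.45).
Real-unit mapping (`examples/04_units_and_predictions.py`): with
σ = 3.4 Å, m = 320 g/mol, k_BT = 4.14×10⁻²¹ J the time unit is 3.85 ps,
and the empirical law τ_c ≈ 0.18 N^2.36 puts the expansion of a released
1 kbp single-stranded genome at τ_c ≈ 8.3 μs.

`examples/03_master_curve_collapse.py` shows the collapse optimizer
recovering θ = 5.13 from a constructed curve family, and the CLI mirrors
these workflows (`chainexpand ensemble --n 64 --phi0 0.4 …`,
`chainexpand fit-stage2 …`, `chainexpand units`).

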