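"""Two-stage kinetic theory of chain expansion after release from a cavity.

Stage 1 (spherical expansion): the compressed chain swells as a uniform
sphere of blobs; balancing the free-energy release of the blob gas against
Rouse friction gives

    R(t) = R0 (1 + t/tau_s)^alpha,      alpha = (3 nu_b - 1)/(6 nu_b + 1),

with nu_b the blob metric exponent (nu_b ~ 1/2 for a melt-like interior)
and tau_s ~ (eta sigma^2/kBT) (R0/sigma)^(1/alpha) N^(-1/(3 nu_b - 1)).

Stage 2 (coil expansion): with the Flory free energy the balance equation
becomes a Bernoulli ODE whose exact solution is

    R(t) = RF (1 - bc exp(-t/tau_c))^(1/5),     tau_c ~ (eta sigma^2/kBT) N^2,

with bc = 1 for a chain released from strong confinement.  The total
expansion time is defined as tau = 3 tau_c, at which the normalized size
(1 - e^-3)^(1/5) = 0.9898 is essentially the final one.

The module also maps simulation units to SI through the single-stranded
DNA/RNA parameterization sigma = 3.4 A, m = 320 g/mol, kBT = 4.14e-21 J.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StageOneParams",
    "StageTwoParams",
    "UnitMap",
    "stage1_size",
    "stage2_size",
    "stage2_normalized",
    "stage1_velocity",
    "stage2_velocity",
    "alpha_from_nub",
    "nub_from_alpha",
    "predicted_tau_s",
    "predicted_tau_c",
    "predicted_xs",
    "free_energy_blob",
    "free_energy_flory",
    "simulation_time_unit",
    "to_real_units",
    "expansion_time",
    "demarcation_exponents",
]


def alpha_from_nub(nu_b: float) -> float:
    """Stage-1 kinetic exponent alpha = (3 nu_b - 1)/(6 nu_b + 1).

    Positive only for nu_b > 1/3 (a blob denser than ideal packing of the
    metric would contradict the free-energy form).
    """
    return (3.0 * nu_b - 1.0) / (6.0 * nu_b + 1.0)


def nub_from_alpha(alpha: float) -> float:
    """Inverse map nu_b = (1 + alpha)/(3 - 6 alpha); requires alpha < 1/2."""
    if alpha >= 0.5:
        raise ValueError("alpha must be < 1/2")
    return (1.0 + alpha) / (3.0 - 6.0 * alpha)


@dataclass(frozen=True)
class StageOneParams:
    """Parameters of the spherical-expansion law R = R0 (1 + t/tau_s)^alpha."""

    R0: float
    tau_s: float
    alpha: float

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.tau_s <= 0 or not 0 < self.alpha < 0.5:
            raise ValueError("require R0 > 0, tau_s > 0, 0 < alpha < 1/2")

    @property
    def nu_b(self) -> float:
        return nub_from_alpha(self.alpha)


@dataclass(frozen=True)
class StageTwoParams:
    """Parameters of the coil-expansion law R = RF (1 - bc e^(-t/tau_c))^beta."""

    RF: float
    tau_c: float
    beta: float = 0.2
    bc: float = 1.0

    def __post_init__(self) -> None:
        if self.RF <= 0 or self.tau_c <= 0 or self.beta <= 0:
            raise ValueError("require RF > 0, tau_c > 0, beta > 0")


def _check_time(t):
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def stage1_size(t, p: StageOneParams):
    """R(t) = R0 (1 + t/tau_s)^alpha; monotone increasing from R(0) = R0."""
    t = _check_time(t)
    return (p.R0 * (1.0 + t / p.tau_s) ** p.alpha)[()]


def stage2_size(t, p: StageTwoParams):
    """R(t) = RF (1 - bc e^(-t/tau_c))^beta."""
    t = _check_time(t)
    base = 1.0 - p.bc * np.exp(-t / p.tau_c)
    if np.any(base < 0):
        raise ValueError("bc > 1 makes the base negative at small t")
    return (p.RF * base ** p.beta)[()]


def stage2_normalized(t, tau_c: float, beta: float = 0.2):
    """Master curve R~(t) = (1 - e^(-t/tau_c))^beta with bc = 1."""
    return stage2_size(t, StageTwoParams(RF=1.0, tau_c=tau_c, beta=beta))


def stage1_velocity(t, p: StageOneParams):
    """dR/dt = alpha R0/tau_s (1 + t/tau_s)^(alpha-1).

    Finite and positive at t=0 (value alpha R0/tau_s): the quasi-static
    balance cannot describe the initial transient where the true speed
    starts from zero.
    """
    t = _check_time(t)
    return (p.alpha * p.R0 / p.tau_s
            * (1.0 + t / p.tau_s) ** (p.alpha - 1.0))[()]


def stage2_velocity(t, p: StageTwoParams):
    """dR/dt = beta RF/tau_c (1 - bc e^(-t/tau_c))^(beta-1) e^(-t/tau_c).

    Diverges as t -> 0+ for bc = 1; the t=0 value is reported as inf.
    """
    t = _check_time(t)
    with np.errstate(divide="ignore"):
        e = np.exp(-t / p.tau_c)
        base = 1.0 - p.bc * e
        v = np.where(base > 0,
                     p.beta * p.RF / p.tau_c
                     * np.power(np.maximum(base, 1e-300), p.beta - 1.0) * e,
                     np.inf)
    return v[()]


def predicted_tau_s(N: int, R0: float, alpha: float, nu_b: float,
                    eta: float = 20.0, sigma: float = 1.0, kBT: float = 1.0,
                    a_s: float = 1.0) -> float:
    """Stage-1 time scale a_s (eta sigma^2/kBT) (R0/sigma)^(1/alpha) N^(-1/(3 nu_b-1)).

    The prefactor a_s is a fit constant, never predicted; nu_b = 1/3 is
    singular.
    """
    if abs(3.0 * nu_b - 1.0) < 1e-12:
        raise ValueError("nu_b = 1/3 is singular")
    return (a_s * eta * sigma ** 2 / kBT * (R0 / sigma) ** (1.0 / alpha)
            * N ** (-1.0 / (3.0 * nu_b - 1.0)))


def predicted_tau_c(N: int, eta: float = 20.0, sigma: float = 1.0,
                    kBT: float = 1.0, a_c: float = 1.0,
                    exponent: float = 2.0) -> float:
    """Stage-2 time scale a_c (eta sigma^2/kBT) N^exponent.

    ``exponent`` defaults to the theoretical 2; pass 2.36 for the
    empirically observed law (a_c = 0.18 with times quoted directly in tu,
    i.e. eta sigma^2/kBT folded into the prefactor).
    """
    return a_c * eta * sigma ** 2 / kBT * N ** exponent


def predicted_xs(delta: float, alpha: float, nu_b: float) -> float:
    """Predicted tau_s-vs-N exponent (1/3 + delta)/alpha - 1/(3 nu_b - 1).

    delta is the deviation of the confined-size scaling R0 ~ N^(1/3+delta)
    from the geometric 1/3.
    """
    if abs(3.0 * nu_b - 1.0) < 1e-12:
        raise ValueError("nu_b = 1/3 is singular")
    return (1.0 / 3.0 + delta) / alpha - 1.0 / (3.0 * nu_b - 1.0)


def free_energy_blob(R, N: int, nu_b: float, kBT: float = 1.0,
                     sigma: float = 1.0):
    """Confined-sphere free energy F ~ kBT N^(3nu_b/(3nu_b-1)) (R/sigma)^(-3/(3nu_b-1)).

    Implied O(1) prefactor taken as 1; decreasing in R (expansion is
    downhill).  nu_b = 1/3 is singular.
    """
    if abs(3.0 * nu_b - 1.0) < 1e-12:
        raise ValueError("nu_b = 1/3 is singular")
    R = np.asarray(R, dtype=np.float64)
    if np.any(R <= 0):
        raise ValueError("R must be positive")
    x = 3.0 * nu_b - 1.0
    return (kBT * N ** (3.0 * nu_b / x) * (R / sigma) ** (-3.0 / x))[()]


def free_energy_flory(R, N: int, v_ex: float | None = None,
                      kBT: float = 1.0, sigma: float = 1.0):
    """Flory coil free energy F ~ kBT [R^2/(N sigma^2) + v_ex N^2/R^3].

    The excluded volume v_ex defaults to sigma^3.  Minimizing over R gives
    the coil size R* ~ N^(3/5).
    """
    if v_ex is None:
        v_ex = sigma ** 3
    R = np.asarray(R, dtype=np.float64)
    if np.any(R <= 0):
        raise ValueError("R must be positive")
    return (kBT * (R ** 2 / (N * sigma ** 2) + v_ex * N ** 2 / R ** 3))[()]


_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class UnitMap:
    """SI values of the simulation units (defaults: ssDNA/RNA mapping)."""

    sigma_SI: float = 3.4e-10        # m
    mass_SI: float = 0.320 / _AVOGADRO  # kg per bead (320 g/mol)
    kBT_SI: float = 4.14e-21         # J (300 K)

    def __post_init__(self) -> None:
        if min(self.sigma_SI, self.mass_SI, self.kBT_SI) <= 0:
            raise ValueError("SI constants must be positive")


def simulation_time_unit(units: UnitMap = UnitMap()) -> float:
    """tu = sigma sqrt(m/kBT) in seconds (3.85e-12 s for the default map)."""
    return units.sigma_SI * np.sqrt(units.mass_SI / units.kBT_SI)


def to_real_units(t_sim, units: UnitMap = UnitMap()):
    """Convert simulation time to seconds (linear, invertible)."""
    return (np.asarray(t_sim, dtype=np.float64)
            * simulation_time_unit(units))[()]


def expansion_time(tau_c: float) -> float:
    """Total expansion time tau = 3 tau_c.

    At t = 3 tau_c the master curve has reached (1 - e^-3)^(1/5) = 0.9898
    of the final size, i.e. the chain is essentially relaxed.
    """
    return 3.0 * tau_c


def demarcation_exponents(xs: float, xc: float, nu_s: float = 1.0 / 3.0,
                          nu_c: float = 0.6) -> tuple[float, float]:
    """Exponents of the two demarcation lines in the scaled-time planes.

    In the t/tau_s plane the fully-relaxed boundary runs as
    t'' ~ R^((xc-xs)/nu_c); in the t/tau_c plane the leaving-the-sphere
    boundary runs as t~* ~ R^((xs-xc)/nu_s).  Prefactors are fit when the
    lines are drawn, not predicted.
    """
    return (xc - xs) / nu_c, (xs - xc) / nu_s
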