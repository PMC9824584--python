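"""Bead-spring force field, spherical cavity geometry, and chain state.

The chain is a linear sequence of N beads: consecutive beads are tied by a
stiff harmonic spring, every bead pair repels through the purely repulsive
WCA (truncated-shifted Lennard-Jones) potential, and during confinement
bead centers are specularly reflected at the cavity wall.  All quantities
are in simulation units: bead diameter sigma, bead mass m, thermal energy
kBT, time unit tu = sigma*sqrt(m/kBT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "ModelParams",
    "CavitySpec",
    "ChainSnapshot",
    "wca_energy",
    "wca_force",
    "bond_energy",
    "total_forces",
    "cavity_diameter",
    "reflect_wall",
    "WCA_CUTOFF",
]

#: WCA cutoff in units of sigma, 2**(1/6).
WCA_CUTOFF = _kernels.RCUT_FACTOR


class ConfigurationError(ValueError):
    """Raised for geometrically impossible model configurations."""


@dataclass(frozen=True)
class ModelParams:
    """Force-field, thermostat and integration constants (simulation units).

    Defaults are the good-solvent aqueous parameter set: epsilon=1.2 kBT,
    b0=1.0 sigma, k_spring=6000 kBT/sigma^2 (bond fluctuations < 1%, so
    chain strands cannot cross), friction eta=20 sqrt(m kBT)/sigma and
    integration step dt=0.005 tu.
    """

    epsilon: float = 1.2
    sigma: float = 1.0
    b0: float = 1.0
    k_spring: float = 6000.0
    mass: float = 1.0
    kBT: float = 1.0
    eta: float = 20.0
    dt: float = 0.005

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma", "b0", "k_spring", "mass",
                     "kBT", "eta", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dt * self.eta / self.mass >= 1.0:
            warnings.warn(
                "dt*eta/mass >= 1: overdamped friction per step, the "
                "Langevin integration may be inaccurate",
                stacklevel=2,
            )

    @property
    def rcut(self) -> float:
        """Nonbonded interaction cutoff 2**(1/6)*sigma."""
        return WCA_CUTOFF * self.sigma


def cavity_diameter(N: int, phi0: float, sigma: float = 1.0) -> float:
    """Cavity diameter D = sigma*(N/phi0)**(1/3) at volume fraction phi0."""
    if not 0.0 < phi0 <= 1.0:
        raise ValueError(f"phi0 must be in (0, 1], got {phi0}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    return sigma * (N / phi0) ** (1.0 / 3.0)


@dataclass(frozen=True)
class CavitySpec:
    """Confining sphere for N monomers at volume fraction phi0 = N sigma^3/D^3."""

    N: int
    phi0: float
    sigma: float = 1.0
    D: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"need at least 2 monomers, got N={self.N}")
        object.__setattr__(
            self, "D", cavity_diameter(self.N, self.phi0, self.sigma))

    @property
    def wall_radius(self) -> float:
        """Radius available to bead centers: D/2 minus the 0.5 sigma bead radius."""
        r = 0.5 * self.D - 0.5 * self.sigma
        if r <= 0:
            raise ConfigurationError(
                f"cavity D={self.D:.3f} leaves no room for bead centers")
        return r


@dataclass
class ChainSnapshot:
    """Positions and velocities of the N beads at one instant."""

    positions: np.ndarray  # (N, 3), sigma
    velocities: np.ndarray  # (N, 3), sigma/tu
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != self.velocities.shape \
                or self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions and velocities must both be (N, 3)")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite coordinates in snapshot")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def copy(self) -> "ChainSnapshot":
        return ChainSnapshot(self.positions.copy(), self.velocities.copy(),
                             self.time)


def wca_energy(r, params: ModelParams = ModelParams()):
    """WCA pair energy 4*eps*[(sigma/r)^12 - (sigma/r)^6 + 1/4] for r <= 2^(1/6) sigma.

    Zero at and beyond the cutoff; continuous there.  Accepts scalars or
    arrays; r <= 0 is a domain error.
    """
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma / r) ** 6
    u = 4.0 * params.epsilon * (sr6 * sr6 - sr6 + 0.25)
    return np.where(r <= params.rcut, u, 0.0)[()]


def wca_force(r, params: ModelParams = ModelParams()):
    """Radial WCA force magnitude -dU/dr; positive = repulsive, 0 beyond cutoff."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    sr6 = (params.sigma / r) ** 6
    f = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return np.where(r <= params.rcut, f, 0.0)[()]


def bond_energy(b, params: ModelParams = ModelParams()):
    """Harmonic bond energy (k/2)*(b - b0)^2."""
    b = np.asarray(b, dtype=np.float64)
    if np.any(b < 0):
        raise ValueError("bond length must be non-negative")
    return (0.5 * params.k_spring * (b - params.b0) ** 2)[()]


def total_forces(snapshot: ChainSnapshot,
                 params: ModelParams = ModelParams(),
                 cavity: CavitySpec | None = None,
                 force_cap: float | None = None) -> np.ndarray:
    """Total bonded + nonbonded force on every bead, shape (N, 3).

    Pair enumeration goes through a cell-binned neighbour search above a
    small-N threshold and an all-pairs loop below it; both are exact for
    the 2^(1/6) sigma cutoff.  ``cavity`` is accepted for interface
    symmetry but contributes no force: the wall acts by reflection, not
    through a potential.  ``force_cap`` (kBT/sigma) bounds the per-pair
    WCA force during initialization push-off; never use it in production.
    """
    pos = snapshot.positions
    dmin = float(_kernels.min_nonbonded_distance(pos)) if pos.shape[0] > 2 \
        else np.inf
    if dmin < 0.3 * params.sigma and force_cap is None:
        warnings.warn(
            f"overlapping beads (min nonbonded distance {dmin:.3f} sigma); "
            "forces are near-singular, consider a force_cap push-off",
            stacklevel=2,
        )
    fcap = -1.0 if force_cap is None else float(force_cap)
    return _kernels.compute_forces(
        pos, params.epsilon, params.sigma, params.k_spring, params.b0, fcap)


def reflect_wall(snapshot: ChainSnapshot, D: float,
                 sigma: float = 1.0) -> ChainSnapshot:
    """Return a snapshot with beads specularly reflected into the cavity.

    Beads whose center exceeds radius D/2 - 0.5*sigma are mirrored about
    that sphere along the radial direction and their outward radial
    velocity component is negated; speed is conserved.  Beads inside are
    untouched.
    """
    wall_radius = 0.5 * D - 0.5 * sigma
    if wall_radius <= 0:
        raise ConfigurationError(
            f"D/2 - 0.5*sigma = {wall_radius:.3f} <= 0: cavity too small")
    out = snapshot.copy()
    _kernels.reflect_wall(out.positions, out.velocities, wall_radius)
    return out
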