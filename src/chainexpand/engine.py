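"""Langevin dynamics driver: equilibration, release runs, replica ensembles.

The integrator is velocity Verlet with a BAOAB splitting of the Langevin
thermostat: the friction/noise substep applies the exact Ornstein-Uhlenbeck
update v -> c v + sqrt((1-c^2) kBT/m) xi with c = exp(-eta dt/m), so a free
bead has the exact Maxwell-Boltzmann velocity distribution at any dt.
Reproducibility contract: (config, master seed) -> bit-identical output;
per-replica seeds are derived from the master seed with
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import _kernels
from .chaingen import PackingError, random_walk_in_sphere, sample_saw
from .model import CavitySpec, ChainSnapshot, ModelParams
from .observables import (EnsembleCurves, ShapeTrace, SizeCurve,
                          ensemble_mean_size, shape_trace_from_tensor_samples)

__all__ = [
    "RunSchedule",
    "EnsembleConfig",
    "EnsembleRecord",
    "IntegrationError",
    "langevin_step",
    "initialize_confined",
    "initialize_free",
    "equilibrate",
    "release_run",
    "run_ensemble",
    "log_sample_times",
    "maxwell_velocities",
    "replica_seeds",
]


class IntegrationError(RuntimeError):
    """Raised when coordinates go non-finite during integration."""


def log_sample_times(t_end: float, n: int = 200,
                     t_min: float = 0.05) -> np.ndarray:
    """Log-spaced output times including t=0: dense early, sparse late.

    The expansion spans several decades in time, so the default sampling
    grid is logarithmic between ``t_min`` and ``t_end`` with t=0 prepended.
    """
    if t_end <= t_min:
        raise ValueError("t_end must exceed t_min")
    return np.concatenate([[0.0], np.geomspace(t_min, t_end, n)])


@dataclass(frozen=True)
class RunSchedule:
    """Step budgets, output grid and seed for one equilibrate+release cycle."""

    equil_steps: int = 1_000_000
    release_steps: int = 200_000
    sample_times: np.ndarray = field(
        default_factory=lambda: log_sample_times(1000.0))
    seed: int = 0

    def __post_init__(self) -> None:
        st = np.asarray(self.sample_times, dtype=np.float64)
        if st.ndim != 1 or len(st) < 1 or st[0] < 0 \
                or np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must be strictly increasing, >= 0")
        object.__setattr__(self, "sample_times", st)


def maxwell_velocities(n: int, params: ModelParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at kBT: per-component variance kBT/m."""
    return rng.normal(0.0, np.sqrt(params.kBT / params.mass), (n, 3))


def _times_to_steps(times: np.ndarray, dt: float) -> np.ndarray:
    steps = np.unique(np.rint(np.asarray(times) / dt).astype(np.int64))
    return steps


def _run(snapshot: ChainSnapshot, params: ModelParams, n_steps: int,
         sample_steps: np.ndarray, wall_radius: float,
         rng: np.random.Generator, noise: bool = True,
         force_cap: float | None = None, record_frames: bool = False):
    fcap = -1.0 if force_cap is None else float(force_cap)
    samples, frames, max_radius, ok = _kernels.run_md(
        snapshot.positions, snapshot.velocities, int(n_steps),
        np.ascontiguousarray(sample_steps, dtype=np.int64),
        params.dt, params.mass, params.eta, params.kBT,
        params.epsilon, params.sigma, params.k_spring, params.b0,
        wall_radius, rng, 1 if noise else 0, fcap,
        1 if record_frames else 0)
    if not ok:
        raise IntegrationError(
            f"integration failed (non-finite coordinates) near "
            f"t={snapshot.time + n_steps * params.dt:.3f}")
    return samples, frames, max_radius


def langevin_step(snapshot: ChainSnapshot, params: ModelParams,
                  rng: np.random.Generator, n_steps: int = 1,
                  wall_radius: float = -1.0,
                  noise: bool = True) -> ChainSnapshot:
    """Advance the snapshot by ``n_steps`` BAOAB Langevin steps.

    With ``noise=False`` (test hook) only deterministic friction acts and
    the velocity of a force-free bead decays geometrically by
    exp(-eta dt/m) per step.
    """
    out = snapshot.copy()
    _run(out, params, n_steps, np.empty(0, dtype=np.int64), wall_radius,
         rng, noise=noise)
    out.time = snapshot.time + n_steps * params.dt
    return out


#: Push-off force-cap ramp (kBT/sigma) used by initialize_confined.
PUSHOFF_RAMP = (5.0, 20.0, 100.0, 1000.0)
PUSHOFF_STEPS = 2000


def initialize_confined(N: int, phi0: float, params: ModelParams,
                        rng: np.random.Generator,
                        max_retries: int = 5) -> ChainSnapshot:
    """Self-avoiding confined chain with thermal velocities, inside the wall.

    A fixed-bond random walk is grown inside the cavity (overlaps allowed),
    then overlaps are removed by short Langevin runs with the pair force
    capped at an increasing ramp; velocities are redrawn from the
    Maxwell-Boltzmann distribution after each stage.  The capped force is
    an initialization-only device, never used in production.
    """
    cavity = CavitySpec(N, phi0, params.sigma)
    wall = cavity.wall_radius
    for _ in range(max_retries):
        pos = random_walk_in_sphere(N, wall, rng, bond=params.b0)
        snap = ChainSnapshot(pos, maxwell_velocities(N, params, rng), 0.0)
        try:
            for fcap in PUSHOFF_RAMP:
                _run(snap, params, PUSHOFF_STEPS, np.empty(0, dtype=np.int64),
                     wall, rng, force_cap=fcap)
                snap.velocities = maxwell_velocities(N, params, rng)
        except IntegrationError:
            continue
        dmin = float(_kernels.min_nonbonded_distance(snap.positions))
        bonds = snap.bond_lengths()
        if dmin >= 0.8 * params.sigma \
                and np.all(np.abs(bonds - params.b0) < 0.05 * params.b0):
            snap.time = 0.0
            return snap
    raise PackingError(
        f"could not prepare an overlap-free confined chain (N={N}, "
        f"phi0={phi0}) after {max_retries} attempts")


def initialize_free(N: int, params: ModelParams,
                    rng: np.random.Generator) -> ChainSnapshot:
    """Free coil start: exact self-avoiding configuration + thermal velocities."""
    pos = sample_saw(N, rng, bond=params.b0)
    pos = pos - pos.mean(axis=0)
    return ChainSnapshot(pos, maxwell_velocities(N, params, rng), 0.0)


def _stationarity_pvalue(times: np.ndarray, values: np.ndarray) -> float:
    """p-value of a zero-slope test on the last half of a series.

    Consecutive samples are correlated, so the series is block-averaged to
    ~16 blocks before the regression; small p flags a residual trend.
    """
    half = len(values) // 2
    t, v = times[half:], values[half:]
    nblock = min(16, len(v) // 4)
    if nblock < 4:
        return 1.0
    edges = np.array_split(np.arange(len(v)), nblock)
    tb = np.array([t[e].mean() for e in edges])
    vb = np.array([v[e].mean() for e in edges])
    res = stats.linregress(tb, vb)
    return float(res.pvalue)


def equilibrate(snapshot: ChainSnapshot, params: ModelParams,
                cavity: CavitySpec | None, n_steps: int,
                rng: np.random.Generator, record_every: int = 1000,
                check_stationarity: bool = True
                ) -> tuple[ChainSnapshot, SizeCurve]:
    """Run ``n_steps`` with the wall active (if cavity given), tracking Rg^2.

    Returns the final snapshot (time reset to 0, ready for release) and the
    recorded Rg^2 series for convergence inspection.  A significant linear
    trend in the last half of the series raises a warning, not an error.
    """
    wall = cavity.wall_radius if cavity is not None else -1.0
    out = snapshot.copy()
    sample_steps = np.arange(0, n_steps + 1, record_every, dtype=np.int64)
    samples, _, max_radius, = _run(out, params, n_steps, sample_steps,
                                   wall, rng)[:3]
    times = sample_steps * params.dt
    curve = SizeCurve(times=times, rg2=samples[:, 0])
    if cavity is not None and max_radius > wall * (1 + 1e-9):
        raise IntegrationError(
            f"bead escaped the cavity: max radius {max_radius:.4f} > "
            f"wall {wall:.4f}")
    if check_stationarity:
        p = _stationarity_pvalue(times, samples[:, 0])
        if p < 0.01:
            warnings.warn(
                f"Rg^2 still trending after equilibration "
                f"(trend-test p={p:.2g}); consider more steps",
                stacklevel=2)
    bonds = out.bond_lengths()
    rms = np.sqrt(np.mean((bonds - params.b0) ** 2)) / params.b0
    if rms > 0.03:
        warnings.warn(
            f"bond-length fluctuation {rms:.1%} after equilibration "
            "(expected ~1% for the default spring)", stacklevel=2)
    out.time = 0.0
    return out, curve


def release_run(snapshot: ChainSnapshot, params: ModelParams,
                sample_times: np.ndarray, rng: np.random.Generator,
                record_frames: bool = False
                ) -> tuple[SizeCurve, ShapeTrace, np.ndarray | None]:
    """Switch the wall off at t=0 and record observables at ``sample_times``.

    The first sample (t=0) reports the confined Rg of the input snapshot.
    """
    out = snapshot.copy()
    sample_steps = _times_to_steps(sample_times, params.dt)
    n_steps = int(sample_steps[-1])
    samples, frames, _ = _run(out, params, n_steps, sample_steps, -1.0, rng,
                              record_frames=record_frames)
    times = sample_steps * params.dt
    size = SizeCurve(times=times, rg2=samples[:, 0])
    shape = shape_trace_from_tensor_samples(times, samples[:, 1:7])
    return size, shape, (frames if record_frames else None)


def replica_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replica seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint32) % np.uint32(2 ** 31)) \
        .astype(np.int64)


@dataclass(frozen=True)
class EnsembleConfig:
    """Declarative description of a replica ensemble.

    ``phi0 is None`` runs free coils (no cavity, no release: production
    sampling of the relaxed chain); otherwise chains are equilibrated in
    the cavity and released at t=0.
    """

    N: int
    phi0: float | None
    replicas: int
    seed: int
    params: ModelParams = ModelParams()
    equil_steps: int = 100_000
    sample_times: np.ndarray = field(
        default_factory=lambda: log_sample_times(1000.0))
    free_relax_steps: int = 20_000

    def describe(self) -> dict:
        return {
            "N": self.N,
            "phi0": self.phi0,
            "replicas": self.replicas,
            "seed": self.seed,
            "equil_steps": self.equil_steps,
            "free_relax_steps": self.free_relax_steps,
            "sample_times": [float(t) for t in self.sample_times],
            "params": {k: getattr(self.params, k) for k in
                       ("epsilon", "sigma", "b0", "k_spring", "mass",
                        "kBT", "eta", "dt")},
        }


@dataclass
class EnsembleRecord:
    """Replica ensemble on a shared time grid."""

    times: np.ndarray            # (T,)
    rg2: np.ndarray              # (replicas, T)
    eigvals: np.ndarray          # (replicas, T, 3), descending
    seeds: np.ndarray            # (replicas,)
    config: dict
    n_failed: int = 0

    @property
    def n_replicas(self) -> int:
        return self.rg2.shape[0]

    def size_curves(self) -> list[SizeCurve]:
        return [SizeCurve(self.times, r) for r in self.rg2]

    def ensemble_curves(self) -> EnsembleCurves:
        return ensemble_mean_size(self.size_curves(), eigvals=self.eigvals)


def run_ensemble(config: EnsembleConfig) -> EnsembleRecord:
    """Run ``config.replicas`` independent replicas on a shared time grid.

    Replica seeds derive deterministically from the master seed; a replica
    that fails to integrate is excluded from the record and counted in
    ``n_failed``.
    """
    if config.replicas < 1:
        raise ValueError("replica count must be >= 1")
    seeds = replica_seeds(config.seed, config.replicas)
    all_rg2, all_eig, used_seeds = [], [], []
    n_failed = 0
    times = None
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        try:
            if config.phi0 is None:
                snap = initialize_free(config.N, config.params, rng)
                # short local thermalization before production sampling
                _run(snap, config.params, config.free_relax_steps,
                     np.empty(0, dtype=np.int64), -1.0, rng)
                size, shape, _ = release_run(
                    snap, config.params, config.sample_times, rng)
            else:
                snap = initialize_confined(
                    config.N, config.phi0, config.params, rng)
                cavity = CavitySpec(config.N, config.phi0,
                                    config.params.sigma)
                snap, _ = equilibrate(snap, config.params, cavity,
                                      config.equil_steps, rng,
                                      check_stationarity=False)
                size, shape, _ = release_run(
                    snap, config.params, config.sample_times, rng)
        except (IntegrationError, PackingError):
            n_failed += 1
            continue
        if times is None:
            times = size.times
        all_rg2.append(size.rg2)
        all_eig.append(shape.eigvals)
        used_seeds.append(seed)
    if not all_rg2:
        raise IntegrationError("all replicas failed")
    return EnsembleRecord(
        times=times,
        rg2=np.array(all_rg2),
        eigvals=np.array(all_eig),
        seeds=np.array(used_seeds),
        config=config.describe(),
        n_failed=n_failed,
    )
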