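"""Synthetic two-stage expansion ensembles for fit and collapse testing.

The generator emulates what the Langevin engine produces — per-replica
Rg(t) curves that follow the spherical-expansion law early, join the coil
master curve where the two intersect, and fluctuate multiplicatively in a
time-correlated way — without running any dynamics.  The generating curve is

    R_gen(t) = max(stage1(t), stage2(t)),

the crossover picture in which the first stage is an add-on riding on top
of the principal second-stage curve until the two meet.  Noise is
multiplicative log-normal with an optional AR(1) correlation, mimicking
the zigzag of single-run trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import EnsembleRecord, replica_seeds
from .theory import StageOneParams, StageTwoParams, stage1_size, stage2_size

__all__ = ["FixtureSpec", "synth_ensemble", "generating_curve"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic expansion ensemble.

    Defaults emulate a long chain (N = 512) released from strong
    confinement (volume fraction 0.4): confined size R0 = 4.05, coil size
    RF = 18.6, coil time tau_c = 4.0e5 with the first-stage add-on three
    orders of magnitude faster, 5% multiplicative noise with a short
    correlation time, and the stage-1 exponent at the melt-blob value.
    """

    R0: float = 4.05
    tau_s: float = 2.5
    alpha: float = 0.098
    RF: float = 18.6
    tau_c: float = 4.0e5
    beta: float = 0.2
    bc: float = 1.0
    noise: float = 0.05
    ar1_corr: float = 0.8          # per-sample AR(1) coefficient, [0, 1)
    replicas: int = 100
    times: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [[0.0], np.geomspace(0.01, 2.0e6, 400)]))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise amplitude must be >= 0")
        if not 0 <= self.ar1_corr < 1:
            raise ValueError("ar1_corr must be in [0, 1)")
        if self.replicas < 1:
            raise ValueError("replica count must be >= 1")
        t = np.asarray(self.times, dtype=np.float64)
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("times must be strictly increasing, >= 0")
        object.__setattr__(self, "times", t)
        s2_0 = stage2_size(0.0, self.stage2)
        s1_0 = stage1_size(0.0, self.stage1)
        if s2_0 > s1_0:
            raise ValueError(
                "stage2(0) > stage1(0): inconsistent crossover (bc < 1 "
                "with a coil larger than the confined chain)")

    @property
    def stage1(self) -> StageOneParams:
        return StageOneParams(self.R0, self.tau_s, self.alpha)

    @property
    def stage2(self) -> StageTwoParams:
        return StageTwoParams(self.RF, self.tau_c, self.beta, self.bc)


def generating_curve(spec: FixtureSpec) -> np.ndarray:
    """Noise-free R(t): the larger of the two stage laws at every time."""
    return np.maximum(stage1_size(spec.times, spec.stage1),
                      stage2_size(spec.times, spec.stage2))


def synth_ensemble(spec: FixtureSpec) -> EnsembleRecord:
    """Generate per-replica Rg^2 curves [R_gen(t) * noise(t)]^2.

    noise(t) = exp(s * z_t - s^2) with z an AR(1) standard-normal
    sequence; the -s^2 offset makes E[noise^2] = 1 exactly, so the
    canonical ensemble statistic R = <Rg^2>^(1/2) converges to the
    generating curve as replicas grow.  The eigenvalue record mimics the
    coil anisotropy by splitting Rg^2 in constant proportions; it exists
    so downstream ensemble plumbing works on fixtures too.
    """
    base = generating_curve(spec)
    T = len(spec.times)
    seeds = replica_seeds(spec.seed, spec.replicas)
    rg2 = np.empty((spec.replicas, T))
    rho = spec.ar1_corr
    s = spec.noise
    for k, seed in enumerate(seeds):
        rng = np.random.default_rng(int(seed))
        if s > 0:
            z = np.empty(T)
            z[0] = rng.standard_normal()
            innov = rng.standard_normal(T - 1)
            for i in range(1, T):
                z[i] = rho * z[i - 1] + np.sqrt(1 - rho * rho) * innov[i - 1]
            noise = np.exp(s * z - s * s)
        else:
            noise = np.ones(T)
        rg2[k] = (base * noise) ** 2
    # fixed coil-like eigenvalue split (fractions of Rg^2)
    split = np.array([0.790, 0.161, 0.049])
    eig = rg2[:, :, None] * split[None, None, :]
    return EnsembleRecord(times=spec.times.copy(), rg2=rg2, eigvals=eig,
                          seeds=seeds, config={"fixture": spec.__dict__ |
                                               {"times": spec.times.tolist()}},
                          n_failed=0)
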