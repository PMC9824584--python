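"""Initial chain configurations.

Two generators feed the Langevin engine:

* a fixed-bond random walk grown inside the cavity sphere (overlaps allowed,
  removed afterwards by a capped-force push-off) for confined starts, and
* an exact hard-core self-avoiding walk sampled by dimerization for free
  coil starts.  Dimerization recursively concatenates two independently
  sampled half-chains and rejects the pair on any overlap, which yields the
  uniform self-avoiding ensemble; it is the standard way to obtain
  equilibrium coil statistics when direct Langevin relaxation of the
  slowest (whole-coil) modes is out of reach.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

__all__ = ["random_walk_in_sphere", "sample_saw", "PackingError"]

#: Hard-core exclusion distance (sigma units) used by the SAW sampler.
#: Slightly below the bead diameter so that the WCA chain accepts the
#: configuration without capped forces (U_WCA(0.9) ~ 1 kBT).
SAW_EXCLUSION = 0.9


class PackingError(RuntimeError):
    """Raised when an initial configuration cannot be constructed."""


def random_walk_in_sphere(n: int, radius: float, rng: np.random.Generator,
                          bond: float = 1.0,
                          max_tries: int = 200) -> np.ndarray:
    """Fixed-bond random walk of ``n`` beads inside a sphere of ``radius``.

    Nonbonded overlaps are allowed; only the wall constraint is enforced.
    """
    if radius <= bond:
        raise PackingError(f"radius {radius} too small for bond {bond}")
    for _ in range(8):
        pos, ok = _kernels.grow_walk_in_sphere(n, bond, radius, rng, max_tries)
        if ok:
            return pos
    raise PackingError(f"failed to grow a {n}-bead walk in radius {radius}")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        u = 2.0 * rng.random(3) - 1.0
        s = u @ u
        if 1e-12 < s <= 1.0:
            return u / np.sqrt(s)


def _dimerize(n: int, bond: float, rmin: float,
              rng: np.random.Generator, budget: list) -> np.ndarray:
    if n == 1:
        return np.zeros((1, 3))
    if n == 2:
        return np.vstack([np.zeros(3), bond * _random_unit(rng)])
    nh = n // 2
    while True:
        if budget[0] <= 0:
            raise PackingError(f"dimerization budget exhausted at n={n}")
        budget[0] -= 1
        a = _dimerize(nh, bond, rmin, rng, budget)
        b = _dimerize(n - nh, bond, rmin, rng, budget)
        shifted = b + (a[-1] + bond * _random_unit(rng))
        if not _kernels.has_overlap(a, shifted, rmin):
            return np.vstack([a, shifted])


def sample_saw(n: int, rng: np.random.Generator, bond: float = 1.0,
               rmin: float = SAW_EXCLUSION,
               max_attempts: int = 2_000_000) -> np.ndarray:
    """Sample one n-bead self-avoiding configuration by dimerization.

    Every pair of beads separated by two or more bonds is at least ``rmin``
    apart; bonds have length ``bond`` exactly.  On rejection both
    half-chains are regenerated, which keeps the sampling exact.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    budget = [max_attempts]
    return _dimerize(n, bond, rmin, rng, budget)
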