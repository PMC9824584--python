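"""Chain-size and shape observables.

Size is tracked through the radius of gyration Rg and the ensemble size
R(t) = <Rg^2(t)>^(1/2) (mean of Rg^2 across replicas, then the square
root).  Shape is read from the gyration tensor: its sorted eigenvalues
lambda1 >= lambda2 >= lambda3 satisfy lambda1+lambda2+lambda3 = Rg^2 at
every instant and define the asphericity A in [0, 1] (0 = sphere, 1 =
rod), the rescaled prolateness P in [-1, 1] (positive = prolate) and the
conventional prolateness Pc in [-1/4, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "SizeCurve",
    "ShapeTrace",
    "EnsembleCurves",
    "radius_of_gyration",
    "gyration_tensor",
    "shape_eigenvalues",
    "asphericity",
    "prolateness",
    "conventional_prolateness",
    "shape_trace_from_tensor_samples",
    "ensemble_mean_size",
    "expansion_velocity",
    "estimate_R0",
    "estimate_RF",
    "PlateauEstimate",
]


@dataclass
class SizeCurve:
    """Rg^2 versus time for a single run."""

    times: np.ndarray
    rg2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.rg2 = np.asarray(self.rg2, dtype=np.float64)
        if self.times.shape != self.rg2.shape:
            raise ValueError("times and rg2 must have equal length")
        if np.any(self.rg2 < 0):
            raise ValueError("Rg^2 must be non-negative")

    @property
    def rg(self) -> np.ndarray:
        return np.sqrt(self.rg2)


@dataclass
class ShapeTrace:
    """Sorted gyration-tensor eigenvalues and shape factors versus time."""

    times: np.ndarray
    eigvals: np.ndarray  # (T, 3) descending
    A: np.ndarray = field(init=False)
    P: np.ndarray = field(init=False)
    Pc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        ev = np.asarray(self.eigvals, dtype=np.float64)
        if ev.ndim != 2 or ev.shape[1] != 3 or ev.shape[0] != len(self.times):
            raise ValueError("eigvals must be (T, 3)")
        if np.any(np.diff(ev, axis=1) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")
        self.eigvals = ev
        l1, l2, l3 = ev[:, 0], ev[:, 1], ev[:, 2]
        self.A = asphericity(l1, l2, l3)
        self.P = prolateness(l1, l2, l3)
        self.Pc = conventional_prolateness(l1, l2, l3)

    @property
    def rg2(self) -> np.ndarray:
        """Trace identity: Rg^2 = lambda1 + lambda2 + lambda3."""
        return self.eigvals.sum(axis=1)


@dataclass
class EnsembleCurves:
    """Replica-averaged size (and optionally shape) on a shared grid."""

    times: np.ndarray
    R: np.ndarray
    stderr: np.ndarray
    n_replicas: int
    mean_eigvals: np.ndarray | None = None  # (T, 3)
    mean_A: np.ndarray | None = None
    mean_P: np.ndarray | None = None
    mean_Pc: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.R < 0) or np.any(self.stderr < 0):
            raise ValueError("R and stderr must be non-negative")


def radius_of_gyration(positions: np.ndarray) -> float:
    """Root-mean-square distance of the beads from their center of mass."""
    pos = np.asarray(positions, dtype=np.float64)
    d = pos - pos.mean(axis=0)
    return float(np.sqrt((d * d).sum() / pos.shape[0]))


def gyration_tensor(positions: np.ndarray) -> np.ndarray:
    """Second-moment tensor G_ab = (1/N) sum_i (r_ia - r_cm,a)(r_ib - r_cm,b)."""
    pos = np.asarray(positions, dtype=np.float64)
    d = pos - pos.mean(axis=0)
    return d.T @ d / pos.shape[0]


def shape_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of a symmetric PSD 3x3 tensor, sorted descending.

    Tiny negative round-off (> -1e-12 relative) is clamped to zero.
    """
    t = np.asarray(tensor, dtype=np.float64)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("input must be a symmetric 3x3 tensor")
    ev = np.linalg.eigvalsh(t)[::-1]
    scale = max(abs(ev[0]), 1.0)
    if ev[-1] < -1e-12 * scale:
        raise ValueError(f"tensor not positive semidefinite: {ev}")
    return np.clip(ev, 0.0, None)


def _eig_moments(l1, l2, l3):
    l1 = np.asarray(l1, dtype=np.float64)
    l2 = np.asarray(l2, dtype=np.float64)
    l3 = np.asarray(l3, dtype=np.float64)
    return l1, l2, l3, l1 + l2 + l3


def asphericity(l1, l2, l3):
    """A = 3(l1^2+l2^2+l3^2) / (2 (l1+l2+l3)^2) - 1/2, in [0, 1]."""
    l1, l2, l3, tr = _eig_moments(l1, l2, l3)
    if np.any(tr <= 0):
        raise ValueError("asphericity undefined for all-zero eigenvalues")
    return (1.5 * (l1 ** 2 + l2 ** 2 + l3 ** 2) / tr ** 2 - 0.5)[()]


def prolateness(l1, l2, l3):
    """Rescaled prolateness P = 27(l1-m)(l2-m)(l3-m)/(2 l1^3), in [-1, 1].

    m is the eigenvalue mean.  P = 1 for a rod, -1 for a disk, 0 for a
    sphere; the sign separates prolate (P > 0) from oblate shapes.
    """
    l1, l2, l3, tr = _eig_moments(l1, l2, l3)
    if np.any(l1 <= 0):
        raise ValueError("prolateness undefined for lambda1 = 0")
    m = tr / 3.0
    return (13.5 * (l1 - m) * (l2 - m) * (l3 - m) / l1 ** 3)[()]


def conventional_prolateness(l1, l2, l3):
    """Pc = (l1-m)(l2-m)(l3-m)/m^3, in [-1/4, 2]."""
    l1, l2, l3, tr = _eig_moments(l1, l2, l3)
    if np.any(tr <= 0):
        raise ValueError("Pc undefined for all-zero eigenvalues")
    m = tr / 3.0
    return ((l1 - m) * (l2 - m) * (l3 - m) / m ** 3)[()]


def shape_trace_from_tensor_samples(times: np.ndarray,
                                    g6: np.ndarray) -> ShapeTrace:
    """Build a ShapeTrace from packed tensor entries.

    ``g6`` columns are [Gxx, Gyy, Gzz, Gxy, Gxz, Gyz] per sample, the
    layout produced by the integration kernel.
    """
    g6 = np.asarray(g6, dtype=np.float64)
    T = g6.shape[0]
    tensors = np.empty((T, 3, 3))
    tensors[:, 0, 0] = g6[:, 0]
    tensors[:, 1, 1] = g6[:, 1]
    tensors[:, 2, 2] = g6[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = g6[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = g6[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = g6[:, 5]
    ev = np.linalg.eigvalsh(tensors)[:, ::-1]
    return ShapeTrace(times=times, eigvals=np.clip(ev, 0.0, None))


def ensemble_mean_size(curves: Sequence[SizeCurve],
                       eigvals: np.ndarray | None = None) -> EnsembleCurves:
    """Average Rg^2 across replicas, then take the square root.

    The standard error of R is propagated from the standard error of the
    Rg^2 mean: SE_R = SE_{Rg^2} / (2 R).  Per-snapshot shape factors are
    averaged as values (A, P, Pc computed per replica and time, then
    averaged), the convention used for averaged shape curves; the mean
    eigenvalues are returned as well so the from-mean-eigenvalue
    convention remains available.
    """
    if len(curves) < 1:
        raise ValueError("need at least one replica")
    times = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(times) or not np.allclose(c.times, times):
            raise ValueError("replicas must share one time grid")
    rg2 = np.array([c.rg2 for c in curves])
    mean = rg2.mean(axis=0)
    n = rg2.shape[0]
    if n > 1:
        se2 = rg2.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        se2 = np.zeros_like(mean)
    R = np.sqrt(mean)
    stderr = np.where(R > 0, se2 / np.maximum(2 * R, 1e-300), 0.0)
    out = EnsembleCurves(times=times, R=R, stderr=stderr, n_replicas=n)
    if eigvals is not None:
        ev = np.asarray(eigvals, dtype=np.float64)
        out.mean_eigvals = ev.mean(axis=0)
        l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
        out.mean_A = asphericity(l1, l2, l3).mean(axis=0)
        out.mean_P = prolateness(l1, l2, l3).mean(axis=0)
        out.mean_Pc = conventional_prolateness(l1, l2, l3).mean(axis=0)
    return out


def expansion_velocity(times: np.ndarray, rg_runs: np.ndarray,
                       zero_initial: bool = True
                       ) -> tuple[np.ndarray, float]:
    """Mean expansion speed VR(t) = <dRg/dt> and its maximum.

    Each run's Rg series is differentiated first with the three-point
    central formula (one-sided at the ends), then the derivatives are
    averaged across runs — the order matters for noisy data only in the
    variance, not the mean, but mirrors how single-trajectory speeds are
    defined.  Requires a uniform time grid.  The initial value is forced
    to zero when ``zero_initial`` (a chain at rest in the cavity has no
    expansion speed; the one-sided stencil would report a spurious one).
    """
    t = np.asarray(times, dtype=np.float64)
    runs = np.atleast_2d(np.asarray(rg_runs, dtype=np.float64))
    if t.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8):
        raise ValueError("expansion_velocity requires a uniform time grid")
    deriv = np.gradient(runs, t, axis=1)
    vr = deriv.mean(axis=0)
    if zero_initial:
        vr[0] = 0.0
    return vr, float(vr.max())


class PlateauEstimate(NamedTuple):
    value: float
    stderr: float
    provisional: bool
    window: tuple[float, float]


def estimate_R0(ens: EnsembleCurves) -> float:
    """Initial ensemble size R(0)."""
    if ens.times[0] != 0.0:
        raise ValueError("curve does not include t=0")
    return float(ens.R[0])


def estimate_RF(ens: EnsembleCurves, tau_c: float | None = None,
                scaled_window: float = 3.0) -> PlateauEstimate:
    """Final (plateau) ensemble size.

    With ``tau_c`` given, RF is the average of R(t) over the fully relaxed
    regime t/tau_c > ``scaled_window``.  Without it, the trailing 20% of
    samples are averaged and a stationarity check (first vs second half of
    the window) marks the estimate provisional when the curve still
    drifts.
    """
    t, R = ens.times, ens.R
    if tau_c is not None:
        mask = t > scaled_window * tau_c
        provisional = mask.sum() < 3
        if mask.sum() == 0:
            mask = t >= t[-1]
            provisional = True
    else:
        mask = t >= t[0] + 0.8 * (t[-1] - t[0])
        if mask.sum() < 2:
            mask = t >= t[-1]
        sel = R[mask]
        half = len(sel) // 2
        provisional = False
        if half >= 1:
            a, b = sel[:half].mean(), sel[half:].mean()
            scatter = sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 \
                else 0.0
            provisional = abs(b - a) > max(4 * scatter, 5e-3 * abs(b))
    sel = R[mask]
    se = sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0
    return PlateauEstimate(float(sel.mean()), float(se), bool(provisional),
                           (float(t[mask][0]), float(t[mask][-1])))
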