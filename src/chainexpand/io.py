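"""File formats: per-run observables, ensemble summaries, XYZ trajectories,
YAML configs and run manifests.

Numeric text is written in full double precision (%.17g) so write/read
round-trips are lossless.  Readers are tolerant: unknown columns are
preserved and ignored; structural problems (missing columns, non-monotone
time) raise with the offending line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .observables import EnsembleCurves, ShapeTrace, SizeCurve

__all__ = [
    "write_size_curve",
    "read_size_curve",
    "write_run_observables",
    "read_run_observables",
    "write_ensemble_summary",
    "read_ensemble_summary",
    "write_xyz",
    "read_xyz",
    "load_config",
    "write_manifest",
    "read_manifest",
    "ParseError",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Raised when an observable file violates the schema."""


def _check_time_column(df: pd.DataFrame, path) -> None:
    if "t" not in df.columns:
        raise ParseError(f"{path}: missing required column 't'")
    t = df["t"].to_numpy()
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        # offending row is bad[0]+1 (0-based); +1 header +1 one-based
        raise ParseError(
            f"{path}: time not strictly increasing at line {bad[0] + 3}")


def _write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_table(path) -> pd.DataFrame:
    try:
        # round_trip parser: exact recovery of %.17g-printed doubles
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as schema error
        raise ParseError(f"{path}: {exc}") from exc


def write_size_curve(curve: SizeCurve, path) -> None:
    _write_table(pd.DataFrame({"t": curve.times, "rg2": curve.rg2}), path)


def read_size_curve(path) -> SizeCurve:
    df = _read_table(path)
    _check_time_column(df, path)
    if "rg2" not in df.columns:
        raise ParseError(f"{path}: missing required column 'rg2'")
    return SizeCurve(df["t"].to_numpy(), df["rg2"].to_numpy())


def write_run_observables(size: SizeCurve, shape: ShapeTrace, path) -> None:
    """One replica's record: columns t, rg2, lambda1..3 (A, P, Pc derived)."""
    df = pd.DataFrame({
        "t": size.times,
        "rg2": size.rg2,
        "lambda1": shape.eigvals[:, 0],
        "lambda2": shape.eigvals[:, 1],
        "lambda3": shape.eigvals[:, 2],
    })
    _write_table(df, path)


def read_run_observables(path) -> tuple[SizeCurve, ShapeTrace]:
    df = _read_table(path)
    _check_time_column(df, path)
    for col in ("rg2", "lambda1", "lambda2", "lambda3"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    t = df["t"].to_numpy()
    size = SizeCurve(t, df["rg2"].to_numpy())
    shape = ShapeTrace(t, df[["lambda1", "lambda2", "lambda3"]].to_numpy())
    return size, shape


def write_ensemble_summary(ens: EnsembleCurves, path,
                           VR: np.ndarray | None = None) -> None:
    data = {"t": ens.times, "R": ens.R, "stderr": ens.stderr}
    if ens.mean_eigvals is not None:
        data |= {"lambda1": ens.mean_eigvals[:, 0],
                 "lambda2": ens.mean_eigvals[:, 1],
                 "lambda3": ens.mean_eigvals[:, 2],
                 "A": ens.mean_A, "P": ens.mean_P, "Pc": ens.mean_Pc}
    if VR is not None:
        data["VR"] = VR
    _write_table(pd.DataFrame(data), path)


def read_ensemble_summary(path) -> EnsembleCurves:
    df = _read_table(path)
    _check_time_column(df, path)
    for col in ("R", "stderr"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    ens = EnsembleCurves(times=df["t"].to_numpy(), R=df["R"].to_numpy(),
                         stderr=df["stderr"].to_numpy(), n_replicas=0)
    if {"lambda1", "lambda2", "lambda3"} <= set(df.columns):
        ens.mean_eigvals = df[["lambda1", "lambda2", "lambda3"]].to_numpy()
    for attr, col in (("mean_A", "A"), ("mean_P", "P"), ("mean_Pc", "Pc")):
        if col in df.columns:
            setattr(ens, attr, df[col].to_numpy())
    return ens


def write_xyz(frames: np.ndarray, times: np.ndarray, path,
              element: str = "M") -> None:
    """Standard XYZ trajectory: count line, comment 't=<time>', coordinates."""
    frames = np.asarray(frames, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must be (n_frames, n_beads, 3)")
    if frames.shape[0] != len(times):
        raise ValueError("one time stamp per frame required")
    if frames.shape[0] == 0:
        import warnings
        warnings.warn("writing an empty XYZ trajectory", stacklevel=2)
    n = frames.shape[1]
    with open(path, "w") as fh:
        for frame, t in zip(frames, times):
            fh.write(f"{n}\n")
            fh.write(f"t={t:.17g}\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an XYZ trajectory back into (frames, times)."""
    frames, times = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nbeads = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        if nbeads is None:
            nbeads = n
        elif n != nbeads:
            raise ParseError(f"{path}: inconsistent bead count at line {i+1}")
        comment = lines[i + 1]
        t = 0.0
        for tok in comment.split():
            if tok.startswith("t="):
                t = float(tok[2:])
        coords = np.array(
            [[float(v) for v in lines[i + 2 + j].split()[1:4]]
             for j in range(n)])
        frames.append(coords)
        times.append(t)
        i += 2 + n
    return np.array(frames), np.array(times)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seeds, files: list) -> None:
    """Run manifest: config echo, per-replica seeds, file checksums."""
    from . import __version__
    manifest = {
        "version": __version__,
        "config": config,
        "seeds": [int(s) for s in np.asarray(seeds).ravel()],
        "files": [{"path": str(Path(f).name), "sha256": _sha256(f)}
                  for f in files],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
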