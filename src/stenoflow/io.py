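"""Deterministic run output: field files, CSV series, manifest, logging.

A saved run directory contains, per snapshot, the velocity fields as
``.npy`` arrays with a JSON metadata sidecar (grid shape, spacings, time,
step index) plus a ``(z, Q, tau)`` CSV of the derived series, and a single
plain-text JSON manifest recording every configuration key, the package
version, a ``deterministic: true`` marker and the SHA-256 content hash of
every file written.  Two runs with identical configurations produce
byte-identical files and therefore identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import StenosisGeometry
from .observables import ObservableSeries, compute_observables
from .solver import FlowState, Grid, RunResult

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_series",
    "write_manifest",
    "save_run",
    "setup_run_logging",
]

logger = logging.getLogger("stenoflow")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_snapshot(
    outdir, state: FlowState, grid: Grid, index: int
) -> list[Path]:
    """Write one snapshot's fields plus its metadata sidecar; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"snapshot_{index:04d}"
    paths = []
    for name, arr in (("u", state.u), ("v", state.v)):
        p = out / f"{stem}_{name}.npy"
        np.save(p, arr)
        paths.append(p)
    meta = {
        "t": state.t,
        "n": state.n,
        "shape": list(state.u.shape),
        "M": grid.M,
        "N": grid.N,
        "domain_length": grid.domain_length,
        "dt": grid.dt,
    }
    meta_path = out / f"{stem}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    paths.append(meta_path)
    return paths


def read_snapshot(outdir, index: int) -> tuple[FlowState, dict]:
    """Read back a snapshot written by :func:`write_snapshot`."""
    out = Path(outdir)
    stem = f"snapshot_{index:04d}"
    meta = json.loads((out / f"{stem}_meta.json").read_text())
    u = np.load(out / f"{stem}_u.npy")
    v = np.load(out / f"{stem}_v.npy")
    return FlowState(u, v, t=meta["t"], n=meta["n"]), meta


def write_series(outdir, obs: ObservableSeries) -> list[Path]:
    """Write per-snapshot (z, Q, tau) CSV files and the psi fields."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, t in enumerate(obs.times):
        frame = pd.DataFrame({"z": obs.z, "Q": obs.Q[k], "tau": obs.tau[k]})
        p = out / f"snapshot_{k:04d}_series.csv"
        frame.to_csv(p, index=False, float_format="%.12g")
        paths.append(p)
        psi_path = out / f"snapshot_{k:04d}_psi.npy"
        np.save(psi_path, obs.psi[k])
        paths.append(psi_path)
    return paths


def write_manifest(outdir, manifest: dict, files: list[Path]) -> Path:
    """Write the run manifest, including content hashes of ``files``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    payload = dict(manifest)
    payload["files"] = {p.name: _sha256(p) for p in sorted(files)}
    path = out / "manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def save_run(result: RunResult, outdir, mu: float = 1.0) -> Path:
    """Persist a full run (fields, series, manifest); returns the manifest path."""
    out = Path(outdir)
    files: list[Path] = []
    for k, snap in enumerate(result.snapshots):
        files += write_snapshot(out, snap, result.grid, k)
    obs = compute_observables(result.snapshots, result.grid, result.geom, mu=mu)
    files += write_series(out, obs)
    manifest = dict(result.manifest)
    manifest.setdefault("deterministic", True)
    manifest.setdefault("n_snapshots", len(result.snapshots))
    path = write_manifest(out, manifest, files)
    logger.info("run saved to %s (%d files)", out, len(files) + 1)
    return path


def setup_run_logging(outdir, level: int = logging.INFO) -> logging.Handler:
    """Attach a file handler writing the run log into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(min(logger.level or level, level))
    return handler
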