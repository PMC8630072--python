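"""Configuration handling and file writers/readers.

All outputs are plain text: trajectories and count series as CSV with a
commented header embedding the full parameter set, grids as long-format CSV,
lattice snapshots as plain (P2) PGM images with the fixed profile colour map
C1 = 0, D1 = 1, C2 = 2, D2 = 3, and metadata as JSON sidecars.  Every output
records the complete parameter set and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .analysis import PhaseGrid
from .lattice import LatticeTrajectory, SnapshotFrame
from .model import ConfigurationError, ModelParams, PROFILES
from .replicator import NAMED_INITIAL_CONDITIONS, Trajectory
from .wellmixed import AbmTrajectory

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "write_counts",
    "write_phase_grid",
    "write_snapshot_pgm",
    "write_metadata",
]

MODES = ("replicator", "abm", "lattice", "scan", "thresholds", "bistability")

_LATTICE_INITS = ("all_defect_random_institution", "random_uniform")


@dataclass
class RunConfig:
    """Fully validated description of one run (any mode)."""

    mode: str = "replicator"
    params: ModelParams = field(default_factory=ModelParams)
    init: str | None = None  # None resolves to the mode's documented default
    T: int = 9000
    window: int = 2000
    seed: int = 1
    out_dir: str = "."
    snapshot_every: int | None = None  # lattice only
    L: int = 200  # lattice only
    N: int = 10_000  # well-mixed ABM only
    r_axis: list[float] | None = None  # scan / thresholds
    cg_axis: list[float] | None = None  # scan
    r: float | None = None  # bistability
    cg: float | None = None  # bistability

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.T < 0:
            raise ConfigurationError("T must be >= 0")
        if not (0 < self.window <= self.T + 1):
            raise ConfigurationError("window must be positive and at most T + 1")
        if self.mode == "lattice":
            if self.init is None:
                self.init = "all_defect_random_institution"
            if not (self.init in _LATTICE_INITS or self.init.startswith("monomorphic:")):
                raise ConfigurationError(f"unknown lattice initial condition {self.init!r}")
        else:
            if self.init is None:
                self.init = "uniform"
            if self.init not in NAMED_INITIAL_CONDITIONS:
                raise ConfigurationError(f"unknown initial condition {self.init!r}")
        if self.mode == "abm" and self.N % self.params.g != 0:
            raise ConfigurationError("N must be divisible by the group size g")
        if self.mode == "bistability" and (self.r is None or self.cg is None):
            raise ConfigurationError("bistability mode requires r and cg")
        if self.mode in ("scan", "thresholds") and self.r_axis is None:
            raise ConfigurationError(f"{self.mode} mode requires r_axis")
        if self.mode == "scan" and self.cg_axis is None:
            raise ConfigurationError("scan mode requires cg_axis")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "params" in d and not isinstance(d["params"], ModelParams):
            d["params"] = ModelParams.from_dict(d["params"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration (fail-closed)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return RunConfig.from_dict(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _params_comment(params: ModelParams, extra: dict | None = None) -> str:
    meta = {"params": params.to_dict()}
    if extra:
        meta.update(extra)
    return "# instpgg " + json.dumps(meta, sort_keys=True) + "\n"


def write_metadata(path: str | Path, params: ModelParams, **extra) -> None:
    """JSON sidecar with full provenance (params, seed, version, timing)."""
    meta = {"params": params.to_dict(), "version": _pkg_version, **extra}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


def write_trajectory(traj: Trajectory, path: str | Path, seed: int | None = None) -> None:
    """Replicator trajectory CSV: step, frequencies, total payoffs.

    Columns follow the fixed profile order (C1, D1, C2, D2); a commented
    header embeds the parameter set and a JSON sidecar carries metadata.
    """
    path = Path(path)
    cols = {"step": traj.times}
    for i, name in enumerate(PROFILES):
        cols[f"rho_{name}"] = traj.freqs[:, i]
    for i, name in enumerate(PROFILES):
        cols[f"pi_{name}"] = traj.payoffs_total[:, i]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(_params_comment(traj.params, {"initial": traj.initial_label}))
        df.to_csv(fh, index=False)
    write_metadata(
        path.with_suffix(".meta.json"),
        traj.params,
        initial=traj.initial_label,
        T=int(traj.times[-1]),
        seed=seed,
    )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.startswith("# instpgg "):
        raise ValueError(f"{path} is not an instpgg trajectory file")
    meta = json.loads(header[len("# instpgg "):])
    params = ModelParams.from_dict(meta["params"])
    df = pd.read_csv(path, comment="#")
    freqs = df[[f"rho_{n}" for n in PROFILES]].to_numpy()
    totals = df[[f"pi_{n}" for n in PROFILES]].to_numpy()
    return Trajectory(
        times=df["step"].to_numpy(),
        freqs=freqs,
        payoffs_total=totals,
        payoffs_game=totals - params.pi0,
        params=params,
        initial_label=meta.get("initial", "custom"),
    )


def write_counts(
    traj: AbmTrajectory | LatticeTrajectory, path: str | Path, seed: int | None = None
) -> None:
    """Per-step profile counts (and mean payoffs for the well-mixed ABM)."""
    path = Path(path)
    cols = {"step": traj.times}
    for i, name in enumerate(PROFILES):
        cols[f"n_{name}"] = traj.counts[:, i]
    if isinstance(traj, AbmTrajectory):
        for i, name in enumerate(PROFILES):
            cols[f"pi_{name}"] = traj.mean_payoffs[:, i]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(_params_comment(traj.params, {"seed": traj.rng_seed if seed is None else seed}))
        df.to_csv(fh, index=False)
    write_metadata(path.with_suffix(".meta.json"), traj.params, seed=traj.rng_seed if seed is None else seed)


def write_phase_grid(grid: PhaseGrid, path: str | Path, params: ModelParams, **meta) -> None:
    """Long-format CSV: one row per (r, cg) cell with label and diagnostics."""
    path = Path(path)
    rows = []
    for i, r in enumerate(grid.r_values):
        for j, cg in enumerate(grid.cg_values):
            row = {
                "r": r,
                "cg": cg,
                "label": grid.labels[i, j],
                "rho_C": grid.rho_C[i, j],
                "gamma": grid.gamma[i, j],
            }
            for k, name in enumerate(PROFILES):
                row[f"mean_{name}"] = grid.mean_freqs[i, j, k]
            for k, name in enumerate(PROFILES):
                row[f"amp_{name}"] = grid.amplitudes[i, j, k]
            rows.append(row)
    df = pd.DataFrame(rows)
    with path.open("w") as fh:
        fh.write(_params_comment(params, meta))
        df.to_csv(fh, index=False)
    write_metadata(path.with_suffix(".meta.json"), params, **meta)


def write_snapshot_pgm(frame: SnapshotFrame, path: str | Path) -> None:
    """Plain (P2) PGM image of a lattice snapshot.

    Pixel values are the profile indices (C1 = 0, D1 = 1, C2 = 2, D2 = 3).
    """
    path = Path(path)
    cells = frame.cells
    lines = [
        "P2",
        f"# instpgg lattice snapshot, step {frame.step}; values: " + ", ".join(
            f"{v}={name}" for v, name in enumerate(PROFILES)
        ),
        f"{cells.shape[1]} {cells.shape[0]}",
        "3",
    ]
    lines += [" ".join(str(v) for v in row) for row in cells]
    path.write_text("\n".join(lines) + "\n")
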