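"""Trajectory summaries: time averages, the gamma statistic, phase
classification, threshold detection, phase-plane scans and bistability probes.

Phase vocabulary (long-run behaviour of the replicator-mutator map):

* ``DEFECT_FP`` — fixed point where only defectors persist (mostly the free
  institution's defectors, up to mutation load).
* ``RED_QUEEN_ORBIT`` — sustained periodic orbit in which cooperators survive
  only in the costly institution and game payoffs oscillate around zero.
* ``BLACK_QUEEN_ORBIT`` — periodic orbit with cooperators of both institution
  preferences, each suppressing defectors of the opposite institution.
* ``COOP_FP`` / ``COSTLY_COOP_FP`` / ``NONCOSTLY_COOP_FP`` /
  ``PARTIAL_COOP_FP`` — non-periodic endpoints, sublabelled by which profiles
  remain present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import C1, C2, D1, D2, ModelParams, N_PROFILES
from .replicator import Trajectory, named_initial_condition, solve_replicator

__all__ = [
    "PhaseThresholds",
    "TimeAverages",
    "PhaseClassification",
    "ThresholdResult",
    "PhaseGrid",
    "BistabilityResult",
    "GammaUndefinedError",
    "time_average",
    "gamma_statistic",
    "time_averaged_gamma",
    "classify_phase",
    "classify_point",
    "detect_threshold",
    "sweep_r",
    "phase_scan",
    "bistability_probe",
    "FIG1_PROTOCOL",
    "SCAN_PROTOCOL",
    "PURE_SELECTION_PROTOCOL",
]


class GammaUndefinedError(ValueError):
    """gamma is undefined when an institution has zero occupancy."""


@dataclass(frozen=True)
class PhaseThresholds:
    """Classification thresholds.

    ``amp_tol``: a trajectory counts as periodic when some profile's
    frequency fluctuation amplitude over the trailing window exceeds this
    (default 1e-3, well above rounding noise and below orbit amplitudes).
    ``presence_tol``: a profile counts as present when its time-averaged
    frequency exceeds this (default 0.05, far above the mutation load at
    nu = 1e-3).
    """

    amp_tol: float = 1e-3
    presence_tol: float = 0.05


@dataclass(frozen=True)
class Protocol:
    """Solver protocol: horizon and trailing averaging window."""

    T: int = 9000
    window: int = 2000
    initial: str = "uniform"
    thresholds: PhaseThresholds = field(default_factory=PhaseThresholds)


FIG1_PROTOCOL = Protocol(T=9000, window=2000)
SCAN_PROTOCOL = Protocol(T=8000, window=2000)
PURE_SELECTION_PROTOCOL = Protocol(T=200_000, window=150_000)


@dataclass
class TimeAverages:
    """Trailing-window summary of a trajectory (fixed profile order)."""

    mean_freqs: np.ndarray
    mean_game_payoffs: np.ndarray
    amplitudes: np.ndarray  # (max - min) / 2 of each frequency series
    window: int


@dataclass
class PhaseClassification:
    label: str
    mean_freqs: np.ndarray
    mean_game_payoffs: np.ndarray
    amplitudes: np.ndarray
    gamma: float


@dataclass
class ThresholdResult:
    criterion: str
    found: bool
    r: float | None
    bracket: tuple[float, float] | None


@dataclass
class PhaseGrid:
    """Rectangular scan of the (r, cg) plane; arrays indexed [i_r, i_cg]."""

    r_values: np.ndarray
    cg_values: np.ndarray
    labels: np.ndarray  # dtype=object, phase label strings
    rho_C: np.ndarray  # time-averaged total cooperator frequency
    gamma: np.ndarray
    mean_freqs: np.ndarray  # (n_r, n_cg, 4)
    amplitudes: np.ndarray  # (n_r, n_cg, 4)


@dataclass
class BistabilityResult:
    lower_branch: PhaseClassification  # from the most facilitative start
    upper_branch: PhaseClassification  # from the worst-case start
    bistable: bool


def time_average(traj: Trajectory, window: int) -> TimeAverages:
    """Means and fluctuation amplitudes over the trailing ``window`` entries.

    The amplitude of a series is (max - min) / 2 over the window.
    """
    if window <= 0:
        raise ValueError("window must be a positive number of steps")
    if window > len(traj):
        raise ValueError(f"window {window} exceeds trajectory length {len(traj)}")
    f = traj.freqs[-window:]
    g = traj.payoffs_game[-window:]
    return TimeAverages(
        mean_freqs=f.mean(axis=0),
        mean_game_payoffs=g.mean(axis=0),
        amplitudes=(f.max(axis=0) - f.min(axis=0)) / 2.0,
        window=window,
    )


def gamma_statistic(rho: np.ndarray) -> float:
    """Cooperator enrichment of the costly institution.

    gamma = rho_C1 / (rho_C1 + rho_D1) - rho_C2 / (rho_C2 + rho_D2): the
    difference between the within-institution cooperator fractions.  Positive
    values mean an individual met in the costly institution is more likely to
    be a cooperator than one met in the free institution.
    """
    rho = np.asarray(rho, dtype=float)
    occ1 = rho[C1] + rho[D1]
    occ2 = rho[C2] + rho[D2]
    if occ1 <= 0.0 or occ2 <= 0.0:
        raise GammaUndefinedError(
            f"gamma undefined: institution occupancies ({occ1}, {occ2}) must both be positive"
        )
    return rho[C1] / occ1 - rho[C2] / occ2


def time_averaged_gamma(traj: Trajectory, window: int) -> float:
    """Per-step gamma averaged over the trailing window."""
    if window <= 0 or window > len(traj):
        raise ValueError("window must be positive and no longer than the trajectory")
    f = traj.freqs[-window:]
    occ1 = f[:, C1] + f[:, D1]
    occ2 = f[:, C2] + f[:, D2]
    if np.any(occ1 <= 0.0) or np.any(occ2 <= 0.0):
        raise GammaUndefinedError("gamma undefined at some step: empty institution")
    return float((f[:, C1] / occ1 - f[:, C2] / occ2).mean())


def classify_phase(
    traj: Trajectory,
    window: int | None = None,
    thresholds: PhaseThresholds = PhaseThresholds(),
) -> PhaseClassification:
    """Label the long-run regime of a trajectory.

    The trajectory is periodic when some profile's frequency amplitude over
    the trailing window exceeds ``amp_tol``; a profile is present when its
    time-averaged frequency exceeds ``presence_tol``.  Periodic trajectories
    with costly cooperators present are red-queen orbits (free cooperators
    absent) or black-queen orbits (both cooperator types present); everything
    else is a fixed point sublabelled by the profiles present.
    """
    if window is None:
        window = min(2000, len(traj))
    ta = time_average(traj, window)
    try:
        gamma = time_averaged_gamma(traj, window)
    except GammaUndefinedError:
        gamma = np.nan
    present = ta.mean_freqs > thresholds.presence_tol
    periodic = bool(ta.amplitudes.max() > thresholds.amp_tol)
    c1, c2 = present[C1], present[C2]
    defectors = present[D1] or present[D2]
    if periodic and c1:
        label = "BLACK_QUEEN_ORBIT" if c2 else "RED_QUEEN_ORBIT"
    elif not (c1 or c2):
        label = "DEFECT_FP"
    elif c1 and c2:
        label = "COOP_FP"
    elif defectors:
        label = "PARTIAL_COOP_FP"
    else:
        label = "COSTLY_COOP_FP" if c1 else "NONCOSTLY_COOP_FP"
    return PhaseClassification(
        label=label,
        mean_freqs=ta.mean_freqs,
        mean_game_payoffs=ta.mean_game_payoffs,
        amplitudes=ta.amplitudes,
        gamma=gamma,
    )


def classify_point(
    params: ModelParams, protocol: Protocol = FIG1_PROTOCOL
) -> PhaseClassification:
    """Solve the replicator map at one parameter point and classify it."""
    traj = solve_replicator(
        named_initial_condition(protocol.initial),
        params,
        protocol.T,
        initial_label=protocol.initial,
    )
    return classify_phase(traj, protocol.window, protocol.thresholds)


_CRITERION_PROFILE = {"costly_coop_onset": C1, "free_coop_onset": C2}


def sweep_r(
    params_base: ModelParams,
    r_grid: np.ndarray,
    protocol: Protocol = FIG1_PROTOCOL,
) -> np.ndarray:
    """Time-averaged frequencies (len(r_grid), 4) along an r scan.

    Both institutions' enhancement factors are set to each grid value
    (the r1 = r2 = r setting); each point is solved from the protocol's
    initial condition.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be sorted strictly ascending")
    means = np.empty((r_grid.size, N_PROFILES))
    init = named_initial_condition(protocol.initial)
    for i, r in enumerate(r_grid):
        p = replace(params_base, r1=float(r), r2=float(r))
        traj = solve_replicator(init, p, protocol.T, initial_label=protocol.initial)
        means[i] = time_average(traj, protocol.window).mean_freqs
    return means


def detect_threshold(
    params_base: ModelParams,
    r_grid: np.ndarray,
    criterion: str,
    protocol: Protocol = FIG1_PROTOCOL,
    sweep_means: np.ndarray | None = None,
) -> ThresholdResult:
    """Smallest grid r at which the criterion profile becomes present.

    ``criterion`` is ``costly_coop_onset`` (time-averaged C1 frequency
    exceeds the presence threshold) or ``free_coop_onset`` (same for C2).  A
    precomputed :func:`sweep_r` result may be passed to share one scan
    between several criteria.
    """
    if criterion not in _CRITERION_PROFILE:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of {sorted(_CRITERION_PROFILE)}"
        )
    r_grid = np.asarray(r_grid, dtype=float)
    if sweep_means is None:
        sweep_means = sweep_r(params_base, r_grid, protocol)
    profile = _CRITERION_PROFILE[criterion]
    hit = sweep_means[:, profile] > protocol.thresholds.presence_tol
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return ThresholdResult(criterion=criterion, found=False, r=None, bracket=None)
    i = int(idx[0])
    lower = float(r_grid[i - 1]) if i > 0 else float(r_grid[0])
    return ThresholdResult(
        criterion=criterion,
        found=True,
        r=float(r_grid[i]),
        bracket=(lower, float(r_grid[i])),
    )


def phase_scan(
    r_axis: np.ndarray,
    cg_axis: np.ndarray,
    params_base: ModelParams,
    protocol: Protocol = SCAN_PROTOCOL,
) -> PhaseGrid:
    """Classify every cell of a rectangular (r, cg) grid.

    Each cell runs the replicator map with r1 = r2 = r and cg1 = cg from the
    protocol's initial condition and classifies the trailing window.
    """
    r_axis = np.asarray(r_axis, dtype=float)
    cg_axis = np.asarray(cg_axis, dtype=float)
    n_r, n_cg = r_axis.size, cg_axis.size
    labels = np.empty((n_r, n_cg), dtype=object)
    rho_c = np.empty((n_r, n_cg))
    gamma = np.empty((n_r, n_cg))
    means = np.empty((n_r, n_cg, N_PROFILES))
    amps = np.empty((n_r, n_cg, N_PROFILES))
    for i, r in enumerate(r_axis):
        for j, cg in enumerate(cg_axis):
            p = replace(params_base, r1=float(r), r2=float(r), cg1=float(cg))
            cls = classify_point(p, protocol)
            labels[i, j] = cls.label
            means[i, j] = cls.mean_freqs
            amps[i, j] = cls.amplitudes
            rho_c[i, j] = cls.mean_freqs[C1] + cls.mean_freqs[C2]
            gamma[i, j] = cls.gamma
    return PhaseGrid(
        r_values=r_axis,
        cg_values=cg_axis,
        labels=labels,
        rho_C=rho_c,
        gamma=gamma,
        mean_freqs=means,
        amplitudes=amps,
    )


def bistability_probe(
    r: float,
    cg: float,
    params_base: ModelParams,
    protocol: Protocol = FIG1_PROTOCOL,
) -> BistabilityResult:
    """Compare the long-run phase from the two extreme initial conditions.

    The lower branch starts from the most facilitative state for cooperation
    (all costly cooperators) and the upper branch from the worst case (all
    defectors split evenly between institutions); the point is bistable when
    the two classifications differ.
    """
    p = replace(params_base, r1=float(r), r2=float(r), cg1=float(cg))
    branches = {}
    for name, label in (("lower", "all_coop_costly"), ("upper", "all_defect_split")):
        traj = solve_replicator(
            named_initial_condition(label), p, protocol.T, initial_label=label
        )
        branches[name] = classify_phase(traj, protocol.window, protocol.thresholds)
    return BistabilityResult(
        lower_branch=branches["lower"],
        upper_branch=branches["upper"],
        bistable=branches["lower"].label != branches["upper"].label,
    )
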