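"""Discrete-time replicator-mutator dynamics on the 4-simplex.

The map advances strategy-profile frequencies one synchronous generation at a
time: frequencies are weighted by reproduction weights (total payoff under
proportional selection, exp(beta * payoff) under exponential selection),
normalised by the population-mean weight, and mixed by the two-trait mutation
kernel:

    rho_x^i(t+1) = sum_{y,j} M[(x,i),(y,j)] rho_y^j(t) w_y^j(t) / <w(t)>

where w is the selection weight and <w> its frequency-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    C1,
    C2,
    D1,
    D2,
    ModelParams,
    N_PROFILES,
    PayoffState,
    expected_payoffs,
    mutation_kernel,
    validate_frequencies,
)

__all__ = [
    "Trajectory",
    "NAMED_INITIAL_CONDITIONS",
    "named_initial_condition",
    "selection_weights",
    "replicator_step",
    "solve_replicator",
]

# Renormalisation policy: rounding drift up to this size is silently fixed ...
RENORM_TOL = 1e-12
# ... while a simplex violation beyond this is treated as a genuine bug.
RENORM_ERROR = 1e-9

NAMED_INITIAL_CONDITIONS = {
    # Equal initial densities of all four profiles.
    "uniform": np.array([0.25, 0.25, 0.25, 0.25]),
    # Most facilitative state for cooperation: everyone a costly cooperator.
    "all_coop_costly": np.array([1.0, 0.0, 0.0, 0.0]),
    # Worst case: all defectors, institutions preferred in equal frequencies.
    "all_defect_split": np.array([0.0, 0.5, 0.0, 0.5]),
}


def named_initial_condition(label: str) -> np.ndarray:
    """Frequency vector for one of the named initial conditions."""
    try:
        return NAMED_INITIAL_CONDITIONS[label].copy()
    except KeyError:
        raise ValueError(
            f"unknown initial condition {label!r}; "
            f"expected one of {sorted(NAMED_INITIAL_CONDITIONS)}"
        ) from None


@dataclass
class Trajectory:
    """Time series of frequencies and expected payoffs.

    All arrays have shape (T + 1, 4) in the fixed (C1, D1, C2, D2) profile
    order; ``payoffs_total[t]`` / ``payoffs_game[t]`` are computed from
    ``freqs[t]`` *before* the update, so payoff series align with frequency
    series.
    """

    times: np.ndarray
    freqs: np.ndarray
    payoffs_total: np.ndarray
    payoffs_game: np.ndarray
    params: ModelParams
    initial_label: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.freqs) == len(self.payoffs_total) == len(self.payoffs_game) == n):
            raise ValueError("times, freqs and payoffs must have equal length")

    def __len__(self) -> int:
        return len(self.times)


def selection_weights(payoffs: PayoffState, params: ModelParams) -> np.ndarray:
    """Reproduction weights from total payoffs under the configured mode."""
    if params.selection_mode == "exponential":
        return np.exp(params.beta * payoffs.total)
    return payoffs.total


def replicator_step(rho: np.ndarray, params: ModelParams) -> np.ndarray:
    """One synchronous generation of the replicator-mutator map."""
    rho = validate_frequencies(rho)
    payoffs = expected_payoffs(rho, params)
    w = selection_weights(payoffs, params)
    mean_w = rho @ w
    if not mean_w > 0.0:
        raise ValueError(
            f"population-mean selection weight is nonpositive ({mean_w}); "
            "proportional selection requires strictly positive payoffs"
        )
    nxt = mutation_kernel(params.nu) @ (rho * w) / mean_w
    drift = abs(nxt.sum() - 1.0)
    if drift > RENORM_ERROR or np.any(nxt < -RENORM_ERROR):
        raise FloatingPointError(
            f"replicator step left the simplex (sum drift {drift:.3e}, min {nxt.min():.3e})"
        )
    if drift > RENORM_TOL or np.any(nxt < 0.0):
        nxt = np.clip(nxt, 0.0, None)
        nxt = nxt / nxt.sum()
    return nxt


def solve_replicator(
    initial: np.ndarray,
    params: ModelParams,
    T: int,
    initial_label: str = "custom",
) -> Trajectory:
    """Iterate the map for ``T`` steps, recording the initial state as step 0.

    Payoffs are recorded for every stored state (pre-update), giving T + 1
    entries in each series.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    rho = validate_frequencies(initial).copy()
    freqs = np.empty((T + 1, N_PROFILES))
    totals = np.empty((T + 1, N_PROFILES))
    kernel = mutation_kernel(params.nu)
    exponential = params.selection_mode == "exponential"
    beta = params.beta
    for t in range(T + 1):
        freqs[t] = rho
        pay = expected_payoffs(rho, params)
        totals[t] = pay.total
        if t == T:
            break
        w = np.exp(beta * pay.total) if exponential else pay.total
        mean_w = rho @ w
        if not mean_w > 0.0:
            raise ValueError("population-mean selection weight is nonpositive")
        rho = kernel @ (rho * w) / mean_w
        drift = abs(rho.sum() - 1.0)
        if drift > RENORM_ERROR or np.any(rho < -RENORM_ERROR):
            raise FloatingPointError(f"simplex violation at step {t} (drift {drift:.3e})")
        if drift > RENORM_TOL or np.any(rho < 0.0):
            rho = np.clip(rho, 0.0, None)
            rho = rho / rho.sum()
    return Trajectory(
        times=np.arange(T + 1),
        freqs=freqs,
        payoffs_total=totals,
        payoffs_game=totals - params.pi0,
        params=params,
        initial_label=initial_label,
    )
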