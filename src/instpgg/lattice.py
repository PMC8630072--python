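"""Structured population on a periodic square lattice.

Individuals occupy an L x L lattice with von Neumann connectivity and periodic
boundaries.  Each site participates in the five overlapping groups centred on
itself and on each of its four neighbours; a group consists of its centre plus
the centre's four neighbours (g = 5).  Within every group, members play the
public goods game of their preferred institution; a site's game payoff is the
average over its five games, with the base payoff added once.

The update is a synchronous death-birth (imitation) process: every site
simultaneously adopts the profile of a member of its extended neighbourhood
(itself plus its four neighbours) chosen with probability proportional to the
member's selection weight (payoff, or exp(beta * payoff) in exponential
mode), after which each trait mutates independently with probability nu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, N_PROFILES

__all__ = [
    "LatticeState",
    "SnapshotFrame",
    "LatticeTrajectory",
    "lattice_initial_condition",
    "lattice_payoffs",
    "imitation_update",
    "run_lattice",
]

# Extended-neighbourhood offsets: self, up, down, left, right.
_OFFSETS = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class LatticeState:
    """L x L array of profile indices with periodic boundaries."""

    cells: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.ndim != 2 or self.cells.shape[0] != self.cells.shape[1]:
            raise ValueError("cells must be a square 2-D array")
        if not (self.cells.min() >= 0 and self.cells.max() < N_PROFILES):
            raise ValueError("profile indices must lie in 0..3")

    @property
    def L(self) -> int:
        return self.cells.shape[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.cells.ravel(), minlength=N_PROFILES)


@dataclass
class SnapshotFrame:
    step: int
    cells: np.ndarray
    counts: np.ndarray


@dataclass
class LatticeTrajectory:
    """Per-step profile counts plus optional lattice snapshots."""

    times: np.ndarray
    counts: np.ndarray
    snapshots: list[SnapshotFrame]
    params: ModelParams
    rng_seed: int | None = None

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)


def lattice_initial_condition(
    L: int, label: str, rng: np.random.Generator | int | None = None
) -> LatticeState:
    """Seeded initial lattice.

    Labels: ``all_defect_random_institution`` (everyone defects, institution
    chosen uniformly at random per site), ``random_uniform`` (each profile
    with probability 1/4), or ``monomorphic:<profile>`` with profile one of
    C1, D1, C2, D2.
    """
    seed = rng if not isinstance(rng, np.random.Generator) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if label == "all_defect_random_institution":
        # D1 = 1 or D2 = 3, institution uniform.
        cells = 1 + 2 * rng.integers(0, 2, size=(L, L))
    elif label == "random_uniform":
        cells = rng.integers(0, N_PROFILES, size=(L, L))
    elif label.startswith("monomorphic:"):
        name = label.split(":", 1)[1]
        from .model import PROFILES

        if name not in PROFILES:
            raise ValueError(f"unknown profile {name!r} in {label!r}")
        cells = np.full((L, L), PROFILES.index(name), dtype=np.int64)
    else:
        raise ValueError(f"unknown lattice initial condition {label!r}")
    return LatticeState(cells, rng_seed=seed)


def _neighbour_sum(a: np.ndarray) -> np.ndarray:
    """Sum of a over the extended (self + von Neumann) neighbourhood."""
    return (
        a
        + np.roll(a, 1, axis=0)
        + np.roll(a, -1, axis=0)
        + np.roll(a, 1, axis=1)
        + np.roll(a, -1, axis=1)
    )


def lattice_payoffs(state: LatticeState, params: ModelParams) -> np.ndarray:
    """Per-site total payoff field.

    Requires g = 5 (a group is a site plus its four von Neumann neighbours).
    The entrance cost and the cooperation cost are charged in each of a
    site's five games and averaged, which is numerically identical to
    charging them once.
    """
    if params.g != 5:
        raise ValueError("the lattice model requires g = 5 (centre + 4 neighbours)")
    cells = state.cells
    coop = (cells & 1) == 0
    inst1 = (cells >> 1) == 0

    # Per-group (centred at each site) institution head counts.
    n1 = _neighbour_sum(inst1.astype(np.int64))
    k1 = _neighbour_sum((coop & inst1).astype(np.int64))
    n2 = 5 - n1
    k2 = _neighbour_sum((coop & ~inst1).astype(np.int64))

    # Pot share a member of each institution would draw from the game
    # centred at each site (sites with no such members never contribute
    # to any member's average, so the guarded divide is inert there).
    share1 = params.c * params.r1 * k1 / np.maximum(n1, 1)
    share2 = params.c * params.r2 * k2 / np.maximum(n2, 1)

    mean_share1 = _neighbour_sum(share1) / 5.0
    mean_share2 = _neighbour_sum(share2) / 5.0

    ecg1, ecg2, epi0 = params.reduced_costs()
    game = np.where(inst1, mean_share1 - ecg1, mean_share2 - ecg2)
    return game - params.c * coop + epi0


def _selection_weights(payoffs: np.ndarray, params: ModelParams) -> np.ndarray:
    if params.selection_mode == "exponential":
        return np.exp(params.beta * (payoffs - payoffs.max()))
    if not np.all(payoffs > 0.0):
        raise ValueError(
            "proportional imitation requires strictly positive payoffs "
            f"(min payoff {payoffs.min()})"
        )
    return payoffs


def imitation_update(
    state: LatticeState,
    payoffs: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    copy: str = "profile",
) -> LatticeState:
    """One synchronous death-birth step.

    Every site picks a model from its extended neighbourhood with probability
    proportional to the model's selection weight and copies it; each trait
    then mutates independently with probability nu.  ``copy`` selects whether
    the full (institution, action) profile is copied (default) or the action
    only, keeping the imitator's institution preference.
    """
    if copy not in ("profile", "action"):
        raise ValueError("copy must be 'profile' or 'action'")
    w = _selection_weights(np.asarray(payoffs, dtype=float), params)
    stacked_w = np.stack([np.roll(w, off, axis=(0, 1)) for off in _OFFSETS])
    stacked_c = np.stack([np.roll(state.cells, off, axis=(0, 1)) for off in _OFFSETS])
    cum = np.cumsum(stacked_w, axis=0)
    total = cum[-1]
    if not np.all(total > 0.0):
        raise ValueError("selection weights failed to normalise (zero total)")
    u = rng.random(state.cells.shape) * total
    choice = (u[None, :, :] < cum).argmax(axis=0)
    models = np.take_along_axis(stacked_c, choice[None, :, :], axis=0)[0]
    if copy == "action":
        new = (state.cells & 2) | (models & 1)
    else:
        new = models.copy()
    if params.nu > 0.0:
        flip_action = rng.random(new.shape) < params.nu
        flip_inst = rng.random(new.shape) < params.nu
        new[flip_action] ^= 1
        new[flip_inst] ^= 2
    return LatticeState(new, rng_seed=state.rng_seed)


def run_lattice(
    initial: LatticeState,
    params: ModelParams,
    T: int,
    rng: np.random.Generator | int | None = None,
    snapshot_every: int | None = None,
    copy: str = "profile",
) -> LatticeTrajectory:
    """Run the lattice model for ``T`` synchronous steps.

    Snapshots (full lattice copies) are stored at step 0 and every
    ``snapshot_every`` steps when requested.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    seed = initial.rng_seed
    if not isinstance(rng, np.random.Generator):
        seed = rng if rng is not None else initial.rng_seed
        rng = np.random.default_rng(seed)
    state = LatticeState(initial.cells.copy(), rng_seed=seed)
    counts = np.empty((T + 1, N_PROFILES), dtype=np.int64)
    snapshots: list[SnapshotFrame] = []
    for t in range(T + 1):
        counts[t] = state.counts()
        if snapshot_every and t % snapshot_every == 0:
            snapshots.append(SnapshotFrame(t, state.cells.copy(), counts[t].copy()))
        if t == T:
            break
        payoffs = lattice_payoffs(state, params)
        state = imitation_update(state, payoffs, params, rng, copy=copy)
    return LatticeTrajectory(
        times=np.arange(T + 1),
        counts=counts,
        snapshots=snapshots,
        params=params,
        rng_seed=seed,
    )
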