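"""Finite well-mixed population: random groups, selection, mutation.

Each generation the population of N individuals is decomposed into N/g groups
uniformly at random.  Within a group, members split by institution preference
and each institution runs one public goods game among its own participants
(entrance cost charged to costly-institution members, base payoff added to
all).  Reproduction is synchronous Wright-Fisher style: every offspring picks
a parent with probability proportional to the parent's selection weight, then
mutates each trait independently with probability nu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import C1, C2, D1, D2, ModelParams, N_PROFILES

__all__ = [
    "Population",
    "AbmTrajectory",
    "population_from_counts",
    "play_round",
    "reproduce",
    "run_abm",
]


@dataclass
class Population:
    """Finite population as an array of profile indices (0..3)."""

    members: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.members.ndim != 1:
            raise ValueError("members must be a 1-D array of profile indices")
        if self.members.size and not (
            self.members.min() >= 0 and self.members.max() < N_PROFILES
        ):
            raise ValueError("profile indices must lie in 0..3")

    @property
    def size(self) -> int:
        return self.members.size

    def counts(self) -> np.ndarray:
        return np.bincount(self.members, minlength=N_PROFILES)


def population_from_counts(counts, rng_seed: int | None = None) -> Population:
    """Deterministic population with exactly the given per-profile counts."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (N_PROFILES,) or np.any(counts < 0):
        raise ValueError("counts must be four nonnegative integers")
    return Population(np.repeat(np.arange(N_PROFILES), counts), rng_seed=rng_seed)


@dataclass
class AbmTrajectory:
    """Per-generation profile counts and mean per-profile payoffs.

    ``counts`` has shape (T + 1, 4); ``mean_payoffs`` is the mean total payoff
    of each profile in the pre-update population of that generation (NaN when
    a profile is absent).  The entry at step T reflects the final population's
    payoffs from one more round of group formation.
    """

    times: np.ndarray
    counts: np.ndarray
    mean_payoffs: np.ndarray
    params: ModelParams
    rng_seed: int | None = None

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)


def _check_divisible(n: int, g: int) -> None:
    if n % g != 0:
        raise ValueError(f"population size {n} must be divisible by group size {g}")


def play_round(pop: Population, params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """One round of random group formation; returns per-individual total payoffs.

    The population is permuted and chunked into N/g disjoint groups.  Within a
    group each institution's participants share their own pot: a member of
    institution i with n_i participants of which k_i cooperate receives
    ``c * r_i * k_i / n_i``, cooperators pay ``c``, institution members pay the
    entrance cost, and pi0 is added to everyone.  Payoffs are returned in the
    original (pre-permutation) member order.
    """
    n = pop.size
    _check_divisible(n, params.g)
    order = rng.permutation(n)
    grouped = pop.members[order].reshape(n // params.g, params.g)

    coop = (grouped & 1) == 0
    inst1 = (grouped >> 1) == 0
    n1 = inst1.sum(axis=1, keepdims=True)
    n2 = params.g - n1
    k1 = (coop & inst1).sum(axis=1, keepdims=True)
    k2 = (coop & ~inst1).sum(axis=1, keepdims=True)

    ecg1, ecg2, epi0 = params.reduced_costs()
    share1 = params.c * params.r1 * k1 / np.maximum(n1, 1)
    share2 = params.c * params.r2 * k2 / np.maximum(n2, 1)
    pay = np.where(inst1, share1 - ecg1, share2 - ecg2)
    pay = pay - params.c * coop + epi0

    out = np.empty(n)
    out[order] = pay.ravel()
    return out


def reproduce(
    pop: Population,
    payoffs: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> Population:
    """Synchronous weight-proportional reproduction followed by mutation."""
    n = pop.size
    payoffs = np.asarray(payoffs, dtype=float)
    if payoffs.shape != (n,):
        raise ValueError("payoffs must be one value per population member")
    if params.selection_mode == "exponential":
        # Subtract the max before exponentiating; the weights are scale-free.
        weights = np.exp(params.beta * (payoffs - payoffs.max()))
    else:
        if not np.all(payoffs > 0.0):
            raise ValueError(
                "proportional selection requires strictly positive payoffs "
                f"(min payoff {payoffs.min()})"
            )
        weights = payoffs
    parents = rng.choice(n, size=n, p=weights / weights.sum())
    offspring = pop.members[parents].copy()
    if params.nu > 0.0:
        flip_action = rng.random(n) < params.nu
        flip_inst = rng.random(n) < params.nu
        offspring[flip_action] ^= 1
        offspring[flip_inst] ^= 2
    return Population(offspring, rng_seed=pop.rng_seed)


def _mean_payoffs_by_profile(members: np.ndarray, payoffs: np.ndarray) -> np.ndarray:
    sums = np.bincount(members, weights=payoffs, minlength=N_PROFILES)
    counts = np.bincount(members, minlength=N_PROFILES)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def run_abm(
    initial: Population,
    params: ModelParams,
    T: int,
    rng: np.random.Generator | int | None = None,
) -> AbmTrajectory:
    """Run the well-mixed agent-based model for ``T`` generations."""
    if T < 0:
        raise ValueError("T must be >= 0")
    seed = initial.rng_seed
    if not isinstance(rng, np.random.Generator):
        seed = rng if rng is not None else initial.rng_seed
        rng = np.random.default_rng(seed)
    pop = Population(initial.members.copy(), rng_seed=seed)
    counts = np.empty((T + 1, N_PROFILES), dtype=np.int64)
    mean_pay = np.empty((T + 1, N_PROFILES))
    for t in range(T + 1):
        counts[t] = pop.counts()
        payoffs = play_round(pop, params, rng)
        mean_pay[t] = _mean_payoffs_by_profile(pop.members, payoffs)
        if t == T:
            break
        pop = reproduce(pop, payoffs, params, rng)
    return AbmTrajectory(
        times=np.arange(T + 1),
        counts=counts,
        mean_payoffs=mean_pay,
        params=params,
        rng_seed=seed,
    )
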