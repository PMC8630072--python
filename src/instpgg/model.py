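"""Core game model: strategy profiles, payoffs, mutation, parameter handling.

A population of individuals repeatedly plays a public goods game (PGG) in
one of two institutions (public resources).  Institution 1 is *costly*: every
member pays an entrance cost ``cg1`` regardless of their action.  Institution
2 charges ``cg2`` (zero by default, the costly-vs-free setup).  Within an
institution, cooperators contribute ``c``, contributions are multiplied by the
institution's enhancement factor ``r_i`` and shared equally among that
institution's participants in the group; defectors contribute nothing but
share the pot.  Everyone additionally receives a base payoff ``pi0`` from
activities unrelated to the game.

An individual's heritable type is a *strategy profile*: the pair
(institution preference, action), giving four types.  The fixed ordering used
for every vector and matrix in this package is::

    index 0: C1  (costly cooperator)
    index 1: D1  (costly defector)
    index 2: C2  (non-costly cooperator)
    index 3: D2  (non-costly defector)

so ``institution = index >> 1`` (0 = costly, 1 = free) and the action is
cooperate when ``index & 1 == 0``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "PROFILES",
    "C1",
    "D1",
    "C2",
    "D2",
    "N_PROFILES",
    "SELECTION_MODES",
    "ConfigurationError",
    "ModelParams",
    "PayoffState",
    "institution_of",
    "is_cooperator",
    "validate_frequencies",
    "group_payoff",
    "expected_payoffs",
    "mutation_kernel",
    "absorb_common_cost",
]

PROFILES = ("C1", "D1", "C2", "D2")
C1, D1, C2, D2 = 0, 1, 2, 3
N_PROFILES = 4

SELECTION_MODES = ("proportional", "exponential")

SIMPLEX_ATOL = 1e-12


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent model parameters."""


def institution_of(profile: int) -> int:
    """Institution index (0 = costly, 1 = free) of a profile index."""
    return profile >> 1


def is_cooperator(profile: int) -> bool:
    """Whether a profile index denotes a cooperator."""
    return (profile & 1) == 0


@dataclass(frozen=True)
class ModelParams:
    """All game and selection constants.

    Parameters
    ----------
    g
        Group size (individuals per group), >= 2.
    r1, r2
        Enhancement factors of institutions 1 (costly) and 2 (free).
    c
        Cooperation contribution cost (payoff units).
    cg1, cg2
        Entrance costs of institutions 1 and 2.  ``cg2 = 0`` gives the
        costly-vs-free setup.
    pi0
        Base payoff added to everyone.  Under payoff-proportional selection
        it must exceed ``c + max(cg1, cg2)`` so that every attainable total
        payoff is strictly positive.
    nu
        Per-trait mutation probability in [0, 1]; institution preference and
        action mutate independently, each flipping with probability ``nu``.
    selection_mode
        ``"proportional"`` (reproduction weight = total payoff) or
        ``"exponential"`` (weight = exp(beta * total payoff)).
    beta
        Selection strength; used only in exponential mode.
    """

    g: int = 5
    r1: float = 1.7
    r2: float = 1.7
    c: float = 1.0
    cg1: float = 0.398
    cg2: float = 0.0
    pi0: float = 2.0
    nu: float = 1e-3
    selection_mode: str = "proportional"
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.g, (int, np.integer)) and self.g >= 2):
            raise ConfigurationError(f"g must be an integer >= 2, got {self.g!r}")
        if not (self.r1 > 0 and self.r2 > 0):
            raise ConfigurationError("enhancement factors r1, r2 must be > 0")
        if not self.c > 0:
            raise ConfigurationError("contribution cost c must be > 0")
        if self.cg1 < 0 or self.cg2 < 0:
            raise ConfigurationError("entrance costs must be >= 0")
        if not (0.0 <= self.nu <= 1.0):
            raise ConfigurationError(f"mutation rate nu must lie in [0, 1], got {self.nu!r}")
        if self.beta < 0:
            raise ConfigurationError("selection strength beta must be >= 0")
        if self.selection_mode not in SELECTION_MODES:
            raise ConfigurationError(
                f"selection_mode must be one of {SELECTION_MODES}, got {self.selection_mode!r}"
            )
        if self.selection_mode == "proportional" and not (
            self.pi0 > self.c + max(self.cg1, self.cg2)
        ):
            raise ConfigurationError(
                "payoff-proportional reproduction requires pi0 > c + max(cg1, cg2) "
                f"(pi0={self.pi0}, c={self.c}, cg1={self.cg1}, cg2={self.cg2}); "
                "every attainable total payoff must be strictly positive"
            )

    # -- derived accessors -------------------------------------------------

    def enhancement(self, inst: int) -> float:
        return self.r1 if inst == 0 else self.r2

    def entrance_cost(self, inst: int) -> float:
        return self.cg1 if inst == 0 else self.cg2

    def reduced_costs(self) -> tuple[float, float, float]:
        """Canonical (cg1, cg2, pi0) with the common entrance cost absorbed.

        Every individual pays at least ``m = min(cg1, cg2)`` regardless of its
        institution choice, so ``m`` acts as a uniform shift that can be folded
        into the base payoff: (cg1 - m, cg2 - m, pi0 - m) yields the same
        payoff for every individual in every group composition.  All payoff
        kernels in this package evaluate on this canonical form, which makes
        parameter sets that are equivalent under the shift produce bitwise
        identical payoffs (and hence identical trajectories).  When
        ``cg2 = 0`` the reduction is the identity.
        """
        m = min(self.cg1, self.cg2)
        return self.cg1 - m, self.cg2 - m, self.pi0 - m

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class PayoffState:
    """Expected payoffs per strategy profile, in the fixed (C1, D1, C2, D2) order.

    ``total`` includes the base payoff pi0; ``game`` = total - pi0 is the
    payoff from the public goods game and entrance cost alone.
    """

    total: np.ndarray
    game: np.ndarray


def validate_frequencies(rho: np.ndarray, atol: float = SIMPLEX_ATOL) -> np.ndarray:
    """Check that ``rho`` is a point on the 4-simplex; return it as float64."""
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (N_PROFILES,):
        raise ValueError(f"frequency vector must have shape (4,), got {rho.shape}")
    if np.any(rho < -atol):
        raise ValueError(f"frequencies must be nonnegative, got {rho}")
    if abs(rho.sum() - 1.0) > max(atol, 1e-12):
        raise ValueError(f"frequencies must sum to 1 (got {rho.sum()!r})")
    return rho


# ---------------------------------------------------------------------------
# Single-group payoff rule
# ---------------------------------------------------------------------------

def group_payoff(nc: int, nd: int, profile: int, params: ModelParams) -> float:
    """Total payoff of a focal individual given its same-institution co-members.

    ``nc`` and ``nd`` count cooperating and defecting *co-members* (the focal
    individual excluded) that share the focal individual's institution; the
    remaining ``g - 1 - nc - nd`` group mates play in the other institution
    and are irrelevant to the focal payoff.

    A cooperator in institution i receives
    ``c * r_i * (1 + nc) / (1 + nc + nd) - c - cg_i + pi0``;
    a defector receives ``c * r_i * nc / (1 + nc + nd) - cg_i + pi0``.
    """
    if nc < 0 or nd < 0 or nc + nd > params.g - 1:
        raise ValueError(
            f"invalid group composition nc={nc}, nd={nd} for g={params.g} "
            "(counts exclude the focal individual and must satisfy nc + nd <= g - 1)"
        )
    if profile not in (C1, D1, C2, D2):
        raise ValueError(f"unknown profile index {profile!r}")
    inst = institution_of(profile)
    ecg1, ecg2, epi0 = params.reduced_costs()
    cg = ecg1 if inst == 0 else ecg2
    r = params.enhancement(inst)
    n_members = 1 + nc + nd
    if is_cooperator(profile):
        share = params.c * r * (1 + nc) / n_members
        return share - params.c - cg + epi0
    share = params.c * r * nc / n_members
    return share - cg + epi0


# ---------------------------------------------------------------------------
# Exact expected payoffs over multinomial group compositions
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _composition_table(g: int):
    """Precomputed enumeration of (nc, nd) co-member compositions for size g.

    Returns arrays over all pairs with nc + nd <= g - 1: the counts, the
    multinomial coefficient (g-1)! / (nc! nd! (g-1-nc-nd)!), the exponent of
    the "other institution" category, and the pot shares per unit c*r for a
    focal cooperator and defector.
    """
    ncs, nds = [], []
    for nc in range(g):
        for nd in range(g - nc):
            ncs.append(nc)
            nds.append(nd)
    ncs = np.array(ncs)
    nds = np.array(nds)
    rest = g - 1 - ncs - nds
    coef = np.array(
        [
            math.factorial(g - 1)
            // (math.factorial(a) * math.factorial(b) * math.factorial(r))
            for a, b, r in zip(ncs, nds, rest)
        ],
        dtype=float,
    )
    coop_frac = (1.0 + ncs) / (1.0 + ncs + nds)
    def_frac = ncs / (1.0 + ncs + nds)
    return ncs, nds, rest, coef, coop_frac, def_frac


def composition_weights(rho_c: float, rho_d: float, g: int) -> np.ndarray:
    """Multinomial probabilities of each (nc, nd) co-member composition.

    The g - 1 co-members of a focal individual are drawn independently from
    the population: same-institution cooperator with probability ``rho_c``,
    same-institution defector with ``rho_d``, other institution otherwise.
    """
    ncs, nds, rest, coef, _, _ = _composition_table(g)
    other = max(1.0 - rho_c - rho_d, 0.0)
    return coef * rho_c**ncs * rho_d**nds * other**rest


def expected_payoffs(rho: np.ndarray, params: ModelParams) -> PayoffState:
    """Exact expected total and game payoffs of the four profiles at ``rho``.

    For each profile the expectation of :func:`group_payoff` is taken over the
    multinomial distribution of the g - 1 co-members, drawn with replacement
    from the population frequencies (infinite-population limit).
    """
    rho = validate_frequencies(rho)
    _, _, _, _, coop_frac, def_frac = _composition_table(params.g)
    ecg1, ecg2, epi0 = params.reduced_costs()
    total = np.empty(N_PROFILES)
    for inst, (i_c, i_d, r, cg) in enumerate(
        ((C1, D1, params.r1, ecg1), (C2, D2, params.r2, ecg2))
    ):
        w = composition_weights(rho[i_c], rho[i_d], params.g)
        total[i_c] = params.c * r * (w @ coop_frac) - params.c - cg + epi0
        total[i_d] = params.c * r * (w @ def_frac) - cg + epi0
    return PayoffState(total=total, game=total - params.pi0)


# ---------------------------------------------------------------------------
# Mutation kernel
# ---------------------------------------------------------------------------

def mutation_kernel(nu: float) -> np.ndarray:
    """Column-stochastic 4x4 mutation matrix M[target, source].

    Institution preference and action mutate independently, each flipping
    with probability ``nu``: the entry is (1 - nu)^2 when both traits are
    preserved, nu (1 - nu) when exactly one flips, and nu^2 when both flip.
    """
    if not (0.0 <= nu <= 1.0):
        raise ConfigurationError(f"mutation rate nu must lie in [0, 1], got {nu!r}")
    a = np.array([[1.0 - nu, nu], [nu, 1.0 - nu]])
    # Profile index = 2 * institution + (0 if C else 1): institution-major,
    # so the kernel factorises as kron(institution flip, action flip).
    return np.kron(a, a)


# ---------------------------------------------------------------------------
# Cost-absorption transform
# ---------------------------------------------------------------------------

def absorb_common_cost(params: ModelParams) -> ModelParams:
    """Fold the entrance cost common to both institutions into the base payoff.

    With two costly institutions (cg1, cg2 > 0) every individual pays at
    least min(cg1, cg2) whatever it chooses, so that amount is a uniform
    payoff shift.  The returned parameter set has the smaller entrance cost
    at zero and the base payoff lowered by the same amount; individual
    payoffs are identical to the original, composition by composition.
    """
    m = min(params.cg1, params.cg2)
    if m == 0.0:
        return params
    try:
        return replace(
            params, cg1=params.cg1 - m, cg2=params.cg2 - m, pi0=params.pi0 - m
        )
    except ConfigurationError as exc:
        raise ConfigurationError(
            "cost absorption drives the base payoff below the positivity "
            f"bound required by proportional selection: {exc}"
        ) from exc
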