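"""Independent reference implementations used as test oracles.

Everything here is written straight from the model definition with naive
loops and shares no code with the package internals, so agreement between the
two routes is a meaningful check.
"""

import math

import numpy as np

from instpgg import ModelParams


def naive_payoff(nc: int, nd: int, coop: bool, r: float, cg: float, params: ModelParams) -> float:
    """Single-composition payoff, written directly from the game rules."""
    if coop:
        return params.c * r * (1 + nc) / (1 + nc + nd) - params.c - cg + params.pi0
    return params.c * r * nc / (1 + nc + nd) - cg + params.pi0


def naive_expected_payoffs(rho, params: ModelParams) -> np.ndarray:
    """Expected total payoffs (C1, D1, C2, D2) via explicit composition loops."""
    g = params.g
    out = np.zeros(4)
    for k, (rc, rd, r, cg, coop) in enumerate(
        [
            (rho[0], rho[1], params.r1, params.cg1, True),
            (rho[0], rho[1], params.r1, params.cg1, False),
            (rho[2], rho[3], params.r2, params.cg2, True),
            (rho[2], rho[3], params.r2, params.cg2, False),
        ]
    ):
        rest = 1.0 - rc - rd
        acc = 0.0
        for nc in range(g):
            for nd in range(g - nc):
                w = (
                    math.factorial(g - 1)
                    / (math.factorial(nc) * math.factorial(nd) * math.factorial(g - 1 - nc - nd))
                    * rc**nc
                    * rd**nd
                    * rest ** (g - 1 - nc - nd)
                )
                acc += w * naive_payoff(nc, nd, coop, r, cg, params)
        out[k] = acc
    return out


def naive_mutation_entry(nu: float, same_inst: bool, same_action: bool) -> float:
    if same_inst and same_action:
        return 1 - 2 * nu + nu**2
    if same_inst != same_action:
        return nu - nu**2
    return nu**2


def naive_replicator_step(rho, params: ModelParams) -> np.ndarray:
    """One generation of the replicator-mutator map via explicit sums."""
    pay = naive_expected_payoffs(rho, params)
    if params.selection_mode == "exponential":
        pay = np.exp(params.beta * pay)
    mean = sum(rho[i] * pay[i] for i in range(4))
    nxt = np.zeros(4)
    for tgt in range(4):
        for src in range(4):
            same_inst = (tgt // 2) == (src // 2)
            same_action = (tgt % 2) == (src % 2)
            nxt[tgt] += (
                naive_mutation_entry(params.nu, same_inst, same_action)
                * rho[src]
                * pay[src]
                / mean
            )
    return nxt


def mc_expected_payoffs(rho, params: ModelParams, rng, n_samples: int):
    """Monte-Carlo group-sampling estimate of the four expected total payoffs.

    For each profile, draws the g - 1 co-members of a focal individual from
    the population frequencies and averages the focal payoff over the sampled
    groups.  Returns (means, standard errors), each length 4.
    """
    means = np.empty(4)
    ses = np.empty(4)
    for k, (rc, rd, r, cg, coop) in enumerate(
        [
            (rho[0], rho[1], params.r1, params.cg1, True),
            (rho[0], rho[1], params.r1, params.cg1, False),
            (rho[2], rho[3], params.r2, params.cg2, True),
            (rho[2], rho[3], params.r2, params.cg2, False),
        ]
    ):
        p = [rc, rd, max(1.0 - rc - rd, 0.0)]
        counts = rng.multinomial(params.g - 1, p, size=n_samples)
        nc, nd = counts[:, 0], counts[:, 1]
        if coop:
            pay = params.c * r * (1 + nc) / (1 + nc + nd) - params.c - cg + params.pi0
        else:
            pay = params.c * r * nc / (1 + nc + nd) - cg + params.pi0
        means[k] = pay.mean()
        ses[k] = pay.std(ddof=1) / math.sqrt(n_samples)
    return means, ses


def naive_lattice_payoffs(cells, params: ModelParams) -> np.ndarray:
    """Per-site payoff field via explicit loops over sites, groups and members."""
    L = cells.shape[0]
    out = np.zeros((L, L))
    offsets = [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)]
    for x in range(L):
        for y in range(L):
            inst = cells[x, y] // 2
            coop = cells[x, y] % 2 == 0
            r = params.r1 if inst == 0 else params.r2
            cg = params.cg1 if inst == 0 else params.cg2
            shares = []
            for cx, cy in offsets:  # the five groups this site belongs to
                centre = ((x + cx) % L, (y + cy) % L)
                members = [
                    cells[(centre[0] + dx) % L, (centre[1] + dy) % L]
                    for dx, dy in offsets
                ]
                n_inst = sum(1 for m in members if m // 2 == inst)
                k_inst = sum(1 for m in members if m // 2 == inst and m % 2 == 0)
                shares.append(params.c * r * k_inst / n_inst)
            game = sum(shares) / 5.0 - (params.c if coop else 0.0) - cg
            out[x, y] = game + params.pi0
    return out
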