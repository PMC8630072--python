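# Methods

## Model

A population plays a public goods game (PGG) in one of two institutions.
Institution 1 charges every participant an entrance cost `cg1` regardless of
action; institution 2 charges `cg2` (0 by default). An individual's heritable
type is the pair (institution preference, action), giving four strategy
profiles ordered `C1, D1, C2, D2` everywhere in the package. In a group of
`g` individuals, the members who prefer institution *i* play one PGG among
themselves: cooperators contribute `c`, the pot is multiplied by `r_i` and
split equally over that institution's participants. A focal individual in
institution *i* whose same-institution co-members comprise `nc` cooperators
and `nd` defectors receives

    cooperator:  c·r_i·(1 + nc)/(1 + nc + nd) − c − cg_i + π0
    defector:    c·r_i·nc/(1 + nc + nd)       − cg_i + π0

where `π0` is a base payoff from unrelated activities. Members of the other
institution in the group are irrelevant to the focal payoff. A lone
institution member still plays: a lone cooperator nets `c(r_i − 1)` from the
game, a lone defector nets 0 (minus the entrance cost in institution 1).

### Infinite well-mixed population (replicator–mutator map)

With groups assembled by sampling with replacement from profile frequencies
`ρ`, the expected payoff of each profile is the exact double sum of the
single-group payoff over the multinomial distribution of the `g − 1`
co-members (categories: same-institution cooperator, same-institution
defector, other institution). Frequencies advance by the synchronous
discrete-time map

    ρ'_x = Σ_y M[x, y] · ρ_y · w_y / ⟨w⟩,

where `w` is the selection weight — the total payoff under proportional
selection, or `exp(β·π)` under exponential selection — and `M` is the
two-trait mutation kernel: institution preference and action each flip
independently with probability `ν`, so `M = A ⊗ A` with
`A = [[1−ν, ν], [ν, 1−ν]]` (diagonal entries `(1−ν)²`, single-flip entries
`ν(1−ν)`, double-flip `ν²`; columns sum to 1).

The finite-`N` hypergeometric correction to group composition is deliberately
not applied here; finite-sampling effects live in the agent-based model.

### Finite well-mixed population (agent-based)

Each generation: permute the `N` individuals (N divisible by `g`), chunk into
`N/g` groups, accrue payoffs by the group rule above, then reproduce
synchronously (Wright–Fisher): every offspring draws a parent with
probability proportional to the parent's selection weight and inherits both
traits, each mutating independently with probability `ν`. Population size is
conserved exactly.

### Structured population (lattice)

Individuals occupy an `L × L` square lattice with von Neumann connectivity
and periodic boundaries; `g = 5` is enforced (a group is a site plus its four
neighbours). Every site belongs to the five groups centred on itself and on
its neighbours; its game payoff is the mean over those five games, with `π0`
added once. The update is a synchronous death–birth (imitation) process:
every site simultaneously adopts the profile of an extended-neighbourhood
member (itself plus its four neighbours) chosen with probability proportional
to the member's selection weight, then mutates each trait with probability
`ν`.

Two readings of "imitation" are possible: copying the action only, or copying
the full (institution, action) profile. Heredity in the well-mixed model
transmits both traits and mutation acts on both, so full-profile copying is
the default; the action-only variant is available through the
`copy="action"` switch of `imitation_update`/`run_lattice`.

The entrance cost is charged inside each of a member's five games and then
averaged, which is numerically identical to charging it once (it appears in
all five games).

## Parameters and defaults

| parameter | meaning | default | units |
|---|---|---|---|
| `g` | group size | 5 | individuals |
| `r1`, `r2` | enhancement factors | 1.7 | dimensionless |
| `c` | contribution cost | 1 | payoff |
| `cg1`, `cg2` | entrance costs | 0.398, 0 | payoff |
| `pi0` | base payoff | 2 | payoff |
| `nu` | per-trait mutation probability | 1e-3 | — |
| `selection_mode` | proportional / exponential | proportional | — |
| `beta` | selection strength (exponential) | 0 (5 for lattice snapshots) | 1/payoff |

These defaults are the standard study conditions used throughout the tests:
`cg = 0.398` puts the first cooperation threshold at `r* = 1 + cg ≈ 1.4`,
`pi0 = 2` keeps every attainable total payoff strictly positive (required by
payoff-proportional reproduction — validated at construction;
exponential mode has no such restriction), and `ν = 1e-3` is small enough
that mutation load (~1e-3) sits far below the presence threshold used in
classification.

Standard protocols: 9000 steps with trailing-2000 averaging from the uniform
initial state for single points and threshold scans; 8000/2000 for
phase-plane scans; 200000/150000 for the pure-selection (`ν = 0`) variant,
whose transients and orbit periods are much longer. Lattice runs use 5000
steps at `L = 200` as the reference protocol; tests use desk-scale versions
(`L = 100`, 2000 steps, trailing 500; `L = 50` for the init-independence
check) — these sizes are the package's own trade-off between statistical
stability and run time, and the scaled-down runs reproduce the same phases.

## Analysis definitions

* **Time averages** are taken over a trailing window; the **amplitude** of a
  series is `(max − min)/2` over that window. Half-range is robust for the
  strongly non-sinusoidal relaxation-type orbits this map produces.
* **γ statistic**: `γ = ρ_C1/(ρ_C1 + ρ_D1) − ρ_C2/(ρ_C2 + ρ_D2)`, the
  cooperator-fraction difference between institutions. It is computed per
  step and then time-averaged (not evaluated at averaged frequencies). It is
  undefined when an institution is empty; that raises an explicit error
  rather than returning 0.
* **Phase classification**: a trajectory is *periodic* when some profile's
  frequency amplitude exceeds `amp_tol` (default 1e-3); a profile is
  *present* when its time-averaged frequency exceeds `presence_tol` (default
  0.05). Periodic with costly cooperators only → red-queen orbit; periodic
  with both cooperator types → black-queen orbit. Non-periodic endpoints are
  sublabelled by the profiles present (defective, cooperative, costly-/
  non-costly-cooperative, or partial when cooperators coexist with a sizable
  defector fraction). Edge case left open by the definitions: a periodic
  trajectory without costly cooperators present falls through to the
  presence-based fixed-point labels; no such regime has been observed in the
  scanned parameter ranges.
* **Thresholds**: the onset of cooperation in an institution is the smallest
  grid `r` at which that institution's cooperator profile becomes present
  under the standard protocol, reported with its bracketing grid interval.
* **Bistability probe**: solve from the most facilitative initial state
  (all costly cooperators) and the worst case (all defectors split evenly
  between institutions); a point is bistable when the two classifications
  differ. On the lattice the corresponding comparison uses independent RNG
  seeds per branch — with a shared seed the two synchronous lattices coalesce
  onto the same configuration and the comparison becomes vacuous.

## Numerical choices

* Fixed profile ordering `(C1, D1, C2, D2)` for every vector, matrix, CSV
  column block and image colour index.
* The replicator step renormalises drift up to 1e-12 defensively; a simplex
  violation beyond 1e-9 raises instead of being silently repaired.
* All payoff kernels first reduce `(cg1, cg2, π0)` to
  `(cg1 − m, cg2 − m, π0 − m)` with `m = min(cg1, cg2)`. The common entrance
  cost is a uniform payoff shift, so real-valued payoffs are unchanged (and
  when `cg2 = 0` the reduction is the identity); the point of the canonical
  form is that parameter sets equivalent under `absorb_common_cost` reach the
  floating-point payoff kernel with bitwise-identical inputs and therefore
  produce bitwise-identical trajectories.
* `absorb_common_cost` subtracts `min(cg1, cg2)` from both costs rather than
  requiring `cg1 ≥ cg2`, keeping institution labels stable.
* Exponential-mode weights subtract the maximum payoff before
  exponentiating in the agent-based simulators (scale-free, avoids overflow
  at large β); the replicator map exponentiates directly since its payoffs
  are O(1).
* Proportional selection requires strictly positive payoffs; `ModelParams`
  enforces `π0 > c + max(cg1, cg2)` at construction in that mode, which
  bounds every attainable payoff away from zero. The positivity margin is
  shift-invariant, so cost absorption cannot invalidate a valid set.

## What the simulators do and do not emulate

The generators cover the model's own universe — there is no external data.
The well-mixed ABM adds demographic noise and within-group sampling without
replacement to the replicator limit; agreement between the two (time averages
within 0.05 at `N = 10^4`) checks the infinite-population derivation, not any
property of empirical populations. The lattice adds spatial correlations and
traveling-wave coexistence. None of the simulators model unequal group
sizes, asynchronous updates, payoff noise, or institutions with differing
group sizes; conclusions from passing tests are claims about this model
class only.

## Known limitations

* Phase boundaries are resolved only to the scan grid; no continuation or
  bifurcation tracing of the critical point where the orbit–orbit transition
  becomes continuous.
* Orbit periodicity is detected by amplitude, not by spectral estimation, so
  a chaotic or quasi-periodic regime would also be labelled "orbit".
* The `ν = 0` protocol needs very long horizons (orbit period and amplitude
  grow as mutation load vanishes); the default scan protocol is unreliable
  there and the long protocol must be requested explicitly.
* Lattice simulations at the reference scale (`L = 200–400`) are supported
  but slow in pure NumPy; the tests run desk-scale versions.
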