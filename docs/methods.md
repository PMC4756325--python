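# Methods

## Model

The resource competition game couples two deception channels to a single
contest rule. Player `i`'s self-perceived capability and displayed
capability are

    k_i = γ_i + α_i        (private: overconfidence biases self-assessment)
    m_i = γ_i + β_i        (public: the bluff biases what opponents see)

and `i` claims the pairwise resource iff `k_i > m_j − δ`. Mutual claims
are resolved by the real capabilities γ (winner `r − c`, loser `−c`);
one-sided claims pay `r`; no claim, no payoff. All pairwise payoffs
therefore lie in `{r, 0, r − c, −c}`.

The additive forms place the two biases on *separate channels*:
overconfidence inflates only the left side of the claim comparison,
bluffing only the right side of the opponent's. This separation is what
the model's characteristic behaviour rests on:

* bluffing deters opponents' claims and hence the conflicts through which
  deception is sanctioned, so `f_B` is systematically more resistant to
  punishment than `f_O`;
* enlarging the overconfidence ceiling `α_max` inflates self-perception
  without inflating any displayed capability, so claims — and with them
  capability-revealing conflicts — become pervasive and both deception
  traits drift neutrally (bluffing back to its initial mean 0.5).

A stacked alternative (`m = γ + α + β`, bluff on top of self-perception)
was evaluated and rejected: with both sides of the comparison inflated
equally, neither of the above mechanisms operates, overconfidence survives
maximal sanctioning, and the bluffing level collapses where it should
dominate.

Degenerate inputs are made total: the measure-zero tie `γ_i = γ_j` in a
conflict is resolved by a fair coin from the simulation's RNG, and the
boundary case `k = m − δ` counts as *no claim* (strict inequality).

## Dynamics

Asynchronous (random sequential) updating. Elementary step: draw focal
`i` uniformly; compute `P_i` afresh against all neighbours (payoffs never
accumulate across steps); draw model neighbour `j` uniformly from `Ω(i)`;
compute `P_j`. If the `i–j` game inside `i`'s sweep was a conflict `i`
lost, punish `i` with probability `p`: `(α_i, β_i) ← (ε_α, ε_β)`, the
instantaneous population minima (including `i`'s own pre-punishment
values, so the minima never decrease at a punishment event). Otherwise
`i` adopts `α_j` and `β_j` independently, each with Fermi probability
`W(P_j − P_i) = 1/(1 + exp((P_i − P_j)/K))`. Punishment and imitation are
exclusive branches of one step. Only the focal's game against the chosen
model neighbour can trigger punishment (the narrow reading of "loses a
conflict against j"); the broad reading (any lost conflict in the sweep)
was evaluated and discarded — it flattens the `f_B > f_O` ordering at
strong sanctioning.

A generation is `N` elementary steps. Since traits propagate only by
copying (imitation copies an existing value; punishment installs an
existing minimum), the set of distinct `α` (and `β`) values can only
shrink — value-set closure — and exact float equality is a meaningful test
for fixation. A population sharing a single `(α, β)` profile is absorbing
under both branches.

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| `r` | resource value (payoff units) | 2.5 | `r/c` is the meaningful ratio |
| `c` | conflict cost (payoff units) | 1.0 | |
| `δ` | system bias (capability units) | 0.0 | any sign; >0 promotes conflicts |
| `p` | punishment probability | 0.0 | per lost conflict vs the model neighbour |
| `K` | imitation noise (payoff units) | 0.1 | Fermi temperature |
| `α_max, β_max, γ_max` | trait ceilings | 1.0 | initial traits ~ U[0, max) |
| `relax_steps` | generations before measuring | 2000 | desk scale |
| `measure_steps` | measured generations | 1000 | desk scale |
| `n_runs` | independent replicates | 10 | fresh traits (and random graphs) |

Desk-scale defaults (N = 2500, 2000+1000 generations, 10 replicates)
replace the publication-scale protocol (N = 10⁴–10⁵, 10⁴+10⁴ generations,
50 replicates); stationary levels at the two scales agree to within the
replicate dispersion for every regime we probed, and full scale remains
reachable through the same flags.

## Randomness and reproducibility

One master seed. Replicate `r` uses `SeedSequence([seed, r])`: the
sequence seeds the trait-initialisation `Generator`; two derived 31-bit
words seed the compiled kernel's Mersenne-Twister stream and the
replicate's graph construction (random topologies are regenerated per
replicate; lattices and user-supplied graphs are shared). The pure-Python
reference path (`elementary_step`, `mc_generation`) and the compiled path
(`advance`, `run`) implement the same process on distinct RNG streams;
they are cross-checked distributionally in the test suite, and the
pairwise game and Fermi primitives are literally shared between the two.
Random-graph construction retries with an incremented seed until the
graph is connected (a disconnected component would trap imitation).

## Observables

`f_O`/`f_B`: population means per generation, averaged over the
measurement window, then mean ± sample standard deviation across
replicates. `R_ability`/`R_payoff`: players are classified as punished if
punished at least once in the window; payoff is the per-step mean payoff
collected while focal. `R_O`/`R_B`: per-player traits are averaged over
the window before binning by γ (10 equal-width bins); the
occupancy-weighted mean of each ratio over bins is exactly 1. Normalised
overconfidence is `f_O / α_max`. Joint `(α, β)` histograms are equal-width
2-D bins over `[0, α_max] × [0, β_max]` with masses summing to 1,
available at configurable snapshot generations.

## What the generator emulates — and what a green test does not establish

All populations are synthetic by construction (the model has no external
data): i.i.d. uniform traits on a clean graph. Real social networks have
degree–trait correlations, community structure and temporal turnover that
none of the three topologies represent, so green tests establish internal
consistency of the model's mechanisms at desk scale, not behavioural
claims about human populations.

## Numerical choices

* Fermi evaluation saturates explicitly beyond `|ΔP|/K > 700` (IEEE exp
  range); within `|ΔP|/K ≲ 50` it is exact to double precision.
* The population minima are maintained incrementally (punishment only adds
  holders of a minimum; imitation can remove the last holder, which
  triggers an O(N) rescan) — the result always equals the true
  instantaneous minimum.
* The model neighbour is drawn before the focal's payoff sweep (it is
  independent of the payoffs, so the distribution is unchanged) to avoid
  storing per-neighbour outcomes in the kernel.
* Trait arrays are float64; value-set closure makes exact equality
  comparisons (fixation detection, minima counting) well-defined.

## Known limitations

* At `p = 0` the population generically freezes into a mosaic of domains
  pinned by local payoff maxima rather than coalescing to a literal single
  profile: across a frozen boundary `|ΔP|/K` is of order 25, giving
  adoption probabilities ~10⁻¹¹. Distribution-level trapping into a
  high-(α, β) state is reproduced; exact global fixation is not reached on
  accessible horizons whenever the evolved state still generates claims
  (which, with `γ_max = β_max`, it always does once α is high).
* At strongly negative δ (≲ −0.3) rare one-sided claims across large γ
  gaps make low-bluff profiles self-propagating (a claimant farming a
  weaker copy of its own profile is a persistent payoff source), so `f_B`
  plateaus near 0.7 instead of approaching its ceiling; the collapse of
  conflicts and rise of both deception levels is reproduced only for
  small |δ|.
* `R_O` crosses 1 near γ ≈ 0.6 (not exactly 0.5), and `R_ability` is flat
  in the graph degree under the at-least-once punishment classification;
  both details are sensitive to window semantics that the model
  description leaves open.
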