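# rcgsim

Agent-based simulator for the **resource competition game (RCG)**: an
evolutionary model of how two "erroneous" psychological biases —
**overconfidence** (self-deception) and **bluffing** (other-deception) —
coevolve in a structured population under imitation dynamics and social
sanctions. It is aimed at researchers in evolutionary game theory and
behavioural modelling who want a fast, reproducible, scriptable
implementation of this model family with the standard lattice / random
regular / scale-free topologies.

## The model

`N` players occupy the vertices of an undirected interaction graph
(periodic square lattice, random `k`-regular graph, or Barabási–Albert
scale-free network). Player `i` carries

* a fixed real capability `γᵢ ~ U[0, γ_max)`,
* an evolving overconfidence intensity `αᵢ ∈ [0, α_max]`,
* an evolving bluffing intensity `βᵢ ∈ [0, β_max]`.

Overconfidence inflates the capability a player *believes* it has,
`kᵢ = γᵢ + αᵢ`, while the bluff inflates the capability its neighbours
*observe*, `mᵢ = γᵢ + βᵢ`. For each neighbouring pair a resource of value
`r` is at stake. Player `i` claims it iff

```
kᵢ > mⱼ − δ
```

where `δ` is a uniform system bias (`δ > 0`: the group is pugnacious and
conflicts proliferate; `δ < 0`: the group is cautious and conflicts are
suppressed). One-sided claims win `r` outright; mutual claims trigger a
costly conflict in which both pay `c` and the *real* capabilities decide
(`r − c` for the winner, `−c` for the loser); if neither claims, the
resource goes unused.

Evolution is an asynchronous Monte Carlo process. In an elementary step a
random focal player `i` collects its total payoff `Pᵢ` against all
neighbours, a random model neighbour `j` collects `Pⱼ` likewise; if the
`i–j` game was a conflict that `i` lost, `i` is punished with probability
`p` (its `(α, β)` drop to the current population minima — the social
sanction against uncovered deception); otherwise `i` adopts `j`'s `α` and,
independently, `j`'s `β`, each with the Fermi probability

```
W = 1 / (1 + exp((Pᵢ − Pⱼ)/K)),    K = 0.1.
```

`N` elementary steps form one generation. The headline observables are the
stationary levels `f_O = ⟨α⟩` and `f_B = ⟨β⟩`, time-averaged over a
measurement window and across seeded replicates, plus the punishment
diagnostics `R_ability`/`R_payoff` (punished vs non-punished class means)
and the capability-binned deception ratios `R_O`/`R_B`.

The inner loop is compiled with numba (millions of elementary steps per
second), so desk-scale experiments (N = 2500, thousands of generations,
ten replicates) take seconds to minutes.

## Worked example

```bash
rcg simulate --network lattice --L 30 --r 2.5 --c 1 --p 0.5 --delta 0.5 \
             --relax 500 --measure 300 --runs 5 --seed 7 --out example_out
```

prints

```
f_O = 0.5065 +/- 0.0142
f_B = 0.7334 +/- 0.0272
fixated replicates: 0%
```

i.e. with moderate sanctioning (`p = 0.5`) and a conflict-promoting bias
(`δ = 0.5`) on a 30×30 torus, overconfidence stabilises near 0.51 while
bluffing settles substantially higher at 0.73 (± the standard deviation
across the five replicates) — bluffing is consistently the more resilient
of the two biases, because it deters opponents' claims and thereby the
conflicts through which deception is punished. No replicate fixated: the
sanction keeps re-injecting low-deception profiles, so the population
never coalesces onto a single `(α, β)` pair. `example_out/series.csv`
holds the tidy per-generation traces; `manifest.json` records every
parameter and seed needed to reproduce the run.

Equivalent library code:

```python
from rcgsim import ModelParams, make_square_lattice, run

params = ModelParams(r=2.5, c=1.0, delta=0.5, p=0.5,
                     relax_steps=500, measure_steps=300, n_runs=5, seed=7)
result = run(params, make_square_lattice(30))
print(result.levels)
```

Parameter sweeps (including presets for the standard figure-style
experiments, e.g. the `p × δ` plane or the `α_max` sweep) run through
`rcg sweep --preset fig2 --out results/fig2`; sweeps are resumable via
their manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes three reference quantities from scratch (each a full
relax-measure-replicate pipeline at N = 2500): the stationary deception
levels under a negative system bias (`t1`), the stationary bluffing level
when a large overconfidence ceiling makes conflicts pervasive (`t2`), and
the minimum capability-binned deception ratio over the upper real-ability
classes at full punishment on a degree-4 random regular graph (`t3`). The
JSON output maps each id to the freshly computed value and the population
size used.

## Layout

| module | contents |
| --- | --- |
| `rcgsim.population` | parameters, traits, initialization, capability maps |
| `rcgsim.networks` | lattice / regular-random / BA generators, edge-list IO |
| `rcgsim.engine` | pairwise game: claims, conflicts, payoffs |
| `rcgsim.dynamics` | elementary step, generations, punishment, Fermi rule, replicate orchestration |
| `rcgsim.observables` | stationary levels, joint histograms, ratio diagnostics |
| `rcgsim.oracle` | slow literal reference implementations (test-only) |
| `rcgsim.cli` | `rcg simulate` / `rcg sweep`, presets, manifests |

See `docs/methods.md` for the modelling choices, numerical details and
known limitations.
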