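"""Asynchronous Monte Carlo dynamics: focal selection, punishment, Fermi
imitation, generation scheduling, fixation detection, and replicate
orchestration.

Two execution paths share the same game and adoption primitives:

* a pure-Python reference path (:func:`elementary_step`,
  :func:`mc_generation`) driven by the population's
  ``numpy.random.Generator`` — transparent, convenient for small systems
  and property tests;
* a compiled fast path (:func:`advance`, :func:`run`) built on
  :mod:`rcgsim._kernel`, with its own seeded stream, used for
  production-size sweeps.

An elementary step: draw a focal player i uniformly; i collects its total
payoff P_i by playing the resource competition with every neighbour; a
model neighbour j is drawn uniformly from i's neighbourhood and collects
P_j the same way.  If the i–j game inside i's payoff collection was a
conflict that i lost, i is punished with probability p — its (alpha, beta)
drop to the instantaneous population minima — and the step ends.
Otherwise i adopts j's alpha and, independently, j's beta, each with the
Fermi probability W(P_j - P_i) = 1/(1 + exp((P_i - P_j)/K)).  Two
independent uniform draws make the two adoptions uncorrelated.  A full
generation is N elementary steps (random sequential update), giving every
player one update chance on average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernel
from .errors import ConfigurationError
from .networks import InteractionGraph
from .observables import ObservableSeries, StationaryLevels, stationary_levels
from .population import (
    ModelParams,
    PopulationState,
    initialize_population,
    population_minima,
)
from .engine import neighborhood_payoff

logger = logging.getLogger(__name__)

__all__ = [
    "StepEvent",
    "RunResult",
    "fermi_probability",
    "punish",
    "imitate_profile",
    "elementary_step",
    "mc_generation",
    "detect_fixation",
    "advance",
    "run",
]


@dataclass(frozen=True)
class StepEvent:
    """Record of one elementary step (reference path)."""

    focal: int
    model_neighbor: int
    punished: bool
    adopted_alpha: bool
    adopted_beta: bool
    payoff_focal: float
    payoff_neighbor: float
    conflict_with_model: bool = False


def fermi_probability(payoff_focal: float, payoff_neighbor: float, K: float) -> float:
    """Adoption probability W = 1 / (1 + exp((P_i - P_j)/K)).

    Overflow-safe; W(0) = 1/2, strictly increasing in P_j - P_i, and
    W(x) + W(-x) = 1.
    """
    if K <= 0:
        raise ConfigurationError(f"K must be > 0, got {K}")
    return float(_kernel.fermi(payoff_focal, payoff_neighbor, K))


def punish(pop: PopulationState, i: int) -> None:
    """Reset player i's deception profile to the instantaneous population
    minima (computed immediately before the reduction, so i's own values
    participate); gamma is untouched."""
    eps_a, eps_b = population_minima(pop)
    pop.alpha[i] = eps_a
    pop.beta[i] = eps_b


def imitate_profile(
    pop: PopulationState,
    i: int,
    j: int,
    W: float,
    rng: np.random.Generator | None = None,
) -> tuple[bool, bool]:
    """Copy j's alpha and beta onto i, each independently with probability W.

    Returns which of the two traits were adopted.
    """
    if rng is None:
        rng = pop.rng
    u1 = rng.random()
    u2 = rng.random()
    adopted_a = u1 < W
    adopted_b = u2 < W
    if adopted_a:
        pop.alpha[i] = pop.alpha[j]
    if adopted_b:
        pop.beta[i] = pop.beta[j]
    return bool(adopted_a), bool(adopted_b)


def elementary_step(
    pop: PopulationState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> StepEvent:
    """One asynchronous update on the reference path (see module docstring)."""
    if rng is None:
        rng = pop.rng
    i = int(rng.integers(pop.n))
    payoff_i, outcomes = neighborhood_payoff(pop, i, params, rng)
    neighbors = pop.graph.neighbors(i)
    j_pos = int(rng.integers(len(neighbors)))
    j = int(neighbors[j_pos])
    payoff_j, _ = neighborhood_payoff(pop, j, params, rng)

    outcome_ij = outcomes[j_pos]
    punished = False
    adopted_a = adopted_b = False
    if (
        outcome_ij.conflict
        and outcome_ij.i_lost_conflict
        and params.p > 0.0
        and rng.random() < params.p
    ):
        punish(pop, i)
        punished = True
    else:
        w = fermi_probability(payoff_i, payoff_j, params.K)
        adopted_a, adopted_b = imitate_profile(pop, i, j, w, rng)
    return StepEvent(
        focal=i,
        model_neighbor=j,
        punished=punished,
        adopted_alpha=adopted_a,
        adopted_beta=adopted_b,
        payoff_focal=payoff_i,
        payoff_neighbor=payoff_j,
        conflict_with_model=outcome_ij.conflict,
    )


def mc_generation(
    pop: PopulationState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> list[StepEvent]:
    """One full Monte Carlo generation: N sequential elementary steps."""
    events = [elementary_step(pop, params, rng) for _ in range(pop.n)]
    pop.time += 1
    return events


def detect_fixation(pop: PopulationState) -> bool:
    """True iff every player carries the same (alpha, beta) profile.

    Exact float equality is meaningful: values propagate only by copying.
    """
    if pop.n <= 1:
        return True
    return bool(
        np.all(pop.alpha == pop.alpha[0]) and np.all(pop.beta == pop.beta[0])
    )


def advance(
    pop: PopulationState,
    params: ModelParams,
    n_generations: int,
    *,
    measure: bool = False,
    check_fixation: bool | None = None,
    kernel_seed: int | None = None,
) -> tuple[ObservableSeries | None, int | None]:
    """Advance the population ``n_generations`` on the compiled fast path.

    Mutates ``pop`` in place.  ``kernel_seed`` (re)seeds the compiled
    stream; omit it to continue the current stream.  ``check_fixation``
    defaults to ``p == 0`` — without punishment a fixated population is
    absorbing and the loop stops early.

    Returns ``(series, fixated_at)``: the measurement record (None unless
    ``measure``) and the absolute generation of fixation (None if not
    detected).
    """
    if check_fixation is None:
        check_fixation = params.p == 0.0
    if kernel_seed is not None:
        _kernel.seed_kernel_rng(int(kernel_seed))
    n = pop.n
    if measure:
        mean_a = np.zeros(n_generations)
        mean_b = np.zeros(n_generations)
        punish_count = np.zeros(n_generations, dtype=np.int64)
        punished = np.zeros(n, dtype=np.bool_)
        payoff_sum = np.zeros(n)
        focal_count = np.zeros(n, dtype=np.int64)
        alpha_accum = np.zeros(n)
        beta_accum = np.zeros(n)
    else:
        mean_a = mean_b = np.empty(0)
        punish_count = np.empty(0, dtype=np.int64)
        punished = np.empty(0, dtype=np.bool_)
        payoff_sum = np.empty(0)
        focal_count = np.empty(0, dtype=np.int64)
        alpha_accum = beta_accum = np.empty(0)

    fix_gen = _kernel.run_phase(
        pop.gamma, pop.alpha, pop.beta,
        pop.graph.indptr, pop.graph.indices,
        float(params.r), float(params.c), float(params.delta),
        float(params.p), float(params.K),
        int(n_generations), bool(measure),
        mean_a, mean_b, punish_count,
        punished, payoff_sum, focal_count,
        alpha_accum, beta_accum, bool(check_fixation),
    )
    fixated_at = None
    if fix_gen >= 0:
        fixated_at = pop.time + int(fix_gen)
        pop.time += int(fix_gen) + 1
    else:
        pop.time += int(n_generations)

    series = None
    if measure:
        series = ObservableSeries(
            mean_alpha=mean_a,
            mean_beta=mean_b,
            punish_count=punish_count,
            punished=punished,
            payoff_sum=payoff_sum,
            focal_count=focal_count,
            player_mean_alpha=alpha_accum / n_generations,
            player_mean_beta=beta_accum / n_generations,
            fixated_at=fixated_at,
        )
    return series, fixated_at


@dataclass
class RunResult:
    """Aggregated outcome of ``n_runs`` independent replicates."""

    params: ModelParams
    replicates: list[ObservableSeries]
    populations: list[PopulationState] = field(repr=False, default_factory=list)
    levels: StationaryLevels | None = None
    fixated_fraction: float = 0.0

    @property
    def f_O(self) -> float:
        return self.levels.f_O

    @property
    def f_B(self) -> float:
        return self.levels.f_B

    @property
    def population(self) -> PopulationState:
        """Final population of the last replicate."""
        return self.populations[-1]


def _replicate_seeds(master_seed: int, n_runs: int) -> list[tuple[np.random.SeedSequence, int, int]]:
    """Derive per-replicate (init seed-sequence, kernel seed, graph seed).

    Each replicate r uses ``SeedSequence([master_seed, r])``: the sequence
    itself seeds the trait-initialisation Generator, and two 31-bit words
    from its state seed the compiled stream and any per-replicate graph.
    """
    out = []
    for rep in range(n_runs):
        ss = np.random.SeedSequence([int(master_seed), rep])
        words = ss.generate_state(3)
        out.append((ss, int(words[1] % (2**31 - 1)), int(words[2] % (2**31 - 1))))
    return out


def run(
    params: ModelParams,
    graph: InteractionGraph | Callable[[int], InteractionGraph],
    *,
    snapshot_gens: Sequence[int] | None = None,
    keep_populations: bool = True,
) -> RunResult:
    """Full experiment: relax, measure, aggregate over replicates.

    Each replicate draws fresh initial traits (and, if ``graph`` is a
    callable ``seed -> InteractionGraph``, a fresh graph) from streams
    derived from ``params.seed``, runs ``relax_steps`` generations, then
    ``measure_steps`` generations while recording observables.  Without
    punishment (p = 0) a replicate stops early at fixation and reports the
    frozen profile.  Stationary levels are averaged over replicates (mean
    and sample standard deviation).

    ``snapshot_gens`` requests copies of the joint (alpha, beta) state at
    the given absolute generations (0 = initial state), stored in each
    series' ``snapshots`` dict.
    """
    snapshot_gens = sorted(set(int(g) for g in snapshot_gens)) if snapshot_gens else []
    replicates: list[ObservableSeries] = []
    populations: list[PopulationState] = []
    n_fixated = 0
    for rep, (ss, kernel_seed, graph_seed) in enumerate(
        _replicate_seeds(params.seed, params.n_runs)
    ):
        g = graph(graph_seed) if callable(graph) else graph
        pop = initialize_population(params, g, rng=np.random.default_rng(ss))
        _kernel.seed_kernel_rng(kernel_seed)

        snapshots = {}
        if snapshot_gens and snapshot_gens[0] == 0:
            snapshots[0] = (pop.alpha.copy(), pop.beta.copy())

        fixated = None
        # Relaxation, split at requested snapshot generations.
        marks = [s for s in snapshot_gens if 0 < s <= params.relax_steps]
        pos = 0
        for mark in marks + [params.relax_steps]:
            span = mark - pos
            if span > 0 and fixated is None:
                _, fixated = advance(pop, params, span, measure=False)
            if mark < params.relax_steps or mark in marks:
                snapshots[mark] = (pop.alpha.copy(), pop.beta.copy())
            pos = mark

        series, fix2 = advance(pop, params, params.measure_steps, measure=True)
        fixated = fixated if fixated is not None else fix2
        series.fixated_at = fixated
        series.snapshots = snapshots
        if fixated is not None:
            n_fixated += 1
            logger.debug("replicate %d fixated at generation %d", rep, fixated)
        replicates.append(series)
        if keep_populations:
            populations.append(pop)
        logger.debug(
            "replicate %d: f_O=%.4f f_B=%.4f",
            rep, series.mean_alpha.mean(), series.mean_beta.mean(),
        )

    levels = stationary_levels(replicates)
    return RunResult(
        params=params,
        replicates=replicates,
        populations=populations,
        levels=levels,
        fixated_fraction=n_fixated / params.n_runs,
    )
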