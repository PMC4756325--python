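"""Player traits, model parameters and population state.

Each of the N agents on the interaction graph carries a fixed real
capability ``gamma`` and an evolving deception profile ``(alpha, beta)``:
``alpha`` is the overconfidence intensity (a self-perception bias) and
``beta`` the bluffing intensity (the bias in the capability an agent
displays to its opponents).  An agent's self-perceived capability is

    k = gamma + alpha

while the capability its neighbours observe is

    m = gamma + beta.

Overconfidence is a private error — it inflates what you believe about
yourself but is invisible to others — whereas bluffing is public: it
inflates only what others see.  Keeping the two biases on separate
channels is what lets them evolve on different trajectories (and is the
reading under which enlarging the overconfidence ceiling floods the
population with conflicts, since self-perception then outruns every
displayed capability).  Both maps are monotone nondecreasing in each
trait, and k >= gamma, m >= gamma always.  Traits are initialised
independently and uniformly on ``[0, trait_max)``; exact collisions
between continuous draws have probability zero and are not treated
specially.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigurationError, StateError
from .networks import InteractionGraph

__all__ = [
    "ModelParams",
    "PlayerState",
    "PopulationState",
    "initialize_population",
    "perceived_capability",
    "displayed_capability",
    "population_minima",
]


@dataclass
class ModelParams:
    """All game, punishment and dynamics constants for one experiment.

    Parameters
    ----------
    r
        Value of the contested resource (payoff units).
    c
        Cost paid by each party to a conflict (payoff units).
    delta
        Uniform system bias shifting both claim thresholds; positive values
        promote conflicts, negative values suppress them.  Any sign.
    p
        Probability that a player who loses a conflict against its model
        neighbour is punished (deception profile reset to the population
        minima).
    K
        Imitation noise of the Fermi rule (payoff units).
    alpha_max, beta_max, gamma_max
        Upper limits of the three traits; initial values are uniform on
        ``[0, max)``.
    relax_steps, measure_steps
        Full Monte Carlo generations run before and during measurement.
    n_runs
        Independent replicates (fresh initial conditions).
    seed
        Master RNG seed; per-replicate streams are derived from it.
    """

    r: float = 2.5
    c: float = 1.0
    delta: float = 0.0
    p: float = 0.0
    K: float = 0.1
    alpha_max: float = 1.0
    beta_max: float = 1.0
    gamma_max: float = 1.0
    relax_steps: int = 2000
    measure_steps: int = 1000
    n_runs: int = 10
    seed: int = 1

    def __post_init__(self):
        if self.r <= 0:
            raise ConfigurationError(f"r must be > 0, got {self.r}")
        if self.c <= 0:
            raise ConfigurationError(f"c must be > 0, got {self.c}")
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(f"p must lie in [0, 1], got {self.p}")
        if self.K <= 0:
            raise ConfigurationError(f"K must be > 0, got {self.K}")
        for name in ("alpha_max", "beta_max", "gamma_max"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("relax_steps", "measure_steps", "n_runs"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        data = json.loads(text)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class PlayerState:
    """One player's fixed real capability and evolving deception profile."""

    gamma: float
    alpha: float
    beta: float


def perceived_capability(player: PlayerState) -> float:
    """Self-perceived capability k = gamma + alpha (overconfidence bias)."""
    return player.gamma + player.alpha


def displayed_capability(player: PlayerState) -> float:
    """Displayed capability m = gamma + beta: the bluff inflates the real
    capability opponents observe; private overconfidence does not show."""
    return player.gamma + player.beta


@dataclass
class PopulationState:
    """Trait arrays plus graph and RNG stream; the object the dynamics mutate.

    ``rng`` drives the pure-Python reference operations; the compiled fast
    path in :mod:`rcgsim.dynamics` uses a separately seeded stream.
    """

    gamma: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    graph: InteractionGraph
    rng: np.random.Generator
    time: int = 0
    params: ModelParams | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.graph.n_vertices
        if not (len(self.gamma) == len(self.alpha) == len(self.beta) == n):
            raise ConfigurationError(
                f"trait arrays of length {len(self.gamma)} do not match graph with {n} vertices"
            )

    @property
    def n(self) -> int:
        return self.graph.n_vertices

    def player(self, i: int) -> PlayerState:
        if not 0 <= i < self.n:
            raise StateError(f"player index {i} out of range for N={self.n}")
        return PlayerState(float(self.gamma[i]), float(self.alpha[i]), float(self.beta[i]))

    def players(self):
        return (self.player(i) for i in range(self.n))

    def copy(self, rng: np.random.Generator | None = None) -> "PopulationState":
        """Deep-copy the trait arrays (graph is shared; it is immutable).

        The RNG stream is not cloned: pass ``rng`` or a fresh default
        generator is attached.
        """
        return PopulationState(
            gamma=self.gamma.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            graph=self.graph,
            rng=rng if rng is not None else np.random.default_rng(),
            time=self.time,
            params=self.params,
        )


def initialize_population(
    params: ModelParams,
    graph: InteractionGraph,
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Draw a fresh population: gamma, alpha, beta i.i.d. uniform on [0, max).

    ``rng`` overrides the stream derived from ``params.seed`` (used by the
    replicate orchestration to hand out independent sub-streams).
    """
    if graph.n_vertices < 1:
        raise ConfigurationError("graph must be non-empty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = graph.n_vertices
    gamma = rng.uniform(0.0, params.gamma_max, n)
    alpha = rng.uniform(0.0, params.alpha_max, n)
    beta = rng.uniform(0.0, params.beta_max, n)
    return PopulationState(gamma=gamma, alpha=alpha, beta=beta, graph=graph, rng=rng, params=params)


def population_minima(pop: PopulationState) -> tuple[float, float]:
    """Current minimum overconfidence and bluffing intensities
    (epsilon_alpha, epsilon_beta) over the whole population."""
    if pop.n == 0:
        raise StateError("population is empty")
    return float(pop.alpha.min()), float(pop.beta.min())
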