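"""Pairwise resource competition: claims, conflict resolution, payoffs.

A resource of value r is available to each pair of neighbours.  Player i
claims it iff its self-perceived capability exceeds the opponent's
displayed capability shifted by the system bias:

    i claims  <=>  k_i > m_j - delta.

One-sided claims win the resource outright (payoff r vs 0); mutual claims
trigger a conflict in which both pay the cost c and the player with the
higher real capability gamma takes the resource (r - c vs -c); if neither
claims the resource stays unused (0, 0).  A gamma tie — probability zero
under continuous initialisation — is resolved by a fair coin so the game
is total.  Every pairwise payoff therefore lies in {r, 0, r - c, -c}.

The branch logic itself lives in the compiled primitive
:func:`rcgsim._kernel.pair_game`, shared with the Monte Carlo kernel so
the two paths cannot diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import pair_game
from .errors import StateError
from .population import ModelParams, PlayerState, PopulationState

__all__ = ["PairOutcome", "claims", "play_pair", "neighborhood_payoff"]


@dataclass(frozen=True)
class PairOutcome:
    """Result of one pairwise game from player i's perspective."""

    i_claims: bool
    j_claims: bool
    conflict: bool
    payoff_i: float
    payoff_j: float
    i_lost_conflict: bool


def claims(i: PlayerState, j: PlayerState, delta: float) -> tuple[bool, bool]:
    """Claim decisions for both players (strict inequalities; the boundary
    case k = m - delta counts as no claim)."""
    k_i = i.gamma + i.alpha
    k_j = j.gamma + j.alpha
    m_i = i.gamma + i.beta
    m_j = j.gamma + j.beta
    return k_i > m_j - delta, k_j > m_i - delta


def play_pair(
    i: PlayerState,
    j: PlayerState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> PairOutcome:
    """Play one resource competition between i and j.

    ``rng`` is consulted only for the measure-zero gamma tie; omit it to
    have ties resolved deterministically in favour of i.
    """
    tie_u = 0.0
    if i.gamma == j.gamma and rng is not None:
        tie_u = float(rng.random())
    payoff_i, payoff_j, i_cl, j_cl, i_lost = pair_game(
        i.gamma, i.alpha, i.beta, j.gamma, j.alpha, j.beta,
        params.r, params.c, params.delta, tie_u,
    )
    return PairOutcome(
        i_claims=bool(i_cl),
        j_claims=bool(j_cl),
        conflict=bool(i_cl and j_cl),
        payoff_i=float(payoff_i),
        payoff_j=float(payoff_j),
        i_lost_conflict=bool(i_lost),
    )


def neighborhood_payoff(
    pop: PopulationState,
    i: int,
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[PairOutcome]]:
    """Total payoff P_i = sum of i's pairwise payoffs against every
    neighbour, recomputed fresh (payoffs never accumulate across steps).

    Returns the total and the per-neighbour outcomes in the order of
    ``pop.graph.neighbors(i)``.  Bounded by -deg(i)*c <= P_i <= deg(i)*r.
    """
    if not 0 <= i < pop.n:
        raise StateError(f"vertex {i} out of range for N={pop.n}")
    if rng is None:
        rng = pop.rng
    player_i = pop.player(i)
    total = 0.0
    outcomes = []
    for j in pop.graph.neighbors(i):
        outcome = play_pair(player_i, pop.player(int(j)), params, rng)
        total += outcome.payoff_i
        outcomes.append(outcome)
    return total, outcomes
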