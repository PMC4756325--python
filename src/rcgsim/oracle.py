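"""Independent brute-force references used only by the test suite.

Deliberately slow and literal: the payoff rule below is transcribed
branch by branch from its prose statement, shares no code with
:mod:`rcgsim.engine`, and is never vectorised, to minimise the chance of
a correlated bug between implementation and check.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

__all__ = ["OracleResult", "naive_pair_payoff", "initial_conflict_probability"]


@dataclass
class OracleResult:
    """One cross-check: an oracle value against the simulator's."""

    quantity: str
    oracle_value: float
    simulator_value: float
    tolerance: float

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def passed(self) -> bool:
        return abs(self.oracle_value - self.simulator_value) <= self.tolerance


def naive_pair_payoff(i, j, params, tie_coin=None):
    """Payoffs (P_ij, P_ji) of one pairwise resource competition.

    ``i`` and ``j`` expose ``gamma``/``alpha``/``beta``; ``params``
    exposes ``r``/``c``/``delta``.  ``tie_coin``: optional callable
    returning True when i should win a real-capability tie (ties have
    probability zero under continuous initialisation; without a coin the
    tie raises).
    """
    # Self-perceived capability: real capability inflated by overconfidence.
    k_i = i.gamma + i.alpha
    k_j = j.gamma + j.alpha
    # Displayed capability: real capability inflated by the public bluff.
    m_i = i.gamma + i.beta
    m_j = j.gamma + j.beta

    # If k_i > m_j - delta and k_j < m_i - delta: only i claims, i takes r.
    if k_i > m_j - params.delta and k_j < m_i - params.delta:
        return params.r, 0.0
    # If k_i < m_j - delta and k_j > m_i - delta: only j claims.
    if k_i < m_j - params.delta and k_j > m_i - params.delta:
        return 0.0, params.r
    # If neither claims, the resource remains unused.
    if k_i < m_j - params.delta and k_j < m_i - params.delta:
        return 0.0, 0.0
    # Both claim: conflict.  Each pays c; the higher real capability wins r.
    if k_i > m_j - params.delta and k_j > m_i - params.delta:
        if i.gamma > j.gamma:
            return params.r - params.c, -params.c
        if i.gamma < j.gamma:
            return -params.c, params.r - params.c
        if tie_coin is None:
            raise ValueError("real-capability tie with no tie_coin supplied")
        if tie_coin():
            return params.r - params.c, -params.c
        return -params.c, params.r - params.c
    # Exact threshold equality (probability zero): strict '>' means no claim.
    i_claims = k_i > m_j - params.delta
    j_claims = k_j > m_i - params.delta
    if i_claims:
        return params.r, 0.0
    if j_claims:
        return 0.0, params.r
    return 0.0, 0.0


def initial_conflict_probability(params, n_samples, seed):
    """Monte-Carlo estimate of P(both claim) for two freshly initialised
    players at the given system bias delta.

    Traits are drawn as at time zero: independently uniform on
    [0, trait_max).  Returns ``(estimate, standard_error)``.  The estimate
    tends to 1 as delta -> +inf and to 0 as delta -> -inf, and is
    nondecreasing in delta (both claim thresholds relax).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = random.Random(seed)
    hits = 0
    for _ in range(n_samples):
        g_i = rng.uniform(0.0, params.gamma_max)
        a_i = rng.uniform(0.0, params.alpha_max)
        b_i = rng.uniform(0.0, params.beta_max)
        g_j = rng.uniform(0.0, params.gamma_max)
        a_j = rng.uniform(0.0, params.alpha_max)
        b_j = rng.uniform(0.0, params.beta_max)
        k_i = g_i + a_i
        k_j = g_j + a_j
        m_i = g_i + b_i
        m_j = g_j + b_j
        if k_i > m_j - params.delta and k_j > m_i - params.delta:
            hits += 1
    estimate = hits / n_samples
    stderr = math.sqrt(max(estimate * (1.0 - estimate), 0.0) / n_samples)
    return estimate, stderr
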