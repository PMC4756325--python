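"""Compiled inner loops of the Monte Carlo dynamics.

Everything here is numba ``@njit`` code operating on flat arrays; the
public modules wrap these primitives in typed, validated interfaces.
The compiled path keeps its own Mersenne-Twister stream (numba's global
``np.random`` state), seeded through :func:`seed_kernel_rng`; it is
deliberately distinct from the ``numpy.random.Generator`` used by the
pure-Python reference operations.
"""

import numpy as np
from numba import njit

__all__ = ["pair_game", "fermi", "seed_kernel_rng", "run_phase"]


@njit(cache=True, inline="always")
def pair_game(gi, ai, bi, gj, aj, bj, r, c, delta, tie_u):
    """One pairwise resource competition between players i and j.

    Claim rule: i claims iff its self-perceived capability k_i = gamma_i +
    alpha_i exceeds the opponent's displayed capability m_j = gamma_j +
    beta_j shifted by the system bias delta.  Mutual claims trigger a
    conflict resolved by the real capabilities; equal gammas (probability
    zero under continuous initialisation) are decided by the pre-drawn
    uniform ``tie_u``.

    Returns ``(payoff_i, payoff_j, i_claims, j_claims, i_lost_conflict)``.
    """
    k_i = gi + ai
    k_j = gj + aj
    m_i = gi + bi
    m_j = gj + bj
    i_claims = k_i > m_j - delta
    j_claims = k_j > m_i - delta
    if i_claims and j_claims:
        if gi > gj:
            return r - c, -c, True, True, False
        elif gj > gi:
            return -c, r - c, True, True, True
        elif tie_u < 0.5:
            return r - c, -c, True, True, False
        else:
            return -c, r - c, True, True, True
    elif i_claims:
        return r, 0.0, True, False, False
    elif j_claims:
        return 0.0, r, False, True, False
    else:
        return 0.0, 0.0, False, False, False


@njit(cache=True, inline="always")
def fermi(payoff_focal, payoff_model, K):
    """Fermi adoption probability W = 1 / (1 + exp((P_i - P_j)/K)).

    Saturates explicitly for |P_i - P_j| / K beyond IEEE exp range.
    """
    x = (payoff_focal - payoff_model) / K
    if x > 700.0:
        return 0.0
    if x < -700.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed the compiled path's global random stream (thread-local MT19937)."""
    np.random.seed(seed)


@njit(cache=True)
def _collect_payoff(idx, track, gamma, alpha, beta, indptr, indices, r, c, delta):
    """Total payoff of ``idx`` against all neighbours.

    Also reports whether the game against neighbour ``track`` (pass -1 to
    disable) was a conflict that ``idx`` lost — the punishment trigger.
    """
    gi = gamma[idx]
    ai = alpha[idx]
    bi = beta[idx]
    total = 0.0
    conflict_t = False
    lost_t = False
    for t in range(indptr[idx], indptr[idx + 1]):
        nb = indices[t]
        tie_u = 0.0
        if gi == gamma[nb]:
            tie_u = np.random.random()
        p_i, _p_j, icl, jcl, lost = pair_game(
            gi, ai, bi, gamma[nb], alpha[nb], beta[nb], r, c, delta, tie_u
        )
        total += p_i
        if nb == track:
            conflict_t = icl and jcl
            lost_t = lost
    return total, conflict_t, lost_t


@njit(cache=True)
def run_phase(
    gamma,
    alpha,
    beta,
    indptr,
    indices,
    r,
    c,
    delta,
    p,
    K,
    n_gens,
    measure,
    mean_a,
    mean_b,
    punish_count,
    punished,
    payoff_sum,
    focal_count,
    alpha_accum,
    beta_accum,
    check_fixation,
):
    """Run ``n_gens`` full Monte Carlo generations in place.

    One generation is N elementary steps (random sequential update).  An
    elementary step: draw a focal player i and a model neighbour j, collect
    both total payoffs afresh, then either punish i (if the i-j game inside
    i's payoff collection was a conflict i lost, with probability p: alpha_i
    and beta_i drop to the instantaneous population minima) or let i adopt
    j's alpha and beta independently, each with the Fermi probability
    W(P_j - P_i).

    When ``measure`` is true the per-generation population means, punishment
    counts, per-player punished flags, focal payoff accumulators and
    per-player trait accumulators are filled in.  When ``check_fixation`` is
    true the loop stops once every player carries the same (alpha, beta)
    profile — an absorbing state — and, if measuring, pads the remaining
    records with the frozen values.

    Returns the generation index at which fixation was detected, or -1.
    """
    n = gamma.shape[0]

    # Instantaneous population minima (epsilon_alpha, epsilon_beta) are
    # maintained incrementally: punishment only adds holders of the minimum,
    # imitation can delete the last holder, in which case we rescan.
    eps_a = alpha[0]
    eps_b = beta[0]
    for q in range(1, n):
        if alpha[q] < eps_a:
            eps_a = alpha[q]
        if beta[q] < eps_b:
            eps_b = beta[q]
    cnt_a = 0
    cnt_b = 0
    for q in range(n):
        if alpha[q] == eps_a:
            cnt_a += 1
        if beta[q] == eps_b:
            cnt_b += 1

    fixated_at = -1
    for g in range(n_gens):
        for _ in range(n):
            i = np.random.randint(0, n)
            s0 = indptr[i]
            deg = indptr[i + 1] - s0
            j = indices[s0 + np.random.randint(0, deg)]
            p_i, conflict_ij, lost_ij = _collect_payoff(
                i, j, gamma, alpha, beta, indptr, indices, r, c, delta
            )
            p_j, _cf, _lo = _collect_payoff(
                j, -1, gamma, alpha, beta, indptr, indices, r, c, delta
            )
            if measure:
                payoff_sum[i] += p_i
                focal_count[i] += 1

            if conflict_ij and lost_ij and p > 0.0 and np.random.random() < p:
                # Punishment: reset to the current minima (which include i's
                # own pre-punishment values, so the minima never decrease).
                if alpha[i] != eps_a:
                    alpha[i] = eps_a
                    cnt_a += 1
                if beta[i] != eps_b:
                    beta[i] = eps_b
                    cnt_b += 1
                if measure:
                    punished[i] = True
                    punish_count[g] += 1
            else:
                w = fermi(p_i, p_j, K)
                # Two independent draws: alpha and beta are imitated
                # independently with the same probability W.
                if np.random.random() < w:
                    old = alpha[i]
                    new = alpha[j]
                    if old != new:
                        if old == eps_a:
                            cnt_a -= 1
                        alpha[i] = new
                        if new == eps_a:
                            cnt_a += 1
                        elif cnt_a == 0:
                            eps_a = alpha[0]
                            for q in range(1, n):
                                if alpha[q] < eps_a:
                                    eps_a = alpha[q]
                            for q in range(n):
                                if alpha[q] == eps_a:
                                    cnt_a += 1
                if np.random.random() < w:
                    old = beta[i]
                    new = beta[j]
                    if old != new:
                        if old == eps_b:
                            cnt_b -= 1
                        beta[i] = new
                        if new == eps_b:
                            cnt_b += 1
                        elif cnt_b == 0:
                            eps_b = beta[0]
                            for q in range(1, n):
                                if beta[q] < eps_b:
                                    eps_b = beta[q]
                            for q in range(n):
                                if beta[q] == eps_b:
                                    cnt_b += 1

        if measure:
            s_a = 0.0
            s_b = 0.0
            for q in range(n):
                s_a += alpha[q]
                s_b += beta[q]
            mean_a[g] = s_a / n
            mean_b[g] = s_b / n
            for q in range(n):
                alpha_accum[q] += alpha[q]
                beta_accum[q] += beta[q]

        if check_fixation:
            a0 = alpha[0]
            b0 = beta[0]
            fixed = True
            for q in range(1, n):
                if alpha[q] != a0 or beta[q] != b0:
                    fixed = False
                    break
            if fixed:
                fixated_at = g
                if measure:
                    for gg in range(g + 1, n_gens):
                        mean_a[gg] = mean_a[g]
                        mean_b[gg] = mean_b[g]
                    remaining = n_gens - 1 - g
                    if remaining > 0:
                        for q in range(n):
                            alpha_accum[q] += alpha[q] * remaining
                            beta_accum[q] += beta[q] * remaining
                break

    return fixated_at
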