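"""Reported statistics: stationary deception levels, joint trait
distributions, and the punishment/capability ratio diagnostics.

The headline observables are the overconfidence level f_O and bluffing
level f_B — population means of alpha and beta averaged over the
measurement window, then over independent replicates (reported with the
replicate standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import StateError, UndefinedRatioError

__all__ = [
    "ObservableSeries",
    "StationaryLevels",
    "stationary_levels",
    "normalized_overconfidence",
    "joint_profile_histogram",
    "punished_ratios",
    "capability_binned_ratios",
]


@dataclass
class ObservableSeries:
    """Per-generation record of one replicate's measurement window.

    ``player_mean_alpha``/``player_mean_beta`` are each player's trait
    averaged over the window (used by the capability-binned ratios);
    ``payoff_sum``/``focal_count`` accumulate the total payoff a player
    collected in the elementary steps where it was the focal player, so
    ``payoff_sum / focal_count`` is its mean per-step payoff.
    """

    mean_alpha: np.ndarray
    mean_beta: np.ndarray
    punish_count: np.ndarray
    punished: np.ndarray
    payoff_sum: np.ndarray
    focal_count: np.ndarray
    player_mean_alpha: np.ndarray
    player_mean_beta: np.ndarray
    fixated_at: int | None = None
    snapshots: dict = field(default_factory=dict)

    @property
    def n_generations(self) -> int:
        return len(self.mean_alpha)

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Tidy per-generation rows (one replicate)."""
        return pd.DataFrame(
            {
                "replicate": replicate,
                "generation": np.arange(self.n_generations),
                "f_O": self.mean_alpha,
                "f_B": self.mean_beta,
                "punishments": self.punish_count,
            }
        )


class StationaryLevels(NamedTuple):
    f_O: float
    f_B: float
    sd_O: float
    sd_B: float


def stationary_levels(series) -> StationaryLevels:
    """Stationary (f_O, f_B) with dispersion.

    For a single :class:`ObservableSeries` the traces of per-generation
    population means are averaged over the window (dispersion = their
    standard deviation in time).  For a sequence of replicates, each
    replicate is first reduced to its window average and the mean and
    sample standard deviation (ddof=1) across replicates are reported.
    """
    if isinstance(series, ObservableSeries):
        if series.n_generations == 0:
            raise StateError("empty measurement window")
        return StationaryLevels(
            float(series.mean_alpha.mean()),
            float(series.mean_beta.mean()),
            float(series.mean_alpha.std()),
            float(series.mean_beta.std()),
        )
    reps: Sequence[ObservableSeries] = list(series)
    if not reps:
        raise StateError("no replicates")
    f_o = np.array([s.mean_alpha.mean() for s in reps])
    f_b = np.array([s.mean_beta.mean() for s in reps])
    ddof = 1 if len(reps) > 1 else 0
    return StationaryLevels(
        float(f_o.mean()), float(f_b.mean()),
        float(f_o.std(ddof=ddof)), float(f_b.std(ddof=ddof)),
    )


def normalized_overconfidence(f_O: float, alpha_max: float) -> float:
    """f_O / alpha_max: dimensionless overconfidence on [0, 1], comparable
    across runs with different trait ceilings."""
    if alpha_max <= 0:
        raise ValueError("alpha_max must be > 0")
    return f_O / alpha_max


def joint_profile_histogram(
    pop_or_alpha,
    beta=None,
    n_bins_alpha: int = 10,
    n_bins_beta: int = 10,
    alpha_max: float = 1.0,
    beta_max: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised 2-D distribution f(alpha, beta) on equal-width bins over
    [0, alpha_max] x [0, beta_max]; masses sum to 1.

    Accepts either a population-like object (attributes ``alpha``/``beta``
    and, when available, ``params`` for the bin ranges) or two arrays.
    Returns ``(hist, alpha_edges, beta_edges)``.
    """
    if beta is None:
        pop = pop_or_alpha
        alpha = np.asarray(pop.alpha)
        beta = np.asarray(pop.beta)
        if getattr(pop, "params", None) is not None:
            alpha_max = pop.params.alpha_max
            beta_max = pop.params.beta_max
    else:
        alpha = np.asarray(pop_or_alpha)
        beta = np.asarray(beta)
    if n_bins_alpha < 1 or n_bins_beta < 1:
        raise ValueError("bin counts must be >= 1")
    hist, a_edges, b_edges = np.histogram2d(
        alpha, beta,
        bins=(n_bins_alpha, n_bins_beta),
        range=((0.0, alpha_max), (0.0, beta_max)),
    )
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, a_edges, b_edges


def punished_ratios(series: ObservableSeries, pop) -> tuple[float, float]:
    """R_ability and R_payoff over one measurement window.

    Players are classified by whether they were punished at least once in
    the window.  R_ability is the mean real capability gamma of the
    punished class divided by that of the non-punished class; R_payoff the
    same ratio of mean per-step payoffs (payoff collected while focal,
    divided by the number of focal steps).
    """
    gamma = np.asarray(pop.gamma if hasattr(pop, "gamma") else pop)
    punished = series.punished.astype(bool)
    n_pun = int(punished.sum())
    n_not = int((~punished).sum())
    if n_pun == 0 or n_not == 0:
        raise UndefinedRatioError(
            f"ratio undefined: {n_pun} punished vs {n_not} non-punished players"
        )
    r_ability = float(gamma[punished].mean() / gamma[~punished].mean())

    with np.errstate(invalid="ignore", divide="ignore"):
        per_step = np.where(series.focal_count > 0, series.payoff_sum, np.nan) / np.where(
            series.focal_count > 0, series.focal_count, 1
        )
    pun_pay = per_step[punished]
    not_pay = per_step[~punished]
    pun_pay = pun_pay[~np.isnan(pun_pay)]
    not_pay = not_pay[~np.isnan(not_pay)]
    if len(pun_pay) == 0 or len(not_pay) == 0:
        raise UndefinedRatioError("a class has no player with focal steps in the window")
    denom = not_pay.mean()
    if denom == 0:
        raise UndefinedRatioError("non-punished class has zero mean payoff")
    r_payoff = float(pun_pay.mean() / denom)
    return r_ability, r_payoff


def capability_binned_ratios(
    gamma,
    alpha,
    beta,
    gamma_max: float = 1.0,
    f_O: float | None = None,
    f_B: float | None = None,
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """R_O and R_B per real-capability subclass.

    [0, gamma_max] is divided into ``n_bins`` equal-width bins; for each
    bin, R_O is the mean alpha of its members divided by the population
    level f_O (by default the mean alpha of the same arrays), likewise R_B
    with beta and f_B.  ``alpha``/``beta`` may be instantaneous values or
    per-player window averages.  Empty bins are reported as NaN.

    Returns ``(R_O, R_B, counts)``.  The occupancy-weighted mean of R_O
    over all bins equals mean(alpha)/f_O exactly (identity used in tests).
    """
    gamma = np.asarray(gamma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if f_O is None:
        f_O = float(alpha.mean())
    if f_B is None:
        f_B = float(beta.mean())
    if f_O <= 0 or f_B <= 0:
        raise UndefinedRatioError("population-level f_O and f_B must be positive")
    edges = np.linspace(0.0, gamma_max, n_bins + 1)
    # np.digitize with right-open bins; clip the (measure-zero) gamma == gamma_max case
    idx = np.clip(np.digitize(gamma, edges) - 1, 0, n_bins - 1)
    r_o = np.full(n_bins, np.nan)
    r_b = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            r_o[b] = alpha[mask].mean() / f_O
            r_b[b] = beta[mask].mean() / f_B
    return r_o, r_b, counts
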