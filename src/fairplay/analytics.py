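"""Closed-form quantities and summary statistics for the model.

Selfish foragers receive the reward R with probability p each step, so
their per-step intake is (up to small Gaussian noise on R) a scaled
Bernoulli variable: expectation pR, variance (1 - p) p R^2.  Fair adults
pool each step's gains and split evenly, so their expectation is also pR
but the within-pool variance of a step's intake is zero.  The functions
here evaluate those quantities, the binomial probability of a selfish
adult re-reaching the reproductive threshold within a delay window, the
delay at which selection for fairness is predicted to peak, and the
estimators used to summarize runs.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "payoff_variance",
    "expected_payoff",
    "cumulative_expected_payoff",
    "prob_reach_threshold",
    "default_required_successes",
    "predicted_peak_delay",
    "gene_birth_frequency",
    "play_mortality_percent",
]


def _check_prob(p: float, name: str = "p") -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p!r}")


def payoff_variance(R: float, p: float) -> float:
    """Per-step intake variance among selfish foragers: (1 - p) p R^2.

    Symmetric under p <-> 1 - p and maximal at p = 0.5 for fixed R; zero
    for the degenerate cases p = 0 and p = 1.
    """
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R!r}")
    _check_prob(p)
    return (1.0 - p) * p * R * R


def expected_payoff(R: float, p: float) -> float:
    """Expected per-step foraging intake pR (same for fair and selfish)."""
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R!r}")
    _check_prob(p)
    return p * R


def cumulative_expected_payoff(d: int, p: float, R: float) -> float:
    """Expected intake accumulated over a reproductive delay of d steps: dpR."""
    if d < 0:
        raise ValueError(f"d must be non-negative, got {d!r}")
    return d * expected_payoff(R, p)


def default_required_successes(P: float, T: float, R: float) -> int:
    """Foraging successes a selfish adult needs to re-reach the threshold.

    After reproducing, a parent has invested the fraction P of its stock;
    near the threshold T it must regain about P*T units, which takes
    ceil(P*T / R) successes of size R.  At the reference condition
    (P = 0.5, T = 100, R = 40) this is 2.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    return math.ceil(P * T / R)


def prob_reach_threshold(d: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(d, p): chance a selfish adult gets k
    successes within a d-step delay window.

    Uses the regularized-beta survival function (numerically stable tail
    sum); k = 0 always yields 1.
    """
    if d < 0 or k < 0:
        raise ValueError("d and k must be non-negative integers")
    _check_prob(p)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, d, p))


def predicted_peak_delay(P: float, T: float, p: float, R: float) -> float:
    """Delay at which selection for fairness is predicted to peak: PT / pR.

    A parent retains (1 - P) of its stock after reproducing, so near the
    threshold T it must regain about P*T units before its next
    reproduction; at expected intake pR per step that takes PT / (pR)
    steps.  When the enforced delay d matches this span, a fair adult's
    steady accumulation just replaces the investment within the delay,
    while a selfish adult often misses the few large wins it needs —
    maximizing fairness's advantage.  Returns a real number; round to the
    nearest integer delay to compare with sweep grids.
    """
    _check_prob(P, "P")
    if p * R <= 0:
        raise ValueError("expected payoff pR must be positive")
    return P * T / (p * R)


def gene_birth_frequency(
    birth_log: Iterable[tuple[int, int]] | np.ndarray,
    window: tuple[int, int],
) -> float | None:
    """Fraction of births in [start, end) that carry the play gene.

    ``birth_log`` holds (step, gene_state) rows; gene_state is 0/1.
    Returns None (undefined, never silently 0) when the window contains
    no births.
    """
    start, end = window
    if start > end:
        raise ValueError(f"window start {start} > end {end}")
    log = np.asarray(list(birth_log) if not isinstance(birth_log, np.ndarray)
                     else birth_log)
    if log.size == 0:
        return None
    log = log.reshape(-1, 2)
    in_win = (log[:, 0] >= start) & (log[:, 0] < end)
    total = int(np.count_nonzero(in_win))
    if total == 0:
        return None
    return float(np.count_nonzero(log[in_win, 1])) / total


def play_mortality_percent(play_deaths: int, playing_juveniles: int) -> float:
    """Realized play mortality: 100 x deaths / juveniles that ever played.

    The denominator is the count of juveniles that entered at least one
    bout (juveniles that never played faced no risk); 0 when none played.
    """
    if play_deaths < 0 or playing_juveniles < 0:
        raise ValueError("counts must be non-negative")
    if playing_juveniles < play_deaths:
        raise ValueError("more play deaths than playing juveniles")
    if playing_juveniles == 0:
        return 0.0
    return 100.0 * play_deaths / playing_juveniles
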