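"""Conjugate Bayesian event-rate inference for placebo groups.

Each group's 28-day hospitalization count x out of n is modeled as Binomial
with a Uniform(0, 1) prior on the rate, giving the Beta(x+1, n-x+1) posterior.
Point estimates are posterior means (x+1)/(n+2) reported as percentages at one
decimal (round half up); interval estimates are equal-tailed 95% credible
intervals from closed-form Beta quantiles.  Rate differences between groups
are compared by Monte Carlo: four chains of paired posterior draws with the
first half of each chain discarded, mirroring burn-in bookkeeping even though
the draws are i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .trial_model import TwoByTwo


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (display convention; python's round is banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PosteriorRate:
    """Beta(alpha, beta) posterior of an event rate, optionally with MC draws."""

    alpha: float
    beta: float
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def mean_pct(self) -> float:
        """Posterior mean as a percentage, 1 decimal, round half up."""
        return round_half_up(100.0 * self.mean, 1)


@dataclass
class RateComparison:
    """Monte Carlo posterior of the rate difference (group B minus group A)."""

    diff_draws: np.ndarray
    diff_mean: float
    cri_95: tuple[float, float]

    def __post_init__(self) -> None:
        if self.cri_95[0] > self.cri_95[1]:
            raise ValueError("credible interval bounds out of order")


def beta_posterior(events: int, n: int) -> PosteriorRate:
    """Beta posterior of the event rate under a uniform prior."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= events <= n):
        raise ValueError("events must satisfy 0 <= events <= n")
    return PosteriorRate(alpha=events + 1.0, beta=n - events + 1.0)


def group_posteriors(table: TwoByTwo) -> tuple[PosteriorRate, PosteriorRate]:
    """Posteriors for (matched, nonmatched) groups of a 2x2 event table."""
    return (
        beta_posterior(table.events_a, table.n_a),
        beta_posterior(table.events_b, table.n_b),
    )


def credible_interval(
    posterior: PosteriorRate, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible interval from closed-form Beta quantiles."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    dist = stats.beta(posterior.alpha, posterior.beta)
    return (float(dist.ppf(tail)), float(dist.ppf(1.0 - tail)))


def credible_interval_pct(
    posterior: PosteriorRate, level: float = 0.95
) -> tuple[float, float]:
    lo, hi = credible_interval(posterior, level)
    return (round_half_up(100 * lo, 1), round_half_up(100 * hi, 1))


def sample_rate_difference(
    p_a: PosteriorRate,
    p_b: PosteriorRate,
    chains: int = 4,
    iters: int = 20_000,
    seed: int = 0,
) -> RateComparison:
    """Monte Carlo posterior of rate_B - rate_A.

    Each of ``chains`` chains draws ``iters`` independent pairs from the two
    Beta posteriors; the first half of every chain is discarded and the
    retained halves are pooled (default 4 x 10,000 = 40,000 retained draws).
    """
    if iters < 2:
        raise ValueError("iters must be >= 2")
    rng = np.random.default_rng(seed)
    kept = []
    for _ in range(chains):
        a = rng.beta(p_a.alpha, p_a.beta, size=iters)
        b = rng.beta(p_b.alpha, p_b.beta, size=iters)
        diff = b - a
        kept.append(diff[iters // 2:])
    draws = np.concatenate(kept)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return RateComparison(
        diff_draws=draws, diff_mean=float(draws.mean()), cri_95=(float(lo), float(hi))
    )


def recover_event_count(printed_rate_pct: float, n: int) -> int | list[int]:
    """Invert a printed posterior-mean percentage back to the event count.

    Scans x in 0..n for round-half-up(100*(x+1)/(n+2), 1) == printed value;
    a unique solution is returned as an int, multiple solutions as a list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= printed_rate_pct <= 100.0):
        raise ValueError("printed rate must be a percentage in [0, 100]")
    hits = [
        x for x in range(n + 1)
        if round_half_up(100.0 * (x + 1) / (n + 2), 1) == printed_rate_pct
    ]
    if not hits:
        raise ValueError(
            f"no event count in 0..{n} yields {printed_rate_pct}% under the "
            "posterior-mean convention"
        )
    return hits[0] if len(hits) == 1 else hits
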