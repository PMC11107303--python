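"""Meta-analysis of dependent study-level log-ORs from shared placebo patients.

The seven comparisons reuse overlapping placebo patients, so their adjusted
log-ORs are correlated.  The pipeline (i) estimates the cross-study covariance
by bootstrap resampling of the unique placebo population, (ii) *decouples* the
dependent estimates — replaces their SEs with inflated, effectively
independent SEs whose inverse-variance pooling reproduces the GLS solution
under the full covariance — and (iii) pools with fixed-effect,
DerSimonian-Laird random-effects, and a Bayesian normal-likelihood model that
yields the posterior probability of pooled equivalence Pr(0.8 <= OR <= 1.2).

Decoupling contract: with diagonal covariance the SEs pass through unchanged;
in general the decoupled inverse-variance pooled point and variance equal the
GLS pooled point (1'S^-1 1)^-1 1'S^-1 theta and variance (1'S^-1 1)^-1.
The realization used here sets s_i^2 = c / w_i with w_i the row sums of
S^-1 (floored at a small positive value) and c = sum(w) / 1'S^-1 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .trial_model import ComparisonSet, PatientRecord

Z_95 = 1.959964  # fixed normal quantile for bit-stable CI round-trips


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio and standard error."""

    label: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.label}: se must be positive")


@dataclass
class CovMatrix:
    """Symmetric PSD covariance of study-level log-ORs."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("matrix must be symmetric within 1e-10")
        if np.any(np.diag(m) <= 0):
            raise ValueError("diagonal must be positive")
        self.matrix = m

    @property
    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(d, d)


@dataclass(frozen=True)
class MetaResult:
    """Pooled log-OR with heterogeneity statistics."""

    pooled_log_or: float
    pooled_se: float
    ci_95: tuple[float, float]
    Q: float
    df: int
    I2: float
    tau2: float

    @property
    def pooled_or(self) -> float:
        return float(np.exp(self.pooled_log_or))

    @property
    def or_ci_95(self) -> tuple[float, float]:
        return (float(np.exp(self.ci_95[0])), float(np.exp(self.ci_95[1])))


@dataclass(frozen=True)
class PooledEquivalence:
    """Bayesian pooled OR and posterior probability of equivalence."""

    or_point: float
    cri_95: tuple[float, float]
    prob_equiv: float
    bounds: tuple[float, float]
    mu_draws: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_equiv <= 1.0):
            raise ValueError("prob_equiv must lie in [0, 1]")


def logor_from_ci(
    or_point: float, lo: float, hi: float, label: str = "", level: float = 0.95
) -> EffectEstimate:
    """Convert a printed OR with CI to log-OR and SE (Wald on the log scale)."""
    if min(or_point, lo, hi) <= 0:
        raise ValueError("OR and CI bounds must be positive")
    if not (lo <= or_point <= hi):
        raise ValueError("need lo <= or_point <= hi")
    z = Z_95 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    se = (np.log(hi) - np.log(lo)) / (2.0 * z)
    if se <= 0:
        raise ValueError("degenerate interval: se must be positive")
    return EffectEstimate(label=label, log_or=float(np.log(or_point)), se=float(se))


def _haldane_log_or(x_a: int, n_a: int, x_b: int, n_b: int) -> float:
    """Unadjusted log-OR (nonmatched vs matched) with 0.5 continuity correction."""
    a, b = x_b + 0.5, n_b - x_b + 0.5
    c, d = x_a + 0.5, n_a - x_a + 0.5
    return float(np.log((a / b) / (c / d)))


def bootstrap_covariance(
    comparisons: Sequence[ComparisonSet],
    records: Sequence[PatientRecord],
    B: int = 1000,
    seed: int = 0,
    fit_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> CovMatrix:
    """Bootstrap the covariance of study log-ORs induced by shared patients.

    Resamples the unique placebo population with replacement; every
    comparison's 2x2 table is rebuilt from the resampled multiplicities and
    its Haldane-corrected unadjusted log-OR recomputed (covariance between
    studies is driven by patient sharing, not by covariate adjustment; a full
    refit can be supplied via ``fit_fn(multiplicity, events)``).  Replicates
    producing an empty group are dropped; more than 10% dropped is an error.
    """
    if len(comparisons) < 2:
        raise ValueError("need at least two comparisons")
    if B < 2:
        raise ValueError("B must be >= 2")
    ids = sorted({r.id for r in records})
    pos = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    events = np.zeros(n)
    for r in records:
        events[pos[r.id]] = float(r.hospitalized_28d)
    matched_idx = [np.array(sorted(pos[p] for p in cs.matched_ids)) for cs in comparisons]
    nonmatched_idx = [
        np.array(sorted(pos[p] for p in cs.nonmatched_ids)) for cs in comparisons
    ]
    rng = np.random.default_rng(seed)
    rows, dropped = [], 0
    while len(rows) < B:
        if dropped > 0.1 * B and dropped > 5:
            raise RuntimeError(
                f"bootstrap unstable: {dropped} replicates with an empty group"
            )
        mult = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
        rep = []
        ok = True
        for mi, ui in zip(matched_idx, nonmatched_idx):
            n_a, n_b = mult[mi].sum(), mult[ui].sum()
            if n_a == 0 or n_b == 0:
                ok = False
                break
            x_a = (mult[mi] * events[mi]).sum()
            x_b = (mult[ui] * events[ui]).sum()
            if fit_fn is not None:
                rep.append(fit_fn(mult, events))
            else:
                rep.append(_haldane_log_or(x_a, n_a, x_b, n_b))
        if ok:
            rows.append(rep)
        else:
            dropped += 1
    arr = np.asarray(rows)
    cov = np.cov(arr, rowvar=False, ddof=1)
    return CovMatrix(labels=[cs.treatment.name for cs in comparisons], matrix=cov)


def decouple(
    estimates: Sequence[EffectEstimate], sigma: CovMatrix, eps: float = 1e-12
) -> list[EffectEstimate]:
    """Replace dependent SEs with independent effective SEs (GLS-matching).

    The covariance's correlation structure is rescaled to the estimates' own
    SEs (S = D R D with D = diag(se)): the bootstrap fixes the dependence
    pattern while the fitted model supplies the marginal scale.  Labels and
    log-ORs pass through unchanged.
    """
    if len(estimates) != len(sigma.labels):
        raise ValueError("estimates and covariance dimensions differ")
    d = np.array([e.se for e in estimates])
    S = sigma.correlation * np.outer(d, d)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance; add a small ridge to the diagonal"
        ) from exc
    total = float(S_inv.sum())
    if total <= 0:
        raise ValueError("covariance implies nonpositive pooled precision")
    w = np.maximum(S_inv.sum(axis=1), eps)
    c = float(w.sum()) / total
    se_tilde = np.sqrt(c / w)
    return [
        EffectEstimate(label=e.label, log_or=e.log_or, se=float(s))
        for e, s in zip(estimates, se_tilde)
    ]


def _pool(estimates: Sequence[EffectEstimate], tau2: float) -> tuple[float, float]:
    w = np.array([1.0 / (e.se**2 + tau2) for e in estimates])
    theta = np.array([e.log_or for e in estimates])
    pooled = float((w * theta).sum() / w.sum())
    return pooled, float(np.sqrt(1.0 / w.sum()))


def _heterogeneity(estimates: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    w = np.array([1.0 / e.se**2 for e in estimates])
    theta = np.array([e.log_or for e in estimates])
    pooled = (w * theta).sum() / w.sum()
    Q = float((w * (theta - pooled) ** 2).sum())
    df = len(estimates) - 1
    I2 = 100.0 * max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, I2


def fixed_effect_meta(estimates: Sequence[EffectEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran Q and I^2."""
    if len(estimates) < 2:
        raise ValueError("need at least two estimates")
    pooled, se = _pool(estimates, 0.0)
    Q, df, I2 = _heterogeneity(estimates)
    return MetaResult(
        pooled_log_or=pooled, pooled_se=se,
        ci_95=(pooled - Z_95 * se, pooled + Z_95 * se),
        Q=Q, df=df, I2=I2, tau2=0.0,
    )


def random_effect_meta(estimates: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling; equals fixed effect when Q <= df."""
    if len(estimates) < 2:
        raise ValueError("need at least two estimates")
    Q, df, I2 = _heterogeneity(estimates)
    w = np.array([1.0 / e.se**2 for e in estimates])
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    pooled, se = _pool(estimates, tau2)
    return MetaResult(
        pooled_log_or=pooled, pooled_se=se,
        ci_95=(pooled - Z_95 * se, pooled + Z_95 * se),
        Q=Q, df=df, I2=I2, tau2=tau2,
    )


def bayes_meta(
    estimates: Sequence[EffectEstimate],
    prior_mean: float = 0.0,
    prior_sd: float = 10.0,
    chains: int = 4,
    total_iters: int = 20_000,
    seed: int = 0,
    bounds: tuple[float, float] = (0.8, 1.2),
) -> PooledEquivalence:
    """Bayesian fixed-effect meta-analysis of (decoupled) independent estimates.

    Model: theta_i ~ Normal(mu, se_i^2) with mu ~ Normal(prior_mean,
    prior_sd^2).  The posterior of mu is conjugate normal and is sampled
    exactly, arranged as ``chains`` chains with the first half discarded to
    mirror the MC bookkeeping used elsewhere in the pipeline.
    """
    if len(estimates) < 1:
        raise ValueError("need at least one estimate")
    if not (0.0 < bounds[0] < bounds[1]):
        raise ValueError("equivalence bounds must satisfy 0 < lo < hi")
    prec = 1.0 / prior_sd**2 + sum(1.0 / e.se**2 for e in estimates)
    mean = (
        prior_mean / prior_sd**2 + sum(e.log_or / e.se**2 for e in estimates)
    ) / prec
    sd = float(np.sqrt(1.0 / prec))
    rng = np.random.default_rng(seed)
    per_chain = max(2, total_iters // chains)
    kept = [
        rng.normal(mean, sd, size=per_chain)[per_chain // 2:] for _ in range(chains)
    ]
    mu = np.concatenate(kept)
    lo_q, med, hi_q = np.percentile(mu, [2.5, 50.0, 97.5])
    or_draws = np.exp(mu)
    prob = float(np.mean((or_draws >= bounds[0]) & (or_draws <= bounds[1])))
    return PooledEquivalence(
        or_point=float(np.exp(med)),
        cri_95=(float(np.exp(lo_q)), float(np.exp(hi_q))),
        prob_equiv=prob,
        bounds=bounds,
        mu_draws=mu,
    )


def gls_pool(theta: np.ndarray, S: np.ndarray) -> tuple[float, float]:
    """Closed-form GLS pooled point and variance for correlated estimates."""
    S_inv = np.linalg.inv(S)
    one = np.ones(len(theta))
    var = 1.0 / float(one @ S_inv @ one)
    point = var * float(one @ S_inv @ theta)
    return point, var
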