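"""Patient-reported outcome models: PROMIS Global-10 and EQ-5D-5L utilities.

PROMIS Global-10 is analyzed as the raw sum of its ten 5-point items (range
10-50) with ordinary least squares.  EQ-5D-5L health states are mapped to a
utility through a value set (a table over all 5^5 = 3125 states anchored at
full health 11111 -> 1.0); because a majority of patients sit at the ceiling
utility of 1 at day 28, the group contrast is estimated with a Bayesian Tobit
model treating ceiling observations as right-censored at 1.  Missing day-28
questionnaires (~15% of patients) are handled by multiple imputation with
chained equations using predictive mean matching (statsmodels), and
per-imputation fits are combined with Rubin's rules (Barnard-Rubin df).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.imputation import mice as sm_mice

from . import _mcmc
from .trial_model import ComparisonSet, PatientRecord

STATES = tuple(itertools.product(range(1, 6), repeat=5))
DEFAULT_DECREMENTS = (0.05, 0.05, 0.05, 0.06, 0.07)


@dataclass
class ValueSet:
    """Total mapping from every EQ-5D-5L state to a utility, anchored at 1.0."""

    utilities: dict[tuple[int, ...], float]

    def __post_init__(self) -> None:
        missing = len(STATES) - len(set(self.utilities) & set(STATES))
        if missing:
            raise ValueError(f"value set incomplete: {missing} states missing")
        if self.utilities[(1, 1, 1, 1, 1)] != 1.0:
            raise ValueError("full-health state 11111 must map to 1.0")
        if max(self.utilities.values()) > 1.0:
            raise ValueError("utilities must not exceed 1.0")

    @property
    def floor(self) -> float:
        return min(self.utilities.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("".join(map(str, s)), u) for s, u in sorted(self.utilities.items())]
        return pd.DataFrame(rows, columns=["state", "utility"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "ValueSet":
        frame = pd.read_csv(path, dtype={"state": str})
        return cls({tuple(int(c) for c in s): float(u)
                    for s, u in zip(frame["state"], frame["utility"])})


def synthetic_value_set(
    decrements: Sequence[float] = DEFAULT_DECREMENTS,
) -> ValueSet:
    """Additive synthetic value set: 1 minus per-dimension level decrements.

    Each step above level 1 in dimension d costs ``decrements[d]``.  This is a
    stand-in with the right structure (total, anchored, monotone within
    dimension), not a published national valuation.
    """
    if len(decrements) != 5:
        raise ValueError("need one decrement per dimension")
    return ValueSet({
        s: round(1.0 - sum(dec * (lvl - 1) for dec, lvl in zip(decrements, s)), 10)
        for s in STATES
    })


def promis_total(items: Sequence[int]) -> int:
    """PROMIS Global-10 raw total: sum of the ten items, range 10..50."""
    if items is None:
        raise ValueError("missing PROMIS items; impute before scoring")
    items = tuple(items)
    if len(items) != 10 or any(not (1 <= int(v) <= 5) for v in items):
        raise ValueError("PROMIS requires 10 items each in 1..5")
    return int(sum(int(v) for v in items))


def eq5d_index(state: Sequence[int], value_set: ValueSet) -> float:
    """Utility of one EQ-5D-5L state via value-set lookup."""
    if state is None:
        raise ValueError("missing EQ-5D state; impute before scoring")
    key = tuple(int(v) for v in state)
    if key not in value_set.utilities:
        raise ValueError(f"state {key} outside the 5-level domain")
    return value_set.utilities[key]


# ---------------------------------------------------------------------------
# Multiple imputation


@dataclass
class ImputationSet:
    """m completed datasets from chained-equation imputation."""

    datasets: list[pd.DataFrame]

    @property
    def m(self) -> int:
        return len(self.datasets)


def mice_pmm(
    data: pd.DataFrame,
    m: int = 15,
    cycles: int = 10,
    donors: int = 5,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equation imputation with predictive mean matching.

    Each incomplete variable is imputed from the ``donors`` observed cases
    nearest in predicted mean, cycling ``cycles`` times per completed dataset.
    Imputed values therefore always belong to the observed-donor pool.
    """
    if m < 2:
        raise ValueError("m must be >= 2 for Rubin pooling")
    for col in data.columns:
        n_obs = data[col].notna().sum()
        if n_obs == 0:
            raise ValueError(f"variable {col!r} has no observed values")
        frac = 1.0 - n_obs / len(data)
        if frac >= 0.5:
            raise ValueError(f"variable {col!r} is >=50% missing")
        if data[col].isna().any() and n_obs < donors:
            raise ValueError(f"variable {col!r} has fewer complete cases than donors")
    if not data.isna().any().any():
        return ImputationSet([data.copy() for _ in range(m)])
    np.random.seed(seed)  # statsmodels MICE draws from the global numpy state
    imputer = sm_mice.MICEData(
        data.astype(float), perturbation_method="gaussian", k_pmm=donors
    )
    completed = []
    for _ in range(m):
        imputer.update_all(cycles)
        completed.append(imputer.data.copy())
    return ImputationSet(completed)


# ---------------------------------------------------------------------------
# Per-imputation fits


@dataclass(frozen=True)
class CoefEstimate:
    """A coefficient estimate with its standard error from one fit."""

    estimate: float
    se: float


PRO_COVARIATES = ["group", "age50", "male", "bmi30", "baseline"]


def fit_linear_pro(
    completed: pd.DataFrame, outcome: str = "promis_d28"
) -> dict[str, CoefEstimate]:
    """OLS of the day-28 score on group, covariates and baseline score."""
    X = sm.add_constant(completed[PRO_COVARIATES], has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(completed[outcome], X).fit()
    return {
        name: CoefEstimate(float(fit.params[name]), float(fit.bse[name]))
        for name in X.columns
    }


@dataclass
class TobitPosterior:
    """Posterior draws of Tobit coefficients and scale; upper censoring at 1."""

    draws: _mcmc.PosteriorDraws
    diagnostics: pd.DataFrame
    censor_bound: float

    def coef(self, name: str) -> np.ndarray:
        return self.draws.marginal(name)

    @property
    def scale_draws(self) -> np.ndarray:
        return np.exp(self.draws.marginal("log_scale"))


def tobit_loglik(
    beta: np.ndarray, log_sigma: np.ndarray, X: np.ndarray, y: np.ndarray,
    upper: float,
) -> np.ndarray:
    """Vectorized censored-normal log-likelihood over walker rows."""
    sigma = np.exp(log_sigma)
    mu = X @ beta.T                                    # (n, walkers)
    cens = y >= upper
    z = (y[:, None] - mu) / sigma
    ll_unc = stats.norm.logpdf(z) - np.log(sigma)
    ll_cen = stats.norm.logsf((upper - mu) / sigma)
    return np.where(cens[:, None], ll_cen, ll_unc).sum(axis=0)


def fit_tobit(
    completed: pd.DataFrame,
    outcome: str = "eq5d_d28",
    upper: float = 1.0,
    covariates: Sequence[str] = PRO_COVARIATES,
    chains: int = 4,
    total_iters: int = 8000,
    seed: int = 0,
    prior_sd: float = 2.5,
    warn: bool = True,
) -> TobitPosterior:
    """Bayesian Tobit regression with observations at the bound right-censored.

    Guards against a misdeclared bound: data strictly above ``upper`` are a
    hard error (the likelihood would be invalid, not merely poor).
    """
    y = completed[outcome].to_numpy(dtype=float)
    if np.any(y > upper + 1e-12):
        raise ValueError("observations exceed the declared censoring bound")
    if np.all(y >= upper):
        raise ValueError("all observations censored; group effect unidentified")
    X = sm.add_constant(completed[list(covariates)], has_constant="add").to_numpy()
    names = ["intercept", *covariates, "log_scale"]
    n_coef = X.shape[1]

    def logp(params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        beta, log_sigma = params[:, :n_coef], params[:, n_coef]
        ll = tobit_loglik(beta, log_sigma, X, y, upper)
        prior = (
            -0.5 * ((beta / prior_sd) ** 2).sum(axis=1)
            - 0.5 * (log_sigma / 1.5) ** 2
        )
        return ll + prior

    # proposal from the penalized mode: start at OLS on the uncensored subset
    from scipy import optimize

    unc = y < upper
    start_beta, *_ = np.linalg.lstsq(X[unc], y[unc], rcond=None)
    resid = y[unc] - X[unc] @ start_beta
    x0 = np.append(start_beta, np.log(max(float(resid.std()), 1e-3)))
    neglp = lambda p: -float(logp(p)[0])  # noqa: E731
    res = optimize.minimize(neglp, x0, method="BFGS")
    cov = _mcmc.numerical_hessian_cov(neglp, res.x)
    draws = _mcmc.run_mh_chains(
        logp, res.x, cov, names, chains=chains, total_iters=total_iters, seed=seed
    )
    diag = _mcmc.diagnostics(draws, warn=warn)
    return TobitPosterior(draws=draws, diagnostics=diag, censor_bound=upper)


def tobit_group_estimate(posterior: TobitPosterior, coef: str = "group") -> CoefEstimate:
    """Posterior mean and SD of a Tobit coefficient, as an estimate for pooling."""
    g = posterior.coef(coef)
    return CoefEstimate(float(g.mean()), float(g.std(ddof=1)))


# ---------------------------------------------------------------------------
# Rubin pooling


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    se: float
    ci_95: tuple[float, float]
    df: float
    between_var: float
    within_var: float


def rubin_pool(
    fits: Sequence[CoefEstimate], dfcom: float | None = None, level: float = 0.95
) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    Total variance = within-mean + (1 + 1/m) * between; the interval uses a t
    reference with Barnard-Rubin small-sample df when the complete-data df is
    supplied, else Rubin's large-sample df.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("need at least two imputation fits")
    q = np.array([f.estimate for f in fits])
    u = np.array([f.se**2 for f in fits])
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    total = ubar + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = np.inf
    else:
        r = (1.0 + 1.0 / m) * b / ubar if ubar > 0 else np.inf
        df_old = (m - 1) * (1.0 + 1.0 / r) ** 2 if np.isfinite(r) else m - 1.0
        if dfcom is None:
            df = df_old
        else:
            lam = (1.0 + 1.0 / m) * b / total
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = float(np.sqrt(total))
    tq = float(stats.t.ppf(0.5 + level / 2.0, df)) if np.isfinite(df) else float(
        stats.norm.ppf(0.5 + level / 2.0)
    )
    return PooledEstimate(
        estimate=qbar, se=se, ci_95=(qbar - tq * se, qbar + tq * se),
        df=float(df), between_var=b, within_var=ubar,
    )


# ---------------------------------------------------------------------------
# Full per-comparison pipeline


def comparison_frame(
    cs: ComparisonSet,
    records: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    instrument: str,
    value_set: ValueSet | None = None,
) -> pd.DataFrame:
    """Analysis frame for one comparison: scores may be NaN (pre-imputation).

    Instrument is ``promis`` (baseline/day-28 raw totals) or ``eq5d``
    (baseline/day-28 utilities via the value set).
    """
    index = records if isinstance(records, Mapping) else {r.id: r for r in records}
    if instrument == "eq5d" and value_set is None:
        raise ValueError("eq5d instrument requires a value set")
    rows = []
    for pid in sorted(cs.matched_ids) + sorted(cs.nonmatched_ids):
        rec = index[pid]
        row = {
            "group": float(pid in cs.nonmatched_ids),
            "age50": float(rec.age_years >= 50),
            "male": float(rec.sex == "M") if rec.sex is not None else np.nan,
            "bmi30": float(rec.bmi >= 30),
        }
        if instrument == "promis":
            row["baseline"] = (
                promis_total(rec.promis_base) if rec.promis_base else np.nan
            )
            row["promis_d28"] = (
                promis_total(rec.promis_d28) if rec.promis_d28 else np.nan
            )
        elif instrument == "eq5d":
            row["baseline"] = (
                eq5d_index(rec.eq5d_base, value_set) if rec.eq5d_base else np.nan
            )
            row["eq5d_d28"] = (
                eq5d_index(rec.eq5d_d28, value_set) if rec.eq5d_d28 else np.nan
            )
        else:
            raise ValueError(f"unknown instrument {instrument!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_pro_comparison(
    cs: ComparisonSet,
    records: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    instrument: str,
    value_set: ValueSet | None = None,
    m: int = 15,
    cycles: int = 10,
    donors: int = 5,
    seed: int = 0,
    tobit_chains: int = 4,
    tobit_iters: int = 8000,
) -> PooledEstimate:
    """Impute -> fit (OLS or Tobit by instrument) -> Rubin-pool the group effect."""
    frame = comparison_frame(cs, records, instrument, value_set)
    imputations = mice_pmm(frame, m=m, cycles=cycles, donors=donors, seed=seed)
    outcome = "promis_d28" if instrument == "promis" else "eq5d_d28"
    fits = []
    for j, completed in enumerate(imputations.datasets):
        if instrument == "promis":
            fits.append(fit_linear_pro(completed, outcome=outcome)["group"])
        else:
            post = fit_tobit(
                completed, outcome=outcome, chains=tobit_chains,
                total_iters=tobit_iters, seed=seed + 7919 * (j + 1), warn=False,
            )
            fits.append(tobit_group_estimate(post))
    dfcom = len(frame) - (len(PRO_COVARIATES) + 1)
    return rubin_pool(fits, dfcom=dfcom)
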