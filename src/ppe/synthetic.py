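"""Synthetic platform-trial placebo data generator.

Emulates the placebo-sharing structure of a multiarm COVID-19 outpatient
trial: one placebo population enrolled over a ~19-month calendar, six distinct
placebo regimens, seven treatment comparison windows that overlap in time, a
hospitalization outcome whose base rate drifts downward over calendar time,
and day-28 patient-reported outcomes with ~15% patient-level missingness.

The default configuration reproduces, by construction, the seven
matched/nonmatched comparison sizes of the motivating trial
(105/97, 319/358, 810/193, 567/171, 322/431, 264/274, 292/265), a total of
2684 unique placebo patients, and the documented regimen sharing (the 10-day
oral b.i.d. placebo serves both the metformin and fluvoxamine comparisons).
Membership in a comparison is induced purely by enrollment date and regimen —
patients are never duplicated across rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
from scipy import stats

from .trial_model import PatientRecord, PlaceboRegimen, TreatmentSpec

TRIAL_START = date(2021, 1, 15)

# Regimens (route, doses/day, duration)
R_ORAL_BID_10 = PlaceboRegimen("oral", 2, 10)          # metformin, fluvoxamine
R_ORAL_QD_3 = PlaceboRegimen("oral", 1, 3)             # ivermectin
R_SUBCUT_1 = PlaceboRegimen("subcutaneous", 1, 1)      # pegylated interferon lambda
R_ORAL_INH_10 = PlaceboRegimen("oral+inhaled", 2, 10)  # fluvoxamine + budesonide
R_ORAL_TID_10 = PlaceboRegimen("oral", 3, 10)          # famotidine
R_ORAL_BID_14 = PlaceboRegimen("oral", 2, 14)          # spirulina


@dataclass(frozen=True)
class Block:
    """A cohort of patients with one regimen enrolled in a closed day range."""

    regimen: PlaceboRegimen | None
    day_lo: int
    day_hi: int
    n: int

    def __post_init__(self) -> None:
        if self.day_lo > self.day_hi:
            raise ValueError("day_lo must not exceed day_hi")
        if self.n < 0:
            raise ValueError("block size must be nonnegative")


@dataclass
class TrialConfig:
    """Everything the generator needs; defaults follow `default_config`."""

    treatments: list[TreatmentSpec]
    blocks: list[Block]
    # covariates
    p_age_ge_50: float = 0.478
    age_mean: float = 47.0
    age_sd: float = 15.2
    p_female: float = 0.604
    p_bmi_ge_30: float = 0.35
    n_sex_missing: int = 1
    # outcome model: logit P(event) = b0 + b_drift * day/day_span + covariate effects
    logit_intercept: float = -1.09
    logit_drift: float = -4.18
    beta_age50: float = 0.7
    beta_male: float = 0.3
    beta_bmi30: float = 0.4
    day_span: int = 570
    # patient-reported outcomes
    generate_pro: bool = True
    promis_probs_base: tuple[float, ...] = (0.05, 0.20, 0.40, 0.25, 0.10)
    promis_probs_d28: tuple[float, ...] = (0.02, 0.08, 0.25, 0.35, 0.30)
    eq5d_probs_base: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    eq5d_probs_d28: tuple[float, ...] = (0.90, 0.06, 0.02, 0.01, 0.01)
    latent_rho: float = 0.4
    missingness_rate: float = 0.15
    missingness_mode: str = "mcar"  # or "mar" (depends on age)
    n_sites: int = 12

    def __post_init__(self) -> None:
        for p in (self.p_age_ge_50, self.p_female, self.p_bmi_ge_30,
                  self.missingness_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.blocks or sum(b.n for b in self.blocks) < 1:
            raise ValueError("config must place at least one patient")
        span = max(b.day_hi for b in self.blocks)
        for spec in self.treatments:
            lo = (spec.window_start - TRIAL_START).days
            hi = (spec.window_end - TRIAL_START).days
            cap = sum(
                b.n for b in self.blocks
                if b.regimen == spec.regimen and not (b.day_hi < lo or b.day_lo > hi)
            )
            if cap < 1:
                raise ValueError(
                    f"{spec.name}: no capacity for matched placebo inside window"
                )


def _window(lo_day: int, hi_day: int) -> tuple[date, date]:
    return (TRIAL_START + timedelta(days=lo_day), TRIAL_START + timedelta(days=hi_day))


def default_config() -> TrialConfig:
    """Default trial layout reproducing the motivating trial's comparison sizes.

    Blocks place regimen cohorts on a day axis (day 0 = 2021-01-15); windows
    are closed day intervals.  The early block of 107 ten-day-oral patients
    (days 0–54) sits before every window — placebo patients from the trial's
    earlier stage who belong to none of the seven comparisons — and 3 patients
    carry no recorded regimen; both groups bring the unique patient total to
    2684 while the seven comparisons sum to 4468 memberships.
    """
    treatments = [
        TreatmentSpec("metformin", R_ORAL_BID_10, *_window(120, 180)),
        TreatmentSpec("ivermectin", R_ORAL_QD_3, *_window(60, 240)),
        TreatmentSpec("pegylated interferon lambda", R_SUBCUT_1, *_window(210, 420)),
        TreatmentSpec("fluvoxamine+budesonide", R_ORAL_INH_10, *_window(432, 510)),
        TreatmentSpec("fluvoxamine", R_ORAL_BID_10, *_window(60, 300)),
        TreatmentSpec("famotidine", R_ORAL_TID_10, *_window(444, 540)),
        TreatmentSpec("spirulina", R_ORAL_BID_14, *_window(456, 570)),
    ]
    blocks = [
        # earlier-stage placebo patients, outside every comparison window
        Block(R_ORAL_BID_10, 0, 54, 107),
        # 10-day oral b.i.d. (metformin + fluvoxamine matched pool)
        Block(R_ORAL_BID_10, 60, 119, 70),
        Block(R_ORAL_BID_10, 120, 180, 105),
        Block(R_ORAL_BID_10, 181, 209, 43),
        Block(R_ORAL_BID_10, 210, 240, 80),
        Block(R_ORAL_BID_10, 241, 300, 24),
        # 3-day oral q.d. (ivermectin matched pool)
        Block(R_ORAL_QD_3, 60, 119, 90),
        Block(R_ORAL_QD_3, 120, 180, 97),
        Block(R_ORAL_QD_3, 181, 209, 43),
        Block(R_ORAL_QD_3, 210, 240, 89),
        # single-dose subcutaneous (interferon matched pool)
        Block(R_SUBCUT_1, 210, 240, 60),
        Block(R_SUBCUT_1, 241, 300, 52),
        Block(R_SUBCUT_1, 301, 420, 698),
        # oral+inhaled 10-day (fluvoxamine+budesonide matched pool)
        Block(R_ORAL_INH_10, 432, 443, 453),
        Block(R_ORAL_INH_10, 444, 455, 102),
        Block(R_ORAL_INH_10, 456, 510, 12),
        # 10-day oral t.i.d. (famotidine matched pool)
        Block(R_ORAL_TID_10, 444, 455, 11),
        Block(R_ORAL_TID_10, 456, 510, 100),
        Block(R_ORAL_TID_10, 511, 540, 153),
        # 14-day oral b.i.d. (spirulina matched pool)
        Block(R_ORAL_BID_14, 456, 510, 60),
        Block(R_ORAL_BID_14, 511, 540, 100),
        Block(R_ORAL_BID_14, 541, 570, 132),
        # regimen never recorded (excluded from every comparison by default)
        Block(None, 150, 150, 3),
    ]
    return TrialConfig(treatments=treatments, blocks=blocks)


def scale_config(config: TrialConfig, factor: float) -> TrialConfig:
    """Shrink (or grow) every block by a common factor, keeping the calendar."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    blocks = [
        replace(b, n=max(1, int(round(b.n * factor)))) for b in config.blocks if b.n
    ]
    return replace(config, blocks=blocks)


_SCALAR_FIELDS = [
    "p_age_ge_50", "age_mean", "age_sd", "p_female", "p_bmi_ge_30",
    "n_sex_missing", "logit_intercept", "logit_drift", "beta_age50",
    "beta_male", "beta_bmi30", "day_span", "generate_pro", "latent_rho",
    "missingness_rate", "missingness_mode", "n_sites",
]


def save_config(config: TrialConfig, path) -> None:
    """Serialize a trial configuration (treatments, blocks, models) to YAML."""
    import yaml

    doc = {
        "treatments": [
            {
                "name": t.name,
                "route": t.regimen.route,
                "doses_per_day": t.regimen.doses_per_day,
                "duration_days": t.regimen.duration_days,
                "window_start": t.window_start.isoformat(),
                "window_end": t.window_end.isoformat(),
            }
            for t in config.treatments
        ],
        "blocks": [
            {
                "route": b.regimen.route if b.regimen else None,
                "doses_per_day": b.regimen.doses_per_day if b.regimen else None,
                "duration_days": b.regimen.duration_days if b.regimen else None,
                "day_lo": b.day_lo,
                "day_hi": b.day_hi,
                "n": b.n,
            }
            for b in config.blocks
        ],
        **{f: getattr(config, f) for f in _SCALAR_FIELDS},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> TrialConfig:
    """Load a trial configuration saved by `save_config`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    treatments = [
        TreatmentSpec(
            name=t["name"],
            regimen=PlaceboRegimen(
                t["route"], int(t["doses_per_day"]), int(t["duration_days"])
            ),
            window_start=date.fromisoformat(t["window_start"]),
            window_end=date.fromisoformat(t["window_end"]),
        )
        for t in doc["treatments"]
    ]
    blocks = [
        Block(
            regimen=(
                PlaceboRegimen(
                    b["route"], int(b["doses_per_day"]), int(b["duration_days"])
                )
                if b["route"] is not None
                else None
            ),
            day_lo=int(b["day_lo"]),
            day_hi=int(b["day_hi"]),
            n=int(b["n"]),
        )
        for b in doc["blocks"]
    ]
    scalars = {f: doc[f] for f in _SCALAR_FIELDS if f in doc}
    for tup in ("promis_probs_base", "promis_probs_d28",
                "eq5d_probs_base", "eq5d_probs_d28"):
        if tup in doc:
            scalars[tup] = tuple(doc[tup])
    return TrialConfig(treatments=treatments, blocks=blocks, **scalars)


def _ordinal_levels(
    rng: np.random.Generator, latent: np.ndarray, probs: tuple[float, ...],
    n_items: int, rho: float,
) -> np.ndarray:
    """Correlated ordinal items via a latent-normal threshold model.

    Each patient's items share a N(0, rho) patient effect; item noise has
    variance 1-rho, so the combined latent is standard normal and the marginal
    category frequencies equal ``probs`` exactly.
    """
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    noise = rng.standard_normal((latent.size, n_items)) * np.sqrt(1.0 - rho)
    z = latent[:, None] * np.sqrt(rho) + noise
    return 1 + np.searchsorted(cuts, z.ravel()).reshape(z.shape)


def generate_trial(config: TrialConfig, seed: int) -> list[PatientRecord]:
    """Draw a full synthetic placebo population; reproducible given (config, seed)."""
    root = np.random.SeedSequence(seed)
    s_dates, s_cov, s_out, s_pro, s_miss = root.spawn(5)
    rng = np.random.default_rng(s_dates)

    regimens: list[PlaceboRegimen | None] = []
    days = []
    for b in config.blocks:
        days.append(rng.integers(b.day_lo, b.day_hi + 1, size=b.n))
        regimens.extend([b.regimen] * b.n)
    days = np.concatenate(days) if days else np.array([], dtype=int)
    n = days.size

    rng = np.random.default_rng(s_cov)
    age50 = rng.random(n) < config.p_age_ge_50
    # age drawn conditionally on the 50-year split so both the split frequency
    # and the overall location/scale track the configured values
    below = stats.truncnorm.rvs(
        (18 - config.age_mean) / config.age_sd, (50 - config.age_mean) / config.age_sd,
        loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    above = stats.truncnorm.rvs(
        (50 - config.age_mean) / config.age_sd, np.inf,
        loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    age = np.where(age50, above, below)
    female = rng.random(n) < config.p_female
    bmi30 = rng.random(n) < config.p_bmi_ge_30
    bmi_lo = stats.truncnorm.rvs(
        (16 - 26.0) / 3.5, (30 - 26.0) / 3.5, loc=26.0, scale=3.5, size=n,
        random_state=rng)
    bmi_hi = stats.truncnorm.rvs(
        0.0, (55 - 30.0) / 4.0, loc=30.0, scale=4.0, size=n, random_state=rng)
    bmi = np.where(bmi30, bmi_hi, bmi_lo)
    sites = rng.integers(0, config.n_sites, size=n)

    rng = np.random.default_rng(s_out)
    logit = (
        config.logit_intercept
        + config.logit_drift * days / config.day_span
        + config.beta_age50 * age50
        + config.beta_male * (~female)
        + config.beta_bmi30 * bmi30
    )
    event = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    promis_b = promis_d = eq5d_b = eq5d_d = None
    if config.generate_pro:
        rng = np.random.default_rng(s_pro)
        latent = rng.standard_normal(n)
        rho = config.latent_rho
        promis_b = _ordinal_levels(rng, latent, config.promis_probs_base, 10, rho)
        promis_d = _ordinal_levels(rng, latent, config.promis_probs_d28, 10, rho)
        eq5d_b = _ordinal_levels(rng, latent, config.eq5d_probs_base, 5, rho)
        eq5d_d = _ordinal_levels(rng, latent, config.eq5d_probs_d28, 5, rho)

    sex: list[str | None] = ["F" if f else "M" for f in female]
    for i in range(min(config.n_sex_missing, n)):
        sex[i * 7 % n] = None  # fixed positions: sex unrecorded for these patients

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"P{i:04d}",
                enrollment_date=TRIAL_START + timedelta(days=int(days[i])),
                site=f"S{sites[i]:02d}",
                age_years=float(np.round(age[i], 1)),
                sex=sex[i],
                bmi=float(np.round(bmi[i], 1)),
                regimen=regimens[i],
                hospitalized_28d=bool(event[i]),
                promis_base=tuple(int(v) for v in promis_b[i]) if promis_b is not None else None,
                promis_d28=tuple(int(v) for v in promis_d[i]) if promis_d is not None else None,
                eq5d_base=tuple(int(v) for v in eq5d_b[i]) if eq5d_b is not None else None,
                eq5d_d28=tuple(int(v) for v in eq5d_d[i]) if eq5d_d is not None else None,
            )
        )
    if config.missingness_rate > 0 and config.generate_pro:
        records = inject_missingness(
            records, config.missingness_rate,
            seed=int(np.random.default_rng(s_miss).integers(2**31)),
            mode=config.missingness_mode,
        )
    return records


def inject_missingness(
    records: list[PatientRecord], rate: float, seed: int, mode: str = "mcar"
) -> list[PatientRecord]:
    """Blank day-28 PRO fields for a fraction of patients.

    MCAR: every patient is masked with the same probability.  MAR: the masking
    probability depends on age (older patients more likely missing), calibrated
    so the marginal rate stays at ``rate``.  The hospitalization outcome is
    never masked.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return [replace(r) for r in records]
    rng = np.random.default_rng(seed)
    if mode == "mcar":
        p = np.full(len(records), rate)
    elif mode == "mar":
        age50 = np.array([r.age_years >= 50 for r in records])
        # odds doubled for age>=50, rescaled to preserve the marginal rate
        w = np.where(age50, 2.0, 1.0)
        p = np.clip(rate * w / w.mean(), 0.0, 0.99)
    else:
        raise ValueError(f"unknown missingness mode {mode!r}")
    mask = rng.random(len(records)) < p
    out = []
    for r, m in zip(records, mask):
        out.append(replace(r, promis_d28=None, eq5d_d28=None) if m else replace(r))
    return out
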