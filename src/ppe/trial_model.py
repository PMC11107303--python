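"""Data model of a platform trial's shared placebo structure.

A multiarm (platform) COVID-19 outpatient trial allocates placebo patients to
regimens that mirror the active arms (route, dosing frequency, duration).  For
a given treatment, the *matched* placebo group is the set of placebo patients
whose regimen is identical to the treatment's placebo regimen and who enrolled
inside the treatment's comparison window; the *nonmatched* group is every other
placebo patient who was chronologically eligible (enrolled inside the same
window) but received a different regimen.  Because regimens are shared between
treatments and windows overlap, one patient can serve as a matched comparator
for several treatments at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROUTES = ("oral", "inhaled", "oral+inhaled", "subcutaneous")


class MissingRegimenError(ValueError):
    """Raised when a patient with no recorded regimen is tested for a match."""


@dataclass(frozen=True)
class PlaceboRegimen:
    """Route, dosing frequency and duration of an inert placebo regimen."""

    route: str
    doses_per_day: int
    duration_days: int

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if self.doses_per_day < 1:
            raise ValueError("doses_per_day must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")


@dataclass(frozen=True)
class TreatmentSpec:
    """A treatment arm's placebo-matching requirement and comparison window."""

    name: str
    regimen: PlaceboRegimen
    window_start: date
    window_end: date

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")

    def contains(self, day: date) -> bool:
        """Chronological eligibility: closed on both ends, day resolution."""
        return self.window_start <= day <= self.window_end


@dataclass
class PatientRecord:
    """One placebo-assigned participant.

    ``hospitalized_28d`` is the composite primary outcome: an emergency-setting
    visit with observation beyond 6 hours, or referral to tertiary hospital
    care, within 28 days of randomization.  PRO fields hold the ten
    PROMIS Global-10 items (1..5 each) and the five EQ-5D-5L dimension levels
    (1..5 each); ``None`` marks a missing instrument.
    """

    id: str
    enrollment_date: date
    site: str
    age_years: float
    sex: str | None          # "F" / "M" / None (missing)
    bmi: float
    regimen: PlaceboRegimen | None
    hospitalized_28d: bool
    promis_base: tuple[int, ...] | None = None
    promis_d28: tuple[int, ...] | None = None
    eq5d_base: tuple[int, ...] | None = None
    eq5d_d28: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise ValueError(f"patient {self.id}: age_years must be >= 18")
        if self.bmi <= 0:
            raise ValueError(f"patient {self.id}: bmi must be positive")
        for name, items, k in (
            ("promis_base", self.promis_base, 10),
            ("promis_d28", self.promis_d28, 10),
            ("eq5d_base", self.eq5d_base, 5),
            ("eq5d_d28", self.eq5d_d28, 5),
        ):
            if items is not None:
                if len(items) != k or any(not (1 <= int(v) <= 5) for v in items):
                    raise ValueError(f"patient {self.id}: {name} must be {k} items in 1..5")


@dataclass
class ComparisonSet:
    """Matched and nonmatched placebo patient-id sets for one treatment."""

    treatment: TreatmentSpec
    matched_ids: frozenset[str]
    nonmatched_ids: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.matched_ids & self.nonmatched_ids
        if overlap:
            raise ValueError(f"matched/nonmatched sets overlap: {sorted(overlap)[:5]}")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.matched_ids | self.nonmatched_ids

    @property
    def n_matched(self) -> int:
        return len(self.matched_ids)

    @property
    def n_nonmatched(self) -> int:
        return len(self.nonmatched_ids)


@dataclass(frozen=True)
class TwoByTwo:
    """Event table feeding the Beta posteriors: group a = matched, b = nonmatched."""

    events_a: int
    n_a: int
    events_b: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0 <= self.events_a <= self.n_a):
            raise ValueError("events_a must satisfy 0 <= events_a <= n_a")
        if not (0 <= self.events_b <= self.n_b):
            raise ValueError("events_b must satisfy 0 <= events_b <= n_b")


def regimen_matches(regimen: PlaceboRegimen | None, spec: TreatmentSpec) -> bool:
    """True iff route, dosing frequency and duration all equal the treatment's regimen."""
    if regimen is None:
        raise MissingRegimenError(
            f"patient regimen not recorded; cannot match against {spec.name}"
        )
    return regimen == spec.regimen


def build_comparison(
    spec: TreatmentSpec,
    records: Sequence[PatientRecord],
    *,
    include_unrecorded_in_nonmatched: bool = False,
    nonmatched_fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> ComparisonSet:
    """Construct the matched/nonmatched comparison sets for one treatment.

    Patients with an unrecorded regimen are never matched; by default they are
    excluded from the nonmatched pool as well.  ``nonmatched_fraction``
    optionally subsamples the eligible nonmatched pool (without replacement),
    since a trial may use only a proportion of the chronologically eligible
    nonmatched placebos.
    """
    if not records:
        raise ValueError("records must be nonempty")
    matched, nonmatched = [], []
    for rec in records:
        if not spec.contains(rec.enrollment_date):
            continue
        if rec.regimen is None:
            if include_unrecorded_in_nonmatched:
                nonmatched.append(rec.id)
            continue
        if regimen_matches(rec.regimen, spec):
            matched.append(rec.id)
        else:
            nonmatched.append(rec.id)
    if nonmatched_fraction is not None:
        if not (0.0 < nonmatched_fraction <= 1.0):
            raise ValueError("nonmatched_fraction must be in (0, 1]")
        # deterministic order before sampling so the draw depends only on rng state
        nonmatched.sort()
        rng = rng if rng is not None else np.random.default_rng(0)
        keep = max(1, int(round(nonmatched_fraction * len(nonmatched))))
        nonmatched = list(rng.choice(nonmatched, size=keep, replace=False))
    if not matched:
        warnings.warn(
            f"{spec.name}: no matched placebo patients in window", stacklevel=2
        )
    return ComparisonSet(
        treatment=spec,
        matched_ids=frozenset(matched),
        nonmatched_ids=frozenset(nonmatched),
    )


def extract_two_by_two(
    cs: ComparisonSet, records: Sequence[PatientRecord] | Mapping[str, PatientRecord]
) -> TwoByTwo:
    """Count 28-day hospitalizations in each group of a comparison set."""
    index = records if isinstance(records, Mapping) else {r.id: r for r in records}
    if not cs.nonmatched_ids:
        raise ValueError(
            f"{cs.treatment.name}: empty nonmatched set; no between-group table"
        )

    def _count(ids: frozenset[str]) -> int:
        total = 0
        for pid in ids:
            if pid not in index:
                raise KeyError(f"patient id {pid!r} not found in records")
            total += bool(index[pid].hospitalized_28d)
        return total

    return TwoByTwo(
        events_a=_count(cs.matched_ids),
        n_a=cs.n_matched,
        events_b=_count(cs.nonmatched_ids),
        n_b=cs.n_nonmatched,
    )


def overlap_matrix(comparisons: Sequence[ComparisonSet]) -> np.ndarray:
    """Symmetric matrix of shared-patient counts between comparison sets.

    Entry (j, k) counts patients in both comparison j and comparison k
    (matched or nonmatched); the diagonal holds each comparison's total size.
    """
    if len(comparisons) < 2:
        raise ValueError("need at least two comparisons")
    sets = [cs.all_ids for cs in comparisons]
    k = len(sets)
    out = np.zeros((k, k), dtype=int)
    for i in range(k):
        out[i, i] = len(sets[i])
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = len(sets[i] & sets[j])
    return out


# ---------------------------------------------------------------------------
# Tabular IO: one row per patient, documented column schema.

_PROMIS_BASE = [f"promis_base_{i}" for i in range(1, 11)]
_PROMIS_D28 = [f"promis_d28_{i}" for i in range(1, 11)]
_EQ5D_BASE = [f"eq5d_base_{i}" for i in range(1, 6)]
_EQ5D_D28 = [f"eq5d_d28_{i}" for i in range(1, 6)]

CSV_COLUMNS = (
    ["id", "enrollment_date", "site", "age_years", "sex", "bmi",
     "route", "doses_per_day", "duration_days", "hospitalized_28d"]
    + _PROMIS_BASE + _PROMIS_D28 + _EQ5D_BASE + _EQ5D_D28
)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "enrollment_date": r.enrollment_date.isoformat(),
            "site": r.site,
            "age_years": r.age_years,
            "sex": r.sex if r.sex is not None else "",
            "bmi": r.bmi,
            "route": r.regimen.route if r.regimen else "",
            "doses_per_day": r.regimen.doses_per_day if r.regimen else "",
            "duration_days": r.regimen.duration_days if r.regimen else "",
            "hospitalized_28d": int(r.hospitalized_28d),
        }
        for cols, items in (
            (_PROMIS_BASE, r.promis_base), (_PROMIS_D28, r.promis_d28),
            (_EQ5D_BASE, r.eq5d_base), (_EQ5D_D28, r.eq5d_d28),
        ):
            for c, v in zip(cols, items if items is not None else [""] * len(cols)):
                row[c] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _items(row: pd.Series, cols: list[str]) -> tuple[int, ...] | None:
    vals = [row[c] for c in cols]
    if any(pd.isna(v) or v == "" for v in vals):
        return None
    return tuple(int(v) for v in vals)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for _, row in frame.iterrows():
        route = row["route"]
        regimen = None
        if not (pd.isna(route) or route == ""):
            regimen = PlaceboRegimen(
                route=str(route),
                doses_per_day=int(row["doses_per_day"]),
                duration_days=int(row["duration_days"]),
            )
        sex = row["sex"]
        records.append(
            PatientRecord(
                id=str(row["id"]),
                enrollment_date=date.fromisoformat(str(row["enrollment_date"])),
                site=str(row["site"]),
                age_years=float(row["age_years"]),
                sex=None if (pd.isna(sex) or sex == "") else str(sex),
                bmi=float(row["bmi"]),
                regimen=regimen,
                hospitalized_28d=bool(int(row["hospitalized_28d"])),
                promis_base=_items(row, _PROMIS_BASE),
                promis_d28=_items(row, _PROMIS_D28),
                eq5d_base=_items(row, _EQ5D_BASE),
                eq5d_d28=_items(row, _EQ5D_D28),
            )
        )
    return records


def write_records(records: Iterable[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path, keep_default_na=False))


def write_comparison_manifest(comparisons: Sequence[ComparisonSet], path) -> None:
    """TSV manifest: treatment, patient_id, group in {matched, nonmatched}."""
    rows = []
    for cs in comparisons:
        for pid in sorted(cs.matched_ids):
            rows.append((cs.treatment.name, pid, "matched"))
        for pid in sorted(cs.nonmatched_ids):
            rows.append((cs.treatment.name, pid, "nonmatched"))
    pd.DataFrame(rows, columns=["treatment", "patient_id", "group"]).to_csv(
        path, sep="\t", index=False
    )
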