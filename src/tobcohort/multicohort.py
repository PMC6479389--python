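"""Time-staggered multi-cohort population model.

A population is represented as a stack of closed birth cohorts, one per
5-year birth quinquennium, each entering the model in age band 0–4 during
its birth period and propagated independently with the transition-rate
table of its *vintage* (birth-cohort-specific rates for older cohorts,
constant rates for recent ones). Calendar-year snapshots are assembled by
aligning cohort age to calendar time: a cohort born in [y, y+5) occupies
age band [a, a+5) during calendar years [y+a, y+a+5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import CohortConfig, ScenarioResult, run_cohort
from .mortality import ERRParams, MortalitySuite
from .transitions import TransitionTable

__all__ = [
    "BirthCohort",
    "PopulationSnapshot",
    "run_population",
    "total_deaths_prevented",
    "validate_against_reference",
    "ValidationResult",
]


@dataclass(frozen=True)
class BirthCohort:
    """One 5-year birth cohort of the population model."""

    birth_period_start: int  # first calendar year of the quinquennium
    initial_size: float
    rate_vintage: str = "default"

    def __post_init__(self) -> None:
        if self.initial_size < 0:
            raise ValueError("initial_size must be >= 0")


@dataclass
class PopulationSnapshot:
    """Population counts by 5-year age band at one calendar year."""

    year: int
    counts: dict[int, float] = field(default_factory=dict)

    def total(self, age_range: tuple[int, int] | None = None) -> float:
        if age_range is None:
            return sum(self.counts.values())
        lo, hi = age_range
        return sum(c for a, c in self.counts.items() if lo <= a and a + 4 <= hi)

    def to_frame(self) -> pd.DataFrame:
        ages = sorted(self.counts)
        return pd.DataFrame(
            {"year": self.year, "age_group": ages, "count": [self.counts[a] for a in ages]}
        )


def cohort_sizes_from_csv(path) -> list[BirthCohort]:
    frame = pd.read_csv(path)
    vintage = frame["rate_vintage"] if "rate_vintage" in frame.columns else None
    return [
        BirthCohort(
            int(r.birth_period_start),
            float(r.initial_size),
            str(vintage.iloc[i]) if vintage is not None else "default",
        )
        for i, r in enumerate(frame.itertuples())
    ]


def run_population(
    cohorts: Sequence[BirthCohort],
    tables: Mapping[str, TransitionTable] | TransitionTable,
    models: MortalitySuite,
    err: ERRParams = ERRParams(),
    horizon_year: int | None = None,
    snapshot_years: Sequence[int] | None = None,
    max_age: int = 105,
    hazard_timing: str = "destination",
) -> list[PopulationSnapshot]:
    """Propagate every birth cohort and assemble calendar-year snapshots.

    ``tables`` maps rate vintages to transition tables (a bare table is
    treated as the vintage every cohort uses). Snapshots are taken at the
    requested calendar years (default: every fifth year from the earliest
    birth period to the horizon) and include each cohort at the age band it
    occupies that year, up to ``max_age``.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    periods = sorted(c.birth_period_start for c in cohorts)
    if len(set(periods)) != len(periods):
        raise ValueError("birth periods must be non-overlapping")
    if isinstance(tables, TransitionTable):
        tables = {c.rate_vintage: tables for c in cohorts}
    missing = {c.rate_vintage for c in cohorts} - set(tables)
    if missing:
        raise ValueError(f"no transition table for rate vintage(s) {sorted(missing)}")

    if horizon_year is None:
        horizon_year = max(periods) + 5
    if snapshot_years is None:
        snapshot_years = list(range(min(periods), horizon_year + 1, 5))

    results: dict[int, ScenarioResult] = {}
    for c in cohorts:
        horizon_age = min(max_age, horizon_year - c.birth_period_start)
        if horizon_age <= 0 or c.initial_size == 0:
            continue
        cfg = CohortConfig(
            initial_size=c.initial_size,
            start_age=0,
            end_age=horizon_age,
            hazard_timing=hazard_timing,
        )
        results[c.birth_period_start] = run_cohort(cfg, tables[c.rate_vintage], models, err)

    snapshots = []
    for year in snapshot_years:
        snap = PopulationSnapshot(year)
        for c in cohorts:
            age = year - c.birth_period_start
            if age < 0 or age >= max_age:
                continue
            res = results.get(c.birth_period_start)
            if res is None:
                if c.initial_size == 0:
                    continue
                snap.counts[age] = snap.counts.get(age, 0.0)
                continue
            if age in res.occupancy:
                snap.counts[age] = snap.counts.get(age, 0.0) + res.survivors(age)
        snapshots.append(snap)
    return snapshots


def _snapshot_for(snapshots, year: int | None) -> PopulationSnapshot:
    if isinstance(snapshots, PopulationSnapshot):
        return snapshots
    if year is None:
        return snapshots[-1]
    for s in snapshots:
        if s.year == year:
            return s
    raise ValueError(f"no snapshot for year {year}")


def total_deaths_prevented(
    base_snapshots,
    modified_snapshots,
    year: int | None = None,
    age_range: tuple[int, int] = (0, 84),
) -> tuple[float, pd.DataFrame]:
    """Modified-minus-Base survivor difference by age band and its total.

    Operates on one calendar-year snapshot from each scenario (pass lists
    plus ``year``, or the snapshots themselves); the total sums the
    per-band differences over bands falling wholly inside ``age_range``.
    """
    base = _snapshot_for(base_snapshots, year)
    mod = _snapshot_for(modified_snapshots, year)
    if base.year != mod.year:
        raise ValueError(f"snapshot years differ: {base.year} vs {mod.year}")
    if set(base.counts) != set(mod.counts):
        raise ValueError("snapshots have mismatched age structures")
    ages = sorted(base.counts)
    frame = pd.DataFrame(
        {
            "age_group": ages,
            "modified": [mod.counts[a] for a in ages],
            "base": [base.counts[a] for a in ages],
        }
    )
    frame["difference"] = frame["modified"] - frame["base"]
    lo, hi = age_range
    in_range = frame["age_group"].between(lo, hi - 4)
    return float(frame.loc[in_range, "difference"].sum()), frame


@dataclass
class ValidationResult:
    """Percent difference of a model total against a reference total."""

    percent_total: float
    per_band: pd.DataFrame | None = None


def validate_against_reference(snapshot, reference) -> ValidationResult:
    """Percent difference between model and reference population counts.

    ``100 · (model_total − reference_total) / reference_total``; accepts
    scalar totals, or a snapshot/mapping against per-band reference counts
    (in which case per-band percent differences are also reported).
    """
    if np.isscalar(snapshot) and np.isscalar(reference):
        if reference == 0:
            raise ValueError("reference total is zero")
        return ValidationResult(100.0 * (snapshot - reference) / reference)

    model_counts = snapshot.counts if isinstance(snapshot, PopulationSnapshot) else dict(snapshot)
    ref_counts = reference.counts if isinstance(reference, PopulationSnapshot) else dict(reference)
    if set(model_counts) != set(ref_counts):
        raise ValueError("model and reference have mismatched age structures")
    ref_total = sum(ref_counts.values())
    if ref_total == 0:
        raise ValueError("reference total is zero")
    ages = sorted(model_counts)
    per_band = pd.DataFrame(
        {
            "age_group": ages,
            "model": [model_counts[a] for a in ages],
            "reference": [ref_counts[a] for a in ages],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_band["percent_diff"] = (
            100.0 * (per_band["model"] - per_band["reference"]) / per_band["reference"]
        )
    total = 100.0 * (sum(model_counts.values()) - ref_total) / ref_total
    return ValidationResult(total, per_band)
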