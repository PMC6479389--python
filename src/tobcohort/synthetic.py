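"""Seeded generators for every input shape the pipeline consumes.

No microdata behind this model are deposited anywhere, so the package
ships generators with known ground truth for all four input kinds:
mortality exposure tables (person-years and deaths over an age × YSM ×
YQSM grid, one per user group), age-specific transition-rate tables,
behavioural-intention summaries, and census-style birth-cohort sizes.
Parameter-recovery and end-to-end tests run against these.

The default :class:`SyntheticSpec` *is* the bundled reference scenario:
Gompertz-like mortality truth chosen so never-user survival resembles a
male life table and the smoker relative risk sits around 2–3 at mid-life,
the published base switch (1.4%) and MST-initiation (1.6%) rates, ERR
ratios 0.09/0.04 and diversion fractions 1%/5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets
from .multicohort import BirthCohort
from .statespace import UseCategory, build_default_catalogue
from .transitions import IntentionSummary, ScenarioDelta, TransitionTable
from .mortality import ERRParams

__all__ = [
    "SyntheticSpec",
    "gen_mortality",
    "gen_transitions",
    "gen_intentions",
    "gen_cohort_sizes",
    "reference_delta",
]

#: ground-truth log-rate coefficients (deaths per 100,000 person-years)
DEFAULT_BETA = {
    "never": {"const": 1.8, "age": 0.095, "age2": -1e-4},
    "current": {
        "const": 1.8, "age": 0.095, "age2": -1e-4,
        "ysm": 0.045, "ysm_age": -3.5e-4,
    },
    "former": {
        "const": 1.8, "age": 0.095, "age2": -1e-4,
        "ysm": 0.045, "yqsm": -0.02, "ysm_age": -3.5e-4, "yqsm_age": 1.5e-4,
    },
}

#: base-case transition rates per 5-year step; age-profile keys are band
#: starts, scalar means constant over all ages
C = UseCategory
DEFAULT_TRANSITION_PROFILES: dict[tuple[UseCategory, UseCategory], object] = {
    (C.NEVER, C.CUR_CIG): {13: 0.10, 18: 0.12, 23: 0.04, 28: 0.01, "default": 0.002},
    (C.NEVER, C.CUR_MST): {13: presets.BASE_MST_INITIATION_RATE,
                           18: presets.BASE_MST_INITIATION_RATE,
                           23: presets.BASE_MST_INITIATION_RATE,
                           "default": 0.0},
    (C.CUR_CIG, C.CUR_MST): presets.BASE_SWITCH_RATE,
    (C.CUR_CIG, C.DUAL): 0.03,
    (C.CUR_MST, C.DUAL): 0.02,
    (C.DUAL, C.CUR_MST): 0.174,
    (C.DUAL, C.CUR_CIG): 0.25,
    (C.CUR_CIG, C.FORMER_CIG): {"default": 0.05, 43: 0.10, 48: 0.10, 53: 0.10, 58: 0.10,
                                63: 0.15, 68: 0.15, 73: 0.15, 78: 0.15, 83: 0.15,
                                88: 0.15, 93: 0.15, 98: 0.15},
    (C.CUR_MST, C.FORMER_MST): 0.10,
    (C.DUAL, C.FORMER_DUAL): 0.05,
    (C.FORMER_CIG, C.CUR_CIG): 0.0,   # relapse: no reliable estimate, kept at 0
    (C.FORMER_MST, C.CUR_MST): 0.0,
    (C.FORMER_DUAL, C.DUAL): 0.0,
}


@dataclass
class SyntheticSpec:
    """Fully determines every generator output given its seed."""

    seed: int = 0
    beta: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BETA.items()})
    person_years_per_cell: float = 200_000.0
    age_midpoints: tuple = tuple(np.arange(17.5, 100.0, 5.0))
    transition_profiles: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_PROFILES)
    )
    table_ages: tuple = tuple(range(13, 103, 5))
    intentions: pd.DataFrame = field(default_factory=lambda: presets.INTENTIONS.copy())
    n_cohorts: int = 21
    first_birth_period: int = 1910
    cohort_size_range: tuple[float, float] = (4.0e6, 11.5e6)

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _truth_rate(beta: dict[str, float], age: float, ysm: float = 0.0, yqsm: float = 0.0) -> float:
    """Ground-truth rate per 100,000 person-years."""
    x = beta["const"] + beta["age"] * age + beta["age2"] * age**2
    x += beta.get("ysm", 0.0) * ysm + beta.get("ysm_age", 0.0) * ysm * age
    x += beta.get("yqsm", 0.0) * yqsm + beta.get("yqsm_age", 0.0) * yqsm * age
    return float(np.exp(x))


def gen_mortality(spec: SyntheticSpec) -> pd.DataFrame:
    """Synthetic exposure table: deaths ~ Poisson(PY · λ_truth / 100,000).

    One record per covariate cell on a factorial grid of age × YSM × YQSM
    consistent with each group's constraints (never users carry no smoking
    durations; current smokers no quit duration; smoking assumed to start
    no earlier than ~13). Columns: age, ysm, yqsm, person_years, deaths,
    group.
    """
    rng = spec.rng(stream=1)
    py = spec.person_years_per_cell
    rows = []
    for age in spec.age_midpoints:
        max_dur = age - 12.5  # durations cannot pre-date adolescence
        ysm_values = np.arange(5.0, min(max_dur, 60.0) + 1e-9, 5.0)
        rows.append(("never", age, 0.0, 0.0))
        for ysm in ysm_values:
            rows.append(("current", age, ysm, 0.0))
            for yqsm in np.arange(5.0, min(max_dur - ysm, 60.0) + 1e-9, 5.0):
                rows.append(("former", age, ysm, yqsm))
    out = []
    for group, age, ysm, yqsm in rows:
        lam = _truth_rate(spec.beta[group], age, ysm, yqsm)
        deaths = int(rng.poisson(py * lam / 1e5))
        out.append((age, ysm, yqsm, py, deaths, group))
    return pd.DataFrame(
        out, columns=["age", "ysm", "yqsm", "person_years", "deaths", "group"]
    )


def truth_suite(spec: SyntheticSpec | None = None):
    """MortalitySuite built from the generator's ground-truth coefficients.

    Noise-free reference models (no covariance): fitted suites converge to
    this as the generated exposure grows.
    """
    from .mortality import DESIGNS, MortalityResults, MortalitySuite

    beta = (spec or SyntheticSpec()).beta
    results = {}
    for group, names in DESIGNS.items():
        params = np.array([beta[group].get(n, 0.0) for n in names])
        results[group] = MortalityResults(group=group, names=list(names), params=params)
    return MortalitySuite(**results)


def _profile_rate(profile, age: int) -> float:
    """Rate for an age band from a scalar or a banded age profile.

    Dict profiles are keyed by band-start age; a lookup matches the key
    falling in the same 5-year band as ``age`` (so profiles written on the
    13, 18, ... grid also serve tables on the 0, 5, 10, ... grid), with a
    ``"default"`` fallback.
    """
    if not isinstance(profile, dict):
        return float(profile)
    for key, r in profile.items():
        if key != "default" and age - 5 < key <= age:
            return float(r)
    return float(profile.get("default", 0.0))


def gen_transitions(spec: SyntheticSpec) -> TransitionTable:
    """Base Case transition table over the spec's age bands."""
    ages = list(spec.table_ages)
    rates = {}
    for (s, t), profile in spec.transition_profiles.items():
        for a in ages:
            rates[(a, s, t)] = _profile_rate(profile, a)
    table = TransitionTable(ages, rates)
    # generated tables must satisfy the consuming row-sum invariant as-is
    table.validate()
    return table


def gen_intentions(spec: SyntheticSpec) -> dict[str, IntentionSummary]:
    """Behavioural-intention summaries (the bundled study proportions)."""
    return presets.intention_summaries(spec.intentions)


def reference_delta(
    spec: SyntheticSpec | None = None, use_rounded_deltas: bool = False
) -> ScenarioDelta:
    """Modified-Case recipe implied by the spec's intention summaries."""
    from .transitions import relative_percent_change, whole_percent

    summaries = gen_intentions(spec or SyntheticSpec())
    deltas = {}
    for behavior, summary in summaries.items():
        d = relative_percent_change(summary)
        if use_rounded_deltas:
            d = whole_percent(d) / 100.0
        deltas[presets.INTENTION_EDGES[behavior]] = d
    return ScenarioDelta(
        deltas,
        would_be_smoker=presets.WOULD_BE_SMOKER_FRACTION,
        would_be_quitter=presets.WOULD_BE_QUITTER_FRACTION,
    )


def gen_cohort_sizes(spec: SyntheticSpec) -> list[BirthCohort]:
    """Census-style birth-cohort sizes, growing across the century."""
    sizes = np.linspace(*spec.cohort_size_range, spec.n_cohorts)
    return [
        BirthCohort(spec.first_birth_period + 5 * i, float(round(s)))
        for i, s in enumerate(sizes)
    ]


def population_table_ages() -> tuple:
    """Age bands for multicohort runs (birth through the open final band)."""
    return tuple(range(0, 105, 5))


def gen_population_transitions(spec: SyntheticSpec) -> TransitionTable:
    """Base Case table extended to birth: zero rates below age 13."""
    ext = replace(spec, table_ages=population_table_ages())
    profiles = {}
    for pair, profile in spec.transition_profiles.items():
        if isinstance(profile, dict):
            profiles[pair] = {**{a: 0.0 for a in range(0, 13, 5)}, **profile}
        else:
            profiles[pair] = {a: (0.0 if a < 13 else float(profile)) for a in ext.table_ages}
    ext.transition_profiles = profiles
    return gen_transitions(ext)
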