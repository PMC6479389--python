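"""Hand-built oracles shared across test modules."""

import math

import numpy as np

from tobcohort.mortality import (
    ERRParams,
    MortalityResults,
    MortalitySuite,
    pathway_hazard,
    survival_5y,
)
from tobcohort.statespace import ExpandedState, UseCategory, step_state


def constant_rate_results(group: str, rate_per_100k: float) -> MortalityResults:
    """Model whose rate ignores age and durations (closed-form oracle)."""
    n = {"never": 3, "current": 5, "former": 7}[group]
    params = np.zeros(n)
    params[0] = math.log(rate_per_100k)
    names = ["const", "age", "age2", "ysm", "yqsm", "ysm_age", "yqsm_age"][:n]
    return MortalityResults(group=group, names=names, params=params)


def constant_suite(never=100.0, current=300.0, former=150.0) -> MortalitySuite:
    return MortalitySuite(
        constant_rate_results("never", never),
        constant_rate_results("current", current),
        constant_rate_results("former", former),
    )


def zero_hazard_suite() -> MortalitySuite:
    return constant_suite(1e-12, 1e-12, 1e-12)


def enumerate_survivors(cfg, table, models, err=ERRParams()):
    """Exhaustive pathway enumeration: independent oracle for run_cohort.

    Sums probability × pathway survival over every category pathway; only
    tractable for tiny catalogues and horizons.
    """
    final: dict[ExpandedState, float] = {}

    def recurse(state, age_idx, prob):
        ages = cfg.band_starts
        if age_idx == len(ages):
            final[state] = final.get(state, 0.0) + prob * cfg.initial_size
            return
        a = ages[age_idx]
        outs = table.outgoing(a, state.category)
        options = [(pair, r) for pair, r in outs.items() if r > 0]
        options.append((None, 1.0 - sum(r for _, r in options)))
        for pair, p in options:
            dest = step_state(state, pair)
            s = survival_5y(pathway_hazard(dest, a + 2.5, models, err))
            recurse(dest, age_idx + 1, prob * p * s)

    recurse(ExpandedState(UseCategory.NEVER), 0, 1.0)
    return final
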