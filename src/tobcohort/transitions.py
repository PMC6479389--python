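"""Age-specific transition rates and scenario derivation.

The Base Case scenario is a table of per-5-year transition probabilities on
the edges of a :class:`~tobcohort.statespace.EdgeCatalogue`, indexed by
5-year age band. The Modified Case is derived from it in two moves:

* *relative-change scaling* — behavioural-intention studies report, for each
  key transition, the pre/post proportion of respondents likely to engage in
  the behaviour under a test (claim-exposed) and a control condition. The
  relative difference of the two pre→post ratios is applied multiplicatively
  to the corresponding Base Case rate;
* *diversion rerouting* — two hypothetical flows that cannot be measured
  pre-market: "would-be smokers" (a fraction of never-users who would have
  initiated cigarettes initiate MST instead) and "would-be quitters" (a
  fraction of smokers who would have quit switch to MST instead). Diversions
  reroute existing flow; they never create probability mass.

Rate uncertainty is propagated by redrawing initiation and cessation rates
from a truncated normal on [0, 1] centred at the stated rate.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .statespace import Edge, UseCategory

__all__ = [
    "TransitionTable",
    "RateUncertainty",
    "IntentionSummary",
    "ScenarioDelta",
    "relative_percent_change",
    "whole_percent",
    "apply_relative_change",
    "derive_modified_table",
    "draw_rates",
]

Pair = tuple[UseCategory, UseCategory]

#: endpoints of the flows the diversion fractions reroute
CIG_INITIATION: Pair = (UseCategory.NEVER, UseCategory.CUR_CIG)
MST_INITIATION: Pair = (UseCategory.NEVER, UseCategory.CUR_MST)
CIG_CESSATION: Pair = (UseCategory.CUR_CIG, UseCategory.FORMER_CIG)
SWITCHING: Pair = (UseCategory.CUR_CIG, UseCategory.CUR_MST)

_ROW_TOL = 1e-9


def _as_pair(edge) -> Pair:
    if isinstance(edge, Edge):
        return edge.pair
    s, t = edge
    return (UseCategory(s), UseCategory(t))


@dataclass
class TransitionTable:
    """Per-5-year transition probabilities by (age band, edge).

    ``rates`` maps ``(age_band_start, source, target)`` to a probability in
    [0, 1]. For every (age band, source) the outgoing probabilities must sum
    to at most 1; the residual is the probability of staying. Missing
    entries are zero.
    """

    ages: list[int]
    rates: dict[tuple[int, UseCategory, UseCategory], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = sorted(int(a) for a in self.ages)
        self.validate()

    # -- access ------------------------------------------------------------
    def get(self, age: int, edge) -> float:
        s, t = _as_pair(edge)
        return self.rates.get((age, s, t), 0.0)

    def set(self, age: int, edge, rate: float) -> None:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate {rate} outside [0, 1] for {edge} at age {age}")
        s, t = _as_pair(edge)
        self.rates[(age, s, t)] = float(rate)

    def set_all_ages(self, edge, rate: float) -> None:
        for a in self.ages:
            self.set(a, edge, rate)

    def outgoing(self, age: int, source: UseCategory) -> dict[Pair, float]:
        return {
            (s, t): r for (a, s, t), r in self.rates.items() if a == age and s == source
        }

    def row_sum(self, age: int, source: UseCategory) -> float:
        return sum(self.outgoing(age, source).values())

    @property
    def pairs(self) -> set[Pair]:
        return {(s, t) for (_, s, t) in self.rates}

    def copy(self) -> "TransitionTable":
        return TransitionTable(list(self.ages), dict(self.rates))

    def validate(self) -> None:
        sums: dict[tuple[int, UseCategory], float] = {}
        for (a, s, t), r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1] on edge ({s}->{t}) at age {a}")
            if a not in self.ages:
                raise ValueError(f"age band {a} not declared in table ages")
            sums[(a, s)] = sums.get((a, s), 0.0) + r
        for (a, s), tot in sums.items():
            if tot > 1.0 + _ROW_TOL:
                raise ValueError(
                    f"outgoing rates from {s} at age {a} sum to {tot:.6f} > 1"
                )

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, s.value, t.value, r)
            for (a, s, t), r in sorted(self.rates.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value))
        ]
        return pd.DataFrame(rows, columns=["age_group", "from_category", "to_category", "rate_fraction"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransitionTable":
        if "rate_fraction" in frame.columns:
            vals = frame["rate_fraction"].astype(float)
        elif "rate_percent" in frame.columns:
            vals = frame["rate_percent"].astype(float) / 100.0
        else:
            raise ValueError("table needs a rate_fraction or rate_percent column")
        rates = {}
        for row, r in zip(frame.itertuples(), vals):
            rates[(int(row.age_group), UseCategory(row.from_category), UseCategory(row.to_category))] = float(r)
        ages = sorted({a for (a, _, _) in rates})
        return cls(ages, rates)

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class RateUncertainty:
    """Truncated-normal uncertainty on a transition rate.

    ``sd`` is in probability points (default 0.02, i.e. 2 percentage
    points); the support is the probability interval [lower, upper].
    """

    sd: float = 0.02
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")


@dataclass(frozen=True)
class IntentionSummary:
    """Pre/post proportions of respondents likely to engage in a behaviour.

    Proportions may be given on any common scale (fractions or percent);
    only ratios are used. All four must be strictly positive.
    """

    control_pre: float
    control_post: float
    test_pre: float
    test_post: float

    def __post_init__(self) -> None:
        if min(self.control_pre, self.control_post, self.test_pre, self.test_post) <= 0:
            raise ValueError("all four proportions must be strictly positive")


@dataclass
class ScenarioDelta:
    """Modified-Case recipe: per-edge relative changes plus diversion fractions."""

    deltas: dict[Pair, float] = field(default_factory=dict)
    would_be_smoker: float = 0.01
    would_be_quitter: float = 0.05

    def __post_init__(self) -> None:
        self.deltas = {_as_pair(k): float(v) for k, v in self.deltas.items()}
        for pair, d in self.deltas.items():
            if d < -1:
                raise ValueError(f"relative change {d} < -1 on edge {pair}")
        for name in ("would_be_smoker", "would_be_quitter"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} fraction {f} outside [0, 1]")


def relative_percent_change(s: IntentionSummary) -> float:
    """Relative difference between test and control pre→post change ratios.

    Returns the signed dimensionless change
    ``((test_post/test_pre) - (control_post/control_pre)) / (control_post/control_pre)``,
    the quantity applied multiplicatively to a Base Case rate. A negative
    value means claim exposure reduced the likelihood of the behaviour
    relative to control.
    """
    control_ratio = s.control_post / s.control_pre
    test_ratio = s.test_post / s.test_pre
    return (test_ratio - control_ratio) / control_ratio


def whole_percent(delta: float) -> int:
    """Report a relative change as a whole percent (presentation helper)."""
    return int(round(100.0 * delta))


def apply_relative_change(base_rate: float, delta: float) -> float:
    """Scale a transition probability by a relative change, clipped to [0, 1]."""
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError(f"base_rate {base_rate} outside [0, 1]")
    if delta < -1:
        raise ValueError(f"relative change {delta} < -1")
    out = base_rate * (1.0 + delta)
    if out > 1.0:
        warnings.warn(f"scaled rate {out:.4f} capped at 1", stacklevel=2)
        return 1.0
    return max(out, 0.0)


def derive_modified_table(base: TransitionTable, delta: ScenarioDelta) -> TransitionTable:
    """Derive the Modified Case transition table from the Base Case.

    Listed edges are scaled by their relative change; the would-be-smoker
    fraction of the Base Case cigarette-initiation flow and the would-be-
    quitter fraction of the Base Case cigarette-cessation flow are rerouted
    to MST use (sources reduced by exactly the rerouted amount). Unlisted
    edges are unchanged and the per-source row-sum invariant is re-validated.
    """
    for pair in delta.deltas:
        if not any((a, *pair) in base.rates for a in base.ages):
            raise ValueError(f"delta edge {pair} absent from base table")

    out = base.copy()
    for pair, d in delta.deltas.items():
        for a in base.ages:
            key = (a, *pair)
            if key in base.rates:
                out.rates[key] = apply_relative_change(base.rates[key], d)

    for a in base.ages:
        if delta.would_be_smoker > 0:
            moved = delta.would_be_smoker * base.get(a, CIG_INITIATION)
            if moved > 0:
                out.rates[(a, *CIG_INITIATION)] = out.get(a, CIG_INITIATION) - moved
                out.rates[(a, *MST_INITIATION)] = out.get(a, MST_INITIATION) + moved
        if delta.would_be_quitter > 0:
            moved = delta.would_be_quitter * base.get(a, CIG_CESSATION)
            if moved > 0:
                out.rates[(a, *CIG_CESSATION)] = out.get(a, CIG_CESSATION) - moved
                out.rates[(a, *SWITCHING)] = out.get(a, SWITCHING) + moved

    for key, r in out.rates.items():
        if r < -_ROW_TOL:
            raise ValueError(f"derived rate negative on {key}")
        out.rates[key] = min(max(r, 0.0), 1.0)
    out.validate()
    return out


def _default_uncertain_pairs(table: TransitionTable) -> set[Pair]:
    """Initiation (out of NEVER) and cessation (into a FORMER category) edges."""
    former = {
        UseCategory.FORMER_CIG,
        UseCategory.FORMER_MST,
        UseCategory.FORMER_DUAL,
        UseCategory.FORMER_ALL,
    }
    return {
        (s, t)
        for (s, t) in table.pairs
        if s == UseCategory.NEVER or t in former
    }


def draw_rates(
    base: TransitionTable,
    unc: RateUncertainty = RateUncertainty(),
    seed: int | np.random.Generator | None = None,
    edges: Iterable | None = None,
    max_redraws: int = 100,
) -> TransitionTable:
    """Draw an uncertain realisation of a transition table.

    Each selected rate is replaced by a truncated-normal draw with mean equal
    to the stated rate, standard deviation ``unc.sd`` and support
    [``unc.lower``, ``unc.upper``]; by default initiation and cessation edges
    are redrawn and all others kept fixed. Rows whose drawn outgoing
    probabilities would exceed 1 are redrawn wholesale (rejection).

    Only entries with a strictly positive stated rate are perturbed (a rate
    the table does not carry has no uncertainty attached). Each draw's
    underlying uniform is keyed to the *content* of its entry — seed plus a
    hash of (age, source, target) — rather than to iteration order, so two
    tables drawn from the same seed receive common random numbers on their
    shared edges: identical tables yield identical draws exactly.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    pairs = _default_uncertain_pairs(base) if edges is None else {_as_pair(e) for e in edges}

    out = base.copy()
    # group selected entries by (age, source) so rejection operates per row
    rows: dict[tuple[int, UseCategory], list[tuple[int, UseCategory, UseCategory]]] = {}
    for (a, s, t) in sorted(base.rates, key=lambda k: (k[0], k[1].value, k[2].value)):
        if (s, t) in pairs and base.rates[(a, s, t)] > 0.0:
            rows.setdefault((a, s), []).append((a, s, t))

    for (a, s), keys in rows.items():
        fixed = sum(
            r for (aa, ss, tt), r in base.rates.items()
            if aa == a and ss == s and ((ss, tt) not in pairs or r == 0.0)
        )
        means = np.array([base.rates[k] for k in keys])
        alpha = (unc.lower - means) / unc.sd
        beta = (unc.upper - means) / unc.sd
        crcs = [
            zlib.crc32(f"{aa}:{ss.value}:{tt.value}".encode()) for (aa, ss, tt) in keys
        ]
        for attempt in range(max_redraws):
            u = np.array(
                [np.random.default_rng([seed, c, attempt]).random() for c in crcs]
            )
            draws = stats.truncnorm.ppf(u, alpha, beta, loc=means, scale=unc.sd)
            if fixed + draws.sum() <= 1.0 + _ROW_TOL:
                break
        else:
            raise RuntimeError(
                f"row ({a}, {s}) rejected {max_redraws} redraws; rates too close to 1"
            )
        for k, d in zip(keys, draws):
            out.rates[k] = float(min(max(d, 0.0), 1.0))
    out.validate()
    return out
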