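"""Poisson mortality models, excess-relative-risk scaling and survival.

Three all-cause mortality models — never users, current cigarette smokers
and former cigarette smokers — are Poisson regressions of death counts on
age and smoking-duration covariates with a person-years exposure offset.
Rates are on the scale of deaths per 100,000 person-years:

* never:    ``ln λ = β0 + β1·AGE + β2·AGE²``
* current:  adds ``β3·YSM + β4·YSM·AGE``
* former:   adds ``β3·YSM + β4·YQSM + β5·YSM·AGE + β6·YQSM·AGE``

where YSM is years smoked and YQSM years since quitting.

MST (moist smokeless tobacco) carries no fitted model of its own; its
hazard is obtained by scaling the *excess* risk of the corresponding
smoking state by an excess-relative-risk (ERR) ratio,

    ERR ratio = (RR_product − 1) / (RR_cigarette − 1),

so an ERR ratio of 0.09 means the product retains 9% of smoking's excess
mortality. The hazard of a full use pathway is the never-user baseline
multiplied by one relative-risk factor per exposure component (current or
former smoking, current or former MST use), each evaluated at the
pathway's own durations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .statespace import (
    MST_CATEGORIES,
    SMOKING_CATEGORIES,
    DurationProfile,
    ExpandedState,
    UseCategory,
    _advance_durations,
)

__all__ = [
    "MortalityRecord",
    "PoissonMortalityModel",
    "MortalityResults",
    "MortalitySuite",
    "ERRParams",
    "fit_mortality_model",
    "fit_suite",
    "err_ratio",
    "pathway_hazard",
    "survival_5y",
    "survival_curve",
    "pathway_from_categories",
    "DESIGNS",
]

#: predictor lists per user group (deaths-per-100,000-person-years scale)
DESIGNS: dict[str, list[str]] = {
    "never": ["const", "age", "age2"],
    "current": ["const", "age", "age2", "ysm", "ysm_age"],
    "former": ["const", "age", "age2", "ysm", "yqsm", "ysm_age", "yqsm_age"],
}


@dataclass(frozen=True)
class MortalityRecord:
    """One exposure cell: person-years and deaths for a covariate combination."""

    age: float  # midpoint of a 5-year band, years
    ysm: float  # years smoked
    yqsm: float  # years since quitting smoking
    person_years: float
    deaths: int
    group: str  # never | current | former

    def __post_init__(self) -> None:
        if self.group not in DESIGNS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.person_years <= 0:
            raise ValueError("person_years must be > 0")
        if self.deaths < 0:
            raise ValueError("deaths must be >= 0")
        if self.group == "never" and (self.ysm != 0 or self.yqsm != 0):
            raise ValueError("never-user records must have ysm = yqsm = 0")
        if self.group == "current" and self.yqsm != 0:
            raise ValueError("current-smoker records must have yqsm = 0")


def records_to_frame(records: Iterable[MortalityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _design_matrix(frame: pd.DataFrame, group: str) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "age": frame["age"].astype(float),
            "age2": frame["age"].astype(float) ** 2,
            "ysm": frame.get("ysm", 0.0),
            "yqsm": frame.get("yqsm", 0.0),
        }
    )
    X["ysm_age"] = X["ysm"] * X["age"]
    X["yqsm_age"] = X["yqsm"] * X["age"]
    return X[DESIGNS[group]]


class PoissonMortalityModel:
    """Poisson mortality regression for one user group.

    Built from exposure records (``MortalityRecord`` objects or a DataFrame
    with columns age, ysm, yqsm, person_years, deaths); ``fit()`` returns a
    :class:`MortalityResults` carrying coefficient estimates, their
    covariance and rate predictions.
    """

    def __init__(self, records, group: str):
        if group not in DESIGNS:
            raise ValueError(f"unknown group {group!r}")
        if isinstance(records, pd.DataFrame):
            frame = records.copy()
            if "group" in frame.columns:
                frame = frame[frame["group"] == group]
        else:
            records = list(records)
            if any(r.group != group for r in records):
                raise ValueError("records must all belong to the fitted group")
            frame = records_to_frame(records)
        if frame.empty:
            raise ValueError(f"no records for group {group!r}")
        if frame["deaths"].sum() == 0:
            raise ValueError("degenerate likelihood: zero deaths in every record")
        self.group = group
        self.frame = frame.reset_index(drop=True)
        self.exog = _design_matrix(self.frame, group)
        if len(self.frame) < self.exog.shape[1]:
            raise ValueError(
                f"need at least {self.exog.shape[1]} records to fit {group} design"
            )
        self.offset = np.log(self.frame["person_years"].astype(float) / 1e5)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, group: str) -> "PoissonMortalityModel":
        return cls(frame, group)

    def fit(self) -> "MortalityResults":
        glm = sm.GLM(
            self.frame["deaths"].astype(float),
            self.exog,
            family=sm.families.Poisson(),
            offset=self.offset,
        )
        try:
            res = glm.fit()
        except Exception as exc:  # singular design, separation
            rank = np.linalg.matrix_rank(self.exog.to_numpy())
            raise ValueError(
                f"{self.group} model failed to fit (design rank {rank} of "
                f"{self.exog.shape[1]} columns): {exc}"
            ) from exc
        if not np.all(np.isfinite(res.params)) or not np.all(
            np.isfinite(res.cov_params())
        ):
            raise ValueError(f"{self.group} fit produced non-finite estimates")
        return MortalityResults(
            group=self.group,
            names=list(self.exog.columns),
            params=np.asarray(res.params, dtype=float),
            cov=np.asarray(res.cov_params(), dtype=float),
            sm_results=res,
        )


def fit_mortality_model(records, group: str) -> "MortalityResults":
    """Fit the group's Poisson mortality model; convenience wrapper."""
    return PoissonMortalityModel(records, group).fit()


@dataclass
class MortalityResults:
    """Fitted (or parameter-substituted) mortality model for one group."""

    group: str
    names: list[str]
    params: np.ndarray
    cov: np.ndarray | None = None
    sm_results: object | None = None

    def rate(self, age: float, ysm: float = 0.0, yqsm: float = 0.0) -> float:
        """Mortality rate per 100,000 person-years at the given covariates."""
        b = self.params
        x = b[0] + b[1] * age + b[2] * age * age
        if self.group == "current":
            x += b[3] * ysm + b[4] * ysm * age
        elif self.group == "former":
            x += b[3] * ysm + b[4] * yqsm + b[5] * ysm * age + b[6] * yqsm * age
        out = math.exp(x)
        if not math.isfinite(out):
            raise ValueError(
                f"{self.group} rate not finite at age={age}, ysm={ysm}, yqsm={yqsm}"
            )
        return out

    def bse(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("no covariance available")
        return np.sqrt(np.diag(self.cov))

    def sample_params(self, rng: np.random.Generator) -> np.ndarray:
        """One posterior draw of β (normal approximation, flat prior)."""
        if self.cov is None:
            raise ValueError("no covariance available for sampling")
        return rng.multivariate_normal(self.params, self.cov, method="cholesky")

    def with_params(self, params: np.ndarray) -> "MortalityResults":
        return replace(self, params=np.asarray(params, dtype=float), sm_results=None)

    def sample_posterior_metropolis(
        self,
        model: PoissonMortalityModel,
        n_samples: int,
        seed: int | np.random.Generator,
        step_scale: float = 0.5,
        burn: int = 500,
    ) -> np.ndarray:
        """Random-walk Metropolis draws of β under a flat prior.

        Verification path for the default normal approximation; proposals
        are N(0, step_scale²·cov).
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        X = model.exog.to_numpy()
        y = model.frame["deaths"].to_numpy(dtype=float)
        off = model.offset.to_numpy()
        chol = np.linalg.cholesky(self.cov) * step_scale

        def loglik(beta: np.ndarray) -> float:
            eta = X @ beta + off
            return float(y @ eta - np.exp(eta).sum())

        beta = self.params.copy()
        ll = loglik(beta)
        out = np.empty((n_samples, beta.size))
        kept = 0
        i = 0
        while kept < n_samples:
            prop = beta + chol @ rng.standard_normal(beta.size)
            ll_prop = loglik(prop)
            if math.log(rng.random()) < ll_prop - ll:
                beta, ll = prop, ll_prop
            i += 1
            if i > burn:
                out[kept] = beta
                kept += 1
        return out

    def summary(self):
        if self.sm_results is not None:
            return self.sm_results.summary()
        return pd.DataFrame({"coef": self.params}, index=self.names)

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "group": self.group,
            "names": self.names,
            "params": self.params.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MortalityResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cov = payload.get("cov")
        return cls(
            group=payload["group"],
            names=list(payload["names"]),
            params=np.asarray(payload["params"], dtype=float),
            cov=None if cov is None else np.asarray(cov, dtype=float),
        )


@dataclass(frozen=True)
class ERRParams:
    """Excess-relative-risk ratios of MST use versus cigarette smoking."""

    err_current: float = 0.09
    err_former: float = 0.04

    def __post_init__(self) -> None:
        for name in ("err_current", "err_former"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                warnings.warn(
                    f"{name}={v} outside the conventional [0, 1] reference scale",
                    stacklevel=2,
                )


@dataclass
class MortalitySuite:
    """The three fitted group models, bundled for pathway evaluation."""

    never: MortalityResults
    current: MortalityResults
    former: MortalityResults

    def __post_init__(self) -> None:
        for g in ("never", "current", "former"):
            if getattr(self, g).group != g:
                raise ValueError(f"suite slot {g} holds a {getattr(self, g).group} model")

    def draw(self, rng: np.random.Generator) -> "MortalitySuite":
        """Suite with one shared posterior draw of every group's β."""
        return MortalitySuite(
            self.never.with_params(self.never.sample_params(rng)),
            self.current.with_params(self.current.sample_params(rng)),
            self.former.with_params(self.former.sample_params(rng)),
        )


def fit_suite(records) -> MortalitySuite:
    """Fit all three group models from one records table (or record list)."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    return MortalitySuite(
        never=fit_mortality_model(frame, "never"),
        current=fit_mortality_model(frame, "current"),
        former=fit_mortality_model(frame, "former"),
    )


def err_ratio(rr_product: float, rr_cig: float) -> float:
    """Excess-relative-risk ratio of a product versus cigarette smoking.

    ``(rr_product − 1) / (rr_cig − 1)``: 0 when the product carries no
    excess risk over never use, 1 when it matches cigarettes.
    """
    if rr_cig <= 1.0:
        raise ValueError(f"cigarette relative risk must exceed 1, got {rr_cig}")
    return (rr_product - 1.0) / (rr_cig - 1.0)


def pathway_hazard(
    state: ExpandedState,
    age: float,
    models: MortalitySuite,
    err: ERRParams = ERRParams(),
    mst_ysm_override: float | None = None,
) -> float:
    """All-cause hazard (per 100,000 person-years) of an expanded state.

    The hazard is the never-user baseline times one relative-risk multiplier
    per exposure component of the pathway:

    * active smoking (current cigarette or dual use) contributes the
      current-smoker RR at the pathway's YSM — dual use is assigned the
      full cigarette risk;
    * a completed smoking spell contributes the former-smoker RR at the
      pathway's YSM and YQSM;
    * exclusive current MST use contributes ``1 + err_current·(RR_cur − 1)``
      with the current-smoker RR evaluated at YSM := MST duration (or at
      ``mst_ysm_override`` years if given);
    * a completed MST spell contributes ``1 + err_former·(RR_for − 1)``
      evaluated at YSM := MST duration, YQSM := time since quitting MST.
    """
    cat = state.category
    d = state.durations
    lam_never = models.never.rate(age)

    # cigarette component
    if cat in SMOKING_CATEGORIES:
        cig_rr = models.current.rate(age, ysm=state.ysm_years) / lam_never
    elif d.ysm_bins > 0:
        cig_rr = models.former.rate(age, ysm=state.ysm_years, yqsm=state.yqsm_years) / lam_never
    else:
        cig_rr = 1.0

    # MST component; dual use already carries full cigarette risk
    if cat in SMOKING_CATEGORIES:
        mst_rr = 1.0
    elif cat == UseCategory.CUR_MST:
        ysm_axis = state.mst_years if mst_ysm_override is None else mst_ysm_override
        rr_cur = models.current.rate(age, ysm=ysm_axis) / lam_never
        mst_rr = 1.0 + err.err_current * (rr_cur - 1.0)
    elif d.mst_bins > 0:
        ysm_axis = state.mst_years if mst_ysm_override is None else mst_ysm_override
        rr_for = models.former.rate(age, ysm=ysm_axis, yqsm=state.yq_mst_years) / lam_never
        mst_rr = 1.0 + err.err_former * (rr_for - 1.0)
    else:
        mst_rr = 1.0

    hazard = lam_never * cig_rr * mst_rr
    if not math.isfinite(hazard) or hazard < 0:
        raise ValueError(f"invalid hazard {hazard} at age {age} for {state}")
    return hazard


def survival_5y(hazard: float) -> float:
    """Probability of surviving one 5-year interval at a constant hazard.

    ``exp(−5 · hazard / 100,000)``; the exponential form keeps the result
    in [0, 1] at any hazard.
    """
    if hazard < 0:
        raise ValueError("hazard must be >= 0")
    return math.exp(-5.0 * hazard / 1e5)


def pathway_from_categories(
    categories: Sequence[UseCategory],
    start: ExpandedState | None = None,
) -> list[ExpandedState]:
    """Occupied expanded states for a category-per-interval pathway.

    ``categories[k]`` is the category occupied during interval ``k``; the
    durations of each occupied state reflect all preceding intervals.
    """
    if not categories:
        return []
    first = ExpandedState(categories[0]) if start is None else start
    if first.category != categories[0]:
        raise ValueError("start state category does not match first interval")
    states = [first]
    for cat in categories[1:]:
        prev = states[-1]
        states.append(
            ExpandedState(cat, _advance_durations(prev.durations, prev.category))
        )
    return states


def survival_curve(
    pathway: Sequence[ExpandedState],
    models: MortalitySuite,
    err: ERRParams = ERRParams(),
    start_age: float = 13.0,
    **hazard_kwargs,
) -> np.ndarray:
    """Cumulative survival along a pathway of occupied states.

    ``pathway[k]`` is occupied during the interval beginning at
    ``start_age + 5k``; hazards are evaluated at interval midpoints and the
    result is the running product of 5-year survival probabilities.
    Rejects pathways whose duration bookkeeping is inconsistent.
    """
    for prev, nxt in zip(pathway, pathway[1:]):
        expected = _advance_durations(prev.durations, prev.category)
        if nxt.durations != expected:
            raise ValueError(
                f"inconsistent pathway: after {prev} expected durations "
                f"{expected}, got {nxt.durations}"
            )
    out = np.empty(len(pathway))
    cum = 1.0
    for k, state in enumerate(pathway):
        h = pathway_hazard(state, start_age + 5.0 * k + 2.5, models, err, **hazard_kwargs)
        cum *= survival_5y(h)
        out[k] = cum
    return out
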