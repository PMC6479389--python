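"""Poisson mortality models, ERR scaling, pathway hazards and survival."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tobcohort.mortality import (
    ERRParams,
    MortalityResults,
    MortalitySuite,
    PoissonMortalityModel,
    err_ratio,
    fit_mortality_model,
    fit_suite,
    pathway_from_categories,
    pathway_hazard,
    survival_5y,
    survival_curve,
)
from tobcohort.statespace import DurationProfile, ExpandedState, UseCategory
from tobcohort.synthetic import DEFAULT_BETA, SyntheticSpec, gen_mortality, _truth_rate

C = UseCategory


def constant_rate_results(group: str, rate_per_100k: float) -> MortalityResults:
    """Hand-built model with an age/duration-independent rate (test oracle)."""
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


class TestErrRatio:
    def test_direct_substitution(self):
        assert err_ratio(1.18, 3.00) == pytest.approx(0.09)

    def test_limits(self):
        assert err_ratio(1.0, 2.5) == 0.0
        assert err_ratio(1.7, 1.7) == 1.0

    def test_rr_cig_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            err_ratio(1.2, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(1.01, 50.0), st.floats(0.0, 1.0))
    def test_round_trip_with_excess_scaling(self, rr, e):
        """Scaling excess risk by e and taking the ratio recovers e."""
        assert err_ratio(1 + e * (rr - 1), rr) == pytest.approx(e, abs=1e-9)


class TestFitting:
    def test_parameter_recovery_on_synthetic_data(self, spec, suite):
        """Fits on synthetic exposure data recover the generating β within 3 SE."""
        for group in ("never", "current", "former"):
            res = getattr(suite, group)
            truth = [DEFAULT_BETA[group][name] for name in res.names]
            assert np.all(np.abs(res.params - truth) <= 3 * res.bse())

    def test_zero_deaths_rejected(self):
        frame = pd.DataFrame(
            {"age": [40.0, 50.0, 60.0], "ysm": 0.0, "yqsm": 0.0,
             "person_years": 1e4, "deaths": 0, "group": "never"}
        )
        with pytest.raises(ValueError, match="degenerate"):
            PoissonMortalityModel(frame, "never")

    def test_null_ysm_effect_recovered(self, spec):
        """Data generated with no smoking-duration effect fit a near-zero β."""
        import dataclasses
        beta = {g: dict(v) for g, v in DEFAULT_BETA.items()}
        beta["current"]["ysm"] = 0.0
        beta["current"]["ysm_age"] = 0.0
        null_spec = dataclasses.replace(spec, beta=beta, seed=77)
        res = fit_mortality_model(gen_mortality(null_spec), "current")
        i = res.names.index("ysm")
        assert abs(res.params[i]) <= 3 * res.bse()[i]

    def test_fit_reproduces_aggregate_death_count(self, spec, suite):
        """Score identity: Poisson MLE with intercept matches total deaths."""
        frame = gen_mortality(spec)
        for group in ("never", "current", "former"):
            res = getattr(suite, group)
            observed = frame.loc[frame["group"] == group, "deaths"].sum()
            assert res.sm_results.fittedvalues.sum() == pytest.approx(
                observed, rel=1e-6
            )

    def test_too_few_records_rejected(self):
        frame = pd.DataFrame(
            {"age": [40.0], "ysm": 0.0, "yqsm": 0.0,
             "person_years": 1e4, "deaths": 5, "group": "never"}
        )
        with pytest.raises(ValueError, match="at least"):
            PoissonMortalityModel(frame, "never")

    def test_json_round_trip(self, suite, tmp_path):
        path = tmp_path / "never.json"
        suite.never.to_json(path)
        back = MortalityResults.from_json(path)
        assert back.group == "never"
        np.testing.assert_allclose(back.params, suite.never.params)
        np.testing.assert_allclose(back.cov, suite.never.cov)
        assert back.rate(52.5) == pytest.approx(suite.never.rate(52.5))

    def test_metropolis_agrees_with_normal_approximation(self, spec):
        model = PoissonMortalityModel(gen_mortality(spec), "never")
        res = model.fit()
        samples = res.sample_posterior_metropolis(model, 400, seed=3)
        se = res.bse()
        assert np.all(np.abs(samples.mean(axis=0) - res.params) < se)


class TestPathwayHazard:
    def test_pure_smoking_pathways_equal_raw_model_rates(self, suite):
        """No MST exposure: the composed hazard is exactly the group model."""
        cur = ExpandedState(C.CUR_CIG, DurationProfile(4, 0, 0, 0))
        assert pathway_hazard(cur, 47.5, suite) == suite.current.rate(47.5, ysm=20)
        fmr = ExpandedState(C.FORMER_CIG, DurationProfile(4, 2, 0, 0))
        assert pathway_hazard(fmr, 57.5, suite) == suite.former.rate(57.5, ysm=20, yqsm=10)
        nvr = ExpandedState(C.NEVER)
        assert pathway_hazard(nvr, 47.5, suite) == suite.never.rate(47.5)

    def test_err_zero_reduces_mst_to_never_user(self, suite):
        mst = ExpandedState(C.CUR_MST, DurationProfile(0, 0, 3, 0))
        h = pathway_hazard(mst, 42.5, suite, ERRParams(err_current=0.0, err_former=0.0))
        assert h == suite.never.rate(42.5)

    def test_err_one_reduces_mst_to_smoker(self, suite):
        mst = ExpandedState(C.CUR_MST, DurationProfile(0, 0, 3, 0))
        h = pathway_hazard(mst, 42.5, suite, ERRParams(err_current=1.0, err_former=1.0))
        assert h == pytest.approx(suite.current.rate(42.5, ysm=15), rel=1e-12)

    def test_mst_multiplier_is_excess_scaled_smoker_rr(self, suite):
        """Hazard of an MST user carries 1 + err·(RR_cur − 1) times baseline."""
        age, bins = 52.5, 4
        rr = suite.current.rate(age, ysm=5 * bins) / suite.never.rate(age)
        expected = suite.never.rate(age) * (1 + 0.09 * (rr - 1))
        mst = ExpandedState(C.CUR_MST, DurationProfile(0, 0, bins, 0))
        assert pathway_hazard(mst, age, suite, ERRParams(0.09, 0.04)) == pytest.approx(expected)

    def test_dual_use_carries_full_cigarette_risk(self, suite):
        dual = ExpandedState(C.DUAL, DurationProfile(3, 0, 3, 0))
        assert pathway_hazard(dual, 47.5, suite) == suite.current.rate(47.5, ysm=15)

    def test_switcher_combines_smoking_history_and_mst_components(self, suite):
        st_ = ExpandedState(C.CUR_MST, DurationProfile(4, 2, 2, 0))
        age = 52.5
        lam_n = suite.never.rate(age)
        rr_hist = suite.former.rate(age, ysm=20, yqsm=10) / lam_n
        rr_cur = suite.current.rate(age, ysm=10) / lam_n
        expected = lam_n * rr_hist * (1 + 0.09 * (rr_cur - 1))
        assert pathway_hazard(st_, age, suite) == pytest.approx(expected)

    def test_hazard_at_least_background_for_nonnegative_excess(self, suite):
        err = ERRParams(0.09, 0.04)
        for cat, d in [
            (C.CUR_CIG, DurationProfile(5, 0, 0, 0)),
            (C.CUR_MST, DurationProfile(0, 0, 5, 0)),
            (C.DUAL, DurationProfile(5, 0, 5, 0)),
        ]:
            for age in (32.5, 52.5, 72.5):
                h = pathway_hazard(ExpandedState(cat, d), age, suite, err)
                assert h >= suite.never.rate(age)


class TestSurvival:
    def test_closed_forms(self):
        assert survival_5y(0.0) == 1.0
        assert survival_5y(100_000.0) == pytest.approx(math.exp(-5))

    def test_strictly_decreasing_in_hazard(self):
        hs = np.linspace(0, 5e4, 30)
        s = [survival_5y(h) for h in hs]
        assert all(a > b for a, b in zip(s, s[1:]))

    def test_constant_hazard_curve_closed_form(self):
        suite = constant_suite(never=200.0)
        pathway = pathway_from_categories([C.NEVER] * 6)
        curve = survival_curve(pathway, suite, start_age=13)
        for k in range(6):
            assert curve[k] == pytest.approx(math.exp(-5 * (k + 1) * 200.0 / 1e5))

    def test_inconsistent_pathway_rejected(self, suite):
        bad = [
            ExpandedState(C.CUR_CIG, DurationProfile(0, 0, 0, 0)),
            ExpandedState(C.CUR_CIG, DurationProfile(0, 0, 0, 0)),  # clock frozen
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            survival_curve(bad, suite)

    def test_curve_ordering_never_switcher_smoker(self, spec):
        """Cumulative survival: never user >= switcher >= lifelong smoker.

        Evaluated on the generator's noise-free reference models, where the
        smoking relative risk is >= 1 at every modelled age.
        """
        from tobcohort.synthetic import truth_suite

        suite = truth_suite(spec)
        n = 18
        never = survival_curve(pathway_from_categories([C.NEVER] * n), suite)
        smoker = survival_curve(
            pathway_from_categories([C.NEVER] + [C.CUR_CIG] * (n - 1)), suite
        )
        switcher = survival_curve(
            pathway_from_categories(
                [C.NEVER] + [C.CUR_CIG] * 5 + [C.CUR_MST] * (n - 6)
            ),
            suite,
        )
        assert np.all(never >= switcher) and np.all(switcher >= smoker)
        assert never[-1] > switcher[-1] > smoker[-1]
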