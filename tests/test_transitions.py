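"""Transition tables, intention-derived scenario deltas, rate uncertainty."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tobcohort import presets
from tobcohort.statespace import UseCategory
from tobcohort.transitions import (
    CIG_CESSATION,
    CIG_INITIATION,
    MST_INITIATION,
    SWITCHING,
    IntentionSummary,
    RateUncertainty,
    ScenarioDelta,
    TransitionTable,
    apply_relative_change,
    derive_modified_table,
    draw_rates,
    relative_percent_change,
    whole_percent,
)

C = UseCategory


class TestRelativePercentChange:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((17.73, 15.87, 13.99, 15.13), 21),  # smokers switching to MST
            ((3.06, 2.42, 4.85, 3.65), -5),  # never-user MST initiation
            ((24.04, 19.90, 17.86, 18.33), 24),  # smokers moving to dual use
            ((34.14, 32.38, 35.48, 35.57), 6),  # dual users to exclusive MST
        ],
    )
    def test_published_intention_rows(self, row, expected):
        assert whole_percent(relative_percent_change(IntentionSummary(*row))) == expected

    def test_equal_pre_post_ratios_give_zero(self):
        assert relative_percent_change(IntentionSummary(10, 5, 30, 15)) == pytest.approx(0)

    def test_zero_proportion_rejected(self):
        with pytest.raises(ValueError):
            IntentionSummary(0.0, 2.0, 3.0, 4.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.tuples(*[st.floats(0.01, 0.99) for _ in range(4)]),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, props, k):
        """Rescaling all four proportions leaves the relative change unchanged."""
        a = relative_percent_change(IntentionSummary(*props))
        b = relative_percent_change(IntentionSummary(*(k * p for p in props)))
        assert b == pytest.approx(a, rel=1e-9)


class TestApplyRelativeChange:
    def test_published_worked_examples(self):
        assert round(100 * apply_relative_change(0.014, 0.21), 1) == 1.7
        assert apply_relative_change(0.016, 1.00) == pytest.approx(0.032)

    def test_identity_and_floor(self):
        assert apply_relative_change(0.3, 0.0) == 0.3
        assert apply_relative_change(0.3, -1.0) == 0.0

    def test_cap_at_one_warns(self):
        with pytest.warns(UserWarning, match="capped"):
            assert apply_relative_change(0.8, 0.5) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.5), st.lists(st.floats(-1.0, 1.0), min_size=2, max_size=2))
    def test_monotone_in_delta(self, rate, deltas):
        lo, hi = sorted(deltas)
        assert apply_relative_change(rate, lo) <= apply_relative_change(rate, hi)


def _small_table():
    ages = [13, 18]
    rates = {}
    for a in ages:
        rates[(a, *CIG_INITIATION)] = 0.10
        rates[(a, *MST_INITIATION)] = 0.016
        rates[(a, *SWITCHING)] = 0.014
        rates[(a, *CIG_CESSATION)] = 0.05
    return TransitionTable(ages, rates)


class TestTransitionTable:
    def test_row_sum_guard(self):
        with pytest.raises(ValueError, match="sum to"):
            TransitionTable([13], {(13, C.NEVER, C.CUR_CIG): 0.7, (13, C.NEVER, C.CUR_MST): 0.4})

    def test_rate_bounds_guard(self):
        with pytest.raises(ValueError, match="outside"):
            TransitionTable([13], {(13, C.NEVER, C.CUR_CIG): 1.2})

    def test_csv_round_trip(self, tmp_path):
        t = _small_table()
        t.to_csv(tmp_path / "t.csv")
        back = TransitionTable.from_csv(tmp_path / "t.csv")
        assert back.rates == t.rates

    def test_percent_dialect(self, tmp_path):
        t = _small_table()
        frame = t.to_frame().rename(columns={"rate_fraction": "rate_percent"})
        frame["rate_percent"] *= 100
        back = TransitionTable.from_frame(frame)
        assert back.get(13, SWITCHING) == pytest.approx(0.014)


class TestDeriveModified:
    def test_no_change_recipe_is_identity(self):
        base = _small_table()
        out = derive_modified_table(
            base, ScenarioDelta({}, would_be_smoker=0.0, would_be_quitter=0.0)
        )
        assert out.rates == base.rates

    def test_switch_delta_worked_example(self):
        base = _small_table()
        out = derive_modified_table(
            base,
            ScenarioDelta({SWITCHING: 0.21}, would_be_smoker=0.0, would_be_quitter=0.0),
        )
        assert out.get(13, SWITCHING) == pytest.approx(0.01694)

    def test_full_would_be_smoker_diversion_reroutes_all_initiation(self):
        base = _small_table()
        out = derive_modified_table(
            base, ScenarioDelta({}, would_be_smoker=1.0, would_be_quitter=0.0)
        )
        assert out.get(13, CIG_INITIATION) == pytest.approx(0.0)
        assert out.get(13, MST_INITIATION) == pytest.approx(0.016 + 0.10)

    def test_diversions_conserve_outgoing_mass(self):
        """Diversions reroute flow between edges; row totals are untouched."""
        base = _small_table()
        out = derive_modified_table(
            base, ScenarioDelta({}, would_be_smoker=0.3, would_be_quitter=0.7)
        )
        for a in base.ages:
            for src in (C.NEVER, C.CUR_CIG):
                assert out.row_sum(a, src) == pytest.approx(base.row_sum(a, src))

    def test_unknown_delta_edge_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            derive_modified_table(
                _small_table(), ScenarioDelta({(C.DUAL, C.CUR_MST): 0.1}, 0.0, 0.0)
            )

    def test_row_sum_violation_names_source(self):
        base = TransitionTable(
            [13], {(13, C.NEVER, C.CUR_CIG): 0.6, (13, C.NEVER, C.CUR_MST): 0.3}
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="NEVER"):
                derive_modified_table(
                    base, ScenarioDelta({CIG_INITIATION: 0.9}, 0.0, 0.0)
                )


class TestDrawRates:
    def test_same_seed_identical_tables(self):
        base = _small_table()
        a = draw_rates(base, seed=11)
        b = draw_rates(base, seed=11)
        assert a.rates == b.rates
        c = draw_rates(base, seed=12)
        assert c.rates != a.rates

    def test_vanishing_sd_recovers_means(self):
        base = _small_table()
        out = draw_rates(base, RateUncertainty(sd=1e-7), seed=5)
        for k, v in base.rates.items():
            assert out.rates[k] == pytest.approx(v, abs=1e-5)

    def test_draw_mean_matches_stated_rate(self):
        """Far from the bounds the truncated-normal mean is the stated rate."""
        t = TransitionTable([13], {(13, C.NEVER, C.CUR_CIG): 0.5})
        draws = [
            draw_rates(t, RateUncertainty(sd=0.02), seed=s).get(13, CIG_INITIATION)
            for s in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.001)

    def test_only_initiation_and_cessation_redrawn_by_default(self):
        base = _small_table()
        out = draw_rates(base, seed=7)
        assert out.get(13, SWITCHING) == base.get(13, SWITCHING)
        assert out.get(13, CIG_INITIATION) != base.get(13, CIG_INITIATION)
        assert out.get(13, CIG_CESSATION) != base.get(13, CIG_CESSATION)

    def test_common_random_numbers_on_shared_edges(self):
        """Two tables sharing an edge layout draw the same perturbations."""
        base = _small_table()
        other = base.copy()
        other.set(13, SWITCHING, 0.02)  # not an uncertain edge
        a = draw_rates(base, seed=9)
        b = draw_rates(other, seed=9)
        assert a.get(13, CIG_INITIATION) == b.get(13, CIG_INITIATION)
        assert a.get(18, CIG_CESSATION) == b.get(18, CIG_CESSATION)
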