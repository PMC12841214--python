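"""Risk direction inference, tertile thresholds and scale assembly."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifra import (
    FeatureRule,
    ScaleDefinition,
    ScaleError,
    Stratum,
    assign_feature_stratum,
    build_scale,
    derive_thresholds,
    infer_direction,
    training_rank_strata,
)
from ifra.selection import SelectionResult

from conftest import make_train_cohort


def _train(values, labels=None):
    return make_train_cohort({"x": values}, labels)


class TestInferDirection:
    def test_slower_fallers_mean_higher_is_riskier(self):
        # TUG-duration-like: fallers take longer
        cohort = _train([20, 25, 30, 10, 12, 11],
                        ["faller"] * 3 + ["non_faller"] * 3)
        assert infer_direction(cohort, "x") == "higher_is_riskier"

    def test_slower_fallers_speed_lower_is_riskier(self):
        # gait-speed-like: fallers are slower
        cohort = _train([0.5, 0.6, 0.4, 1.2, 1.1, 1.3],
                        ["faller"] * 3 + ["non_faller"] * 3)
        assert infer_direction(cohort, "x") == "lower_is_riskier"

    def test_hint_overrides_data(self):
        cohort = _train([20, 25, 30, 10, 12, 11],
                        ["faller"] * 3 + ["non_faller"] * 3)
        assert infer_direction(cohort, "x", hint="lower_is_riskier") == "lower_is_riskier"

    def test_tie_defaults_to_higher_with_warning(self, caplog):
        cohort = _train([1, 2, 3, 1, 2, 3], ["faller"] * 3 + ["non_faller"] * 3)
        with caplog.at_level(logging.WARNING):
            assert infer_direction(cohort, "x") == "higher_is_riskier"
        assert "equal group means" in caplog.text


class TestDeriveThresholds:
    def test_93_subjects_ascending(self):
        cohort = _train(list(range(1, 94)))
        rule = derive_thresholds(cohort, "x", "higher_is_riskier")
        assert (rule.threshold_a, rule.threshold_b) == (31.0, 62.0)
        ranked = training_rank_strata(cohort, "x", "higher_is_riskier")
        assert [int((ranked == s).sum()) for s in ("low", "medium", "high")] == [31, 31, 31]
        # value-based reassignment: the rank-62 subject sits on the closed
        # high boundary, so it moves from medium to high
        strata = [assign_feature_stratum(v, rule) for v in range(1, 94)]
        sizes = [strata.count(s) for s in Stratum]
        assert sizes == [31, 30, 32]
        assert strata[61] is Stratum.high

    def test_93_subjects_descending(self):
        # brute-force oracle: sort descending, take ranks 31 and 62
        values = list(range(1, 94))
        ordered = sorted(values, reverse=True)
        assert (ordered[30], ordered[61]) == (63, 32)
        rule = derive_thresholds(_train(values), "x", "lower_is_riskier")
        assert (rule.threshold_a, rule.threshold_b) == (63.0, 32.0)

    def test_small_n_ceil_rule(self):
        rule = derive_thresholds(_train([1, 2, 3, 4, 5, 6]), "x", "higher_is_riskier")
        assert (rule.threshold_a, rule.threshold_b) == (2.0, 4.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ScaleError, match="at least 3"):
            derive_thresholds(_train([1.0, 2.0]), "x", "higher_is_riskier")

    def test_thresholds_are_observed_values(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=40)
        for direction in ("higher_is_riskier", "lower_is_riskier"):
            rule = derive_thresholds(_train(values), "x", direction)
            assert rule.threshold_a in values
            assert rule.threshold_b in values

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=60,
            unique=True,
        ),
        direction=st.sampled_from(["higher_is_riskier", "lower_is_riskier"]),
    )
    def test_tie_free_strata_sizes_follow_cut_ranks(self, values, direction):
        import math

        n = len(values)
        k1, k2 = math.ceil(n / 3), math.ceil(2 * n / 3)
        cohort = _train(values)
        ranked = training_rank_strata(cohort, "x", direction)
        assert [int((ranked == s).sum()) for s in ("low", "medium", "high")] == [
            k1, k2 - k1, n - k2,
        ]
        # value-based assignment keeps the low tertile and absorbs the
        # rank-k2 subject into high (closed extreme intervals)
        rule = derive_thresholds(cohort, "x", direction)
        strata = [assign_feature_stratum(v, rule) for v in values]
        sizes = [strata.count(s) for s in Stratum]
        assert sizes == [k1, k2 - k1 - 1, n - k2 + 1]


class TestBuildScale:
    @staticmethod
    def _selection(counts, n_retained):
        from ifra.selection import consensus_select

        return SelectionResult(
            relevance_counts=counts,
            n_retained_subsets=n_retained,
            n_iterations_run=n_retained,
            consensus_fraction=0.5,
            consensus_denominator="retained",
            selected_features=consensus_select(counts, n_retained, 0.5),
        )

    def test_one_rule_per_selected_feature_ordered_by_fraction(self):
        rng = np.random.default_rng(1)
        labels = ["faller"] * 10 + ["non_faller"] * 10
        cohort = make_train_cohort(
            {"a": rng.normal(size=20), "b": rng.normal(size=20),
             "c": rng.normal(size=20)},
            labels,
        )
        selection = self._selection({"a": 6, "b": 10, "c": 8}, 10)
        scale = build_scale(cohort, selection)
        assert scale.features == ["b", "c", "a"]
        assert [r.selection_fraction for r in scale.rules] == [1.0, 0.8, 0.6]

    def test_single_feature_scale_classifies(self):
        cohort = _train(list(range(1, 94)))
        scale = build_scale(cohort, self._selection({"x": 9}, 10))
        assert len(scale) == 1
        assert assign_feature_stratum(1.0, scale.rules[0]) in list(Stratum)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = ["faller"] * 8 + ["non_faller"] * 8
        values = {"a": rng.normal(size=16), "b": rng.normal(size=16)}
        cohort = make_train_cohort(values, labels)
        perm = rng.permutation(16)
        shuffled = make_train_cohort(
            {k: np.asarray(v)[perm] for k, v in values.items()},
            [labels[i] for i in perm],
        )
        selection = self._selection({"a": 9, "b": 7}, 10)
        assert build_scale(cohort, selection).rules == build_scale(shuffled, selection).rules

    def test_empty_selection_rejected(self):
        cohort = _train(list(range(10)))
        with pytest.raises(ScaleError):
            build_scale(cohort, self._selection({"x": 2}, 10))

    def test_json_round_trip(self, tmp_path):
        cohort = _train(list(range(1, 94)))
        scale = build_scale(cohort, self._selection({"x": 9}, 10))
        scale.to_json(tmp_path / "scale.json")
        loaded = ScaleDefinition.from_json(tmp_path / "scale.json")
        assert loaded.rules == scale.rules
        assert loaded.training_size == 93

    def test_table_layout_columns(self):
        cohort = _train(list(range(1, 94)))
        table = build_scale(cohort, self._selection({"x": 9}, 10)).to_table()
        assert list(table.columns) == [
            "feature",
            "low_risk_threshold",
            "medium_risk_threshold",
            "high_risk_threshold",
            "pct_of_selections",
        ]
        assert table.loc[0, "pct_of_selections"] == "90%"
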