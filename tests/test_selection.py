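"""Balanced subsampling, the SVM validation gate, group testing and consensus."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ifra import (
    Cohort,
    EmptySelectionError,
    FeatureMeta,
    SamplingExhaustedError,
    SelectionConfig,
    SelectionResult,
    SimulationConfig,
    gate_subset,
    generate_cohort,
    mark_relevant,
    run_selection,
    sample_balanced_subset,
)
from ifra.selection import consensus_select

from conftest import make_train_cohort


def _toy_separable(n_per_class=10, n_val=10, n_flipped=0, seed=0):
    """Linearly separable 1-feature cohorts; ``n_flipped`` validation labels
    are wrong, pinning validation accuracy of a perfect classifier to
    (n_val - n_flipped) / n_val."""
    rng = np.random.default_rng(seed)
    def build(n_f, n_nf, flip):
        values = np.concatenate(
            [10 + rng.normal(0, 0.1, n_f), -10 + rng.normal(0, 0.1, n_nf)]
        )
        labels = ["faller"] * n_f + ["non_faller"] * n_nf
        for i in range(flip):
            labels[i] = "non_faller" if labels[i] == "faller" else "faller"
        frame = pd.DataFrame(
            {
                "id": [f"t{seed}_{i}" for i in range(len(values))],
                "fall_label": labels,
                "provenance": "real",
                "split": "train",
                "x": values,
            }
        )
        return Cohort(frame, [FeatureMeta("x")])

    train = build(n_per_class, n_per_class, 0)
    validation = build(n_val // 2, n_val - n_val // 2, n_flipped)
    return train, validation


class TestSampleBalancedSubset:
    def test_subset_size_is_study_shaped(self, planted_cohort, small_selection_config):
        train = planted_cohort.view(split="train")
        ids = sample_balanced_subset(train, small_selection_config, draw_index=0)
        # 14 fallers (all of train) + 14 sampled non-fallers
        assert len(ids) == 28
        labels = train.frame.set_index("id").loc[ids, "fall_label"]
        assert (labels == "faller").sum() == 14

    def test_fallers_fixed_across_draws(self, planted_cohort, small_selection_config):
        train = planted_cohort.view(split="train")
        faller_ids = set(train.frame.loc[train.frame["fall_label"] == "faller", "id"])
        for draw in range(5):
            ids = set(sample_balanced_subset(train, small_selection_config, draw))
            assert faller_ids <= ids

    def test_distinct_draws_differ(self, planted_cohort, small_selection_config):
        train = planted_cohort.view(split="train")
        a = sample_balanced_subset(train, small_selection_config, 0)
        b = sample_balanced_subset(train, small_selection_config, 1)
        assert set(a) != set(b)

    def test_deterministic_in_seed_and_index(self, planted_cohort, small_selection_config):
        train = planted_cohort.view(split="train")
        assert sample_balanced_subset(
            train, small_selection_config, 3
        ) == sample_balanced_subset(train, small_selection_config, 3)

    def test_combinatorial_exhaustion_detected(self):
        train, validation = _toy_separable()
        config = SelectionConfig(n_iterations=2, subset_nonfallers=10, seed=0)
        with pytest.raises(SamplingExhaustedError, match="C\\(10,10\\) = 1"):
            run_selection(train, validation, config)


class TestGateSubset:
    def test_separable_case_reaches_accuracy_one(self):
        train, validation = _toy_separable()
        config = SelectionConfig(subset_nonfallers=10, seed=0)
        assert gate_subset(train, validation, config) == 1.0

    def test_accuracy_exactly_at_gate_is_not_retained(self):
        # 2 of 10 validation labels flipped: a perfect separator scores 0.80
        train, validation = _toy_separable(n_val=10, n_flipped=2, seed=1)
        config = SelectionConfig(
            n_iterations=1, subset_nonfallers=10, accuracy_gate=0.80, seed=1
        )
        assert gate_subset(train, validation, config) == pytest.approx(0.80)
        with pytest.raises(EmptySelectionError):
            run_selection(train, validation, config)

    def test_accuracy_above_gate_is_retained(self):
        # 14/17 correct = 0.8235 > 0.80
        train, validation = _toy_separable(n_val=17, n_flipped=3, seed=2)
        config = SelectionConfig(
            n_iterations=1, subset_nonfallers=10, accuracy_gate=0.80, seed=2
        )
        assert gate_subset(train, validation, config) == pytest.approx(14 / 17)
        result = run_selection(train, validation, config)
        assert result.n_retained_subsets == 1
        assert result.per_iteration_log[0].retained

    def test_zero_sd_feature_tolerated(self):
        train, validation = _toy_separable()
        for cohort in (train, validation):
            cohort.frame["const"] = 1.0
            cohort.registry.append(FeatureMeta("const"))
            cohort.__post_init__()
        config = SelectionConfig(subset_nonfallers=10, seed=0)
        assert gate_subset(train, validation, config) == 1.0


class TestMarkRelevant:
    def test_identical_groups_not_marked(self):
        values = list(range(1, 21)) * 2
        labels = ["faller"] * 20 + ["non_faller"] * 20
        cohort = make_train_cohort({"x": values}, labels)
        assert mark_relevant(cohort, SelectionConfig()) == set()

    def test_shifted_group_marked(self):
        values = [v + 10 for v in range(1, 21)] + list(range(1, 21))
        labels = ["faller"] * 20 + ["non_faller"] * 20
        cohort = make_train_cohort({"x": values}, labels)
        assert mark_relevant(cohort, SelectionConfig()) == {"x"}

    def test_constant_feature_not_marked(self):
        labels = ["faller"] * 5 + ["non_faller"] * 5
        cohort = make_train_cohort({"x": [3.0] * 10, "y": list(range(10))}, labels)
        assert "x" not in mark_relevant(cohort, SelectionConfig())

    def test_null_marking_rate_matches_alpha(self):
        """Independent null subsets: per-feature marking rate ~ alpha."""
        alpha, n_reps = 0.05, 500
        rng = np.random.default_rng(99)
        config = SelectionConfig(alpha_relevance=alpha)
        marked = 0
        labels = ["faller"] * 15 + ["non_faller"] * 15
        for _ in range(n_reps):
            cohort = make_train_cohort({"x": rng.standard_normal(30)}, labels)
            marked += "x" in mark_relevant(cohort, config)
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert marked / n_reps == pytest.approx(alpha, abs=2 * se)

    def test_too_few_subjects_rejected(self):
        labels = ["faller"] * 2 + ["non_faller"] * 5
        cohort = make_train_cohort({"x": list(range(7))}, labels)
        with pytest.raises(Exception, match="fewer than 3"):
            mark_relevant(cohort, SelectionConfig())


class TestConsensus:
    def test_exactly_half_is_selected(self):
        assert consensus_select({"a": 5, "b": 4}, 10, 0.5) == ["a"]

    def test_ordering_descending_with_lexicographic_ties(self):
        counts = {"b": 7, "a": 7, "c": 9}
        assert consensus_select(counts, 10, 0.5) == ["c", "a", "b"]

    def test_raising_consensus_never_grows_selection(self):
        rng = np.random.default_rng(0)
        counts = {f"f{i}": int(rng.integers(0, 11)) for i in range(30)}
        previous = None
        for fraction in (0.2, 0.4, 0.6, 0.8, 1.0):
            selected = set(consensus_select(counts, 10, fraction))
            if previous is not None:
                assert selected <= previous
            previous = selected


class TestRunSelection:
    def test_recovers_planted_features(self, planted_cohort, small_selection_config):
        result = run_selection(
            planted_cohort.view(split="train"),
            planted_cohort.view(split="validation"),
            small_selection_config,
        )
        planted = set(planted_cohort.planted_features)
        selected = set(result.selected_features)
        assert len(selected & planted) >= 4  # most of the 6 planted
        assert result.n_retained_subsets <= result.n_iterations_run

    def test_rerun_is_bit_identical(self, planted_cohort, small_selection_config, tmp_path):
        args = (
            planted_cohort.view(split="train"),
            planted_cohort.view(split="validation"),
            small_selection_config,
        )
        first, second = run_selection(*args), run_selection(*args)
        assert first == second
        first.to_json(tmp_path / "sel.json")
        assert SelectionResult.from_json(tmp_path / "sel.json") == first

    def test_counts_bounded_by_retained(self, planted_cohort, small_selection_config):
        result = run_selection(
            planted_cohort.view(split="train"),
            planted_cohort.view(split="validation"),
            small_selection_config,
        )
        assert all(
            0 <= c <= result.n_retained_subsets
            for c in result.relevance_counts.values()
        )

    def test_impossible_gate_raises_empty_selection(
        self, planted_cohort, small_selection_config
    ):
        config = dataclasses.replace(small_selection_config, accuracy_gate=1.01)
        with pytest.raises(EmptySelectionError):
            run_selection(
                planted_cohort.view(split="train"),
                planted_cohort.view(split="validation"),
                config,
            )

    def test_no_duplicate_fingerprints(self, planted_cohort, small_selection_config):
        result = run_selection(
            planted_cohort.view(split="train"),
            planted_cohort.view(split="validation"),
            small_selection_config,
        )
        fingerprints = [r.fingerprint for r in result.per_iteration_log]
        assert len(set(fingerprints)) == len(fingerprints)
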