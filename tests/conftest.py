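import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from ifra import (
    AugmentationConfig,
    Cohort,
    FeatureMeta,
    SelectionConfig,
    SimulationConfig,
    assign_splits,
    augment_fallers,
    generate_cohort,
)

#: split design for the small planted cohort below (30 non-fallers, 15+5 fallers)
SMALL_DESIGN = {
    ("train", "non_faller"): 18,
    ("train", "faller"): 14,
    ("validation", "non_faller"): 6,
    ("validation", "faller"): 3,
    ("test", "non_faller"): 6,
    ("test", "faller"): 3,
}


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three hand-built subjects over two features."""
    frame = pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "fall_label": ["faller", "non_faller", "faller"],
            "provenance": ["real", "real", "real"],
            "split": ["unassigned"] * 3,
            "x": [1.0, 2.0, 3.0],
            "y": [0.5, 0.25, 0.125],
        }
    )
    registry = [FeatureMeta("x", units="s"), FeatureMeta("y")]
    return Cohort(frame, registry)


def make_train_cohort(values_by_feature: dict[str, list[float]], labels=None) -> Cohort:
    """Training-split cohort from explicit per-feature value lists."""
    n = len(next(iter(values_by_feature.values())))
    if labels is None:
        labels = ["faller" if i % 2 == 0 else "non_faller" for i in range(n)]
    frame = pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "fall_label": labels,
            "provenance": ["real"] * n,
            "split": ["train"] * n,
            **{k: list(map(float, v)) for k, v in values_by_feature.items()},
        }
    )
    return Cohort(frame, [FeatureMeta(k) for k in values_by_feature])


@pytest.fixture(scope="session")
def planted_cohort() -> Cohort:
    """Small cohort with 6 planted informative features among 20, augmented
    and split; used by selection/model tests."""
    sim = SimulationConfig(
        n_fallers=15,
        n_nonfallers=30,
        n_features=20,
        n_informative=6,
        effect_size=1.5,
        seed=42,
    )
    cohort = generate_cohort(sim)
    planted = cohort.planted_features
    cohort = augment_fallers(cohort, AugmentationConfig(k=5, noise_scale=0.1, seed=43))
    cohort = assign_splits(cohort, SMALL_DESIGN, seed=44)
    cohort.planted_features = planted  # survive the pipeline for assertions
    return cohort


@pytest.fixture(scope="session")
def small_selection_config() -> SelectionConfig:
    return SelectionConfig(
        n_iterations=30,
        subset_nonfallers=14,
        accuracy_gate=0.6,
        seed=45,
    )
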