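"""Consensus feature selection over repeatedly subsampled balanced training sets.

The procedure explores many balanced views of an imbalanced training split:
every draw keeps all training fallers and samples an equal number of
non-fallers without replacement (no two draws repeat the same non-faller
set).  A draw contributes to the consensus only if an RBF-kernel SVM trained
on it classifies the held-out validation split with accuracy strictly above
the gate (default 0.80) — a safeguard that only population configurations
with stable separability on unseen data vote.  Within each retained draw,
every feature is tested for a group difference: Shapiro–Wilk normality per
group routes the comparison to a Welch t-test (both groups consistent with
normality) or a Wilcoxon rank-sum test, and the feature is marked relevant
when the two-sided p-value falls below ``alpha_relevance``.  Features marked
relevant in at least ``consensus_fraction`` of the retained draws are
selected, ranked by how often they were marked.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort import Cohort
from .exceptions import EmptySelectionError, IngestError, SamplingExhaustedError

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "consensus_select",
    "sample_balanced_subset",
    "gate_subset",
    "mark_relevant",
    "run_selection",
]

_MAX_REDRAWS = 1000  # per draw, before declaring the fingerprint space exhausted


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the consensus selection run.

    The defaults are the study protocol: 1000 iterations, all training
    fallers plus 39 of the 54 training non-fallers per draw, a strict >0.80
    validation-accuracy gate, two-group tests at alpha 0.05 routed by
    Shapiro–Wilk at alpha 0.05, and a 50% consensus over retained draws.
    ``consensus_denominator`` may be ``"retained"`` (default: the fraction is
    over gated draws) or ``"iterations"`` (over all draws run).
    """

    n_iterations: int = 1000
    subset_fallers: int | None = None  # None: all training fallers
    subset_nonfallers: int = 39
    accuracy_gate: float = 0.80
    alpha_relevance: float = 0.05
    alpha_normality: float = 0.05
    consensus_fraction: float = 0.50
    consensus_denominator: str = "retained"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise IngestError("n_iterations must be >= 1")
        if not 0 < self.accuracy_gate:
            raise IngestError("accuracy_gate must be positive")
        if self.consensus_denominator not in ("retained", "iterations"):
            raise IngestError("consensus_denominator must be 'retained' or 'iterations'")

    @classmethod
    def from_yaml(cls, path) -> "SelectionConfig":
        return cls(**(yaml.safe_load(open(path)) or {}))


@dataclass
class IterationRecord:
    """One subsampling draw: fingerprint of the non-faller set, gate accuracy,
    and whether the draw was retained."""

    draw_index: int
    fingerprint: str
    gate_accuracy: float
    retained: bool


@dataclass
class SelectionResult:
    """Outcome of a consensus selection run."""

    relevance_counts: dict[str, int]
    n_retained_subsets: int
    n_iterations_run: int
    consensus_fraction: float
    consensus_denominator: str
    selected_features: list[str]
    per_iteration_log: list[IterationRecord] = field(default_factory=list)

    @property
    def denominator(self) -> int:
        if self.consensus_denominator == "iterations":
            return self.n_iterations_run
        return self.n_retained_subsets

    def selection_fraction(self, feature: str) -> float:
        if self.denominator == 0:
            return 0.0
        return self.relevance_counts.get(feature, 0) / self.denominator

    def ranking(self) -> pd.DataFrame:
        """Ranking table (feature, times marked, fraction) sorted as selected."""
        rows = sorted(
            self.relevance_counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return pd.DataFrame(
            {
                "feature": [f for f, _ in rows],
                "n_marked": [c for _, c in rows],
                "selection_fraction": [
                    self.selection_fraction(f) for f, _ in rows
                ],
            }
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "relevance_counts": self.relevance_counts,
            "n_retained_subsets": self.n_retained_subsets,
            "n_iterations_run": self.n_iterations_run,
            "consensus_fraction": self.consensus_fraction,
            "consensus_denominator": self.consensus_denominator,
            "selected_features": self.selected_features,
            "per_iteration_log": [asdict(r) for r in self.per_iteration_log],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        payload["per_iteration_log"] = [
            IterationRecord(**r) for r in payload["per_iteration_log"]
        ]
        return cls(**payload)


def consensus_select(
    relevance_counts: Mapping[str, int], denominator: int, consensus_fraction: float
) -> list[str]:
    """Features whose relevance fraction reaches the consensus threshold
    (inclusive: marked in *at least* that fraction), ordered by descending
    count with lexicographic tie-break."""
    if denominator <= 0:
        return []
    return sorted(
        (
            f
            for f, c in relevance_counts.items()
            if c / denominator >= consensus_fraction
        ),
        key=lambda f: (-relevance_counts[f], f),
    )


def _fingerprint(ids: Sequence[str]) -> str:
    joined = "\x1f".join(sorted(map(str, ids)))
    return hashlib.sha1(joined.encode()).hexdigest()[:16]


def _draw_rng(seed: int, draw_index: int) -> np.random.Generator:
    # independent substream per draw, so iteration results do not depend on
    # execution order
    return np.random.default_rng(np.random.SeedSequence([seed, draw_index]))


def sample_balanced_subset(
    train: Cohort, config: SelectionConfig, draw_index: int
) -> list[str]:
    """Subject ids for one balanced draw: all training fallers (or the first
    ``subset_fallers``) plus ``subset_nonfallers`` non-fallers sampled
    uniformly without replacement.  Deterministic in (seed, draw_index)."""
    fallers = train.frame.loc[train.frame["fall_label"] == "faller", "id"].tolist()
    nonfallers = train.frame.loc[
        train.frame["fall_label"] == "non_faller", "id"
    ].tolist()
    if config.subset_fallers is not None:
        fallers = fallers[: config.subset_fallers]
    k = config.subset_nonfallers
    if k > len(nonfallers):
        raise SamplingExhaustedError(
            f"requested {k} non-fallers, training split has {len(nonfallers)}"
        )
    rng = _draw_rng(config.seed, draw_index)
    chosen = rng.choice(len(nonfallers), size=k, replace=False)
    return fallers + [nonfallers[i] for i in sorted(chosen)]


def gate_subset(subset: Cohort, validation: Cohort, config: SelectionConfig) -> float:
    """Validation accuracy of an SVM trained on the balanced subset.

    Features are standardized with the subset's own mean/SD (zero-SD features
    standardize to zero, with a warning); the classifier is an RBF-kernel SVM.
    The caller retains the subset iff the returned accuracy is strictly above
    ``config.accuracy_gate``.
    """
    x_train = subset.matrix()
    y_train = (subset.frame["fall_label"] == "faller").to_numpy()
    x_val = validation.matrix()
    y_val = (validation.frame["fall_label"] == "faller").to_numpy()

    scaler = StandardScaler()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        x_train_s = scaler.fit_transform(x_train)
    if np.any(scaler.scale_ == 1.0) and np.any(x_train.std(axis=0) == 0):
        constant = [
            subset.feature_names[j]
            for j in np.flatnonzero(x_train.std(axis=0) == 0)
        ]
        logger.warning("zero-SD feature(s) standardized to zero: %s", constant)
    x_val_s = scaler.transform(x_val)

    clf = SVC(C=config.svm_C, kernel="rbf", gamma=config.svm_gamma)
    clf.fit(x_train_s, y_train)
    return float(np.mean(clf.predict(x_val_s) == y_val))


def _two_group_p(a: np.ndarray, b: np.ndarray, alpha_normality: float) -> float | None:
    """Two-sided p for a group difference, routed by per-group normality.

    Returns None when the comparison is undefined (both groups constant).
    A group that is constant cannot be tested by Shapiro–Wilk and is treated
    as non-normal, routing to the rank-sum test.
    """
    a_const = np.ptp(a) == 0
    b_const = np.ptp(b) == 0
    if a_const and b_const:
        return None

    def _normal(x: np.ndarray, const: bool) -> bool:
        if const:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue > alpha_normality

    if _normal(a, a_const) and _normal(b, b_const):
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return float(stats.ranksums(a, b).pvalue)


def mark_relevant(subset: Cohort, config: SelectionConfig) -> set[str]:
    """Features whose faller/non-faller difference is significant in this subset.

    Per feature: Shapiro–Wilk on each group at ``alpha_normality``; both
    normal -> Welch t-test, otherwise Wilcoxon rank-sum; marked relevant iff
    the two-sided p < ``alpha_relevance``.  Features constant in both groups
    are never marked (the comparison is undefined).
    """
    for label in ("faller", "non_faller"):
        if (subset.frame["fall_label"] == label).sum() < 3:
            raise IngestError(f"subset has fewer than 3 {label} subjects")
    relevant: set[str] = set()
    faller_mask = (subset.frame["fall_label"] == "faller").to_numpy()
    matrix = subset.matrix()
    for j, name in enumerate(subset.feature_names):
        p = _two_group_p(
            matrix[faller_mask, j], matrix[~faller_mask, j], config.alpha_normality
        )
        if p is None:
            logger.warning("feature %s constant in both groups; not testable", name)
            continue
        if p < config.alpha_relevance:
            relevant.add(name)
    return relevant


def run_selection(
    train: Cohort, validation: Cohort, config: SelectionConfig
) -> SelectionResult:
    """Execute the full sample -> gate -> mark -> aggregate loop.

    Runs ``n_iterations`` distinct balanced draws (distinctness enforced by
    fingerprinting the sorted non-faller id set, with bounded redraws), gates
    each on validation accuracy, accumulates per-feature relevance counts
    over retained draws, and selects features whose relevance fraction
    reaches ``consensus_fraction``.  Deterministic given ``config.seed``.

    Raises
    ------
    SamplingExhaustedError
        If more distinct draws are requested than combinations exist.
    EmptySelectionError
        If no draw passes the accuracy gate; relax the gate or enlarge the
        validation split.
    """
    n_nonfallers = int((train.frame["fall_label"] == "non_faller").sum())
    k = config.subset_nonfallers
    n_possible = math.comb(n_nonfallers, k)
    if config.n_iterations > n_possible:
        raise SamplingExhaustedError(
            f"{config.n_iterations} distinct subsets requested but only "
            f"C({n_nonfallers},{k}) = {n_possible} exist"
        )

    counts: dict[str, int] = {name: 0 for name in train.feature_names}
    log: list[IterationRecord] = []
    seen: set[str] = set()
    n_retained = 0

    for draw_index in range(config.n_iterations):
        ids = None
        rng = _draw_rng(config.seed, draw_index)
        nonfaller_ids = train.frame.loc[
            train.frame["fall_label"] == "non_faller", "id"
        ].tolist()
        faller_ids = train.frame.loc[
            train.frame["fall_label"] == "faller", "id"
        ].tolist()
        if config.subset_fallers is not None:
            faller_ids = faller_ids[: config.subset_fallers]
        for _ in range(_MAX_REDRAWS):
            chosen = rng.choice(len(nonfaller_ids), size=k, replace=False)
            candidate_nonfallers = [nonfaller_ids[i] for i in sorted(chosen)]
            fp = _fingerprint(candidate_nonfallers)
            if fp not in seen:
                seen.add(fp)
                ids = faller_ids + candidate_nonfallers
                break
        if ids is None:
            raise SamplingExhaustedError(
                f"could not draw a fresh non-faller set at iteration {draw_index} "
                f"after {_MAX_REDRAWS} redraws (C({n_nonfallers},{k}) = {n_possible})"
            )

        subset = Cohort(
            train.frame[train.frame["id"].isin(ids)].reset_index(drop=True),
            train.registry,
            rng_seed=train.rng_seed,
        )
        accuracy = gate_subset(subset, validation, config)
        retained = accuracy > config.accuracy_gate
        log.append(IterationRecord(draw_index, fp, accuracy, retained))
        logger.debug("draw %d: gate accuracy %.4f retained=%s", draw_index, accuracy, retained)
        if retained:
            n_retained += 1
            for name in mark_relevant(subset, config):
                counts[name] += 1

    if n_retained == 0:
        raise EmptySelectionError(
            f"no subset out of {config.n_iterations} passed the accuracy gate "
            f"{config.accuracy_gate:.2f}; consider relaxing the gate"
        )

    denominator = (
        config.n_iterations
        if config.consensus_denominator == "iterations"
        else n_retained
    )
    selected = consensus_select(counts, denominator, config.consensus_fraction)
    return SelectionResult(
        relevance_counts=counts,
        n_retained_subsets=n_retained,
        n_iterations_run=config.n_iterations,
        consensus_fraction=config.consensus_fraction,
        consensus_denominator=config.consensus_denominator,
        selected_features=selected,
        per_iteration_log=log,
    )
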