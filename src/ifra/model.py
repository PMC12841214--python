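"""Model / results interface tying the pipeline together.

:class:`FallRiskModel` is built from a cohort (or a plain DataFrame) whose
splits are already assigned; ``fit()`` runs consensus feature selection on
the training split gated by the validation split, derives tertile thresholds,
and returns a :class:`FallRiskResults` carrying the scale, the selection
diagnostics, a ``summary()`` table, classification of new subjects and exact
evaluation against observed fall status.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, FeatureMeta, assign_splits
from .evaluate import ContingencyTable, build_contingency, fisher_freeman_halton
from .exceptions import DesignError
from .scale import ScaleDefinition, build_scale
from .selection import SelectionConfig, SelectionResult, run_selection
from .stratify import PatientAssessment, classify_cohort, assessments_to_frame

__all__ = ["FallRiskModel", "FallRiskResults"]


class FallRiskModel:
    """Derives a three-stratum fall-risk scale from a labelled feature table.

    Parameters
    ----------
    cohort : Cohort
        Subjects x features table with ``train`` and ``validation`` splits
        assigned (``test`` optional until evaluation).
    config : SelectionConfig, optional
        Consensus-selection tunables; defaults follow the study protocol.
    feature_family : str or None
        Restrict selection to one registry family (e.g. ``"itug"``);
        ``None`` uses every feature.

    Examples
    --------
    >>> from ifra import SimulationConfig, generate_cohort, FallRiskModel
    >>> cohort = assign_splits(augment_fallers(generate_cohort(cfg), aug), seed=0)
    >>> results = FallRiskModel(cohort).fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        cohort: Cohort,
        config: SelectionConfig | None = None,
        feature_family: str | None = None,
    ) -> None:
        self.cohort = cohort
        self.config = config or SelectionConfig()
        self.feature_family = feature_family
        counts = cohort.counts()
        for split in ("train", "validation"):
            if not any(s == split for (s, _), n in counts.items() if n > 0):
                raise DesignError(f"cohort has no subjects in the {split!r} split")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        registry: Sequence[FeatureMeta] | None = None,
        config: SelectionConfig | None = None,
        split_design: Mapping[tuple[str, str], int] | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "FallRiskModel":
        """Build from a DataFrame with the reserved columns; if the split
        column is all ``unassigned``, draw splits from ``split_design``."""
        if registry is None:
            feature_cols = [
                c
                for c in frame.columns
                if c not in ("id", "fall_label", "provenance", "split")
            ]
            registry = [FeatureMeta(name=c) for c in feature_cols]
        cohort = Cohort(frame.reset_index(drop=True), list(registry))
        if (cohort.frame["split"] == "unassigned").all():
            cohort = assign_splits(cohort, split_design, seed=seed)
        return cls(cohort, config=config, **kwargs)

    def _working_cohort(self) -> Cohort:
        if self.feature_family is None:
            return self.cohort
        keep = [m for m in self.cohort.registry if m.family == self.feature_family]
        names = [m.name for m in keep]
        cols = ["id", "fall_label", "provenance", "split"] + names
        return Cohort(
            self.cohort.frame[cols].copy(), keep, rng_seed=self.cohort.rng_seed
        )

    def fit(self) -> "FallRiskResults":
        """Run selection + threshold derivation and return the results object."""
        working = self._working_cohort()
        train = working.view(split="train")
        validation = working.view(split="validation")
        selection = run_selection(train, validation, self.config)
        scale = build_scale(train, selection, registry=working.registry)
        return FallRiskResults(model=self, selection=selection, scale=scale)


@dataclass
class FallRiskResults:
    """Fitted scale plus diagnostics; entry point for stratification and tests."""

    model: FallRiskModel
    selection: SelectionResult
    scale: ScaleDefinition
    _assessment_cache: dict = field(default_factory=dict, repr=False)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Text summary in the spirit of a fitted-model report."""
        sel = self.selection
        buf = io.StringIO()
        counts = self.model.cohort.counts()
        n_train = sum(n for (s, _), n in counts.items() if s == "train")
        n_val = sum(n for (s, _), n in counts.items() if s == "validation")
        gate_rate = sel.n_retained_subsets / max(sel.n_iterations_run, 1)
        buf.write("Instrumented fall-risk scale\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"Training subjects:        {n_train}\n")
        buf.write(f"Validation subjects:      {n_val}\n")
        buf.write(
            f"Subsampling draws:        {sel.n_iterations_run} "
            f"(retained {sel.n_retained_subsets}, gate pass rate {gate_rate:.1%})\n"
        )
        buf.write(
            f"Consensus rule:           marked relevant in >= "
            f"{sel.consensus_fraction:.0%} of {sel.consensus_denominator} draws\n"
        )
        buf.write(f"Selected features (M):    {len(self.scale)}\n\n")
        table = self.scale.to_table()
        buf.write(table.to_string(index=False))
        return buf.getvalue()

    # -- application -------------------------------------------------------

    def classify(
        self, cohort: Cohort | None = None, split: str | None = "test"
    ) -> list[PatientAssessment]:
        """Stratify subjects (default: the model cohort's test split)."""
        target = cohort if cohort is not None else self.model.cohort
        return classify_cohort(target, self.scale, split=split)

    def assessments_frame(
        self, cohort: Cohort | None = None, split: str | None = "test"
    ) -> pd.DataFrame:
        return assessments_to_frame(self.classify(cohort, split))

    def contingency(
        self, cohort: Cohort | None = None, split: str | None = "test"
    ) -> ContingencyTable:
        """2x3 fall-status x stratum table for a split."""
        target = cohort if cohort is not None else self.model.cohort
        assessments = self.classify(target, split)
        view = target if split is None else target.view(split=split)
        labels = view.frame["fall_label"].tolist()
        return build_contingency(
            [(label, a.final) for label, a in zip(labels, assessments)]
        )

    def evaluate(
        self, cohort: Cohort | None = None, split: str | None = "test"
    ) -> float:
        """Exact p-value for association between strata and fall status."""
        return fisher_freeman_halton(self.contingency(cohort, split))

    def plot_strata(self, cohort: Cohort | None = None, split: str | None = "test",
                    ax=None):
        """Grouped bar chart of stratum occupancy by fall status."""
        import matplotlib.pyplot as plt

        table = self.contingency(cohort, split)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        x = np.arange(3)
        width = 0.38
        ax.bar(x - width / 2, table.counts[0], width, label="non-fallers")
        ax.bar(x + width / 2, table.counts[1], width, label="fallers")
        ax.set_xticks(x, table.col_labels)
        ax.set_ylabel("subjects")
        ax.set_xlabel("assigned risk stratum")
        ax.legend(frameon=False)
        return ax
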