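"""Risk-scale construction: per-feature risk direction and tertile cut-points.

For each selected feature the training values are ranked in the
risk-increasing direction (ascending when higher values mean more risk,
descending otherwise) and the values of the subjects at ranks ceil(n/3) and
ceil(2n/3) become the two thresholds — at the study's training size n=93
these are ranks 31 and 62, splitting the ranking into three sets of 31.
Thresholds are therefore always observed training values, never
interpolations.  The assembled scale orders its rules by descending
selection frequency, the analogue of ordering a published scale's rows by
discriminative power.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, FeatureMeta
from .exceptions import ScaleError
from .selection import SelectionResult

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRule",
    "ScaleDefinition",
    "infer_direction",
    "derive_thresholds",
    "training_rank_strata",
    "build_scale",
]

HIGHER = "higher_is_riskier"
LOWER = "lower_is_riskier"


@dataclass(frozen=True)
class FeatureRule:
    """One scale row: a feature, its risk direction and two tertile thresholds.

    ``threshold_a`` delimits the low stratum and ``threshold_b`` the high
    stratum.  For a higher-is-riskier feature threshold_a <= threshold_b and
    low means value <= threshold_a, high means value >= threshold_b; for a
    lower-is-riskier feature the inequalities mirror (threshold_a >=
    threshold_b, low iff value >= threshold_a, high iff value <= threshold_b).
    The medium stratum is the open interval between the two.
    """

    feature: str
    direction: str
    threshold_a: float
    threshold_b: float
    selection_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise ScaleError(f"unknown direction {self.direction!r}")
        if self.direction == HIGHER and self.threshold_a > self.threshold_b:
            raise ScaleError(
                f"{self.feature}: higher_is_riskier requires threshold_a <= threshold_b"
            )
        if self.direction == LOWER and self.threshold_a < self.threshold_b:
            raise ScaleError(
                f"{self.feature}: lower_is_riskier requires threshold_a >= threshold_b"
            )

    def describe(self) -> dict[str, str]:
        """Interval rendering in the printed-scale convention."""
        a, b = self.threshold_a, self.threshold_b
        if self.direction == LOWER:
            return {
                "low": f"x >= {a:g}",
                "medium": f"{b:g} < x < {a:g}",
                "high": f"x <= {b:g}",
            }
        return {
            "low": f"x <= {a:g}",
            "medium": f"{a:g} < x < {b:g}",
            "high": f"x >= {b:g}",
        }


@dataclass
class ScaleDefinition:
    """An ordered collection of feature rules plus provenance of its derivation."""

    rules: list[FeatureRule]
    training_size: int
    provenance: dict | None = None

    def __post_init__(self) -> None:
        names = [r.feature for r in self.rules]
        if len(set(names)) != len(names):
            raise ScaleError("duplicate features in scale")

    @property
    def features(self) -> list[str]:
        return [r.feature for r in self.rules]

    def rule(self, feature: str) -> FeatureRule:
        for r in self.rules:
            if r.feature == feature:
                return r
        raise KeyError(feature)

    def __len__(self) -> int:
        return len(self.rules)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "training_size": self.training_size,
            "provenance": self.provenance,
            "rules": [asdict(r) for r in self.rules],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleDefinition":
        payload = json.loads(Path(path).read_text())
        return cls(
            rules=[FeatureRule(**r) for r in payload["rules"]],
            training_size=payload["training_size"],
            provenance=payload.get("provenance"),
        )

    def to_table(self) -> pd.DataFrame:
        """Human-readable table in the printed-scale layout."""
        rows = []
        for r in self.rules:
            desc = r.describe()
            rows.append(
                {
                    "feature": r.feature,
                    "low_risk_threshold": desc["low"],
                    "medium_risk_threshold": desc["medium"],
                    "high_risk_threshold": desc["high"],
                    "pct_of_selections": (
                        f"{100 * r.selection_fraction:.0f}%"
                        if not math.isnan(r.selection_fraction)
                        else ""
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def infer_direction(
    train: Cohort, feature: str, hint: str | None = None
) -> str:
    """Risk direction for a feature: the registry hint when present, otherwise
    the sign of the faller-minus-non-faller training mean difference (exact
    ties resolve to higher_is_riskier with a warning)."""
    if hint is not None:
        return hint
    faller_mean = float(np.mean(train.values(feature, "faller")))
    nonfaller_mean = float(np.mean(train.values(feature, "non_faller")))
    if faller_mean > nonfaller_mean:
        return HIGHER
    if faller_mean < nonfaller_mean:
        return LOWER
    logger.warning(
        "feature %s: equal group means; defaulting to higher_is_riskier", feature
    )
    return HIGHER


def derive_thresholds(
    train: Cohort,
    feature: str,
    direction: str,
    selection_fraction: float = float("nan"),
) -> FeatureRule:
    """Tertile thresholds of a feature over the training split.

    The n training values are sorted in risk-increasing order and the values
    at ranks ceil(n/3) and ceil(2n/3) (1-based) become the thresholds; at
    n=93 these are ranks 31 and 62 and the three rank tertiles have 31
    subjects each.
    """
    values = train.values(feature)
    n = len(values)
    if n < 3:
        raise ScaleError(f"{feature}: need at least 3 training subjects, have {n}")
    ascending = direction == HIGHER
    ordered = np.sort(values)
    if not ascending:
        ordered = ordered[::-1]
    k1 = math.ceil(n / 3)
    k2 = math.ceil(2 * n / 3)
    threshold_a = float(ordered[k1 - 1])
    threshold_b = float(ordered[k2 - 1])
    if threshold_a == threshold_b:
        logger.warning(
            "feature %s: tied values collapse the medium stratum (both thresholds %g)",
            feature,
            threshold_a,
        )
    return FeatureRule(
        feature=feature,
        direction=direction,
        threshold_a=threshold_a,
        threshold_b=threshold_b,
        selection_fraction=selection_fraction,
    )


def training_rank_strata(
    train: Cohort, feature: str, direction: str
) -> np.ndarray:
    """The rank-tertile division of the training subjects for one feature.

    This is the partition the threshold derivation is built on: subjects
    ranked in risk-increasing order, ranks <= ceil(n/3) low, ranks up to
    ceil(2n/3) medium, the rest high — exactly (31, 31, 31) at n=93.
    Returned as an array of ``"low"``/``"medium"``/``"high"`` aligned with
    the training frame's row order.  Note that re-applying the *value*-based
    boundary rule (extreme intervals closed) moves the rank-k2 subject into
    the high stratum, since its value sits on the high boundary.
    """
    values = train.values(feature)
    n = len(values)
    if n < 3:
        raise ScaleError(f"{feature}: need at least 3 training subjects, have {n}")
    ascending = direction == HIGHER
    order = np.argsort(values if ascending else -values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    k1 = math.ceil(n / 3)
    k2 = math.ceil(2 * n / 3)
    out = np.where(ranks <= k1, "low", np.where(ranks <= k2, "medium", "high"))
    return out


def build_scale(
    train: Cohort,
    selection: SelectionResult,
    registry: Sequence[FeatureMeta] | None = None,
) -> ScaleDefinition:
    """Assemble a scale from a selection result over the training split.

    One rule per selected feature (direction from the registry hint when
    available, else inferred from training means; thresholds from the rank
    tertiles), ordered by descending selection fraction with lexicographic
    tie-break.
    """
    if not selection.selected_features:
        raise ScaleError("selection produced no features; cannot build a scale")
    if registry is None:
        registry = train.registry
    hints = {m.name: m.direction_hint for m in registry}
    rules = []
    for feature in selection.selected_features:
        direction = infer_direction(train, feature, hints.get(feature))
        rules.append(
            derive_thresholds(
                train, feature, direction, selection.selection_fraction(feature)
            )
        )
    rules.sort(key=lambda r: (-r.selection_fraction, r.feature))
    return ScaleDefinition(
        rules=rules,
        training_size=train.n_subjects,
        provenance={
            "n_retained_subsets": selection.n_retained_subsets,
            "n_iterations_run": selection.n_iterations_run,
            "consensus_fraction": selection.consensus_fraction,
            "consensus_denominator": selection.consensus_denominator,
        },
    )
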