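"""Assigning subjects to ordinal risk strata and combining per-feature votes.

Each feature value is compared against its rule's two thresholds; boundary
values belong to the extreme strata (the low and high intervals are closed,
the medium interval is open on both sides, matching the printed convention
"x >= a / b < x < a / x <= b").  A subject's overall stratum is the mode of
the per-feature strata, with frequency ties resolved to the higher-risk
stratum (medium over low, high over medium).

Clinical comparator rules — single-feature three-stratum rules for eight
bedside scales (Mini-BESTest, FIM total and motor, POMA-B, TUG total
duration, FES-I, Conley, 10 m walking speed) with literature-derived
thresholds — ship as a versioned YAML fixture.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .cohort import Cohort
from .exceptions import ClassificationError
from .scale import HIGHER, LOWER, FeatureRule, ScaleDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "PatientAssessment",
    "ClinicalRule",
    "load_clinical_rules",
    "assign_feature_stratum",
    "combine_strata",
    "classify_patient",
    "classify_cohort",
    "clinical_stratify",
]


class Stratum(enum.IntEnum):
    """Ordered risk stratum; comparisons follow low < medium < high."""

    low = 0
    medium = 1
    high = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class ClinicalRule:
    """Three-stratum rule for one clinical scale (literature thresholds)."""

    scale: str
    feature: str
    direction: str
    threshold_a: float
    threshold_b: float
    source: str = ""


@dataclass
class PatientAssessment:
    """Per-feature and final strata for one subject."""

    subject_id: str
    per_feature_strata: dict[str, Stratum]
    final: Stratum
    n_features_used: int


def load_clinical_rules(path: str | Path | None = None) -> list[ClinicalRule]:
    """Load the bundled clinical comparator rules (or a user-supplied YAML)."""
    if path is None:
        text = (
            resources.files("ifra").joinpath("data/clinical_rules.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text)
    return [ClinicalRule(**e) for e in entries]


def assign_feature_stratum(value: float, rule: FeatureRule | ClinicalRule) -> Stratum:
    """Stratum of a single value under a rule; boundaries go to the extremes."""
    if not math.isfinite(value):
        raise ClassificationError(f"non-finite value {value!r} for {rule.feature}")
    if rule.direction == LOWER:
        if value >= rule.threshold_a:
            return Stratum.low
        if value <= rule.threshold_b:
            return Stratum.high
        return Stratum.medium
    if rule.direction == HIGHER:
        if value <= rule.threshold_a:
            return Stratum.low
        if value >= rule.threshold_b:
            return Stratum.high
        return Stratum.medium
    raise ClassificationError(f"unknown direction {rule.direction!r}")


def combine_strata(per_feature: Iterable[Stratum]) -> Stratum:
    """Mode of the per-feature strata; frequency ties resolve to higher risk."""
    counts = Counter(per_feature)
    if not counts:
        raise ClassificationError("cannot combine an empty stratum list")
    top = max(counts.values())
    return max(s for s, c in counts.items() if c == top)


def classify_patient(
    subject: Mapping[str, float] | pd.Series,
    scale: ScaleDefinition,
    subject_id: str = "",
    min_features_required: int | None = None,
) -> PatientAssessment:
    """Assess one subject against a scale.

    ``subject`` maps feature names to values.  By default every scale feature
    must be present (complete records); ``min_features_required`` admits
    subjects with at least that many scale features, taking the mode over the
    available ones.
    """
    if min_features_required is None:
        min_features_required = len(scale)
    available = [r for r in scale.rules if r.feature in subject]
    if len(available) < min_features_required:
        missing = [r.feature for r in scale.rules if r.feature not in subject]
        raise ClassificationError(
            f"subject {subject_id or '?'}: {len(available)} of {len(scale)} scale "
            f"features available (need {min_features_required}); missing: {missing}"
        )
    strata = {
        r.feature: assign_feature_stratum(float(subject[r.feature]), r)
        for r in available
    }
    return PatientAssessment(
        subject_id=subject_id or str(subject.get("id", "")),
        per_feature_strata=strata,
        final=combine_strata(strata.values()),
        n_features_used=len(strata),
    )


def classify_cohort(
    cohort: Cohort,
    scale: ScaleDefinition,
    split: str | None = None,
    min_features_required: int | None = None,
) -> list[PatientAssessment]:
    """Assess every subject (optionally of one split) against a scale."""
    view = cohort if split is None else cohort.view(split=split)
    out = []
    for _, row in view.frame.iterrows():
        out.append(
            classify_patient(
                row,
                scale,
                subject_id=str(row["id"]),
                min_features_required=min_features_required,
            )
        )
    return out


def clinical_stratify(
    subject: Mapping[str, float] | pd.Series,
    rules: Sequence[ClinicalRule] | None = None,
) -> dict[str, Stratum]:
    """Independent single-feature stratification by each clinical scale.

    Scales whose feature the subject lacks are skipped with a log message
    rather than failing the whole assessment.
    """
    if rules is None:
        rules = load_clinical_rules()
    out: dict[str, Stratum] = {}
    for rule in rules:
        if rule.feature not in subject or (
            isinstance(subject, pd.Series) and pd.isna(subject[rule.feature])
        ):
            logger.warning(
                "subject lacks %s (feature %s); scale skipped", rule.scale, rule.feature
            )
            continue
        out[rule.scale] = assign_feature_stratum(float(subject[rule.feature]), rule)
    return out


def assessments_to_frame(assessments: Sequence[PatientAssessment]) -> pd.DataFrame:
    """Tabular rendering: id, one column per feature stratum, final stratum."""
    rows = []
    for a in assessments:
        row = {"id": a.subject_id}
        row.update({f: s.name for f, s in a.per_feature_strata.items()})
        row["final"] = a.final.name
        row["n_features_used"] = a.n_features_used
        rows.append(row)
    return pd.DataFrame(rows)
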