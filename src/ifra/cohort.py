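"""Subject-level feature tables: the cohort container, its CSV I/O and split design.

A *cohort* is a subjects x features matrix plus, per subject, a binary fall
label (``faller`` / ``non_faller``), a provenance flag (``real`` subjects were
measured; ``synthetic`` ones were created by augmentation and are confined to
the training split) and a split assignment (``train`` / ``validation`` /
``test`` / ``unassigned``).  A *feature registry* lists the feature names with
units, family (``clinical`` or ``itug``) and an optional prior on the risk
direction.

The container wraps a :class:`pandas.DataFrame` with four reserved columns
(``id``, ``fall_label``, ``provenance``, ``split``) followed by one float
column per registered feature.  CSV serialisation uses 17 significant digits
so that write -> read round-trips are bit-exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DesignError, IngestError

logger = logging.getLogger(__name__)

RESERVED_COLUMNS = ("id", "fall_label", "provenance", "split")
FALL_LABELS = ("faller", "non_faller")
PROVENANCES = ("real", "synthetic")
SPLITS = ("train", "validation", "test", "unassigned")

#: The study's fixed split design: 93 training (54 non-fallers + 39 fallers,
#: synthetic fallers included), 17 validation (12 + 5), 32 test (22 + 10).
PAPER_SPLIT_DESIGN: dict[tuple[str, str], int] = {
    ("train", "non_faller"): 54,
    ("train", "faller"): 39,
    ("validation", "non_faller"): 12,
    ("validation", "faller"): 5,
    ("test", "non_faller"): 22,
    ("test", "faller"): 10,
}


@dataclass(frozen=True)
class FeatureMeta:
    """Registry entry for one feature.

    Parameters
    ----------
    name : str
        Unique feature identifier (CSV column name).
    units : str
        Free-text units, e.g. ``"m/s^2"``.
    family : str
        ``"clinical"`` (bedside scales, TUG stopwatch time, walking speed)
        or ``"itug"`` (IMU-derived measures from the instrumented TUG).
    direction_hint : str or None
        Optional prior on the risk direction: ``"higher_is_riskier"``,
        ``"lower_is_riskier"`` or ``None``/``"unknown"`` when no prior exists.
    """

    name: str
    units: str = ""
    family: str = "itug"
    direction_hint: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("clinical", "itug"):
            raise IngestError(f"feature {self.name!r}: unknown family {self.family!r}")
        if self.direction_hint in ("", "unknown"):
            object.__setattr__(self, "direction_hint", None)
        if self.direction_hint not in (None, "higher_is_riskier", "lower_is_riskier"):
            raise IngestError(
                f"feature {self.name!r}: unknown direction_hint {self.direction_hint!r}"
            )


@dataclass
class Cohort:
    """Subjects x features table with labels, provenance and split assignment.

    ``frame`` holds one row per subject with the reserved columns followed by
    one float64 column per feature in ``registry``; ``rng_seed`` records the
    seed used to create the cohort when it came from the simulator.
    """

    frame: pd.DataFrame
    registry: list[FeatureMeta]
    rng_seed: int | None = None
    _meta_by_name: dict[str, FeatureMeta] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._meta_by_name = {m.name: m for m in self.registry}
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.registry]

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def n_features(self) -> int:
        return len(self.registry)

    def meta(self, feature: str) -> FeatureMeta:
        return self._meta_by_name[feature]

    def validate(self) -> None:
        """Check the container invariants; raise :class:`IngestError` on violation."""
        names = [m.name for m in self.registry]
        if len(set(names)) != len(names):
            raise IngestError("duplicate feature names in registry")
        for col in RESERVED_COLUMNS:
            if col not in self.frame.columns:
                raise IngestError(f"missing reserved column {col!r}")
        missing = set(names) - set(self.frame.columns)
        if missing:
            raise IngestError(f"cohort lacks registered features: {sorted(missing)}")
        extra = set(self.frame.columns) - set(names) - set(RESERVED_COLUMNS)
        if extra:
            raise IngestError(f"cohort has unregistered columns: {sorted(extra)}")
        ids = self.frame["id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise IngestError(f"duplicate subject id: {dup.iloc[0]!r}")
        for col, allowed in (
            ("fall_label", FALL_LABELS),
            ("provenance", PROVENANCES),
            ("split", SPLITS),
        ):
            bad = ~self.frame[col].isin(allowed)
            if bad.any():
                value = self.frame.loc[bad, col].iloc[0]
                raise IngestError(f"invalid {col} value {value!r}")
        synth_outside = (self.frame["provenance"] == "synthetic") & ~self.frame[
            "split"
        ].isin(["train", "unassigned"])
        if synth_outside.any():
            sid = self.frame.loc[synth_outside, "id"].iloc[0]
            raise IngestError(f"synthetic subject {sid!r} outside the training split")
        values = self.frame[names].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            row = int(np.argwhere(~np.isfinite(values))[0, 0])
            sid = self.frame["id"].iloc[row]
            raise IngestError(f"non-finite feature value for subject {sid!r}")

    # -- queries -----------------------------------------------------------

    def counts(self) -> dict[tuple[str, str], int]:
        """Subject counts keyed by (split, fall_label)."""
        grouped = self.frame.groupby(["split", "fall_label"], observed=True).size()
        return {(s, l): int(n) for (s, l), n in grouped.items()}

    def label_counts(self) -> dict[str, int]:
        return {l: int(n) for l, n in self.frame["fall_label"].value_counts().items()}

    def view(
        self,
        split: str | None = None,
        fall_label: str | None = None,
        provenance: str | None = None,
    ) -> "Cohort":
        """Row-filtered shallow view sharing the registry (a new Cohort)."""
        mask = pd.Series(True, index=self.frame.index)
        if split is not None:
            mask &= self.frame["split"] == split
        if fall_label is not None:
            mask &= self.frame["fall_label"] == fall_label
        if provenance is not None:
            mask &= self.frame["provenance"] == provenance
        return Cohort(
            self.frame.loc[mask].reset_index(drop=True),
            self.registry,
            rng_seed=self.rng_seed,
        )

    def values(self, feature: str, fall_label: str | None = None) -> np.ndarray:
        """Feature values as float array, optionally restricted to one label."""
        if fall_label is None:
            return self.frame[feature].to_numpy(dtype=float)
        mask = self.frame["fall_label"] == fall_label
        return self.frame.loc[mask, feature].to_numpy(dtype=float)

    def matrix(self) -> np.ndarray:
        """Subjects x features float matrix in registry order."""
        return self.frame[self.feature_names].to_numpy(dtype=float)


# -- registry I/O ----------------------------------------------------------


def read_registry(path: str | Path) -> list[FeatureMeta]:
    """Load a feature registry from CSV (columns name/units/family/direction_hint)
    or from YAML (a list of mappings with the same keys)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        entries = yaml.safe_load(path.read_text())
        if not isinstance(entries, list):
            raise IngestError(f"registry {path}: expected a YAML list")
    else:
        table = pd.read_csv(path, dtype=str).fillna("")
        if "name" not in table.columns:
            raise IngestError(f"registry {path}: missing column 'name'")
        entries = table.to_dict(orient="records")
    registry = []
    for entry in entries:
        registry.append(
            FeatureMeta(
                name=str(entry["name"]),
                units=str(entry.get("units", "") or ""),
                family=str(entry.get("family", "itug") or "itug"),
                direction_hint=(entry.get("direction_hint") or None),
            )
        )
    return registry


def write_registry(registry: Sequence[FeatureMeta], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "name": m.name,
            "units": m.units,
            "family": m.family,
            "direction_hint": m.direction_hint or "",
        }
        for m in registry
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


# -- cohort I/O ------------------------------------------------------------


def read_cohort(
    path: str | Path,
    registry_path: str | Path | None = None,
    registry: Sequence[FeatureMeta] | None = None,
    drop_incomplete: bool = False,
) -> Cohort:
    """Read a cohort CSV (reserved columns + one column per feature).

    Exactly one of ``registry_path`` / ``registry`` may be given; with neither,
    every non-reserved column becomes an ``itug`` feature with no hints.
    Missing or unparseable feature values are rejected (the upstream study
    excluded incomplete records); ``drop_incomplete=True`` downgrades this to
    dropping the offending rows with a logged count.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    for col in RESERVED_COLUMNS:
        if col not in raw.columns:
            raise IngestError(f"cohort {path}: missing reserved column {col!r}")
    if registry is not None and registry_path is not None:
        raise IngestError("pass registry_path or registry, not both")
    if registry_path is not None:
        registry = read_registry(registry_path)
    feature_cols = [c for c in raw.columns if c not in RESERVED_COLUMNS]
    if registry is None:
        registry = [FeatureMeta(name=c) for c in feature_cols]
    names = [m.name for m in registry]
    missing = set(names) - set(feature_cols)
    if missing:
        raise IngestError(f"cohort {path}: missing feature columns {sorted(missing)}")

    # pd.to_numeric's fast parser is not round-trip exact, so it is used only
    # to locate bad rows; the kept values go through Python's float(), which
    # is correctly rounded and makes write -> read lossless.
    coerced = raw[names].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(coerced.to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        if drop_incomplete:
            logger.warning(
                "dropping %d incomplete row(s) from %s", int(bad.sum()), path
            )
            raw = raw.loc[~bad].reset_index(drop=True)
        else:
            sid = raw.loc[bad, "id"].iloc[0]
            raise IngestError(
                f"cohort {path}: non-numeric or missing feature value for subject {sid!r}"
            )
    numeric = pd.DataFrame(
        raw[names].to_numpy(dtype=object).astype(np.float64),
        columns=names,
    )
    frame = pd.concat(
        [raw[list(RESERVED_COLUMNS)].astype(str).reset_index(drop=True), numeric],
        axis=1,
    )
    return Cohort(frame, list(registry))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort CSV with 17 significant digits (lossless round-trip)."""
    path = Path(path)
    cols = list(RESERVED_COLUMNS) + cohort.feature_names
    cohort.frame[cols].to_csv(path, index=False, float_format="%.17g")


# -- split assignment ------------------------------------------------------


def assign_splits(
    cohort: Cohort,
    design: Mapping[tuple[str, str], int] | None = None,
    seed: int = 0,
) -> Cohort:
    """Assign train/validation/test splits by a label-stratified uniform draw.

    ``design`` maps ``(split, fall_label)`` to a subject count and must use up
    every subject of each label exactly.  Synthetic subjects are confined to
    the training split, so each label's synthetic count must fit inside its
    training quota.  Deterministic given ``seed``; returns a new cohort.
    """
    if design is None:
        design = PAPER_SPLIT_DESIGN
    design = {k: int(v) for k, v in design.items()}
    for (split, label), n in design.items():
        if split not in SPLITS or label not in FALL_LABELS or n < 0:
            raise DesignError(f"invalid design entry {(split, label)}: {n}")

    frame = cohort.frame.copy()
    rng = np.random.default_rng(seed)
    new_split = pd.Series("unassigned", index=frame.index)

    for label in FALL_LABELS:
        quota = {
            s: design.get((s, label), 0) for s in ("train", "validation", "test")
        }
        label_mask = frame["fall_label"] == label
        available = int(label_mask.sum())
        if sum(quota.values()) != available:
            raise DesignError(
                f"design requests {sum(quota.values())} {label} subjects, "
                f"cohort has {available}"
            )
        synth_idx = frame.index[label_mask & (frame["provenance"] == "synthetic")]
        if len(synth_idx) > quota["train"]:
            raise DesignError(
                f"{len(synth_idx)} synthetic {label} subjects exceed the "
                f"training quota of {quota['train']}"
            )
        # synthetic subjects are pinned to train; the rest is a uniform draw
        new_split.loc[synth_idx] = "train"
        quota["train"] -= len(synth_idx)
        real_idx = frame.index[label_mask & (frame["provenance"] == "real")].to_numpy()
        rng.shuffle(real_idx)
        start = 0
        for split_name in ("train", "validation", "test"):
            stop = start + quota[split_name]
            new_split.loc[real_idx[start:stop]] = split_name
            start = stop

    frame["split"] = new_split
    return Cohort(frame, cohort.registry, rng_seed=cohort.rng_seed)
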