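"""Synthetic cohorts with planted group differences, and minority-class augmentation.

The generator emulates the structure the scale-derivation pipeline assumes: a
small imbalanced cohort (default 39 fallers vs 88 non-fallers over 108
continuous features, matching the study population after exclusion of
incomplete records) in which a subset of features carries a standardized
group-mean shift between fallers and non-fallers while the rest are
exchangeable noise.  Augmentation implements the study's minority-class
scheme: copy k randomly chosen fallers and perturb every feature with
zero-mean Gaussian noise whose SD is proportional to that feature's
faller-group SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import RESERVED_COLUMNS, Cohort, FeatureMeta
from .exceptions import AugmentationError, IngestError

__all__ = ["SimulationConfig", "AugmentationConfig", "generate_cohort", "augment_fallers"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the study cohort: 39 fallers, 88 non-fallers, 108
    features of which 22 are informative (the study's scale retained 22).

    effect_size
        Standardized mean difference (Cohen's d) applied to each informative
        feature, in a per-feature random direction.
    within_class_correlation
        Equicorrelation among the informative features (single shared factor).
    heavy_tail_fraction
        Fraction of features transformed to a log-normal scale before the
        shift is applied, to mimic skewed mobility measures.
    """

    n_fallers: int = 39
    n_nonfallers: int = 88
    n_features: int = 108
    n_informative: int = 22
    effect_size: float = 1.0
    within_class_correlation: float = 0.0
    heavy_tail_fraction: float = 0.0
    lognormal_sigma: float = 0.5
    record_direction_hints: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise IngestError("n_informative exceeds n_features")
        if self.effect_size < 0:
            raise IngestError("effect_size must be nonnegative")
        if not 0 <= self.within_class_correlation < 1:
            raise IngestError("within_class_correlation must be in [0, 1)")
        if not 0 <= self.heavy_tail_fraction <= 1:
            raise IngestError("heavy_tail_fraction must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls(**(yaml.safe_load(open(path)) or {}))


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the minority-class Gaussian augmentation.

    ``noise_scale`` multiplies the per-feature faller-group sample SD; the
    default 0.1 keeps synthetic subjects close to their templates while
    avoiding exact duplicates.
    """

    k: int = 15
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise AugmentationError("k must be nonnegative")
        if self.noise_scale <= 0:
            raise AugmentationError("noise_scale must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AugmentationConfig":
        return cls(**(yaml.safe_load(open(path)) or {}))


def _lognormal_sd(sigma: float) -> float:
    # SD of exp(sigma * Z), Z standard normal
    return math.sqrt((math.exp(sigma**2) - 1.0) * math.exp(sigma**2))


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a cohort of real subjects with planted informative features.

    Informative features get a faller-group mean shift of
    ``effect_size x SD(feature)`` in a randomly chosen direction; null
    features are identically distributed in both groups.  The planted
    direction is recorded in the registry's ``direction_hint`` unless
    ``record_direction_hints`` is off (forcing downstream inference).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    p, n_inf = config.n_features, config.n_informative
    n = config.n_fallers + config.n_nonfallers

    informative = np.sort(rng.choice(p, size=n_inf, replace=False))
    directions = rng.choice([1.0, -1.0], size=n_inf)  # +1: fallers shifted up
    heavy = rng.random(p) < config.heavy_tail_fraction

    z = rng.standard_normal((n, p))
    rho = config.within_class_correlation
    if rho > 0 and n_inf > 0:
        shared = rng.standard_normal(n)[:, None]
        z[:, informative] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * z[
            :, informative
        ]

    x = np.where(heavy[None, :], np.exp(config.lognormal_sigma * z), z)
    feature_sd = np.where(heavy, _lognormal_sd(config.lognormal_sigma), 1.0)

    is_faller = np.zeros(n, dtype=bool)
    is_faller[: config.n_fallers] = True
    for j, sign in zip(informative, directions):
        x[is_faller, j] += sign * config.effect_size * feature_sd[j]

    width = len(str(p))
    names = [f"f{j + 1:0{width}d}" for j in range(p)]
    hint_by_index = {
        j: ("higher_is_riskier" if s > 0 else "lower_is_riskier")
        for j, s in zip(informative, directions)
    }
    registry = [
        FeatureMeta(
            name=name,
            family="itug",
            direction_hint=(
                hint_by_index.get(j) if config.record_direction_hints else None
            ),
        )
        for j, name in enumerate(names)
    ]

    frame = pd.DataFrame(x, columns=names)
    frame.insert(0, "id", [f"S{i + 1:03d}" for i in range(n)])
    frame.insert(1, "fall_label", np.where(is_faller, "faller", "non_faller"))
    frame.insert(2, "provenance", "real")
    frame.insert(3, "split", "unassigned")
    cohort = Cohort(frame, registry, rng_seed=config.seed)
    # stash ground truth for simulation studies (not serialized)
    cohort.planted_features = [names[j] for j in informative]  # type: ignore[attr-defined]
    cohort.planted_directions = {  # type: ignore[attr-defined]
        names[j]: ("higher_is_riskier" if s > 0 else "lower_is_riskier")
        for j, s in zip(informative, directions)
    }
    return cohort


def augment_fallers(cohort: Cohort, config: AugmentationConfig) -> Cohort:
    """Append k noisy copies of distinct randomly chosen real fallers.

    Each copy adds independent N(0, (noise_scale * sd_f)^2) noise per feature,
    where sd_f is the faller-group sample SD of that feature among real
    fallers; zero-variance features are copied verbatim.  New subjects carry
    ``provenance="synthetic"``, ``fall_label="faller"`` and ``split="train"``.
    Existing rows are never modified.
    """
    if config.k == 0:
        return cohort
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    frame = cohort.frame
    faller_mask = (frame["fall_label"] == "faller") & (frame["provenance"] == "real")
    n_real_fallers = int(faller_mask.sum())
    if config.k > n_real_fallers:
        raise AugmentationError(
            f"cannot augment: k={config.k} exceeds {n_real_fallers} real fallers"
        )
    names = cohort.feature_names
    faller_values = frame.loc[faller_mask, names].to_numpy(dtype=float)
    sd = faller_values.std(axis=0, ddof=1) if n_real_fallers > 1 else np.zeros(len(names))

    template_rows = rng.choice(np.flatnonzero(faller_mask.to_numpy()), size=config.k,
                               replace=False)
    noise = rng.standard_normal((config.k, len(names))) * (config.noise_scale * sd)
    new_values = frame.iloc[template_rows][names].to_numpy(dtype=float) + noise

    new_frame = pd.DataFrame(new_values, columns=names)
    new_frame.insert(0, "id", [f"syn{i + 1:03d}" for i in range(config.k)])
    new_frame.insert(1, "fall_label", "faller")
    new_frame.insert(2, "provenance", "synthetic")
    new_frame.insert(3, "split", "train")
    existing_ids = set(frame["id"].astype(str))
    clash = [i for i in new_frame["id"] if i in existing_ids]
    if clash:
        new_frame["id"] = [f"syn{i + 1:03d}x" for i in range(config.k)]

    combined = pd.concat([frame, new_frame], ignore_index=True)
    out = Cohort(combined, cohort.registry, rng_seed=cohort.rng_seed)
    for attr in ("planted_features", "planted_directions"):
        if hasattr(cohort, attr):
            setattr(out, attr, getattr(cohort, attr))
    return out
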