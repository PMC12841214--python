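"""Exact association testing between fall status and assigned risk strata.

The evaluation tabulates (fall label x stratum) counts into a 2x3 table and
computes the Fisher–Freeman–Halton exact p-value: under fixed margins the
table probability is multivariate hypergeometric,

    P(T) = (prod_i r_i!)(prod_j c_j!) / (N! prod_ij t_ij!),

and the two-sided p is the sum of P over every margin-consistent table whose
probability does not exceed that of the observed table (probability
ordering, the convention of standard exact-test implementations, with a
small relative tolerance guarding floating-point ties).  Helpers reconstruct
integer counts from published row percentages so that reported comparator
results can be re-tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .exceptions import EvaluationError
from .stratify import Stratum

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "build_contingency",
    "fisher_freeman_halton",
    "reconstruct_counts",
    "evaluate_scales",
    "load_clinical_benchmark",
]

ROW_LABELS = ("non_faller", "faller")
COL_LABELS = ("low", "medium", "high")


@dataclass
class ContingencyTable:
    """2x3 table of counts: rows (non-faller, faller) x strata (low, medium, high)."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ROW_LABELS
    col_labels: tuple[str, str, str] = COL_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise EvaluationError(f"bad table shape {self.counts.shape}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(int)
            if not np.array_equal(as_int, self.counts):
                raise EvaluationError("table entries must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise EvaluationError("table entries must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-wise percentages (rows summing to 100 up to rounding)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, 0.0)


def build_contingency(
    assessments: Iterable[tuple[str, Stratum]],
) -> ContingencyTable:
    """Tabulate (fall_label, stratum) pairs into a 2x3 table."""
    counts = np.zeros((2, 3), dtype=int)
    n = 0
    for label, stratum in assessments:
        if label not in ROW_LABELS:
            raise EvaluationError(f"unknown fall label {label!r}")
        counts[ROW_LABELS.index(label), int(Stratum(stratum))] += 1
        n += 1
    if n == 0:
        raise EvaluationError("no assessments to tabulate")
    return ContingencyTable(counts)


def _enumerate_tables(row_sums: Sequence[int], col_sums: Sequence[int]):
    """Yield every nonnegative integer matrix (as a flat tuple, row-major)
    with the given margins.

    Recursion over rows: choose the current row cell-by-cell within the
    remaining column budgets, then recurse.  At the table sizes used here
    (2 x 3, N of a few hundred) this is at most a few thousand tables.
    """
    if len(row_sums) == 1:
        yield tuple(col_sums)
        return

    def rows_for(remaining: int, budgets: tuple[int, ...]):
        if len(budgets) == 1:
            if remaining <= budgets[0]:
                yield (remaining,)
            return
        upper = min(remaining, budgets[0])
        lower = max(0, remaining - sum(budgets[1:]))
        for v in range(lower, upper + 1):
            for rest in rows_for(remaining - v, budgets[1:]):
                yield (v,) + rest

    for first in rows_for(row_sums[0], tuple(col_sums)):
        reduced = [c - v for c, v in zip(col_sums, first)]
        for rest in _enumerate_tables(row_sums[1:], reduced):
            yield first + rest


def fisher_freeman_halton(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    tie_tolerance: float = 1e-7,
) -> float:
    """Two-sided exact p-value for an r x c table (probability ordering).

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of those no more probable than
    the observed table (within ``tie_tolerance`` relative slack for float
    ties).  Accepts any r x c array of nonnegative integers; with a zero
    column the computation reduces exactly to the two-sided 2x2
    hypergeometric test.  The sum is normalised by the enumerated total so
    degenerate margins return exactly 1.0.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table)
        if counts.ndim != 2:
            raise EvaluationError(f"expected a 2-d table, got shape {counts.shape}")
        as_int = counts.astype(int)
        if not np.array_equal(as_int, counts):
            raise EvaluationError("table entries must be integers")
        counts = as_int
        if (counts < 0).any():
            raise EvaluationError("table entries must be nonnegative")
    n = int(counts.sum())
    if n == 0:
        raise EvaluationError("table has zero grand total")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    lfact = gammaln(np.arange(n + 2))[1:]  # lfact[k] = log(k!)
    log_margin_const = float(
        lfact[row_sums].sum() + lfact[col_sums].sum() - lfact[n]
    )
    log_p_obs = log_margin_const - float(lfact[counts.ravel()].sum())
    log_cutoff = log_p_obs + math.log1p(tie_tolerance)
    included = 0.0
    everything = 0.0
    for candidate in _enumerate_tables(list(row_sums), list(col_sums)):
        log_p = log_margin_const - sum(lfact[v] for v in candidate)
        p = math.exp(log_p)
        everything += p
        if log_p <= log_cutoff:
            included += p
    return min(included / everything, 1.0)


def reconstruct_counts(
    row_percentages: Sequence[float], n: int
) -> tuple[int, ...]:
    """Integer counts summing to ``n`` from published row percentages.

    Chooses the vector minimizing the maximum absolute deviation from
    ``percentage x n / 100`` (largest-remainder apportionment, which also
    breaks ties toward the largest remainder).  Raises when no vector gets
    within 1.0 count of every target — the percentages are then inconsistent
    with the stated group size.
    """
    if n <= 0:
        raise EvaluationError("group size must be positive")
    targets = np.asarray(row_percentages, dtype=float) * n / 100.0
    if abs(targets.sum() - n) > 0.05 * n + 0.5:
        raise EvaluationError(
            f"percentages {row_percentages} do not sum near 100 for n={n}"
        )
    base = np.floor(targets).astype(int)
    shortfall = n - int(base.sum())
    if shortfall < 0 or shortfall > len(targets):
        raise EvaluationError(f"cannot apportion {row_percentages} over n={n}")
    remainders = targets - base
    order = np.argsort(-remainders, kind="stable")
    counts = base.copy()
    counts[order[:shortfall]] += 1
    if np.max(np.abs(counts - targets)) > 1.0:
        raise EvaluationError(
            f"no integer counts within 1.0 of {row_percentages} at n={n}"
        )
    return tuple(int(c) for c in counts)


@dataclass
class EvaluationReport:
    """Per-scale stratum percentages by fall status and exact p-values."""

    rows: list[dict] = field(default_factory=list)
    null_hypothesis: str = (
        "the assigned risk strata are not related to faller / non-faller status"
    )
    alternative_hypothesis: str = (
        "the assigned risk strata are related to faller / non-faller status"
    )

    def add(self, scale: str, table: ContingencyTable) -> None:
        pct = table.row_percentages()
        self.rows.append(
            {
                "scale": scale,
                "nonfaller_low_pct": round(pct[0, 0], 1),
                "nonfaller_medium_pct": round(pct[0, 1], 1),
                "nonfaller_high_pct": round(pct[0, 2], 1),
                "faller_low_pct": round(pct[1, 0], 1),
                "faller_medium_pct": round(pct[1, 1], 1),
                "faller_high_pct": round(pct[1, 2], 1),
                "p_value": fisher_freeman_halton(table),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.3g")


def evaluate_scales(
    assessments_by_scale: Mapping[str, Iterable[tuple[str, Stratum]]],
) -> EvaluationReport:
    """Contingency + exact test for each named scale's assessments."""
    report = EvaluationReport()
    for scale, assessments in assessments_by_scale.items():
        report.add(scale, build_contingency(list(assessments)))
    return report


def load_clinical_benchmark(path: str | Path | None = None) -> pd.DataFrame:
    """Published comparator results: per clinical scale, the stratum
    percentages of 22 non-fallers and 10 fallers on a held-out test cohort.

    These percentages are inputs for re-testing (via
    :func:`reconstruct_counts` + :func:`fisher_freeman_halton`), not outputs
    of this package.
    """
    if path is None:
        text = (
            resources.files("ifra")
            .joinpath("data/clinical_benchmark.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    payload = yaml.safe_load(text)
    frame = pd.DataFrame(payload["scales"])
    frame.attrs["n_nonfallers"] = payload["n_nonfallers"]
    frame.attrs["n_fallers"] = payload["n_fallers"]
    return frame


def benchmark_report(path: str | Path | None = None) -> pd.DataFrame:
    """Recompute exact p-values for the published comparator percentages.

    Returns the benchmark table with reconstructed counts and a recomputed
    ``p_value`` column.
    """
    bench = load_clinical_benchmark(path)
    n_nf = bench.attrs["n_nonfallers"]
    n_f = bench.attrs["n_fallers"]
    rows = []
    for _, row in bench.iterrows():
        nf = reconstruct_counts(
            (row["nonfaller_low"], row["nonfaller_medium"], row["nonfaller_high"]),
            n_nf,
        )
        f = reconstruct_counts(
            (row["faller_low"], row["faller_medium"], row["faller_high"]), n_f
        )
        table = ContingencyTable(np.array([nf, f]))
        rows.append(
            {
                "scale": row["scale"],
                "nonfaller_counts": nf,
                "faller_counts": f,
                "p_value": fisher_freeman_halton(table),
            }
        )
    return pd.DataFrame(rows)
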