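"""Dataset construction, cross-validation, and group comparisons.

Transcripts are grouped into fixed-size datasets (default 50) by a
seeded random partition.  Datasets are cross-validated against each
other with two-sided Student's t-tests on the per-transcript rho* of
each of the 16 dinucleotides; a dataset is retained only when none of
its pairwise tests detects a compositional difference.  No
multiple-testing correction is applied across the 16-dinucleotide panel:
the screen is deliberately conservative about homogeneity (a dataset is
discarded on any single discordant dinucleotide).

"Student's t-test" is the equal-variance test; Welch's correction is
available behind ``equal_var=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import SequenceRecord
from .signature import DINUCLEOTIDES, GenomeBaseline, rho_matrix, ts_matrix

__all__ = [
    "DatasetSummary",
    "ComparisonResult",
    "make_datasets",
    "cross_validate",
    "summarize",
    "compare_groups",
    "ts_values",
    "summary_table",
]

logger = logging.getLogger(__name__)


@dataclass
class DatasetSummary:
    """Per-dataset location/dispersion of per-transcript TS (or rho*)."""

    label: str
    n: int
    per_dinucleotide: dict[str, dict[str, float | None]]


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    groups: tuple[str, str]
    dinucleotide: str


def make_datasets(
    records: Sequence[SequenceRecord], size: int = 50, seed: int = 0
) -> list[list[SequenceRecord]]:
    """Random partition into datasets of ``size`` without replacement.

    The leftover (< size) records are discarded with a log entry; the
    same seed always yields the identical partition.
    """
    if len(records) < size:
        raise ValueError(f"need at least {size} records, got {len(records)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    n_sets = len(records) // size
    leftover = len(records) - n_sets * size
    if leftover:
        logger.info("discarding %d leftover records (< dataset size)", leftover)
    return [
        [records[j] for j in perm[i * size : (i + 1) * size]] for i in range(n_sets)
    ]


def _pairwise_tests(
    matrices: list[np.ndarray], labels: list[str], equal_var: bool
) -> list[ComparisonResult]:
    results = []
    for i in range(len(matrices)):
        for j in range(i + 1, len(matrices)):
            t, p = stats.ttest_ind(
                matrices[i], matrices[j], axis=0, equal_var=equal_var, nan_policy="omit"
            )
            for k, d in enumerate(DINUCLEOTIDES):
                results.append(
                    ComparisonResult(
                        statistic=float(t[k]),
                        p_value=float(p[k]),
                        groups=(labels[i], labels[j]),
                        dinucleotide=d,
                    )
                )
    return results


def cross_validate(
    datasets: Sequence[Sequence[SequenceRecord]],
    alpha: float = 0.05,
    equal_var: bool = True,
    labels: Sequence[str] | None = None,
) -> tuple[list[int], list[ComparisonResult]]:
    """Pairwise per-dinucleotide t-tests on per-transcript rho*.

    Returns the indices of datasets whose every pairwise test has
    p > alpha, plus all test results.  Undefined rho* entries are
    dropped pairwise; tests with too few defined values yield NaN
    p-values, which count as failures for the keeping rule.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    for ds in datasets:
        if len(ds) < 2:
            raise ValueError("every dataset needs n >= 2")
    labels = list(labels) if labels is not None else [f"ds{i}" for i in range(len(datasets))]
    matrices = [rho_matrix(list(ds)) for ds in datasets]
    results = _pairwise_tests(matrices, labels, equal_var)
    bad: set[str] = set()
    for r in results:
        if not (r.p_value > alpha):  # NaN fails too
            bad.update(r.groups)
    kept = [i for i, lab in enumerate(labels) if lab not in bad]
    return kept, results


def _column_summary(values: np.ndarray) -> dict[str, float | None]:
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        return {"mean": None, "median": None, "sd": None, "sem": None, "n": 0}
    mean = float(values.mean())
    median = float(np.median(values))
    if n > 1:
        sd = float(values.std(ddof=1))
        sem = sd / np.sqrt(n)
    else:
        sd = None
        sem = None
    return {"mean": mean, "median": median, "sd": sd, "sem": sem, "n": int(n)}


def summarize(
    dataset: Sequence[SequenceRecord],
    baseline: GenomeBaseline | None = None,
    label: str = "",
    metric: str = "ts",
) -> DatasetSummary:
    """Mean/median/sd/sem of per-transcript TS (or rho*) per dinucleotide.

    Undefined entries are excluded per-dinucleotide (pairwise deletion);
    sem = sd/sqrt(n) and requires n > 1.  Raises when no transcript has a
    defined value for any dinucleotide.
    """
    if metric == "ts":
        if baseline is None:
            raise ValueError("TS summary requires a baseline")
        mat = ts_matrix(list(dataset), baseline)
    elif metric == "rho":
        mat = rho_matrix(list(dataset))
    else:
        raise ValueError("metric must be 'ts' or 'rho'")
    per = {d: _column_summary(mat[:, k]) for k, d in enumerate(DINUCLEOTIDES)}
    if all(v["n"] == 0 for v in per.values()):
        raise ValueError("empty summary: no defined values in dataset")
    return DatasetSummary(label=label, n=len(dataset), per_dinucleotide=per)


def ts_values(
    records: Sequence[SequenceRecord], baseline: GenomeBaseline, dinucleotide: str
) -> np.ndarray:
    """Per-transcript TS values for one dinucleotide (NaN-free)."""
    col = DINUCLEOTIDES.index(dinucleotide)
    values = ts_matrix(list(records), baseline)[:, col]
    return values[~np.isnan(values)]


def compare_groups(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    dinucleotide: str = "CG",
    groups: tuple[str, str] = ("a", "b"),
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided Student's t-test between two samples of per-transcript
    TS values for one dinucleotide."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two defined values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        statistic=float(t), p_value=float(p), groups=groups, dinucleotide=dinucleotide
    )


def summary_table(summaries: Sequence[DatasetSummary]) -> pd.DataFrame:
    """One row per dataset x dinucleotide, for TSV export."""
    rows = []
    for s in summaries:
        for d, stats_ in s.per_dinucleotide.items():
            rows.append({"dataset": s.label, "n": s.n, "dinucleotide": d, **stats_})
    return pd.DataFrame(rows)
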