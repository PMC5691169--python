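"""Nonparametric permutation comparison of topology metrics between
two groups.

The statistic is the difference of group means.  Subject labels are
shuffled (preserving group sizes) either a fixed number of times with
an add-one-corrected p-value,

    p = (1 + #{|null| >= |observed|}) / (n_perm + 1),

or exhaustively over all label assignments when ``exact=True``.  The
default test is two-sided; the comparison is run independently per
(measure, metric, density) cell with no correction across cells, and a
Bonferroni option for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PermutationResult",
    "permutation_test",
    "group_comparison_report",
    "cohort_metric_table",
    "compare_cohorts",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("cc", "cpl", "ge")


@dataclass(frozen=True)
class PermutationResult:
    """Observed mean difference, its permutation null and the p-value."""

    observed: float
    null: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int | None
    alternative: str


def _validate_group(a, name):
    arr = np.asarray(a, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"group {name} needs at least 2 subjects, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"group {name} contains non-finite values")
    return arr


def _tail_count(null, observed, alternative):
    if alternative == "two-sided":
        return np.abs(null) >= abs(observed)
    if alternative == "greater":
        return null >= observed
    if alternative == "less":
        return null <= observed
    raise ValueError(f"unknown alternative {alternative!r}")


def permutation_test(
    a,
    b,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
    exact: bool = False,
) -> PermutationResult:
    """Permutation test on the difference of group means, mean(a) - mean(b).

    ``exact=True`` enumerates every assignment of the pooled values to
    the two group sizes (feasible for small cohorts) and reports the
    exact tail fraction without the add-one correction.
    """
    av = _validate_group(a, "a")
    bv = _validate_group(b, "b")
    pooled = np.concatenate([av, bv])
    na = av.size
    observed = float(av.mean() - bv.mean())

    if exact:
        idx_all = range(pooled.size)
        null = np.array(
            [
                pooled[list(c)].mean() - np.delete(pooled, list(c)).mean()
                for c in combinations(idx_all, na)
            ]
        )
        hits = _tail_count(null, observed, alternative)
        p = float(hits.mean())
        return PermutationResult(observed, null, p, len(null), seed, alternative)

    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: each row is one permutation of the pool
    perm = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    shuffled = pooled[perm]
    null = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
    hits = int(_tail_count(null, observed, alternative).sum())
    p = (1 + hits) / (n_perm + 1)
    return PermutationResult(observed, null, float(p), n_perm, seed, alternative)


def group_comparison_report(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    metrics=METRIC_COLUMNS,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(measure, metric, density) permutation comparison.

    ``metrics_a`` / ``metrics_b`` are tidy metric tables (one row per
    subject, measure and density; see :func:`fracnet.metrics.metric_table`).
    The report has one row per cell with group means, the observed
    difference (A minus B), the p-value, and a significance flag at
    ``alpha``.  p-values are uncorrected across cells unless
    ``bonferroni=True``.
    """
    keys = ["measure", "density"]
    cells = (
        pd.concat([metrics_a[keys], metrics_b[keys]])
        .drop_duplicates()
        .sort_values(keys)
        .itertuples(index=False)
    )
    rng = np.random.default_rng(seed)
    rows = []
    for measure, density in cells:
        sel_a = metrics_a[
            (metrics_a["measure"] == measure) & (metrics_a["density"] == density)
        ]
        sel_b = metrics_b[
            (metrics_b["measure"] == measure) & (metrics_b["density"] == density)
        ]
        for metric in metrics:
            res = permutation_test(
                sel_a[metric].to_numpy(),
                sel_b[metric].to_numpy(),
                n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
                alternative=alternative,
            )
            rows.append(
                {
                    "measure": measure,
                    "metric": metric,
                    "density": density,
                    "mean_a": float(sel_a[metric].mean()),
                    "mean_b": float(sel_b[metric].mean()),
                    "observed_diff": res.observed,
                    "p_value": res.p_value,
                }
            )
    report = pd.DataFrame(rows)
    n_cells = len(report)
    threshold = alpha / n_cells if bonferroni else alpha
    report["significant"] = report["p_value"] < threshold
    return report


def cohort_metric_table(
    subjects, measures, densities, measure_params: dict | None = None
) -> pd.DataFrame:
    """Run connectivity -> thresholding -> topology metrics for every
    subject, measure and density of a cohort.

    ``subjects`` is an iterable of :class:`fracnet.cohort.Subject`.
    Returns the tidy metric table with a ``group`` column appended.
    """
    from .metrics import graph_metrics, metric_table
    from .network import connectivity_matrix, threshold_sweep

    measure_params = measure_params or {}
    records, groups = [], {}
    for sub in subjects:
        groups[sub.subject_id] = sub.group
        for measure in measures:
            w = connectivity_matrix(sub.data, measure, **measure_params.get(measure, {}))
            for g in threshold_sweep(w, densities):
                records.append(
                    graph_metrics(g, measure=measure, subject=sub.subject_id)
                )
    table = metric_table(records)
    table["group"] = table["subject"].map(groups)
    return table


def compare_cohorts(
    cohort,
    measures=("lc", "mi", "bcfd"),
    densities=(0.1, 0.2, 0.3, 0.4, 0.5),
    n_perm: int = 1000,
    seed: int | None = None,
    measure_params: dict | None = None,
    **report_kwargs,
) -> pd.DataFrame:
    """Full two-group pipeline: metrics for every subject, then the
    per-cell permutation report (group A minus group B)."""
    table = cohort_metric_table(cohort.subjects, measures, densities, measure_params)
    name_a, name_b = cohort.spec.group_names
    return group_comparison_report(
        table[table["group"] == name_a],
        table[table["group"] == name_b],
        n_perm=n_perm,
        seed=seed,
        **report_kwargs,
    )
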