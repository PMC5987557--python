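"""Cohort validation statistics for clone-based bisulfite assays.

A candidate promoter region is re-assayed in a case/control cohort by
bisulfite clone sequencing: each sample yields a clones × CpG binary
matrix.  The per-sample mean methylation is thresholded into a
hypermethylation call, the calls are crossed with disease status in a 2×2
table tested by Fisher's exact test, and promoter methylation is related
to expression by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CloneMatrix
from .dmr import UndefinedStatisticError


@dataclass
class CohortRecord:
    sample_id: str
    group: str  # "case" or "control"
    mean_methylation: float
    hyper_call: bool
    expression: float | None = None


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = (case, control), columns = (hyper, not-hyper)."""

    a: int  # case & hyper
    b: int  # case & not hyper
    c: int  # control & hyper
    d: int  # control & not hyper

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def clone_mean_profile(cm: CloneMatrix) -> tuple[np.ndarray, float]:
    """Per-CpG column means and the overall sample mean, ignoring missing.

    A CpG column with no observed entries gets NaN.
    """
    observed_per_col = (~np.isnan(cm.matrix)).sum(axis=0)
    sums = np.nansum(cm.matrix, axis=0)
    per_cpg = np.where(
        observed_per_col > 0, sums / np.maximum(observed_per_col, 1), np.nan
    )
    observed = cm.matrix[~np.isnan(cm.matrix)]
    if observed.size == 0:
        raise UndefinedStatisticError(f"{cm.sample_id}: clone matrix has no observed entries")
    return per_cpg, float(observed.mean())


def call_hypermethylated(sample_mean: float, threshold: float = 0.5) -> bool:
    """True iff the sample mean strictly exceeds the threshold."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    return sample_mean > threshold


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by the probability-mass method.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table (within
    relative tolerance 1e-7).
    """
    arr = table.as_array()
    row1, row2 = arr.sum(axis=1)
    col1, col2 = arr.sum(axis=0)
    n = arr.sum()
    if row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        raise UndefinedStatisticError("Fisher test undefined with an empty margin")
    # a ~ Hypergeom(N=n, K=col1 successes, n=row1 draws)
    rv = stats.hypergeom(n, col1, row1)
    lo = max(0, row1 - col2)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(table.a)
    mask = pmf <= p_obs * (1 + 1e-7)
    if mask.all():
        return 1.0
    return min(1.0, float(pmf[mask].sum()))


def methylation_expression_correlation(
    cohort: list[CohortRecord],
) -> tuple[float, float]:
    """Pearson r between sample mean methylation and expression, with p.

    Two-sided p from the t-distribution with n − 2 degrees of freedom;
    needs >= 3 complete records with variance in both variables.
    """
    pairs = [
        (r.mean_methylation, r.expression)
        for r in cohort
        if r.expression is not None and not np.isnan(r.expression)
    ]
    if len(pairs) < 3:
        raise UndefinedStatisticError("correlation needs >= 3 complete records")
    m = np.array([p[0] for p in pairs])
    e = np.array([p[1] for p in pairs])
    if m.std() == 0 or e.std() == 0:
        raise UndefinedStatisticError("correlation undefined with zero variance")
    res = stats.pearsonr(m, e)
    return float(res.statistic), float(res.pvalue)


def build_cohort(
    clone_matrices: dict[str, CloneMatrix],
    cohort_table: pd.DataFrame,
    threshold: float = 0.5,
) -> list[CohortRecord]:
    """Join clone matrices with the cohort table into scored records."""
    records = []
    for row in cohort_table.itertuples(index=False):
        if row.sample_id not in clone_matrices:
            raise KeyError(f"no clone matrix for sample {row.sample_id}")
        _, mean = clone_mean_profile(clone_matrices[row.sample_id])
        expr = float(row.expression) if not pd.isna(row.expression) else None
        records.append(
            CohortRecord(
                sample_id=row.sample_id,
                group=row.group,
                mean_methylation=mean,
                hyper_call=call_hypermethylated(mean, threshold),
                expression=expr,
            )
        )
    return records


def cohort_contingency(cohort: list[CohortRecord]) -> ContingencyTable2x2:
    a = sum(1 for r in cohort if r.group == "case" and r.hyper_call)
    b = sum(1 for r in cohort if r.group == "case" and not r.hyper_call)
    c = sum(1 for r in cohort if r.group == "control" and r.hyper_call)
    d = sum(1 for r in cohort if r.group == "control" and not r.hyper_call)
    return ContingencyTable2x2(a, b, c, d)


def run_validation(
    clone_matrices: dict[str, CloneMatrix],
    cohort_table: pd.DataFrame,
    threshold: float = 0.5,
) -> dict:
    """Full validation arm: means, calls, 2×2 table, Fisher p, correlation."""
    cohort = build_cohort(clone_matrices, cohort_table, threshold)
    table = cohort_contingency(cohort)
    fisher_p = fisher_exact_two_sided(table)
    try:
        r, r_p = methylation_expression_correlation(cohort)
        corr = {"pearson_r": r, "p_value": r_p}
    except UndefinedStatisticError as exc:
        corr = {"error": str(exc)}
    return {
        "threshold": threshold,
        "samples": [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "mean_methylation": r.mean_methylation,
                "hyper_call": r.hyper_call,
                "expression": r.expression,
            }
            for r in cohort
        ],
        "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "fisher_p": fisher_p,
        "methylation_expression": corr,
    }
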