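"""Differential-expression selection and qPCR normalisation utilities.

Implements the screening rules of a two-group (3 vs 3) microarray comparison:
per-gene fold change on log2 intensities, two-sided Student's t test,
Benjamini-Hochberg adjustment, and the combined up/down/non-DE call
(fold change > 2.0 and nominal p < 0.05 by default). Also provides the
global-mean delta-Ct normalisation used for qPCR panels (one PCR cycle = one
log2 unit) and a generic Pearson r^2 helper for level-vs-age correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "fold_change",
    "t_test_p",
    "bh_adjust",
    "select_de",
    "global_mean_relative",
    "correlation_r2",
    "CALLS",
]

CALLS = ("up", "down", "non_de")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with optional two-group labels.

    ``data`` holds log2-scale array intensities (or raw Ct values for qPCR
    use); ``groups`` maps each sample id to one of two group names and
    ``group_order`` fixes which group is the reference (group A) and which is
    the contrast (group B) — fold changes are B over A. Missing values are
    rejected: impute or drop rows upstream.
    """

    data: pd.DataFrame
    groups: Mapping[str, str] | None = None
    group_order: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r} in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.groups is not None:
            missing = [s for s in self.data.columns if s not in self.groups]
            if missing:
                raise ValueError(f"samples without group label: {missing}")
            labels = sorted({self.groups[s] for s in self.data.columns})
            if len(labels) != 2:
                raise ValueError(f"need exactly 2 groups, got {labels}")
            if self.group_order is None:
                self.group_order = (labels[0], labels[1])
            elif sorted(self.group_order) != labels:
                raise ValueError(
                    f"group_order {self.group_order} does not match labels {labels}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def group_columns(self, which: str) -> list[str]:
        """Sample ids belonging to group 'A' (reference) or 'B' (contrast)."""
        if self.groups is None or self.group_order is None:
            raise ValueError("expression matrix has no group labels")
        label = self.group_order[0] if which == "A" else self.group_order[1]
        return [s for s in self.data.columns if self.groups[s] == label]

    def require_replicates(self, min_n: int = 2) -> None:
        for which in ("A", "B"):
            n = len(self.group_columns(which))
            if n < min_n:
                raise ValueError(
                    f"group {which} has {n} samples; need >= {min_n} for testing"
                )


def fold_change(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Linear fold change (B over A) and log2 fold change from log2 values.

    Inputs are per-sample log2 intensities; the fold change is geometric
    (computed from log-scale means): ``log2fc = mean(B) - mean(A)`` and the
    linear fold change is ``2**log2fc``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    log2fc = float(b.mean() - a.mean())
    return 2.0 ** log2fc, log2fc


def t_test_p(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> float:
    """Two-sided two-sample t-test p-value (Student's pooled-variance test).

    Degenerate zero-variance rows are kept total: if both groups are constant
    the p-value is 1.0 when the means agree and 0.0 otherwise.
    Set ``equal_var=False`` for Welch's unequal-variance variant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t test requires >= 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(b, a, equal_var=equal_var)
    return float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Adjusted values are monotone non-decreasing in the rank of the raw
    p-values and invariant under permutation of the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def _vectorised_t_p(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided t-test p-values with degenerate rows kept total."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0.0) & (b.var(axis=1, ddof=1) == 0.0)
    if degenerate.any():
        equal_means = a.mean(axis=1) == b.mean(axis=1)
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def select_de(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene DE table with up/down/non-DE calls.

    A gene is called ``up`` iff its linear fold change (group B over group A)
    strictly exceeds ``fc_threshold`` and its (nominal or BH-adjusted)
    p-value is strictly below ``p_threshold``; ``down`` symmetric with
    fold change strictly below ``1/fc_threshold``. Thresholds are strict, so
    a gene at exactly the fold-change cutoff is non-DE.

    Returns a DataFrame indexed by gene_id with columns
    ``fold_change, log2fc, p_value, adj_p, call``.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    matrix.require_replicates(2)
    cols_a = matrix.group_columns("A")
    cols_b = matrix.group_columns("B")
    a = matrix.data[cols_a].to_numpy(dtype=float)
    b = matrix.data[cols_b].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    fc = 2.0 ** log2fc
    p = _vectorised_t_p(a, b, equal_var)
    adj = bh_adjust(p)
    gate_p = adj if use_adjusted else p
    call = np.full(len(fc), "non_de", dtype=object)
    call[(fc > fc_threshold) & (gate_p < p_threshold)] = "up"
    call[(fc < 1.0 / fc_threshold) & (gate_p < p_threshold)] = "down"
    return pd.DataFrame(
        {
            "fold_change": fc,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
            "call": call,
        },
        index=pd.Index(matrix.data.index, name="gene_id"),
    )


def global_mean_relative(ct_matrix: ExpressionMatrix, target_id: str) -> pd.Series:
    """Relative log2 levels of one miRNA from a raw-Ct qPCR panel.

    Global-mean normalisation: for each sample ``s`` the target's
    ``delta_Ct(s)`` is its Ct minus the mean Ct of all assayed miRNAs in that
    sample; the relative level is ``-(delta_Ct(s) - mean_s(delta_Ct))``,
    centred across samples and already on the log2 scale because one PCR
    cycle corresponds to a twofold difference.
    """
    df = ct_matrix.data
    if target_id not in df.index:
        raise KeyError(f"target {target_id!r} not in Ct matrix")
    if df.shape[1] < 2:
        raise ValueError("global-mean relative levels need >= 2 samples")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("Ct values must be finite")
    delta_ct = df.loc[target_id] - df.mean(axis=0)
    rel = -(delta_ct - delta_ct.mean())
    rel.name = target_id
    return rel


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r^2 and two-sided p-value (e.g. miRNA level vs donor age)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r * r), float(p)
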