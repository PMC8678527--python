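"""Functional network connectivity (FNC) matrices and group statistics.

For each subject the pairwise Pearson correlations between network time
courses form a labelled symmetric matrix: 8 networks split into AN and RIN
give the 16 x 16 ``all`` matrix (ordering ``net1_i, net1_a, net2_i, ...``),
while ``act`` / ``inert`` / ``original`` modes use only the AN, only the
RIN, or the unsplit network time courses (8 x 8).

Group comparison tests every unique off-diagonal element with a two-sample
t-test (Welch by default, optionally on Fisher z-transformed correlations)
and controls the family — the unique tested elements — by Benjamini-
Hochberg FDR.  Alteration counts per network summarise how many significant
edges touch each row, split into enhanced (group B > group A) and weakened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .split import NetworkSplit

MODES = ("all", "act", "inert", "original")


@dataclass
class FncMatrix:
    """Labelled symmetric correlation matrix over network time courses."""

    values: np.ndarray
    labels: list[str]
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.labels) != n:
            raise ValueError("values must be square and match labels")
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def side(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _corr_with_missing(tcs: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Pearson correlation; rows flagged missing (or constant) become NaN."""
    n = tcs.shape[0]
    C = np.full((n, n), np.nan)
    ok = ~missing & (tcs.std(axis=1) > 0)
    flat = ~missing & (tcs.std(axis=1) == 0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant time courses; "
                      "their correlations are recorded as missing")
    idx = np.flatnonzero(ok)
    if idx.size:
        C[np.ix_(idx, idx)] = np.corrcoef(tcs[idx])
    np.fill_diagonal(C, 1.0)
    return C


def compute_fnc(splits: list[NetworkSplit], mode: str = "all",
                original_tcs: np.ndarray | None = None) -> FncMatrix:
    """Build one subject's FNC matrix from its network splits.

    ``mode`` selects the time courses: ``all`` interleaves RIN then AN per
    network (side ``2n``), ``act`` / ``inert`` take one side each, and
    ``original`` uses the full-network time courses supplied via
    ``original_tcs`` (n x n_time).  Empty sides are flagged missing, never
    imputed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "original":
        if original_tcs is None:
            raise ValueError("original mode needs original_tcs")
        tcs = np.asarray(original_tcs, dtype=float)
        labels = [s.label for s in splits]
        missing = np.zeros(len(labels), dtype=bool)
    else:
        tcs_list, labels, miss = [], [], []
        for s in splits:
            la, li = s.labels
            if mode in ("all", "inert"):
                tcs_list.append(s.t_ine)
                labels.append(li)
                miss.append(s.rin_empty)
            if mode in ("all", "act"):
                tcs_list.append(s.t_act)
                labels.append(la)
                miss.append(s.an_empty)
        tcs = np.vstack(tcs_list)
        missing = np.asarray(miss)
    if tcs.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlations")
    return FncMatrix(_corr_with_missing(tcs, missing), labels, missing)


@dataclass
class FncComparison:
    """Elementwise two-group comparison of FNC matrices."""

    labels: list[str]
    t_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    direction: np.ndarray       # sign of (group B mean - group A mean)
    alpha: float
    n_tested: int

    def significant_edges(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.significant[i, j]:
                    rows.append({
                        "edge": f"{self.labels[i]}-{self.labels[j]}",
                        "t": self.t_values[i, j],
                        "p": self.p_values[i, j],
                        "q": self.q_values[i, j],
                        "direction": int(self.direction[i, j]),
                    })
        return pd.DataFrame(rows)


def group_compare(fncA: list[FncMatrix], fncB: list[FncMatrix],
                  alpha: float = 0.05, fisher: bool = True,
                  equal_var: bool = False) -> FncComparison:
    """Two-sample t-test per unique FNC element with BH-FDR correction.

    Edges involving any subject's missing network are excluded from the
    tested family.  ``direction`` is + where group B exceeds group A.
    """
    if len(fncA) < 2 or len(fncB) < 2:
        raise ValueError("need at least 2 subjects per group")
    labels = fncA[0].labels
    for m in fncA + fncB:
        if m.labels != labels:
            raise ValueError("FNC label sets differ across subjects")
    n = len(labels)
    A = np.stack([m.values for m in fncA])
    B = np.stack([m.values for m in fncB])
    if fisher:
        A = np.arctanh(np.clip(A, -0.999999, 0.999999))
        B = np.arctanh(np.clip(B, -0.999999, 0.999999))
    t_values = np.zeros((n, n))
    p_values = np.ones((n, n))
    direction = np.zeros((n, n), dtype=np.int8)
    tested, pvals = [], []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = A[:, i, j], B[:, i, j]
            if np.isnan(a).any() or np.isnan(b).any():
                continue
            t, p = stats.ttest_ind(b, a, equal_var=equal_var)
            if not np.isfinite(p):
                continue
            t_values[i, j] = t_values[j, i] = t
            p_values[i, j] = p_values[j, i] = p
            direction[i, j] = direction[j, i] = int(np.sign(b.mean() - a.mean()))
            tested.append((i, j))
            pvals.append(p)
    significant = np.zeros((n, n), dtype=bool)
    q_values = np.ones((n, n))
    if tested:
        rej, qv, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for (i, j), r, q in zip(tested, rej, qv):
            significant[i, j] = significant[j, i] = r
            q_values[i, j] = q_values[j, i] = q
    return FncComparison(labels, t_values, p_values, q_values, significant,
                         direction, alpha, len(tested))


def alteration_counts(cmp: FncComparison) -> pd.DataFrame:
    """Per-network counts of significant edges: total, enhanced, weakened."""
    n = len(cmp.labels)
    rows = []
    for i in range(n):
        total = enhanced = weakened = 0
        for j in range(n):
            if j == i or not cmp.significant[i, j]:
                continue
            total += 1
            if cmp.direction[i, j] > 0:
                enhanced += 1
            elif cmp.direction[i, j] < 0:
                weakened += 1
        rows.append({"network": cmp.labels[i], "total": total,
                     "enhanced": enhanced, "weakened": weakened})
    return pd.DataFrame(rows)


class FncGroupComparison:
    """Model front-end: subject FNC stacks in, comparison results out."""

    def __init__(self, fncA: list[FncMatrix], fncB: list[FncMatrix],
                 alpha: float = 0.05, fisher: bool = True,
                 equal_var: bool = False):
        self.fncA, self.fncB = fncA, fncB
        self.alpha, self.fisher, self.equal_var = alpha, fisher, equal_var

    def fit(self) -> "FncComparisonResults":
        cmp = group_compare(self.fncA, self.fncB, self.alpha, self.fisher,
                            self.equal_var)
        return FncComparisonResults(self, cmp)


class FncComparisonResults:
    def __init__(self, model: FncGroupComparison, comparison: FncComparison):
        self.model = model
        self.comparison = comparison

    @property
    def n_significant(self) -> int:
        n = len(self.comparison.labels)
        iu = np.triu_indices(n, k=1)
        return int(self.comparison.significant[iu].sum())

    def summary(self) -> pd.DataFrame:
        return self.comparison.significant_edges()

    def alteration_counts(self) -> pd.DataFrame:
        return alteration_counts(self.comparison)
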