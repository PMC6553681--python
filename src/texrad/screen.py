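"""Univariate discriminative screening with family-wise error control.

Each feature is compared between the two label groups with a two-sided
Mann-Whitney U test; the Holm step-down procedure controls the family-wise
error rate over the tested features.  Significant-feature counts before and
after correction are tabulated per (sequence, tissue) dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from texrad.pipeline import FeatureTable, split_column_id

#: Largest combined sample size at which the exact U distribution is used
#: (ties always force the normal approximation).
DEFAULT_EXACT_THRESHOLD = 12


def mann_whitney_u(
    x, y, exact_threshold: int = DEFAULT_EXACT_THRESHOLD
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for the first sample.

    ``U = sum over pairs of [x_i > y_j] + 1/2 [x_i = y_j]``.  The p-value is
    exact (full enumeration) when the combined size is at most
    ``exact_threshold`` and there are no ties, otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= exact_threshold and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down rejection flags and adjusted p-values, input order.

    Sort p ascending and reject ``p_(k)`` while ``p_(k) <= alpha/(m-k+1)``;
    the adjusted p-value is the running maximum of ``(m-k+1) p_(k)`` capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    running_max = 0.0
    still_rejecting = True
    for k, idx in enumerate(order):
        factor = m - k
        running_max = max(running_max, min(1.0, factor * p[idx]))
        adjusted[idx] = running_max
        if still_rejecting and p[idx] <= alpha / factor:
            reject[idx] = True
        else:
            still_rejecting = False
    return reject, adjusted


@dataclass
class ScreenResult:
    """Per-feature statistics and the per-dataset significance tabulation."""

    per_feature: pd.DataFrame  # columns: U, p, significant_raw, reject_holm, p_holm
    summary: pd.DataFrame      # index: sequence, columns: tissue, cells "before / after"
    alpha: float
    n_tests: int

    @property
    def n_significant_raw(self) -> int:
        return int(self.per_feature["significant_raw"].sum())

    @property
    def n_rejected(self) -> int:
        return int(self.per_feature["reject_holm"].sum())


def screen_table(
    table: FeatureTable,
    alpha: float = 0.05,
    family: str = "per_dataset",
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> ScreenResult:
    """Mann-Whitney screening of every column against the labels.

    ``family`` selects the Holm multiplicity family: ``"per_dataset"``
    corrects within each (sequence, tissue) group of columns,
    ``"pooled"`` over all columns jointly.
    """
    if family not in ("per_dataset", "pooled"):
        raise ValueError("family must be 'per_dataset' or 'pooled'")
    labels = table.labels.to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("screening requires both classes present")
    g1 = table.data.loc[labels == 1]
    g0 = table.data.loc[labels == 0]

    if len(g1) + len(g0) > exact_threshold:
        # always the asymptotic path -> one vectorized call over columns
        res = stats.mannwhitneyu(g1.to_numpy(), g0.to_numpy(), axis=0,
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        per_feature = pd.DataFrame(
            {"U": res.statistic, "p": res.pvalue}, index=table.data.columns
        )
    else:
        rows = {}
        for col in table.data.columns:
            u, p = mann_whitney_u(g1[col], g0[col], exact_threshold)
            rows[col] = {"U": u, "p": p}
        per_feature = pd.DataFrame.from_dict(rows, orient="index")
    per_feature["significant_raw"] = per_feature["p"] < alpha

    groups = {}
    for col in per_feature.index:
        sequence, tissue, _ = split_column_id(col)
        groups.setdefault((sequence, tissue), []).append(col)

    reject = pd.Series(False, index=per_feature.index)
    p_holm = pd.Series(np.nan, index=per_feature.index)
    if family == "pooled":
        flags, adj = holm_bonferroni(per_feature["p"].to_numpy(), alpha)
        reject[:] = flags
        p_holm[:] = adj
    else:
        for cols in groups.values():
            flags, adj = holm_bonferroni(per_feature.loc[cols, "p"].to_numpy(), alpha)
            reject[cols] = flags
            p_holm[cols] = adj
    per_feature["reject_holm"] = reject
    per_feature["p_holm"] = p_holm

    sequences = sorted({k[0] for k in groups})
    tissues = sorted({k[1] for k in groups})
    summary = pd.DataFrame(index=sequences, columns=tissues, dtype=object)
    summary.index.name = "sequence"
    for (sequence, tissue), cols in groups.items():
        before = int(per_feature.loc[cols, "significant_raw"].sum())
        after = int(per_feature.loc[cols, "reject_holm"].sum())
        summary.loc[sequence, tissue] = f"{before} / {after}"

    return ScreenResult(per_feature=per_feature, summary=summary,
                        alpha=alpha, n_tests=len(per_feature))
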