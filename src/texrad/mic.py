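"""Maximal information coefficient (MIC) approximation.

Normalized maximal mutual information over grid partitions whose area is
bounded by ``B(n) = n ** exponent``.  One axis is equipartitioned by rank;
the other is optimized by dynamic programming over candidate cut points
(an equipartition-candidate approximation of the MINE search); both
orientations are tried and the maximum over all admissible grid shapes is
returned.
"""

from __future__ import annotations

import numpy as np

DEFAULT_GRID_EXPONENT = 0.6


def _rank_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equipartition-by-rank bin label (0..n_bins-1) of each value."""
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=np.int64)
    labels[order] = (np.arange(len(values)) * n_bins) // len(values)
    return labels


def _best_mi_given_y(x: np.ndarray, y_lab: np.ndarray, a: int, b: int) -> float:
    """Max mutual information over partitions of x into <= a bins.

    ``y_lab`` is a fixed b-bin labelling of y.  Candidate cut points are the
    boundaries of a rank equipartition of x into ``c >= 2a`` superbins; the
    optimal grouping of consecutive superbins is found by dynamic
    programming.  Returns MI in nats.
    """
    n = len(x)
    c = min(n, max(2 * a, 4))
    order = np.argsort(x, kind="stable")
    y_sorted = y_lab[order]
    super_lab = (np.arange(n) * c) // n

    # hist[j, t]: count of y-bin t within superbin j; cumulative over j
    hist = np.zeros((c, b))
    np.add.at(hist, (super_lab, y_sorted), 1.0)
    cum = np.vstack([np.zeros(b), np.cumsum(hist, axis=0)])  # (c+1, b)
    totals = cum.sum(axis=1)

    def seg_score(i: int, j: int) -> float:
        # sum_t m_t log m_t  -  M log M  for superbins i..j-1
        m = cum[j] - cum[i]
        mm = m[m > 0]
        total = totals[j] - totals[i]
        if total == 0:
            return 0.0
        return float((mm * np.log(mm)).sum() - total * np.log(total))

    seg = np.full((c + 1, c + 1), -np.inf)
    for i in range(c):
        for j in range(i + 1, c + 1):
            seg[i, j] = seg_score(i, j)

    # dp[k][j]: best score splitting the first j superbins into k parts
    dp = np.full((a + 1, c + 1), -np.inf)
    dp[0, 0] = 0.0
    for k in range(1, a + 1):
        for j in range(k, c + 1):
            cand = dp[k - 1, :j] + seg[:j, j]
            dp[k, j] = cand.max()
    best = dp[1:, c].max()

    # MI = H(Y) + best/n
    counts_y = cum[c]
    py = counts_y[counts_y > 0] / n
    h_y = float(-(py * np.log(py)).sum())
    return max(0.0, h_y + best / n)


def mic_score(x, y, grid_exponent: float = DEFAULT_GRID_EXPONENT) -> float:
    """MIC of two equal-length samples, in [0, 1].

    Constant inputs score 0.  Requires at least 4 samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D samples")
    n = len(x)
    if n < 4:
        raise ValueError("mic_score requires at least 4 samples")
    if not (0 < grid_exponent < 1):
        raise ValueError("grid_exponent must be in (0, 1)")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return 0.0

    b_max = max(4.0, n**grid_exponent)
    best = 0.0
    for a in range(2, int(b_max // 2) + 1):
        for b in range(2, int(b_max // a) + 1):
            norm = np.log(min(a, b))
            if norm <= 0:
                continue
            y_lab = _rank_bins(y, b)
            mi = _best_mi_given_y(x, y_lab, a, b)
            best = max(best, mi / norm)
            x_lab = _rank_bins(x, b)
            mi = _best_mi_given_y(y, x_lab, a, b)
            best = max(best, mi / norm)
    return float(min(1.0, best))
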