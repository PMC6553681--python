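"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is written as plain enumeration (O(n^2) pair loops, pixel
run scans, concordant-pair counting) so it shares no code with the package
implementations it verifies.
"""

import math

import numpy as np

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm_matrix(levels, mask, n_grey, angle, distance=1):
    """Symmetrised normalized GLCM by explicit ordered-pair enumeration."""
    h, w = levels.shape
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((n_grey, n_grey))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def oracle_haralick(p):
    """The 13 co-occurrence statistics by naive double loops (natural log)."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))

    def xlogx(v):
        return v * math.log(v) if v > 0 else 0.0

    energy = contrast = homogeneity = variance = entropy = 0.0
    cross = 0.0
    p_sum = [0.0] * (2 * ng + 1)
    p_diff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            energy += v * v
            contrast += (i - j) ** 2 * v
            homogeneity += v / (1 + (i - j) ** 2)
            variance += (i + 1 - mu_x) ** 2 * v
            entropy -= xlogx(v)
            cross += (i + 1) * (j + 1) * v
            p_sum[i + j + 2] += v
            p_diff[abs(i - j)] += v
    correlation = ((cross - mu_x * mu_y) / math.sqrt(var_x * var_y)
                   if var_x > 0 and var_y > 0 else float("nan"))
    sum_avg = sum(k * p_sum[k] for k in range(2, 2 * ng + 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2, 2 * ng + 1))
    sum_ent = -sum(xlogx(p_sum[k]) for k in range(2, 2 * ng + 1))
    d_mean = sum(k * p_diff[k] for k in range(ng))
    d_var = sum((k - d_mean) ** 2 * p_diff[k] for k in range(ng))
    d_ent = -sum(xlogx(p_diff[k]) for k in range(ng))
    hxy1 = -sum(p[i, j] * math.log(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(xlogx(px[i] * py[j]) for i in range(ng) for j in range(ng))
    hx = -sum(xlogx(v) for v in px)
    hy = -sum(xlogx(v) for v in py)
    denom = max(hx, hy)
    fimc = (entropy - hxy1) / denom if denom > 0 else float("nan")
    simc = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return {
        "Energy": energy, "Contrast": contrast, "Correlation": correlation,
        "Variance": variance, "Homogeneity": homogeneity,
        "SumAverage": sum_avg, "SumVariance": sum_var, "SumEntropy": sum_ent,
        "Entropy": entropy, "DiffVariance": d_var, "DiffEntropy": d_ent,
        "FIMC": fimc, "SIMC": simc,
    }


def oracle_glcm_features(levels, mask, n_grey, angles=(0, 45, 90, 135), distance=1):
    per_dir = []
    for angle in angles:
        p = oracle_glcm_matrix(levels, mask, n_grey, angle, distance)
        if p.sum() > 0:
            per_dir.append(oracle_haralick(p))
    names = per_dir[0].keys() if per_dir else []
    out = {}
    for name in names:
        vals = [d[name] for d in per_dir if math.isfinite(d[name])]
        out[name] = sum(vals) / len(vals) if vals else float("nan")
    return out


def oracle_runs(levels, mask, angle):
    """All (level, length) runs along one angle by walking every line."""
    h, w = levels.shape
    dr, dc = ANGLE_STEPS[angle]
    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dr, c - dc
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        current, length = None, 0
        while 0 <= r < h and 0 <= c < w:
            lev = levels[r, c] if mask[r, c] else None
            if lev is not None and lev == current:
                length += 1
            else:
                if current is not None:
                    runs.append((current, length))
                current, length = lev, (1 if lev is not None else 0)
            r, c = r + dr, c + dc
        if current is not None:
            runs.append((current, length))
    return runs


def oracle_glrlm_features(levels, mask, n_grey, angles=(0, 45, 90, 135)):
    n_pixels = int(mask.sum())
    per_dir = []
    for angle in angles:
        runs = oracle_runs(levels, mask, angle)
        if not runs:
            continue
        nr = len(runs)
        feats = {
            "SRE": sum(1.0 / (ln * ln) for _, ln in runs) / nr,
            "LRE": sum(float(ln * ln) for _, ln in runs) / nr,
            "GLN": 0.0, "RLN": 0.0,
            "RP": nr / n_pixels,
            "LGRE": sum(1.0 / (g * g) for g, _ in runs) / nr,
            "HGRE": sum(float(g * g) for g, _ in runs) / nr,
            "SRLGE": sum(1.0 / (g * g * ln * ln) for g, ln in runs) / nr,
            "SRHGE": sum(g * g / (ln * ln) for g, ln in runs) / nr,
            "LRLGE": sum(ln * ln / (g * g) for g, ln in runs) / nr,
            "LRHGE": sum(float(g * g * ln * ln) for g, ln in runs) / nr,
        }
        by_level = {}
        by_length = {}
        for g, ln in runs:
            by_level[g] = by_level.get(g, 0) + 1
            by_length[ln] = by_length.get(ln, 0) + 1
        feats["GLN"] = sum(v * v for v in by_level.values()) / nr
        feats["RLN"] = sum(v * v for v in by_length.values()) / nr
        per_dir.append(feats)
    if not per_dir:
        return {}
    return {name: sum(d[name] for d in per_dir) / len(per_dir)
            for name in per_dir[0]}


def oracle_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_mann_whitney_u(x, y):
    """U for x by full pair enumeration, and the exact two-sided p-value
    from all label reassignments (no ties assumed)."""
    from itertools import combinations

    def u_stat(a, b):
        return sum(1.0 if xi > yj else (0.5 if xi == yj else 0.0)
                   for xi in a for yj in b)

    u_obs = u_stat(x, y)
    pooled = list(x) + list(y)
    nx = len(x)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(a, b))
    mean_u = nx * (len(pooled) - nx) / 2.0
    dev = abs(u_obs - mean_u)
    p = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12) / len(us)
    return u_obs, p
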