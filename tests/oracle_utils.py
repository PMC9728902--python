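"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (interval
sweeps, closed-form sums, permutations) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def _intersection_time(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    a, b = sorted(a), sorted(b)
    total, i, j = 0.0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def interval_confusion_times(
    true_ivs: list[tuple[float, float]],
    pred_ivs: list[tuple[float, float]],
    total_s: float,
) -> tuple[float, float, float, float]:
    """Exact (tp, fp, fn, tn) *durations* for disjoint interval sets on [0, T]."""
    true_ivs = [(a, min(b, total_s)) for a, b in true_ivs if a < total_s]
    pred_ivs = [(a, min(b, total_s)) for a, b in pred_ivs if a < total_s]
    tp = _intersection_time(true_ivs, pred_ivs)
    fp = sum(b - a for a, b in pred_ivs) - tp
    fn = sum(b - a for a, b in true_ivs) - tp
    tn = total_s - tp - fp - fn
    return tp, fp, fn, tn


def shoelace_hull_area(points: np.ndarray) -> float:
    """2-D convex hull area: gift-wrap the hull, then the shoelace formula."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    # Andrew's monotone chain
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def cross2(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(points_iter):
        out: list[np.ndarray] = []
        for p in points_iter:
            while len(out) >= 2 and cross2(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    hull = half(pts)[:-1] + half(pts[::-1])[:-1]
    hull = np.array(hull)
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept from the closed-form normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    sxy = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    slope = sxy / sxx
    intercept = (np.sum(y) - slope * np.sum(x)) / n
    return float(slope), float(intercept)


def anova_sums_oracle(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """(ss_between, ss_within, F) by the computational textbook formulas."""
    groups = [np.asarray(g, float) for g in groups]
    all_vals = np.concatenate(groups)
    n = all_vals.size
    correction = all_vals.sum() ** 2 / n
    ss_total = np.sum(all_vals**2) - correction
    ss_between = sum(g.sum() ** 2 / g.size for g in groups) - correction
    ss_within = ss_total - ss_between
    df_b = len(groups) - 1
    df_w = n - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(ss_between), float(ss_within), float(f)


def tukey_permutation_pvalues(
    groups: list[np.ndarray], n_perm: int = 10_000, seed: int = 0
) -> dict[tuple[int, int], float]:
    """Permutation approximation to familywise-adjusted pairwise p-values.

    Adjusted p for pair (i, j) is the fraction of label permutations whose
    *maximum* absolute pairwise mean difference exceeds the observed
    difference for that pair (single-step max-T adjustment).
    """
    rng = np.random.default_rng(seed)
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    pairs = list(itertools.combinations(range(len(groups)), 2))

    def pair_diffs(vals: np.ndarray) -> dict[tuple[int, int], float]:
        bounds = np.cumsum([0] + sizes)
        means = [vals[bounds[k]: bounds[k + 1]].mean() for k in range(len(sizes))]
        return {(i, j): abs(means[i] - means[j]) for i, j in pairs}

    observed = pair_diffs(pooled)
    exceed = {p: 0 for p in pairs}
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        max_diff = max(pair_diffs(perm).values())
        for p in pairs:
            if max_diff >= observed[p]:
                exceed[p] += 1
    return {p: exceed[p] / n_perm for p in pairs}
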