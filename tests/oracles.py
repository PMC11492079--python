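"""Independent brute-force reference implementations used only by tests.

Deliberately naive (explicit loops, flood fill, rank arithmetic) so they
share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> int:
    """Count connected components by breadth-first flood fill."""
    offsets = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if (a, b, c) == (0, 0, 0):
                    continue
                manhattan = abs(a) + abs(b) + abs(c)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((a, b, c))
    visited = np.zeros(mask.shape, dtype=bool)
    n = 0
    for idx in zip(*np.nonzero(mask)):
        if visited[idx]:
            continue
        n += 1
        stack = [idx]
        visited[idx] = True
        while stack:
            i, j, k = stack.pop()
            for a, b, c in offsets:
                p = (i + a, j + b, k + c)
                if all(0 <= p[d] < mask.shape[d] for d in range(3)):
                    if mask[p] and not visited[p]:
                        visited[p] = True
                        stack.append(p)
    return n


def brute_match(ref_labels: np.ndarray, pred_labels: np.ndarray, min_overlap: int = 1):
    """Exhaustive pairwise-overlap lesion matching."""
    ref_ids = sorted(set(ref_labels[ref_labels > 0].tolist()))
    pred_ids = sorted(set(pred_labels[pred_labels > 0].tolist()))
    tp, fp = set(), set(pred_ids)
    for r in ref_ids:
        rmask = ref_labels == r
        for p in pred_ids:
            shared = int(np.count_nonzero(rmask & (pred_labels == p)))
            if shared >= 1:
                fp.discard(p)
            if shared >= min_overlap:
                tp.add(r)
    fn = set(ref_ids) - tp
    return sorted(tp), sorted(fn), sorted(fp)


def anova_mean_squares(x: np.ndarray):
    """Two-way (rows x columns, one obs/cell) mean squares by explicit sums."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i, :].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def friedman_chi2(x: np.ndarray) -> float:
    """Friedman statistic with midranks and tie correction, from scratch."""
    n, k = x.shape
    ranks = np.empty_like(x, dtype=float)
    tie_sum = 0.0
    for i in range(n):
        row = x[i]
        order = np.argsort(row, kind="stable")
        r = np.empty(k, dtype=float)
        pos = 0
        while pos < k:
            tied = [order[pos]]
            while pos + len(tied) < k and row[order[pos + len(tied)]] == row[order[pos]]:
                tied.append(order[pos + len(tied)])
            avg = np.mean([pos + 1 + t for t in range(len(tied))])
            for t in tied:
                r[t] = avg
            tie_sum += len(tied) ** 3 - len(tied)
            pos += len(tied)
        ranks[i] = r
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    correction = 1.0 - tie_sum / (n * (k**3 - k))
    return stat / correction if correction > 0 else np.nan
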