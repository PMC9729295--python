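"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorised code paths of the package: plain
Python loops over definitions, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_force_es(ranked_ids, members) -> float:
    """Classic running-sum enrichment score by direct walk, tracking the
    signed extremum (first occurrence on ties)."""
    ranked_ids = list(ranked_ids)
    n = len(ranked_ids)
    n_hit = sum(1 for r in ranked_ids if r in members)
    running = 0.0
    path = []
    for r in ranked_ids:
        if r in members:
            running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        path.append(running)
    # report the first point within round-off (1e-12) of the extremum
    peak = max(abs(v) for v in path)
    for v in path:
        if abs(v) >= peak - 1e-12:
            return v
    raise AssertionError("unreachable")


def step_up_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up formula:
    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        val = m * p[order[rank - 1]] / rank
        running_min = min(running_min, val)
        q_sorted[rank - 1] = min(1.0, running_min)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def chi2_textbook(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square statistic sum((O-E)^2 / E) on a 2x2 table."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i, j] - e) ** 2 / e
    return stat


def pooled_t(x, y) -> float:
    """Two-sample pooled-variance t by direct formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    sp2 = ss / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
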