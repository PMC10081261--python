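"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive -- double loops, explicit path
enumeration, closed-form sums of squares -- and shares no code with the
package paths it verifies.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def pearson_sums_oracle(x, y) -> float:
    """Sample Pearson r via explicit standardized sums of products."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    return float(np.sum(zx * zy) / (n - 1))


def correlation_matrix_oracle(rows: np.ndarray) -> np.ndarray:
    """Region x region correlation by double loop over region pairs."""
    n = rows.shape[0]
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            R[i, j] = R[j, i] = pearson_sums_oracle(rows[i], rows[j])
    return R


def betweenness_oracle(nodes, edges) -> dict:
    """Unnormalized betweenness by BFS shortest-path enumeration.

    For every unordered pair (s, t) count all shortest paths and the share
    passing through each interior node; disconnected pairs contribute 0.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        # BFS from s recording distance
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        if t not in dist:
            continue
        # enumerate all shortest s-t paths by walking the BFS DAG backwards
        paths: list[tuple] = []
        stack = [(t, (t,))]
        while stack:
            v, path = stack.pop()
            if v == s:
                paths.append(path)
                continue
            for w in adj[v]:
                if w in dist and dist[w] == dist[v] - 1:
                    stack.append((w, (w,) + path))
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def participation_oracle(nodes, edges, module_of) -> dict:
    """P_i from explicit per-module edge counting."""
    adj = {v: [] for v in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    out = {}
    for v in nodes:
        k = len(adj[v])
        if k == 0:
            out[v] = 0.0
            continue
        acc = 0.0
        for module in {module_of[w] for w in adj[v]}:
            kappa = sum(1 for w in adj[v] if module_of[w] == module)
            acc += (kappa / k) ** 2
        out[v] = 1.0 - acc
    return out


def bh_stepup_oracle(p, q=0.05):
    """Largest i with p_(i) <= i*q/m rule; returns boolean discovery flags."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def two_way_anova_oracle(values, a_labels, b_labels):
    """Classic sums-of-squares two-way ANOVA for *balanced* layouts.

    Returns dict of (F, df1, df2, p) per effect using scipy's F survival
    function only at the very end.
    """
    from scipy.stats import f as fdist

    values = np.asarray(values, dtype=float)
    a_levels = sorted(set(a_labels))
    b_levels = sorted(set(b_labels))
    a = len(a_levels)
    b = len(b_levels)
    cell = {}
    for v, ai, bi in zip(values, a_labels, b_labels):
        cell.setdefault((ai, bi), []).append(v)
    ns = {len(v) for v in cell.values()}
    assert len(ns) == 1, "oracle requires a balanced layout"
    n = ns.pop()
    grand = values.mean()
    ss_a = b * n * sum((np.mean([v for (ai, _), vs in cell.items() for v in vs if ai == lev]) - grand) ** 2 for lev in a_levels)
    ss_b = a * n * sum((np.mean([v for (_, bi), vs in cell.items() for v in vs if bi == lev]) - grand) ** 2 for lev in b_levels)
    ss_cells = n * sum((np.mean(vs) - grand) ** 2 for vs in cell.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum((v - np.mean(vs)) ** 2 for vs in cell.values() for v in vs)
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err
    out = {}
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("ab", ss_ab, df_ab)):
        F = (ss / df) / ms_err
        out[name] = (F, df, df_err, float(fdist.sf(F, df, df_err)))
    return out


def pairwise_agreement_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from explicit pair-agreement counts."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n = len(labels_a)
    both = same_a = same_b = 0
    for i, j in combinations(range(n), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        same_a += sa
        same_b += sb
        both += sa and sb
    total = n * (n - 1) // 2
    expected = same_a * same_b / total
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)
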