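"""Independent reference implementations used as test oracles.

Everything here is written directly from the method definitions as plain
double loops and exhaustive enumeration, deliberately sharing no code
with the package's vectorised engine, so agreement between the two is a
meaningful check.
"""

from __future__ import annotations

import math
from typing import Sequence


def naive_zone_weight(
    t: float, breaks: Sequence[float], weights: Sequence[float]
) -> float:
    """Stepwise decay weight, 0 outside the last break. t=0 is in zone 1."""
    if math.isinf(t):
        return 0.0
    lower = 0.0
    for b, w in zip(breaks, weights):
        if (lower < t <= b) or (lower == 0.0 and t == 0.0):
            return w
        lower = b
    return 0.0


def naive_scores(
    severity_counts: Sequence[Sequence[int]],
    beds: Sequence[int],
    times: Sequence[Sequence[float]],
    breaks: Sequence[float],
    zone_weights: Sequence[float],
    severity_weights: Sequence[float] | None,
) -> list[float]:
    """Double-loop two-step floating catchment computation.

    ``times[i][j]`` is minutes from region i to facility j. Plain
    thresholding is the single-zone case (breaks=[d0], weights=[1]).
    Facilities with zero weighted catchment demand contribute nothing.
    """
    n_regions = len(severity_counts)
    n_fac = len(beds)

    def demand(i: int) -> float:
        if severity_weights is None:
            return float(sum(severity_counts[i]))
        return float(
            sum(c * w for c, w in zip(severity_counts[i], severity_weights))
        )

    # step 1: per-facility supply-to-demand ratio
    ratios = []
    for j in range(n_fac):
        total = 0.0
        for k in range(n_regions):
            total += naive_zone_weight(times[k][j], breaks, zone_weights) * demand(k)
        ratios.append(beds[j] / total if total > 0 else 0.0)

    # step 2: per-region sum of reachable ratios
    scores = []
    for i in range(n_regions):
        a = 0.0
        for j in range(n_fac):
            a += naive_zone_weight(times[i][j], breaks, zone_weights) * ratios[j]
        scores.append(a)
    return scores


def enumerate_shortest_time(graph, source, target) -> float:
    """Minimum travel time by exhaustive simple-path enumeration (DFS).

    Only feasible on tiny graphs (<= ~10 nodes). Returns inf when no path
    exists. Edge cost attribute: ``minutes``.
    """
    best = math.inf

    def dfs(node, visited, acc):
        nonlocal best
        if acc >= best:
            return
        if node == target:
            best = acc
            return
        for nbr in graph[node]:
            if nbr not in visited:
                dfs(nbr, visited | {nbr}, acc + graph[node][nbr]["minutes"])

    dfs(source, {source}, 0.0)
    return best


def manual_spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho from first principles: average ranks + Pearson formula."""

    def avg_ranks(v: Sequence[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0  # average of 1-based positions
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
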