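"""Method comparison and map-level summaries of accessibility scores.

Accessibility configurations are validated against an external yardstick:
the travel time from each region to its closest facility (CFD). A good
score should fall as that distance grows, so each method's per-region
scores are rank-correlated (Spearman) with the CFD vector and a more
negative rho indicates the better-behaved measure. The module also
provides the overlaid (average-of-methods) score, descriptive summaries,
and shared interval classification for visually comparable choropleths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .accessibility import AccessResult

__all__ = [
    "SummaryStats",
    "spearman_rho",
    "compare_methods",
    "overlay_mean",
    "summarize",
    "classify",
    "percentage_breakdown",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary of a score vector.

    ``sd`` is the sample standard deviation (n-1 denominator); it is NaN
    for a single observation. ``n_above``/``prop_above`` count scores
    strictly above the high-access threshold.
    """

    n: int
    mean: float
    sd: float
    min: float
    max: float
    threshold: float
    n_above: int
    prop_above: float

    @property
    def pct_above(self) -> float:
        """Percentage above threshold, rounded to one decimal."""
        return round(100.0 * self.prop_above, 1)


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    *,
    method: str = "t",
) -> tuple[float, float]:
    """Spearman rank correlation of two equal-length vectors, with p-value.

    Both vectors are ranked with average ranks for ties and the
    product-moment correlation of the ranks is returned. ``method="t"``
    uses the large-sample t approximation for the two-sided p-value;
    ``method="permutation"`` enumerates all pairings exactly and is
    limited to n <= 10.

    A constant vector leaves the rank correlation undefined and raises
    (rather than silently reporting 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    if method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        res = stats.permutation_test(
            (x, y),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=math.inf,
            alternative="two-sided",
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; use 't' or 'permutation'")


def compare_methods(
    results: Sequence[AccessResult],
    cfd: Mapping[str, float],
) -> pd.DataFrame:
    """Spearman rho of every method's scores against closest-facility time.

    All results must cover the same region set as ``cfd``. Regions whose
    closest facility is unreachable (infinite CFD) are excluded pairwise,
    with the exclusion count logged; silent NA propagation would hide data
    problems.

    Returns a DataFrame indexed by method with ``rho``, ``p_value`` and
    ``n_regions`` columns.
    """
    if not results:
        raise ValueError("no results to compare")
    region_ids = results[0].region_ids
    for res in results[1:]:
        if res.region_ids != region_ids:
            raise ValueError(
                f"region sets differ between methods {results[0].method!r} "
                f"and {res.method!r}"
            )
    if set(cfd) != set(region_ids):
        raise ValueError("closest-facility distances cover a different region set")

    d = np.array([cfd[rid] for rid in region_ids], dtype=float)
    finite = np.isfinite(d)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.info(
            "excluding %d region(s) with unreachable closest facility "
            "from the correlation", n_excluded,
        )
    rows = []
    for res in results:
        rho, p = spearman_rho(res.scores[finite], d[finite])
        rows.append(
            {"method": res.method, "rho": rho, "p_value": p, "n_regions": int(finite.sum())}
        )
    return pd.DataFrame(rows).set_index("method")


def overlay_mean(results: Sequence[AccessResult]) -> AccessResult:
    """Overlaid score: the arithmetic mean of the methods' scores per region."""
    if not results:
        raise ValueError("overlay of an empty result list is undefined")
    region_ids = results[0].region_ids
    for res in results[1:]:
        if res.region_ids != region_ids:
            raise ValueError("region sets differ across results")
    mean = np.mean([res.scores for res in results], axis=0)
    return AccessResult(
        method="overlay_mean",
        region_ids=region_ids,
        scores=mean,
        params={"methods": [res.method for res in results]},
    )


def summarize(scores: Sequence[float], high_threshold: float) -> SummaryStats:
    """Mean/SD/min/max of scores and the share strictly above a threshold."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot summarize an empty score vector")
    sd = float(np.std(s, ddof=1)) if s.size > 1 else float("nan")
    if s.size == 1:
        logger.warning("single observation: sample SD undefined (NaN)")
    n_above = int((s > high_threshold).sum())
    return SummaryStats(
        n=int(s.size),
        mean=float(s.mean()),
        sd=sd,
        min=float(s.min()),
        max=float(s.max()),
        threshold=float(high_threshold),
        n_above=n_above,
        prop_above=n_above / s.size,
    )


def classify(
    scores: Sequence[float],
    breaks: Sequence[float] | None = None,
    n_classes: int | None = None,
) -> np.ndarray:
    """Assign interval class labels (0 = lowest) to scores.

    Either explicit strictly-increasing interior ``breaks`` or a quantile
    ``n_classes`` count must be given. The same edges should be applied to
    every method so the resulting maps are visually comparable. A score
    exactly at a break belongs to the lower interval (upper edges
    inclusive).
    """
    s = np.asarray(scores, dtype=float)
    if (breaks is None) == (n_classes is None):
        raise ValueError("give exactly one of breaks or n_classes")
    if breaks is not None:
        edges = np.asarray(breaks, dtype=float)
        if edges.ndim != 1 or edges.size == 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("breaks must be non-empty and strictly increasing")
    else:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        qs = np.linspace(0, 1, n_classes + 1)[1:-1]
        edges = np.unique(np.quantile(s, qs))  # degenerate data collapses classes
    # upper-inclusive: score <= edge stays in the lower class
    return np.searchsorted(edges, s, side="left").astype(int)


def percentage_breakdown(
    counts: Mapping[str, int], decimals: int = 2
) -> pd.DataFrame:
    """Share of a total per category, as printed-report percentages.

    Used for registry-style characterization tables (counts by disability
    type or severity). Returns a DataFrame with ``count`` and ``pct``
    (percent of the grand total rounded to ``decimals``).
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return pd.DataFrame(
        {
            "count": list(counts.values()),
            "pct": [round(100.0 * c / total, decimals) for c in counts.values()],
        },
        index=list(counts.keys()),
    )
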