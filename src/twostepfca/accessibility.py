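"""Floating catchment area accessibility scores.

This module implements the two-step floating catchment area (2SFCA) family
of potential spatial accessibility (PSA) measures for a set of demand
regions (neighbourhoods holding people living with disability, stratified
by severity of disability) and supply facilities (hospitals, capacity in
beds).

Four configurations are supported:

``2sfca``
    Plain two-step floating catchment area with a single travel-time
    threshold (default 5 minutes). Step 1 gives each facility *j* a
    bed-to-population ratio ``R_j = S_j / sum_{k: t_kj <= d0} P_k``;
    step 2 gives each region *i* the score ``A_i = sum_{j: t_ij <= d0} R_j``.

``e2sfca``
    Enhanced 2SFCA: the catchment is split into nested travel-time zones
    (default breaks 5/10/15 min) and each contribution is multiplied by a
    zone-specific distance-decay weight (default 1.00/0.68/0.22, a stepwise
    Gaussian-type decay). The same weights apply in both steps.

``sev_2sfca`` / ``sev_e2sfca``
    The same two measures with severity-weighted demand: each region's
    count in a severity category is multiplied by that category's weight
    (default mild=1, moderate=2, severe=3, very severe=4) before entering
    the step-1 denominator. Step 2 sums the ratios unmodified.

Scores are in beds per person (per *weighted* person for the severity
variants). All four configurations share one vectorised engine built on a
zone-weight matrix; the plain threshold is the one-zone special case with
weight 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SEVERITY_CATEGORIES",
    "DEFAULT_THRESHOLD_MIN",
    "DEFAULT_DECAY",
    "DEFAULT_SEVERITY",
    "METHODS",
    "Region",
    "Facility",
    "DecayScheme",
    "SeverityWeights",
    "AccessResult",
    "effective_demand",
    "zone_of",
    "supply_ratio",
    "access_score",
    "run_configuration",
]

logger = logging.getLogger(__name__)

#: Severity categories of disability, in increasing order of severity.
SEVERITY_CATEGORIES = ("mild", "moderate", "severe", "very_severe")

#: Travel-time threshold (minutes) for the plain 2SFCA variants.
DEFAULT_THRESHOLD_MIN = 5.0

#: The four method tags, in the order they are conventionally reported.
METHODS = ("2sfca", "sev_2sfca", "e2sfca", "sev_e2sfca")


@dataclass(frozen=True)
class Region:
    """A demand unit: a neighbourhood with severity-stratified counts."""

    id: str
    centroid: tuple[float, float]
    severity_counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.severity_counts) != len(SEVERITY_CATEGORIES):
            raise ValueError(
                f"region {self.id!r}: expected {len(SEVERITY_CATEGORIES)} "
                f"severity counts, got {len(self.severity_counts)}"
            )
        if any(c < 0 for c in self.severity_counts):
            raise ValueError(f"region {self.id!r}: negative severity count")

    @property
    def population(self) -> int:
        """Total disability count (sum over severity categories)."""
        return int(sum(self.severity_counts))


@dataclass(frozen=True)
class Facility:
    """A supply unit: a hospital with its capacity in beds."""

    id: str
    location: tuple[float, float]
    beds: int

    def __post_init__(self) -> None:
        if self.beds <= 0:
            raise ValueError(f"facility {self.id!r}: beds must be > 0, got {self.beds}")


@dataclass(frozen=True)
class DecayScheme:
    """Nested travel-time zones with a distance-decay weight per zone.

    ``zone_breaks`` are the upper edges in minutes of zones 1..R
    (``b_1 < b_2 < ... < b_R``); ``zone_weights`` are the weights
    ``W_r`` in (0, 1], strictly decreasing. Travel times beyond the last
    break fall outside every catchment (weight 0).
    """

    zone_breaks: tuple[float, ...]
    zone_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.zone_breaks) != len(self.zone_weights):
            raise ValueError("zone_breaks and zone_weights must have equal length")
        if not self.zone_breaks:
            raise ValueError("at least one zone is required")
        breaks = np.asarray(self.zone_breaks, dtype=float)
        if np.any(breaks <= 0) or np.any(np.diff(breaks) <= 0):
            raise ValueError("zone_breaks must be positive and strictly increasing")
        w = np.asarray(self.zone_weights, dtype=float)
        if np.any(w <= 0) or w[0] > 1 or np.any(np.diff(w) >= 0):
            raise ValueError("zone_weights must be in (0, 1] and strictly decreasing")

    @classmethod
    def single_threshold(cls, d0: float) -> "DecayScheme":
        """The plain-2SFCA catchment as a one-zone scheme with weight 1."""
        return cls((float(d0),), (1.0,))

    def weight_of(self, t: float) -> float:
        """Decay weight at travel time ``t``; 0 outside every zone."""
        z = zone_of(t, self)
        return 0.0 if z is None else float(self.zone_weights[z - 1])

    def weight_matrix(self, times: np.ndarray) -> np.ndarray:
        """Element-wise zone weights for a travel-time array (0 outside)."""
        t = np.asarray(times, dtype=float)
        out = np.zeros_like(t)
        lower = 0.0
        for b, w in zip(self.zone_breaks, self.zone_weights):
            out[(t > lower) & (t <= b)] = w
            lower = b
        out[t == 0.0] = self.zone_weights[0]
        return out


#: Default travel-time zones (5/10/15-minute drive) with stepwise
#: Gaussian-type decay weights for the enhanced variants.
DEFAULT_DECAY = DecayScheme((5.0, 10.0, 15.0), (1.00, 0.68, 0.22))


@dataclass(frozen=True)
class SeverityWeights:
    """Demand weight per severity category (mild, moderate, severe, very severe).

    Higher-need categories exert proportionally more demand in the step-1
    denominator. The default (1, 2, 3, 4) makes a very severely disabled
    person count four times a mildly disabled one.
    """

    weights: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.weights) != len(SEVERITY_CATEGORIES):
            raise ValueError(
                f"expected {len(SEVERITY_CATEGORIES)} severity weights"
            )
        if any(w < 0 for w in self.weights):
            raise ValueError("severity weights must be non-negative")

    @property
    def is_unit(self) -> bool:
        return all(w == 1.0 for w in self.weights)


#: Paper-style default severity weights (mild=1 ... very severe=4).
DEFAULT_SEVERITY = SeverityWeights((1.0, 2.0, 3.0, 4.0))


@dataclass(frozen=True)
class AccessResult:
    """Per-region accessibility scores for one method configuration.

    ``scores[i]`` is A_i in beds per (weighted) person for
    ``region_ids[i]``; ``params`` echoes the full configuration so results
    are self-describing.
    """

    method: str
    region_ids: tuple[str, ...]
    scores: np.ndarray
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.region_ids),):
            raise ValueError("scores must be one value per region")
        if np.any(~np.isfinite(scores)) or np.any(scores < 0):
            raise ValueError("scores must be finite and non-negative")
        object.__setattr__(self, "scores", scores)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.region_ids, self.scores.tolist()))


def effective_demand(
    region: Region, severity: SeverityWeights | None = None
) -> float:
    """Demand exerted by a region, optionally severity-weighted.

    With ``severity=None`` this is the plain head count; otherwise each
    category count is multiplied by its severity weight and summed.
    """
    if severity is None:
        return float(region.population)
    return float(
        sum(c * w for c, w in zip(region.severity_counts, severity.weights))
    )


def zone_of(t: float, scheme: DecayScheme) -> int | None:
    """Travel-time zone (1-based) containing ``t``, or None outside all zones.

    Zones are half-open on the left, ``b_{r-1} < t <= b_r`` with
    ``b_0 = 0``; zone 1 additionally includes ``t = 0`` (a demand point
    co-located with the facility). Infinite times (unreachable pairs) fall
    outside every zone.
    """
    if t < 0:
        raise ValueError(f"travel time must be non-negative, got {t}")
    if not np.isfinite(t) or t > scheme.zone_breaks[-1]:
        return None
    lower = 0.0
    for r, b in enumerate(scheme.zone_breaks, start=1):
        if (t > lower and t <= b) or (r == 1 and t == 0.0):
            return r
        lower = b
    return None  # pragma: no cover - unreachable given the guard above


def _demand_vector(
    regions: Sequence[Region], severity: SeverityWeights | None
) -> np.ndarray:
    return np.array([effective_demand(r, severity) for r in regions], dtype=float)


def _resolve_scheme(scheme_or_threshold: DecayScheme | float) -> DecayScheme:
    if isinstance(scheme_or_threshold, DecayScheme):
        return scheme_or_threshold
    return DecayScheme.single_threshold(float(scheme_or_threshold))


def supply_ratio(
    facility: Facility,
    regions: Sequence[Region],
    times_to_facility: Sequence[float],
    scheme_or_threshold: DecayScheme | float,
    severity: SeverityWeights | None = None,
) -> float:
    """Step 1: bed-to-population ratio R_j of one facility.

    ``times_to_facility[k]`` is the travel time in minutes from region
    ``k``'s centroid to the facility. With a plain threshold ``d0`` the
    denominator is the total (weighted) demand within ``d0``; with a decay
    scheme each zone's demand is multiplied by its weight.

    A facility with zero catchment demand gets ``R_j = 0`` with a logged
    warning rather than an error, so result shapes stay stable.
    """
    scheme = _resolve_scheme(scheme_or_threshold)
    w = scheme.weight_matrix(np.asarray(times_to_facility, dtype=float))
    demand = float(w @ _demand_vector(regions, severity))
    if demand <= 0:
        logger.warning(
            "facility %s has zero (weighted) demand in its catchment; R_j set to 0",
            facility.id,
        )
        return 0.0
    return facility.beds / demand


def access_score(
    region_times: Sequence[float],
    ratios: Sequence[float],
    scheme_or_threshold: DecayScheme | float,
) -> float:
    """Step 2: accessibility score A_i of one region.

    ``region_times[j]`` is the travel time from the region to facility
    ``j`` and ``ratios[j]`` its step-1 ratio R_j, computed under the same
    scheme/threshold. Facilities outside every zone contribute nothing; a
    region reaching no facility scores 0.
    """
    scheme = _resolve_scheme(scheme_or_threshold)
    w = scheme.weight_matrix(np.asarray(region_times, dtype=float))
    return float(w @ np.asarray(ratios, dtype=float))


def _compute_scores(
    regions: Sequence[Region],
    facilities: Sequence[Facility],
    times: np.ndarray,
    scheme: DecayScheme,
    severity: SeverityWeights | None,
) -> np.ndarray:
    """Vectorised two-step engine shared by all four configurations."""
    with warnings.catch_warnings():
        # inf travel times are legitimate (unreachable) and weight to 0
        warnings.simplefilter("ignore", RuntimeWarning)
        w = scheme.weight_matrix(times)
    demand = _demand_vector(regions, severity)
    supply = np.array([f.beds for f in facilities], dtype=float)
    denom = w.T @ demand  # per-facility weighted catchment demand
    ratios = np.zeros_like(supply)
    served = denom > 0
    if not np.all(served):
        for f in np.asarray(facilities, dtype=object)[~served]:
            logger.warning(
                "facility %s has zero (weighted) demand in its catchment; "
                "R_j set to 0",
                f.id,
            )
    ratios[served] = supply[served] / denom[served]
    return w @ ratios


def run_configuration(
    regions: Sequence[Region],
    facilities: Sequence[Facility],
    times: np.ndarray,
    method: str,
    *,
    threshold: float = DEFAULT_THRESHOLD_MIN,
    scheme: DecayScheme | None = None,
    severity: SeverityWeights | None = None,
) -> AccessResult:
    """Run one full 2SFCA configuration and return per-region scores.

    Parameters
    ----------
    regions, facilities
        Demand and supply units.
    times
        Region-by-facility travel times in minutes (``np.inf`` where
        unreachable), aligned with ``regions`` and ``facilities``.
    method
        One of ``"2sfca"``, ``"e2sfca"``, ``"sev_2sfca"``, ``"sev_e2sfca"``.
    threshold
        Single catchment threshold in minutes for the plain variants.
    scheme
        Decay zones for the enhanced variants (default 5/10/15 min with
        weights 1.00/0.68/0.22). Rejected for plain variants.
    severity
        Severity demand weights, required for (and only for) the
        severity-integrated variants; passing them to a plain method is an
        error rather than a silent no-op.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    is_sev = method.startswith("sev_")
    is_enhanced = method.endswith("e2sfca")

    if is_sev and severity is None:
        severity = DEFAULT_SEVERITY
    if not is_sev and severity is not None:
        raise ValueError(
            f"severity weights supplied to non-severity method {method!r}"
        )
    if is_enhanced:
        scheme = scheme if scheme is not None else DEFAULT_DECAY
    elif scheme is not None:
        raise ValueError(f"decay scheme supplied to plain method {method!r}")
    else:
        scheme = DecayScheme.single_threshold(threshold)

    times = np.asarray(times, dtype=float)
    if times.shape != (len(regions), len(facilities)):
        raise ValueError(
            f"travel-time matrix shape {times.shape} does not match "
            f"{len(regions)} regions x {len(facilities)} facilities"
        )

    scores = _compute_scores(regions, facilities, times, scheme, severity)
    params: dict[str, object] = {
        "zone_breaks_min": list(scheme.zone_breaks),
        "zone_weights": list(scheme.zone_weights),
    }
    if not is_enhanced:
        params = {"threshold_min": float(threshold)}
    if is_sev:
        params["severity_weights"] = list(severity.weights)  # type: ignore[union-attr]
    return AccessResult(
        method=method,
        region_ids=tuple(r.id for r in regions),
        scores=scores,
        params=params,
    )
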