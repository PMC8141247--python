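"""Synthetic cities for exercising the accessibility pipeline end to end.

The generator emulates the statistical structure of a mid-sized Iranian
metropolis as it appears to the accessibility method: a few dozen
contiguous neighbourhoods tiling a rectangle, a disability population in
the low tens of thousands with a fixed severity mix (defaults: the
registered mix 10.46% mild / 28.44% moderate / 43.31% severe / 17.79%
very severe), ~20 hospitals of heterogeneous capacity (55-750 beds)
preferentially located toward the city centre, and a connected grid road
network whose edges carry one of four hierarchy classes.

Everything is drawn from a single seeded NumPy generator in a documented
order (region demand shares, severity split, type split, facility sites,
beds, road classes), so a fixed seed reproduces a city bit for bit.
Coordinates are planar metres in a local frame; the method needs
distances and times, not geodesy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .accessibility import SEVERITY_CATEGORIES, Facility, Region
from .travel import ROAD_CLASSES, RoadSegment

__all__ = [
    "DISABILITY_TYPES",
    "CityParams",
    "SyntheticCity",
    "generate_city",
    "generate_individual_points",
]

#: Types of disability tracked in the registry data the generator mimics.
DISABILITY_TYPES = ("physical", "intellectual", "hearing_vocal", "visual", "mental")

# Registered severity mix: counts (1693, 4603, 7010, 2880) of 16,186.
_SEVERITY_COUNTS = (1693, 4603, 7010, 2880)
# Registered type mix: counts (6206, 4864, 2127, 1835, 1154) of 16,186.
_TYPE_COUNTS = (6206, 4864, 2127, 1835, 1154)
_REGISTRY_TOTAL = 16186


def _normalized(counts: Sequence[int]) -> tuple[float, ...]:
    total = sum(counts)
    return tuple(c / total for c in counts)


@dataclass(frozen=True)
class CityParams:
    """Parameters of a synthetic city.

    Defaults mirror the study population the package targets: 68
    neighbourhoods over ~258 km^2, 22 hospitals of 55-750 beds, 1.186
    million inhabitants with a disability registry of ~16,186 people
    (rate 16186/1186000), severity and type mixes from the registry
    counts. ``road_class_shares`` orders (expressway, main, secondary,
    local); no registry value exists, so the default is a plausible urban
    hierarchy with few expressways and many local streets.

    Geography defaults encode the centre-rich/periphery-poor pattern of
    the emulated city: hospitals cluster tightly around the city centre
    (placement probability decays exponentially with ``facility_scale``
    x extent), while demand concentrates toward an off-centre
    (south-western) focus at ``demand_centre`` (in extent fractions) with
    spatial scale ``demand_scale`` and heavy lognormal rate noise
    (``demand_noise_sd``), matching the order-of-magnitude spread of
    neighbourhood disability rates in registry data.
    """

    n_regions: int = 68
    grid_extent: float = 16000.0
    n_facilities: int = 22
    bed_range: tuple[int, int] = (55, 750)
    total_population: int = 1_186_000
    disability_rate: float = _REGISTRY_TOTAL / 1_186_000
    severity_mix: tuple[float, float, float, float] = _normalized(_SEVERITY_COUNTS)
    type_mix: tuple[float, float, float, float, float] = _normalized(_TYPE_COUNTS)
    road_class_shares: tuple[float, float, float, float] = (0.10, 0.20, 0.30, 0.40)
    centre_weighted_facilities: bool = True
    facility_scale: float = 0.05
    demand_centre: tuple[float, float] = (0.35, 0.35)
    demand_scale: float = 0.30
    demand_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix, k in (
            ("severity_mix", self.severity_mix, len(SEVERITY_CATEGORIES)),
            ("type_mix", self.type_mix, len(DISABILITY_TYPES)),
            ("road_class_shares", self.road_class_shares, len(ROAD_CLASSES)),
        ):
            if len(mix) != k:
                raise ValueError(f"{name} must have {k} entries")
            if any(p < 0 for p in mix):
                raise ValueError(f"{name} entries must be non-negative")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(mix)!r})")
        if self.n_regions < 1 or self.n_facilities < 1:
            raise ValueError("n_regions and n_facilities must be >= 1")
        if self.bed_range[0] < 1 or self.bed_range[0] > self.bed_range[1]:
            raise ValueError("bed_range must satisfy 1 <= min <= max")
        if self.grid_extent <= 0:
            raise ValueError("grid_extent must be > 0")
        if not 0 <= self.disability_rate <= 1:
            raise ValueError("disability_rate must be a fraction in [0, 1]")
        if self.total_population < 1:
            raise ValueError("total_population must be >= 1")
        if self.facility_scale <= 0 or self.demand_scale <= 0:
            raise ValueError("facility_scale and demand_scale must be > 0")
        if self.demand_noise_sd < 0:
            raise ValueError("demand_noise_sd must be >= 0")
        if not all(0.0 <= v <= 1.0 for v in self.demand_centre):
            raise ValueError("demand_centre is in extent fractions [0, 1]")
        if self.n_facilities > self.n_regions * 4:
            raise ValueError(
                f"n_facilities={self.n_facilities} exceeds placement capacity "
                f"({self.n_regions} regions x 4)"
            )

    @property
    def total_disability(self) -> int:
        return int(round(self.total_population * self.disability_rate))

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the most nearly square tiling with rows*cols = n_regions."""
        best = (1, self.n_regions)
        for r in range(1, int(math.isqrt(self.n_regions)) + 1):
            if self.n_regions % r == 0:
                best = (r, self.n_regions // r)
        return best


@dataclass
class SyntheticCity:
    """A generated city: demand regions, hospitals, and the road grid."""

    params: CityParams
    regions: list[Region]
    facilities: list[Facility]
    roads: list[RoadSegment]
    region_polygons: dict[str, Polygon]
    type_counts: dict[str, tuple[int, ...]]
    individuals: list[tuple[float, float, str, str]] | None = field(default=None)

    @property
    def total_disability(self) -> int:
        return sum(r.population for r in self.regions)


def _region_grid(params: CityParams) -> tuple[list[str], list[Polygon], float, float]:
    rows, cols = params.grid_shape
    cw = params.grid_extent / cols
    ch = params.grid_extent / rows
    ids, polys = [], []
    for r in range(rows):
        for c in range(cols):
            ids.append(f"R{r * cols + c:03d}")
            x0, y0 = c * cw, r * ch
            polys.append(Polygon([(x0, y0), (x0 + cw, y0), (x0 + cw, y0 + ch), (x0, y0 + ch)]))
    return ids, polys, cw, ch


def _lattice_nodes(params: CityParams) -> np.ndarray:
    """Corner-lattice node coordinates of the road grid, row-major."""
    rows, cols = params.grid_shape
    cw = params.grid_extent / cols
    ch = params.grid_extent / rows
    xs = np.arange(cols + 1) * cw
    ys = np.arange(rows + 1) * ch
    return np.array([(x, y) for y in ys for x in xs])


def generate_city(params: CityParams) -> SyntheticCity:
    """Generate a synthetic city deterministically from ``params.seed``.

    Regions tile the extent as an r x c rectangular grid. The disability
    total is split multinomially over regions with spatially structured
    demand shares (exponential decay from ``demand_centre`` times
    lognormal rate noise), then over severity categories with
    ``severity_mix`` (and, bookkeeping only, over disability types with
    ``type_mix``). Facilities occupy distinct road nodes, by default with
    probability decaying in distance from the city centre so that access
    is centre-rich and periphery-poor; bed counts are log-uniform over
    ``bed_range`` (most hospitals small, a few large). Road edges connect
    lattice neighbours and draw their hierarchy class i.i.d. from
    ``road_class_shares``, so the grid graph is connected by construction.

    All draws consume one seeded stream in a fixed order (demand noise,
    region totals, per-region severity then type splits, facility sites,
    beds, road classes), so a fixed seed is bit-reproducible.
    """
    rng = np.random.default_rng(params.seed)
    ids, polys, cw, ch = _region_grid(params)

    # 1) demand shares over regions, then severity and type splits
    centroids = np.array([(p.centroid.x, p.centroid.y) for p in polys])
    focus = np.asarray(params.demand_centre) * params.grid_extent
    gravity = np.exp(
        -np.linalg.norm(centroids - focus, axis=1)
        / (params.demand_scale * params.grid_extent)
    )
    shares = gravity * rng.lognormal(0.0, params.demand_noise_sd, params.n_regions)
    shares /= shares.sum()
    region_totals = rng.multinomial(params.total_disability, shares)
    regions: list[Region] = []
    type_counts: dict[str, tuple[int, ...]] = {}
    for rid, poly, n in zip(ids, polys, region_totals):
        sev = rng.multinomial(n, params.severity_mix)
        typ = rng.multinomial(n, params.type_mix)
        cx, cy = poly.centroid.x, poly.centroid.y
        regions.append(Region(id=rid, centroid=(cx, cy), severity_counts=tuple(int(v) for v in sev)))
        type_counts[rid] = tuple(int(v) for v in typ)

    # 2) facility sites on distinct road nodes, centre-weighted by default
    nodes = _lattice_nodes(params)
    centre = np.array([params.grid_extent / 2.0, params.grid_extent / 2.0])
    if params.centre_weighted_facilities:
        dist = np.linalg.norm(nodes - centre, axis=1)
        p = np.exp(-dist / (params.facility_scale * params.grid_extent))
        p /= p.sum()
    else:
        p = np.full(len(nodes), 1.0 / len(nodes))
    site_idx = rng.choice(len(nodes), size=params.n_facilities, replace=False, p=p)
    lo, hi = params.bed_range
    beds = np.round(lo * (hi / lo) ** rng.random(params.n_facilities)).astype(int)
    facilities = [
        Facility(id=f"H{k:02d}", location=(float(nodes[i][0]), float(nodes[i][1])), beds=int(b))
        for k, (i, b) in enumerate(zip(site_idx, beds))
    ]

    # 3) road grid on the corner lattice, class per edge from the shares
    rows, cols = params.grid_shape
    edges: list[tuple[tuple[float, float], tuple[float, float]]] = []
    for r in range(rows + 1):
        for c in range(cols + 1):
            a = (c * cw, r * ch)
            if c < cols:
                edges.append((a, ((c + 1) * cw, r * ch)))
            if r < rows:
                edges.append((a, (c * cw, (r + 1) * ch)))
    classes = rng.choice(len(ROAD_CLASSES), size=len(edges), p=params.road_class_shares)
    roads = [
        RoadSegment(geometry=(a, b), road_class=ROAD_CLASSES[k])
        for (a, b), k in zip(edges, classes)
    ]

    return SyntheticCity(
        params=params,
        regions=regions,
        facilities=facilities,
        roads=roads,
        region_polygons=dict(zip(ids, polys)),
        type_counts=type_counts,
    )


def generate_individual_points(
    city: SyntheticCity, params: CityParams
) -> list[tuple[float, float, str, str]]:
    """Scatter one point per counted individual inside its region.

    Points are uniform within the (rectangular) region polygon and tagged
    ``(x, y, severity_category, region_id)``. Drawn from a dedicated
    stream seeded by ``(params.seed, 1)`` so individual placement never
    perturbs the city-level draws.
    """
    rng = np.random.default_rng([params.seed, 1])
    points: list[tuple[float, float, str, str]] = []
    for region in city.regions:
        poly = city.region_polygons[region.id]
        x0, y0, x1, y1 = poly.bounds
        for cat, n in zip(SEVERITY_CATEGORIES, region.severity_counts):
            if n == 0:
                continue
            xs = rng.uniform(x0, x1, size=n)
            ys = rng.uniform(y0, y1, size=n)
            points.extend((float(x), float(y), cat, region.id) for x, y in zip(xs, ys))
    city.individuals = points
    return points
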