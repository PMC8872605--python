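"""Synthetic city generator for supply-demand analysis.

Emulates the statistical structure of the real inputs the analysis
consumes — none of which are distributable — so every downstream stage is
testable end to end:

* a rectangular TAZ (traffic-analysis-zone) grid whose cell populations
  form a spatially autocorrelated positive field (smoothed white noise),
* hospitals placed preferentially in populous cells, with beds, personnel
  and an ordinal grade drawn so the composite supply score attains a
  target correlation with local population, plus optional planted
  mismatch zones (quadrants forced under- or over-supplied),
* a lattice road network over cell centroids with per-edge lengths, from
  which shortest-path origin-destination distances are computed, and
* a yearly "yearbook" indicator panel with multiplicative growth and
  noise, whose supply layer follows a kinked growth path (slow early,
  fast after a boost year) so that the normalized supply index crosses
  above the demand index late in the series.

Everything is driven by explicit integer seeds: a fixed seed regenerates
every artifact bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from medcarry.accessibility import ODMatrix
from medcarry.weighting import composite_score, entropy_weights, min_max_normalize

__all__ = [
    "SyntheticCityConfig",
    "YearbookConfig",
    "generate_city",
    "generate_od_matrix",
    "generate_yearbook",
    "hospital_supply_scores",
    "WORKLOAD_COLUMNS",
]

#: the five workload indicators recorded per hospital (counts per year)
WORKLOAD_COLUMNS = (
    "total_visits",
    "outpatient_visits",
    "emergency_visits",
    "inpatient_visits",
    "discharges",
)

#: overall workload magnitude of each planted demand level (1 = heaviest)
_LEVEL_MAGNITUDE = {1: 8.0, 2: 6.0, 3: 4.0, 4: 2.0}

#: case-mix profile per level, one factor per workload indicator: regional
#: hubs are inpatient-heavy, general hospitals outpatient-heavy, district
#: hospitals emergency-heavy, community hospitals ambulatory — tiers differ
#: in mix as well as volume, as real hospital strata do
_LEVEL_MIX = {
    1: (1.0, 0.55, 0.45, 1.9, 1.9),
    2: (1.0, 1.7, 0.55, 0.65, 0.65),
    3: (1.0, 0.65, 2.4, 0.9, 0.9),
    4: (1.0, 1.35, 1.0, 0.35, 0.35),
}

#: yearly per-unit scale of each workload indicator
_WORKLOAD_SCALE = {
    "total_visits": 60_000.0,
    "outpatient_visits": 48_000.0,
    "emergency_visits": 3_500.0,
    "inpatient_visits": 2_200.0,
    "discharges": 2_100.0,
}


@dataclass
class SyntheticCityConfig:
    """Parameters of the synthetic city.

    ``supply_demand_corr`` is the target Pearson correlation between a
    hospital's composite supply score and the population of its cell;
    generation resamples the latent supply noise until the empirical
    correlation lands within +/-0.1 of the target (before mismatch zones
    are applied, which deliberately break the relation locally).

    ``mismatch_zones`` is a list of ``(region, direction)`` pairs where
    region is a quadrant code in {"NW", "NE", "SW", "SE"} and direction is
    "under" or "over"; hospitals in the region get their resource
    attributes scaled down (x0.2, grade demoted) or up (x3, grade 3).
    """

    grid_nx: int = 20
    grid_ny: int = 20
    cell_size: float = 1000.0
    n_hospitals: int = 67
    pop_range: tuple[float, float] = (2_000.0, 60_000.0)
    supply_demand_corr: float = 0.7
    mismatch_zones: list[tuple[str, str]] = field(default_factory=list)
    smoothing_sigma: float = 1.5
    placement_exponent: float = 2.0
    resample_budget: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx * self.grid_ny < self.n_hospitals:
            raise ValueError("fewer grid cells than hospitals")
        if self.n_hospitals < 2:
            raise ValueError("need at least 2 hospitals")
        if self.pop_range[0] <= 0 or self.pop_range[1] <= self.pop_range[0]:
            raise ValueError("pop_range must be positive and increasing")
        if not -1.0 <= self.supply_demand_corr <= 1.0:
            raise ValueError("supply_demand_corr must lie in [-1, 1]")
        for region, direction in self.mismatch_zones:
            if region not in ("NW", "NE", "SW", "SE"):
                raise ValueError(f"unknown region {region!r}")
            if direction not in ("under", "over"):
                raise ValueError(f"unknown direction {direction!r}")


def _quadrant(x: np.ndarray, y: np.ndarray, width: float, height: float) -> np.ndarray:
    """Quadrant code per point; north = upper half (larger y)."""
    ns = np.where(y >= height / 2.0, "N", "S")
    ew = np.where(x < width / 2.0, "W", "E")
    return np.char.add(ns, ew).astype(object)


def generate_city(
    config: SyntheticCityConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, nx.Graph]:
    """Generate demand points, hospitals and the lattice road network.

    Returns
    -------
    demand_points
        One row per TAZ cell: id, row, col, x, y (centroid), population,
        quadrant.
    hospitals
        One row per hospital: id, row, col, x, y, beds, personnel, grade
        (ordinal 1-3, 3 = highest), the five workload indicators,
        demand_level_true (the planted workload tier), quadrant.
    road_network
        networkx Graph on (row, col) nodes with "pos" attributes and
        per-edge "length" = cell_size (4-neighbor lattice).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nx_, ny_ = cfg.grid_nx, cfg.grid_ny
    width, height = nx_ * cfg.cell_size, ny_ * cfg.cell_size

    # spatially autocorrelated positive population: smoothed white noise,
    # min-max mapped onto pop_range
    noise = rng.standard_normal((ny_, nx_))
    smooth = gaussian_filter(noise, sigma=cfg.smoothing_sigma, mode="nearest")
    lo, hi = cfg.pop_range
    span = smooth.max() - smooth.min()
    pop = lo + (smooth - smooth.min()) / span * (hi - lo)

    rows, cols = np.mgrid[0:ny_, 0:nx_]
    rows, cols = rows.ravel(), cols.ravel()
    cx = (cols + 0.5) * cfg.cell_size
    cy = (rows + 0.5) * cfg.cell_size
    population = pop.ravel()
    demand = pd.DataFrame(
        {
            "id": [f"taz_{r}_{c}" for r, c in zip(rows, cols)],
            "row": rows,
            "col": cols,
            "x": cx,
            "y": cy,
            "population": population,
            "quadrant": _quadrant(cx, cy, width, height),
        }
    )

    # hospitals preferentially in populous cells
    probs = population**cfg.placement_exponent
    probs = probs / probs.sum()
    cells = rng.choice(len(demand), size=cfg.n_hospitals, replace=False, p=probs)
    hosp_pop = population[cells]
    z_pop = (hosp_pop - hosp_pop.mean()) / hosp_pop.std()

    # latent supply correlated with local population; resample the noise
    # until the realized composite-score correlation is within tolerance
    rho = cfg.supply_demand_corr
    latent = None
    for _ in range(cfg.resample_budget):
        eps = rng.standard_normal(cfg.n_hospitals)
        cand = rho * z_pop + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        beds, personnel, grade = _attributes_from_latent(cand, rng)
        score = hospital_supply_scores(
            pd.DataFrame({"beds": beds, "personnel": personnel, "grade": grade})
        )
        r = np.corrcoef(hosp_pop, score)[0, 1]
        if abs(r - rho) <= 0.1:
            latent = cand
            break
    if latent is None:
        raise RuntimeError(
            f"could not reach supply-demand correlation {rho} +/- 0.1 "
            f"within {cfg.resample_budget} resamples"
        )

    hx, hy = cx[cells], cy[cells]
    hospitals = pd.DataFrame(
        {
            "id": [f"hosp_{i:03d}" for i in range(cfg.n_hospitals)],
            "row": rows[cells],
            "col": cols[cells],
            "x": hx,
            "y": hy,
            "beds": beds,
            "personnel": personnel,
            "grade": grade,
            "quadrant": _quadrant(hx, hy, width, height),
        }
    )

    # planted mismatch zones override local supply
    for region, direction in cfg.mismatch_zones:
        mask = hospitals["quadrant"] == region
        if direction == "under":
            hospitals.loc[mask, "beds"] = np.maximum(
                20, (hospitals.loc[mask, "beds"] * 0.2).round()
            ).astype(int)
            hospitals.loc[mask, "personnel"] = np.maximum(
                10, (hospitals.loc[mask, "personnel"] * 0.2).round()
            ).astype(int)
            hospitals.loc[mask, "grade"] = np.maximum(
                1, hospitals.loc[mask, "grade"] - 1
            )
        else:
            hospitals.loc[mask, "beds"] = (
                hospitals.loc[mask, "beds"] * 3
            ).astype(int)
            hospitals.loc[mask, "personnel"] = (
                hospitals.loc[mask, "personnel"] * 3
            ).astype(int)
            hospitals.loc[mask, "grade"] = 3

    # workload: planted 4-tier structure, volume magnitude x case-mix
    # profile x per-hospital size factor, multiplicative noise per cell
    tiers = rng.choice([1, 2, 3, 4], size=cfg.n_hospitals, p=[0.15, 0.40, 0.20, 0.25])
    size_factor = np.exp(rng.normal(0.0, 0.08, cfg.n_hospitals))
    magnitude = np.array([_LEVEL_MAGNITUDE[t] for t in tiers]) * size_factor
    for i, name in enumerate(WORKLOAD_COLUMNS):
        mix = np.array([_LEVEL_MIX[t][i] for t in tiers])
        values = (
            _WORKLOAD_SCALE[name]
            * magnitude
            * mix
            * (1.0 + rng.normal(0.0, 0.08, cfg.n_hospitals))
        )
        hospitals[name] = np.maximum(values, 1.0).round().astype(int)
    hospitals["demand_level_true"] = tiers

    road = _lattice_network(nx_, ny_, cfg.cell_size)
    return demand, hospitals, road


def _attributes_from_latent(
    latent: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a latent supply score to hospital resource attributes.

    Beds and personnel are affine in the latent score (so min-max
    normalization preserves the correlation structure) with mild
    independent noise; the ordinal grade follows latent terciles
    (bottom 30% -> 1, middle 40% -> 2, top 30% -> 3, 3 = highest).
    """
    n = latent.size
    u = (latent - latent.min()) / (latent.max() - latent.min())
    beds = np.round(50 + u * 1450 + rng.normal(0, 30, n)).clip(min=20).astype(int)
    personnel = np.round(60 + u * 1940 + rng.normal(0, 40, n)).clip(min=10).astype(int)
    q30, q70 = np.quantile(latent, [0.3, 0.7])
    grade = np.where(latent >= q70, 3, np.where(latent >= q30, 2, 1))
    return beds, personnel, grade.astype(int)


def hospital_supply_scores(hospitals: pd.DataFrame) -> pd.Series:
    """Composite supply score S_j per hospital.

    Entropy-weighted composite of beds, personnel and ordinal grade over
    the hospital panel; in [0, 1], larger = better-resourced.
    """
    panel = hospitals[["beds", "personnel", "grade"]].astype(float)
    norm = min_max_normalize(panel)
    weights = entropy_weights(norm)
    scores = composite_score(norm, weights)
    scores.name = "supply_score"
    return scores


def _lattice_network(nx_: int, ny_: int, cell_size: float) -> nx.Graph:
    g = nx.Graph()
    for r in range(ny_):
        for c in range(nx_):
            g.add_node((r, c), pos=((c + 0.5) * cell_size, (r + 0.5) * cell_size))
    for r in range(ny_):
        for c in range(nx_):
            if c + 1 < nx_:
                g.add_edge((r, c), (r, c + 1), length=cell_size)
            if r + 1 < ny_:
                g.add_edge((r, c), (r + 1, c), length=cell_size)
    return g


def _snap(points: pd.DataFrame, network: nx.Graph) -> list:
    """Nearest network node per point (Euclidean on node positions)."""
    from scipy.spatial import cKDTree

    nodes = list(network.nodes)
    pos = np.array([network.nodes[n]["pos"] for n in nodes])
    xy = points[["x", "y"]].to_numpy(dtype=float)
    _, idx = cKDTree(pos).query(xy)
    return [nodes[i] for i in np.atleast_1d(idx)]


def generate_od_matrix(
    demand_points: pd.DataFrame,
    hospitals: pd.DataFrame,
    road_network: nx.Graph,
) -> ODMatrix:
    """Shortest-path network distances, every demand point x hospital.

    Both point sets are snapped to their nearest network node; distances
    are shortest paths along edge "length" weights.  A point whose snapped
    node cannot reach the others raises an error naming the orphans.
    """
    d_nodes = _snap(demand_points, road_network)
    h_nodes = _snap(hospitals, road_network)

    components = list(nx.connected_components(road_network))
    if len(components) > 1:
        comp_of = {}
        for ci, comp in enumerate(components):
            for node in comp:
                comp_of[node] = ci
        used = [comp_of[n] for n in d_nodes + h_nodes]
        main = max(set(used), key=used.count)
        orphans = [
            pid
            for pid, n in zip(
                list(demand_points["id"]) + list(hospitals["id"]),
                d_nodes + h_nodes,
            )
            if comp_of[n] != main
        ]
        if orphans:
            raise ValueError(
                f"road network is disconnected; orphan points: {orphans}"
            )

    values = np.empty((len(demand_points), len(hospitals)))
    node_index = {n: i for i, n in enumerate(dict.fromkeys(d_nodes))}
    unique_d = list(node_index)
    for j, hn in enumerate(h_nodes):
        lengths = nx.single_source_dijkstra_path_length(
            road_network, hn, weight="length"
        )
        col = np.array([lengths[n] for n in unique_d])
        values[:, j] = col[[node_index[n] for n in d_nodes]]
    return ODMatrix(
        demand_ids=list(demand_points["id"]),
        supply_ids=list(hospitals["id"]),
        values=values,
    )


# --- yearbook panel ---------------------------------------------------------

#: default indicator system: (name, layer, initial value, growth spec);
#: growth "kinked" = supply path with a post-boost-year acceleration
_DEFAULT_INDICATORS: tuple[tuple[str, str, float, object], ...] = (
    ("health_institutions", "supply", 200.0, "kinked"),
    ("total_hospitals", "supply", 20.0, "kinked"),
    ("beds", "supply", 4_000.0, "kinked"),
    ("licensed_doctors", "supply", 3_000.0, "kinked"),
    ("registered_nurses", "supply", 2_500.0, "kinked"),
    ("pharmacists", "supply", 600.0, "kinked"),
    ("lab_technicians", "supply", 500.0, "kinked"),
    ("gdp", "supply", 400_000.0, "kinked"),
    ("total_patients_treated", "demand", 800.0, 0.100),
    ("total_inpatients", "demand", 30.0, 0.110),
    ("bed_utilization_rate", "demand", 80.0, 0.004),
    ("bed_turnover", "demand", 25.0, 0.010),
    ("permanent_population", "demand", 100.0, 0.065),
    ("beds_per_1000", "demand", 2.26, 0.016),
    ("physicians_per_1000", "demand", 2.37, 0.007),
    ("nurses_per_1000", "demand", 2.00, 0.020),
    ("per_capita_disposable_income", "demand", 0.20, 0.110),
)


@dataclass
class YearbookConfig:
    """Parameters of the synthetic yearly indicator panel.

    Each indicator follows ``value_t = value_0 * growth(t) * (1 + eps)``
    with ``eps ~ N(0, noise_sd)`` and a floor at 10% of the trend value so
    every draw stays positive.  Supply-layer indicators use a kinked
    growth path — rate ``supply_growth_pre`` up to ``boost_year`` and
    ``supply_growth_post`` after — which, under per-column min-max
    normalization, keeps the supply composite below the demand composite
    early in the series and above it late.
    """

    year_start: int = 1986
    year_end: int = 2019
    noise_sd: float = 0.03
    supply_growth_pre: float = 0.05
    supply_growth_post: float = 0.12
    boost_year: int = 2005
    growth_rates: dict[str, float] = field(default_factory=dict)
    indicators: tuple = _DEFAULT_INDICATORS

    def __post_init__(self) -> None:
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def layer_map(self) -> dict[str, str]:
        return {name: layer for name, layer, _, _ in self.indicators}


def generate_yearbook(config: YearbookConfig, seed: int = 0) -> pd.DataFrame:
    """Year x indicator panel of positive, trending values."""
    cfg = config
    rng = np.random.default_rng(seed)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    t = years - cfg.year_start
    panel = {}
    for name, layer, v0, growth in cfg.indicators:
        if name in cfg.growth_rates:
            trend = v0 * (1.0 + cfg.growth_rates[name]) ** t
        elif growth == "kinked":
            pre = np.minimum(t, cfg.boost_year - cfg.year_start)
            post = np.maximum(t - (cfg.boost_year - cfg.year_start), 0)
            trend = (
                v0
                * (1.0 + cfg.supply_growth_pre) ** pre
                * (1.0 + cfg.supply_growth_post) ** post
            )
        else:
            trend = v0 * (1.0 + float(growth)) ** t
        noisy = trend * (1.0 + rng.normal(0.0, cfg.noise_sd, len(t)))
        panel[name] = np.maximum(noisy, 0.1 * trend)
    return pd.DataFrame(panel, index=pd.Index(years, name="year"))
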