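"""Synthetic city generator: determinism, structure, OD distances, yearbook."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from medcarry import (
    SyntheticCityConfig,
    YearbookConfig,
    generate_city,
    generate_od_matrix,
    generate_yearbook,
)
from medcarry.synth_city import WORKLOAD_COLUMNS, hospital_supply_scores


class TestGenerateCity:
    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticCityConfig(grid_nx=8, grid_ny=8, n_hospitals=10, seed=1)
        d1, h1, _ = generate_city(cfg)
        d2, h2, _ = generate_city(cfg)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_population_positive_and_in_range(self, small_city):
        cfg, demand, hospitals, _, _ = small_city
        pop = demand["population"]
        assert (pop > 0).all()
        assert pop.min() >= cfg.pop_range[0] - 1e-9
        assert pop.max() <= cfg.pop_range[1] + 1e-9
        assert set(hospitals["grade"]) <= {1, 2, 3}
        assert (hospitals["beds"] >= 20).all()
        assert (hospitals[list(WORKLOAD_COLUMNS)] >= 1).all().all()

    def test_population_spatially_autocorrelated(self, small_city):
        """Neighboring cells have more similar population than random pairs."""
        _, demand, _, _, _ = small_city
        grid = demand.pivot(index="row", columns="col", values="population").to_numpy()
        horiz = np.abs(np.diff(grid, axis=1)).mean()
        rng = np.random.default_rng(0)
        flat = grid.ravel()
        random_pairs = np.abs(
            flat[rng.integers(0, flat.size, 2000)]
            - flat[rng.integers(0, flat.size, 2000)]
        ).mean()
        assert horiz < random_pairs

    def test_supply_demand_correlation_target(self):
        cfg = SyntheticCityConfig(
            grid_nx=20, grid_ny=20, n_hospitals=67, supply_demand_corr=0.9, seed=3
        )
        demand, hospitals, _ = generate_city(cfg)
        scores = hospital_supply_scores(hospitals)
        pop_at_hosp = (
            demand.set_index(["row", "col"])
            .loc[list(zip(hospitals["row"], hospitals["col"])), "population"]
            .to_numpy()
        )
        r = np.corrcoef(pop_at_hosp, scores.to_numpy())[0, 1]
        assert 0.8 <= r <= 1.0

    def test_unreachable_correlation_budget_errors(self):
        cfg = SyntheticCityConfig(
            grid_nx=8, grid_ny=8, n_hospitals=10, supply_demand_corr=0.9,
            resample_budget=0, seed=0,
        )
        with pytest.raises(RuntimeError):
            generate_city(cfg)

    def test_under_supply_zone_scales_down_resources(self):
        base = SyntheticCityConfig(grid_nx=12, grid_ny=12, n_hospitals=30, seed=4)
        planted = SyntheticCityConfig(
            grid_nx=12, grid_ny=12, n_hospitals=30, seed=4,
            mismatch_zones=[("NW", "under")],
        )
        _, h0, _ = generate_city(base)
        _, h1, _ = generate_city(planted)
        nw = h1["quadrant"] == "NW"
        assert nw.any()
        assert (h1.loc[nw, "beds"].to_numpy() < h0.loc[nw.to_numpy(), "beds"].to_numpy()).all()
        other = ~nw
        np.testing.assert_array_equal(
            h1.loc[other, "beds"].to_numpy(), h0.loc[other.to_numpy(), "beds"].to_numpy()
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCityConfig(grid_nx=2, grid_ny=2, n_hospitals=10)
        with pytest.raises(ValueError):
            SyntheticCityConfig(pop_range=(0.0, 10.0))
        with pytest.raises(ValueError):
            SyntheticCityConfig(mismatch_zones=[("XX", "under")])


class TestOdMatrix:
    def test_single_edge(self):
        g = nx.Graph()
        g.add_node((0, 0), pos=(0.0, 0.0))
        g.add_node((0, 1), pos=(5.0, 0.0))
        g.add_edge((0, 0), (0, 1), length=5.0)
        demand = pd.DataFrame({"id": ["d"], "x": [0.0], "y": [0.0]})
        supply = pd.DataFrame({"id": ["s"], "x": [5.0], "y": [0.0]})
        od = generate_od_matrix(demand, supply, g)
        assert od.values[0, 0] == 5.0

    def test_colocated_zero_distance(self):
        g = nx.Graph()
        g.add_node((0, 0), pos=(0.0, 0.0))
        g.add_node((0, 1), pos=(1.0, 0.0))
        g.add_edge((0, 0), (0, 1), length=1.0)
        demand = pd.DataFrame({"id": ["d"], "x": [0.0], "y": [0.0]})
        supply = pd.DataFrame({"id": ["s"], "x": [0.0], "y": [0.0]})
        od = generate_od_matrix(demand, supply, g)
        assert od.values[0, 0] == 0.0

    def test_lattice_opposite_corners(self):
        """3x3 unit lattice: opposite corners are 4 apart (brute force)."""
        from medcarry.synth_city import _lattice_network

        g = _lattice_network(3, 3, 1.0)
        # brute-force shortest path over all simple paths
        best = min(
            sum(g.edges[e]["length"] for e in zip(path, path[1:]))
            for path in nx.all_simple_paths(g, (0, 0), (2, 2), cutoff=8)
        )
        assert best == 4.0
        demand = pd.DataFrame({"id": ["d"], "x": [0.5], "y": [0.5]})
        supply = pd.DataFrame({"id": ["s"], "x": [2.5], "y": [2.5]})
        od = generate_od_matrix(demand, supply, g)
        assert od.values[0, 0] == 4.0

    def test_triangle_inequality_on_small_lattice(self):
        """d(a,c) <= d(a,b) + d(b,c) for all point triples on a 4x4 city."""
        cfg = SyntheticCityConfig(grid_nx=4, grid_ny=4, n_hospitals=5, seed=2)
        demand, hospitals, road = generate_city(cfg)
        od = generate_od_matrix(demand, hospitals, road)
        # distances between all snapped nodes via the same metric
        all_nodes = dict(
            nx.all_pairs_dijkstra_path_length(road, weight="length")
        )
        cells_d = list(zip(demand["row"], demand["col"]))
        cells_h = list(zip(hospitals["row"], hospitals["col"]))
        for i, j in itertools.product(range(4), range(len(cells_h))):
            for m in range(len(cells_h)):
                lhs = od.values[i, j]
                via = all_nodes[cells_d[i]][cells_h[m]] + all_nodes[cells_h[m]][cells_h[j]]
                assert lhs <= via + 1e-9

    def test_disconnected_network_lists_orphans(self):
        g = nx.Graph()
        g.add_node((0, 0), pos=(0.0, 0.0))
        g.add_node((5, 5), pos=(100.0, 100.0))  # isolated
        g.add_node((0, 1), pos=(1.0, 0.0))
        g.add_edge((0, 0), (0, 1), length=1.0)
        demand = pd.DataFrame({"id": ["d1", "orphan"], "x": [0.0, 100.0], "y": [0.0, 100.0]})
        supply = pd.DataFrame({"id": ["s"], "x": [1.0], "y": [0.0]})
        with pytest.raises(ValueError, match="orphan"):
            generate_od_matrix(demand, supply, g)

    def test_long_frame_roundtrip(self, small_city):
        _, _, _, _, od = small_city
        from medcarry import ODMatrix

        back = ODMatrix.from_long_frame(od.to_long_frame())
        order = [back.demand_ids.index(i) for i in od.demand_ids]
        cols = [back.supply_ids.index(j) for j in od.supply_ids]
        np.testing.assert_array_equal(back.values[np.ix_(order, cols)], od.values)


class TestYearbook:
    def test_zero_growth_zero_noise_constant(self):
        cfg = YearbookConfig(
            year_start=2000, year_end=2005, noise_sd=0.0,
            growth_rates={name: 0.0 for name, *_ in YearbookConfig().indicators},
        )
        panel = generate_yearbook(cfg, seed=0)
        assert (panel.nunique() == 1).all()

    def test_closed_form_growth(self):
        cfg = YearbookConfig(
            year_start=1986, year_end=2019, noise_sd=0.0,
            growth_rates={name: 0.05 for name, *_ in YearbookConfig().indicators},
        )
        panel = generate_yearbook(cfg, seed=0)
        ratio = panel.iloc[-1] / panel.iloc[0]
        np.testing.assert_allclose(ratio.to_numpy(), 1.05**33, rtol=1e-12)

    def test_all_values_positive(self):
        panel = generate_yearbook(YearbookConfig(noise_sd=0.5), seed=8)
        assert (panel > 0).all().all()

    def test_fixed_seed_identical(self):
        p1 = generate_yearbook(YearbookConfig(), seed=3)
        p2 = generate_yearbook(YearbookConfig(), seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_seventeen_indicators_two_layers(self):
        cfg = YearbookConfig()
        panel = generate_yearbook(cfg, seed=0)
        assert panel.shape[1] == 17
        layers = set(cfg.layer_map.values())
        assert layers == {"supply", "demand"}

    def test_invalid_years_rejected(self):
        with pytest.raises(ValueError):
            YearbookConfig(year_start=2020, year_end=2019)
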