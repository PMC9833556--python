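"""Regulatory-unit construction: gridding, the two unit designs, port
selection, and the threshold sweep, each against independent geometric or
combinatorial oracles."""

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon, box

import stockshift as ss
from stockshift import regulatory as reg
from stockshift.synthetic import GeometryError

from conftest import rect_distance


class TestBuildGrid:
    def test_aligned_square_cell_count(self):
        eez = box(0.0, 0.0, 3.0, 3.0)
        grid = ss.build_grid(eez, 0.3)
        assert len(grid.cells) == 100
        assert ss.build_grid(eez, 3.0).n_lon == 1
        assert len(ss.build_grid(eez, 3.0).cells) == 1

    def test_triangle_matches_per_center_point_in_polygon(self):
        tri = Polygon([(0, 0), (3, 0), (3, 3)])
        grid = ss.build_grid(tri, 0.3, origin=(0.0, 0.0))
        expected = set()
        for i in range(10):
            for j in range(10):
                cx, cy = 0.3 * (i + 0.5), 0.3 * (j + 0.5)
                if tri.covers(shapely.Point(cx, cy)):
                    expected.add((i, j))
        assert grid.cells == frozenset(expected)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ss.build_grid(box(0, 0, 1, 1), 0.0)
        with pytest.raises(GeometryError):
            ss.build_grid(Polygon(), 0.3)

    def test_cell_centers(self):
        grid = ss.build_grid(box(0, 0, 1, 1), 0.5)
        assert grid.cell_center(0, 0) == (0.25, 0.25)
        assert grid.cell_center(1, 1) == (0.75, 0.75)


def oracle_state_waters(geo, grid, radius):
    """Per-centre ownership by exact rectangle distances (numpy only)."""
    cells = grid.sorted_cells
    C = grid.centers(cells)
    sids = [s for s, _ in geo.state_waters]
    D = np.column_stack(
        [rect_distance(C[:, 0], C[:, 1], p.bounds) for _, p in geo.state_waters]
    )
    owners = {}
    for n, c in enumerate(cells):
        own = {sids[k] for k in range(len(sids)) if D[n, k] <= radius}
        if not own:
            own = {sids[k] for k in range(len(sids)) if D[n, k] <= D[n].min() + 1e-12}
        owners[c] = own
    return owners


class TestExpandStateWaters:
    def test_two_state_symmetry_and_equal_split(self, geo2):
        grid = ss.build_grid(geo2.eez, 0.5)
        units = ss.expand_state_waters(geo2, grid)
        # every cell owned, weights sum to 1
        assert set(units.weights) == set(grid.cells)
        for wmap in units.weights.values():
            assert sum(wmap.values()) == pytest.approx(1.0, abs=1e-12)
        # mirror symmetry about the mid-latitude: S01 at (i, j) = S02 at (i, J-1-j)
        J = grid.n_lat
        for (i, j), wmap in units.weights.items():
            mirror = units.weights[(i, J - 1 - j)]
            assert wmap.get("S01", 0.0) == pytest.approx(mirror.get("S02", 0.0))
        # shared cells split 0.5/0.5
        shared = [w for w in units.weights.values() if len(w) == 2]
        assert shared and all(
            w == {"S01": 0.5, "S02": 0.5} for w in shared
        )

    def test_matches_bruteforce_distance_oracle(self, geo11, grid11):
        radius = ss.find_covering_radius(geo11)
        units = ss.expand_state_waters(geo11, grid11)
        oracle = oracle_state_waters(geo11, grid11, radius)
        assert {c: set(w) for c, w in units.weights.items()} == oracle

    def test_covers_every_eez_cell(self, geo11, grid11):
        units = ss.expand_state_waters(geo11, grid11)
        assert set(units.weights) == set(grid11.cells)

    def test_covering_radius_is_minimal_to_tolerance(self, geo11):
        from shapely.ops import unary_union

        r = ss.find_covering_radius(geo11)
        strips = [p for _, p in geo11.state_waters]
        assert unary_union([p.buffer(r, quad_segs=16) for p in strips]).covers(geo11.eez)
        smaller = r - 2e-3
        assert not unary_union(
            [p.buffer(smaller, quad_segs=16) for p in strips]
        ).covers(geo11.eez)


def make_landings(amounts, stock="fish", year=2015):
    return pd.DataFrame(
        {
            "stock": stock,
            "port": [f"P{k:03d}" for k in range(len(amounts))],
            "year": year,
            "landings_kg": amounts,
        }
    )


def make_ports(n, state="S01"):
    return pd.DataFrame(
        {
            "port": [f"P{k:03d}" for k in range(n)],
            "state": state,
            "lon": -74.0,
            "lat": np.linspace(34.0, 45.0, n),
        }
    )


class TestSelectTopPorts:
    def test_quarter_of_76_ports_is_19(self):
        rng = np.random.default_rng(0)
        landings = make_landings(rng.lognormal(3, 1, size=76))
        sel = ss.select_top_ports(landings, make_ports(76), "fish", (2015, 2015), 0.25)
        assert len(sel) == 19

    def test_rounding_floor_one(self):
        landings = make_landings([10.0, 5.0, 1.0, 1.0])
        sel = ss.select_top_ports(landings, make_ports(4), "fish", (2015, 2015), 0.25)
        assert list(sel["port"]) == ["P000"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(42)
        amounts = rng.lognormal(2, 1, size=10)
        landings = make_landings(amounts)
        sel = ss.select_top_ports(landings, make_ports(10), "fish", (2015, 2015), 0.3)
        order = np.argsort(-amounts, kind="stable")
        expected = [f"P{k:03d}" for k in order[:3]]
        assert list(sel["port"]) == expected

    def test_zero_average_ports_excluded_from_universe(self):
        landings = make_landings([0.0, 0.0, 4.0, 3.0, 2.0, 1.0])
        sel = ss.select_top_ports(landings, make_ports(6), "fish", (2015, 2015), 0.5)
        # universe is the 4 ports with landings; half-up round(2.0) = 2
        assert list(sel["port"]) == ["P002", "P003"]

    def test_empty_universe_raises(self):
        landings = make_landings([0.0, 0.0])
        with pytest.raises(ss.EmptyPortUniverseError):
            ss.select_top_ports(landings, make_ports(2), "fish", (2015, 2015))

    def test_ties_broken_by_total_landings_then_name(self):
        landings = pd.concat(
            [
                make_landings([5.0, 5.0, 5.0], stock="fish"),
                make_landings([0.0, 9.0, 0.0], stock="other"),
            ],
            ignore_index=True,
        )
        sel = ss.select_top_ports(landings, make_ports(3), "fish", (2015, 2015), 0.34)
        assert list(sel["port"]) == ["P001"]  # wins the tie on cross-stock total

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_row_order(self, rnd):
        rng = np.random.default_rng(7)
        landings = make_landings(rng.lognormal(2, 1, size=12))
        shuffled = landings.sample(frac=1, random_state=rnd.randrange(2**31)).reset_index(
            drop=True
        )
        a = ss.select_top_ports(landings, make_ports(12), "fish", (2015, 2015), 0.3)
        b = ss.select_top_ports(shuffled, make_ports(12), "fish", (2015, 2015), 0.3)
        assert list(a["port"]) == list(b["port"])


class TestExpandFishingPorts:
    def test_single_port_huge_radius_owns_everything(self, geo2):
        grid = ss.build_grid(geo2.eez, 0.5)
        ports = pd.DataFrame(
            {"port": ["A"], "state": ["S01"], "lon": [-72.5], "lat": [40.0]}
        )
        units = ss.expand_fishing_ports(ports, grid, geo2.eez, radius=50.0)
        assert set(units.weights) == set(grid.cells)
        assert all(w == {"S01": 1.0} for w in units.weights.values())

    def test_coincident_ports_of_two_states_split_half_half(self, geo2):
        grid = ss.build_grid(geo2.eez, 0.5)
        ports = pd.DataFrame(
            {
                "port": ["A", "B"],
                "state": ["S01", "S02"],
                "lon": [-72.5, -72.5],
                "lat": [40.0, 40.0],
            }
        )
        units = ss.expand_fishing_ports(ports, grid, geo2.eez, radius=1.2)
        assert len(units.weights) > 0
        assert all(w == {"S01": 0.5, "S02": 0.5} for w in units.weights.values())

    def test_matches_bruteforce_distance_oracle(self, geo11, grid11):
        rng = np.random.default_rng(3)
        n = 8
        minx, miny, maxx, maxy = geo11.eez.bounds
        ports = pd.DataFrame(
            {
                "port": [f"P{k}" for k in range(n)],
                "state": rng.choice(geo11.state_ids, size=n),
                "lon": rng.uniform(minx, maxx, size=n),
                "lat": rng.uniform(miny, maxy, size=n),
            }
        )
        radius = 0.8
        units = ss.expand_fishing_ports(
            ports, grid11, geo11.eez, radius, state_waters=geo11
        )
        strips = dict(geo11.state_waters)
        for c in grid11.sorted_cells:
            cx, cy = grid11.cell_center(*c)
            owners = set()
            for _, p in ports.iterrows():
                if np.hypot(cx - p["lon"], cy - p["lat"]) <= radius:
                    owners.add(p["state"])
            for sid, strip in strips.items():
                minx, miny, maxx, maxy = strip.bounds
                if minx <= cx <= maxx and miny <= cy <= maxy:
                    owners.add(sid)
            got = set(units.weights.get(c, {}))
            assert got == owners, f"cell {c}: {got} != {owners}"

    def test_portless_state_keeps_only_state_waters(self, geo2):
        grid = ss.build_grid(geo2.eez, 0.02)  # fine enough to resolve the strip
        ports = pd.DataFrame(
            {"port": ["A"], "state": ["S02"], "lon": [-72.5], "lat": [43.0]}
        )
        units = ss.expand_fishing_ports(ports, grid, geo2.eez, 1.0, state_waters=geo2)
        s01 = units.owned_cells("S01")
        strip = geo2.state_polygon("S01")
        assert s01  # the strip is resolved
        for c in s01:
            assert strip.covers(shapely.Point(*grid.cell_center(*c)))

    def test_radius_monotonicity_of_port_derived_cells(self, geo11, grid11):
        rng = np.random.default_rng(5)
        minx, miny, maxx, maxy = geo11.eez.bounds
        ports = pd.DataFrame(
            {
                "port": [f"P{k}" for k in range(6)],
                "state": rng.choice(geo11.state_ids, size=6),
                "lon": rng.uniform(minx, maxx, size=6),
                "lat": rng.uniform(miny, maxy, size=6),
            }
        )
        prev = None
        for radius in (0.3, 0.6, 1.2, 2.4):
            units = ss.expand_fishing_ports(ports, grid11, geo11.eez, radius)
            owned = {sid: units.owned_cells(sid) for sid in set(ports["state"])}
            if prev is not None:
                for sid, cells in prev.items():
                    assert cells <= owned[sid]
            prev = owned

    def test_rejects_bad_arguments(self, geo2):
        grid = ss.build_grid(geo2.eez, 0.5)
        ports = pd.DataFrame(
            {"port": ["A"], "state": ["S01"], "lon": [-72.5], "lat": [40.0]}
        )
        with pytest.raises(ValueError):
            ss.expand_fishing_ports(ports, grid, geo2.eez, radius=0.0)
        with pytest.raises(ValueError):
            ss.expand_fishing_ports(ports.iloc[:0], grid, geo2.eez, radius=1.0)


@pytest.fixture(scope="module")
def sweep(geo11, grid11):
    scen = ss.default_scenario(seed=2)
    ports, landings = ss.simulate_ports_landings(
        geo11, scen, ports_per_state=3, landings_years=(2010, 2019), seed=8
    )
    thresholds = [0.1, 0.25, 0.5, 0.75, 1.0]
    tab = ss.threshold_sensitivity(
        landings, ports, grid11, geo11.eez, 0.75, thresholds,
        scen.stock_id, (2010, 2019), state_waters=geo11,
    )
    return thresholds, tab


class TestThresholdSensitivity:
    def test_cell_counts_non_decreasing_in_threshold(self, sweep):
        thresholds, tab = sweep
        for _, g in tab.groupby("state"):
            counts = g.set_index("threshold")["n_cells"].loc[thresholds]
            assert (counts.diff().dropna() >= 0).all()

    def test_full_threshold_is_maximal(self, sweep):
        thresholds, tab = sweep
        full = tab[tab["threshold"] == 1.0].set_index("state")["n_cells"]
        for th in thresholds:
            part = tab[tab["threshold"] == th].set_index("state")["n_cells"]
            assert (part <= full.loc[part.index]).all()


class TestWeightInvariants:
    def test_owned_cell_weights_sum_to_one(self, geo11, grid11):
        sw = ss.expand_state_waters(geo11, grid11)
        scen = ss.default_scenario(seed=2)
        ports, landings = ss.simulate_ports_landings(
            geo11, scen, ports_per_state=3, landings_years=(2010, 2019), seed=8
        )
        sel = ss.select_top_ports(landings, ports, scen.stock_id, (2010, 2019))
        fp = ss.expand_fishing_ports(sel, grid11, geo11.eez, 0.75, state_waters=geo11)
        for units in (sw, fp):
            for wmap in units.weights.values():
                assert abs(sum(wmap.values()) - 1.0) < 1e-12
                k = len(wmap)
                assert all(w == pytest.approx(1.0 / k, abs=1e-15) for w in wmap.values())


def test_units_frame_roundtrip(geo2):
    grid = ss.build_grid(geo2.eez, 0.5)
    units = ss.expand_state_waters(geo2, grid)
    frame = ss.units_to_frame(units)
    assert list(frame.columns) == ["method", "cell_i", "cell_j", "state", "weight"]
    back = ss.frame_to_units(frame)
    assert back.method == units.method
    assert back.weights == units.weights
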