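import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridrisk import assign_cells, build_neighborhoods, build_weights
from gridrisk.geo_grid import cell_polygon

from conftest import make_grid_cells


def make_households(xy, **overrides):
    n = len(xy)
    base = {
        "household_id": np.arange(n),
        "x": [p[0] for p in xy],
        "y": [p[1] for p in xy],
        "head_sex": ["male"] * n,
        "head_schooling_years": [6] * n,
        "water_source": ["tap"] * n,
        "dist_river_km": [1.0] * n,
        "dist_health_km": [2.0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def make_persons(household_ids, sexes=None, died=None):
    n = len(household_ids)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "household_id": household_ids,
            "sex": sexes if sexes is not None else ["male"] * n,
            "age_years": [30] * n,
            "person_years": [2.0] * n,
            "died": died if died is not None else [False] * n,
            "cause": [None] * n,
        }
    )


class TestAssignCells:
    def test_origin_and_half_open_boundaries(self):
        hh = make_households([(1000.0, 1000.0), (1000.0 + 499.9, 1000.0 + 500.0)])
        out = assign_cells(hh, 500.0)
        assert tuple(out.loc[0, ["cell_row", "cell_col"]]) == (0, 0)
        # a point exactly on the upper edge belongs to the next (higher) cell
        assert tuple(out.loc[1, ["cell_row", "cell_col"]]) == (1, 0)

    def test_rejects_geographic_looking_coordinates(self):
        hh = make_households([(105.8, 21.0), (106.1, 20.5)])
        with pytest.raises(ValueError, match="projected"):
            assign_cells(hh, 500.0)

    def test_scattered_points_stay_in_grid_and_partition(self):
        rng = np.random.default_rng(42)
        pts = np.column_stack(
            [rng.uniform(10_000, 15_000, 1000), rng.uniform(10_000, 15_000, 1000)]
        )
        out = assign_cells(make_households(list(map(tuple, pts))), 500.0)
        # brute-force bound: 5 km box at 500 m cells -> indices 0..9
        assert out["cell_row"].between(0, 9).all()
        assert out["cell_col"].between(0, 9).all()
        # partition: every household in exactly one cell
        assert len(out) == 1000
        assert out.groupby(["cell_row", "cell_col"]).size().sum() == 1000

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cell=st.floats(50.0, 2000.0),
        dx=st.floats(0.0, 9999.0),
        dy=st.floats(0.0, 9999.0),
    )
    def test_point_lies_inside_its_half_open_cell(self, cell, dx, dy):
        hh = make_households([(10_000.0, 10_000.0), (10_000.0 + dx, 10_000.0 + dy)])
        out = assign_cells(hh, cell)
        row, col = out.loc[1, "cell_row"], out.loc[1, "cell_col"]
        rel_y = (10_000.0 + dy) - 10_000.0
        rel_x = (10_000.0 + dx) - 10_000.0
        assert cell * row <= rel_y and rel_y / cell < row + 1
        assert cell * col <= rel_x and rel_x / cell < col + 1

    def test_invalid_cell_size(self):
        with pytest.raises(ValueError):
            assign_cells(make_households([(1000.0, 1000.0)]), 0.0)


class TestBuildNeighborhoods:
    def _two_cells(self):
        # cell (0,0): 3 households; cell (0,1): 5 households
        xy = [(1000.0 + 50 * i, 1000.0) for i in range(3)]
        xy += [(1600.0 + 10 * i, 1000.0) for i in range(5)]
        hh = make_households(
            xy,
            head_sex=["male", "male", "female"] + ["male", "female"] * 2 + ["male"],
            head_schooling_years=[6, 6, 6, 0, 3, 5, 7, 12],
        )
        return assign_cells(hh, 500.0)

    def test_min_household_exclusion_and_schooling_percent(self):
        hh = self._two_cells()
        persons = make_persons(list(range(8)))
        nbhd = build_neighborhoods(hh, persons, "male", min_households=4)
        nbhd = nbhd.set_index(["cell_row", "cell_col"])
        assert not nbhd.loc[(0, 0), "included"]  # 3 households < 4
        assert nbhd.loc[(0, 1), "included"]
        # schooling years (0, 3, 5, 7, 12): 3 of 5 heads at >= 5 years
        assert nbhd.loc[(0, 1), "pct_head_schooled"] == pytest.approx(60.0)

    def test_male_head_percent(self):
        xy = [(1000.0 + 20 * i, 1000.0) for i in range(4)]
        hh = assign_cells(
            make_households(xy, head_sex=["male", "male", "female", "female"]), 500.0
        )
        persons = make_persons([0, 1, 2, 3])
        nbhd = build_neighborhoods(hh, persons, "male")
        assert nbhd["pct_male_head"].iloc[0] == pytest.approx(50.0)

    def test_covariates_pooled_but_outcomes_stratified(self):
        hh = self._two_cells()
        persons = make_persons(
            [3, 4, 5, 6, 7, 3, 4],
            sexes=["male"] * 3 + ["female"] * 4,
            died=[True, False, False, True, False, False, False],
        )
        male = build_neighborhoods(hh, persons, "male", min_households=4)
        female = build_neighborhoods(hh, persons, "female", min_households=4)
        m = male.set_index(["cell_row", "cell_col"]).loc[(0, 1)]
        f = female.set_index(["cell_row", "cell_col"]).loc[(0, 1)]
        # identical covariates (all households), different outcomes (stratum)
        assert m["pct_head_schooled"] == f["pct_head_schooled"]
        assert m["pct_male_head"] == f["pct_male_head"]
        assert (m["population"], m["deaths"]) == (3, 1)
        assert (f["population"], f["deaths"]) == (4, 1)

    def test_population_conserved_across_aggregation(self):
        hh = self._two_cells()
        persons = make_persons([0, 1, 2, 3, 4, 5, 6, 7], sexes=["male"] * 8)
        nbhd = build_neighborhoods(hh, persons, "male", min_households=1)
        assert nbhd["population"].sum() == 8
        assert nbhd["person_years"].sum() == pytest.approx(16.0)

    def test_exclusion_threshold_does_not_change_covariates(self):
        hh = self._two_cells()
        persons = make_persons(list(range(8)))
        strict = build_neighborhoods(hh, persons, "male", min_households=4)
        loose = build_neighborhoods(hh, persons, "male", min_households=1)
        cols = ["pct_male_head", "pct_head_schooled", "mean_dist_river_km"]
        pd.testing.assert_frame_equal(strict[cols], loose[cols])

    def test_errors(self):
        hh = self._two_cells()
        with pytest.raises(ValueError, match="empty"):
            build_neighborhoods(hh, make_persons([]), "male")
        with pytest.raises(ValueError, match="unknown household"):
            build_neighborhoods(hh, make_persons([99]), "male")
        with pytest.raises(ValueError):
            build_neighborhoods(hh, make_persons([0]), "unknown_sex")


class TestBuildWeights:
    def test_queen_neighbor_counts_on_full_grids(self):
        w3 = build_weights(make_grid_cells((3, 3)), order=1)
        idx = {cid: i for i, cid in enumerate(w3.cell_ids)}
        assert len(w3.neighbors[idx[(1, 1)]]) == 8  # interior
        assert len(w3.neighbors[idx[(0, 0)]]) == 3  # corner
        # order 2 on 5x5: full Chebyshev ball minus self
        w5 = build_weights(make_grid_cells((5, 5)), order=2)
        idx5 = {cid: i for i, cid in enumerate(w5.cell_ids)}
        assert len(w5.neighbors[idx5[(2, 2)]]) == 24

    def test_order_k_matches_brute_force_chebyshev(self):
        cells = make_grid_cells((6, 7))
        for order in (1, 2, 3):
            w = build_weights(cells, order=order)
            for i, (r, c) in enumerate(w.cell_ids):
                expect = {
                    (rr, cc)
                    for rr in range(6)
                    for cc in range(7)
                    if (rr, cc) != (r, c) and max(abs(rr - r), abs(cc - c)) <= order
                }
                got = {w.cell_ids[j] for j in w.neighbors[i]}
                assert got == expect

    def test_rook_contiguity(self):
        w = build_weights(make_grid_cells((3, 3)), order=1, contiguity="rook")
        idx = {cid: i for i, cid in enumerate(w.cell_ids)}
        assert len(w.neighbors[idx[(1, 1)]]) == 4
        assert len(w.neighbors[idx[(0, 0)]]) == 2

    def test_symmetry_and_row_normalization(self):
        rng = np.random.default_rng(7)
        included = {
            (r, c): bool(rng.random() < 0.7) for r in range(8) for c in range(8)
        }
        included[(0, 0)] = True
        cells = make_grid_cells((8, 8), included=included)
        w = build_weights(cells, order=1, scheme="binary")
        for i, nb in enumerate(w.neighbors):
            for j in nb:
                assert i in w.neighbors[j]
            assert i not in nb  # no self-neighbors
        wr = build_weights(cells, order=1, scheme="row_normalized")
        for i, nb in enumerate(wr.neighbors):
            if len(nb):
                assert abs(wr.weight_row(i).sum() - 1.0) < 1e-12

    def test_isolated_cell_retained_and_flagged(self):
        included = {(r, c): False for r in range(5) for c in range(5)}
        included[(0, 0)] = True
        included[(4, 4)] = True
        w = build_weights(make_grid_cells((5, 5), included=included), order=1)
        assert w.n == 2
        assert w.isolated.all()

    def test_invalid_arguments(self):
        cells = make_grid_cells((3, 3))
        with pytest.raises(ValueError):
            build_weights(cells, order=0)
        with pytest.raises(ValueError):
            build_weights(cells, scheme="bad")


def test_cell_polygon_is_closed_square():
    ring = cell_polygon((2, 3), 500.0, (1000.0, 2000.0))
    assert ring[0] == ring[-1]
    assert ring[0] == [1000.0 + 3 * 500.0, 2000.0 + 2 * 500.0]
    xs = {p[0] for p in ring}
    ys = {p[1] for p in ring}
    assert max(xs) - min(xs) == 500.0 and max(ys) - min(ys) == 500.0
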