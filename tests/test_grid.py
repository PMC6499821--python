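"""Grid construction, polygon overlay, land fraction and subsampling."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from langdiv.grid import (
    GridError,
    GridSpec,
    LanguageRecord,
    land_fraction,
    make_grid,
    overlay,
    read_cells_csv,
    read_language_geojson,
    subsample,
    subsample_regimes,
    write_cells_csv,
    write_language_geojson,
)


def planar_spec(n=6, cell=1.0):
    return GridSpec(mode="planar", cell_size_km=cell, extent=(0, 0, n * cell, n * cell))


def rec(lid, geom, fam=None, speakers=100, path=None):
    return LanguageRecord(
        language_id=lid,
        classification_path=path or (fam or lid,),
        range_polygon=geom,
        speaker_count=speakers,
        crs="planar",
    )


class TestMakeGrid:
    def test_planar_toy_centroids(self):
        cells = make_grid(planar_spec(6, 1.0))
        assert len(cells) == 36
        assert sorted(set(cells["x"])) == [i + 0.5 for i in range(6)]
        assert sorted(set(cells["y"])) == [i + 0.5 for i in range(6)]

    def test_spherical_cells_have_equal_area(self):
        spec = GridSpec(mode="spherical", cell_size_km=1000.0)
        areas = spec.dx * spec.dy * np.ones(spec.n_rows * spec.n_cols)
        assert np.all(np.abs(areas / areas[0] - 1.0) < 1e-6)
        # nominal size respected to within the tiling adjustment
        assert spec.cell_area == pytest.approx(1000.0**2, rel=0.05)
        cells = make_grid(spec)
        assert {"lon", "lat"} <= set(cells.columns)
        assert cells["lat"].abs().max() <= 90.0

    def test_extent_smaller_than_cell_gives_one_cell(self):
        spec = GridSpec(mode="planar", cell_size_km=10.0, extent=(0, 0, 3, 3))
        assert len(make_grid(spec)) == 1

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(GridError):
            GridSpec(mode="planar", cell_size_km=0.0, extent=(0, 0, 1, 1))


class TestOverlay:
    def test_global_polygon_occupies_every_cell(self):
        spec = planar_spec(3, 1.0)
        cells = overlay(make_grid(spec), [rec("L1", box(-1, -1, 4, 4))], spec)
        assert len(cells) == 9
        assert (cells["diversity"] == 1).all()

    def test_disjoint_rectangles_keep_only_their_cells(self):
        spec = planar_spec(2, 1.0)
        records = [
            rec("L1", box(0.2, 0.2, 0.4, 0.4)),
            rec("L2", box(1.2, 1.2, 1.4, 1.4)),
        ]
        cells = overlay(make_grid(spec), records, spec)
        assert len(cells) == 2
        assert set(cells["diversity"]) == {1}
        assert {occ for tup in cells["occupants"] for occ in tup} == {"L1", "L2"}

    def test_boundary_touch_counts_as_occupancy(self):
        spec = planar_spec(2, 1.0)
        # polygon inside cell (0,0) touching the x=1 boundary of cell (0,1)
        cells = overlay(make_grid(spec), [rec("L1", box(0.5, 0.2, 1.0, 0.4))], spec)
        assert len(cells) == 2

    def test_family_and_population_summaries(self):
        spec = planar_spec(1, 1.0)
        records = [
            rec("L1", box(0, 0, 1, 1), fam="F1", speakers=100),
            rec("L2", box(0, 0, 1, 1), fam="F1", speakers=300),
        ]
        cells = overlay(make_grid(spec), records, spec)
        row = cells.iloc[0]
        assert row["diversity"] == 2
        assert row["n_families"] == 1
        assert row["min_pop"] == 100
        assert row["avg_pop"] == 200.0

    def test_adding_a_language_never_decreases_diversity(self, rng):
        spec = planar_spec(4, 1.0)
        records = []
        for i in range(8):
            x, y = rng.uniform(0, 4, size=2)
            r = rng.uniform(0.2, 1.5)
            records.append(rec(f"L{i}", box(x - r, y - r, x + r, y + r)))
        base = overlay(make_grid(spec), records[:-1], spec)
        more = overlay(make_grid(spec), records, spec)
        merged = base.set_index("cell_id")["diversity"]
        for cid, div in more.set_index("cell_id")["diversity"].items():
            assert div >= merged.get(cid, 0)
        # every language is present somewhere
        present = {occ for tup in more["occupants"] for occ in tup}
        assert present == {f"L{i}" for i in range(8)}

    def test_irreparable_polygon_raises_listing_language(self):
        spec = planar_spec(2, 1.0)
        empty = Polygon()
        with pytest.raises(GridError, match="Lbad"):
            overlay(make_grid(spec), [rec("Lbad", empty)], spec)


class TestLandFraction:
    def test_full_half_and_none(self):
        spec = planar_spec(2, 1.0)
        cells = make_grid(spec)
        land = box(0, 0, 2, 1.5)  # bottom row full, top row half
        out = land_fraction(cells, land, spec, landmask_crs="planar")
        frac = out.set_index(["row", "col"])["land_fraction"]
        assert frac[(0, 0)] == pytest.approx(1.0)
        assert frac[(1, 0)] == pytest.approx(0.5)

    def test_small_island_floor_for_occupied_cells(self):
        spec = planar_spec(1, 1.0)
        island = box(0.0, 0.0, 0.06, 0.05)  # 0.3% of the cell
        cells = overlay(make_grid(spec), [rec("L1", island)], spec)
        out = land_fraction(cells, island, spec, landmask_crs="planar")
        assert out["land_fraction"].iloc[0] == pytest.approx(0.01)

    def test_planar_default_is_all_land(self):
        spec = planar_spec(2, 1.0)
        out = land_fraction(make_grid(spec), None, spec)
        assert (out["land_fraction"] == 1.0).all()

    def test_spherical_requires_landmask(self):
        spec = GridSpec(mode="spherical", cell_size_km=2000.0)
        with pytest.raises(GridError, match="landmask"):
            land_fraction(make_grid(spec), None, spec)


class TestSubsample:
    def test_step_one_is_identity(self):
        cells = make_grid(planar_spec(4, 1.0))
        assert subsample(cells, 1).equals(cells)

    def test_six_by_six_step_three_keeps_four_cells(self):
        cells = make_grid(planar_spec(6, 1.0))
        kept = subsample(cells, 3, 0, 0)
        assert len(kept) == 4
        assert set(zip(kept["row"], kept["col"])) == {(0, 0), (0, 3), (3, 0), (3, 3)}

    def test_step_three_has_nine_regimes_partitioning_cells(self):
        cells = make_grid(planar_spec(6, 1.0))
        regimes = subsample_regimes(cells, 3)
        assert len(regimes) == 9
        all_ids = [cid for reg in regimes.values() for cid in reg["cell_id"]]
        assert len(all_ids) == len(cells)
        assert set(all_ids) == set(cells["cell_id"])

    def test_offsets_out_of_range_rejected(self):
        cells = make_grid(planar_spec(3, 1.0))
        with pytest.raises(GridError):
            subsample(cells, 3, 3, 0)
        with pytest.raises(GridError):
            subsample(cells, 0)


class TestIO:
    def test_cells_csv_round_trip(self, tmp_path):
        spec = planar_spec(2, 1.0)
        cells = overlay(make_grid(spec), [rec("L1", box(0, 0, 2, 2), fam="F1")], spec)
        path = tmp_path / "cells.csv"
        write_cells_csv(cells, path)
        back = read_cells_csv(path)
        assert list(back["occupants"]) == list(cells["occupants"])
        assert np.allclose(back["x"], cells["x"])

    def test_language_geojson_round_trip(self, tmp_path):
        records = [
            rec("L1", box(0, 0, 1, 1), path=("F1", "G1"), speakers=12),
            rec("L2", box(1, 1, 2, 2), path=("L2",), speakers=0),
        ]
        path = tmp_path / "langs.geojson"
        write_language_geojson(records, path)
        back = read_language_geojson(path)
        assert [r.language_id for r in back] == ["L1", "L2"]
        assert back[0].classification_path == ("F1", "G1")
        assert back[0].range_polygon.equals(records[0].range_polygon)
        assert back[1].speaker_count == 0
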