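"""Buffer geometry, cover profiles and grid/site file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scaleofeffect.errors import (
    InvalidArgumentError,
    OutOfExtentError,
    ParseError,
)
from scaleofeffect.landscape import (
    CLASSES,
    LandscapeGrid,
    build_cover_profile,
    cover_fraction,
    make_radius_series,
    read_grid,
    read_sites,
    write_grid,
    write_sites,
)

from conftest import brute_force_cover_fraction


class TestRadiusSeries:
    @pytest.mark.parametrize(
        "args, n, first, last",
        [
            ((150, 5000, 10), 485, 150, 4990),
            ((150, 160, 10), 1, 150, 150),
            ((150, 5000, 4850), 1, 150, 150),
            ((150, 2050, 50), 38, 150, 2000),
        ],
    )
    def test_series_bounds(self, args, n, first, last):
        radii = make_radius_series(*args)
        assert radii.size == n
        assert radii[0] == first and radii[-1] == last
        assert np.all(np.diff(radii) == args[2])

    @pytest.mark.parametrize("args", [(150, 150, 10), (150, 100, 10), (150, 5000, 0),
                                      (0, 5000, 10)])
    def test_invalid_arguments(self, args):
        with pytest.raises(InvalidArgumentError):
            make_radius_series(*args)


class TestCoverFraction:
    def test_homogeneous_grid(self):
        grid = LandscapeGrid(np.zeros((40, 40), dtype=int), cell_size=10.0)
        assert cover_fraction(grid, (200, 200), 80, "forest") == 1.0
        assert cover_fraction(grid, (200, 200), 80, "urban") == 0.0

    def test_half_plane_boundary(self, half_plane_grid):
        # disc centred on the forest/other boundary: close to half forest
        frac = cover_fraction(half_plane_grid, (500.0, 500.0), 300.0, "forest")
        oracle = brute_force_cover_fraction(half_plane_grid, (500.0, 500.0), 300.0, "forest")
        assert frac == oracle
        assert abs(frac - 0.5) < 0.05

    @pytest.mark.parametrize("radius", [35.0, 80.0, 125.0, 200.0])
    @pytest.mark.parametrize("cls", ["forest", "agriculture"])
    def test_matches_brute_force_enumeration(self, random_grid, radius, cls):
        center = (290.0, 310.0)
        assert cover_fraction(random_grid, center, radius, cls) == (
            brute_force_cover_fraction(random_grid, center, radius, cls)
        )

    def test_class_proportions_partition_unity(self, random_grid):
        fracs = [cover_fraction(random_grid, (300, 300), 150, c) for c in CLASSES]
        assert sum(fracs) == pytest.approx(1.0, abs=1e-9)

    def test_class_merging_is_additive(self, random_grid):
        # merging two classes into one code yields the sum of their fractions
        merged = np.where(
            random_grid.values == CLASSES.index("urban"),
            CLASSES.index("forest"),
            random_grid.values,
        )
        merged_grid = LandscapeGrid(merged, cell_size=10.0)
        f = cover_fraction(random_grid, (300, 300), 180, "forest")
        u = cover_fraction(random_grid, (300, 300), 180, "urban")
        both = cover_fraction(merged_grid, (300, 300), 180, "forest")
        assert both == pytest.approx(f + u, abs=1e-12)

    def test_out_of_extent_is_an_error(self, random_grid):
        with pytest.raises(OutOfExtentError):
            cover_fraction(random_grid, (50.0, 300.0), 100.0, "forest")

    def test_unknown_class_is_an_error(self, random_grid):
        with pytest.raises(InvalidArgumentError, match="unknown class"):
            cover_fraction(random_grid, (300, 300), 100, "swamp")

    @given(
        dx=st.floats(-1e4, 1e4, allow_nan=False),
        dy=st.floats(-1e4, 1e4, allow_nan=False),
    )
    def test_translation_equivariance(self, dx, dy):
        rng = np.random.default_rng(7)
        values = rng.integers(0, 4, size=(30, 30))
        g0 = LandscapeGrid(values, cell_size=10.0, origin=(0.0, 0.0))
        g1 = LandscapeGrid(values, cell_size=10.0, origin=(dx, dy))
        assert cover_fraction(g0, (150, 150), 60, "urban") == (
            cover_fraction(g1, (150 + dx, 150 + dy), 60, "urban")
        )


class TestCoverProfile:
    def test_single_site_uniform_grid(self):
        grid = LandscapeGrid(np.zeros((40, 40), dtype=int), cell_size=10.0)
        sites = pd.DataFrame({"site_id": ["s"], "x": [200.0], "y": [200.0], "effort": [5]})
        prof = build_cover_profile(grid, sites, [100.0])
        assert prof.at("s", 100.0, "forest") == 1.0
        assert prof.at("s", 100.0, "urban") == 0.0

    def test_entries_match_cover_fraction(self, random_grid, toy_sites):
        radii = [40.0, 80.0, 120.0, 160.0, 200.0]
        prof = build_cover_profile(random_grid, toy_sites, radii)
        for row in toy_sites.itertuples(index=False):
            for r in radii:
                for cls in CLASSES:
                    assert prof.at(row.site_id, r, cls) == (
                        cover_fraction(random_grid, (row.x, row.y), r, cls)
                    )

    def test_proportions_sum_to_one(self, random_grid, toy_sites):
        prof = build_cover_profile(random_grid, toy_sites, [50.0, 120.0, 200.0])
        sums = prof.proportions.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_site_order_invariance(self, random_grid, toy_sites):
        radii = [60.0, 140.0]
        p1 = build_cover_profile(random_grid, toy_sites, radii)
        p2 = build_cover_profile(
            random_grid, toy_sites.iloc[::-1].reset_index(drop=True), radii
        )
        for s in p1.site_ids:
            for r in radii:
                for c in CLASSES:
                    assert p1.at(s, r, c) == p2.at(s, r, c)

    def test_out_of_extent_names_site(self, random_grid):
        sites = pd.DataFrame(
            {"site_id": ["edge"], "x": [30.0], "y": [300.0], "effort": [5]}
        )
        with pytest.raises(OutOfExtentError, match="edge"):
            build_cover_profile(random_grid, sites, [100.0])

    def test_csv_round_trip(self, random_grid, toy_sites, tmp_path):
        from scaleofeffect.landscape import CoverProfile

        prof = build_cover_profile(random_grid, toy_sites, [50.0, 100.0])
        prof.to_csv(tmp_path / "prof.csv")
        back = CoverProfile.from_csv(tmp_path / "prof.csv")
        assert np.allclose(back.proportions, prof.proportions)


class TestGridIO:
    def test_round_trip(self, random_grid, tmp_path):
        path = tmp_path / "grid.asc"
        write_grid(random_grid, path)
        back = read_grid(path)
        assert np.array_equal(back.values, random_grid.values)
        assert back.cell_size == random_grid.cell_size
        assert back.origin == random_grid.origin
        assert back.classes == random_grid.classes

    def test_small_ascii_fixture_by_hand(self, tmp_path):
        path = tmp_path / "tiny.asc"
        path.write_text(
            "ncols 2\nnrows 2\nxllcorner 100.0\nyllcorner 200.0\ncellsize 50.0\n"
            "0 1\n2 3\n"
        )
        grid = read_grid(path)
        assert grid.values.shape == (2, 2)
        # row 0 is the northern edge; cell (0, 0) is the NW cell
        assert grid.classes[grid.values[0, 0]] == "forest"
        assert grid.classes[grid.values[1, 1]] == "other"
        assert grid.extent == (100.0, 200.0, 200.0, 300.0)

    def test_missing_header_key(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 2\n0 1\n2 3\n")
        with pytest.raises(ParseError, match="missing header"):
            read_grid(path)

    def test_non_integer_cell(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 10\n0 x\n2 3\n"
        )
        with pytest.raises(ParseError):
            read_grid(path)


class TestSiteIO:
    def test_round_trip(self, toy_sites, tmp_path):
        path = tmp_path / "sites.csv"
        write_sites(toy_sites, path)
        back = read_sites(path)
        pd.testing.assert_frame_equal(back, toy_sites)

    def test_duplicate_site_id(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text("site_id,x,y,effort\na,1,2,3\na,4,5,6\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_sites(path)

    def test_non_numeric_coordinate(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text("site_id,x,y,effort\na,east,2,3\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_sites(path)

    def test_effort_below_one(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text("site_id,x,y,effort\na,1,2,0\n")
        with pytest.raises(ParseError, match="effort"):
            read_sites(path)
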