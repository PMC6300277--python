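"""ESRI ASCII grid parsing, writing, and landscape-stack validation."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from gridshade.grids import (CoRegistrationError, GridFormatError, GridRaster,
                             build_landscape_stack, read_ascii_grid,
                             write_ascii_grid)

from conftest import grid


def _write(tmp_path, text, name="g.asc"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 10\nNODATA_value -9999\n"


class TestReadAsciiGrid:
    def test_basic_parse(self, tmp_path):
        g = read_ascii_grid(_write(tmp_path, HEADER + "1 2\n3 4\n"))
        assert g.ncols == 2 and g.nrows == 2
        assert g.cellsize == 10
        assert g.nodata_value == -9999
        np.testing.assert_array_equal(g.values, [[1, 2], [3, 4]])

    def test_first_row_is_north(self, tmp_path):
        # file order maps row 0 to the top (northernmost) row
        g = read_ascii_grid(_write(tmp_path, HEADER + "9 9\n0 0\n"))
        assert g.values[0, 0] == 9 and g.values[1, 0] == 0

    def test_cell_count_mismatch(self, tmp_path):
        with pytest.raises(GridFormatError, match="expected 4 cell values"):
            read_ascii_grid(_write(tmp_path, HEADER + "1 2 3\n"))

    def test_zero_cellsize_rejected(self, tmp_path):
        text = HEADER.replace("cellsize 10", "cellsize 0") + "1 2\n3 4\n"
        with pytest.raises(GridFormatError, match="cellsize"):
            read_ascii_grid(_write(tmp_path, text))

    def test_non_numeric_token_reports_position(self, tmp_path):
        with pytest.raises(GridFormatError, match="'x' at position 2"):
            read_ascii_grid(_write(tmp_path, HEADER + "1 2\nx 4\n"))

    def test_missing_nodata_defaults(self, tmp_path):
        text = HEADER.replace("NODATA_value -9999\n", "") + "1 2\n3 4\n"
        assert read_ascii_grid(_write(tmp_path, text)).nodata_value == -9999

    def test_center_dialect_converted_to_corner(self, tmp_path):
        text = ("ncols 2\nnrows 2\nxllcenter 5\nyllcenter 105\ncellsize 10\n"
                "1 2\n3 4\n")
        g = read_ascii_grid(_write(tmp_path, text))
        assert g.xllcorner == 0.0 and g.yllcorner == 100.0

    def test_missing_header_key(self, tmp_path):
        with pytest.raises(GridFormatError, match="ncols"):
            read_ascii_grid(_write(tmp_path, "nrows 2\ncellsize 10\n1 2\n"))


class TestWriteAsciiGrid:
    def test_round_trip(self, tmp_path):
        g = grid([[1.0, 2.0], [3.0, 4.0]], cellsize=5.0, xll=100.0, yll=-30.0)
        back = read_ascii_grid(write_ascii_grid(g, tmp_path / "o.asc"))
        assert back.same_geometry(g) == []
        np.testing.assert_allclose(back.values, g.values)

    def test_nodata_written_verbatim(self, tmp_path):
        g = grid([[1.0, -9999.0]])
        text = write_ascii_grid(g, tmp_path / "o.asc", decimals=3).read_text()
        assert "-9999 " in text.replace("\n", " ") or text.rstrip().endswith("-9999")
        back = read_ascii_grid(tmp_path / "o.asc")
        assert back.is_nodata()[0, 1]

    def test_decimals_formatting(self, tmp_path):
        g = grid([[0.123456]])
        text = write_ascii_grid(g, tmp_path / "o.asc", decimals=3).read_text()
        assert text.splitlines()[-1] == "0.123"

    @settings(deadline=None, max_examples=25, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(values=st.lists(st.floats(-1e6, 1e6), min_size=6, max_size=6),
           cellsize=st.floats(0.5, 100.0))
    def test_round_trip_property(self, values, cellsize, tmp_path):
        g = grid(np.array(values).reshape(2, 3), cellsize=cellsize)
        back = read_ascii_grid(write_ascii_grid(g, tmp_path / "p.asc",
                                                decimals=6))
        assert back.same_geometry(g) == []
        np.testing.assert_allclose(back.values, g.values, atol=1e-6)


class TestLandscapeStack:
    def test_dem_only_topographic_mode(self):
        stack = build_landscape_stack(dem=grid(np.zeros((3, 3))))
        assert stack.ndsm is None
        assert stack.ceiling == 0.0

    def test_ceiling_is_cellwise_max(self):
        # dem max 100 and ndsm max 30 sit at different cells: the ceiling
        # is max over cells of (dem + ndsm), not the sum of the maxima
        dem = grid([[100.0, 50.0]])
        ndsm = grid([[0.0, 30.0]])
        otm = grid([[1.0, 0.5]])
        stack = build_landscape_stack(dem=dem, ndsm=ndsm, otm=otm)
        assert stack.ceiling == 100.0

    def test_otm_out_of_range_reports_cell(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            build_landscape_stack(dem=grid([[0.0, 0.0]]),
                                  ndsm=grid([[0.0, 5.0]]),
                                  otm=grid([[1.0, 1.2]]))

    def test_ndsm_requires_otm(self):
        with pytest.raises(CoRegistrationError, match="OTM"):
            build_landscape_stack(dem=grid([[0.0]]), ndsm=grid([[5.0]]))

    def test_geometry_mismatch_lists_fields(self):
        with pytest.raises(CoRegistrationError, match="cellsize"):
            build_landscape_stack(dem=grid([[0.0]], cellsize=10),
                                  ndsm=grid([[5.0]], cellsize=20),
                                  otm=grid([[1.0]], cellsize=10))

    def test_negative_ndsm_rejected(self):
        with pytest.raises(ValueError, match="negative nDSM"):
            build_landscape_stack(dem=grid([[0.0]]), ndsm=grid([[-2.0]]),
                                  otm=grid([[1.0]]))

    def test_understory_height_bounded_by_ndsm(self):
        with pytest.raises(ValueError, match="understory"):
            build_landscape_stack(
                dem=grid([[0.0]]), ndsm=grid([[10.0]]), otm=grid([[0.5]]),
                understory_height=grid([[12.0]]),
                understory_otm=grid([[0.8]]))

    def test_rebuild_is_idempotent(self):
        dem, ndsm, otm = grid(np.zeros((2, 2))), grid(np.full((2, 2), 7.0)), \
            grid(np.full((2, 2), 0.5))
        a = build_landscape_stack(dem=dem, ndsm=ndsm, otm=otm)
        b = build_landscape_stack(dem=a.dem, ndsm=a.ndsm, otm=a.otm)
        assert a.ceiling == b.ceiling == 7.0

    def test_at_least_one_layer_required(self):
        with pytest.raises(CoRegistrationError):
            build_landscape_stack()

    def test_nodata_dem_cells_excluded_as_origins(self):
        dem = grid([[0.0, -9999.0]])
        stack = build_landscape_stack(dem=dem)
        np.testing.assert_array_equal(stack.origin_mask(), [[True, False]])

    def test_mask_restricts_origins(self):
        stack = build_landscape_stack(dem=grid(np.zeros((1, 2))),
                                      mask=grid([[1.0, 0.0]]))
        np.testing.assert_array_equal(stack.origin_mask(), [[True, False]])
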