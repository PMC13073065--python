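"""Plate data model, position algebra, and table I/O round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qhtcp import plate_io
from qhtcp.plate_io import (
    ParseError,
    PlateLayout,
    SchemaError,
    SpotTimeSeries,
    position_to_rc,
    rc_to_position,
)


@given(st.integers(1, 16), st.integers(1, 24))
def test_position_roundtrip(row, col):
    assert position_to_rc(rc_to_position(row, col)) == (row, col)


@pytest.mark.parametrize("bad", ["Q1", "A0", "A25", "", "11", "Ax"])
def test_invalid_positions_rejected(bad):
    with pytest.raises(ParseError):
        position_to_rc(bad)


def test_spot_series_requires_increasing_times():
    with pytest.raises(ValueError, match="strictly increasing"):
        SpotTimeSeries("p", 1, 1, "GENE", 0.0, [0.0, 3.5, 3.5], [1, 2, 3])


def _write(tmp_path, text, name="ts.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


def test_read_timeseries_groups_and_sorts(tmp_path):
    path = _write(
        tmp_path,
        "plate\trow\tcol\tstrain\tcondition_ugml\ttime_h\tintensity\n"
        "p1\t1\t1\tRAD9\t0\t7\t30\n"
        "p1\t1\t1\tRAD9\t0\t0\t5\n"
        "p1\t1\t1\tRAD9\t0\t3.5\t12\n",
    )
    series = plate_io.read_timeseries(path)
    assert len(series) == 1
    s = series[0]
    assert s.n_obs == 3
    assert list(s.times) == [0.0, 3.5, 7.0]
    assert s.strain_id == "RAD9" and s.position == "A1"


def test_read_timeseries_duplicate_observation(tmp_path):
    path = _write(
        tmp_path,
        "plate\trow\tcol\tstrain\tcondition_ugml\ttime_h\tintensity\n"
        "p1\t1\t1\tRAD9\t0\t0\t5\n"
        "p1\t1\t1\tRAD9\t0\t0\t6\n",
    )
    with pytest.raises(ParseError, match="duplicate"):
        plate_io.read_timeseries(path)


def test_read_timeseries_missing_column_named(tmp_path):
    path = _write(
        tmp_path,
        "plate\trow\tcol\tstrain\tcondition_ugml\ttime_h\n" "p1\t1\t1\tRAD9\t0\t0\n",
    )
    with pytest.raises(SchemaError, match="intensity"):
        plate_io.read_timeseries(path)


def test_read_timeseries_nonnumeric_reports_line(tmp_path):
    path = _write(
        tmp_path,
        "plate\trow\tcol\tstrain\tcondition_ugml\ttime_h\tintensity\n"
        "p1\t1\t1\tRAD9\t0\t0\t5\n"
        "p1\t1\t1\tRAD9\t0\toops\t6\n",
    )
    with pytest.raises(ParseError, match="line 3"):
        plate_io.read_timeseries(path)


def test_timeseries_roundtrip_exact(tmp_path, small_screen):
    subset = small_screen.series[:40]
    path = tmp_path / "ts.tsv"
    plate_io.write_timeseries(subset, path)
    back = plate_io.read_timeseries(path)
    orig = {(s.plate_id, s.row, s.col, s.condition): s for s in subset}
    assert len(back) == len(subset)
    for s in back:
        o = orig[(s.plate_id, s.row, s.col, s.condition)]
        np.testing.assert_array_equal(s.times, o.times)
        np.testing.assert_array_equal(s.intensities, o.intensities)
        assert s.strain_id == o.strain_id


def test_layout_roundtrip_and_reference_flag(tmp_path, small_screen):
    path = tmp_path / "layouts.tsv"
    plate_io.write_layouts(small_screen.layouts, path)
    back = plate_io.read_layouts(path)
    assert set(back) == set(small_screen.layouts)
    ref = next(p for p in back if p.startswith("ref"))
    dele = next(p for p in back if p.startswith("arr"))
    assert back[ref].is_reference and not back[dele].is_reference
    assert back[dele].positions == small_screen.layouts[dele].positions


def test_validate_design_complete_screen(small_screen):
    report = plate_io.validate_design(
        small_screen.design, small_screen.layouts, small_screen.series
    )
    assert report.ok, report.issues


def test_validate_design_missing_reference_and_condition(small_screen):
    layouts = dict(small_screen.layouts)
    missing = next(p for p in layouts if p.startswith("ref") and p.endswith("c3"))
    del layouts[missing]
    report = plate_io.validate_design(small_screen.design, layouts)
    assert any(missing in issue for issue in report.issues)

    manifest = small_screen.design.manifest
    trimmed = plate_io.ScreenDesign(
        concentrations=small_screen.design.concentrations,
        manifest=manifest[manifest["condition_ugml"] < 20].reset_index(drop=True),
    )
    report = plate_io.validate_design(trimmed, small_screen.layouts)
    assert any("missing condition 20" in issue for issue in report.issues)


def test_validate_design_flags_undersized_layout(small_screen):
    layouts = dict(small_screen.layouts)
    plate = next(iter(layouts))
    positions = dict(layouts[plate].positions)
    positions.pop(next(iter(positions)))
    layouts[plate] = PlateLayout(plate, positions)
    report = plate_io.validate_design(small_screen.design, layouts)
    assert any("383 positions" in issue for issue in report.issues)


def test_result_table_roundtrip_with_provenance(tmp_path):
    df = pd.DataFrame({"strain": ["A", "B"], "z": [1.25, -0.5]})
    path = tmp_path / "out.tsv"
    plate_io.write_table(df, path, seed=42)
    text = path.read_text()
    assert text.startswith("# qhtcp") and "seed=42" in text.splitlines()[0]
    back = plate_io.read_table(path)
    pd.testing.assert_frame_equal(back, df)
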