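"""Recording persistence: ATF/CSV round-trips, units, parse errors."""

import numpy as np
import pytest

import cavclamp as cc
from cavclamp.errors import AnalysisError, ParseError


@pytest.fixture(scope="module")
def small_recording(wt_cell):
    proto = cc.build_protocol("reversal_tail")
    return cc.simulate_recording(proto, wt_cell, seed=3)


def _assert_recordings_equal(a, b):
    assert a.cell_id == b.cell_id
    assert a.genotype == b.genotype
    assert a.sweep_tags == b.sweep_tags
    assert len(a.sweeps) == len(b.sweeps)
    for sa, sb in zip(a.sweeps, b.sweeps):
        np.testing.assert_array_equal(sa.current, sb.current)
        np.testing.assert_array_equal(sa.command, sb.command)


@pytest.mark.parametrize("ext", [".atf", ".csv"])
def test_lossless_round_trip(small_recording, tmp_path, ext):
    """write -> read reproduces every sample bit-for-bit (text persistence
    uses 17 significant digits)."""
    path, sidecar = cc.write_recording(small_recording, tmp_path / f"rec{ext}")
    assert sidecar.exists()
    again = cc.read_recording(path)
    _assert_recordings_equal(small_recording, again)
    assert again.protocol.to_dict() == small_recording.protocol.to_dict()


def test_atf_header_declares_units(small_recording, tmp_path):
    path, _ = cc.write_recording(small_recording, tmp_path / "rec.atf")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("ATF\t1.0")
    titles = lines[2 + int(lines[1].split("\t")[0])]
    assert "(ms)" in titles and "(pA)" in titles


def test_step_iv_column_count(quiet_wt, tmp_path):
    """14 main sweeps (+ their -P/4 sub-sweeps) -> 1 time column + one
    current column per stored sweep."""
    proto = cc.build_protocol("step_iv")
    rec = cc.simulate_recording(proto, quiet_wt, seed=0)
    path, _ = cc.write_recording(rec, tmp_path / "iv.atf")
    lines = path.read_text().splitlines()
    n_cols = int(lines[1].split("\t")[1])
    assert n_cols == 1 + 14 * 5  # each sweep stores main + 4 sub-sweeps
    # and the corrected recording stores exactly the 14 combined sweeps
    corr = cc.correct_recording(rec)
    path2, _ = cc.write_recording(corr, tmp_path / "iv_corr.atf")
    assert int(path2.read_text().splitlines()[1].split("\t")[1]) == 15


def test_truncated_file_names_the_line(small_recording, tmp_path):
    path, _ = cc.write_recording(small_recording, tmp_path / "rec.atf")
    lines = path.read_text().splitlines()
    lines[100] = lines[100].rsplit("\t", 1)[0]  # drop last column of a row
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParseError, match="line 101"):
        cc.read_recording(path)


def test_wrong_units_rejected(small_recording, tmp_path):
    path, _ = cc.write_recording(small_recording, tmp_path / "rec.atf")
    text = path.read_text().replace("(pA)", "(nA)")
    path.write_text(text)
    with pytest.raises(ParseError, match="pA"):
        cc.read_recording(path)


def test_csv_without_sidecar_is_protocol_unknown(small_recording, tmp_path):
    path, sidecar = cc.write_recording(small_recording, tmp_path / "rec.csv")
    sidecar.unlink()
    rec = cc.read_recording(path)
    assert rec.protocol is None
    assert rec.genotype == "unknown"
    with pytest.raises(AnalysisError):
        cc.correct_recording(rec)
    with pytest.raises(AnalysisError):
        cc.measure_cm(rec)


def test_p4_grouping_survives_round_trip(quiet_wt, tmp_path):
    proto = cc.build_protocol("reversal_tail")
    rec = cc.simulate_recording(proto, quiet_wt, seed=1)
    path, _ = cc.write_recording(rec, tmp_path / "rec.atf")
    again = cc.read_recording(path)
    assert again.sweeps_where(role="p4sub") == rec.sweeps_where(role="p4sub")
    # correction works identically on the reloaded recording
    a = cc.correct_recording(rec).sweeps[0].current
    b = cc.correct_recording(again).sweeps[0].current
    np.testing.assert_array_equal(a, b)
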