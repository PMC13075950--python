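"""Writer/reader: field formats, layout, tolerance and round trips."""

import io
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hxmsio import (
    INFINITE,
    FormatError,
    IsotopicEnvelope,
    format_time,
    parse_time,
    read_hxms,
    write_hxms,
)
from hxmsio.codec import HXMSParseWarning, snap

from .conftest import minimal_dataset


class TestTimeNotation:
    @pytest.mark.parametrize(
        "seconds, text",
        [
            (0.0, "0.000000e+00"),
            (60.0, "6.000000e+01"),
            (0.5, "5.000000e-01"),
            (INFINITE, "inf"),
        ],
    )
    def test_format(self, seconds, text):
        assert format_time(seconds) == text

    @pytest.mark.parametrize(
        "text, seconds",
        [("inf", INFINITE), ("0.000000e+00", 0.0), ("3.0e1", 30.0), ("45", 45.0)],
    )
    def test_parse(self, text, seconds):
        assert parse_time(text) == seconds

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            format_time(-1.0)
        with pytest.raises(FormatError):
            parse_time("-5.0")
        with pytest.raises(FormatError):
            parse_time("soon")

    @given(st.floats(min_value=0, max_value=1e9, allow_nan=False))
    def test_round_trip_within_notation_precision(self, t):
        back = parse_time(format_time(t))
        assert back == pytest.approx(t, rel=5e-7)


class TestWriter:
    def test_no_ptm_record_serializes_ptm_id_0000(self, dataset):
        line = write_hxms(dataset).splitlines()[7]
        assert line[46:54] == "0000    "

    def test_example_envelope_serialization(self, dataset):
        line = write_hxms(dataset).splitlines()[7]
        assert line.endswith("0.527,0.298,0.116,0.036,0.000,0.023,0.000")

    def test_time_field_occupies_16_characters(self, dataset):
        for line in write_hxms(dataset).splitlines():
            if line.startswith("TP"):
                assert line[54:70].strip() in ("0.000000e+00", "6.000000e+01")
                assert len(line[54:70]) == 16

    def test_version_remark_emitted_automatically(self, dataset):
        assert "REMARK\tHXMS_VERSION\tv1.0" in write_hxms(dataset).splitlines()

    def test_write_is_deterministic(self, dataset):
        assert write_hxms(dataset) == write_hxms(minimal_dataset())

    def test_invalid_dataset_refused(self, dataset):
        from dataclasses import replace

        from hxmsio import DatasetValidationError

        dataset.timepoints[0] = replace(dataset.timepoints[0], start=9, end=2)
        with pytest.raises(DatasetValidationError):
            write_hxms(dataset)

    def test_write_to_stream_and_path(self, dataset, tmp_path):
        buf = io.StringIO()
        text = write_hxms(dataset, buf)
        assert buf.getvalue() == text
        path = tmp_path / "out.hxms"
        write_hxms(dataset, path)
        assert path.read_text(encoding="utf-8") == text


class TestReader:
    def test_round_trip_identity(self, dataset):
        assert read_hxms(write_hxms(dataset)) == dataset

    def test_metadata_line(self):
        text = (
            "METADATA\tPROTEIN_SEQUENCE\tGSHMKTVEVNGADASDDN\n"
            "METADATA\tTEMPERATURE (K)\t293.15\n"
        )
        ds = read_hxms(text)
        assert ds.metadata.temperature_K == 293.15
        assert ds.metadata.protein_sequence == "GSHMKTVEVNGADASDDN"

    def test_tab_separated_tp_rows_accepted(self, dataset):
        text = (
            "METADATA\tPROTEIN_SEQUENCE\tGSHMKTVEVNGADASDDN\n"
            "TP\t0\tA\t1\t10\t0\t0000\tinf\t4.50\t0.100,0.900\n"
        )
        tp = read_hxms(text).timepoints[0]
        assert tp.time_s == INFINITE
        assert tp.uptake_Da == 4.50
        assert tp.envelope == IsotopicEnvelope((0.1, 0.9))

    def test_sections_in_any_order(self, dataset):
        lines = write_hxms(dataset).splitlines()
        shuffled = lines[7:] + lines[:7]  # data before metadata
        assert read_hxms("\n".join(shuffled) + "\n") == dataset

    def test_empty_input_raises_format_error(self):
        with pytest.raises(FormatError):
            read_hxms("")

    def test_malformed_tp_row_reports_line_number(self):
        text = "METADATA\tPROTEIN_SEQUENCE\tAAAA\nTP    0   A\n"
        with pytest.raises(FormatError, match="line 2"):
            read_hxms(text)

    def test_duplicate_required_metadata_raises(self):
        text = (
            "METADATA\tPROTEIN_SEQUENCE\tAAAA\n"
            "METADATA\tPROTEIN_SEQUENCE\tCCCC\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_hxms(text)

    def test_unknown_row_tag_warns_not_fatal(self):
        text = "METADATA\tPROTEIN_SEQUENCE\tAAAA\nBOGUS\tstuff\n"
        with pytest.warns(HXMSParseWarning):
            ds = read_hxms(text)
        assert ds.timepoints == []

    def test_remark_lines_survive_round_trip(self, dataset):
        from hxmsio import MetadataEntry

        dataset.metadata.remarks.append(
            MetadataEntry(kind="REMARK", title="QUENCH", value="pH 2.5, 0 C")
        )
        assert read_hxms(write_hxms(dataset)) == dataset


@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12
    ).filter(lambda xs: sum(xs) > 0.1)
)
def test_arbitrary_envelope_round_trips_within_serialization_precision(peaks):
    """Peak-wise drift through serialize/parse stays below half of the
    3-decimal resolution."""
    ds = minimal_dataset()
    total = sum(peaks)
    env = IsotopicEnvelope([p / total for p in peaks])
    from dataclasses import replace

    ds.timepoints[1] = replace(ds.timepoints[1], envelope=env)
    back = read_hxms(write_hxms(ds)).timepoints[1].envelope
    assert len(back) == len(env)
    for a, b in zip(env.peaks, back.peaks):
        assert abs(a - b) <= 5e-4


def test_snap_matches_serialize_parse_cycle():
    assert snap(1.23456, "%.2f") == 1.23
    assert snap(math.pi, "%.3f") == 3.142
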