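"""Vendor-dialect converters on hand-written mini exports."""

import textwrap

import pytest

from hxmsio import (
    DIALECTS,
    INFINITE,
    MissingZeroError,
    SchemaError,
    Severity,
    convert_table,
    parse_biopharma,
    parse_custom_csv,
    parse_dynamx,
    parse_hdexaminer,
    parse_hdx_workbench,
    read_experiment_info,
    validate_dataset,
    write_hxms,
)


def errors(dataset):
    return [v for v in validate_dataset(dataset) if v.severity is Severity.ERROR]


def tp_by(dataset, **kw):
    out = [
        tp
        for tp in dataset.timepoints
        if all(getattr(tp, k) == v for k, v in kw.items())
    ]
    assert out, f"no timepoint matches {kw}"
    return out


class TestDialectCapabilities:
    def test_uptake_direct_dialects(self):
        assert DIALECTS["dynamx"].uptake_direct
        assert DIALECTS["biopharma_finder"].uptake_direct

    def test_envelope_dialects(self):
        assert DIALECTS["hdx_workbench"].envelopes_available
        assert DIALECTS["hdexaminer"].envelopes_available

    def test_no_ptm_dialects(self):
        assert not DIALECTS["hdexaminer"].ptms_supported
        assert not DIALECTS["biopharma_finder"].ptms_supported


class TestCustom(object):
    TABLE = textwrap.dedent(
        """\
        start,end,replicate,mode,time_s,uptake,envelope,ptm
        1,10,0,A,0,0.0,1;0;0,
        1,10,0,A,60,1.2,0.2;0.5;0.3,
        1,10,0,A,inf,2.1,0.05;0.15;0.8,
        11,18,0,A,0,0.0,1;0;0,Phosphoryl STY (12)
        11,18,0,A,60,0.8,0.4;0.4;0.2,Phosphoryl STY (12)
        11,18,1,A,0,0.0,1;0;0,Phosphoryl STY (12)
        """
    )

    def test_basic_conversion(self, metadata):
        ds = parse_custom_csv(self.TABLE, metadata)
        assert len(ds.timepoints) == 6
        assert errors(ds) == []
        fd = tp_by(ds, start=1, time_s=INFINITE)[0]
        assert fd.uptake_Da == 2.1

    def test_empty_ptm_column_gives_ptm_id_0(self, metadata):
        ds = parse_custom_csv(self.TABLE, metadata)
        assert all(tp.ptm_id == 0 for tp in tp_by(ds, start=1))

    def test_shared_ptm_text_shares_one_entry(self, metadata):
        ds = parse_custom_csv(self.TABLE, metadata)
        assert len(ds.ptms) == 1
        assert ds.ptms[0].content == "Phosphoryl STY (12)"
        assert all(tp.ptm_id == ds.ptms[0].ptm_id for tp in tp_by(ds, start=11))

    def test_envelopes_are_normalized(self, metadata):
        ds = parse_custom_csv(self.TABLE, metadata)
        for tp in ds.timepoints:
            assert tp.envelope.total == pytest.approx(1.0)

    def test_uptake_recomputed_from_envelopes_when_column_absent(self, metadata):
        table = textwrap.dedent(
            """\
            start,end,replicate,mode,time_s,envelope
            1,10,0,A,0,1;0
            1,10,0,A,60,0;1
            """
        )
        ds = parse_custom_csv(table, metadata)
        assert tp_by(ds, time_s=60.0)[0].uptake_Da == pytest.approx(1.0)

    def test_missing_required_column_names_it(self, metadata):
        with pytest.raises(SchemaError, match="mode"):
            parse_custom_csv("start,end,replicate,time_s,uptake\n1,5,0,0,0.0\n", metadata)

    def test_unparseable_cell_reports_row(self, metadata):
        bad = "start,end,replicate,mode,time_s,uptake\n1,10,0,A,60,not-a-number\n"
        with pytest.raises(SchemaError, match="row 1"):
            parse_custom_csv(bad, metadata)


class TestDynamX:
    TABLE = textwrap.dedent(
        """\
        start,end,modification,replicate,exposure,uptake
        1,10,,0,0,0.0
        1,10,,0,60,1.37
        1,10,,0,FD,3.25
        11,18,Phosphoryl STY (12),0,0,0.0
        11,18,Phosphoryl STY (12),0,60,0.91
        """
    )

    def test_uptake_used_as_is(self, metadata):
        ds = parse_dynamx(self.TABLE, metadata)
        assert errors(ds) == []
        assert tp_by(ds, start=1, time_s=60.0)[0].uptake_Da == 1.37
        assert all(tp.envelope is None for tp in ds.timepoints)

    def test_fd_sentinel_maps_to_inf(self, metadata):
        ds = parse_dynamx(self.TABLE, metadata)
        assert tp_by(ds, start=1, time_s=INFINITE)[0].uptake_Da == 3.25

    def test_modification_harvested_into_ptm_dictionary(self, metadata):
        ds = parse_dynamx(self.TABLE, metadata)
        assert len(ds.ptms) == 1
        assert tp_by(ds, start=11)[0].ptm_id == 1

    def test_round_trips_through_hxms(self, metadata):
        from hxmsio import read_hxms

        ds = parse_dynamx(self.TABLE, metadata)
        assert read_hxms(write_hxms(ds)) == ds


class TestWorkbench:
    TABLE = textwrap.dedent(
        """\
        start,end,replicate,charge,timepoint,centroid,abundance
        1,10,0,2,0,800.00,1.0
        1,10,0,2,60,802.50,1.0
        1,10,1,2,60,802.80,1.0
        1,10,2,2,0,801.00,1.0
        1,10,2,2,60,803.10,1.0
        """
    )

    def test_uptake_recomputed_by_centroid_subtraction(self, metadata):
        ds = parse_hdx_workbench(self.TABLE, metadata)
        assert tp_by(ds, replicate=0, time_s=60.0)[0].uptake_Da == pytest.approx(2.50)
        assert tp_by(ds, replicate=0, time_s=0.0)[0].uptake_Da == 0.0

    def test_replicate_average_fallback(self, metadata):
        # replicate 1 has no 0 s row; siblings' zero centroids are 800 and 801
        ds = parse_hdx_workbench(self.TABLE, metadata)
        assert tp_by(ds, replicate=1, time_s=60.0)[0].uptake_Da == pytest.approx(
            802.80 - 800.50
        )

    def test_no_zero_anywhere_raises_missing_zero(self, metadata):
        table = "start,end,replicate,charge,timepoint,centroid\n1,10,0,2,60,802.5\n"
        with pytest.raises(MissingZeroError):
            parse_hdx_workbench(table, metadata)

    def test_charge_states_merge_by_weighted_average(self, metadata):
        table = textwrap.dedent(
            """\
            start,end,replicate,charge,timepoint,centroid,abundance,envelope
            1,10,0,2,0,800.00,3.0,1;0;0
            1,10,0,3,0,800.40,1.0,0;1;0
            1,10,0,2,60,802.00,1.0,0;1;0
            """
        )
        ds = parse_hdx_workbench(table, metadata)
        zero = tp_by(ds, time_s=0.0)[0]
        # merged centroid 0.75*800 + 0.25*800.4 = 800.1
        assert tp_by(ds, time_s=60.0)[0].uptake_Da == pytest.approx(802.0 - 800.1)
        assert zero.envelope.peaks == pytest.approx((0.75, 0.25, 0.0))


class TestHDExaminer:
    RESULTS = textwrap.dedent(
        """\
        start,end,replicate,mode,time,centroid
        1,10,0,A,0,800.00
        1,10,0,A,60,802.50
        1,10,0,B,60,805.75
        1,10,0,A,FD,806.00
        """
    )
    SPECTRA = textwrap.dedent(
        """\
        start,end,replicate,mode,time,conf,rt,charge,monomass,spectrum
        1,10,0,A,60,0.95,8.680,4,2091.977598,"523.9764:2.076;523.9792:2698.8441,524.3190:7.059;524.3218:3170.0975"
        """
    )

    def test_bimodal_rows_map_to_mode_letters(self, metadata):
        ds = parse_hdexaminer(self.RESULTS, metadata)
        modes = {tp.mode for tp in tp_by(ds, time_s=60.0)}
        assert modes == {"A", "B"}
        # mode B is referenced against the mode-A zero centroid
        assert tp_by(ds, mode="B")[0].uptake_Da == pytest.approx(5.75)

    def test_ptms_never_harvested(self, metadata):
        results = self.RESULTS.replace("mode,time", "mode,modification,time").replace(
            "A,0,", "A,Phosphoryl STY (3),0,"
        ).replace("A,60,", "A,Phosphoryl STY (3),60,").replace(
            "B,60,", "B,Phosphoryl STY (3),60,"
        ).replace("A,FD,", "A,Phosphoryl STY (3),FD,")
        ds = parse_hdexaminer(results, metadata)
        assert ds.ptms == []
        assert all(tp.ptm_id == 0 for tp in ds.timepoints)

    def test_spectra_attach_envelope_and_match(self, metadata):
        ds = parse_hdexaminer(self.RESULTS, metadata, spectra=self.SPECTRA)
        assert len(ds.matches) == 1
        m = ds.matches[0]
        linked = ds.timepoints[m.tp_id]
        assert (linked.time_s, linked.mode) == (60.0, "A")
        assert m.charge == 4 and m.confidence == 0.95
        assert len(m.mz_structure) == 2
        assert linked.envelope is not None and len(linked.envelope) == 2

    def test_without_spectra_dataset_is_mean_deuteration_level(self, metadata):
        ds = parse_hdexaminer(self.RESULTS, metadata)
        assert ds.matches == []
        assert errors(ds) == []


class TestBioPharma:
    TABLE = textwrap.dedent(
        """\
        start,end,replicate,time,uptake
        1,10,0,0,0.0
        1,10,0,60,1.85
        1,10,0,MAX,4.10
        """
    )

    def test_uptake_copied_verbatim(self, metadata):
        ds = parse_biopharma(self.TABLE, metadata)
        assert tp_by(ds, time_s=60.0)[0].uptake_Da == 1.85

    def test_max_sentinel_is_fully_deuterated(self, metadata):
        ds = parse_biopharma(self.TABLE, metadata)
        assert tp_by(ds, time_s=INFINITE)[0].uptake_Da == 4.10

    def test_zero_row_table_raises(self, metadata):
        with pytest.raises(SchemaError, match="empty"):
            parse_biopharma("start,end,replicate,time,uptake\n", metadata)


class TestDispatchAndInfo:
    def test_unknown_dialect_rejected(self, metadata):
        with pytest.raises(ValueError, match="unknown dialect"):
            convert_table("waters", "start\n1\n", metadata)

    def test_converter_output_is_order_stable(self, metadata):
        text_a = write_hxms(parse_dynamx(TestDynamX.TABLE, metadata))
        text_b = write_hxms(parse_dynamx(TestDynamX.TABLE, metadata))
        assert text_a == text_b

    def test_experiment_info_file(self, tmp_path):
        path = tmp_path / "info.txt"
        path.write_text(
            "PROTEIN_SEQUENCE\tGSHMKTVEVNGADASDDN\n"
            "TEMPERATURE (K)\t293.15\n"
            "PH_READ=6.0\n"
            "D2O_SATURATION=0.91\n"
            "QUENCH\tpH 2.5\n"
        )
        meta = read_experiment_info(path)
        assert meta.protein_sequence == "GSHMKTVEVNGADASDDN"
        assert meta.temperature_K == 293.15
        assert meta.pH_read == 6.0
        assert meta.d2o_saturation == 0.91
        assert meta.remarks[0].title == "QUENCH"
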