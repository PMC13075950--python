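"""Synthetic experiment generator: kinetics, Poisson-binomial envelopes,
determinism and internal consistency."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hxmsio import (
    INFINITE,
    Severity,
    SynthConfig,
    centroid,
    envelope_from_fractions,
    generate_experiment,
    simulate_residue_deuteration,
    validate_dataset,
    write_hxms,
)


def brute_force_envelope(fractions):
    """Independent oracle: enumerate all 2^n deuteration outcomes."""
    n = len(fractions)
    peaks = [0.0] * (n + 1)
    for outcome in itertools.product((0, 1), repeat=n):
        p = 1.0
        for d, hit in zip(fractions, outcome):
            p *= d if hit else (1.0 - d)
        peaks[sum(outcome)] += p
    return peaks


class TestKinetics:
    def test_time_zero_gives_no_deuteration(self):
        assert np.all(simulate_residue_deuteration([0.1, 1.0, 10.0], 0.0, 0.91) == 0.0)

    def test_fully_deuterated_control_saturates(self):
        d = simulate_residue_deuteration([0.1, 1.0], INFINITE, 0.91)
        assert np.all(d == 0.91)

    def test_half_life_identity(self):
        d = simulate_residue_deuteration([math.log(2)], 1.0, 1.0)
        assert d[0] == pytest.approx(0.5)

    def test_negative_time_and_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_residue_deuteration([1.0], -1.0, 0.9)
        with pytest.raises(ValueError):
            simulate_residue_deuteration([0.0], 1.0, 0.9)


class TestPoissonBinomial:
    def test_all_zero_fractions_give_delta_at_0(self):
        env = envelope_from_fractions([0.0, 0.0, 0.0])
        assert env.peaks == (1.0, 0.0, 0.0, 0.0)

    def test_all_one_fractions_give_delta_at_n(self):
        env = envelope_from_fractions([1.0, 1.0, 1.0])
        assert env.peaks == (0.0, 0.0, 0.0, 1.0)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_matches_brute_force_enumeration(self, fractions):
        env = envelope_from_fractions(fractions)
        oracle = brute_force_envelope(fractions)
        assert np.allclose(env.peaks, oracle, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_centroid_equals_sum_of_fractions(self, fractions):
        if sum(fractions) == 0:
            fractions = [f + 0.01 for f in fractions]
        env = envelope_from_fractions(fractions)
        assert centroid(env) == pytest.approx(sum(fractions), abs=1e-9)


class TestGenerator:
    CFG = dict(n_peptides=3, sequence_length=30)

    def test_same_seed_is_byte_identical(self):
        a = generate_experiment(SynthConfig(seed=7, **self.CFG))
        b = generate_experiment(SynthConfig(seed=7, **self.CFG))
        assert write_hxms(a.dataset) == write_hxms(b.dataset)
        for name in a.exports:
            ta, tb = a.exports[name], b.exports[name]
            if isinstance(ta, dict):
                assert all(ta[k].equals(tb[k]) for k in ta)
            else:
                assert ta.equals(tb)

    def test_different_seeds_differ(self):
        a = generate_experiment(SynthConfig(seed=1, **self.CFG))
        b = generate_experiment(SynthConfig(seed=2, **self.CFG))
        assert write_hxms(a.dataset) != write_hxms(b.dataset)

    def test_zero_bimodal_fraction_keeps_modes_unimodal(self):
        exp = generate_experiment(SynthConfig(seed=3, bimodal_fraction=0.0, **self.CFG))
        assert {tp.mode for tp in exp.dataset.timepoints} == {"A"}

    def test_bimodal_peptides_emit_a_and_b_records(self):
        exp = generate_experiment(SynthConfig(seed=3, bimodal_fraction=1.0, **self.CFG))
        assert {tp.mode for tp in exp.dataset.timepoints} == {"A", "B"}

    def test_generated_dataset_validates_cleanly(self):
        exp = generate_experiment(
            SynthConfig(seed=5, bimodal_fraction=0.5, ptm_probability=0.5, **self.CFG)
        )
        assert [v for v in validate_dataset(exp.dataset) if v.severity is Severity.ERROR] == []

    def test_noise_free_uptake_matches_truth_at_serialization_precision(self):
        exp = generate_experiment(SynthConfig(seed=11, noise_sd=0.0, **self.CFG))
        truth = exp.truth.set_index(["start", "end", "replicate", "mode", "time_s"])
        for tp in exp.dataset.timepoints:
            expected = truth.loc[
                (tp.start, tp.end, tp.replicate, tp.mode, tp.time_s), "uptake_true"
            ]
            assert tp.uptake_Da == pytest.approx(float(expected), abs=0.005 + 1e-9)

    def test_fd_controls_present_with_infinite_time(self):
        exp = generate_experiment(SynthConfig(seed=2, **self.CFG))
        fd = [tp for tp in exp.dataset.timepoints if tp.time_s == INFINITE]
        assert fd and all(tp.envelope is not None for tp in fd)

    def test_config_requires_zero_timepoint(self):
        with pytest.raises(ValueError):
            SynthConfig(times_s=(30.0, 300.0))

    def test_write_outputs_all_artifacts(self, tmp_path):
        exp = generate_experiment(SynthConfig(seed=4, **self.CFG), out_dir=tmp_path)
        names = {p.name for p in tmp_path.iterdir()}
        assert {
            "reference.hxms",
            "custom.csv",
            "dynamx.csv",
            "hdx_workbench.csv",
            "hdexaminer_results.csv",
            "hdexaminer_spectra.csv",
            "biopharma_finder.csv",
            "truth.tsv",
            "site_rates.tsv",
        } <= names
        from hxmsio import read_hxms

        assert read_hxms(tmp_path / "reference.hxms") == exp.dataset
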