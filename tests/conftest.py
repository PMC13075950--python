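"""Shared fixtures: a minimal valid dataset and a reference file built
from the format's published example values."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from hxmsio import (
    HXMSDataset,
    IsotopicEnvelope,
    Metadata,
    TimepointRecord,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: the published 7-peak ENVELOPE example
EXAMPLE_ENVELOPE = (0.527, 0.298, 0.116, 0.036, 0.000, 0.023, 0.000)

#: the published two-group M/Z example (3 fine-structure points in the
#: first envelope peak, 7 in the second), spaces after semicolons as printed
EXAMPLE_MZ = (
    "523.9764:2.076; 523.9792:2698.8441; 523.982:1595.0798,"
    "524.319:7.059; 524.3218:3170.0975; 524.3246:8130.5251; "
    "524.3273:9330.6525; 524.3301:7816.5479; 524.3329:3718.9259; "
    "524.3357:1818.192"
)


def _pad(text: str, width: int) -> str:
    return str(text).ljust(width)


def reference_example_text() -> str:
    """An HXMS file assembled from the format's documented example
    values: the metadata examples, the TP example row (fixed-width), a
    second TP row so the MATCH example's TP_ID 1 resolves, and the MATCH
    example row."""
    tp0 = (
        _pad("TP", 12) + _pad(0, 8) + _pad("A", 7) + _pad(1, 7) + _pad(10, 7)
        + _pad(0, 5) + _pad("0000", 8) + _pad("0.000000e+00", 16) + _pad("0.00", 9)
        + "0.527,0.298,0.116,0.036,0.000,0.023,0.000"
    )
    tp1 = (
        _pad("TP", 12) + _pad(1, 8) + _pad("A", 7) + _pad(1, 7) + _pad(10, 7)
        + _pad(0, 5) + _pad("0000", 8) + _pad("6.000000e+01", 16) + _pad("1.25", 9)
        + "0.100,0.300,0.250,0.180,0.100,0.050,0.020"
    )
    match = (
        _pad("MATCH", 12) + _pad(1, 8) + _pad("1.00", 8) + _pad("8.680", 8)
        + _pad(4, 5) + _pad("2091.977598", 16) + EXAMPLE_MZ
    )
    return "\n".join(
        [
            "METADATA\tPROTEIN_SEQUENCE\tGSHMKTVEVNGADASDDN",
            "METADATA\tPROTEIN_NAME\tHuman PFK-1",
            "METADATA\tPROTEIN_STATE\tAPO",
            "METADATA\tTEMPERATURE (K)\t293.15",
            "METADATA\tpH(READ)\t6.0",
            "METADATA\tD_2_O_SATURATION\t0.91",
            tp0,
            tp1,
            match,
        ]
    ) + "\n"


@pytest.fixture
def example_text() -> str:
    return reference_example_text()


def minimal_metadata() -> Metadata:
    return Metadata(
        protein_sequence="GSHMKTVEVNGADASDDN",
        protein_name="Human PFK-1",
        protein_state="APO",
        temperature_K=293.15,
        pH_read=6.0,
        d2o_saturation=0.91,
    )


@pytest.fixture
def metadata() -> Metadata:
    return minimal_metadata()


def minimal_dataset() -> HXMSDataset:
    """Two timepoints of one peptide, valid by construction."""
    return HXMSDataset(
        metadata=minimal_metadata(),
        timepoints=[
            TimepointRecord(
                index=0, mode="A", start=1, end=10, time_s=0.0, uptake_Da=0.0,
                envelope=IsotopicEnvelope(EXAMPLE_ENVELOPE),
            ),
            TimepointRecord(
                index=1, mode="A", start=1, end=10, time_s=60.0, uptake_Da=1.25,
                envelope=IsotopicEnvelope((0.1, 0.3, 0.25, 0.18, 0.1, 0.05, 0.02)),
            ),
        ],
    )


@pytest.fixture
def dataset() -> HXMSDataset:
    return minimal_dataset()
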