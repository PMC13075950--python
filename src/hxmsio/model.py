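"""Typed in-memory model of an HXMS v1.0 dataset and dataset-level validation.

An HXMS file describes one protein state's hydrogen/deuterium-exchange
time course. It carries a metadata block (protein sequence and labeling
conditions), a tabular experimental section of per-peptide timepoint
records ("TP" rows), a dictionary of post-translational modifications
("PTM" rows) and an optional "MATCH" section binding each timepoint back
to its raw m/z-intensity spectral evidence.

This module is the single source of truth for the format's semantics:
every structural rule is expressed either as a light constructor check
(things that make an object meaningless, e.g. an empty envelope) or as a
:func:`validate_dataset` rule (everything content-level, reported rather
than raised, so that a malformed file can be loaded, inspected and
repaired).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "INFINITE",
    "FORMAT_VERSION",
    "REQUIRED_METADATA_TITLES",
    "Severity",
    "Violation",
    "MetadataEntry",
    "Metadata",
    "IsotopicEnvelope",
    "TimepointRecord",
    "PTMEntry",
    "EnvelopePeakGroup",
    "MatchRecord",
    "HXMSDataset",
    "validate_dataset",
    "renumber_indices",
]

#: Distinguished incubation time of a fully deuterated (FD) control sample.
#: Serializes as the literal ``inf`` in the TIME(SEC) column.
INFINITE = math.inf

#: Version string automatically written to the REMARK block on serialization.
FORMAT_VERSION = "v1.0"

#: Metadata titles that must be present exactly once per dataset.
REQUIRED_METADATA_TITLES = (
    "PROTEIN_SEQUENCE",
    "TEMPERATURE (K)",
    "pH(READ)",
    "D_2_O_SATURATION",
)

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Maximum PTM_ID value (the column is serialized zero-padded to 4 digits).
MAX_PTM_ID = 9999


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Violation:
    """One validation finding with a stable machine-readable code.

    ``locator`` points at the offending object, e.g. ``"TP[3]"`` for the
    fourth timepoint row or ``"METADATA"`` for the header block.
    """

    code: str
    severity: Severity
    message: str
    locator: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity.value}] {self.code} at {self.locator}: {self.message}"


@dataclass(frozen=True)
class MetadataEntry:
    """A free-form ``METADATA`` or ``REMARK`` line (tag, title, value)."""

    kind: str  # "METADATA" or "REMARK"
    title: str
    value: str


@dataclass
class Metadata:
    """The experimental-conditions header of an HXMS file.

    ``protein_sequence`` (one-letter amino-acid codes), ``temperature_K``,
    ``pH_read`` and ``d2o_saturation`` are required by the format; they are
    typed as optional here so that an incomplete file can still be loaded
    and reported on by :func:`validate_dataset`.
    """

    protein_sequence: str | None = None
    protein_name: str | None = None
    protein_state: str | None = None
    temperature_K: float | None = None
    pH_read: float | None = None
    d2o_saturation: float | None = None
    remarks: list[MetadataEntry] = field(default_factory=list)
    format_version: str = FORMAT_VERSION


@dataclass(frozen=True)
class IsotopicEnvelope:
    """Relative intensities of consecutive isotope peaks of one peptide ion.

    Peak index 0 is the lightest isotopologue; adjacent peaks are one
    deuteron apart. A well-formed envelope is normalized to unit sum; a
    5e-3 tolerance absorbs the 3-decimal serialization rounding.
    """

    peaks: tuple[float, ...]

    def __init__(self, peaks: Sequence[float]):
        peaks = tuple(float(p) for p in peaks)
        if len(peaks) == 0:
            raise ValueError("an isotopic envelope needs at least one peak")
        object.__setattr__(self, "peaks", peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def total(self) -> float:
        return sum(self.peaks)


@dataclass(frozen=True)
class TimepointRecord:
    """One peptide x incubation-time x replicate x mode measurement (a TP row).

    ``start``/``end`` are 1-based residue positions, inclusive of both ends.
    ``mode`` indexes coexisting envelope populations A-Z ("A" for a
    unimodal distribution). ``time_s`` is the D2O incubation time in
    seconds, ``INFINITE`` for a fully deuterated control. ``uptake_Da`` is
    raw deuterium incorporation relative to the 0 s timepoint, uncorrected
    for back exchange.
    """

    index: int
    mode: str
    start: int
    end: int
    time_s: float
    uptake_Da: float
    replicate: int = 0
    ptm_id: int = 0
    envelope: IsotopicEnvelope | None = None


@dataclass(frozen=True)
class PTMEntry:
    """PTM dictionary row: an ID and a free-text content field.

    ``content`` holds one or more comma-separated modification
    descriptions, each naming the modification and its absolute position
    in the protein sequence (e.g. ``"Phosphoryl STY (18)"``). ID 0 is
    reserved to mean "no PTM" and never appears as a dictionary entry.
    """

    ptm_id: int
    content: str


@dataclass(frozen=True)
class EnvelopePeakGroup:
    """Uncentroided fine structure behind a single envelope peak: an
    ordered sequence of (m/z, intensity) points."""

    points: tuple[tuple[float, float], ...]

    def __init__(self, points: Iterable[tuple[float, float]]):
        pts = tuple((float(m), float(i)) for m, i in points)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MatchRecord:
    """Raw matched spectral evidence for one timepoint (a MATCH row).

    ``tp_id`` keys into :attr:`TimepointRecord.index`. ``mz_structure``
    holds one :class:`EnvelopePeakGroup` per envelope peak of the matched
    timepoint (centroided exports may carry fewer groups).
    """

    tp_id: int
    confidence: float
    rt_min: float
    charge: int
    mono_mass_Da: float
    mz_structure: tuple[EnvelopePeakGroup, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mz_structure", tuple(self.mz_structure))


@dataclass
class HXMSDataset:
    """One protein state's full HX-MS experiment."""

    metadata: Metadata
    timepoints: list[TimepointRecord] = field(default_factory=list)
    ptms: list[PTMEntry] = field(default_factory=list)
    matches: list[MatchRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# validation


def _err(code, message, locator):
    return Violation(code, Severity.ERROR, message, locator)


def _warn(code, message, locator):
    return Violation(code, Severity.WARNING, message, locator)


#: Envelope unit-sum tolerance (absorbs 3-decimal peak rounding).
ENVELOPE_SUM_TOL = 5e-3

#: Uptake below this many daltons is flagged as suspicious (warning only:
#: small negative uptake is ordinary measurement noise).
UPTAKE_WARN_FLOOR = -1.0


def _validate_metadata(meta: Metadata) -> list[Violation]:
    out: list[Violation] = []
    loc = "METADATA"
    if not meta.protein_sequence:
        out.append(_err("MISSING_METADATA", "PROTEIN_SEQUENCE is required", loc))
    else:
        if not meta.protein_sequence.isalpha():
            out.append(_err("BAD_METADATA", "PROTEIN_SEQUENCE must be alphabetic", loc))
        else:
            unknown = set(meta.protein_sequence.upper()) - _AMINO_ACIDS
            if unknown:
                out.append(
                    _warn(
                        "BAD_METADATA",
                        f"PROTEIN_SEQUENCE has non-standard residue codes: {sorted(unknown)}",
                        loc,
                    )
                )
    if meta.temperature_K is None:
        out.append(_err("MISSING_METADATA", "TEMPERATURE (K) is required", loc))
    elif meta.temperature_K <= 0:
        out.append(_err("BAD_METADATA", "temperature must be positive kelvin", loc))
    if meta.pH_read is None:
        out.append(_err("MISSING_METADATA", "pH(READ) is required", loc))
    if meta.d2o_saturation is None:
        out.append(_err("MISSING_METADATA", "D_2_O_SATURATION is required", loc))
    elif not (0.0 < meta.d2o_saturation <= 1.0):
        out.append(_err("BAD_METADATA", "D2O saturation must lie in (0, 1]", loc))
    for j, entry in enumerate(meta.remarks):
        if entry.kind not in ("METADATA", "REMARK"):
            out.append(_err("BAD_METADATA", f"unknown entry kind {entry.kind!r}", f"REMARK[{j}]"))
        for text in (entry.title, entry.value):
            if "\t" in text or "\n" in text:
                out.append(
                    _err(
                        "BAD_METADATA",
                        "metadata titles and values may not contain tabs or newlines",
                        f"REMARK[{j}]",
                    )
                )
    return out


def _validate_timepoints(ds: HXMSDataset) -> list[Violation]:
    out: list[Violation] = []
    seq_len = len(ds.metadata.protein_sequence) if ds.metadata.protein_sequence else None
    for i, tp in enumerate(ds.timepoints):
        loc = f"TP[{i}]"
        if tp.index != i:
            out.append(
                _err(
                    "INDEX_GAP",
                    f"INDEX must increase by 1 from 0 in file order; saw {tp.index}, expected {i}",
                    loc,
                )
            )
        if not (len(tp.mode) == 1 and "A" <= tp.mode <= "Z"):
            out.append(_err("BAD_MODE", f"MOD must be a single letter A-Z, got {tp.mode!r}", loc))
        if tp.start < 1:
            out.append(_err("BAD_RANGE", "START is 1-based and must be >= 1", loc))
        if tp.start > tp.end:
            out.append(_err("START_GT_END", f"start {tp.start} > end {tp.end}", loc))
        if seq_len is not None and tp.end > seq_len:
            out.append(
                _err("END_OUT_OF_RANGE", f"end {tp.end} exceeds sequence length {seq_len}", loc)
            )
        if tp.replicate < 0:
            out.append(_err("BAD_REPLICATE", "REP must be non-negative", loc))
        if not (0 <= tp.ptm_id <= MAX_PTM_ID):
            out.append(_err("BAD_PTM_ID", f"PTM_ID must be in [0, {MAX_PTM_ID}]", loc))
        if not (tp.time_s >= 0):  # also catches NaN
            out.append(_err("BAD_TIME", "TIME(SEC) must be non-negative or inf", loc))
        if tp.uptake_Da < UPTAKE_WARN_FLOOR:
            out.append(
                _warn(
                    "NEGATIVE_UPTAKE",
                    f"uptake {tp.uptake_Da:.2f} Da is below {UPTAKE_WARN_FLOOR} Da",
                    loc,
                )
            )
        if tp.envelope is not None and abs(tp.envelope.total - 1.0) > ENVELOPE_SUM_TOL:
            out.append(
                _err(
                    "ENVELOPE_SUM",
                    f"envelope sums to {tp.envelope.total:.4f}, expected 1 within {ENVELOPE_SUM_TOL}",
                    loc,
                )
            )
        if tp.envelope is not None and any(p < 0 for p in tp.envelope.peaks):
            out.append(_err("ENVELOPE_NEGATIVE", "envelope peaks must be non-negative", loc))

    # every group holding a mode letter above "A" must also hold mode "A"
    groups: dict[tuple, set[str]] = {}
    for tp in ds.timepoints:
        key = (tp.start, tp.end, tp.replicate, tp.ptm_id, tp.time_s)
        groups.setdefault(key, set()).add(tp.mode)
    for key, modes in groups.items():
        if "A" not in modes and any(m > "A" for m in modes):
            out.append(
                _err(
                    "MISSING_MODE_A",
                    f"peptide {key[0]}-{key[1]} rep {key[2]} t={key[4]} has modes "
                    f"{sorted(modes)} but no mode A",
                    "TP",
                )
            )
    return out


def _validate_ptms(ds: HXMSDataset) -> list[Violation]:
    out: list[Violation] = []
    seen: dict[int, int] = {}
    for j, ptm in enumerate(ds.ptms):
        loc = f"PTM[{j}]"
        if ptm.ptm_id == 0:
            out.append(_err("RESERVED_PTM_ID", "PTM_ID 0 means 'no PTM' and may not be defined", loc))
        elif not (0 < ptm.ptm_id <= MAX_PTM_ID):
            out.append(_err("BAD_PTM_ID", f"PTM_ID must be in [1, {MAX_PTM_ID}]", loc))
        if ptm.ptm_id in seen:
            out.append(_err("DUPLICATE_PTM_ID", f"PTM_ID {ptm.ptm_id} defined twice", loc))
        seen[ptm.ptm_id] = j
        if not ptm.content.strip():
            out.append(_err("EMPTY_PTM_CONTENT", "PTM content must be non-empty", loc))
    referenced = {tp.ptm_id for tp in ds.timepoints if tp.ptm_id != 0}
    for i, tp in enumerate(ds.timepoints):
        if tp.ptm_id != 0 and tp.ptm_id not in seen:
            out.append(
                _err("DANGLING_PTM_ID", f"PTM_ID {tp.ptm_id} has no PTM dictionary entry", f"TP[{i}]")
            )
    for j, ptm in enumerate(ds.ptms):
        if ptm.ptm_id != 0 and ptm.ptm_id not in referenced:
            out.append(
                _warn("UNUSED_PTM_ID", f"PTM_ID {ptm.ptm_id} is referenced by no timepoint", f"PTM[{j}]")
            )
    return out


def _validate_matches(ds: HXMSDataset) -> list[Violation]:
    out: list[Violation] = []
    indices = {tp.index: tp for tp in ds.timepoints}
    for k, m in enumerate(ds.matches):
        loc = f"MATCH[{k}]"
        if m.tp_id not in indices:
            out.append(_err("TP_ID_UNRESOLVED", f"TP_ID {m.tp_id} matches no timepoint INDEX", loc))
        if not (0.0 <= m.confidence <= 1.0):
            out.append(_err("BAD_CONF", f"CONF must lie in [0, 1], got {m.confidence}", loc))
        if m.rt_min < 0:
            out.append(_err("BAD_RT", "retention time must be non-negative", loc))
        if m.charge < 1:
            out.append(_err("BAD_CHARGE", "charge state must be a positive integer", loc))
        if not m.mono_mass_Da > 0:
            out.append(_err("BAD_MONO_MASS", "monoisotopic mass must be positive", loc))
        for g, group in enumerate(m.mz_structure):
            mzs = [p[0] for p in group.points]
            if any(mz <= 0 for mz in mzs):
                out.append(_err("BAD_MZ", "m/z values must be positive", f"{loc}.group[{g}]"))
            if any(b <= a for a, b in zip(mzs, mzs[1:])):
                out.append(
                    _err("MZ_NOT_INCREASING", "m/z must strictly increase within a group", f"{loc}.group[{g}]")
                )
            if any(p[1] < 0 for p in group.points):
                out.append(_err("BAD_INTENSITY", "intensities must be non-negative", f"{loc}.group[{g}]"))
        tp = indices.get(m.tp_id)
        if tp is not None and tp.envelope is not None and m.mz_structure:
            if len(m.mz_structure) != len(tp.envelope):
                out.append(
                    _warn(
                        "GROUP_COUNT_MISMATCH",
                        f"MATCH has {len(m.mz_structure)} M/Z groups but the linked envelope has "
                        f"{len(tp.envelope)} peaks",
                        loc,
                    )
                )
    return out


def validate_dataset(dataset: HXMSDataset) -> list[Violation]:
    """Check every format invariant and return the findings.

    Bad content is reported, never raised: the empty list means the
    dataset satisfies every HXMS v1.0 rule and carries all required
    metadata. Violations have stable codes (``MISSING_METADATA``,
    ``INDEX_GAP``, ``DANGLING_PTM_ID``, ``ENVELOPE_SUM``,
    ``START_GT_END``, ``TP_ID_UNRESOLVED``, ...) and a severity; writers
    refuse only error-severity findings.
    """
    out: list[Violation] = []
    out += _validate_metadata(dataset.metadata)
    out += _validate_timepoints(dataset)
    out += _validate_ptms(dataset)
    out += _validate_matches(dataset)
    return out


def renumber_indices(dataset: HXMSDataset) -> HXMSDataset:
    """Rewrite timepoint indices to 0..n-1 in file order, remapping
    MATCH ``tp_id`` keys consistently.

    Useful after filtering rows, which leaves INDEX gaps. Matches whose
    ``tp_id`` resolves to no surviving timepoint are kept unchanged (the
    validator will flag them as ``TP_ID_UNRESOLVED``). Returns a new
    dataset; the input is not modified.
    """
    remap = {tp.index: i for i, tp in enumerate(dataset.timepoints)}
    new_tps = [replace(tp, index=i) for i, tp in enumerate(dataset.timepoints)]
    new_matches = [
        replace(m, tp_id=remap.get(m.tp_id, m.tp_id)) for m in dataset.matches
    ]
    meta = replace(dataset.metadata, remarks=list(dataset.metadata.remarks))
    return HXMSDataset(
        metadata=meta,
        timepoints=new_tps,
        ptms=list(dataset.ptms),
        matches=new_matches,
    )
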