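"""Writer and reader for HXMS v1.0 text files.

Layout rules
------------
* Metadata lines are ``METADATA<tab>TITLE<tab>value`` (or ``REMARK``);
  the format version is emitted automatically as a REMARK.
* Tabular rows (TP / PTM / MATCH) are written fixed-width: each field is
  left-justified and space-padded to the column widths below, except the
  final variable-length field (ENVELOPE / CONTENT / M/Z) which is
  unpadded. No header row is emitted — the leading row tag types each
  line.
* The reader is tolerant: it accepts both fixed-width and tab-separated
  tabular rows (detected per row), sections in any order, and REMARK
  lines anywhere; unknown row tags are collected as warnings, not fatal.

Numeric serialization: TIME(SEC) in scientific notation with 6
fractional digits (``inf`` for fully deuterated controls), UPTAKE and
CONF at 2 decimals, RT at 3, MONO_M at 6, envelope peaks at 3. Writing
is deterministic: equal datasets yield byte-identical files. Encoding is
UTF-8 with ``\\n`` line endings.
"""

from __future__ import annotations

import math
import os
import warnings
from typing import IO, Mapping

from .errors import DatasetValidationError, FormatError
from .matchmz import decode_mz, encode_mz
from .model import (
    FORMAT_VERSION,
    INFINITE,
    HXMSDataset,
    IsotopicEnvelope,
    MatchRecord,
    Metadata,
    MetadataEntry,
    PTMEntry,
    Severity,
    TimepointRecord,
    validate_dataset,
)

__all__ = [
    "SerializationProfile",
    "DEFAULT_PROFILE",
    "write_hxms",
    "read_hxms",
    "format_time",
    "parse_time",
    "HXMSParseWarning",
]


class HXMSParseWarning(UserWarning):
    """Non-fatal oddity met while reading an HXMS file (unknown row tag,
    unknown metadata title, ...)."""


_VERSION_REMARK_TITLE = "HXMS_VERSION"

_META_TITLES = {
    "PROTEIN_SEQUENCE": "protein_sequence",
    "PROTEIN_NAME": "protein_name",
    "PROTEIN_STATE": "protein_state",
    "TEMPERATURE (K)": "temperature_K",
    "pH(READ)": "pH_read",
    "D_2_O_SATURATION": "d2o_saturation",
}
_FLOAT_META = {"TEMPERATURE (K)", "pH(READ)", "D_2_O_SATURATION"}


class SerializationProfile:
    """Column widths and numeric formats of the reference dialect.

    The widths are the format's published character counts; the final
    variable-length column of each row type carries width ``None``
    (unpadded).
    """

    tp_widths: Mapping[str, int | None] = {
        "TITLE": 12,
        "INDEX": 8,
        "MOD": 7,
        "START": 7,
        "END": 7,
        "REP": 5,
        "PTM_ID": 8,
        "TIME(SEC)": 16,
        "UPTAKE": 9,
        "ENVELOPE": None,
    }
    ptm_widths: Mapping[str, int | None] = {"TITLE": 12, "PTM_ID": 8, "CONTENT": None}
    match_widths: Mapping[str, int | None] = {
        "TITLE": 12,
        "TP_ID": 8,
        "CONF": 8,
        "RT(min)": 8,
        "Z": 5,
        "MONO_M": 16,
        "M/Z": None,
    }
    numeric_formats: Mapping[str, str] = {
        "UPTAKE": "%.2f",
        "ENVELOPE_PEAK": "%.3f",
        "CONF": "%.2f",
        "RT(min)": "%.3f",
        "MONO_M": "%.6f",
    }


DEFAULT_PROFILE = SerializationProfile()


# ---------------------------------------------------------------------------
# scalar field formats


def format_time(seconds: float) -> str:
    """TIME(SEC) notation: lowercase scientific with 6 fractional digits
    and a 2-digit signed exponent; ``INFINITE`` serializes as ``inf``."""
    seconds = float(seconds)
    if math.isnan(seconds):
        raise ValueError("time may not be NaN")
    if seconds == INFINITE:
        return "inf"
    if seconds < 0:
        raise ValueError(f"time must be non-negative, got {seconds}")
    return f"{seconds:.6e}"


def parse_time(text: str) -> float:
    """Inverse of :func:`format_time`; plain decimals also accepted."""
    token = text.strip()
    if token.lower() == "inf":
        return INFINITE
    try:
        value = float(token)
    except ValueError:
        raise FormatError("TIME(SEC) is not numeric and not 'inf'", token=token) from None
    if math.isnan(value) or value < 0:
        raise FormatError("TIME(SEC) must be non-negative", token=token)
    return value


def snap(value: float, fmt: str) -> float:
    """The float a value becomes after one serialize/parse round trip
    under printf format ``fmt`` (used by fixture generators so that their
    in-memory datasets round-trip bit-exactly)."""
    return float(fmt % float(value))


# ---------------------------------------------------------------------------
# writing


def _pad(text: str, width: int | None) -> str:
    return text if width is None else text.ljust(width)


def _write_metadata(meta: Metadata, out: list[str]) -> None:
    def metaline(title: str, value: str) -> None:
        out.append(f"METADATA\t{title}\t{value}")

    if meta.protein_sequence is not None:
        metaline("PROTEIN_SEQUENCE", meta.protein_sequence)
    if meta.protein_name is not None:
        metaline("PROTEIN_NAME", meta.protein_name)
    if meta.protein_state is not None:
        metaline("PROTEIN_STATE", meta.protein_state)
    if meta.temperature_K is not None:
        metaline("TEMPERATURE (K)", repr(float(meta.temperature_K)))
    if meta.pH_read is not None:
        metaline("pH(READ)", repr(float(meta.pH_read)))
    if meta.d2o_saturation is not None:
        metaline("D_2_O_SATURATION", repr(float(meta.d2o_saturation)))
    # the format version is added automatically, always
    out.append(f"REMARK\t{_VERSION_REMARK_TITLE}\t{meta.format_version}")
    for entry in meta.remarks:
        out.append(f"{entry.kind}\t{entry.title}\t{entry.value}")


def _tp_line(tp: TimepointRecord, profile: SerializationProfile) -> str:
    w = profile.tp_widths
    fmt = profile.numeric_formats
    fields = [
        _pad("TP", w["TITLE"]),
        _pad(str(tp.index), w["INDEX"]),
        _pad(tp.mode, w["MOD"]),
        _pad(str(tp.start), w["START"]),
        _pad(str(tp.end), w["END"]),
        _pad(str(tp.replicate), w["REP"]),
        _pad(f"{tp.ptm_id:04d}", w["PTM_ID"]),
        _pad(format_time(tp.time_s), w["TIME(SEC)"]),
        _pad(fmt["UPTAKE"] % tp.uptake_Da, w["UPTAKE"]),
    ]
    line = "".join(fields)
    if tp.envelope is not None:
        peak_fmt = fmt["ENVELOPE_PEAK"]
        line += ",".join(peak_fmt % p for p in tp.envelope.peaks)
    return line.rstrip()


def _ptm_line(ptm: PTMEntry, profile: SerializationProfile) -> str:
    w = profile.ptm_widths
    return (_pad("PTM", w["TITLE"]) + _pad(f"{ptm.ptm_id:04d}", w["PTM_ID"]) + ptm.content).rstrip()


def _match_line(m: MatchRecord, profile: SerializationProfile) -> str:
    w = profile.match_widths
    fmt = profile.numeric_formats
    line = "".join(
        [
            _pad("MATCH", w["TITLE"]),
            _pad(str(m.tp_id), w["TP_ID"]),
            _pad(fmt["CONF"] % m.confidence, w["CONF"]),
            _pad(fmt["RT(min)"] % m.rt_min, w["RT(min)"]),
            _pad(str(m.charge), w["Z"]),
            _pad(fmt["MONO_M"] % m.mono_mass_Da, w["MONO_M"]),
        ]
    )
    if m.mz_structure:
        line += encode_mz(m.mz_structure)
    return line.rstrip()


def write_hxms(
    dataset: HXMSDataset,
    dest: str | os.PathLike | IO[str] | None = None,
    profile: SerializationProfile = DEFAULT_PROFILE,
) -> str:
    """Serialize a dataset to HXMS v1.0 text.

    Sections are emitted in the fixed order metadata -> TP -> PTM ->
    MATCH. The dataset must carry no error-severity validation findings;
    otherwise :class:`~hxmsio.errors.DatasetValidationError` is raised
    (validate and repair first). Returns the text; when ``dest`` is a
    path or stream the text is also written there.
    """
    errors = [v for v in validate_dataset(dataset) if v.severity is Severity.ERROR]
    if errors:
        raise DatasetValidationError(errors)
    lines: list[str] = []
    _write_metadata(dataset.metadata, lines)
    for tp in dataset.timepoints:
        lines.append(_tp_line(tp, profile))
    for ptm in dataset.ptms:
        lines.append(_ptm_line(ptm, profile))
    for m in dataset.matches:
        lines.append(_match_line(m, profile))
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# reading


def _split_row(line: str, n_fixed: int) -> list[str]:
    """Split one tabular row into at most ``n_fixed`` leading fields plus
    an optional variable-length remainder.

    Tab-separated rows split on tabs; fixed-width rows split on runs of
    whitespace (no non-final field may contain spaces, so this recovers
    the columns without knowing the pad widths).
    """
    if "\t" in line:
        tokens = [t.strip() for t in line.split("\t")]
        while tokens and tokens[-1] == "":
            tokens.pop()
        return tokens
    return line.split(None, n_fixed)


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{what} is not an integer", line=lineno, token=token) from None


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{what} is not numeric", line=lineno, token=token) from None


def _parse_tp(line: str, lineno: int) -> TimepointRecord:
    tokens = _split_row(line, n_fixed=9)
    if len(tokens) < 9:
        raise FormatError(
            f"TP row has {len(tokens)} fields, expected at least 9", line=lineno
        )
    envelope = None
    if len(tokens) >= 10 and tokens[9].strip():
        try:
            peaks = [float(p) for p in tokens[9].strip().split(",")]
        except ValueError:
            raise FormatError("ENVELOPE peaks are not numeric", line=lineno, token=tokens[9]) from None
        envelope = IsotopicEnvelope(peaks)
    mode = tokens[2].strip()
    if len(mode) != 1:
        raise FormatError("MOD must be a single letter", line=lineno, token=mode)
    try:
        time_s = parse_time(tokens[7])
    except FormatError as exc:
        raise FormatError(str(exc), line=lineno) from None
    return TimepointRecord(
        index=_parse_int(tokens[1], "INDEX", lineno),
        mode=mode,
        start=_parse_int(tokens[3], "START", lineno),
        end=_parse_int(tokens[4], "END", lineno),
        replicate=_parse_int(tokens[5], "REP", lineno),
        ptm_id=_parse_int(tokens[6], "PTM_ID", lineno),
        time_s=time_s,
        uptake_Da=_parse_float(tokens[8], "UPTAKE", lineno),
        envelope=envelope,
    )


def _parse_ptm(line: str, lineno: int) -> PTMEntry:
    tokens = _split_row(line, n_fixed=2)
    if len(tokens) < 3 or not tokens[2].strip():
        raise FormatError("PTM row needs PTM_ID and CONTENT fields", line=lineno)
    return PTMEntry(ptm_id=_parse_int(tokens[1], "PTM_ID", lineno), content=tokens[2].strip())


def _parse_match(line: str, lineno: int) -> MatchRecord:
    tokens = _split_row(line, n_fixed=6)
    if len(tokens) < 6:
        raise FormatError(
            f"MATCH row has {len(tokens)} fields, expected at least 6", line=lineno
        )
    structure: tuple = ()
    if len(tokens) >= 7 and tokens[6].strip():
        try:
            structure = decode_mz(tokens[6])
        except FormatError as exc:
            raise FormatError(f"bad M/Z field: {exc}", line=lineno) from None
    return MatchRecord(
        tp_id=_parse_int(tokens[1], "TP_ID", lineno),
        confidence=_parse_float(tokens[2], "CONF", lineno),
        rt_min=_parse_float(tokens[3], "RT(min)", lineno),
        charge=_parse_int(tokens[4], "Z", lineno),
        mono_mass_Da=_parse_float(tokens[5], "MONO_M", lineno),
        mz_structure=structure,
    )


def _resolve_source(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, os.PathLike):
        with open(source, encoding="utf-8") as fh:
            return fh.read()
    if isinstance(source, str):
        # a path if it names an existing file and is not multi-line content
        if "\n" not in source and "\t" not in source and os.path.exists(source):
            with open(source, encoding="utf-8") as fh:
                return fh.read()
        return source
    raise TypeError(f"cannot read HXMS from {type(source).__name__}")


def read_hxms(source: str | os.PathLike | IO[str]) -> HXMSDataset:
    """Parse HXMS v1.0 text into a dataset.

    ``source`` may be file content, a path or an open text stream. Rows
    are dispatched on their leading tag; unknown tags raise an
    :class:`HXMSParseWarning` and are skipped. Structural problems (a row
    matching no known shape, duplicate required metadata, input with no
    metadata block at all) raise :class:`~hxmsio.errors.FormatError` with
    the line number; content-level problems are left to
    :func:`~hxmsio.model.validate_dataset`.
    """
    text = _resolve_source(source)
    meta = Metadata()
    seen_titles: set[str] = set()
    timepoints: list[TimepointRecord] = []
    ptms: list[PTMEntry] = []
    matches: list[MatchRecord] = []
    saw_metadata = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        tag = line.split("\t", 1)[0].split(None, 1)[0]
        if tag in ("METADATA", "REMARK"):
            saw_metadata = True
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{tag} line needs tag<tab>title<tab>value", line=lineno
                )
            title, value = parts[1].strip(), "\t".join(parts[2:]).strip()
            if tag == "METADATA" and title in _META_TITLES:
                if title in seen_titles:
                    raise FormatError(f"duplicate metadata {title!r}", line=lineno)
                seen_titles.add(title)
                if title in _FLOAT_META:
                    setattr(meta, _META_TITLES[title], _parse_float(value, title, lineno))
                else:
                    setattr(meta, _META_TITLES[title], value)
            elif tag == "REMARK" and title == _VERSION_REMARK_TITLE:
                meta.format_version = value
            else:
                if tag == "METADATA":
                    warnings.warn(
                        f"line {lineno}: unknown metadata title {title!r} kept as extra entry",
                        HXMSParseWarning,
                        stacklevel=2,
                    )
                meta.remarks.append(MetadataEntry(kind=tag, title=title, value=value))
        elif tag == "TP":
            timepoints.append(_parse_tp(line, lineno))
        elif tag == "PTM":
            ptms.append(_parse_ptm(line, lineno))
        elif tag == "MATCH":
            matches.append(_parse_match(line, lineno))
        else:
            warnings.warn(
                f"line {lineno}: unknown row tag {tag!r} skipped",
                HXMSParseWarning,
                stacklevel=2,
            )
    if not saw_metadata:
        raise FormatError("no metadata section found (empty or non-HXMS input)")
    return HXMSDataset(metadata=meta, timepoints=timepoints, ptms=ptms, matches=matches)
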