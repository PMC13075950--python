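"""Converters from vendor-export dialects to HXMS datasets.

Real vendor schemas are proprietary and version-dependent, so each
dialect here is a documented minimal schema (the column set a practical
export can be reduced to); tables with extra columns are accepted,
tables missing a required column fail with
:class:`~hxmsio.errors.SchemaError`. Comma- or tab-delimited input is
auto-detected.

Dialect capabilities follow the tools they model:

=================  =============  ==================  ==============
dialect            uptake direct  envelopes/spectra   PTM harvesting
=================  =============  ==================  ==============
custom             yes (or env.)  yes                 yes
dynamx             yes            no                  yes
hdx_workbench      recomputed     yes                 yes
hdexaminer         recomputed     yes (spectra file)  no (manual)
biopharma_finder   yes            no                  no (manual)
=================  =============  ==================  ==============

Where uptake is recomputed, the zero-timepoint centroid of each peptide
is identified per replicate (falling back to the average across the
replicates that have one, when a replicate is missing its 0 s point)
and subtracted from every timepoint centroid.

Fully deuterated control rows are recognized by a dialect-specific
sentinel in the time column: ``inf`` (custom, hdx_workbench), ``FD``
(dynamx, hdexaminer) or ``MAX`` (biopharma_finder).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .envelope import (
    PeptideSeries,
    SeriesKey,
    centroid,
    normalize_envelope,
    zero_reference_for_replicate,
)
from .errors import SchemaError
from .matchmz import decode_mz
from .model import (
    INFINITE,
    EnvelopePeakGroup,
    HXMSDataset,
    MatchRecord,
    Metadata,
    PTMEntry,
    TimepointRecord,
)

__all__ = [
    "DialectSpec",
    "DIALECTS",
    "parse_custom_csv",
    "parse_dynamx",
    "parse_hdx_workbench",
    "parse_hdexaminer",
    "parse_biopharma",
    "read_experiment_info",
    "convert_table",
]

_PROTON_MASS = 1.00727646688
_DEUTERIUM_INCREMENT = 1.00627674589


@dataclass(frozen=True)
class DialectSpec:
    """Name and capability flags of one supported export dialect."""

    name: str
    uptake_direct: bool
    envelopes_available: bool
    ptms_supported: bool
    fd_sentinel: str


DIALECTS: dict[str, DialectSpec] = {
    d.name: d
    for d in (
        DialectSpec("custom", True, True, True, "inf"),
        DialectSpec("dynamx", True, False, True, "FD"),
        DialectSpec("hdx_workbench", False, True, True, "inf"),
        DialectSpec("hdexaminer", False, True, False, "FD"),
        DialectSpec("biopharma_finder", True, False, False, "MAX"),
    )
}


# ---------------------------------------------------------------------------
# table plumbing


def _read_table(source) -> pd.DataFrame:
    """Load a delimited table (path, text, stream or DataFrame) with all
    cells as strings and normalized lower-case column names."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
        return df.astype(str)
    if hasattr(source, "read"):
        buf = source
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        buf = os.fspath(source)
    elif isinstance(source, str):
        buf = io.StringIO(source)
    else:
        raise TypeError(f"cannot read a table from {type(source).__name__}")
    try:
        df = pd.read_csv(buf, sep=None, engine="python", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError("empty export: table has no header row") from None
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: list[str], dialect: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{dialect} export is missing a required column", column=col)
    if len(df) == 0:
        raise SchemaError(f"empty export: {dialect} table has no data rows")


def _cell_int(value: str, column: str, row: int) -> int:
    try:
        return int(float(value))
    except ValueError:
        raise SchemaError(f"unparseable integer {value!r}", column=column, row=row) from None


def _cell_float(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"unparseable number {value!r}", column=column, row=row) from None


def _cell_time(value: str, sentinel: str, row: int) -> float:
    token = value.strip()
    if token.lower() in {sentinel.lower(), "inf", "infinite"}:
        return INFINITE
    t = _cell_float(token, "time", row)
    if t < 0:
        raise SchemaError(f"negative incubation time {t}", column="time", row=row)
    return t


def _cell_envelope(value: str, row: int) -> np.ndarray | None:
    token = value.strip()
    if not token:
        return None
    try:
        peaks = np.array([float(p) for p in token.replace(",", ";").split(";")])
    except ValueError:
        raise SchemaError(f"unparseable envelope {token!r}", column="envelope", row=row) from None
    return peaks


# ---------------------------------------------------------------------------
# shared assembly


def _recompute_uptake(raws: list[dict]) -> None:
    """Fill ``raw['uptake']`` from absolute centroids by zero-timepoint
    referencing (per replicate, averaging fallback).

    Each peptide's mode-"A" 0 s centroid is the reference for every mode
    of that peptide and replicate (0 s samples are taken as unimodal).
    """
    peptides: dict[tuple, list[dict]] = {}
    for raw in raws:
        peptides.setdefault((raw["start"], raw["end"], raw["ptm_text"]), []).append(raw)
    for (start, end, _ptm), rows in peptides.items():
        series_by_rep: dict[int, PeptideSeries] = {}
        for raw in rows:
            if raw["mode"] != "A":
                continue
            key = SeriesKey(start, end, raw["replicate"], 0, "A")
            s = series_by_rep.setdefault(raw["replicate"], PeptideSeries(key=key))
            s.points.append((raw["time_s"], raw["centroid"]))
        series_list = list(series_by_rep.values())
        for raw in rows:
            ref = zero_reference_for_replicate(series_list, raw["replicate"])
            raw["uptake"] = raw["centroid"] - ref


def _centroided_groups(peaks, mono: float, charge: int) -> tuple[EnvelopePeakGroup, ...]:
    """One single-point M/Z group per envelope peak, at the isotopologue's
    theoretical m/z with the peak's relative intensity (scaled 1e4)."""
    return tuple(
        EnvelopePeakGroup(
            [((mono + i * _DEUTERIUM_INCREMENT) / charge + _PROTON_MASS, p * 1.0e4)]
        )
        for i, p in enumerate(peaks)
    )


def _finalize(raws: list[dict], experiment_info: Metadata, harvest_ptms: bool) -> HXMSDataset:
    """Sort raw rows canonically, assign INDEX and PTM_IDs, and build the
    dataset. ``raw`` dicts carry start/end/replicate/mode/time_s/uptake
    plus optional envelope (array), ptm_text and match info."""
    raws = sorted(
        raws,
        key=lambda r: (r["start"], r["end"], r.get("ptm_text", ""), r["replicate"], r["time_s"], r["mode"]),
    )
    ptm_ids: dict[str, int] = {}
    if harvest_ptms:
        for raw in raws:
            text = raw.get("ptm_text", "")
            if text and text not in ptm_ids:
                ptm_ids[text] = len(ptm_ids) + 1
    timepoints: list[TimepointRecord] = []
    matches: list[MatchRecord] = []
    for i, raw in enumerate(raws):
        env = raw.get("envelope")
        timepoints.append(
            TimepointRecord(
                index=i,
                mode=raw["mode"],
                start=raw["start"],
                end=raw["end"],
                replicate=raw["replicate"],
                ptm_id=ptm_ids.get(raw.get("ptm_text", ""), 0) if harvest_ptms else 0,
                time_s=raw["time_s"],
                uptake_Da=float(raw["uptake"]),
                envelope=normalize_envelope(env) if env is not None else None,
            )
        )
        m = raw.get("match")
        if m is not None:
            matches.append(
                MatchRecord(
                    tp_id=i,
                    confidence=m["conf"],
                    rt_min=m["rt"],
                    charge=m["charge"],
                    mono_mass_Da=m["mono"],
                    mz_structure=m["groups"],
                )
            )
    ptms = [PTMEntry(ptm_id=n, content=text) for text, n in sorted(ptm_ids.items(), key=lambda kv: kv[1])]
    metadata = replace(experiment_info, remarks=list(experiment_info.remarks))
    return HXMSDataset(metadata=metadata, timepoints=timepoints, ptms=ptms, matches=matches)


# ---------------------------------------------------------------------------
# dialects


def parse_custom_csv(table, experiment_info: Metadata) -> HXMSDataset:
    """Convert the custom key-column CSV.

    Required columns: ``start, end, replicate, mode, time_s`` plus
    ``uptake`` and/or ``envelope``. Optional: ``ptm`` (free text; equal
    texts share one PTM_ID). Envelope cells hold semicolon-separated raw
    intensities, normalized on conversion. When the ``uptake`` column is
    absent, uptake is recomputed from envelope centroids with
    zero-timepoint referencing.
    """
    spec = DIALECTS["custom"]
    df = _read_table(table)
    _require(df, ["start", "end", "replicate", "mode", "time_s"], spec.name)
    if "uptake" not in df.columns and "envelope" not in df.columns:
        raise SchemaError("custom export needs an 'uptake' and/or 'envelope' column")
    direct = "uptake" in df.columns
    raws: list[dict] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(
            start=_cell_int(row.start, "start", row_no),
            end=_cell_int(row.end, "end", row_no),
            replicate=_cell_int(row.replicate, "replicate", row_no),
            mode=str(row.mode).strip() or "A",
            time_s=_cell_time(row.time_s, spec.fd_sentinel, row_no),
            ptm_text=str(getattr(row, "ptm", "")).strip(),
        )
        env = _cell_envelope(str(getattr(row, "envelope", "")), row_no)
        if env is not None:
            rec["envelope"] = env
        if direct:
            rec["uptake"] = _cell_float(row.uptake, "uptake", row_no)
        else:
            if env is None:
                raise SchemaError("row lacks both uptake and envelope", row=row_no)
            rec["centroid"] = centroid(env)
        raws.append(rec)
    if not direct:
        _recompute_uptake(raws)
    return _finalize(raws, experiment_info, harvest_ptms=spec.ptms_supported)


def parse_dynamx(table, experiment_info: Metadata) -> HXMSDataset:
    """Convert a DynamX-style uptake table.

    Required: ``start, end, exposure, uptake`` (uptake is taken as-is,
    giving a mean-deuteration-level HXMS file). Optional:
    ``modification`` (harvested into the PTM dictionary), ``replicate``.
    FD sentinel: ``exposure == "FD"``.
    """
    spec = DIALECTS["dynamx"]
    df = _read_table(table)
    _require(df, ["start", "end", "exposure", "uptake"], spec.name)
    raws = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        raws.append(
            dict(
                start=_cell_int(row.start, "start", row_no),
                end=_cell_int(row.end, "end", row_no),
                replicate=_cell_int(str(getattr(row, "replicate", "0")) or "0", "replicate", row_no),
                mode="A",
                time_s=_cell_time(row.exposure, spec.fd_sentinel, row_no),
                uptake=_cell_float(row.uptake, "uptake", row_no),
                ptm_text=str(getattr(row, "modification", "")).strip(),
            )
        )
    return _finalize(raws, experiment_info, harvest_ptms=spec.ptms_supported)


def parse_hdx_workbench(table, experiment_info: Metadata) -> HXMSDataset:
    """Convert an HDX Workbench-style per-charge centroid table.

    Required: ``start, end, timepoint, centroid`` (absolute neutral-mass
    centroid, Da). Optional: ``charge, replicate, abundance, envelope,
    modification, rt, monomass``. Rows of the same peptide, replicate
    and timepoint that differ only in charge state are merged by
    abundance-weighted envelope/centroid averaging. Uptake is recomputed
    by zero-timepoint referencing with the replicate-average fallback.
    When envelopes and ``monomass`` are present, ENVELOPE fields and
    centroided MATCH rows are emitted.
    """
    spec = DIALECTS["hdx_workbench"]
    df = _read_table(table)
    _require(df, ["start", "end", "timepoint", "centroid"], spec.name)
    grouped: dict[tuple, list[dict]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(
            start=_cell_int(row.start, "start", row_no),
            end=_cell_int(row.end, "end", row_no),
            replicate=_cell_int(str(getattr(row, "replicate", "0")) or "0", "replicate", row_no),
            time_s=_cell_time(row.timepoint, spec.fd_sentinel, row_no),
            centroid=_cell_float(row.centroid, "centroid", row_no),
            abundance=float(str(getattr(row, "abundance", "1")) or "1"),
            ptm_text=str(getattr(row, "modification", "")).strip(),
            charge=_cell_int(str(getattr(row, "charge", "1")) or "1", "charge", row_no),
            rt=float(str(getattr(row, "rt", "0")) or "0"),
            monomass=str(getattr(row, "monomass", "")).strip(),
        )
        rec["envelope"] = _cell_envelope(str(getattr(row, "envelope", "")), row_no)
        key = (rec["start"], rec["end"], rec["replicate"], rec["ptm_text"], rec["time_s"])
        grouped.setdefault(key, []).append(rec)

    raws = []
    for key, rows in grouped.items():
        weights = np.array([r["abundance"] for r in rows], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(rows))
        weights = weights / weights.sum()
        merged = dict(
            start=key[0],
            end=key[1],
            replicate=key[2],
            ptm_text=key[3],
            time_s=key[4],
            mode="A",
            centroid=float(np.dot(weights, [r["centroid"] for r in rows])),
        )
        envs = [r["envelope"] for r in rows]
        if all(e is not None for e in envs):
            width = max(e.size for e in envs)
            stack = np.zeros((len(envs), width))
            for j, e in enumerate(envs):
                stack[j, : e.size] = e / e.sum()
            merged["envelope"] = weights @ stack
        best = rows[int(np.argmax(weights))]
        if merged.get("envelope") is not None and best["monomass"]:
            mono = float(best["monomass"])
            peaks = merged["envelope"] / merged["envelope"].sum()
            merged["match"] = dict(
                conf=1.0,
                rt=best["rt"],
                charge=best["charge"],
                mono=mono,
                groups=_centroided_groups(peaks, mono, best["charge"]),
            )
        raws.append(merged)
    _recompute_uptake(raws)
    return _finalize(raws, experiment_info, harvest_ptms=spec.ptms_supported)


def parse_hdexaminer(table, experiment_info: Metadata, spectra=None) -> HXMSDataset:
    """Convert an HDExaminer-style results table, optionally with spectra.

    Results table required columns: ``start, end, time, centroid``
    (absolute, Da); optional ``replicate, mode`` (multimodal rows carry
    mode letters). Uptake is recomputed by zero-timepoint referencing
    against the mode-"A" 0 s centroid. PTMs are *not* harvested (this
    dialect cannot carry them; add PTM rows to the HXMS file manually).

    ``spectra`` is an optional companion table keyed by
    ``start, end, replicate, mode, time`` with columns
    ``conf, rt, charge, monomass, spectrum`` where ``spectrum`` holds the
    hierarchical comma/semicolon/colon m/z-intensity encoding. Matching
    records gain an ENVELOPE (per-group summed intensities, normalized)
    and a MATCH row preserving the fine structure.
    """
    spec = DIALECTS["hdexaminer"]
    df = _read_table(table)
    _require(df, ["start", "end", "time", "centroid"], spec.name)

    spectra_map: dict[tuple, dict] = {}
    if spectra is not None:
        sdf = _read_table(spectra)
        _require(sdf, ["start", "end", "time", "spectrum"], "hdexaminer spectra")
        for row_no, row in enumerate(sdf.itertuples(index=False), start=1):
            key = (
                _cell_int(row.start, "start", row_no),
                _cell_int(row.end, "end", row_no),
                _cell_int(str(getattr(row, "replicate", "0")) or "0", "replicate", row_no),
                (str(getattr(row, "mode", "A")).strip() or "A"),
                _cell_time(row.time, spec.fd_sentinel, row_no),
            )
            groups = decode_mz(str(row.spectrum))
            spectra_map[key] = dict(
                conf=float(str(getattr(row, "conf", "1")) or "1"),
                rt=float(str(getattr(row, "rt", "0")) or "0"),
                charge=_cell_int(str(getattr(row, "charge", "1")) or "1", "charge", row_no),
                mono=float(str(getattr(row, "monomass", "0")) or "0"),
                groups=groups,
            )

    raws = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(
            start=_cell_int(row.start, "start", row_no),
            end=_cell_int(row.end, "end", row_no),
            replicate=_cell_int(str(getattr(row, "replicate", "0")) or "0", "replicate", row_no),
            mode=(str(getattr(row, "mode", "A")).strip() or "A"),
            time_s=_cell_time(row.time, spec.fd_sentinel, row_no),
            centroid=_cell_float(row.centroid, "centroid", row_no),
            ptm_text="",
        )
        key = (rec["start"], rec["end"], rec["replicate"], rec["mode"], rec["time_s"])
        m = spectra_map.get(key)
        if m is not None:
            sums = np.array([sum(p[1] for p in g.points) for g in m["groups"]])
            if sums.sum() > 0:
                rec["envelope"] = sums
            rec["match"] = m
        raws.append(rec)
    _recompute_uptake(raws)
    return _finalize(raws, experiment_info, harvest_ptms=spec.ptms_supported)


def parse_biopharma(table, experiment_info: Metadata) -> HXMSDataset:
    """Convert a BioPharma Finder-style uptake table.

    Required: ``start, end, time, uptake`` (uptake used as-is). Optional:
    ``replicate``. FD sentinel: ``time == "MAX"``. No PTM or envelope
    support in this dialect.
    """
    spec = DIALECTS["biopharma_finder"]
    df = _read_table(table)
    _require(df, ["start", "end", "time", "uptake"], spec.name)
    raws = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        raws.append(
            dict(
                start=_cell_int(row.start, "start", row_no),
                end=_cell_int(row.end, "end", row_no),
                replicate=_cell_int(str(getattr(row, "replicate", "0")) or "0", "replicate", row_no),
                mode="A",
                time_s=_cell_time(row.time, spec.fd_sentinel, row_no),
                uptake=_cell_float(row.uptake, "uptake", row_no),
                ptm_text="",
            )
        )
    return _finalize(raws, experiment_info, harvest_ptms=spec.ptms_supported)


_PARSERS = {
    "custom": parse_custom_csv,
    "dynamx": parse_dynamx,
    "hdx_workbench": parse_hdx_workbench,
    "hdexaminer": parse_hdexaminer,
    "biopharma_finder": parse_biopharma,
}


def convert_table(dialect: str, table, experiment_info: Metadata, spectra=None) -> HXMSDataset:
    """Dispatch to the parser for ``dialect`` (see :data:`DIALECTS`)."""
    if dialect not in _PARSERS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(_PARSERS)}")
    if dialect == "hdexaminer":
        return parse_hdexaminer(table, experiment_info, spectra=spectra)
    if spectra is not None:
        raise ValueError(f"dialect {dialect!r} takes no spectra table")
    return _PARSERS[dialect](table, experiment_info)


_INFO_KEYS = {
    "PROTEIN_SEQUENCE": ("protein_sequence", str),
    "PROTEIN_NAME": ("protein_name", str),
    "PROTEIN_STATE": ("protein_state", str),
    "TEMPERATURE (K)": ("temperature_K", float),
    "TEMPERATURE_K": ("temperature_K", float),
    "pH(READ)": ("pH_read", float),
    "PH_READ": ("pH_read", float),
    "D_2_O_SATURATION": ("d2o_saturation", float),
    "D2O_SATURATION": ("d2o_saturation", float),
}


def read_experiment_info(source) -> Metadata:
    """Read the small key-value experiment-info file carrying the
    required metadata (``KEY<tab>value`` or ``KEY=value`` lines; ``#``
    comments ignored). Unknown keys become REMARK entries."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)
    meta = Metadata()
    from .model import MetadataEntry

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            key, _, value = line.partition("\t")
        else:
            key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _INFO_KEYS:
            attr, cast = _INFO_KEYS[key]
            setattr(meta, attr, cast(value))
        else:
            meta.remarks.append(MetadataEntry(kind="REMARK", title=key, value=value))
    return meta
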