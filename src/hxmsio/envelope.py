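"""Numeric core: envelope normalization, mean deuteration and uptake.

The conventional peptide-level HX-MS summary of an isotopic envelope is
its intensity-weighted mean peak position (the field calls this the
"centroid", i.e. mean deuteration). Deuterium uptake at time t is the
centroid at t minus the centroid of the same peptide's 0 s timepoint;
no back-exchange or D2O-saturation correction is applied — fully
deuterated controls exist precisely so that downstream analysis can make
that correction itself.

Adjacent envelope peaks are treated as exactly ``DEFAULT_PEAK_SPACING_DA``
= 1 dalton apart. The physical H->D increment (~1.00628 Da) and the 13C
spacing (~1.00336 Da) differ from 1 only at the third decimal, below the
2-decimal precision at which uptake is serialized; the spacing is an
explicit argument everywhere for callers who need the physical value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import MissingZeroError
from .model import HXMSDataset, IsotopicEnvelope

__all__ = [
    "DEFAULT_PEAK_SPACING_DA",
    "SeriesKey",
    "PeptideSeries",
    "normalize_envelope",
    "centroid",
    "compute_uptake",
    "zero_reference_for_replicate",
    "series_from_dataset",
]

#: Assumed mass gap between adjacent envelope peaks, in daltons.
DEFAULT_PEAK_SPACING_DA = 1.0


class SeriesKey(NamedTuple):
    start: int
    end: int
    replicate: int
    ptm_id: int
    mode: str


@dataclass
class PeptideSeries:
    """The time course of one peptide x replicate x mode.

    ``points`` is an ordered list of ``(time_s, value)`` pairs where the
    value is either a mean-deuteration centroid in daltons or an
    :class:`~hxmsio.model.IsotopicEnvelope` (centroided on demand).
    Times are non-decreasing with at most one point per time.
    """

    key: SeriesKey
    points: list[tuple[float, object]] = field(default_factory=list)

    def point_at(self, time_s: float):
        for t, v in self.points:
            if t == time_s:
                return v
        return None


def normalize_envelope(intensities: Sequence[float]) -> IsotopicEnvelope:
    """Scale raw peak intensities to unit sum.

    Raises ``ValueError`` on an empty, all-zero or negative input: such a
    spectrum carries no distribution to normalize.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("intensities must be a non-empty 1-D sequence")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    total = arr.sum()
    if not total > 0:
        raise ValueError("at least one intensity must be strictly positive")
    return IsotopicEnvelope(arr / total)


def centroid(
    envelope: IsotopicEnvelope | Sequence[float],
    peak_spacing_da: float = DEFAULT_PEAK_SPACING_DA,
) -> float:
    """Intensity-weighted mean peak index of an envelope, in daltons.

    ``sum(i * p_i) / sum(p_i)``, scaled by the peak spacing. For an
    envelope built from per-residue deuteration probabilities d_1..d_n
    (a Poisson-binomial), this equals ``sum(d_j)`` exactly.
    """
    peaks = envelope.peaks if isinstance(envelope, IsotopicEnvelope) else tuple(envelope)
    arr = np.asarray(peaks, dtype=float)
    total = arr.sum()
    if not total > 0:
        raise ValueError("cannot centroid an envelope with zero total intensity")
    return float(np.arange(arr.size) @ arr / total) * peak_spacing_da


def _as_centroid(value, peak_spacing_da: float) -> float:
    if isinstance(value, IsotopicEnvelope):
        return centroid(value, peak_spacing_da)
    return float(value)


def compute_uptake(
    series: PeptideSeries,
    zero_reference: float | None = None,
    peak_spacing_da: float = DEFAULT_PEAK_SPACING_DA,
) -> list[float]:
    """Deuterium uptake (Da) of every point in a series relative to 0 s.

    ``uptake(t) = centroid(t) - centroid(0 s)``. The 0 s point itself
    therefore maps to exactly 0; fully deuterated (``INFINITE``) points
    are referenced the same way as any other time. If the series has no
    0 s point, ``zero_reference`` (e.g. from
    :func:`zero_reference_for_replicate`) must be supplied, else
    :class:`~hxmsio.errors.MissingZeroError` is raised.
    """
    ref = None
    for t, v in series.points:
        if t == 0:
            ref = _as_centroid(v, peak_spacing_da)
            break
    if ref is None:
        if zero_reference is None:
            raise MissingZeroError(peptide=series.key)
        ref = float(zero_reference)
    return [_as_centroid(v, peak_spacing_da) - ref for _, v in series.points]


def zero_reference_for_replicate(
    all_series_for_peptide: Sequence[PeptideSeries],
    replicate: int,
    peak_spacing_da: float = DEFAULT_PEAK_SPACING_DA,
) -> float:
    """The 0 s centroid to reference a replicate's uptake against.

    Returns the replicate's own 0 s centroid when it has one; otherwise
    falls back to the arithmetic mean of the 0 s centroids of the sibling
    replicates that do. Raises :class:`~hxmsio.errors.MissingZeroError`
    when no replicate of the peptide has a 0 s point.
    """
    zeros: list[tuple[int, float]] = []
    for s in all_series_for_peptide:
        v = s.point_at(0)
        if v is not None:
            zeros.append((s.key.replicate, _as_centroid(v, peak_spacing_da)))
    for rep, c in zeros:
        if rep == replicate:
            return c
    if zeros:
        return float(np.mean([c for _, c in zeros]))
    key = all_series_for_peptide[0].key if all_series_for_peptide else None
    raise MissingZeroError(peptide=None if key is None else (key.start, key.end))


def series_from_dataset(dataset: HXMSDataset) -> list[PeptideSeries]:
    """Group a dataset's timepoints into per-(peptide, replicate, mode)
    series of envelope points (records without an envelope contribute
    their uptake value tagged as None and are skipped).

    Points are sorted by time with fully deuterated controls last.
    """
    grouped: dict[SeriesKey, PeptideSeries] = {}
    for tp in dataset.timepoints:
        key = SeriesKey(tp.start, tp.end, tp.replicate, tp.ptm_id, tp.mode)
        series = grouped.setdefault(key, PeptideSeries(key=key))
        if tp.envelope is not None:
            series.points.append((tp.time_s, tp.envelope))
    out = [s for s in grouped.values() if s.points]
    for s in out:
        s.points.sort(key=lambda p: p[0])
    return out
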