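"""Codec for the MATCH section's hierarchical M/Z field.

The field stores raw matched isotopic envelopes with three delimiter
levels: commas separate envelope peaks (one group per peak of the
matched timepoint's ENVELOPE), semicolons separate uncentroided
isotopologue fine-structure points within a peak, and a colon separates
each point's m/z value from its intensity::

    523.9764:2.076;523.9792:2698.8441;523.9820:1595.0798,524.3190:7.059;...

m/z is written at 4 decimals; intensities at 4 decimals with trailing
zeros trimmed.
"""

from __future__ import annotations

from typing import Sequence

from .errors import FormatError
from .model import (
    EnvelopePeakGroup,
    HXMSDataset,
    MatchRecord,
    Severity,
    Violation,
)

__all__ = ["encode_mz", "decode_mz", "link_match"]

_MZ_DECIMALS = 4


def _fmt_intensity(value: float) -> str:
    text = f"{value:.{_MZ_DECIMALS}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text or "0"


def encode_mz(groups: Sequence[EnvelopePeakGroup]) -> str:
    """Serialize peak groups to the comma/semicolon/colon M/Z notation."""
    if not groups:
        raise ValueError("M/Z field needs at least one envelope peak group")
    parts = []
    for group in groups:
        if len(group) == 0:
            raise ValueError("empty envelope peak group cannot be encoded")
        for mz, _ in group.points:
            if mz <= 0:
                raise ValueError(f"m/z must be positive, got {mz}")
        parts.append(
            ";".join(f"{mz:.{_MZ_DECIMALS}f}:{_fmt_intensity(i)}" for mz, i in group.points)
        )
    return ",".join(parts)


def decode_mz(text: str) -> tuple[EnvelopePeakGroup, ...]:
    """Parse an M/Z field back into peak groups.

    Whitespace around any delimiter is tolerated. A point lacking a
    colon, or with a non-numeric m/z or intensity, raises
    :class:`~hxmsio.errors.FormatError` naming the offending token.
    """
    if text is None or not text.strip():
        raise FormatError("empty M/Z field")
    groups = []
    for group_text in text.split(","):
        points = []
        for token in group_text.split(";"):
            token = token.strip()
            if not token:
                raise FormatError("empty point in M/Z group", token=group_text.strip())
            head, sep, tail = token.partition(":")
            if not sep:
                raise FormatError("M/Z point lacks a ':' separator", token=token)
            try:
                mz = float(head)
                intensity = float(tail)
            except ValueError:
                raise FormatError("non-numeric m/z or intensity", token=token) from None
            points.append((mz, intensity))
        groups.append(EnvelopePeakGroup(points))
    return tuple(groups)


def link_match(dataset: HXMSDataset, match: MatchRecord) -> list[Violation]:
    """Consistency report binding one MATCH record to its timepoint.

    Checks that ``tp_id`` resolves to an existing timepoint INDEX and,
    when that timepoint carries an ENVELOPE, that the number of M/Z
    groups equals the envelope's peak count. Mismatched counts are
    warnings (centroided-only exports legitimately store fewer groups);
    a dangling ``tp_id`` is an error. Nothing is raised.
    """
    report: list[Violation] = []
    by_index = {tp.index: tp for tp in dataset.timepoints}
    tp = by_index.get(match.tp_id)
    if tp is None:
        report.append(
            Violation(
                "TP_ID_UNRESOLVED",
                Severity.ERROR,
                f"TP_ID {match.tp_id} matches no timepoint INDEX",
                f"MATCH(tp_id={match.tp_id})",
            )
        )
        return report
    if tp.envelope is not None and match.mz_structure:
        n_groups = len(match.mz_structure)
        n_peaks = len(tp.envelope)
        if n_groups != n_peaks:
            report.append(
                Violation(
                    "GROUP_COUNT_MISMATCH",
                    Severity.WARNING,
                    f"{n_groups} M/Z groups vs {n_peaks} envelope peaks",
                    f"MATCH(tp_id={match.tp_id})",
                )
            )
    for g, group in enumerate(match.mz_structure):
        mzs = [p[0] for p in group.points]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            report.append(
                Violation(
                    "MZ_NOT_INCREASING",
                    Severity.ERROR,
                    "m/z must strictly increase within a group",
                    f"MATCH(tp_id={match.tp_id}).group[{g}]",
                )
            )
    return report
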