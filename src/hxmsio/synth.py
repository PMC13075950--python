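"""Ground-truthed synthetic HX-MS experiments and vendor-export fixtures.

The generator emulates the data shapes an HXMS file must carry —
peptide time courses with replicates, fully deuterated controls,
coexisting bimodal populations, PTM annotations and raw MATCH spectra —
from a simple forward model:

* per-residue exchange follows first-order kinetics,
  ``d_j(t) = saturation * (1 - exp(-k_j * t))``, with site rates drawn
  log-uniformly from ``rate_log10_range`` (s^-1);
* a peptide's isotopic envelope is the Poisson-binomial distribution of
  its number of incorporated deuterons, built by iterative convolution
  over the exchangeable residues (all residues except the peptide's
  first two, whose amide deuterons back-exchange too fast to observe);
* measurement noise is independent lognormal multiplicative noise per
  peak, followed by renormalization (so envelopes stay valid).

Everything derives from one seeded generator: the same seed yields
byte-identical outputs. What the model deliberately omits: intrinsic-
rate chemistry (Bai-Englander), EX1/EX2 kinetic regimes, retention-time
structure, and m/z calibration error.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .codec import format_time, snap, write_hxms
from .envelope import centroid
from .matchmz import encode_mz
from .model import (
    INFINITE,
    EnvelopePeakGroup,
    HXMSDataset,
    IsotopicEnvelope,
    MatchRecord,
    Metadata,
    PTMEntry,
    TimepointRecord,
)

__all__ = [
    "SynthConfig",
    "SynthExperiment",
    "simulate_residue_deuteration",
    "envelope_from_fractions",
    "generate_experiment",
]

# no prolines (no backbone amide H) and no ambiguous codes
_ALPHABET = np.array(list("ACDEFGHIKLMNQRSTVWY"))

#: residues at a peptide's N-terminus whose deuterons are lost to fast
#: back exchange and are not counted as exchangeable
N_TERM_NON_EXCHANGING = 2

_PHOSPHO_MASS = 79.966331  # HPO3
_PROTON_MASS = 1.00727646688
_DEUTERIUM_INCREMENT = 1.00627674589  # H -> D
_C13_FRACTION = 0.0107
_CARBONS_PER_RESIDUE = 5.1  # average over the 20 amino acids


@dataclass
class SynthConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a typical small bottom-up HX-MS run: a 60-residue
    protein tiled by 8 peptides, a 4-decade spread of site exchange
    rates, timepoints from 30 s to 1 h plus a 0 s reference and a fully
    deuterated control, duplicate measurements, 91% D2O saturation and
    2% multiplicative peak noise.
    """

    seed: int = 0
    sequence_length: int = 60
    n_peptides: int = 8
    times_s: Sequence[float] = (0.0, 30.0, 300.0, 3600.0, INFINITE)
    n_replicates: int = 2
    d2o_saturation: float = 0.91
    rate_log10_range: tuple[float, float] = (-4.0, -0.5)
    bimodal_fraction: float = 0.25
    noise_sd: float = 0.02
    ptm_probability: float = 0.15
    include_match: bool = True
    fine_structure: bool = False
    natural_isotopes: bool = False
    protein_name: str = "SYNTH-1"
    protein_state: str = "APO"
    temperature_K: float = 293.15
    pH_read: float = 6.0

    def __post_init__(self):
        if 0.0 not in self.times_s:
            raise ValueError("times_s must include the 0 s reference timepoint")
        if not (0.0 < self.d2o_saturation <= 1.0):
            raise ValueError("d2o_saturation must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_residue_deuteration(
    rates: Sequence[float], time_s: float, saturation: float
) -> np.ndarray:
    """Per-residue deuteration fractions after ``time_s`` seconds.

    First-order exchange: ``d_j = saturation * (1 - exp(-k_j * t))``.
    A fully deuterated control (``time_s = INFINITE``) saturates every
    residue.
    """
    k = np.asarray(rates, dtype=float)
    if np.any(k <= 0):
        raise ValueError("exchange rates must be positive")
    if math.isnan(time_s) or time_s < 0:
        raise ValueError(f"time must be non-negative or INFINITE, got {time_s}")
    if time_s == INFINITE:
        return np.full(k.shape, float(saturation))
    return saturation * -np.expm1(-k * float(time_s))


def envelope_from_fractions(fractions: Sequence[float]) -> IsotopicEnvelope:
    """Poisson-binomial deuteron-count distribution of a peptide.

    ``peak[i]`` is the probability that exactly ``i`` of the exchanging
    residues carry a deuteron, built by convolving one two-point
    distribution per residue. Length is ``n_residues + 1``; the mean of
    the result equals ``sum(fractions)`` (the closed-form Poisson-
    binomial mean), which is what makes recovered uptake checkable
    against ground truth.
    """
    d = np.asarray(fractions, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("deuteration fractions must lie in [0, 1]")
    dist = np.array([1.0])
    for dj in d:
        dist = np.convolve(dist, [1.0 - dj, dj])
    return IsotopicEnvelope(dist)


def _binom_pmf(n: int, p: float, k_max: int) -> np.ndarray:
    """Truncated binomial pmf for the natural 13C isotope pattern."""
    k = np.arange(k_max + 1)
    log_pmf = (
        np.array([math.lgamma(n + 1) - math.lgamma(kk + 1) - math.lgamma(n - kk + 1) for kk in k])
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )
    return np.exp(log_pmf)


@dataclass
class SynthExperiment:
    """Bundle returned by :func:`generate_experiment`."""

    config: SynthConfig
    dataset: HXMSDataset
    #: dialect name -> export table; ``hdexaminer`` maps to a dict with
    #: ``results`` and ``spectra`` tables
    exports: dict
    #: one row per timepoint record with ground-truth and noisy uptake
    truth: pd.DataFrame
    #: per-residue exchange rates (s^-1), 1-based positions
    site_rates: pd.DataFrame

    def write(self, out_dir: str | os.PathLike) -> dict[str, str]:
        """Write the reference HXMS file, all dialect CSVs and the truth
        tables into ``out_dir``; returns the mapping of names to paths."""
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths: dict[str, str] = {}

        def save(name: str, frame: pd.DataFrame) -> None:
            path = os.path.join(out_dir, f"{name}.csv")
            frame.to_csv(path, index=False)
            paths[name] = path

        hxms_path = os.path.join(out_dir, "reference.hxms")
        write_hxms(self.dataset, hxms_path)
        paths["hxms"] = hxms_path
        for name, table in self.exports.items():
            if isinstance(table, dict):
                for sub, frame in table.items():
                    save(f"{name}_{sub}", frame)
            else:
                save(name, table)
        truth_path = os.path.join(out_dir, "truth.tsv")
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        rates_path = os.path.join(out_dir, "site_rates.tsv")
        self.site_rates.to_csv(rates_path, sep="\t", index=False)
        paths["site_rates"] = rates_path
        return paths


def _peptide_mono_mass(sequence: str, phospho: bool) -> float:
    m = _ptmass.calculate_mass(sequence=sequence, monoisotopic=True)
    return m + (_PHOSPHO_MASS if phospho else 0.0)


def _match_groups(
    peaks: Sequence[float], mono: float, charge: int, fine: bool
) -> tuple[EnvelopePeakGroup, ...]:
    groups = []
    for i, p in enumerate(peaks):
        center = (mono + i * _DEUTERIUM_INCREMENT) / charge + _PROTON_MASS
        if fine:
            offsets, weights = (-0.003, 0.0, 0.003), (0.25, 0.5, 0.25)
        else:
            offsets, weights = (0.0,), (1.0,)
        pts = [
            (snap(center + off, "%.4f"), snap(p * 1.0e4 * wt, "%.4f"))
            for off, wt in zip(offsets, weights)
        ]
        groups.append(EnvelopePeakGroup(pts))
    return tuple(groups)


def _time_sentinel(t: float, sentinel: str) -> str:
    return sentinel if t == INFINITE else repr(float(t))


def generate_experiment(
    config: SynthConfig, out_dir: str | os.PathLike | None = None
) -> SynthExperiment:
    """Simulate one experiment and derive every artifact from it.

    Returns the reference :class:`~hxmsio.model.HXMSDataset` (with all
    numeric fields pre-rounded to serialization precision, so writing
    and re-reading it is an exact identity), the five vendor-dialect
    export tables, and the ground-truth table. With ``out_dir`` set, all
    of it is also written to disk.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seq = "".join(rng.choice(_ALPHABET, size=cfg.sequence_length))
    lo, hi = cfg.rate_log10_range
    site_rates = 10.0 ** rng.uniform(lo, hi, size=cfg.sequence_length)

    # --- peptides (random tiling, unique start/end spans) -------------
    peptides = []
    spans: set[tuple[int, int]] = set()
    attempts = 0
    while len(peptides) < cfg.n_peptides and attempts < 50 * cfg.n_peptides:
        attempts += 1
        length = int(rng.integers(8, 16))
        start = int(rng.integers(1, max(2, cfg.sequence_length - length + 1)))
        end = min(start + length - 1, cfg.sequence_length)
        if (start, end) in spans:
            continue
        spans.add((start, end))
        pep_seq = seq[start - 1 : end]
        bimodal = bool(rng.random() < cfg.bimodal_fraction)
        slow_factor = float(10.0 ** rng.uniform(-2.5, -1.0)) if bimodal else 1.0
        has_ptm = bool(rng.random() < cfg.ptm_probability)
        ptm_pos = int(rng.integers(start, end + 1)) if has_ptm else 0
        ptm_text = f"Phosphoryl STY ({ptm_pos})" if has_ptm else ""
        charge = int(rng.integers(2, 5))
        rt = snap(rng.uniform(5.0, 15.0), "%.3f")
        mono = snap(_peptide_mono_mass(pep_seq, has_ptm), "%.6f")
        peptides.append(
            dict(
                start=start,
                end=end,
                seq=pep_seq,
                bimodal=bimodal,
                slow_factor=slow_factor,
                ptm_text=ptm_text,
                charge=charge,
                rt=rt,
                mono=mono,
            )
        )
    peptides.sort(key=lambda p: (p["start"], p["end"], p["ptm_text"]))

    ptm_ids: dict[str, int] = {}
    for pep in peptides:
        if pep["ptm_text"] and pep["ptm_text"] not in ptm_ids:
            ptm_ids[pep["ptm_text"]] = len(ptm_ids) + 1

    times = sorted(float(t) for t in cfg.times_s)

    # --- master record loop -------------------------------------------
    records: list[dict] = []
    zero_centroid: dict[tuple[int, int], float] = {}
    for ip, pep in enumerate(peptides):
        rates = site_rates[pep["start"] - 1 + N_TERM_NON_EXCHANGING : pep["end"]]
        nat = None
        if cfg.natural_isotopes:
            n_c = max(1, round(_CARBONS_PER_RESIDUE * (pep["end"] - pep["start"] + 1)))
            nat = _binom_pmf(n_c, _C13_FRACTION, k_max=4)
            nat = nat / nat.sum()
        for rep in range(cfg.n_replicates):
            for t in times:
                modes = ["A"]
                if pep["bimodal"] and t > 0:
                    modes.append("B")
                for mode in modes:
                    k = rates if mode == "A" else rates * pep["slow_factor"]
                    fractions = simulate_residue_deuteration(k, t, cfg.d2o_saturation)
                    env = envelope_from_fractions(fractions)
                    peaks = np.asarray(env.peaks)
                    if nat is not None:
                        peaks = np.convolve(peaks, nat)
                    if cfg.noise_sd > 0:
                        peaks = peaks * np.exp(rng.normal(0.0, cfg.noise_sd, peaks.size))
                        peaks = peaks / peaks.sum()
                    c_noisy = centroid(peaks)
                    if t == 0 and mode == "A":
                        zero_centroid[(ip, rep)] = c_noisy
                    records.append(
                        dict(
                            pep=ip,
                            start=pep["start"],
                            end=pep["end"],
                            replicate=rep,
                            mode=mode,
                            time_s=t,
                            d_sum=float(np.sum(fractions)),
                            peaks=peaks,
                            centroid_noisy=c_noisy,
                            conf=snap(rng.uniform(0.8, 1.0), "%.2f"),
                        )
                    )

    for r in records:
        r["uptake_noisy"] = r["centroid_noisy"] - zero_centroid[(r["pep"], r["replicate"])]

    records.sort(key=lambda r: (r["start"], r["end"], r["replicate"], r["time_s"], r["mode"]))

    # --- reference dataset (serialization-rounded) --------------------
    metadata = Metadata(
        protein_sequence=seq,
        protein_name=cfg.protein_name,
        protein_state=cfg.protein_state,
        temperature_K=cfg.temperature_K,
        pH_read=cfg.pH_read,
        d2o_saturation=cfg.d2o_saturation,
    )
    timepoints: list[TimepointRecord] = []
    match_rows: list[MatchRecord] = []
    for i, r in enumerate(records):
        pep = peptides[r["pep"]]
        env = IsotopicEnvelope([snap(p, "%.3f") for p in r["peaks"]])
        t_snapped = r["time_s"] if r["time_s"] == INFINITE else float(format_time(r["time_s"]))
        timepoints.append(
            TimepointRecord(
                index=i,
                mode=r["mode"],
                start=r["start"],
                end=r["end"],
                replicate=r["replicate"],
                ptm_id=ptm_ids.get(pep["ptm_text"], 0),
                time_s=t_snapped,
                uptake_Da=snap(r["uptake_noisy"], "%.2f"),
                envelope=env,
            )
        )
        if cfg.include_match:
            match_rows.append(
                MatchRecord(
                    tp_id=i,
                    confidence=r["conf"],
                    rt_min=pep["rt"],
                    charge=pep["charge"],
                    mono_mass_Da=pep["mono"],
                    mz_structure=_match_groups(
                        env.peaks, pep["mono"], pep["charge"], cfg.fine_structure
                    ),
                )
            )
    ptms = [PTMEntry(ptm_id=i, content=text) for text, i in sorted(ptm_ids.items(), key=lambda kv: kv[1])]
    dataset = HXMSDataset(metadata=metadata, timepoints=timepoints, ptms=ptms, matches=match_rows)

    # --- dialect export tables ----------------------------------------
    def pep_of(r):
        return peptides[r["pep"]]

    custom = pd.DataFrame(
        {
            "start": [r["start"] for r in records],
            "end": [r["end"] for r in records],
            "replicate": [r["replicate"] for r in records],
            "mode": [r["mode"] for r in records],
            "time_s": [_time_sentinel(r["time_s"], "inf") for r in records],
            "uptake": [f"{r['uptake_noisy']:.6f}" for r in records],
            "envelope": [";".join(f"{p:.6f}" for p in r["peaks"]) for r in records],
            "ptm": [pep_of(r)["ptm_text"] for r in records],
        }
    )

    a_records = [r for r in records if r["mode"] == "A"]
    dynamx = pd.DataFrame(
        {
            "start": [r["start"] for r in a_records],
            "end": [r["end"] for r in a_records],
            "modification": [pep_of(r)["ptm_text"] for r in a_records],
            "replicate": [r["replicate"] for r in a_records],
            "exposure": [_time_sentinel(r["time_s"], "FD") for r in a_records],
            "uptake": [f"{r['uptake_noisy']:.6f}" for r in a_records],
        }
    )

    wb_rows: list[dict] = []
    for r in a_records:
        pep = pep_of(r)
        for zi, abundance in ((0, 0.7), (1, 0.3)):
            wb_rows.append(
                dict(
                    start=r["start"],
                    end=r["end"],
                    replicate=r["replicate"],
                    charge=pep["charge"] + zi,
                    timepoint=_time_sentinel(r["time_s"], "inf"),
                    centroid=f"{pep['mono'] + r['centroid_noisy']:.6f}",
                    abundance=abundance,
                    envelope=";".join(f"{p:.6f}" for p in r["peaks"]),
                    modification=pep["ptm_text"],
                    rt=pep["rt"],
                    monomass=f"{pep['mono']:.6f}",
                )
            )
    workbench = pd.DataFrame(wb_rows)

    hdx_results = pd.DataFrame(
        {
            "start": [r["start"] for r in records],
            "end": [r["end"] for r in records],
            "replicate": [r["replicate"] for r in records],
            "mode": [r["mode"] for r in records],
            "time": [_time_sentinel(r["time_s"], "FD") for r in records],
            "centroid": [f"{pep_of(r)['mono'] + r['centroid_noisy']:.6f}" for r in records],
        }
    )
    hdx_spectra = pd.DataFrame(
        {
            "start": [r["start"] for r in records],
            "end": [r["end"] for r in records],
            "replicate": [r["replicate"] for r in records],
            "mode": [r["mode"] for r in records],
            "time": [_time_sentinel(r["time_s"], "FD") for r in records],
            "conf": [f"{r['conf']:.2f}" for r in records],
            "rt": [f"{pep_of(r)['rt']:.3f}" for r in records],
            "charge": [pep_of(r)["charge"] for r in records],
            "monomass": [f"{pep_of(r)['mono']:.6f}" for r in records],
            "spectrum": [
                encode_mz(
                    _match_groups(
                        [snap(p, "%.3f") for p in r["peaks"]],
                        pep_of(r)["mono"],
                        pep_of(r)["charge"],
                        cfg.fine_structure,
                    )
                )
                for r in records
            ],
        }
    )

    biopharma = pd.DataFrame(
        {
            "start": [r["start"] for r in a_records],
            "end": [r["end"] for r in a_records],
            "replicate": [r["replicate"] for r in a_records],
            "time": [_time_sentinel(r["time_s"], "MAX") for r in a_records],
            "uptake": [f"{r['uptake_noisy']:.6f}" for r in a_records],
        }
    )

    exports = {
        "custom": custom,
        "dynamx": dynamx,
        "hdx_workbench": workbench,
        "hdexaminer": {"results": hdx_results, "spectra": hdx_spectra},
        "biopharma_finder": biopharma,
    }

    truth = pd.DataFrame(
        {
            "start": [r["start"] for r in records],
            "end": [r["end"] for r in records],
            "replicate": [r["replicate"] for r in records],
            "mode": [r["mode"] for r in records],
            "time_s": [r["time_s"] for r in records],
            "d_sum": [r["d_sum"] for r in records],
            "uptake_true": [r["d_sum"] for r in records],
            "uptake_noisy": [r["uptake_noisy"] for r in records],
        }
    )
    rates_frame = pd.DataFrame(
        {"position": np.arange(1, cfg.sequence_length + 1), "rate_per_s": site_rates}
    )

    experiment = SynthExperiment(
        config=cfg,
        dataset=dataset,
        exports=exports,
        truth=truth,
        site_rates=rates_frame,
    )
    if out_dir is not None:
        experiment.write(out_dir)
    return experiment
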