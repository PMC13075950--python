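# Methods

## Scope

`hxmsio` implements the HXMS v1.0 flat-file format for peptide-level
hydrogen/deuterium-exchange mass spectrometry (HX-MS) data and the
surrounding machinery: model + validator, writer/reader, the M/Z codec
for raw matched spectra, vendor-dialect converters with uptake
recomputation, and a ground-truthed synthetic generator. It does not
parse raw instrument files (mzML etc.), perform peptide identification,
fit protection factors or exchange rates, deconvolve bimodal spectra, or
correct for back exchange.

## The format semantics as implemented

* **Sections.** `METADATA`/`REMARK` lines are tab-delimited
  (`tag<tab>title<tab>value`). `TP`, `PTM` and `MATCH` rows are written
  fixed-width with each field left-justified and space-padded to the
  format's published character counts (TP: 12/8/7/7/7/5/8/16/9; PTM:
  12/8; MATCH: 12/8/8/8/5/16), the final variable-length field
  (ENVELOPE / CONTENT / M/Z) unpadded. The pad character is not fixed by
  the format description, so the reader additionally accepts
  tab-separated rows, detected per row; fixed-width rows are recovered
  by whitespace splitting with a bounded field count (no non-final field
  can contain spaces), which also tolerates width overruns. Sections are
  written in the order metadata → TP → PTM → MATCH and accepted in any
  order; REMARK lines are legal anywhere. No per-section header row is
  emitted: the leading row tag already types each line.
* **Numeric precision.** TIME(SEC) is lowercase scientific notation
  with 6 fractional digits (`0.000000e+00`), `inf` for fully deuterated
  controls; UPTAKE and CONF 2 decimals; RT 3; MONO_M 6; envelope peaks
  3; m/z and intensities 4 (intensities with trailing zeros trimmed, as
  in the format's own examples). The published character budget for
  ENVELOPE ("4 per peak") is ambiguous against its 5-character example
  values; 3 decimals per peak reproduces the example byte-for-byte and
  keeps round-trip drift below 5e-4 per peak. In-memory values keep full
  precision; only serialization rounds.
* **PTM_ID** is an integer in [0, 9999], serialized zero-padded to 4
  digits. ID 0 is reserved to mean "no PTM" and may not be defined in
  the PTM dictionary (the format's own example table pairs `0000` with a
  real modification, which contradicts the stated default; the reserved
  reading is enforced here because converters must be able to rely on
  it). Mode letters are capped at A–Z; every group of records holding a
  mode above "A" must also hold the "A" record.
* **Validation** is report-based: `validate_dataset` returns a list of
  coded findings and never raises on bad content, so malformed files can
  be loaded, inspected and repaired (`renumber_indices` closes INDEX
  gaps and remaps MATCH keys). Uptake below −1 Da is a warning, not an
  error: small negative uptake is ordinary measurement noise and the
  format nowhere forbids it. The writer refuses only error-severity
  findings.
* **TP_ID ≡ INDEX.** The MATCH key is bound to the timepoint INDEX; the
  format description leaves open whether it is an independent counter,
  and a shared key is the only reading that makes `renumber_indices`
  well-defined.

## Centroid, uptake and zero referencing

The centroid of an envelope is $\sum_i i\,p_i / \sum_i p_i$ with
adjacent peaks treated as exactly 1 Da apart (`peak_spacing_da`
argument to override). The physical H→D increment (≈1.00628 Da) and the
¹³C spacing (≈1.00336 Da) differ from 1 below the 2-decimal precision at
which uptake is serialized, so the unit spacing is the default rather
than a per-isotopologue mass axis.

Uptake is `centroid(t) − centroid(0 s)` per peptide, replicate and
mode; the 0 s point maps to exactly 0 and FD (`inf`) points are
referenced the same way. No natural-isotope-abundance deconvolution is
performed: uptake is a difference, so a time-invariant natural envelope
shape cancels in the subtraction. When a replicate lacks a 0 s point the
reference falls back to the arithmetic mean of the sibling replicates'
0 s centroids; if no replicate has one, `MissingZeroError` is raised.
Multimodal records are referenced against the mode-"A" 0 s centroid,
because 0 s samples are undeuterated and therefore unimodal; there is no
field in the format for the relative abundance of coexisting modes, so
none is modeled.

## Vendor dialects

Exact vendor schemas are proprietary; each converter accepts a
documented minimal column set (extra columns ignored, missing required
columns fail with `SchemaError`), chosen so that a practical export can
be reduced to it with a spreadsheet. Capabilities mirror the modeled
tools: `dynamx` and `biopharma_finder` report uptake directly (used
as-is, mean-deuteration-level output); `hdx_workbench` and `hdexaminer`
report absolute centroids, from which uptake is recomputed by the zero
referencing above, and can carry envelopes/spectra; PTM text is
harvested into the dictionary for `custom`, `dynamx` and
`hdx_workbench` only. FD rows are recognized by per-dialect sentinels in
the time column (`inf`, `FD`, `MAX`), a necessarily implementation-
defined choice. Workbench per-charge rows of the same peptide, replicate
and timepoint are merged by abundance-weighted envelope and centroid
averaging (keep-best-charge is available by filtering the table before
conversion). Converter output is canonically ordered (peptide,
replicate, time, mode), so identical input bytes yield identical HXMS
bytes.

## Synthetic experiments

The generator emulates the data shapes the format must carry, not the
chemistry of any particular protein:

* per-residue exchange is first-order,
  $d_j(t) = s\,(1 - e^{-k_j t})$, with site rates log-uniform over
  `rate_log10_range` (default 10⁻⁴–10⁻⁰·⁵ s⁻¹, spanning the sub-second
  to hours window typical of bottom-up experiments) and D₂O saturation
  *s* (default 0.91);
* a peptide's envelope is the Poisson-binomial distribution of its
  deuteron count, by iterative convolution; its mean is exactly
  $\sum_j d_j$, which is what makes converter-recovered uptake checkable
  against ground truth. The first two residues of each peptide are
  non-exchanging (fast back-exchange convention; the generator's random
  sequences contain no proline, sidestepping the missing-amide case);
* defaults: 60-residue sequence, 8 unique peptides of length 8–15,
  timepoints {0, 30, 300, 3600, ∞} s, 2 replicates, 25% bimodal
  peptides (mode-B rates slowed 10–300×, emitted for every t > 0), 15%
  PTM probability (phospho-style annotations, +79.966 Da on MONO_M), 2%
  lognormal multiplicative peak noise with renormalization (keeps
  envelopes valid); natural ¹³C structure optionally convolved (default
  off) for realistic MATCH fine structure;
* the returned reference dataset has every numeric field pre-rounded to
  serialization precision, so write→read is an exact identity; the
  truth table keeps full precision. All five dialect export tables are
  derived from the same noisy realization, so cross-converter checks
  compare like with like.

What passing tests on these fixtures does **not** show: robustness to
real chromatographic artifacts, overlapping envelopes, charge-state
disagreement, EX1/EX2 kinetics beyond a two-population mixture, or
vendor files that deviate from the documented minimal schemas.

## Numerical and testing choices

Envelope unit-sum is validated to 5e-3 (absorbing 3-decimal rounding);
the Poisson-binomial convolution is compared against brute-force
enumeration over all 2ⁿ outcomes for n ≤ 10 at 1e-12; converter-
recovered uptake must match simulation truth within 0.01 Da on
noise-free fixtures (the 2-decimal serialization floor). Round-trip
identity is exercised over 100 seeded configurations covering bimodal,
PTM, FD, MATCH and fine-structure cases; problem sizes (3–8 peptides,
30–60 residues) keep the full suite in a few seconds while still
exercising every format feature. Hypothesis-based property tests run
derandomized. The command-line layer uses exit codes 0 (ok), 1 (empty
selection), 2 (I/O or schema), 3 (validation errors).
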