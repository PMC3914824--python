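# Methods

## Signal model and assumptions

The pipeline treats a single EEG channel as a piecewise-stationary
process: a concatenation of quasi-stationary stretches, each dominated
by a small set of narrowband oscillations in 1–30 Hz over a 1/f-plus-
white background. The observable is the *shape* of the short-term power
spectrum, not its absolute magnitude — every comparison in the
classifier is a Pearson correlation, which is invariant to positive
rescaling of the spectrum. Consequently no re-referencing is performed
(the reference changes power magnitude and topography, not SP shape),
power is kept on the raw linear scale, and the periodogram's absolute
scaling constant is irrelevant (plain |DFT|² of the Hann-tapered frame
is used).

Frequencies above 30 Hz are out of scope; channels are analysed
independently throughout (local states, not global microstates).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| target_fs | 128 | Hz | analysis rate; higher-rate recordings are polyphase-downsampled (alias-free below 64 Hz); upsampling is rejected |
| highpass_cutoff | 1 | Hz | 4th-order Butterworth, zero-phase (filtfilt); removes DC/drift so the amplitude rule sees a zero-mean signal |
| artifact_amp | 80 | µV | epoch rejected iff any sample on any channel is strictly above this in magnitude (a sample at exactly 80 µV is kept) |
| epoch_len | 60 (20 for short protocols) | s | processing unit; windows and segments never cross epochs |
| window_len / shift | 2 s / 50 samples | — | 256-sample Hann window, 0.390625 s lag; gives 0.5 Hz bins, 59 in-band, 149 windows per 60-s channel |
| peak_threshold | 0.60 | fraction | a dominant peak is a strict local maximum above 60% of the SP maximum |
| cc_accept | 0.71 | r | smallest two-decimal correlation with r² > 0.5: accepted pairs share a majority of variance |
| shift_bins | 1 | bins | correlations maximised over shifts {−1, 0, +1} (±0.5 Hz peak jitter) |
| mutual_cc_max | 0.71 | r | admission to the standard set requires correlation below this with every admitted template; reuses the sole stated similarity criterion rather than inventing a second threshold |
| min_count | 2 | — | a candidate signature must recur; "highest count" implies recurrence |
| subject_fraction | 0.80 | — | cluster enters a repertoire iff present (≥1 window, ≥1 channel) for ≥80% of subjects |
| universal_fraction | 0.85 | — | universal iff N₁ ≥ ceil(0.85·C); with C = 13 the cut is 12 |
| polyrhythmic_min_peaks | 5 | peaks | smallest majority of the ten default sub-bands |

The sub-band map (delta 1–3.5, theta₁ 4–5, theta₂ 5.5–6, theta₃
6.5–7.5, alpha₁ 8–9, alpha₂ 9.5–10.5, alpha₃ 11–12.5, beta₁ 13–17.5,
beta₂ 18–23.5, beta₃ 24–30 Hz) is conventional, carried as
configuration, and only used for labelling output tables — no
computation branches on it.

## Numerical and tie-breaking choices

- **"Identical SPs" for counting** are SPs with the same dominant-peak
  signature (same set of peak bins). Exact floating equality would
  never recur; the signature is the invariant part of an SP's shape.
- **Peaks on plateaus**: a run of equal values counts as one peak at its
  leftmost bin, and only when the run is strictly above both external
  neighbours; edge bins compare against their single neighbour. A flat
  or all-zero spectrum has no peaks.
- **Zero-variance overlap** in a correlation is defined as r = 0.
- **Ties** are broken deterministically everywhere: candidate ranking by
  (higher count, earlier first occurrence in pool order); final labels
  by lower class id; cluster seeding by (higher window count, lower
  class id).
- **Shift correction** is applied uniformly — in standard-set admission,
  attribution and final classification alike.
- **Empty classes at actualization** keep the study-wide standard
  template, flagged; if an actual template's peaks move more than one
  bin from the standard's, a warning is logged (actualization should
  reshape the spectrum, not move its main peaks).
- **Sub-threshold windows** get the unrestricted argmax label with a
  low-confidence flag: labelling is total by construction, and the flag
  preserves the information that adaptivity fell short.
- **Degenerate pools** (no recurring peaked signature, e.g. flat noise)
  raise an error rather than fabricating a template.
- **Segment duration** spans first-window onset to last-window offset:
  (n−1)·0.390625 + 2 s. Boundaries are only defined up to the 0.39-s
  lag; this convention is stated and used consistently. No smoothing is
  applied (minimum segment = 1 window).
- **Chance model**: Binomial(C, 0.5) conditioned on ≥1 occurrence,
  because only observed clusters enter the table (switchable to the
  unconditioned form). Categories with zero chance mass (possible at
  small C) are dropped from the chi-square comparison. The chi-square
  for percent-change comparisons is computed on the underlying
  repertoire-size counts, and the construction used is emitted with the
  result, since a contingency layout is not otherwise determined.
- A 20-s epoch yields floor((2560−256)/50)+1 = 47 windows by the window
  formula; the formula's value is always used.

## The synthetic generator

`spstates.synthetic` generates the ground truth every stage is tested
against. A state is a set of sinusoids (frequencies in [1, 30] Hz,
amplitudes in µV) plus white Gaussian noise and a spectrally shaped 1/f
("pink") component; tone phases are drawn per segment from the seeded
generator, so records are bit-reproducible while state boundaries stay
phase-incoherent. Channels are independent realizations of the same
state plan via per-channel substreams spawned from the root seed.

Two levels exist:

- `gen_piecewise_record` glues arbitrary state segments inside one
  record and returns per-window truth labels (window-centre membership,
  which is unambiguous for overlapping windows). This is the fixture
  for segmentation-boundary recovery.
- `gen_study` builds a multi-subject, multi-condition study from a
  `StudyDesign` (per-state condition sets and occurrence
  probabilities). Each subject expresses each allowed state by an
  independent Bernoulli draw, and **each expressed state occupies one
  epoch-length block**, so state changes coincide with epoch boundaries
  and no analysis window mixes two states. This choice isolates what
  study-level recovery should test (clustering, repertoires,
  universality) from transition effects, which `gen_piecewise_record`
  covers separately; transition windows genuinely contain two states'
  spectra and, in studies designed with within-epoch gluing, can form
  low-count two-peak classes of their own — real behaviour of the
  method, but noise for a truth-table comparison.

Default study conditions used in validation: single-tone states of
20 µV over 1 µV white + 1 µV pink background (tone-to-floor power ratio
far above the 60% peak rule's sensitivity), tones ≥ 3.5 Hz apart
(pairwise template correlations ≪ 0.71), 20-s epochs, 2 channels, 3–5
subjects, 13 conditions for universality designs. These are desk-scale
stand-ins for the original pools of 10⁴–10⁶ SPs: large enough that
every designed signature recurs hundreds of times, small enough that
the full suite runs in seconds.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: volume conduction and
inter-channel correlation, ocular/muscle artifacts, non-sinusoidal or
amplitude-modulated oscillations, spectral drift within a state, and
realistic between-subject variability of peak frequency beyond the
±0.5 Hz the clustering absorbs. Recovery rates near 100% on these
fixtures demonstrate correctness of the machinery, not expected
performance on clinical EEG.

## Known limitations

- The standard set is study-specific by design; no transfer of
  templates across studies is provided.
- ICA-based artifact removal and visual artifact marking are out of
  scope; an amplitude rule plus an optional user-supplied exclusion of
  epochs (simply drop them before analysis) is the only cleaning.
- `min_count = 2` is permissive for very large pools; genuinely rare
  transient shapes can enter the standard set. Raising `min_count` (or
  inspecting per-class counts, which are reported) is advisable for
  pools above ~10⁵ SPs.
- EDF writing is not implemented (reading is, via mne); synthetic
  datasets are written as delimited text plus a manifest.
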