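# Methods

This note documents the models, parameter choices and numerical decisions
behind `fpvs`, and what the synthetic-data tests do and do not establish
about real recordings.

## Paradigm and design model

A stimulation sequence presents one item every 1/*f*<sub>base</sub> s
(*f*<sub>base</sub> = 10 Hz) for 60 s, flanked by 2-s fade-in/out ramps.
Every 5th presentation (positions 5, 10, …, counted from 1) is a deviant,
so deviants recur at exactly 2 Hz and a 60-s sequence holds 600
presentations: 480 base items and 120 deviants.  Two balancing schemes are
supported: *set size* control (30 base vs 30 deviant items; base items
then repeat 16× vs 4×) and *item repetition* control (120 base vs 30
deviant items; every item repeats exactly 4×).  A session is two
task-blocked halves (central-cross vs flanking-bars colour monitoring) of
4 conditions × 3 repetitions = 24 sequences.

**Scheduler.** Items are assigned to deviant/base slots by
shuffle-with-rejection: both multisets are shuffled, interleaved in the
B B B B D pattern, and adjacent label repeats are repaired by swapping
with a randomly chosen same-role position that introduces no new clash;
after 10,000 failed attempts a scheduling error is raised (reachable only
for degenerate inputs such as single-item sets).  The underlying
randomization of the original acquisition software is not documented
anywhere we know of; any schedule satisfying the periodicity, count and
no-immediate-repeat constraints is equivalent for the frequency-domain
analysis, which depends only on the deviant timing.

**Task events.** Eight 200-ms colour changes per sequence are placed
uniformly at random with a minimum 1.0-s gap (uniform-spacings
construction: sorted uniforms plus fixed offsets), restricted to the 60-s
stimulation window so fades stay event-free.  In the cross task every
event is a go trial; in the bars task both bars change together with
probability 0.5 (go) and one side only otherwise, left/right
equiprobable, giving 4 expected go trials per sequence.  The minimum gap
and the exact go/no-go randomization are design choices; the protocol
specifies only the event count, duration and "random" timing.

## Synthetic EEG

The generator writes 68-channel recordings (Biosemi-64 labels plus PO9,
I1, I2, PO10) at 1024 Hz.  Each recording is a sum of deterministic
steady-state responses and stochastic noise:

- **Oddball response**: cosines at 2/4/6/8 Hz with default peak
  amplitudes 0.30/0.22/0.15/0.10 µV, phase-locked to stimulation onset,
  weighted by a left occipito-temporal topography peaking at PO7 with
  right-hemisphere homologues at roughly one third — emulating the
  left-dominant word-discrimination response.  Defaults put the
  single-sequence summed response near 0.5 µV before referencing, the
  order of magnitude of published group values.
- **Base-rate response**: cosines at 10/20/30/40 Hz (1.0/0.5/0.25/0.12
  µV) over a medial-occipital topography (Oz, Iz, O1, O2 strongest).
- **Noise**: per-channel independent 1/f noise generated by spectral
  shaping of complex Gaussian coefficients (`σ(f) ∝ f^(−exponent/2)`,
  random phases), calibrated so the expected amplitude-spectrum value at
  1 Hz on a 60-s window equals `pink_scale` (default 0.15 µV — a noise
  floor of ≈0.05–0.1 µV per 1/60-Hz bin in the 2–10 Hz range, a plausible
  single-sequence occipital floor); optional narrow-band alpha (off by
  default) and white sensor noise (SD 0.02 µV).

Responses ramp linearly over the fades.  All response frequencies are
commensurate with the 60-s window, so after cycle cropping every injected
component sits exactly on an FFT bin.

**Average-reference ground truth.**  Common-average referencing subtracts
the across-channel mean, so a topography with mean weight w̄ leaves
channel *c* with effective weight *w<sub>c</sub>* − w̄; since amplitude
spectra are magnitudes, the recoverable amplitude is |*w<sub>c</sub>* −
w̄|·A.  The generator stores these *referenced* per-channel amplitudes in
the recording sidecar and all recovery oracles compare against them.

**What the generator does not emulate**: eye blinks, muscle and movement
artifacts, electrode drift, inter-channel noise correlations, non-
stationarity, or realistic inter-participant variability in topography
and amplitude.  Passing recovery and lateralization tests therefore
demonstrates correctness of the analysis chain, not robustness to
artifact-ridden data.

## Preprocessing

Fixed order: FFT band-pass (hard spectral mask 0.1–100 Hz, zero-phase;
an optional raised-cosine transition is available for ringing-sensitive
uses) → segmentation −2 to +62 s around stimulation onset → polyphase
resampling to 512 Hz → bad-channel interpolation → common-average
reference → cropping from onset to the largest whole number of 500-ms
oddball cycles (120 cycles, 30,720 samples; last retained timestamp
30,719/512 = 59.998 s).  Segmentation is relative to stimulation onset
(end of fade-in), since the sequence item-count arithmetic covers exactly
the 60-s window; a `pre_s`/`post_s` switch allows fade-relative windows.

Bad-channel interpolation is inverse-distance weighting over the k = 4
nearest good electrodes on the unit sphere ("linear interpolation" in the
field's toolboxes is not specified further); electrode positions come
from MNE's standard 10-05 montage.  Sample indexing is 0-based and epoch
timestamps are sample/fs.

## Spectral analysis

Amplitude spectra use a plain FFT of the cropped window — no taper, no
zero padding — because the responses are bin-locked by design and a
rectangular window keeps exact-bin amplitudes unbiased.  Normalization is
2|X|/N (DC and Nyquist unscaled), so a cosine of peak amplitude A µV on a
bin reads A µV.  The bin spacing is 1/duration ≈ 0.0167 Hz for the
120-cycle window (conventionally printed truncated as .016 Hz).

## Oddball statistics

Two neighbouring-bin noise windows reconcile the two conventions used in
the field, both exposed in `NoiseWindowSpec`:

- **SNR window**: the 10 bins on each side of the target (20 bins,
  adjacent included).
- **Z / baseline window**: 12 bins per side, minus the bin adjacent to
  the target on each side, minus the single global minimum and maximum of
  the remaining 22 (ties broken toward the lowest bin index) — 20 bins.

z uses the sample SD (n−1).  A zero-SD window (possible only on
degenerate synthetic input) yields an infinite z with a warning rather
than an exception.  Harmonic selection applies z > 3.1 once on a
grand-averaged, ROI-averaged spectrum and the selected set is then used
unchanged for every participant; per-harmonic baseline-subtracted
amplitudes (negative values retained) are summed per participant, task,
condition and ROI.  Multiples of the base rate are always excluded from
oddball candidates because oddball and general visual responses
superimpose there.

**Individual-level z of the summed response** (`summed_amplitude_z`,
default `method="sum"`): the non-corrected target amplitudes are summed
over the selected harmonics, and the null distribution is formed by
summing, for each relative window offset, the amplitudes at that offset
across the same harmonics; min/max trimming is applied to the summed
values and z = (sum − mean)/SD.  An alternative `method="mean_z"`
(average of per-harmonic z-scores × √k) is provided since the aggregation
rule for summed amplitudes is a genuine open choice; the default keeps
the statistic on the same footing as the single-bin z.

### Calibration of the z-criterion

The z statistic estimates its mean and SD from only 20 bins, and the
min/max trimming biases the SD estimate downward.  Both effects make the
criterion *anticonservative*: even for exactly Gaussian bin values,
(x − x̄)/s with a trimmed 20-bin window exceeds 1.64 about 10% of the
time, not 5%; on FFT amplitude bins of Gaussian noise (Rayleigh-
distributed) the measured rates in this package's Monte-Carlo are
P(z > 1.64) ≈ 0.117 and P(z > 3.1) ≈ 0.021 per bin (≥20,000 simulated
bins).  The acceptance suite states the nominal 5%/0.35% expectation and
is allowed to fail there, documenting the gap; the regular test suite
pins the measured operating characteristics instead.  Users should read
individual-level "z > 1.64" decisions as a liberal screening criterion,
not a calibrated 5% test.

## ROIs, reports, behaviour

Default ROIs: LROI = {PO7, P7, P9, PO9, O1}, its mirror RROI = {PO8, P8,
P10, PO10, O2}, and MO = {Oz, Iz, O1, O2} for the base-rate response.
The published description fixes only "5 electrodes around PO7", so the
set is configurable and every report echoes the channels actually used.
Behavioural scoring matches each keypress to the earliest unmatched go
event whose response window (default 0.15–1.0 s after onset; no window is
specified in the protocol) contains it; unmatched presses are false
alarms, with the false-alarm rate per no-go trial when no-go trials exist
(bars task) and per go trial otherwise.  Group inferential statistics
(rm-ANOVA, Bayes factors) are deliberately out of scope; the tidy TSV
exports feed external tools.

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale versions of the
study: 1–4 simulated participants, 1–2 repetitions per cell, synthesis at
512 Hz where the resampling step is exercised separately, 100 seeded runs
for lateralization and ≥20,000 bins for null calibration.  These sizes
were chosen as the package's own trade-off between Monte-Carlo error and
turnaround; the full 22-participant, 24-sequence, 1024-Hz protocol is the
configuration default and runs unchanged, just longer.  All randomness
derives from a single root seed via `numpy` seed sequences; identical
seeds reproduce plans, recordings and result tables byte for byte.

## Known limitations

- The baseline-subtraction estimator is negatively biased under noise
  (E|signal+noise| at the target bin grows by ≈σ²/2|S| while the full
  noise mean is subtracted), so noisy summed amplitudes underestimate the
  injected ground truth; the bias shrinks with time-domain averaging.
  Recovery oracles therefore use noiseless data.
- The z-criterion is anticonservative (see above).
- EDF/BDF reading is supported through MNE, but the packaged fixture
  container (raw float32 matrix + JSON sidecar) is the primary format;
  EDF writing is not implemented.
- No artifact rejection/ICA, no notch filter, no topographic plotting.
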