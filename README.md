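# fpvs — frequency-tagging oddball EEG analysis

`fpvs` is a Python package for designing, simulating and analysing
**fast periodic visual stimulation (FPVS) oddball** EEG experiments, the
frequency-tagging paradigm used to measure automatic category
discrimination (for example, words embedded in streams of pseudowords or
nonwords).

In this paradigm, stimuli are presented at a fast base rate *f*<sub>base</sub>
(10 Hz) and every 5th item is a *deviant* from a contrasting category, so
deviants recur at *f*<sub>odd</sub> = *f*<sub>base</sub>/5 = 2 Hz.  Any neural
process that distinguishes the categories produces a response exactly at
*f*<sub>odd</sub> and its harmonics (4, 6, 8 Hz, ...), while general visual
processing projects to *f*<sub>base</sub> and its harmonics.  Because the
responses are confined to known frequency bins, they can be quantified
without subtraction conditions, at the level of single participants.

## What it computes

For a target bin with amplitude *x* and a set of neighbouring noise bins
*N* (20 bins):

- **SNR** = *x* / mean(*N*), with *N* the 10 bins on each side of the
  target.  Baseline level 1 under pure noise.
- **Baseline-subtracted amplitude** = *x* − mean(*N*), in µV, with *N* the
  12 bins per side minus the immediately adjacent bin on each side and
  minus the single global minimum and maximum (20 bins).
- **Z-score** = (*x* − mean(*N*)) / SD(*N*), thresholded one-tailed at
  *z* > 3.1 (*p* < .001) for group-level harmonic selection and *z* > 1.64
  (*p* < .05) for individual-level significance.
- **Summed harmonic response** = Σ baseline-subtracted amplitudes over
  the significant harmonics of *f*<sub>odd</sub>, excluding every multiple
  of *f*<sub>base</sub>.

The package covers the whole chain: oddball sequence design with the
set-size / item-repetition controls and orthogonal go/no-go task events;
a synthetic 68-channel EEG generator with 1/f noise and known injected
responses; the preprocessing chain (FFT band-pass 0.1–100 Hz,
segmentation −2 to +62 s, resampling to 512 Hz, bad-channel
interpolation, common-average reference, cropping to 120 oddball cycles);
amplitude spectra with exact bin bookkeeping; ROI aggregation
(left/right occipito-temporal and medial-occipital); and behavioural
hit/false-alarm/RT scoring.

## Worked example

Simulate one 60-s sequence (600 items, 120 word deviants among nonwords)
with the default left-lateralized oddball response and 1/f noise, run the
full preprocessing chain, and quantify the discrimination response in the
left occipito-temporal ROI:

```python
from fpvs import (NoiseSpec, amplitude_spectrum, bin_stats, default_rois,
                  plan_sequence, preprocess, roi_average, sum_harmonics,
                  summed_amplitude_z, synthesize_recording)
from fpvs.design import demo_stimulus_sets

stim = demo_stimulus_sets(seed=0)
words, nonwords = stim[("NWW", "set_size")]
plan = plan_sequence(words, nonwords, control_type="set_size", seed=1)

rec = synthesize_recording(plan, noise=NoiseSpec(), fs_hz=1024.0, seed=1)
epoch = preprocess(rec)                  # filter/segment/resample/reref/crop
spec = amplitude_spectrum(epoch)         # df = 1/60 Hz, exact-bin responses
lroi = roi_average(spec, default_rois()["LROI"])

for f in (2.0, 4.0, 6.0, 8.0, 10.0):
    b = bin_stats(lroi, f)
    print(f"{f:4.1f} Hz  amp={b.amp:.3f} uV  SNR={b.snr:5.2f}  "
          f"corrected={b.corrected_amp:+.3f} uV  z={b.z:6.2f}")
summary = sum_harmonics(lroi, [2.0, 4.0, 6.0, 8.0])
z = summed_amplitude_z(lroi, [2.0, 4.0, 6.0, 8.0])
print(f"summed corrected amplitude (2-8 Hz): "
      f"{summary.summed_corrected_amp:.3f} uV, z = {z:.2f}")
```

Output:

```
 2.0 Hz  amp=0.214 uV  SNR= 1.90  corrected=+0.103 uV  z=  4.24
 4.0 Hz  amp=0.158 uV  SNR= 2.22  corrected=+0.088 uV  z=  7.51
 6.0 Hz  amp=0.114 uV  SNR= 1.87  corrected=+0.056 uV  z=  4.60
 8.0 Hz  amp=0.080 uV  SNR= 1.53  corrected=+0.025 uV  z=  3.08
10.0 Hz  amp=0.243 uV  SNR= 5.02  corrected=+0.196 uV  z= 17.91
summed corrected amplitude (2-8 Hz): 0.272 uV, z = 9.10
```

Reading: single-sequence oddball responses at 2–8 Hz stand clearly above
the neighbouring-bin noise floor in the left ROI (z up to 7.5), the
base-rate response at 10 Hz is much larger still (SNR 5), and the summed
discrimination response is 0.27 µV with an individual-level z of 9.1 —
far above the 1.64 criterion.

## Command line

```sh
fpvs simulate --out data/ --participants 4 --seed 1    # synthetic dataset
fpvs analyze  --data data/ --out results/ --seed 1     # tidy TSV tables
fpvs report   --results results/                       # console summary
```

A YAML configuration (`--config run.yaml`, see `fpvs.config.RunConfig`)
drives every stage; all randomness flows from the single root seed, and
reruns are byte-identical.

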