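# vibrokit

Analysis toolkit for **vibroscapes** — the ensemble of substrate-borne
vibrations (arthropod signals, bird song transmitted into the ground,
anthropogenic noise) recorded by contact-microphone arrays on a forest
floor. It targets studies of vibratory communication in ground-dwelling
arthropods such as *Schizocosa* wolf spiders: long unattended recordings,
strong and variable background noise, and signals organised as pulses →
bouts → signaling activities.

The package covers the full chain from raw WAV to ecology statistics:

1. **Adaptive denoising** (`vibrokit.denoise`). Each 10-min chunk gets its
   own amplitude threshold *T = m + ασ* (median *m* and standard deviation
   *σ* of the rectified signal; α chosen on a 1.0–10.0 grid by the elbow of
   the count-above-threshold curve). The longest stretch whose loudness
   stays below *T* provides the chunk's background-noise spectrum, and a
   stationary spectral gate removes time–frequency cells consistent with
   that noise.
2. **Event detection** (`vibrokit.events`). Pulses are local maxima above a
   re-selected threshold on the denoised signal. Inter-pulse intervals are
   modelled with a 3-component Gaussian mixture on log10 intervals
   (within-bout / between-bout / between-activity) and pulses are grouped
   into bouts at every non-within-bout interval. Catalog rules mirror field
   protocol: a 60-s same-sensor merge, collapse of simultaneous multi-sensor
   detections into single *airborne* events, and a strict >100-occurrence
   type filter.
3. **Acoustic features** (`vibrokit.features`). Bout duration; dominant
   frequency as the median over non-silent 0.1-s STFT frames (10-Hz
   resolution, 0.05-s hop); idle duration from labelled signal components
   (the complexity proxy for *S. stridulans* courtship).
4. **Niche statistics** (`vibrokit.niche`). Events are binned along four
   niche dimensions — substrate (or plot), calendar date, 96 × 15-min
   time-of-day bins, 10-Hz dominant-frequency bins — and pairwise overlap is
   Pianka's index

   PI<sub>ij</sub> = Σ<sub>k</sub> P<sub>ik</sub>P<sub>jk</sub> /
   √(Σ<sub>k</sub> P<sub>ik</sub>² · Σ<sub>k</sub> P<sub>jk</sub>²),

   with temporal overlap the product of the date and time-of-day indices and
   overall overlap the product over all four dimensions.
5. **Interaction windows** (`vibrokit.interaction`). For each focal bout,
   counts and normalized Shannon diversity (H/ln n) of co-occurring events
   within ±15 min at the same sensor, conspecific/heterospecific relative
   abundances, and regression-ready tables (model fitting itself is left to
   standard mixed-model software).
6. **Synthetic scenes** (`vibrokit.scenes`). A generator of recordings with
   exact ground truth — colored noise, damped-sinusoid pulse trains with
   three-scale lognormal interval structure, planted quiet gaps — plus a
   catalog sampler with analytic niche-distribution targets, and scoring of
   detections against truth.

## Worked example

```python
import numpy as np
from vibrokit import audio_io, denoise, events, scenes

spec = scenes.default_scene(seed=1)          # 10 min, pink noise, 20 bouts,
wave, truth = scenes.render_scene(spec)      # 10 dB peak SNR, 400 Hz pulses

chunk = audio_io.RecordingChunk(waveform=wave)
result = denoise.denoise_chunk(chunk)
bouts, detection = events.segment_chunk(result.chunk, seed=1)

score = scenes.score_detection(
    np.array([p.time for p in detection.pulses]),
    [(b.start_s, b.end_s) for b in bouts],
    truth,
)
print(f"threshold T = {detection.scan.threshold.T:.3f} mV "
      f"(alpha = {detection.scan.selected_alpha})")
print(f"pulses: {len(detection.pulses)}, bouts: {len(bouts)}")
print(f"precision {score.pulse_precision:.3f}  recall {score.pulse_recall:.3f}  "
      f"bout recovery {score.bout_recovery:.2f}")
```

prints

```
threshold T = 0.371 mV (alpha = 4.3)
pulses: 122, bouts: 20
precision 0.984  recall 0.984  bout recovery 1.00
```

i.e. on a 10-min scene with 122 planted pulses in 20 bouts, the adaptive
threshold settles at 0.371 mV, 120 of 122 detections land within 5 ms of a
true pulse, and every bout boundary is recovered within 0.5 s.

A command-line interface exposes the same stages
(`vibrokit simulate | chunk | denoise | detect | label | niche | windows`).

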