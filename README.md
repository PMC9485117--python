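# hdring

Analysis of head-direction (HD) cells — neurons in the anterodorsal thalamus
(ADn) and connected circuits whose firing rate peaks when the animal's head
points in a particular allocentric direction. The package implements the
standard single-cell and population analyses used to ask how sensory cues
anchor the HD system, together with a synthetic ring-attractor session
generator so every analysis can be exercised, with ground truth, without any
recorded data.

It is written for systems-neuroscience researchers analysing open-field
electrophysiology: spike trains plus a head-direction/position trace.

## What it computes

**Tuning and classification.** Tuning curves over sixty 6° bins: spikes are
assigned the angle of the nearest tracking sample, counts are normalized by
the occupancy of each bin, and the rate is smoothed with a wrapped Gaussian
(σ = 3 bins). From the curve: mean/peak rate, mean resultant vector length
R̄ ∈ [0, 1], full-width-at-half-maximum tuning width, preferred firing
direction (PFD, the argmax bin), and directional information

&nbsp;&nbsp;&nbsp;&nbsp;I = Σⱼ Pⱼ (λⱼ/λ) log₂(λⱼ/λ)  [bits/spike],

with Pⱼ the occupancy probability and λⱼ the rate in bin j. A unit is an HD
cell under the standard criterion iff Rayleigh p < 10⁻⁴, Rayleigh z = n·R̄² >
50 and peak rate > 1 Hz. Independently, a gradient-boosted (XGBoost)
classifier identifies HD cells from the shape of their spike-train
autocorrelogram (2 ms bins, 400 ms window, session halves stacked), and a
Fourier screen on the autocorrelogram excludes theta-modulated (4–8 Hz)
units from ADn cell counts.

**Decoding and population geometry.** A Bayesian decoder computes
P(dir | spikes) ∝ P(spikes | dir)·P(dir) per 200 ms window with independent
Poisson likelihoods from training-half tuning curves. Population vectors
(200 ms counts, square-root transformed) are embedded with Isomap (50
neighbors); the internal direction is the arctangent of the centroid-centered
embedding, and a Vietoris–Rips Betti-1 barcode (computed exactly, in-package)
tests for the ring topology against per-cell circular time-shift shuffles.

**Drift and experimental scores.** The angular difference
Ang_diff = arctan2(sin(HD_actual − HD_iso), cos(HD_actual − HD_iso)) is
unwrapped, smoothed (σ = 2 samples) and differentiated into the angular
drift velocity (ADV), compared against angular head velocity (AHV) with a
cross-session null; cue-rotation gain = |ΔPFD| / |Δcue| with a 10,000-draw
re-exposure shuffle null; 360° head-turn epochs and spike-count-matched
vector-length controls; the two-chamber odor preference
CP = (t_neut − t_avers)/(t_neut + t_avers); and the intraclass correlation
ICC = σ_b² / (σ_b² + σ_e²) via one-way random-effects ANOVA.

The synthetic generator produces all of it with known ground truth:
Ornstein–Uhlenbeck head trajectories, von Mises HD cells spiking as
burst-augmented inhomogeneous Poisson processes, non-HD cells with slow
log-normal rate envelopes, and an internal direction that is anchored,
cue-rotated with a gain, or drifting (a fraction of true AHV plus diffusion).

## Worked example

```python
import numpy as np
import hdring as hr

session, truth, _ = hr.simulate_session(seed=7)       # 40 HD + 10 non-HD cells, 10 min

m = hr.compute_hd_metrics(session.unit("hd000"), session.tracking)
hd_ids = list(truth[truth.is_hd].unit_id)
decoded = hr.decode_session_halves(session, unit_ids=hd_ids[:20])
err = np.abs(hr.angular_difference(decoded.map_angle, decoded.actual_angle))

mat = hr.build_population_matrix(session, hd_ids)
emb = hr.isomap_embed(mat, seed=0)
barcode = hr.betti1_barcode(emb, seed=0)
```

prints (via the session's ground-truth table and the metric fields):

```
hd000: true PFD 248.6 deg, kappa 4.85, peak 20.0 Hz
  estimated PFD 249.0 deg | vector length 0.565 | width 83.3 deg
  MI 0.602 bits/spike | Rayleigh z 890 (p 0) | peak rate 15.6 Hz
  standard HD criterion: True
Bayesian decoding (20 cells, second half): median error 9.2 deg
Isomap ring: circular r(decoded, actual) = 0.948; top H1 bar 0.72 vs next 0.10
```

The cell's preferred direction is recovered to half a degree; the population
decoder tracks the head to ~9° median error from spikes alone; and the
population manifold is a clean ring (one dominant Betti-1 bar, seven times
the next) whose coordinate matches the actual head direction (circular
r = 0.95). In a `drifting`-mode session the same pipeline keeps the ring but
the circular correlation collapses — the signature of an intact attractor
that has lost its allothetic anchor.

A CLI wraps the same functions for shell use:

```bash
hdring simulate --seed 42 --out session_dir
hdring validate session_dir
hdring tuning session_dir --out metrics.csv curves.csv
hdring decode session_dir --out decoded.csv
hdring manifold session_dir --shuffles 20 --seed 0
```

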