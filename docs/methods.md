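# Methods

This note records the models, conventions and numerical choices behind
`hdring`, and what the synthetic tests do and do not demonstrate.

## Conventions

Time is 0-based seconds from session start; every binned quantity uses
half-open windows [t, t + Δ). Angles are degrees in [0, 360) at all public
boundaries (radians internally where trigonometry demands), 0° the arena
reference, counter-clockwise positive. Signed angular differences are
computed as arctan2(sin Δ, cos Δ) and lie in (−180, 180], with the antipodal
case mapped to +180. Tracking is nominally 120 Hz (camera frame rate) but
the loader accepts any fixed rate declared in the session manifest. Tracking
gaps of ≤ 2 samples are interpolated on the circle (shorter-arc, unit-vector
interpolation); longer gaps abort the load rather than guess.

## Tuning curves

Spikes are assigned the head direction of the temporally nearest tracking
sample, counted in sixty 6° bins, divided by per-bin occupancy, and the
resulting rate is smoothed with a circular Gaussian kernel, σ = 3 bins,
truncated at ±4σ, wrapped and renormalized. Two properties follow exactly:
the kernel sums to one, so smoothing conserves the integral of the rate
curve; and the unsmoothed rate times occupancy recovers the spike count to
floating precision. We normalize *before* smoothing: smoothing counts and
occupancy separately and dividing afterwards conserves Σ rate·occupancy
exactly but weights the kernel by occupancy, which drags the estimated peak
toward occupancy gradients (in simulation this cost ~10% of cells their
one-bin PFD recovery). The price of the unbiased order is that
Σ smoothed-rate·occupancy can differ from the spike count at the ~1% level
under occupancy gradients; the curve retains raw counts, occupancy and the
unsmoothed rate so either accounting is available.

Zero-occupancy bins with zero counts yield rate 0; spikes landing in a
zero-occupancy bin (possible only with degenerate tracking) raise a warning.
Ties at the curve argmax resolve to the smallest angle. The FWHM tuning
width interpolates the half-max crossings linearly in angle, walking
outward from the peak; a curve that never falls below half max reports
(360, flagged). Mutual information uses the occupancy-weighted mean rate as
λ, which makes I ≥ 0 an exact Jensen inequality and I = 0 iff the curve is
flat. The Rayleigh statistic is z = n·R̄² with n the spike count and R̄ the
resultant of the occupancy-corrected curve (raw spike angles would inherit
the occupancy bias), with Zar's large-sample p approximation; under a
direction-independent cell its p-values are uniform (property-tested).

## HD classification

Standard criterion: Rayleigh p < 10⁻⁴ AND z > 50 AND peak rate > 1 Hz. The
"z" of the criterion is interpreted as the Rayleigh z statistic — the only z
computed from a tuning curve in this workflow; the thresholds are exposed as
arguments.

Autocorrelogram (ACG) classifier: per session half, lags of ordered spike
pairs in right-inclusive 2 ms bins over (0, 400] ms; each half is smoothed
(Gaussian σ = 1.5 bins) and normalized to unit maximum — ACG shape, not
rate, is the feature — then the halves are concatenated (400 features). The
model is XGBoost with library-default hyperparameters; the training set is
balanced by seeded down-sampling of the majority class; the decision
threshold is 0.5 on predicted probability. Max-normalization per half makes
the feature invariant to firing-rate scale, which is what lets a model
trained on anchored sessions generalize to drifting ones (tested).

Theta screen: cells whose ACG spectrum concentrates in 4–8 Hz are excluded
from ADn unit counts. The screen gets its own ACG spanning 2 s — a 400 ms
window cannot spectrally separate 1 Hz from 4–8 Hz modulation — which is
mean-subtracted, Hann-tapered, zero-padded and Fourier transformed; the
cell is flagged iff mean band power exceeds 5× the median power over
1–50 Hz outside the band. The 5× ratio and the 2 s window are this
package's choices (only the band is given by convention); both are
constants at the top of the module.

## Bayesian decoding

Per 200 ms window, P(dir | k) ∝ P(dir) Π_c Poisson(k_c; λ_c(dir)·w): the
likelihood is independent Poisson per cell — the standard choice, and
exactly the process the generator realizes — with λ from training-interval
tuning curves floored at 10⁻³ Hz so an empty training bin cannot veto a
direction outright. The prior is the training-interval occupancy
distribution by default (the direction-distribution component of "fit on
the first half"), floored and renormalized; a uniform prior is one argument
away. Accumulation is in log space and is tested to match the direct
product to 1e-9 relative. The decoded angle is the MAP bin center; the
actual angle per window is the tracking sample nearest the window midpoint;
errors are mean absolute wrapped differences.

## Ring manifold and topology

Population vectors are 200 ms spike counts, square-root transformed
(variance stabilization), for sessions with ≥ 10 simultaneously recorded HD
cells. Isomap (2 components, 50 neighbors) embeds them; the ring coordinate
is the arctangent of the centroid-centered embedding, and decoded angular
velocity is the wrapped difference of consecutive ring angles over 0.2 s.
An embedding is only defined up to rotation and reflection (the ring's two
leading eigenvalues are nearly degenerate, so the eigensolver returns an
arbitrary basis of that plane); all downstream statistics are therefore
invariant to rotation/reflection, and comparisons to the actual direction
fit one global offset (circular mean of residuals) and one reflection sign,
choosing the combination with the larger resultant. The eigensolver's
random start vector is seeded (and the global RNG state restored), so the
embedding is exactly reproducible for a given seed.

Betti-1 barcodes are computed in-package: the Vietoris–Rips boundary matrix
of all triangles over filtration-ordered edges is reduced over Z/2 with
columns stored as bitmask integers; pivots pair each cycle-creating edge
(birth radius) with the triangle that fills it (death radius). The
reduction is exact and is validated against closed-form barcodes (a unit
square yields one bar (1, √2); a unit-circumradius hexagon (1, √3)).
Because the reduction enumerates all C(n, 3) triangles, the point cloud is
first subsampled to 150 points (seeded) and scaled to unit mean radius so
persistences are comparable across sessions; at 150 points a barcode takes
a few seconds. The ring test compares the top H1 persistence of the real
embedding against embeddings of shuffled matrices (independent circular
time-shift per cell, which preserves each cell's count statistics but
destroys co-activation structure). With ~40 cells the separation is an
order of magnitude; below ~20 cells it degrades — sessions near the 10-cell
floor should not be over-interpreted.

## Drift analysis

Ang_diff between actual and ring-decoded direction, arctan2(sin Δ, cos Δ),
is unwrapped, smoothed with a Gaussian of σ = 2
samples on the 200 ms grid, and differenced; ADV is the absolute rate of
change, with half a (truncated) kernel width — 8 samples — trimmed from
each edge before averaging. AHV is the first difference of the unwrapped
head direction interpolated to the same grid; the AHV–ADV correlation uses
|AHV| (ADV is unsigned by construction; a signed variant is an argument).
The cross-session null pairs each session's AHV with every other session's
ADV (series truncated to the common length, one r per ordered pair); a
session is flagged only if p < 0.05 and |r| exceeds the null's 99th
percentile. Under-signaling is the through-origin regression slope of
decoded on actual AHV plus a |AHV|-binned error profile; total angular path
lengths are sums of absolute wrapped steps.

## Rotation, epochs, behavior, ICC

Gain = |ΔPFD| / |Δcue| per cell, Δcue ∈ {±90, ±180}. The shuffle null draws
(re-exposure PFD pair, experimental rotation angle) combinations 10,000
times. 360° head-turn epochs accumulate *absolute* rotation (a ±180°
back-and-forth completes an epoch); the net-rotation variant is an
argument. Per-epoch vector lengths use unsmoothed curves (epochs are short);
the control draws the same number of spikes per epoch from the whole
session without replacement, seeded. At ~25 s epochs a residual ~0.1
resultant inflation survives the count-matched control — the epoch's
one-pass occupancy structure, which count matching cannot mimic — so only
differences well above that (the drifting-session effect is ~0.35) are
meaningful. CP = (t_neut − t_avers)/(t_neut + t_avers). ICC uses the
one-way random-effects ANOVA estimator: σ_e² = MSW,
σ_b² = max(0, (MSB − MSW)/n₀) with n₀ the harmonic-adjusted group size;
for balanced designs it coincides with ICC(1,1) (cross-checked against
pingouin). Circular–circular correlation is the Fisher–Lee coefficient.
Generic group tests (Mann–Whitney, Wilcoxon, Bonferroni) are deliberately
left to scipy/statsmodels.

## Synthetic sessions

The generator is phenomenological — the statistical structure the analyses
assume, not a mechanistic attractor network.

*Trajectory.* AHV is an Ornstein–Uhlenbeck process (τ = 1 s, stationary
σ = 18 deg/s), integrated and wrapped; with these defaults mean |AHV| ≈
14 deg/s, so a cumulative 360° head turn takes ~25 s, matching reported
open-field mouse behavior, and 10 min covers every 6° bin in ≥ 95% of
seeds. Position is a reflected random walk in a 30 cm-radius arena
(tracking plumbing only). An optional von Mises restoring drift biases
angular occupancy.

*Cells.* HD cells: λ(t) = b + (peak − b)·exp(κ(cos(θ_int − PFD) − 1)), κ ∈
[2, 6], peak ∈ [10, 30] Hz, baseline ∈ [0.1, 2] Hz, spiked per tracking
interval as Poisson counts with uniform jitter, a 2 ms absolute refractory,
and short ~250 Hz bursts appended after base spikes (Binomial(2, 0.25)
extra spikes at ~4 ms intervals, base intensity divided by the mean burst
size so stated rates hold). The bursts reproduce the short-lag ACG peak
that makes thalamic HD autocorrelograms distinctive — without them the ACG
classifier has essentially no signal, with them it is the dominant feature.
Non-HD cells are a documented stand-in (their real ADn statistics are not
characterized): direction-independent Poisson with a slow log-normal
envelope (OU in log-rate, τ = 5 s, σ = 0.5), no bursts.

*Anchoring.* `anchored`: internal = actual. `rotated`: from the rotation
time the internal direction shifts by −gain×rotation, so *measured* PFDs
shift by +gain×rotation, as in cue-rotation experiments; rotation pairs are
simulated as two sessions sharing a population. `drifting`: the internal
direction integrates ahv_gain × actual AHV (default 0.7) plus Brownian
diffusion (default 8 deg/√s) — an unanchored attractor that under-signals
head turns; the generator returns the offset series as ground truth.

*Two-chamber test.* Alternating exponential dwells with mean cycle 30 s
split so the stationary neutral occupancy equals p_neutral, starting in the
neutral chamber.

What passing tests show — and don't. The generator realizes exactly the
model class the analyses assume (von Mises tuning, Poisson spiking, a true
ring). Recovery and topology results therefore validate the estimators and
the pipeline's internal consistency, not robustness to real-data
pathologies: no sorting errors, no lost tracking frames, no
non-stationarity beyond the modeled drift, no correlated noise across
cells, and non-HD cells follow an invented envelope. Classifier accuracies
on synthetic cells say the pipeline can learn ACG shape, not that real-data
accuracy will match.

## Problem sizes and determinism

Default tests and examples use 10-min sessions at 120 Hz, 40 HD + 10 non-HD
cells, 150-point persistence subsamples and 20 shuffle draws — sizes chosen
so the whole suite runs in a few minutes on one core while keeping every
effect far from its decision boundary. Every stochastic step takes an
explicit seed, sub-seeds are spawned per stage, and all generators are pure
functions of (params, seed).
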