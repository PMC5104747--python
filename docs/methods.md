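# Methods

This note records the models, the numerical choices behind them, and the
limits of what the synthetic-data tests demonstrate.

## Kinematic features

All features are computed from a planar head-marker trajectory sampled
nominally at 180 fps inside a 4.66 × 5.40 m tracked area, in a
room-centered frame in meters.

**Derivatives.** First and second derivatives come from central finite
differences (`numpy.gradient` on the true time stamps) after a
zero-phase moving average of width `smooth_frames` (default 5 frames ≈
28 ms). Raw 180 fps differencing is noise-dominated for second
derivatives; the moving-average width is a configuration knob and is
recorded in the metadata of every feature table. Samples without full
central-difference support — the first and last `smooth_frames//2 + 2`
frames, where edge padding and one-sided differences bias the estimates
— are excluded from curvature, from smoothness windows, and from the
per-observation energy mean.

**Energy.** `EI(f) = ½ v(f)²` for the single tracked point with unit
mass. Per-observation `EI_mean` averages the interior frames.

**Curvature.** `k = (ẋÿ − ẏẍ)/(ẋ² + ẏ²)^{3/2}`, masked wherever speed
is at or below `v_floor` (default 10⁻³ m/s: both the denominator and
`log v` degenerate there). Curvature magnitudes below `k_floor`
(default 10⁻⁶ m⁻¹, an osculating radius of 1000 km) are numerical noise
on straight segments and are excluded from smoothness windows; without
this floor a perfectly straight path would contribute meaningless
correlations computed on rounding error.

**Smoothness.** The trajectory is cut into non-overlapping 30 ms
windows (hop = window length; only the window length is prescribed by
the feature definition). Within each window the Pearson correlation of
`log |k|` and `log v` is computed over valid samples; windows with
fewer than 3 valid samples or zero variance in either log series yield
missing values rather than errors. `SI_mean` is the mean over valid
windows. The simplified variant `1/(σ_log k σ_log v)` (obtained by
approximating the covariance by 1) is provided for completeness but is
dimensional and unbounded — its scale changes with the units of `k` and
`v` — so the Pearson form is the default and the one used everywhere in
the analysis chain. Window sign: with only ~5 samples per window the
correlation of two smooth series is close to ±1 with either sign, so
the signed window mean of a generic smooth trajectory is near zero;
meaningful style comparisons use the correlation magnitude, and a
strongly negative mean arises only when the curvature–velocity power
law actually holds (verified on a log-spiral fixture traversed with
`v = c·k^{−1/3}`, which yields `SI ≤ −0.99` in every window).

**Directness.** `DI` = endpoint chord over summed segment lengths,
computed once per 25 s excerpt (the excerpt is the movement unit of the
analysis). `DI ∈ [0, 1]`, invariant under rigid motions.

## Preprocessing

Raw 36 s observations (plus 1 s cross-fade) are trimmed by 6 s at each
end to the 25 s analysis excerpt. Exclusion rules replace the study's
manual screening with automatic proxies:

* **crossover** — any inter-sample displacement implying speed above
  `v_max` (default 10 m/s): marker-label swaps teleport the track, real
  heads do not;
* **occlusion_gap** — a sampling gap longer than `max_gap` (default 1 s);
* **too_few_samples** — fewer than 50% of the nominal excerpt samples;
* **out_of_area** — more than 20% of samples outside the tracked area.

Feature columns are min–max normalized to [0, 1] per feature over the
whole retained dataset, *not* per participant — per-participant scaling
would erase exactly the between-participant contrasts the mixed model
estimates.

## Sound models

All three models filter seeded white noise through a two-pole section
whose center frequency and Q follow the normalized speed linearly
(`f_c = f_min + v_norm (f_max − f_min)`, same for Q; the mapping curve
is not otherwise constrained, and linear is the simplest monotone
choice). "Resonant" uses the constant-peak-gain band-pass form,
"band-pass" the constant-skirt form, both in the standard audio-cookbook
parameterization. Coefficients update once per control frame (default
control rate 100 Hz, i.e. 10 ms blocks, with filter state carried across
block boundaries); at movement rates the induced stepping is far below
audibility, and block processing keeps offline rendering vectorized.

Speed normalization uses `v_ref = 2 m/s` (fast child locomotion) for
full scale. Amplitude follows `20 log10(v_norm)` mapped affinely from
[−60 dB, 0 dB] to [0, 1], with gain exactly zero at `v_norm = 0` — rest
produces digital silence, not merely quiet noise. S1/S2 multiply by a
band-limited random envelope (uniform [0, 1] targets drawn at 3 Hz /
18 Hz, linearly interpolated — the documented behavior of the original
band-limited noise object). S3 multiplies by a train of convex
exponential-approach ramps of 250 ms, launched at intervals
interpolated linearly from 0.8 s at rest down to 0.05 s at full speed;
whether trigger density rises or falls with speed is a config flag
(`faster_with_speed`, default true — choppier sound for faster
movement). The abrupt ramp release is what makes S3 clicking.

Spatialization places the source on an 8-speaker ring: pairwise
constant-power panning between the two speakers adjacent to the bearing
from room center, blended toward the uniform gain vector as the
distance from center (normalized by the area half-diagonal) grows, with
a final renormalization so `Σ g² = 1` holds exactly per control frame.
Renders are bit-reproducible for a fixed (controls, parameters, sample
rate, seed) tuple. WAV output is 16-bit (default) or 24-bit PCM.

## Synthetic data

`gen_trajectory` emulates one child's head marker in the tracked area;
`gen_cohort` draws feature tables from the hierarchical model directly.

Movement styles: `straight`, `circle` and `square` are analytic, with
closed-form speed and curvature, and exist as oracles. `smooth` is a
correlated random walk — heading diffuses by 1 rad² per
`smoothing_time` (default 6 s) and speed is a lognormal modulation (OU
in the log, CV ≈ 0.4) — producing sweeping, continuously varying paths.
`jerky` draws piecewise-constant headings with Poisson-timed abrupt
turns (default 1.5 s⁻¹), Bernoulli full stops (speed exactly zero, so
silence-at-rest is exercised end to end), multiplicative per-frame
speed jitter and heading wobble; the jitter matters because a perfectly
constant inter-turn speed would make most 30 ms windows zero-variance
and the smoothness index undefined rather than low. Boundaries reflect
specularly, keeping kinematics stationary without trapping at walls.

The default time-averaged speed is 0.15 m/s. This is deliberately slow:
directness is chord over path, and in a 4.66 × 5.40 m area a 25 s
excerpt stops discriminating movement styles once the path length (speed
× 25 s) far exceeds the room diagonal — every style then has a
wall-limited chord. Directness values near 0.7 for continuous movement,
the regime the study reports, require only a few meters of path per
excerpt, i.e. children mostly swaying and stepping with occasional
locomotion bursts. At these defaults the smooth style scores DI ≈ 0.6
and the jerky style ≈ 0.2–0.35.

What the generator does *not* emulate: group play and interpersonal
entrainment, deliberate goal-directed runs, marker jitter of a real
optical system, or a learned coupling between sound and movement. In
particular the smooth style does not embed the biological
curvature–velocity power law, so its window correlations have mixed
signs; passing style-separation tests therefore shows that the indices
rank tortuosity and speed-roughness correctly, not that the generator
reproduces child behavior.

`gen_cohort` simulates
`y = β₀ + β_model + β_session·(session−1) + β_obs·obs + b_group +
b_participant + ε` with three sound models × 12 observations (1–6 in
session 1, 7–12 in session 2) per participant. Defaults use the
estimated variance components for the normalized energy index of the
original cohort — group SD 0.054, participant SD 0.052, residual SD
0.168 — a −0.06 S3 shift (the scale of the reported S2–S3 contrast), a
−0.043 session step and a −0.009 per-observation slope, with 3 groups
of 4 participants. Ground truth (drawn intercepts included) is returned
with the table.

## Mixed-model analysis

`MovementFeatureModel` constructs the nested random-intercept model —
groups as the outer factor, participants as a variance component within
groups (participant labels are unique within group) — and delegates the
(restricted) likelihood optimization to statsmodels `MixedLM`. L-BFGS
is tried first with a BFGS refit whenever the likelihood comes back
non-finite (L-BFGS can silently degenerate on small balanced designs).
With a single group the group variance is unidentifiable (confounded
with the grand mean); the model then drops the group term, reports the
variance at the boundary 0 and warns, rather than returning an
arbitrary split.

Conventions: likelihood-ratio tests compare ML fits (REML likelihoods
are not comparable across fixed-effect structures); reported
coefficients come from REML. The sound-model factor uses treatment
coding with S1 as reference. The LR test for the 3-level factor has 2
degrees of freedom and is reported as such. Pairwise contrasts are exact
differences of coefficient estimates with studentized-range (Tukey)
family-wise p-values on `n − p` error degrees of freedom; with two
levels this reduces exactly to the unadjusted two-sided t-test.
Pseudo-R² follows the variance-partition form: marginal
`var(Xβ̂)/(var(Xβ̂)+σ²_g+σ²_p+σ²_ε)`, conditional adds the two
random-intercept variances to the numerator, so conditional ≥ marginal
by construction. Random-slope extensions are out of the default path
(they did not converge on the original data) but the fixed-effect
subset is freely configurable.

Calibration at study scale (verified in the test suite): with 30 groups
× 4 participants × 12 observations, REML variance components average
within 20% of the generating values over seeds; the S3–S2 contrast sign
is recovered in ≥ 95/100 seeds; the 5% LR test rejects a true null in
3–7% of 500 reduced-size cohorts (3 groups × 4 participants × 4
observations per model — reduced to keep the Monte-Carlo run within a
desk-scale budget while retaining the three-level structure).

## Known limitations

* The crossover detector is a speed-threshold proxy for what was manual
  screening; subtle swaps between nearby markers pass it.
* The simplified smoothness variant is reported but carries units; its
  values are not comparable across datasets with different length
  scales.
* Sound rendering is an offline reconstruction of the documented
  synthesis chain, not a sample-exact emulation of the original
  real-time patch; the S3 ramp shape and the amplitude log-scaling
  constants are package choices where only qualitative descriptions
  exist.
* Feature normalization requires the full dataset; single observations
  cannot be normalized in isolation.
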