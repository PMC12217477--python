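# Methods

This note documents the models, conventions and parameter choices behind
each stage of the pipeline, what the synthetic-session generator does and
does not emulate, and the known limitations.

## Signal model and demodulation

The photodetector voltage is modeled as two amplitude-modulated channels
sharing one wire:

```
v(t) = E_ca(t)·sin(2π·211·t) + E_iso(t)·sin(2π·531·t) + ε(t)
```

where `E_ca` is the Ca²⁺-dependent fluorescence envelope, `E_iso` the
isosbestic (Ca²⁺-independent) envelope, and `ε` broadband noise.
Demodulation is quadrature lock-in: the voltage is multiplied by sine and
cosine references at the carrier, both products are low-pass filtered
(4th-order Butterworth, 10 Hz, forward-backward), and the envelope is
`2·√(I² + Q²)`. This is phase-agnostic — it needs no knowledge of the
carrier phase — and matches the behavior of commercial lock-in hardware.

*Parameters.* Demodulation bandwidth 10 Hz: well above fast-indicator
kinetics (jGCaMP7f decay time constant ≈ 0.2 s → ≈ 0.8 Hz) and far below
half the carrier spacing (160 Hz), so cross-channel leakage is negligible
(measured < 10⁻²⁰ of the neighbor's power). Output rate 100 Hz. The
demodulator refuses cutoffs at or beyond half the carrier spacing and
sampling rates at or below twice the highest carrier.

*Settling.* The first and last 1 s of the demodulated trace are dominated
by the product filters' edge transients. These samples are flagged and
excluded from normalization statistics, and are additionally held at the
nearest settled value: left in place, a single large edge sample injected
into the 0.0051 Hz zero-phase high-pass downstream spreads over ~100 s of
the recording (the backward pass smears it into the data proper).

## Isosbestic correction, detrending, Z-score

Motion and bleaching affect both excitation wavelengths; Ca²⁺ binding
affects only the 465 nm channel. The default correction fits
`ca ≈ a·iso + b` by least squares over the whole recording and subtracts
the fitted prediction. The unscaled alternative (`ca − iso`) is kept as
`method="direct"`: it is only correct when the two channels have exactly
equal gains, but it is the more literal reading of channel subtraction, so
both are provided. A zero-variance isosbestic trace makes the fit
degenerate; the code falls back to direct subtraction with a warning.

The corrected trace is detrended with a 3rd-order Butterworth high-pass at
0.0051 Hz (removes bleaching drift; time constant ≈ 200 s) and smoothed
with a 5th-order low-pass at 2.29 Hz. Both default to zero-phase
(forward-backward) application: causal filtering at these orders delays
event-locked features by tens of milliseconds, which would corrupt the
peri-event alignment that is the pipeline's core readout. A causal mode is
kept for sensitivity analysis. Forward-backward application squares the
magnitude response, so the single-pass −3 dB frequency becomes the
half-amplitude point: a 0.0051 Hz sinusoid comes through the zero-phase
high-pass with gain 0.50, and that is what the filter-contract check
asserts. Recordings shorter than 600 s trigger a warning — the high-pass
cannot settle meaningfully within them.

The Z-score is `(x − mean)/SD` with the sample SD (n−1 denominator),
computed over the scored span (settling edges excluded). The convention is
fixed so tests can be exact; at tens of thousands of samples the n vs n−1
difference is far below any tolerance used.

*Numerical notes.* All filters are designed and applied in second-order
sections; at 0.0051 Hz relative to a 100 Hz rate a transfer-function
representation is numerically unusable. Single-pass (causal) high-pass and
low-pass stages commute to ~10⁻¹² RMS; the zero-phase variants are
signal-dependent at the edges (padding), so order invariance is only
asserted causally.

## Tracking, speed, bouts

Arena calibration divides the nominal side length (40 cm) by the mean of
the four corner-to-corner side lengths in pixels; the corners are ordered
around their centroid and must form a convex quadrilateral. Containment
uses that convex polygon rather than a nominal square, because camera
perspective distorts the arena.

QC removes frames in a fixed order, each frame counted against the first
rule it fails: tracking likelihood < 0.8 (strict), position outside the
corner polygon, implied step speed > 334 cm/s (the fastest locomotion
recorded in mice). Speed is computed only between consecutive valid
frames; a QC gap leaves the following frame's speed missing, and no
interpolation is performed — the strictest reading, since any gap-bridging
rule would be an invention.

A locomotor bout is a maximal run of consecutive valid frames with speed
strictly above 3 cm/s whose duration reaches 0.5 s. Each frame represents
one frame period, so a run of n frames lasts n/fps: ten frames at 20 fps
qualify exactly. The duration comparison is done in whole frame counts,
not accumulated float time, so the ten-frame boundary case cannot be lost
to rounding. Runs are never merged across sub-threshold or missing frames.
A stimulus trial is a locomotor response when a bout *starts* within
(onset, onset + 5 s]; an any-overlap alternative is available
(`mode="overlap"`).

## Alignment

Stimulus epochs span −5…+10 s around the alignment point (stimulus onset,
plus 0.803 s for visual looming, where the disk's exponential expansion
begins); the Z trace is linearly interpolated onto a shared relative axis
at the signal rate and companion speed is averaged into 50 ms bins. Trials
whose window is not fully covered are dropped with a warning (padding
would fabricate data).

Motor events of duration D are mapped onto normalized time
`u = (t − onset)/D` and averaged over u ∈ [−0.5, 1.5] into fixed bins —
0.002 of normalized time for photometry, 0.05 for the motor parameter —
with bin edges anchored exactly on 0 (onset) and 1 (offset), the two
scientifically meaningful landmarks. Empty bins are recorded as missing
and ignored by cross-event averaging. Overlapping windows from closely
spaced bouts are all kept (a sample may serve two bouts); no exclusion
rule is imposed.

Window means (stimulus: pre (−5,0), during (0,5), post (5,10); motor:
pre (−0.5,0), first half (0,0.5), second half (0.5,1), post (1,1.5)) use
half-open intervals [a, b) so a sample on a shared edge is never counted
twice. Bin assignments add an epsilon of 10⁻⁹ bin widths before flooring
so samples that land on an edge up to float error stay in the bin they
belong to.

## Statistics

For more than two dependent groups, Shapiro-Wilk per group and the Levene
test (mean-centered) across groups gate the branch at α = 0.05: both pass
→ one-way repeated-measures ANOVA; otherwise Friedman ANOVA on ranks. The
RM-ANOVA is the standard two-way decomposition without replication,
implemented directly (the 2000-replication calibration checks need a fast
path) and cross-checked against statsmodels' AnovaRM in the test suite.
Friedman uses the chi-square approximation; its null rejection rate at
10 subjects × 3 windows was verified by simulation to sit within the
0.05 ± 0.01 calibration band. No sphericity correction is applied to the
RM-ANOVA — a known limitation.

A significant omnibus triggers the Student-Newman-Keuls stepwise post hoc:
group means are ordered, ranges are tested widest-first against the
studentized-range distribution at the number of means spanned and the
error degrees of freedom, and any non-significant range blocks every range
nested inside it. On the nonparametric branch the same stepwise scheme
runs on within-subject rank sums with
`SE = √(n·p·(p+1)/12)` and infinite degrees of freedom. For two dependent
groups, Shapiro-Wilk on the paired differences gates a two-tailed paired
t-test against the Wilcoxon signed-rank test; all-zero differences are
degenerate and reported as statistic 0, p = 1.

The speed regression averages Z and speed per bout over [onset, offset),
sorts bouts into 1 cm/s bins [k, k+1), averages Z per bin, and fits
ordinary least squares against bin centers. The habituation regression
averages the response per trial index across mice and fits OLS against
trial number; percent change between trials i and j is read off the
fitted line, `100·(fit(j) − fit(i))/fit(i)` — more robust than raw means,
whose single-trial noise would make the ratio erratic. In the validation
analyses the per-trial response is the during-window mean minus the same
trial's pre-window mean: Z-scoring removes the whole-recording mean, which
includes the transient mass itself, so raw during means share a negative
offset that biases any ratio-based measure; baseline subtraction cancels
it exactly.

## The synthetic-session generator

The generator fabricates everything the pipeline consumes, with the
injected components exported as ground truth.

*Photometry.* Ca²⁺ transients are difference-of-exponentials kernels
normalized to unit peak (rise τ 25 ms, decay τ 200 ms — fast-indicator,
jGCaMP7f-like kinetics), superposed at stimulus-locked times (latency
150 ms) and at background Poisson times (0.02 s⁻¹, kept ≥ 1.5 s clear of
other transients so peak recovery is well-defined). Both envelope
baselines decay with a shared double-exponential bleach (10% with
τ = 150 s on top of a τ = 6000 s component); the bleach scales the
baselines only, so injected transient amplitudes remain the ground truth
that recovery tests compare against. A motion artifact (white noise
low-passed at 0.3 Hz, SD 0.05) enters both envelopes, scaled by the
mixing coefficient on the Ca²⁺ side; white noise (SD 0.003 V) is added to
the multiplexed voltage. The raw rate is fixed at 6103.52 Hz — a
power-of-two division of a common acquisition master clock, comfortably
above twice the 531 Hz carrier. Noise magnitudes are free parameters of
the generator, not claims about any particular rig.

*Behavior.* Trajectories are built frame by frame from a per-frame speed
profile — planned bout speed inside bouts, a 1 cm/s sub-threshold wander
elsewhere — with smoothly turning headings reflected away from the walls.
Because each frame's displacement is the profile speed divided by the
frame rate, the speed the pipeline computes from positions equals the
profile exactly, and the true bouts are, by construction, precisely what
the bout detector must find on the noiseless track. Stimuli arrive at
60.1 s intervals with ±0.3 s uniform jitter; a configurable fraction of
trials (default 0.5) get an evoked bout starting inside the 5 s response
window, spontaneous bouts and grooming/rearing annotations are placed in
zones clear of every response window, and trial-wise habituation scales
the stimulus-locked transient amplitudes (linear decay between a first-
and last-trial multiplier).

*What it does not emulate.* Tracking noise defaults to zero (the
round-trip contract is defined on the noiseless track); real pose
estimates jitter and drop out. Transients are identical in shape across
events; real indicators show amplitude-dependent kinetics and saturation.
The motion artifact is stationary and perfectly shared across channels up
to one global coefficient; real artifacts are wavelength-dependent and
non-stationary. Bleaching does not attenuate transient amplitudes.
Passing tests therefore demonstrate that the pipeline's operations are
correct and internally consistent — not that real recordings meet these
assumptions.

## Validation problem sizes

The round-trip check runs one 600 s session (10 trials, half responders)
through the full pipeline. Filter corners are measured by fitting
Butterworth magnitude curves to the Welch PSD ratio of 2²¹ white-noise
samples at 10 Hz passed causally through the cascade. The bout detector
is compared with a brute-force run enumerator on 1000 random traces.
Each omnibus branch is calibrated with 2000 null simulations of
10 subjects × 3 windows. Habituation recovery pools 20 full synthetic
sessions with amplitudes declining linearly to 50% by trial 9 (±10%
amplitude jitter); the fitted decline lands near −50% with a few percent
of spread contributed by the jitter and by background transients falling
into analysis windows. Slope recovery fits 200 processed-level sessions
with Z linearly coupled to speed (slope 0.1 Z per cm/s, noise SD 0.5 Z).

## Known limitations

- No sphericity correction in the RM-ANOVA branch.
- The habituation analysis aggregates across mice per trial index before
  regressing; a per-mouse mixed-effects alternative is out of scope.
- `ΔF/F₀` baselines are not computed; the pipeline normalizes by Z-score
  only.
- The zero-phase filters are non-causal and therefore unsuitable for
  online analysis; the causal mode shifts latencies and is provided only
  for sensitivity checks.
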