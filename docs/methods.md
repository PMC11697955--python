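# Methods

This note documents the models and procedures implemented in `gapassr`,
the tunable parameters and their defaults, the synthetic-data generator's
assumptions, and the design decisions taken where the underlying
experimental description left the design open.

## Stimuli and session schedule

Two stimuli drive the analyses.

*Noise bursts* (ERP stimulus): Gaussian noise band-limited to
1–12 kHz (4th-order Butterworth band-pass, applied forward-backward),
100 ms long with 5 ms cosine-squared rise/fall ramps, nominally 120
repetitions at 0.25 Hz. Sound level is symbolic in silico: 75 dB SPL maps
to a waveform RMS calibration constant (default 1.0). The protocol's
"20 min of broadband noise" at 0.25 Hz admits 300 onsets, while the
nominal count is 120 (8 min); the two are not reconcilable from the
protocol description alone, so the scheduler is duration-driven (onsets
tile the block) and the repetition count is carried as documentation.

*Gap-ASSR segments*: 250 ms of the same noise with 10 gaps spaced exactly
25 ms apart, giving a 40 Hz presentation rate. Gap onsets sit at k·25 ms
(k = 0…9) from segment start so that every gap lies wholly inside the
segment; gap edges are instantaneous amplitude steps (no ramp is
specified for gaps, and sharp edges maximize 40 Hz drive). Inside a gap
the envelope is multiplied by 1 − depth/100 (depth 75% ⇒ envelope 25%).
Each gap segment carries one gap width drawn uniformly at random from
{3,…,9} ms; gap segments alternate with plain-noise segments.

The default session is 8 min rest, 30 min gap-ASSR, 20 min noise bursts
(58 min), with the two stimulus blocks counterbalanced via
`block_order`. A 30-min gap block yields ≥ ~480 segments per gap width,
comfortably above the >100-trials-per-condition requirement.

## Preprocessing and ERP

Analysis operates at 1024 Hz. `io.downsample` provides the acquisition-
to-analysis conversion (zero-phase Butterworth low-pass at 0.4·target
rate, then rational-ratio polyphase resampling); event times are stored
in seconds and survive the conversion. Epochs are half-open windows
[t_min, t_max) with onset at t = 0; the ERP window is −250 ms to
+500 ms (the pre-onset 250 ms is the prescribed baseline; the post-onset
extent is our choice, bracketing the P1–P2 latencies). No artifact
rejection is applied by default (a per-trial hook exists), matching the
reference protocol in which no data were rejected.

Each trial is baseline-corrected (subtract the mean of the 250 ms
pre-onset span) and then linearly detrended over the whole trial; the ERP
is the pointwise trial average. Peaks are measured baseline-to-peak in
configurable search windows — P1 10–40 ms (maximum), N1 25–100 ms
(minimum), P2 60–250 ms (maximum); ties resolve to the earliest
latency. The windows and the baseline-to-peak convention are package
choices (the source protocol does not state them); N1 is reported signed
and compared across groups by magnitude.

## Dynamic Morlet transform, STP and ITPC

The cycle count follows an anchored logistic in frequency: the raw
logistic σ(k(f − f_infl)) with k = 0.05/Hz and f_infl = 70 Hz is affinely
rescaled so its value is exactly 0 at the 1 Hz anchor and 1 at infinity,
then mapped to [3, 29] cycles. This honors all four printed constants
simultaneously (the unrescaled logistic would give ≈3.8 cycles at 1 Hz).

Atoms are Gaussian-windowed complex exponentials with σ_t = n(f)/(2πf),
truncated at ±3σ_t, and scaled by 2/Σ(envelope) so that a unit-amplitude
sinusoid at the atom frequency yields |coefficient| = 1 in steady state
("Gabor normalization" interpreted as amplitude normalization, which
makes STP read in µV² and gives analytic oracles). Samples within one
truncation radius of an epoch edge are flagged invalid; inside the valid
region the coefficient of a stationary sinusoid is exactly its
steady-state value, which is what makes the ITPC identities hold to
1e-9 (identical trials ⇒ 1; exactly evenly spaced phases ⇒ 0).

STP is the trial mean of |coefficient|², with no baseline normalization.
ITPC is the magnitude of the trial mean of unit phase vectors; points
where a coefficient is exactly zero are flagged and contribute zero.
Under wrapped-normal phase jitter with SD σ, E[ITPC] → exp(−σ²/2); under
uniform phases E[ITPC] ≈ √(π/4)/√N, the estimator's positive bias floor.

Frequency grids: 5–100 Hz in 1 Hz steps for 750 ms ERP epochs and
15–100 Hz for 250 ms gap segments — below these, the widest wavelet no
longer fits the epoch. Mean 40 Hz ITPC per gap width averages the 40 Hz
row over the edge-valid part of the segment window.

## Cluster-based permutation test

Group STP maps are compared with a two-sample Welch t-test at every
time-frequency point (Welch because group sizes are typically unequal);
points with two-sided p < 0.025 are kept and connected components
(4-neighbour connectivity by default) are measured by area in grid
points. Group labels are then shuffled — 2000 random relabelings by
default, or exhaustive enumeration when the assignment count is smaller —
and the **maximum** surrogate cluster area per relabeling forms the null;
observed clusters larger than 95% of the null are significant. The
max-statistic null is the standard FWER-controlling construction; a
pooled null (all surrogate areas) is available behind
`null_statistic="pool"` since the prose description is ambiguous between
the two. "Area" is point count, not physical extent. Wavelet edge
regions are excluded from cluster membership via a validity mask, which
preserves each frequency's own valid span instead of cropping the map to
the worst-case row.

## Group statistics

*ERP peaks*: Mann-Whitney U (exact enumeration for combined n ≤ 12
without ties, tie-corrected normal approximation otherwise) with
Holm-Sidak step-down adjustment, adjusted_i = 1 − (1 − p_(i))^(m − i),
with running-maximum monotonicity. The family in the pipeline report is
the four comparisons per region × peak (genotype within each treatment,
treatment within each genotype).

*Gap-ASSR ITPC*: mixed repeated-measures ANOVA with gap width within
subjects and genotype × treatment (or sex) between. The partition is
computed in two strata: between effects from a Type III factorial ANOVA
of subject means (its residual is the subject-within-groups error), and
within effects from per-subject-centered data tested against the
subject × gap-width residual with df (N_subj − cells)(K − 1). For
balanced designs this reproduces the textbook split-plot partition
exactly (verified against a direct sums-of-squares oracle to 1e-10 and
against pingouin for one-between designs). Greenhouse-Geisser epsilon is
estimated from the within-cell-pooled condition covariance,
ε = tr(M)²/((K−1)tr(M²)) with M the double-centered covariance, bounded
to [1/(K−1), 1] (exactly 1 for K = 2); the corrected p is reported
alongside the uncorrected one and selected when ε < 0.75 (the "as
needed" threshold is configurable). Regions and ages are analyzed
separately, never as factors; sexes are pooled in the main analysis,
with a sex × gap-width repeated ANOVA per group available as the
supplementary machinery. Post hoc cell contrasts use single-step Sidak
adjustment 1 − (1 − p)^m.

Degenerate inputs are mapped explicitly: constant data give F = 0,
p = 1; empty or single-subject between-cells are design errors;
incomplete within-subject data excludes the subject with a log message.

## Synthetic EEG generator

Each virtual animal's recording is the sum of

1. 1/f^α Gaussian background (α = 1, RMS 60 µV per channel, independent
   between channels);
2. band-limited 30–100 Hz gamma noise (RMS 10 µV, shared between
   channels as part of the "source");
3. a P1–N1–P2 Gaussian-bump template (defaults +15/−45/+20 µV at
   25/50/110 ms, widths 6/12/25 ms) at each burst onset, with 10%
   amplitude and 2 ms latency jitter per trial;
4. for each gap segment, with probability sigmoid(1.2·(width − 4 ms)),
   a 40 Hz sinusoidal train across the segment whose phase is drawn
   wrapped-normal with SD σ (the per-animal jitter parameter).

The frontal channel is the source attenuated ×0.8, lagged 5 ms, plus
independent background — a phenomenological stand-in for the observed
AC/FC similarity, not a connectivity model. The per-segment Bernoulli ×
shared-phase construction keeps the analytic oracle
E[ITPC] ≈ p(width)·exp(−σ²/2) exact in the high-SNR limit, and realizes
the gap-width modulation of temporal reliability through the response
probability.

Group effects are configuration multipliers, not published values (the
source work reports effect directions and significance only): knockouts
scale |N1| ×1.25, gamma amplitude ×2.0 and phase jitter ×1.5; treatment
scales jitter ×0.6 in both genotypes and, in knockouts at P30 only,
returns gamma to the wild-type level. The magnitudes were chosen by a
priori contrast analysis so that the synthetic world reproduces the
reported qualitative structure: the gamma elevation is large relative to
between-animal variability (clearly detectable by the cluster test at
n = 8–10 per group), while the N1 elevation is measurable in the peak
tables yet contributes too little evoked low-frequency power to create
spurious low-frequency STP clusters — mirroring the reported absence of
differences below the gamma band. Between-animal variability is a
lognormal multiplier (SD 0.15 on the log scale) applied per animal to
amplitudes and jitter; no published variance components exist, so this
is a free parameter.

`simulate_cohort_measures` additionally draws per-animal mean-ITPC
tables directly from the analytic model (plus Gaussian measurement noise,
SD 0.03, clipped to [0, 1]) for statistics-level simulations that need
hundreds of cohorts (null calibration, power); the waveform-to-measure
link it bypasses is validated separately by parameter-recovery tests.

What the generator does **not** emulate: biophysical cortical dynamics,
volume conduction, electrode artifacts, non-stationarities over the
session, or realistic inter-regional coupling. Passing tests therefore
demonstrate that the analysis chain recovers known ground truth with
correct calibration — not that it would behave identically on real
recordings with structured artifacts or model mismatch.

## Problem sizes and numerical choices

Default pipeline runs use shortened blocks — 120 s of noise bursts at
0.5 Hz (60 ERP trials) and 240 s of gap-ASSR (~34 trials per width) —
and n = 8 per genotype × treatment group, chosen so a full cohort run
completes in about a minute on one CPU while every per-condition trial
count stays in a regime where the estimators are well-behaved; the full
58-min protocol remains the stimulus-module default. STP maps are
decimated in time (every 8th sample, ~7.8 ms) before group statistics;
cluster geometry lives on the decimated grid. The permutation count is
2000 (the protocol's value) for single comparisons and is reduced in
repeated-simulation tests.

All randomness flows from named integer seeds through
`numpy.random.SeedSequence` spawning, so cohorts, permutation draws and
the entire report bundle are bit-reproducible; re-running a pipeline with
the same config and seed produces byte-identical CSVs.

## Known limitations

- EDF+ writing requires whole 1-second records and integer sampling
  rates; arbitrary-length recordings round-trip through the NPZ fixture
  container instead.
- The 250 ms gap segment leaves no edge-valid samples below ~15 Hz, so
  gap-ASSR ITPC maps are restricted to 15–100 Hz; the 40 Hz statistic is
  unaffected.
- The mixed ANOVA assumes a complete within-subject factor; missing gap
  widths exclude the animal rather than being imputed.
- Mann-Whitney exactness switches to the tie-corrected approximation in
  the presence of ties, whatever the sample size.
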