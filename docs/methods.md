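# Methods

This note documents the generative models, the analysis pipeline, the
parameter choices that matter, and what the synthetic tests do and do
not establish about real data.

## Stimulus model

Reverse-correlation stimuli are random spectral equalizers: a frequency
grid of `n_bands = 25` geometrically spaced points from 100 to
10,000 Hz, with independent per-band gains drawn from N(0, 5² dB) and
hard-clipped at ±2.5 SD (±12.5 dB). Clipping (not truncation by
resampling) shrinks the pooled SD by ≈1.1%, to ≈4.94 dB; conformance
tests use that analytic value. Gains are interpolated linearly over
**log**-frequency (the bands are log-spaced, so this is the natural
axis), with flat extrapolation outside the grid, and realized as a
single zero-phase FFT magnitude multiplication. The filter realization
is a design choice; nothing downstream depends on it because all
analyses operate on the gain profiles and choices, not the audio.

The smile filter is a parameterized spectral-envelope transform: the
envelope (1/3-octave-smoothed log magnitude) is shifted upward by a
ratio (default 1.05) inside the F1/F2 region (default 300–2500 Hz,
cosine skirts) and boosted (default +2 dB) in the F2–F4 energy region
(default 1000–4500 Hz). The unsmiling direction applies the inverse
shift and attenuation, computed from the filtered signal's own
envelope, so the round trip restores the smoothed spectrum to within
1% on smooth-spectrum signals (second-order envelope-estimation error
remains). Magnitudes are configurable because published descriptions of
such filters state the direction of the manipulation, not its size.
The bundled base stimulus is a synthetic 500 ms harmonic /a/-like tone
(f0 = 120 Hz, resonances near 700 and 1200 Hz); audio is demo-level
only.

## Observer model

A participant is a linear template matcher: evidence is the dot product
of the trial's band gains with a spectral template plus Gaussian
decision noise, compared with a bias. The canonical template puts
positive weight around 500–2000 Hz and negative weight on the low
flank; individual templates add smooth jitter and are renormalized.
Decision noise is not set directly: it is solved (Gauss–Hermite
quadrature + Brent root finding) so that the observer's double-pass
choice consistency equals a target, 75% by default — a typical value
for psychophysical observers and one at which 600 trials recover the
template well (median kernel–template correlation ≈ 0.96). The number
of reverse-correlation trials per session is not a published quantity;
600 is the package default and is configurable.

In the main task the evidence is ±`filter_strength` plus the same
decision noise; `filter_strength` is set from a target expected
accuracy (default 75%, i.e. `Φ⁻¹(0.75)·σ`). Ratings use symmetric
thresholds (−θ, 0, +θ) with θ = 0.7σ; only the binary collapse enters
any analysis.

## EMG generative model

EMG is envelope-modulated noise, **not** a motor-unit simulation: a
unit-variance Gaussian carrier synthesized in the frequency domain with
support exactly 50–250 Hz, multiplied by a microvolt envelope. The
envelope is composed of:

* baseline tonus (ZM 4 µV, CS 6 µV) — present throughout, including the
  pre-stimulus baseline;
* tonic task activation 0–4000 ms (ZM 0.8 ± 0.5 µV, CS 1.6 ± 0.8 µV
  across participants) — larger on CS, producing the Muscle main
  effect;
* condition increments with 150 ms cosine ramps over 2400–3900 ms,
  NT only: ZM +1.0 ± 1.0 µV on Smiling-F trials; CS +1.2 ± 1.2 µV on
  Unsmile-C trials;
* an ASD-only linear relaxation of the whole envelope across
  1900–4000 ms (fraction 0.15 ± 0.08, clipped to [0, 0.9]);
* movement artifacts: with probability 0.2 per trial, a 250 ms
  transient at a random latency on both channels — an 8 Hz sway plus a
  broadband burst (amplitude 150 µV); the broadband component is what
  survives the 50 Hz high-pass, as with real electrode-motion
  artifacts.

Condition-effect amplitudes are drawn once per participant (Gaussian
across participants). The means-to-SD ratio ≈ 1 was chosen at design
time by a power analysis: with 21 participants a subject-level
standardized difference near 0.9 gives per-effect power above 0.9, so
the *joint* qualitative pattern (two NT effects present, four ASD
condition tests silent, the Timing × Group interaction present) is
recovered in roughly three quarters of cohorts — comfortably above the
60% recovery bar the acceptance suite demands, while keeping
between-group overlap realistic. All amplitudes live in one
`effect_map`, so null cohorts (for false-positive studies) simply drop
the condition entries and the relaxation.

Covariates are drawn per group from Gaussians centered on published
questionnaire means (AQ: NT 15.8 ± 7, ASD 33.9 ± 7; EQ: NT 44.2 ± 9,
ASD 24.9 ± 15). They correlate with nothing by construction — the
generator encodes no accuracy–AQ relation.

Per-participant random substreams are derived as `default_rng([seed,
index])`, so enlarging a cohort never reshuffles earlier participants,
and a fixed seed reproduces every array bit for bit.

## EMG pipeline

Filtering: 4th-order Butterworth band-pass 50–250 Hz applied
forward–backward (zero phase) as second-order sections; single-precision
epoch stacks are filtered in single precision, and all z-scores are
computed in double precision. Epochs span −800…+4000 ms (4,915 samples
at 1024 Hz); events whose epoch would leave the recording are dropped
with a warning. The epoch end extends to 4000 ms so that the Listening
[0, 1900) and Processing [1900, 4000) windows — half-open, so they
partition 0–4000 ms without double-counting — are fully covered; the
2900–3400 ms target window contains exactly 512 samples.

Artifact rejection is an automated surrogate for manual screening: per
muscle, an epoch is rejected when its peak absolute amplitude exceeds
median + 8 × 1.4826 × MAD of all epochs' peaks; either muscle rejects
the trial. Median/MAD thresholds assume artifacts are a minority of
trials (breakdown at 50% contamination). Under generator defaults the
rejected fraction lands near 20%, inside the 10–35% range reported for
comparable recordings.

Envelopes are |signal| smoothed by a centered 300 ms moving average
whose window shrinks at the epoch edges (every output sample averages
only in-range input); smoothing precedes z-normalization. The baseline
statistics (mean and SD over [−800, 0) ms, SD with one delta degree of
freedom) are computed on the smoothed envelope — the quantity being
normalized; a zero baseline SD marks the trial rejected. One consequence
worth knowing: with a 300 ms smoother an 800 ms baseline holds roughly
three independent samples, so 1/SD is noisy and post-stimulus z values
carry a small positive bias (≈+0.2 z) that is identical across
conditions and windows and therefore cancels from every contrast the
analyses use; the test suite verifies it vanishes as the baseline
lengthens.

## Statistics

The mixed repeated-measures ANOVA is the classical univariate solution,
computed by projecting each subject's cell means onto orthonormal
(Helmert) contrasts per within-subject stratum: the between stratum
tests Group against subjects-within-groups; each within stratum tests
the effect and its Group interaction against the pooled
contrast × subjects-within-groups term. The scaling of the projections
makes the sums of squares equal the textbook weighted-means sums of
squares exactly (verified against an explicit-loop oracle to 1e-9 and
against `pingouin.mixed_anova` to ~1e-9, including unequal group sizes
and partial η²). Sphericity corrections are unnecessary in every design
used here because all within factors have two levels; multi-level
within factors use the pooled (sphericity-assuming) univariate test.
Sums of squares below the data's machine precision are treated as zero
so constant responses yield F = 0 rather than numerical noise.

t-tests are pooled-variance Student tests (the published degrees of
freedom imply pooling); the Bayes factor is the default two-sided JZS
test — Cauchy(0, 0.707) prior on the standardized effect, marginal
likelihood by adaptive quadrature of the noncentral-t density, with the
quadrature error reported. At t = −0.07 with groups 21/20 this yields
BF₁₀ = 0.3065; since BF₁₀ is minimized at t = 0 (0.3059 for these
sizes), any published value below that for the same prior and sizes
cannot arise from this test. Pearson correlations report r, df,
t = r·√(df/(1−r²)), and p explicitly.

Kernel Distance is the per-band mean absolute difference to the
combined reference kernel (all 41 participants pooled, groups weighted
by size); an RMS variant is available. Per-band group comparisons are
independent-samples t-tests without multiplicity correction — the
band-wise screen is intentionally exploratory.

## Problem sizes

Defaults everywhere are the study-scale conditions: 21 + 20
participants, 80-sentence sessions, 600 reverse-correlation trials,
1024 Hz EMG. The recovery studies in the acceptance suite run 200
effect cohorts and 60 null cohorts end to end (simulation → pipeline →
ANOVAs, about 3 s per cohort); the ANOVA calibration study uses 5,000
null replicates; generator conformance pools 10⁶ gain draws.

## Limitations

* The EMG model validates the *pipeline and inference*, not
  electrophysiology: no motor-unit statistics, electrode cross-talk,
  line noise, or impedance drift. Passing tests show the analysis chain
  recovers effects of the assumed envelope form at the assumed SNR —
  not that real recordings satisfy those assumptions.
* The smile filter is a generic spectral-envelope transform; it is not
  a reimplementation of any specific voice-transformation toolbox, and
  its inverse property is approximate (≈1% on smooth spectra).
* Choice labels in the EMG analysis come from the same simulated
  observer that drives accuracy, so Filter and Choice are correlated
  exactly as in real data (accuracy ≈ 75%); cells of the
  Filter × Choice design are therefore unbalanced, which the
  cell-means ANOVA absorbs.
* Artifact rejection is automated and threshold-based; it stands in
  for, and cannot reproduce, expert manual screening.
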