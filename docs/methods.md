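# Methods

This note documents the models behind `pulseloop`, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Real-time feature path

The engine consumes a 1000 Hz multichannel stream through a 3 s circular
buffer and emits one feature per second: the most recent 1 s (N = 1000
samples) of the target channel is linearly detrended (least-squares line,
removing both offset and drift), band-passed, and summarized as
`P_dB = 10·log10((1/N)·Σ x_i²)`. Update step = window length = 1 s, so
features never overlap and consecutive samples are exactly 1 s apart.

**Filter.** A 180th-order (181-tap) Hamming windowed-sinc bandpass —
type-I linear phase, so the group delay is exactly 90 samples (90 ms) at
every frequency. At this order the theta design (4–7 Hz) holds the band
center within ±1 dB of unity and reaches −40 dB by ~13 Hz past the upper
edge; sharper roll-off is physically unavailable at 181 taps and 1000 Hz,
which is why out-of-band rejection is specified at 20 Hz for theta rather
than immediately adjacent to the band.

**Filter settling.** The FIR is causal and is warmed with the samples that
immediately precede the evaluation window (the buffer always holds them,
as would any streaming implementation), so the window is filter-settled
and the power is computed over the *full* window — nothing is trimmed.
Without that context a fresh-start transient costs ~0.5 dB on a stationary
tone and ~8 dB of out-of-band rejection. No group-delay compensation is
applied in the live path (a causal system cannot); the 90 ms lag is simply
part of the loop latency.

## Adaptive control

Calibration features give μ and σ (sample SD). Initial thresholds are
lenient — μ + 0.5σ for theta suppression, μ − 0.5σ for SMR enhancement —
so early trials succeed and the trainee stays motivated. σ is *frozen* at
its calibration value for the whole session; only the threshold moves.

Trial success: the 3 s before each shot is split into four overlapping 1 s
sub-windows starting at −3.0, −2.5, −2.0, −1.5 s (the last ends 0.5 s
before firing, clear of movement artifact). Each runs through the same
detrend → FIR → log-power pipeline; a window "hits" when it is strictly
below (suppression) or strictly above (enhancement) the threshold, and the
trial succeeds on ≥ 2 hits. Ties at exactly the threshold count as misses:
with continuous features ties are measure-zero, and strictness is the
conservative reading. A non-overlapping robustness variant uses windows
[−3,−2], [−2,−1], [−1,0] with a two-of-three rule; on stationary input the
two schemes agree on the large majority of trials, with the overlapping
scheme slightly more permissive.

After each 10-trial block with success rate ≥ 70% (the criterion read
inclusively), the threshold steps in the stricter direction and the level
boundaries are recomputed from the frozen σ. The default step is 0.75σ,
exposed in config. The step plays the role of the experimenter's manual
adjustment, whose job is to keep the success rate in the 50–70% operating
zone: the session opens 0.5σ lenient with a ~85–90% success rate, so the
threshold has to traverse roughly 1.5σ within the four blocks to reach the
trainee's operating point; at 0.25σ per block it cannot get there and the
session never leaves the >85% regime, while at 0.75σ the simulated
sessions settle at a median block success of ~0.7.

The exact placement of the four sub-windows inside "the 3 s before the
shot" admits alternatives (the chosen spans cover −3.0..−0.5 s); the
non-overlapping scheme is config-selectable rather than a second truth.

## Five-level feedback

Boundaries at threshold ± 0.5σ and ± 1.0σ split the feature axis into five
zones, lower-bound-inclusive so boundary values are deterministic. Level 1
is always optimal: in enhancement mode the highest-power zone, in
suppression mode the lowest-power zone (pure inversion, so
`level_enhance(f) = 6 − level_suppress(f)`).

Guard band: while the feature sits in the Level-3 zone (threshold ±
0.5σ), levels 2–4 hold and levels 1/5 step one level toward 3 per update —
small fluctuations near threshold never flip the sound. Outside the zone
the emitted level jumps directly to the raw zone level: large deviations
are signalled promptly rather than rate-limited (the alternative —
stepwise everywhere — would delay a 1→5 alarm by four updates).

Acoustics ("better state, quieter feedback"): per level, volume
coefficients (0.20 / 0.35 / 0.60 / 0.90–0.60 / 1.00–0.75–0.50), playback
rate multipliers (0.55–1.30), single/double/triple beats with 80/60 ms
gaps, and linear fade-in/out (150/100/60/40/30 ms) to kill onset clicks.
Rate change is implemented as polyphase resampling of the template, so
pitch shifts with rate — the "playback rate" semantics of a sampler.
Multi-beat volumes map positionally to beats (loudest first). The bundled
template is synthetic — a 55 Hz tone under a gamma envelope peaking 150 ms
in, peak-normalized — and any mono WAV can replace it; the envelope peak
sits late enough that no level's fade-in touches the peak, keeping the
rendered peak exactly the volume coefficient times the template peak.

## Synthetic EEG and the closed-loop agent

Background noise is 1/f ("pink"): a 1/√f amplitude profile with uniform
random phases, inverse-FFT'd, de-meaned and scaled to 10 µV RMS per
channel. The spectral slope is exact by construction (−1 on the log-PSD),
which is what the generator's own test measures. Oscillations are added as
sinusoids with arbitrary instantaneous-amplitude envelopes;
`mix_instantaneous` provides zero-lag mixtures as volume-conduction
fixtures.

The closed-loop simulator advances on the 1 s feature clock. Each second
it composes that second's signal (background + target-band sinusoid at the
agent's current amplitude), extracts the feature exactly as the live path
does, emits a guarded feedback level, and logs everything. Shots fire
self-paced at uniform 6–12 s spacing (wide enough that a pre-shot window
never overlaps the previous feedback burst; the real timing distribution
of a self-paced trainee is unknown, so this is a deliberate, documented
choice). Defaults follow the training protocol: 60 s calibration, 4 blocks
× 10 shots, theta-suppression at Fz with a 5.5 Hz carrier.

**Agent.** The stand-in learner holds a target-band amplitude (baseline
6 µV, floored at 0) and reacts to the feedback heard around each shot:
with probability `1 − lapse_prob` (default lapse 0.1) it moves its
amplitude by `gain · max(level − 3, 0)` dB in the improving direction
(default gain 0.2 dB per level of error) plus N(0, 0.3²) dB of noise. The
error term is *rectified* deliberately: a learner corrects the deviations
the sound signals and holds an achieved good state. The unrectified
alternative (±gain·(level−3)) is a proportional controller whose fixed
point is the threshold itself — it pins success at ~50%, never trips the
70% staircase, and produces no learning trend, which is not how operant
feedback training behaves. One global seed fans out to independent
substreams (noise, agent, inter-shot intervals), so each component is
reproducible on its own.

**What the simulation shows and does not.** Passing closed-loop tests
demonstrate that the engine's bookkeeping (thresholds, windows, levels,
logs) is correct and that the loop produces the qualitative signatures of
training — a declining block-mean target feature and success rates
hovering in the staircase's operating zone. They say nothing about human
learnability: the agent has no physiology, no artifacts (no EOG/EMG, no
electrode drift beyond the detrended ramp), no inter-subject variability
beyond its noise terms, and the synthetic EEG has no true cross-channel
dynamics (volume conduction appears only via explicit mixing fixtures).

## Offline analysis

**Epoching.** Task epochs are [−6, 0) s before each firing trigger (0-based
sample indexing, half-open intervals); duplicate triggers within 1 s
collapse to the first; epochs without full pre-data are dropped and
counted. Rest segments use non-overlapping 2 s epochs.

**Morlet TFR.** Complex Morlet wavelets, 5 cycles, ±5σ_t support,
amplitude-calibrated so a stationary sinusoid of amplitude A yields power
A²/2 — the same mean-square convention as the live feature, making the
closed-form oracle exact. Per-trial convolution (FFT overlap), trial
averaging, then dB; the default grid is 4–45 Hz in 1 Hz steps at 50 ms.
Samples within half the wavelet support of an epoch edge are flagged
invalid and excluded from every ROI statistic. ROI metrics are reported as
log10 power (dB/10): dB for maps, log10 for scalar ROI/responder metrics.

**Responders.** A subject is an SMR responder when Cz 12–15 Hz log10 power
(−3.0..−0.5 s pre-shot mean) is strictly higher under SMR feedback than
under the no-sound baseline, and a theta responder when Fz 4–7 Hz power is
strictly lower under theta feedback; equality is non-response.

**Surface Laplacian.** Hjorth finite difference: each scalp channel minus
the mean of its spatial neighbors. Neighbors come from template 10–20
coordinates with a 70 mm Euclidean radius (median ~5 neighbors on the
32-channel montage); mastoids are excluded from the neighbor graph and
passed through unchanged, though they remain in connectivity matrices.

**dwPLI.** Observations are trial × DPSS-taper spectra (multitaper FFT,
±1 Hz smoothing; below a unit time-bandwidth product a single Hann taper
is used). Per frequency bin the debiased WPLI-square estimator

    Σ_{j≠k} Im(Z_j)·Im(Z_k) / Σ_{j≠k} |Im(Z_j)·Im(Z_k)|

is computed over observations j,k and averaged across the band's bins.
Built on the imaginary cross-spectrum, it is insensitive to zero-lag
(volume-conducted) coupling — the property the mixing fixtures test — and
debiasing removes the positive small-sample bias of squared WPLI.
Degenerate bins (denominator 0) contribute 0.

**Graphs.** Global FC is the mean of the strictly-upper triangle.
Binarization keeps the ⌈0.20·E⌉ strongest edges, ties broken by
lexicographic channel-pair order for determinism. Efficiency and
clustering are binary (networkx; disconnected pairs contribute 0),
weighted strength is the node-mean sum of retained-edge weights, and
degree heterogeneity — never given a formula in the connectivity
literature this follows — is implemented as the coefficient of variation
SD(degree)/mean(degree) of the binary degree sequence.

**Cluster permutation tests.** Both variants use one-sample t over
subjects on within-subject condition differences (sign-flip of a paired
difference is equivalent to exchanging condition labels in a paired
design), a two-sided cluster-forming threshold at α_cluster = 0.05
(|t| > t_{1−α/2, n−1}), summed t as the cluster statistic, and a Monte
Carlo null of the *maximum* |cluster statistic| over random per-subject
sign flips, giving corrected p = (1 + #{null ≥ |obs|})/(n_perm + 1), never
below 1/(n_perm+1). TFR clusters connect over the frequency–time grid
(4-neighborhood) within a channel and across spatially adjacent channels
at the same grid point; edge clusters connect significant edges that share
a node, positive and negative edges separately. Significance is declared
at α/2 = 0.025 per tail for the two-tailed map test and 0.05 for the edge
test. Implementation note: sign-flipped t-maps for all permutations come
from a single matrix product (squares are sign-invariant), so 500–5000
permutations over a few hundred points cost milliseconds; the reference
default is 5000 permutations, and the property suites run 500 to fit 200
null datasets into the empirical type-I checks.

## Statistics

Power for the paired two-tailed t-test uses the noncentral t distribution:
δ = d·√n, power = P(|T′_{n−1}(δ)| > t_{1−α/2,n−1}); at n = 21, α = 0.05
this gives 0.9364 for d = 0.80 and 0.5873 for d = 0.50, and it tends to α
as d → 0. The Pearson CI uses Fisher's z with SE = 1/√(n−3) (the method is
a package choice; bootstrap agreement is tested); r = 0.67, n = 22 →
[0.35, 0.85] at 2 dp. Cohen's κ, BH-FDR (statsmodels step-up) and Spearman
(average ranks) are standard. Angular subtense is 2·arctan(w/d) in
degrees: 2·arctan(10/1000) = 2·arctan(25/2500) ≈ 1.146°, the invariance
that justifies a proportionally scaled shooting range. All tests are
two-tailed unless configured otherwise.

## Problem sizes in the verification suites

The property suites choose sizes that make the statistical assertions
sharp rather than large: dwPLI simulations use 200 one-second trials at
250 Hz; cluster recovery plants a −1 dB effect (noise SD 0.5) in 12
subjects on a 6-channel × 10-frequency × 15-time grid (and 8 edges on 5
nodes across 13 subjects for the edge variant); empirical type-I rates use
200 null datasets at 500 permutations; the closed-loop trend test runs 20
seeded full sessions and the windowing-oracle comparison 12 stationary
sessions against 200 Monte-Carlo trials per session threshold. The
windowing oracle is an independent re-implementation (polyfit detrend,
direct firwin/lfilter, manual rule) evaluated at each session's initial
threshold, so the comparison is conditioned on the calibration draw — the
dominant noise source — and tests the windowing scheme itself.

## I/O and reproducibility

EEG travels as plain EDF (16-bit, per-channel physical scaling in µV, 1 s
records; non-integer-second recordings are zero-padded into the final
record), events as `time_s,kind` CSV, engine logs as JSONL, reports as
JSON. Configs are validated against a closed key set — unknown keys are
errors, not warnings. Every pipeline report embeds the resolved config,
the seed and SHA-256 hashes of its inputs, and identical config + seed
yields a byte-identical report.

## Known limitations

- The synthetic agent is a one-dimensional amplitude controller; it cannot
  model strategy switching, fatigue, or frequency-band interactions, so
  cross-band spillover effects are outside what the simulator can produce.
- The finite-difference Laplacian is a local approximation; a spline-based
  scalp current density is out of scope.
- The EDF writer emits the plain (non-plus) format without embedded
  annotations; events live in the CSV sidecar.
- Streaming cadence is exact when the delivery chunk divides the sampling
  rate (the 40 ms default at 1000 Hz does); other chunk sizes stamp
  features at the following chunk boundary.
- Artifact handling (ocular/muscular components, bad channels) is not
  implemented; inputs are assumed clean or pre-cleaned.
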