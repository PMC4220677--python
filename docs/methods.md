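# Methods

## Pipeline model

The package treats a training session as a multivariate per-second time
series: an EEG-engagement probability, an EEG-workload probability (both
produced upstream by discriminant classifiers and consumed here as given),
and heart rate in beats per minute, with a per-epoch validity mask. Epochs
are 1-s half-open intervals [t, t+1), 0-based from session start.

**Self-normalization.** Each metric is z-scored with the mean and sample
(N−1) standard deviation over the session's *valid* epochs. This removes
between-subject baselines and measurement units; the feature pipeline is
therefore invariant to affine rescaling of any raw metric (a property test
asserts this). Normalization happens after artifact discarding, on valid
epochs only: contaminated epochs are excluded from all further analysis, and
interpolating through them would fabricate data. A constant metric is an
error — the z-score is undefined, and a session without dispersion carries no
usable signal.

**Windowing.** A 3-s window shifted in 1-s steps yields 9-vectors ordered
(engagement s1–s3, workload s1–s3, heart rate s1–s3), referenced to the
middle second. Windows touching any invalid epoch are not emitted, so a fully
valid T-second session yields exactly T−2 windows. Transitions between
consecutive *available* windows are counted even across artifact gaps; a
maximum-gap filter is available but off by default.

**The map.** A 1-D self-organizing map with N = 20 nodes is trained for 200
iterations with the batch rule: per iteration every vector is assigned to its
best matching unit (Euclidean distance, ties to the lowest index), then each
node's weights become the neighborhood-weighted mean of the assigned vectors.
The neighborhood kernel is squared-exponential in grid distance,
exp(−d²/2σ²); σ decays linearly from N/2 to 1 over the ordering phase (the
first half of the iterations), after which only the BMU is updated — exactly
a Lloyd k-means step on the current assignments, so the quantization error is
non-increasing through the convergence phase and training ends at (or very
near) a fixed point. Weights are initialized evenly along the first principal
axis of the training data, spanning ±2 SD of the projections, so the map
starts ordered. Nothing in initialization or training is stochastic:
identical data and configuration reproduce the weights bit for bit. Nodes
receiving zero kernel mass keep their previous weights (the batch formula is
undefined for empty nodes).

**Transition score.** For a session's BMU sequence i(1)…i(t), the score is
Σ_{j=2..t} |i(j) − i(j−1)|, bounded by (t−1)(N−1). It is reported raw (a
per-transition mean is available as a non-default option since session
lengths differ) and equals Σ_{a,b} count(a,b)·|a−b| over the session's
transition matrix — a consistency identity the tests enforce exactly.

**Inference.** Transition scores are correlated with per-session performance
(Pearson r; two-tailed p from t = r√((n−2)/(1−r²))), with no multiple-testing
adjustment. Event-aligned node distributions use one observation per matched
event instance — the one-hot activation indicator of the node whose window
reference time equals the event second. The one-way MANOVA computes Wilks'
Λ = det(E)/det(E+H), Rao's F approximation, partial η² = 1 − Λ^{1/s}
(s = min(p, g−1)), and observed power from the noncentral F with ncp = F·df1
at α = 0.05 (a common package convention; approximate). One-hot observations
make the within-group scatter singular, so a configurable ridge
(ridge · mean-diagonal · I) is added and flagged in the result; the
regularization strength is the analyst's choice.

**Cross-validation.** The person-independent scheme uses small *training*
folds: with n subjects and k folds, the first k−1 training folds hold
⌊n/k⌋ subjects and the last takes the remainder (51 subjects → nine folds of
5 and one of 6); every subject trains exactly once, and each fold's test set
is all remaining subjects. A session is tested by every fold excluding its
subject; its cross-validated score is the mean across those folds, so each
session enters the pooled correlation once.

**Regression baseline.** OLS (no regularization) of the session performance
score, replicated to each of the session's windows, on the 9 window features
— the unit of analysis that makes 9 predictors meaningful and yields the
characteristically tiny r² of per-window prediction; session-mean aggregation
is available as an option. Tolerance and VIF come from auxiliary regressions
of each predictor on the other eight (VIF = 1/(1−R²), tolerance = 1/VIF);
exact collinearity raises rather than silently pseudo-inverting.

## Signal-processing defaults

| Parameter | Default | Notes |
|---|---|---|
| ECG band-pass | 15–35 Hz, 4th-order Butterworth, forward-only | causal, matching a real-time chain; sharpens QRS against the T wave |
| Peak threshold | running mean + 3·SD over a causal 2-s window | standard QRS-detection practice; all configurable |
| Refractory | 250 ms | first candidate wins |
| Beat quality | RR deviating > 3·SD from the mean of up to 6 preceding RRs | SD floored at 10 ms; beats with < 2 predecessors pass |
| Heart rate | 60/RR bpm, carried to each 1-s epoch from the latest usable beat | epochs ending before the second peak are missing |
| Epoch PSD | 1-s periodogram on 1-Hz bins, Parseval-normalized | natural-log transform, power floored at 1e−12 |
| Relative PSD | log(bin) − log(total 1–40 Hz) | log-domain difference, i.e. log share of band power |
| EMG screen | mean log power 35–40 Hz > log(1e−4) AND √(Σ power 70–128 Hz) > 0.05 | calibrated on the synthetic generator; real data require re-calibration |

The EEG front end (0.5–65 Hz band-pass, 50/60/100/120 Hz notches) is provided
for raw-signal input and is inert for the synthetic metric pathway.

## The synthetic cohorts

Sessions are driven by a hidden chain of 5 latent states whose (engagement,
workload, heart-rate) offsets are collinear — spaced along one direction,
±(0.15, 0.12, 10 bpm) around baselines (0.5, 0.5, 75 bpm) — so the latent
index is a 1-D coordinate a line-shaped map can recover. Per second the chain
stays put with probability *stickiness* and otherwise moves to an adjacent
state; scheduled task events force a jump to a uniformly chosen different
state with probability 0.8. Observation noise is AR(1) (coefficient 0.5)
with innovation SDs (0.03, 0.03, 1.2 bpm). Artifact masking is Bernoulli per
epoch at rate 0.22, emulating the ~22% contamination typical of field EEG
recordings.

Cohorts draw each session's stickiness uniformly from (0.70, 0.98): sessions
genuinely differ in state volatility, which is the between-session variation
the transition score measures. With a single shared stickiness, path
variability differs only by chain noise, and per-session z-scoring largely
cancels it — no planted effect would then be recoverable by any method, so
volatility heterogeneity is a deliberate modeling choice, not a tuning knob.
Session performance is clip(70 + β·z(path variability) + ε, 0, 100) with the
unclipped scores retained as ground truth; defaults β = 5, SD(ε) = 8.66 give
a true latent correlation of β/√(β²+SD²) = 0.5.

What the generator does **not** emulate: realistic EEG/ECG morphology beyond
what peak detection needs (the QRS template is an 80-ms windowed biphasic
pulse), circadian or fatigue drift, inter-subject differences in baseline
physiology beyond what z-scoring removes, and any true cognitive semantics of
the latent states. Passing tests therefore demonstrate the *pipeline's*
correctness and statistical calibration, not that real physiology behaves
like the chain.

## Problem sizes and numerical choices

The default study-scale run is 10 subjects × 5 sessions × 300 s (50 sessions,
≈ 11,000 windows); the test suite and the acceptance script use this size for
recovery checks, a 20-session × 120-s cohort with a 60-iteration map for the
200-replicate null-calibration loop (the null property is size-independent),
and 10,000-s single chains for occupancy convergence. Occupancy is checked
against the kernel's analytic stationary distribution with the Markov-chain
CLT standard deviation from the fundamental matrix — occupancy samples are
autocorrelated, so an iid binomial bound would reject a correct chain.
Planted-effect recovery is asserted on the aggregate over 20 cohort seeds:
the realized correlation of one 50-session cohort has sampling SD ≈ 0.11, and
the score measures the latent variability with fidelity ≈ 0.8, so individual
seeds legitimately scatter while the mean recovers the planted value well
within ±0.2.

Other numerics: Euclidean BMU ties break to the lowest node index; the PCA
leading eigenvector's sign is fixed by its largest-magnitude component;
z-scores use the sample (N−1) SD; log-PSD floors power at 1e−12; peak
matching in evaluation uses a 50-ms window (the causal band-pass delays
detected peaks by a constant ≈ 43 ms at 256 Hz).

## Known limitations

- EMG-screen thresholds are generator-calibrated stand-ins; the original
  thresholds were tuned by visual inspection of a proprietary cohort and are
  unknown.
- The upstream engagement/workload classifiers are out of scope; the pipeline
  starts from their per-second outputs.
- 2-D map grids, online (non-batch) training, and alternative distance
  metrics are not implemented.
- The MANOVA observed-power figure inherits the usual post-hoc-power caveats
  and is reported for format compatibility, not recommended for inference.
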