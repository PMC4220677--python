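"""Synthetic cohorts of per-second physiological metric sessions.

No human study data ship with this package, so every downstream stage is
exercised on simulated sessions with known ground truth.  A session is driven
by a small hidden state chain: each latent state fixes a triple of metric
offsets (engagement, workload, heart rate), the chain is sticky — most
transitions stay put or move to a neighboring state — and scheduled task
events can force a jump to a different state.  Observed metrics are the state
means plus AR(1) noise, which reproduces the qualitative structure the method
targets: locally smooth dynamics with rare large excursions tied to events.

Session performance scores carry a plantable linear dependence on the
latent path variability (the summed absolute state jumps), so correlation and
cross-validation stages can be checked for parameter recovery and null
calibration.  A minimal ECG simulator with exact ground-truth R-peak times
feeds the heart-rate chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import PerformanceRecord
from .biosignals import ECGRecord
from .features import MetricTimeSeries

# Pre-normalization baselines. Engagement/workload are probability-like and
# heart rate is in bpm; the exact scale is irrelevant after self-normalization.
BASELINES = np.array([0.5, 0.5, 75.0])

PERFORMANCE_BASELINE = 70.0  # percent, before the planted effect and noise


@dataclass
class EventLog:
    """Task events for one session: a time (s) and a label per instance."""

    times: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels must align")

    def __len__(self) -> int:
        return len(self.times)

    def of_label(self, label: str) -> np.ndarray:
        return self.times[np.array([l == label for l in self.labels], dtype=bool)]


@dataclass
class LatentStateSpec:
    """Hidden chain driving a session's metric dynamics.

    ``state_means`` is an ``n_states × 3`` array of (engagement, workload,
    heart-rate) offsets added to :data:`BASELINES`.  Per second the chain
    stays in place with probability ``transition_stickiness`` and otherwise
    moves to an adjacent state; a scheduled event forces a jump to a uniformly
    chosen different state with probability ``event_jump_prob``.  Observation
    noise is AR(1) per metric with coefficient ``ar_coefficient`` and
    innovation scale ``noise_sd``.
    """

    n_states: int = 5
    state_means: np.ndarray | None = None
    transition_stickiness: float = 0.90
    ar_coefficient: float = 0.5
    noise_sd: tuple[float, float, float] = (0.03, 0.03, 1.2)
    event_jump_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not 0.0 <= self.transition_stickiness <= 1.0:
            raise ValueError("transition_stickiness must be in [0, 1]")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be non-negative")
        if self.state_means is None:
            # states ordered along one direction so the latent index is a
            # 1-D coordinate the map can recover
            u = np.linspace(-1.0, 1.0, self.n_states) if self.n_states > 1 else np.zeros(1)
            self.state_means = np.column_stack([0.15 * u, 0.12 * u, 10.0 * u])
        self.state_means = np.asarray(self.state_means, dtype=np.float64).reshape(
            self.n_states, 3
        )

    def transition_kernel(self) -> np.ndarray:
        """Row-stochastic per-second kernel: sticky with nearest-neighbor moves."""
        n, p = self.n_states, self.transition_stickiness
        K = np.zeros((n, n))
        if n == 1:
            return np.ones((1, 1))
        for i in range(n):
            K[i, i] = p
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
            for j in nbrs:
                K[i, j] += (1.0 - p) / len(nbrs)
        if not np.allclose(K.sum(axis=1), 1.0):
            raise ValueError("transition kernel rows must sum to 1")
        return K

    def stationary_distribution(self) -> np.ndarray:
        """Left Perron eigenvector of the kernel, normalized to sum to 1."""
        K = self.transition_kernel()
        w, v = np.linalg.eig(K.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class CohortSpec:
    """Study-scale knobs for a simulated cohort.

    Sessions differ in how volatile their latent state path is: each
    session's chain stickiness is drawn uniformly from ``stickiness_range``,
    so the cohort spans calm to volatile sessions — the between-session
    variation the transition score is meant to pick up.  The planted
    performance link has true correlation
    ``beta / sqrt(beta² + noise_sd²)`` with the latent path variability
    (0.5 at the defaults).
    """

    n_subjects: int = 10
    sessions_per_subject: int = 5
    session_duration_s: int = 300
    artifact_rate: float = 0.22
    stickiness_range: tuple[float, float] = (0.70, 0.98)
    performance_beta: float = 5.0
    performance_noise_sd: float = 8.66
    performance_metric: str = "percent_enemy_hits"
    event_interval_s: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")
        if self.session_duration_s < 10:
            raise ValueError("session_duration_s must be >= 10")
        if self.n_subjects < 2:
            raise ValueError("cohort-level analyses need n_subjects >= 2")


@dataclass
class SyntheticSession:
    metrics: MetricTimeSeries
    events: EventLog
    truth_state_path: np.ndarray
    truth_path_variability: float

    def __post_init__(self) -> None:
        self.truth_state_path = np.asarray(self.truth_state_path, dtype=np.int64)
        if len(self.truth_state_path) != len(self.metrics):
            raise ValueError("truth_state_path must cover every second")


@dataclass
class Cohort:
    sessions: list[SyntheticSession]
    performance: list[PerformanceRecord]
    spec: CohortSpec
    state_spec: LatentStateSpec
    raw_scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def path_variabilities(self) -> np.ndarray:
        return np.array([s.truth_path_variability for s in self.sessions], dtype=float)


def generate_session(
    spec: LatentStateSpec,
    duration_s: int,
    event_schedule: EventLog | None = None,
    seed: int = 0,
    subject_id: str = "S00",
    session_id: str = "T00",
    task_label: str = "task",
) -> SyntheticSession:
    """Simulate one session of per-second metrics from the hidden chain.

    Fully deterministic given the spec and seed.  Event seconds in the
    schedule override the chain step: with probability ``event_jump_prob``
    the state jumps to a uniformly chosen *different* state.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10")
    if event_schedule is None:
        event_schedule = EventLog(np.empty(0, dtype=int), [])
    rng = np.random.default_rng(seed)
    K = spec.transition_kernel()
    n = spec.n_states
    event_seconds = set(int(t) for t in event_schedule.times)

    path = np.empty(duration_s, dtype=np.int64)
    path[0] = rng.integers(n)
    for t in range(1, duration_s):
        s = path[t - 1]
        if t in event_seconds and n > 1 and rng.random() < spec.event_jump_prob:
            others = [j for j in range(n) if j != s]
            path[t] = others[rng.integers(len(others))]
        else:
            path[t] = rng.choice(n, p=K[s])

    sd = np.asarray(spec.noise_sd, dtype=float)
    innov = rng.standard_normal((duration_s, 3)) * sd
    noise = np.empty_like(innov)
    noise[0] = innov[0]
    for t in range(1, duration_s):
        noise[t] = spec.ar_coefficient * noise[t - 1] + innov[t]
    values = BASELINES + spec.state_means[path] + noise

    metrics = MetricTimeSeries(
        time_s=np.arange(duration_s),
        engagement=values[:, 0],
        workload=values[:, 1],
        heart_rate=values[:, 2],
        valid=np.ones(duration_s, dtype=bool),
        subject_id=subject_id,
        session_id=session_id,
        task_label=task_label,
    )
    variability = float(np.abs(np.diff(path)).sum())
    return SyntheticSession(metrics, event_schedule, path, variability)


def default_event_schedule(duration_s: int, interval_s: int, seed: int) -> EventLog:
    """Alternating friend/enemy appearances with jittered spacing."""
    rng = np.random.default_rng(seed)
    times, labels = [], []
    t = interval_s
    k = 0
    while t < duration_s - 2:
        times.append(t)
        labels.append("visible_friend" if k % 2 == 0 else "visible_enemy")
        t += int(interval_s + rng.integers(-interval_s // 4, interval_s // 4 + 1))
        k += 1
    return EventLog(np.array(times, dtype=int), labels)


def inject_artifacts(
    metrics: MetricTimeSeries, artifact_rate: float, seed: int = 0
) -> MetricTimeSeries:
    """Mark a Bernoulli(rate) subset of epochs invalid; values untouched."""
    if not 0.0 <= artifact_rate < 1.0:
        raise ValueError("artifact_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hit = rng.random(len(metrics)) < artifact_rate
    return replace(metrics, valid=metrics.valid & ~hit)


def generate_cohort(spec: CohortSpec, state_spec: LatentStateSpec | None = None) -> Cohort:
    """Simulate a cohort with a planted path-variability → performance link.

    Each session's performance score is
    ``clip(70 + beta * z(path variability) + noise, 0, 100)`` where the
    z-score is taken across the cohort's sessions; ``raw_scores`` keeps the
    unclipped values.  Everything derives deterministically from
    ``master_seed`` via spawned per-session seed sequences.
    """
    if state_spec is None:
        state_spec = LatentStateSpec()
    root = np.random.SeedSequence(spec.master_seed)
    n_sessions = spec.n_subjects * spec.sessions_per_subject
    children = root.spawn(n_sessions + 1)

    lo, hi = spec.stickiness_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("stickiness_range must satisfy 0 <= lo <= hi <= 1")
    sessions: list[SyntheticSession] = []
    idx = 0
    for s in range(spec.n_subjects):
        for r in range(spec.sessions_per_subject):
            seeds = children[idx].generate_state(4) % (2**31)
            events = default_event_schedule(
                spec.session_duration_s, spec.event_interval_s, int(seeds[0])
            )
            stickiness = float(
                np.random.default_rng(int(seeds[3])).uniform(lo, hi)
            )
            sess = generate_session(
                replace(state_spec, transition_stickiness=stickiness),
                spec.session_duration_s,
                events,
                seed=int(seeds[1]),
                subject_id=f"S{s:02d}",
                session_id=f"T{r:02d}",
            )
            if spec.artifact_rate > 0:
                sess = SyntheticSession(
                    inject_artifacts(sess.metrics, spec.artifact_rate, int(seeds[2])),
                    sess.events,
                    sess.truth_state_path,
                    sess.truth_path_variability,
                )
            sessions.append(sess)
            idx += 1

    var = np.array([s.truth_path_variability for s in sessions])
    sd = var.std(ddof=1) if len(var) > 1 else 0.0
    z = (var - var.mean()) / sd if sd > 0 else np.zeros_like(var)
    perf_rng = np.random.default_rng(children[-1].generate_state(1)[0] % (2**31))
    noise = perf_rng.standard_normal(n_sessions) * spec.performance_noise_sd
    raw = PERFORMANCE_BASELINE + spec.performance_beta * z + noise

    performance, raw_scores = [], {}
    for sess, score in zip(sessions, raw):
        key = sess.metrics.key
        raw_scores[key] = float(score)
        performance.append(
            PerformanceRecord(
                subject_id=key[0],
                session_id=key[1],
                metric=spec.performance_metric,
                value=float(np.clip(score, 0.0, 100.0)),
            )
        )
    return Cohort(sessions, performance, spec, state_spec, raw_scores)


# ----------------------------------------------------------------------------
# ECG simulation

QRS_SUPPORT_S = 0.08  # ~80 ms biphasic template


def qrs_template(sampling_rate: float) -> np.ndarray:
    """Narrow biphasic pulse with unit peak at its center sample."""
    half = int(round(QRS_SUPPORT_S / 2 * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    carrier = np.cos(2 * np.pi * t / QRS_SUPPORT_S)
    window = 0.5 * (1 + np.cos(np.pi * t / (QRS_SUPPORT_S / 2)))
    return carrier * window


def generate_ecg(
    rr_intervals: np.ndarray,
    sampling_rate: float = 256.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ECGRecord, np.ndarray]:
    """Synthesize a single-lead ECG as QRS pulses at cumulative RR times.

    Returns the record and the exact ground-truth peak times in seconds.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if np.any((rr < 0.3) | (rr > 2.0)):
        raise ValueError("rr_intervals must lie in [0.3, 2.0] s")
    if sampling_rate < 100:
        raise ValueError("sampling_rate must be >= 100 Hz to resolve the template")
    peak_times = np.cumsum(rr)
    n = int(np.ceil((peak_times[-1] + 0.5) * sampling_rate))
    x = np.zeros(n)
    tmpl = qrs_template(sampling_rate)
    half = (len(tmpl) - 1) // 2
    peak_samples = np.round(peak_times * sampling_rate).astype(int)
    for p in peak_samples:
        lo, hi = p - half, p + half + 1
        a, b = max(lo, 0), min(hi, n)
        x[a:b] += tmpl[a - lo : len(tmpl) - (hi - b)]
    if noise_sd > 0:
        x += np.random.default_rng(seed).standard_normal(n) * noise_sd
    true_times = peak_samples / sampling_rate
    return ECGRecord(samples=x, sampling_rate=sampling_rate), true_times
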