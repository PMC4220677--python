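"""Per-second metric series and the 3-s sliding-window feature builder.

The pipeline consumes three per-second physiological metrics — an
EEG-engagement probability, an EEG-workload probability and heart rate in
beats per minute — together with a per-epoch validity mask produced by the
artifact screen.  Each metric is self-normalized (z-scored) within the
session so that between-subject baseline differences drop out, and a 3-s
sliding window shifted in 1-s increments turns the series into 9-dimensional
feature vectors: the three metrics over three consecutive seconds.  The
middle second of each window is its reference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Column order of a feature row: each metric over window seconds 1..3.
FEATURE_NAMES: tuple[str, ...] = (
    "engagement_sec1", "engagement_sec2", "engagement_sec3",
    "workload_sec1", "workload_sec2", "workload_sec3",
    "heart_rate_sec1", "heart_rate_sec2", "heart_rate_sec3",
)

METRIC_NAMES: tuple[str, ...] = ("engagement", "workload", "heart_rate")

WINDOW_LEN = 3  # seconds per feature window; 1-s step is implied


@dataclass
class MetricTimeSeries:
    """Aligned per-second engagement/workload/heart-rate samples for one session.

    All three metrics live on the same integer-second grid (1-s half-open
    epochs ``[t, t+1)``, 0-based from session start).  ``valid`` marks epochs
    that survived artifact screening; invalid epochs keep their raw values but
    are excluded from normalization and never enter a feature window.
    """

    time_s: np.ndarray
    engagement: np.ndarray
    workload: np.ndarray
    heart_rate: np.ndarray
    valid: np.ndarray
    subject_id: str = "S00"
    session_id: str = "T00"
    task_label: str = "task"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.int64)
        for name in METRIC_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_s)
        for name in (*METRIC_NAMES, "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length != {n}")
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            bad = int(np.argmax(np.diff(self.time_s) <= 0)) + 1
            raise ValueError(f"time_s not strictly increasing at row {bad}")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.session_id)

    def metric(self, name: str) -> np.ndarray:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "engagement": self.engagement,
                "workload": self.workload,
                "heart_rate": self.heart_rate,
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class FeatureMatrix:
    """Windowed 9-dimensional feature vectors with middle-second references.

    ``X`` has one row per emitted window in :data:`FEATURE_NAMES` order;
    ``reference_times`` holds the middle second of each window and is strictly
    increasing within a session.  ``session_index`` maps each row to an entry
    of ``session_keys`` so multi-session matrices can be split back apart.
    """

    X: np.ndarray
    reference_times: np.ndarray
    session_keys: list[tuple[str, str]] = field(default_factory=lambda: [("S00", "T00")])
    session_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64).reshape(-1, len(FEATURE_NAMES))
        self.reference_times = np.asarray(self.reference_times, dtype=np.int64)
        if self.session_index is None:
            self.session_index = np.zeros(len(self.X), dtype=np.int64)
        else:
            self.session_index = np.asarray(self.session_index, dtype=np.int64)
        if not (len(self.X) == len(self.reference_times) == len(self.session_index)):
            raise ValueError("X, reference_times and session_index must align")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.X)

    def rows_for(self, key: tuple[str, str]) -> np.ndarray:
        idx = self.session_keys.index(key)
        return np.flatnonzero(self.session_index == idx)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        keys = [self.session_keys[i] for i in self.session_index]
        df.insert(0, "subject_id", [k[0] for k in keys])
        df.insert(1, "session_id", [k[1] for k in keys])
        df.insert(2, "reference_time_s", self.reference_times)
        return df


def concat_features(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-session feature matrices, re-indexing their session keys."""
    keys: list[tuple[str, str]] = []
    blocks, times, index = [], [], []
    for fm in parts:
        for local, key in enumerate(fm.session_keys):
            if key in keys:
                raise ValueError(f"duplicate session key {key}")
            keys.append(key)
        offset = len(keys) - len(fm.session_keys)
        blocks.append(fm.X)
        times.append(fm.reference_times)
        index.append(fm.session_index + offset)
    if not blocks:
        return FeatureMatrix(np.empty((0, 9)), np.empty(0, dtype=int), [], np.empty(0, dtype=int))
    return FeatureMatrix(
        np.vstack(blocks), np.concatenate(times), keys, np.concatenate(index)
    )


def self_normalize(series: MetricTimeSeries) -> MetricTimeSeries:
    """Z-score each metric using the session's valid epochs only.

    Centers and scales with the mean and sample (N−1) standard deviation over
    valid epochs, independently per metric.  Invalid epochs are carried through
    untouched — they never enter a window, so their values are inert.

    Raises
    ------
    ValueError
        If fewer than two valid epochs are available, or a metric has zero
        dispersion over the valid epochs (the metric is named in the message).
    """
    mask = series.valid
    if int(mask.sum()) < 2:
        raise ValueError("need at least 2 valid epochs to self-normalize")
    out = {}
    for name in METRIC_NAMES:
        x = series.metric(name)
        mu = float(np.mean(x[mask]))
        sd = float(np.std(x[mask], ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"metric {name!r} has zero dispersion over valid epochs")
        out[name] = (x - mu) / sd
    return replace(series, **out)


def build_windows(series: MetricTimeSeries) -> FeatureMatrix:
    """Slide a 3-s window in 1-s steps over a normalized series.

    A window is emitted only when all three of its epochs are valid; windows
    touching an invalid epoch are dropped rather than interpolated.  Row
    layout follows :data:`FEATURE_NAMES`: engagement over window seconds
    1..3, then workload, then heart rate; the reference time is the middle
    epoch.  A series without any run of 3 consecutive valid epochs yields an
    empty matrix.
    """
    v = series.valid
    n = len(series)
    if n < WINDOW_LEN:
        ok = np.zeros(0, dtype=bool)
    else:
        ok = v[:-2] & v[1:-1] & v[2:]
    starts = np.flatnonzero(ok)
    X = np.empty((len(starts), 9))
    for m, name in enumerate(METRIC_NAMES):
        x = series.metric(name)
        for k in range(WINDOW_LEN):
            X[:, 3 * m + k] = x[starts + k]
    ref = series.time_s[starts + 1] if len(starts) else np.empty(0, dtype=np.int64)
    return FeatureMatrix(
        X, ref, [series.key], np.zeros(len(starts), dtype=np.int64)
    )


def featurize_session(series: MetricTimeSeries) -> FeatureMatrix:
    """Normalize then window one session (the standard per-session path)."""
    return build_windows(self_normalize(series))
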