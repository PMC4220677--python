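"""File formats, run configuration, and the end-to-end pipeline.

All artifacts are plain text: per-second metric sessions, event logs,
feature matrices and result tables as strict comma-delimited CSV (exact
headers, '.' decimal, UTF-8, times in seconds from session start), and
models/matrices/manifests as JSON.  A :class:`RunConfig` carries every
tunable of the pipeline; unknown keys are rejected before any computation,
and a manifest with the config hash and per-stage row counts makes each run
reproducible from its configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, synthetic
from .analysis import PerformanceRecord
from .biosignals import ECGRecord
from .features import FeatureMatrix, MetricTimeSeries, FEATURE_NAMES, concat_features, featurize_session
from .som import SOMConfig, SOMModel, map_sequence, train_batch
from .synthetic import CohortSpec, EventLog, LatentStateSpec

logger = logging.getLogger("cogstates")

METRIC_HEADER = ["time_s", "engagement", "workload", "heart_rate", "valid"]
EVENT_HEADER = ["time_s", "event_type"]
ECG_HEADER = ["time_s", "amplitude"]
PERF_HEADER = ["subject_id", "session_id", "metric", "value"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# ----------------------------------------------------------------------------
# Delimited-text readers and writers (strict dialect)

def write_metric_series(series: MetricTimeSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_metric_series(
    path: str | Path, subject_id: str = "S00", session_id: str = "T00",
    task_label: str = "task",
) -> MetricTimeSeries:
    """Read a per-second metric session, validating structure strictly.

    The header must be exactly ``time_s,engagement,workload,heart_rate,valid``
    (no aliases); malformed rows and non-monotone times are reported with
    1-based line numbers.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if header != METRIC_HEADER:
            raise FormatError(
                f"{path.name}: expected header {','.join(METRIC_HEADER)!r}, got {','.join(header)!r}"
            )
        rows = []
        prev_t = None
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise FormatError(f"{path.name}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                t = int(parts[0])
                vals = [float(p) for p in parts[1:4]]
                valid = int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from None
            if valid not in (0, 1):
                raise FormatError(f"{path.name}:{lineno}: valid must be 0 or 1")
            if prev_t is not None and t <= prev_t:
                raise FormatError(f"{path.name}:{lineno}: time_s not strictly increasing")
            prev_t = t
            rows.append((t, *vals, valid))
    if not rows:
        raise FormatError(f"{path.name}: no data rows")
    arr = np.asarray(rows, dtype=float)
    return MetricTimeSeries(
        time_s=arr[:, 0].astype(int),
        engagement=arr[:, 1],
        workload=arr[:, 2],
        heart_rate=arr[:, 3],
        valid=arr[:, 4].astype(bool),
        subject_id=subject_id,
        session_id=session_id,
        task_label=task_label,
    )


def write_events(events: EventLog, path: str | Path) -> None:
    pd.DataFrame({"time_s": events.times, "event_type": events.labels}).to_csv(
        path, index=False
    )


def read_events(path: str | Path) -> EventLog:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != EVENT_HEADER:
        raise FormatError(f"{path.name}: expected header {','.join(EVENT_HEADER)!r}")
    return EventLog(df["time_s"].to_numpy(), df["event_type"].astype(str).tolist())


def write_ecg(ecg: ECGRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": ecg.times, "amplitude": ecg.samples}).to_csv(path, index=False)


def read_ecg(path: str | Path) -> ECGRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != ECG_HEADER:
        raise FormatError(f"{path.name}: expected header {','.join(ECG_HEADER)!r}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise FormatError(f"{path.name}: need at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ECGRecord(df["amplitude"].to_numpy(), round(fs, 6))


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    fm.to_frame().to_csv(path, index=False)


def write_performance(records: list[PerformanceRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_performance(path: str | Path) -> list[PerformanceRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != PERF_HEADER:
        raise FormatError(f"{path.name}: expected header {','.join(PERF_HEADER)!r}")
    return [
        PerformanceRecord(str(r.subject_id), str(r.session_id), str(r.metric), float(r.value))
        for r in df.itertuples()
    ]


# ----------------------------------------------------------------------------
# Run configuration

def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {context} config key(s): {sorted(unknown)}")
    return cls(**data)


@dataclass
class AnalysisConfig:
    n_folds: int = 10
    performance_metric: str | None = None
    run_crossval: bool = True
    run_regression: bool = True


@dataclass
class RunConfig:
    """Everything a pipeline run needs; unknown keys are rejected on load."""

    output_dir: str = "results"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    states: LatentStateSpec = field(default_factory=LatentStateSpec)
    som: SOMConfig = field(default_factory=SOMConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    write_sessions: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, sub_cls, ctx in (
            ("cohort", CohortSpec, "cohort"),
            ("states", LatentStateSpec, "states"),
            ("som", SOMConfig, "som"),
            ("analysis", AnalysisConfig, "analysis"),
        ):
            if key in data:
                kwargs[key] = _from_mapping(sub_cls, data.pop(key), ctx)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config document must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["states"]["state_means"] = np.asarray(d["states"]["state_means"]).tolist()
        d["states"]["noise_sd"] = list(d["states"]["noise_sd"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ----------------------------------------------------------------------------
# End-to-end pipeline

def run_pipeline(config: RunConfig) -> Path:
    """simulate → features → train → map → score → correlate, with a manifest.

    Returns the output directory.  Outputs are deterministic functions of the
    configuration (the cohort master seed is taken from ``config.seed``), so
    a rerun with the same config hash reproduces every table byte for byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    spec = dataclasses.replace(config.cohort, master_seed=config.seed)
    logger.info("simulating cohort: %d subjects x %d sessions", spec.n_subjects,
                spec.sessions_per_subject)
    cohort = synthetic.generate_cohort(spec, config.states)
    counts["sessions"] = len(cohort.sessions)
    write_performance(cohort.performance, out / "performance.csv")
    if config.write_sessions:
        sess_dir = out / "sessions"
        sess_dir.mkdir(exist_ok=True)
        for s in cohort.sessions:
            key = "_".join(s.metrics.key)
            write_metric_series(s.metrics, sess_dir / f"{key}_metrics.csv")
            write_events(s.events, sess_dir / f"{key}_events.csv")

    logger.info("building features")
    feats = [featurize_session(s.metrics) for s in cohort.sessions]
    all_fm = concat_features(feats)
    counts["windows"] = len(all_fm)
    write_features(all_fm, out / "features.csv")

    logger.info("training %d-node map (%d iterations)", config.som.n_nodes,
                config.som.n_iterations)
    model = train_batch(all_fm, config.som)
    model.save(out / "model.json")

    bmus = map_sequence(model, all_fm)
    scores = analysis.transition_scores(bmus)
    counts["scored_sessions"] = len(scores)
    pd.DataFrame(
        [{"subject_id": s.subject_id, "session_id": s.session_id,
          "score": s.score, "t": s.t} for s in scores]
    ).to_csv(out / "transition_scores.csv", index=False)

    T = analysis.transition_matrix(bmus)
    hist = analysis.distance_histogram(T)
    (out / "transition_matrix.json").write_text(
        json.dumps({"counts": T.tolist(), "distance_histogram": hist.tolist()}, indent=1)
    )

    results = []
    corr = analysis.correlate_performance(
        scores, cohort.performance, config.analysis.performance_metric
    )
    results.append({"analysis": "auto_validation", "r": corr.r, "r_squared": corr.r_squared,
                    "p_value": corr.p_value, "n": corr.n})
    if config.analysis.run_crossval and spec.n_subjects >= config.analysis.n_folds:
        cv = analysis.run_crossval(
            cohort, config.som, config.analysis.n_folds, config.analysis.performance_metric
        )
        results.append({"analysis": "crossval", "r": cv.correlation.r,
                        "r_squared": cv.correlation.r_squared,
                        "p_value": cv.correlation.p_value, "n": cv.correlation.n})
    pd.DataFrame(results).to_csv(out / "correlations.csv", index=False)

    if config.analysis.run_regression:
        reg = analysis.regression_baseline(
            all_fm, cohort.performance, config.analysis.performance_metric
        )
        rows = [
            {"variable": name, "coefficient": reg.coefficients[name],
             "t_test_p": reg.p_values[name],
             "tolerance": reg.tolerance.get(name, float("nan")),
             "vif": reg.vif.get(name, float("nan"))}
            for name in ("intercept", *FEATURE_NAMES)
        ]
        pd.DataFrame(rows).to_csv(out / "regression.csv", index=False)
        (out / "regression_summary.json").write_text(
            json.dumps({"r_squared": reg.r_squared, "f_test_p": reg.f_pvalue, "n": reg.n},
                       indent=1)
        )

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "package_version": __version__,
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
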