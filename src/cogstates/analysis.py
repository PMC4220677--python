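"""Downstream analytics on mapped cognitive-state sequences.

Once per-second feature vectors have been mapped to the 1-D grid, a session
is a sequence of activated node indices i(1)..i(t).  This module derives
everything the method reports from those sequences:

* node profiles (mean member vectors and activation counts),
* event-aligned activation distributions with a one-way MANOVA
  (Wilks' lambda, Rao's F approximation, partial eta-squared, observed
  power),
* transition matrices of consecutive activations and their aggregation by
  grid distance,
* the transition score — the statistic at the core of the method,
  ``score = Σ_{j=2..t} |i(j) − i(j−1)|`` — which measures how far the
  cognitive state travels along the grid during a session,
* Pearson correlation of transition scores with session performance,
* person-independent 10-fold cross-validation, and
* an ordinary-least-squares regression baseline on the same 9 features with
  tolerance/VIF multicollinearity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, FeatureMatrix, concat_features
from .som import BMUSequence, SOMConfig, SOMModel, map_sequence, train_batch


@dataclass
class PerformanceRecord:
    """One session's outcome on a percent scale (0–100)."""

    subject_id: str
    session_id: str
    metric: str
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"performance value {self.value} outside [0, 100]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.session_id)


@dataclass
class NodeProfile:
    node: int
    mean_vector: np.ndarray | None
    size: int
    size_fraction: float


@dataclass
class TransitionScoreResult:
    subject_id: str
    session_id: str
    score: int
    t: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.session_id)


@dataclass
class EventDistribution:
    label: str
    counts: np.ndarray
    n_instances: int
    n_unmatched: int


@dataclass
class MANOVAResult:
    wilks_lambda: float
    f_statistic: float
    df1: float
    df2: float
    p_value: float
    partial_eta_squared: float
    observed_power: float
    regularized: bool = False


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    f_pvalue: float
    tolerance: dict[str, float]
    vif: dict[str, float]
    n: int


@dataclass
class CrossValResult:
    fold_train_subjects: list[list[str]]
    scores: list[TransitionScoreResult]
    correlation: CorrelationResult
    models: list[SOMModel] = field(default_factory=list, repr=False)


# ----------------------------------------------------------------------------
# Node profiles and event-aligned distributions

def node_profiles(
    model: SOMModel, features: FeatureMatrix, bmus: BMUSequence
) -> list[NodeProfile]:
    """Mean member vector and activation count per node.

    Empty nodes get size 0 and an undefined (None) mean.  Sizes partition the
    mapped windows, so fractions sum to 1.
    """
    if len(features) != len(bmus):
        raise ValueError("features and BMU sequence are misaligned")
    total = len(bmus)
    out = []
    for node in range(1, model.n_nodes + 1):
        rows = np.flatnonzero(bmus.node_indices == node)
        mean = features.X[rows].mean(axis=0) if len(rows) else None
        out.append(
            NodeProfile(node, mean, len(rows), len(rows) / total if total else 0.0)
        )
    return out


def event_distribution(bmus: BMUSequence, events, label: str) -> EventDistribution:
    """Histogram of activated nodes at the seconds a given event occurred.

    For each instance of ``label`` at time t, the node of the window whose
    middle-second reference equals t is counted — i.e. the state during the
    event's epoch, informed by the seconds just before and after.  Instances
    falling into artifact gaps have no matching window and are counted as
    unmatched.
    """
    labels = list(events.labels)
    if label not in labels:
        raise KeyError(f"unknown event label {label!r}")
    times = np.asarray(events.times)
    wanted = times[np.array([l == label for l in labels], dtype=bool)]
    counts = np.zeros(bmus.n_nodes, dtype=np.int64)
    unmatched = 0
    ref = {int(t): int(i) for t, i in zip(bmus.reference_times, bmus.node_indices)}
    for t in wanted:
        node = ref.get(int(t))
        if node is None:
            unmatched += 1
        else:
            counts[node - 1] += 1
    return EventDistribution(label, counts, int(len(wanted) - unmatched), unmatched)


def event_observations(bmus: BMUSequence, events, label: str) -> np.ndarray:
    """One-hot activation indicator (length n_nodes) per matched event instance.

    These are the observation units of the event MANOVA: each matched
    instance contributes the indicator of the node active during its epoch.
    """
    labels = list(events.labels)
    times = np.asarray(events.times)
    wanted = times[np.array([l == label for l in labels], dtype=bool)]
    ref = {int(t): int(i) for t, i in zip(bmus.reference_times, bmus.node_indices)}
    rows = []
    for t in wanted:
        node = ref.get(int(t))
        if node is not None:
            row = np.zeros(bmus.n_nodes)
            row[node - 1] = 1.0
            rows.append(row)
    return np.asarray(rows).reshape(-1, bmus.n_nodes)


# ----------------------------------------------------------------------------
# MANOVA

def manova_oneway(
    observations: np.ndarray, group_labels, ridge: float = 0.0, alpha: float = 0.05
) -> MANOVAResult:
    """One-way MANOVA via Wilks' lambda with Rao's F approximation.

    ``Λ = det(E) / det(E + H)`` with E the pooled within-group and H the
    between-group scatter.  The F approximation, degrees of freedom, partial
    eta-squared ``1 − Λ^{1/s}`` (s = min(p, g−1)) and observed power (from
    the noncentral F with ncp = F·df1 at the given alpha) follow the
    conventions of standard statistical packages.

    A singular within-group scatter raises unless ``ridge > 0``, in which
    case ``ridge · mean(diag(E)) · I`` is added and the result is flagged
    ``regularized`` — needed e.g. for one-hot activation observations, whose
    rows sum to 1.
    """
    Y = np.asarray(observations, dtype=np.float64)
    groups = np.asarray(group_labels)
    uniq = pd.unique(groups)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, p = Y.shape
    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for lab in uniq:
        sub = Y[groups == lab]
        m = sub.mean(axis=0)
        C = sub - m
        E += C.T @ C
        d = (m - grand)[:, None]
        H += len(sub) * (d @ d.T)

    regularized = False
    sign_e, logdet_e = np.linalg.slogdet(E)
    if sign_e <= 0 or np.linalg.matrix_rank(E) < p:
        if ridge <= 0:
            raise np.linalg.LinAlgError(
                "singular within-group scatter; pass ridge > 0 to regularize"
            )
        E = E + ridge * max(np.trace(E) / p, 1.0) * np.eye(p)
        regularized = True
        sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    lam = float(np.exp(logdet_e - logdet_t))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)

    dfh = g - 1
    denom = p**2 + dfh**2 - 5
    t_exp = np.sqrt((p**2 * dfh**2 - 4) / denom) if denom > 0 else 1.0
    w = n - 1 - (p + g) / 2.0
    df1 = p * dfh
    df2 = w * t_exp - (p * dfh - 2) / 2.0
    if df2 <= 0:
        raise ValueError("insufficient observations for the F approximation")
    lam_root = lam ** (1.0 / t_exp)
    F = (1.0 - lam_root) / lam_root * df2 / df1
    p_value = float(stats.f.sf(F, df1, df2))
    s = min(p, dfh)
    eta = 1.0 - lam ** (1.0 / s)
    ncp = F * df1
    fcrit = stats.f.ppf(1 - alpha, df1, df2)
    power = float(1.0 - stats.ncf.cdf(fcrit, df1, df2, ncp)) if ncp > 0 else alpha
    return MANOVAResult(lam, float(F), float(df1), float(df2), p_value, float(eta),
                        power, regularized)


# ----------------------------------------------------------------------------
# Transition matrices and the transition score

def transition_matrix(bmus: BMUSequence | list[BMUSequence]) -> np.ndarray:
    """N×N counts of consecutive activations (a→b); never bridges sessions."""
    seqs = bmus if isinstance(bmus, list) else [bmus]
    n_nodes = seqs[0].n_nodes
    T = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    for seq in seqs:
        for _, idx, _ in seq.per_session():
            for a, b in zip(idx[:-1], idx[1:]):
                T[a - 1, b - 1] += 1
    return T


def distance_histogram(T: np.ndarray) -> np.ndarray:
    """Transition counts aggregated by grid distance |a − b| = 0..N−1."""
    n = T.shape[0]
    hist = np.zeros(n, dtype=np.int64)
    for a in range(n):
        for b in range(n):
            hist[abs(a - b)] += T[a, b]
    return hist


def transition_score(
    node_indices: np.ndarray | BMUSequence,
    subject_id: str = "S00",
    session_id: str = "T00",
    n_nodes: int | None = None,
) -> TransitionScoreResult:
    """Σ_{j=2..t} |i(j) − i(j−1)| for one session's activation sequence."""
    if isinstance(node_indices, BMUSequence):
        sessions = node_indices.per_session()
        if len(sessions) != 1:
            raise ValueError("pass a single-session sequence (or use transition_scores)")
        (subject_id, session_id), idx, _ = sessions[0]
        n_nodes = node_indices.n_nodes
    else:
        idx = np.asarray(node_indices, dtype=np.int64)
    if n_nodes is not None and len(idx) and (idx.min() < 1 or idx.max() > n_nodes):
        raise ValueError(f"node indices outside [1, {n_nodes}]")
    score = int(np.abs(np.diff(idx)).sum()) if len(idx) > 1 else 0
    return TransitionScoreResult(subject_id, session_id, score, int(len(idx)))


def transition_scores(bmus: BMUSequence) -> list[TransitionScoreResult]:
    """Per-session transition scores of a (possibly multi-session) sequence."""
    out = []
    for (sub, ses), idx, _ in bmus.per_session():
        out.append(transition_score(idx, sub, ses, bmus.n_nodes))
    return out


# ----------------------------------------------------------------------------
# Correlation with performance

def correlate_performance(
    scores: list[TransitionScoreResult],
    perf: list[PerformanceRecord],
    metric: str | None = None,
) -> CorrelationResult:
    """Pearson r between session transition scores and performance.

    Sessions are matched by (subject, session) key; the two-tailed p-value
    comes from ``t = r·sqrt((n−2)/(1−r²))`` on n−2 degrees of freedom.
    """
    perf_map = {
        rec.key: rec.value for rec in perf if metric is None or rec.metric == metric
    }
    pairs = [(s.score, perf_map[s.key]) for s in scores if s.key in perf_map]
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched sessions")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in scores or performance")
    r, p_value = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(r) ** 2, float(p_value), len(pairs))


# ----------------------------------------------------------------------------
# Person-independent cross-validation

def crossval_split(subject_ids: list[str], n_folds: int = 10) -> list[tuple[list[str], list[str]]]:
    """Small-training-fold person-independent splits.

    Each subject appears in exactly one fold's *training* set: the first
    ``n_folds − 1`` folds train on ``floor(n / n_folds)`` subjects and the
    final fold takes the remainder as well; the test set of each fold is all
    other subjects.  With 51 subjects and 10 folds this yields nine training
    folds of five subjects and a final fold of six.
    """
    subjects = list(subject_ids)
    n = len(subjects)
    if n < n_folds:
        raise ValueError("need at least n_folds subjects")
    base = n // n_folds
    folds = []
    for f in range(n_folds):
        lo = f * base
        hi = (f + 1) * base if f < n_folds - 1 else n
        train = subjects[lo:hi]
        test = subjects[:lo] + subjects[hi:]
        folds.append((train, test))
    return folds


def _featurize_cohort(cohort) -> dict[tuple[str, str], FeatureMatrix]:
    from .features import featurize_session

    return {s.metrics.key: featurize_session(s.metrics) for s in cohort.sessions}


def run_autoval(
    cohort, som_config: SOMConfig | None = None, metric: str | None = None
) -> CrossValResult:
    """Train on the whole cohort and score the same sessions (auto-validation)."""
    feats = _featurize_cohort(cohort)
    all_fm = concat_features(list(feats.values()))
    model = train_batch(all_fm, som_config or SOMConfig())
    scores = transition_scores(map_sequence(model, all_fm))
    corr = correlate_performance(scores, cohort.performance, metric)
    subjects = sorted({k[0] for k in feats})
    return CrossValResult([subjects], scores, corr, [model])


def run_crossval(
    cohort,
    som_config: SOMConfig | None = None,
    n_folds: int = 10,
    metric: str | None = None,
    keep_models: bool = False,
) -> CrossValResult:
    """Person-independent cross-validation of the whole pipeline.

    Per fold, a map is trained on the training subjects' feature vectors
    only, every other subject's sessions are mapped through it, and their
    transition scores are computed.  A session is tested by every fold that
    excludes its subject from training; its cross-validated score is the
    mean over those folds, so each session enters the pooled correlation
    once.
    """
    som_config = som_config or SOMConfig()
    feats = _featurize_cohort(cohort)
    subjects = sorted({k[0] for k in feats})
    folds = crossval_split(subjects, n_folds)

    acc: dict[tuple[str, str], list[int]] = {k: [] for k in feats}
    models: list[SOMModel] = []
    train_lists: list[list[str]] = []
    for train_subj, test_subj in folds:
        if not train_subj:
            raise ValueError("empty training fold")
        train_fm = concat_features([feats[k] for k in sorted(feats) if k[0] in set(train_subj)])
        model = train_batch(train_fm, som_config)
        test_set = set(test_subj)
        for key in sorted(feats):
            if key[0] in test_set:
                res = transition_scores(map_sequence(model, feats[key]))[0]
                acc[key].append(res.score)
        if keep_models:
            models.append(model)
        train_lists.append(list(train_subj))

    scores = [
        TransitionScoreResult(k[0], k[1], float(np.mean(v)) if v else 0, len(feats[k]))
        for k, v in sorted(acc.items())
        if v
    ]
    corr = correlate_performance(scores, cohort.performance, metric)
    return CrossValResult(train_lists, scores, corr, models)


# ----------------------------------------------------------------------------
# Linear-regression baseline

def regression_baseline(
    features: FeatureMatrix,
    perf: list[PerformanceRecord],
    metric: str | None = None,
    unit: str = "window",
) -> RegressionResult:
    """OLS of session performance on the 9 window features, with VIF diagnostics.

    With ``unit="window"`` (default) the session's performance score is
    replicated to each of its windows; ``unit="session"`` aggregates features
    to session means first.  Tolerance and VIF come from auxiliary
    regressions of each predictor on the other eight
    (``VIF_k = 1 / (1 − R²_k)``, tolerance = 1/VIF).  No regularization is
    applied; an exactly collinear design raises.
    """
    import statsmodels.api as sm

    perf_map = {
        rec.key: rec.value for rec in perf if metric is None or rec.metric == metric
    }
    rows, y = [], []
    for i, key in enumerate(features.session_keys):
        if key not in perf_map:
            continue
        block = features.X[features.session_index == i]
        if len(block) == 0:
            continue
        if unit == "session":
            rows.append(block.mean(axis=0))
            y.append(perf_map[key])
        elif unit == "window":
            rows.append(block)
            y.extend([perf_map[key]] * len(block))
        else:
            raise ValueError(f"unknown unit {unit!r}")
    X = np.vstack(rows) if unit == "window" else np.asarray(rows)
    y = np.asarray(y, dtype=float)
    if len(y) < len(FEATURE_NAMES) + 2:
        raise ValueError("need more observations than predictors + intercept")

    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError("exactly collinear predictors: singular design")
    fit = sm.OLS(y, Xc).fit()

    names = ["intercept", *FEATURE_NAMES]
    coeffs = dict(zip(names, fit.params))
    pvals = dict(zip(names, fit.pvalues))
    tol, vif = {}, {}
    for k, name in enumerate(FEATURE_NAMES):
        others = np.delete(X, k, axis=1)
        aux = sm.OLS(X[:, k], sm.add_constant(others, has_constant="add")).fit()
        r2k = min(float(aux.rsquared), 1.0 - 1e-12)
        vif[name] = 1.0 / (1.0 - r2k)
        tol[name] = 1.0 - r2k
    return RegressionResult(
        coefficients=coeffs,
        p_values=pvals,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        tolerance=tol,
        vif=vif,
        n=len(y),
    )
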