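import numpy as np
import pytest

import cogstates as cs


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 2 sessions of 120 s with the default planted effect."""
    spec = cs.CohortSpec(
        n_subjects=10, sessions_per_subject=2, session_duration_s=120, master_seed=11
    )
    return cs.generate_cohort(spec)


@pytest.fixture(scope="session")
def curve_data():
    """Points along a smooth 1-D curve embedded in 9-D, plus their parameter."""
    rng = np.random.default_rng(42)
    u = np.sort(rng.uniform(0, 1, 600))
    t = 2 * np.pi * u
    curve = np.column_stack(
        [
            np.sin(t), np.cos(t), t / np.pi, 0.5 * np.sin(2 * t), 0.3 * t,
            np.cos(0.5 * t), 0.2 * np.sin(3 * t), t**2 / 10, 0.1 * t,
        ]
    )
    X = curve + 0.02 * rng.standard_normal(curve.shape)
    return X, u


@pytest.fixture(scope="session")
def trained_on_cohort(small_cohort):
    """Features, trained map, and mapped sequences for the small cohort."""
    feats = cs.concat_features(
        [cs.featurize_session(s.metrics) for s in small_cohort.sessions]
    )
    model = cs.train_batch(feats, cs.SOMConfig(n_iterations=60))
    bmus = cs.map_sequence(model, feats)
    return feats, model, bmus


def make_series(eng, wl=None, hr=None, valid=None, **kw):
    """Convenience MetricTimeSeries builder for unit tests."""
    eng = np.asarray(eng, dtype=float)
    n = len(eng)
    if wl is None:
        wl = eng * 2 + 1
    if hr is None:
        hr = 60 + 10 * eng
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return cs.MetricTimeSeries(
        time_s=np.arange(n), engagement=eng, workload=wl, heart_rate=hr,
        valid=valid, **kw,
    )
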