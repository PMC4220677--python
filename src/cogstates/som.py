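"""1-D batch self-organizing map: PCA initialization, training, BMU mapping.

The map is a line of ``n_nodes`` (default 20) weight vectors in the 9-D
feature space.  Weights are initialized along the first principal axis of
the training data, then refined with the batch learning rule: every
iteration assigns all vectors to their best matching units (BMUs) and
replaces each node's weights with the neighborhood-kernel-weighted mean of
the assigned vectors.  The neighborhood is a squared-exponential in grid
distance whose radius decays linearly over an ordering phase; the remaining
convergence phase updates only each vector's BMU, which is exactly a Lloyd
k-means step on the current assignments.

Training is fully deterministic: PCA initialization plus batch updates
involve no randomness, so identical data and configuration reproduce the
weights bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

N_NODES_DEFAULT = 20
N_ITERATIONS_DEFAULT = 200


@dataclass
class SOMConfig:
    """Training configuration for the 1-D map.

    ``ordering_fraction`` of the iterations form the ordering phase, during
    which the neighborhood radius decays linearly from ``initial_radius``
    (default ``n_nodes / 2``) to ``final_ordering_radius``; the remaining
    iterations are the BMU-only convergence phase.  ``init_span_sd`` sets how
    many standard deviations of the data's first-principal-axis projections
    the initial weights span on each side of the mean.  ``seed`` covers only
    optional data subsampling; training itself is deterministic.
    """

    n_nodes: int = N_NODES_DEFAULT
    n_iterations: int = N_ITERATIONS_DEFAULT
    ordering_fraction: float = 0.5
    initial_radius: float | None = None
    final_ordering_radius: float = 1.0
    init_span_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.initial_radius is None:
            self.initial_radius = self.n_nodes / 2.0
        if self.initial_radius <= 0 or self.final_ordering_radius <= 0:
            raise ValueError("radii must be positive")

    @property
    def ordering_iterations(self) -> int:
        return int(round(self.ordering_fraction * self.n_iterations))


@dataclass
class SOMModel:
    """A trained map: ``n_nodes × dim`` code vectors on a 1..N line."""

    weights: np.ndarray
    config: SOMConfig
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def grid_positions(self) -> np.ndarray:
        """Node indices 1..N on the line (1-based, as reported downstream)."""
        return np.arange(1, self.n_nodes + 1)

    def save(self, path: str | Path) -> None:
        doc = {
            "config": asdict(self.config),
            "grid_positions": self.grid_positions.tolist(),
            "weights": self.weights.tolist(),
            "training_log": self.training_log,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(doc["weights"], dtype=np.float64),
            config=SOMConfig(**doc["config"]),
            training_log=list(doc["training_log"]),
        )


@dataclass
class BMUSequence:
    """Per-window activated node indices (1-based) for one or more sessions."""

    node_indices: np.ndarray
    reference_times: np.ndarray
    session_keys: list[tuple[str, str]] = field(default_factory=lambda: [("S00", "T00")])
    session_index: np.ndarray | None = None
    n_nodes: int = N_NODES_DEFAULT

    def __post_init__(self) -> None:
        self.node_indices = np.asarray(self.node_indices, dtype=np.int64)
        self.reference_times = np.asarray(self.reference_times, dtype=np.int64)
        if self.session_index is None:
            self.session_index = np.zeros(len(self.node_indices), dtype=np.int64)
        else:
            self.session_index = np.asarray(self.session_index, dtype=np.int64)
        if len(self.node_indices) and (
            self.node_indices.min() < 1 or self.node_indices.max() > self.n_nodes
        ):
            raise ValueError(f"node indices must lie in [1, {self.n_nodes}]")

    def __len__(self) -> int:
        return len(self.node_indices)

    def per_session(self) -> list[tuple[tuple[str, str], np.ndarray, np.ndarray]]:
        """Split into (key, indices, reference_times) triples, one per session."""
        out = []
        for i, key in enumerate(self.session_keys):
            rows = np.flatnonzero(self.session_index == i)
            out.append((key, self.node_indices[rows], self.reference_times[rows]))
        return out


def _as_array(data: FeatureMatrix | np.ndarray) -> np.ndarray:
    X = data.X if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("training data must be a 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("training data contains NaN or infinite features")
    return X


def init_pca(data: FeatureMatrix | np.ndarray, config: SOMConfig) -> np.ndarray:
    """Seed the code vectors evenly along the data's first principal axis.

    Nodes span ``mean ± init_span_sd`` standard deviations of the projections
    onto the leading eigenvector of the covariance, so the initial map is
    already ordered along the dominant direction of variation.
    """
    X = _as_array(data)
    if len(X) < config.n_nodes:
        raise ValueError("need at least n_nodes training vectors")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    lead = evecs[:, -1]
    var = evals[-1]
    if var <= 0:
        raise ValueError("zero-variance data: PCA initialization undefined")
    if lead[np.argmax(np.abs(lead))] < 0:  # sign convention for reproducibility
        lead = -lead
    sd = np.sqrt(var)
    if config.n_nodes == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-config.init_span_sd * sd, config.init_span_sd * sd, config.n_nodes)
    return mu + offsets[:, None] * lead[None, :]


def _bmu_indices(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """0-based argmin of Euclidean distance, first (lowest) node on ties."""
    return np.argmin(cdist(X, weights), axis=1)


def batch_update(
    weights: np.ndarray, X: np.ndarray, bmu: np.ndarray, sigma: float | None
) -> np.ndarray:
    """One batch step: kernel-weighted means of the vectors assigned per node.

    ``sigma is None`` means the convergence-phase rule: only each vector's
    BMU receives it (a Lloyd step on the current assignments).  Nodes with
    zero total kernel mass keep their previous weights.
    """
    n_nodes = weights.shape[0]
    counts = np.bincount(bmu, minlength=n_nodes).astype(float)
    sums = np.zeros_like(weights)
    np.add.at(sums, bmu, X)
    if sigma is None:
        H = np.eye(n_nodes)
    else:
        d = np.arange(n_nodes)
        H = np.exp(-((d[:, None] - d[None, :]) ** 2) / (2.0 * sigma**2))
    mass = H @ counts
    new = weights.copy()
    nz = mass > 0
    new[nz] = (H @ sums)[nz] / mass[nz, None]
    return new


def train_batch(data: FeatureMatrix | np.ndarray, config: SOMConfig | None = None) -> SOMModel:
    """Train the map with the two-phase batch algorithm.

    Every iteration presents all vectors: assignments to BMUs, then
    kernel-weighted mean updates.  The radius decays linearly from
    ``initial_radius`` to ``final_ordering_radius`` across the ordering
    phase; the convergence phase is BMU-only.  The per-iteration mean
    quantization error (distance to the BMU before the update) is logged.
    """
    if config is None:
        config = SOMConfig()
    X = _as_array(data)
    if len(X) == 0:
        raise ValueError("empty training data")
    weights = init_pca(X, config) if len(X) >= config.n_nodes else np.tile(X.mean(0), (config.n_nodes, 1))
    n_order = config.ordering_iterations
    log: list[float] = []
    for it in range(config.n_iterations):
        bmu = _bmu_indices(weights, X)
        log.append(float(np.linalg.norm(X - weights[bmu], axis=1).mean()))
        if it < n_order and n_order > 1:
            frac = it / (n_order - 1)
            sigma = config.initial_radius + frac * (config.final_ordering_radius - config.initial_radius)
        elif it < n_order:
            sigma = config.final_ordering_radius
        else:
            sigma = None
        weights = batch_update(weights, X, bmu, sigma)
    return SOMModel(weights=weights, config=config, training_log=log)


def find_bmu(model: SOMModel, x: np.ndarray) -> int:
    """1-based index of the node Euclidean-closest to ``x``; ties → lowest."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (model.weights.shape[1],):
        raise ValueError(f"expected a length-{model.weights.shape[1]} vector")
    return int(np.argmin(np.linalg.norm(model.weights - x, axis=1))) + 1


def map_sequence(model: SOMModel, features: FeatureMatrix) -> BMUSequence:
    """Assign every feature row to its BMU, preserving order and session keys."""
    if len(features) == 0:
        return BMUSequence(
            np.empty(0, dtype=int), np.empty(0, dtype=int),
            features.session_keys, np.empty(0, dtype=int), model.n_nodes,
        )
    idx = _bmu_indices(model.weights, features.X) + 1
    return BMUSequence(
        idx, features.reference_times, features.session_keys,
        features.session_index, model.n_nodes,
    )
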