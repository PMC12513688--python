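"""Discrete state-space learning: embedding + ensemble k-means, with diagnostics.

A state definition maps a continuous feature vector to one of ``k`` discrete
states by (1) projecting it into a lower-dimensional embedding space and
(2) assigning it to the nearest of ``k`` cluster centers. The embedding is a
pluggable contract (:class:`EmbeddingModel`); the default is a z-score
standardization followed by PCA, which is deterministic under a seed. Cluster
centers come either from a single k-means fit (``runs=1``) or from a cluster
ensemble: several seeded k-means runs are combined through a co-association
matrix cut by average-linkage agglomerative clustering.

Before policy learning, a state definition is screened for generalizability
(trajectories should visit several distinct states, occupancy should not be
concentrated on a few states) and informativeness (per-state aggregates such
as mortality rate and treatment rates, overlaid on a 2-D PCA projection of
the cluster centers, should show clinically sensible structure).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from ._util import child_seeds, rng_from
from .windows import feature_columns

#: Candidate state-space sizes searched by default.
DEFAULT_K_GRID = (20, 40, 60, 80, 100, 120, 140, 160)


@runtime_checkable
class EmbeddingModel(Protocol):
    """Contract for feature embeddings: deterministic, defined on any d-vector."""

    input_dim: int
    embedding_dim: int

    def transform(self, X: np.ndarray) -> np.ndarray: ...


class IdentityEmbedding:
    """Pass-through embedding (e = d)."""

    def __init__(self, input_dim: int):
        self.input_dim = self.embedding_dim = input_dim

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X

    def to_dict(self) -> dict:
        return {"method": "identity", "input_dim": self.input_dim}

    @classmethod
    def from_dict(cls, d: dict) -> "IdentityEmbedding":
        return cls(d["input_dim"])


class PCAEmbedding:
    """Z-score standardization (fit on the training split only) + PCA.

    Constant feature columns get unit scale from the standardizer and are
    thereby zero-centered to 0 rather than producing NaNs.
    """

    def __init__(self, input_dim: int, embedding_dim: int, seed: int = 0):
        self.input_dim = input_dim
        self.embedding_dim = embedding_dim
        self.seed = seed
        self._scaler: StandardScaler | None = None
        self._pca: PCA | None = None

    def fit(self, X: np.ndarray) -> "PCAEmbedding":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.embedding_dim:
            raise ValueError("need at least as many rows as embedding dimensions")
        self._scaler = StandardScaler().fit(X)
        Z = self._scaler.transform(X)
        self._pca = PCA(
            n_components=self.embedding_dim, svd_solver="full", random_state=self.seed
        ).fit(Z)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"expected (n, {self.input_dim}) array")
        return self._pca.transform(self._scaler.transform(X))

    def to_dict(self) -> dict:
        return {
            "method": "pca",
            "input_dim": self.input_dim,
            "embedding_dim": self.embedding_dim,
            "seed": self.seed,
            "scaler_mean": self._scaler.mean_.tolist(),
            "scaler_scale": self._scaler.scale_.tolist(),
            "pca_mean": self._pca.mean_.tolist(),
            "pca_components": self._pca.components_.tolist(),
            "pca_explained_variance": self._pca.explained_variance_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAEmbedding":
        m = cls(d["input_dim"], d["embedding_dim"], d["seed"])
        m._scaler = StandardScaler()
        m._scaler.mean_ = np.array(d["scaler_mean"])
        m._scaler.scale_ = np.array(d["scaler_scale"])
        m._scaler.var_ = m._scaler.scale_**2
        m._scaler.n_features_in_ = d["input_dim"]
        m._pca = PCA(n_components=d["embedding_dim"], svd_solver="full")
        m._pca.mean_ = np.array(d["pca_mean"])
        m._pca.components_ = np.array(d["pca_components"])
        m._pca.explained_variance_ = np.array(d["pca_explained_variance"])
        m._pca.n_features_in_ = d["input_dim"]
        return m


def fit_embedding(
    features: np.ndarray,
    method: str = "pca",
    embedding_dim: int | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Fit the feature embedding on the training split.

    ``method='identity'`` returns inputs unchanged (e = d); ``method='pca'``
    (default) standardizes and projects to ``embedding_dim`` dimensions. Both
    are deterministic under a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values must be imputed before embedding")
    if method == "identity":
        return IdentityEmbedding(X.shape[1])
    if method == "pca":
        e = embedding_dim if embedding_dim is not None else min(8, X.shape[1])
        return PCAEmbedding(X.shape[1], e, seed=seed).fit(X)
    raise ValueError(f"unknown embedding method {method!r}")


@dataclass
class StateDefinition:
    """Fitted mapping from feature vectors to one of ``k`` discrete states."""

    k: int
    centers: np.ndarray  # (k, e) in embedding space
    embedding: EmbeddingModel
    partition_id: int | None = None
    seed: int | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.centers.shape != (self.k, self.embedding.embedding_dim):
            raise ValueError("centers must have shape (k, embedding_dim)")

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-center state ids for feature rows; ties break to lowest id."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in features")
        Z = self.embedding.transform(X)
        d2 = ((Z[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def save(self, path) -> None:
        payload = {
            "format_version": 1,
            "k": self.k,
            "partition_id": self.partition_id,
            "seed": self.seed,
            "centers": self.centers.tolist(),
            "embedding": self.embedding.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "StateDefinition":
        d = json.loads(Path(path).read_text())
        emb_d = d["embedding"]
        emb = (
            IdentityEmbedding.from_dict(emb_d)
            if emb_d["method"] == "identity"
            else PCAEmbedding.from_dict(emb_d)
        )
        return cls(
            k=d["k"],
            centers=np.array(d["centers"]),
            embedding=emb,
            partition_id=d["partition_id"],
            seed=d["seed"],
        )


def assign_state(x: np.ndarray, sd: StateDefinition) -> int:
    """State id of a single feature vector (nearest-center decoding)."""
    return int(sd.assign(np.atleast_2d(x))[0])


def _consensus_centers(
    Z: np.ndarray, k: int, runs: int, seed: int, subsample_cap: int
) -> np.ndarray:
    """Cluster-ensemble centers: co-association matrix + average-linkage cut."""
    rng = rng_from(seed)
    n = Z.shape[0]
    idx = (
        rng.choice(n, size=subsample_cap, replace=False) if n > subsample_cap
        else np.arange(n)
    )
    Zs = Z[idx]
    coassoc = np.zeros((len(idx), len(idx)))
    for s in child_seeds(seed, runs):
        labels = KMeans(n_clusters=k, n_init=5, random_state=s).fit_predict(Zs)
        coassoc += labels[:, None] == labels[None, :]
    coassoc /= runs
    groups = AgglomerativeClustering(
        n_clusters=k, metric="precomputed", linkage="average"
    ).fit_predict(1.0 - coassoc)
    return np.vstack([Zs[groups == g].mean(axis=0) for g in range(k)])


def fit_state_definition(
    embedded: np.ndarray,
    k: int,
    runs: int = 10,
    seed: int = 0,
    embedding: EmbeddingModel | None = None,
    partition_id: int | None = None,
    subsample_cap: int = 2000,
) -> StateDefinition:
    """Fit ``k`` cluster centers in embedding space by (ensemble) k-means.

    ``runs=1`` reduces to a single k-means fit; ``runs>1`` uses the consensus
    construction. If nearest-center assignment leaves a state empty on the
    training data, the largest occupied state is re-split (logged) until every
    state is populated.
    """
    Z = np.asarray(embedded, dtype=float)
    if k > Z.shape[0]:
        raise ValueError("k cannot exceed the number of training vectors")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if runs == 1:
        centers = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(Z).cluster_centers_
    else:
        centers = _consensus_centers(Z, k, runs, seed, subsample_cap)

    # guarantee total assignment with no empty state on the training data
    for _ in range(k):
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        occupancy = np.bincount(labels, minlength=k)
        if occupancy.min() > 0:
            break
        import logging

        empty = int(np.argmin(occupancy))
        biggest = int(np.argmax(occupancy))
        logging.getLogger(__name__).warning(
            "empty consensus state %d; re-splitting state %d", empty, biggest
        )
        sub = Z[labels == biggest]
        two = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(sub).cluster_centers_
        centers[biggest], centers[empty] = two[0], two[1]

    emb = embedding if embedding is not None else IdentityEmbedding(Z.shape[1])
    return StateDefinition(
        k=k, centers=centers, embedding=emb, partition_id=partition_id, seed=seed
    )


@dataclass
class StateDiagnostics:
    """Generalizability/informativeness screen of a state definition."""

    multi_state_fraction: float
    occupancy: np.ndarray  # (k,) shares, sum 1
    aggregates: pd.DataFrame  # per-state mortality, prev/next action rate, features
    centers_pca: np.ndarray  # (k, 2) projection of cluster centers
    passed: bool
    failures: list[str] = field(default_factory=list)

    @property
    def occupancy_mean(self) -> float:
        return float(self.occupancy.mean())

    @property
    def occupancy_sd(self) -> float:
        return float(self.occupancy.std())


def diagnose_states(
    decision_table: pd.DataFrame,
    sd: StateDefinition,
    features: list[str] | None = None,
    multi_state_min: float = 0.95,
    max_occupancy_factor: float = 5.0,
) -> StateDiagnostics:
    """Screen a state definition on a decision-step table.

    Checks that the fraction of trajectories visiting >= 2 distinct states is
    at least ``multi_state_min`` and that no state holds more than
    ``max_occupancy_factor / k`` of all windows; computes per-state occupancy
    shares, mortality rate, previous/next treatment rates, and means of any
    named features, plus a 2-D PCA projection of the cluster centers for the
    overlay plots.
    """
    df = decision_table.sort_values(["stay_id", "t"], kind="stable")
    fcols = feature_columns(df)
    X = df[fcols].to_numpy(dtype=float)
    states = sd.assign(X)
    k = sd.k

    per_stay = pd.DataFrame({"stay_id": df["stay_id"].to_numpy(), "state": states})
    nuniq = per_stay.groupby("stay_id")["state"].nunique()
    multi_frac = float((nuniq >= 2).mean())

    occupancy = np.bincount(states, minlength=k) / len(states)

    died = df.groupby("stay_id")["reward"].transform("min") < 0
    next_action = df["action"].to_numpy()
    prev_action = df.groupby("stay_id")["action"].shift(1)

    agg = pd.DataFrame(index=pd.RangeIndex(k, name="state"))
    by = pd.DataFrame(
        {
            "state": states,
            "mortality": died.to_numpy().astype(float),
            "next_action": next_action.astype(float),
            "prev_action": prev_action.to_numpy(),
        }
    )
    for name in features or []:
        by[name] = df[name].to_numpy(dtype=float)
    grouped = by.groupby("state").mean()
    agg = agg.join(grouped)  # states with zero windows stay NaN (undefined)
    agg["n_windows"] = np.bincount(states, minlength=k)
    agg["occupancy"] = occupancy

    centers_pca = PCA(n_components=min(2, sd.centers.shape[1]), svd_solver="full").fit_transform(
        sd.centers
    )

    failures = []
    if multi_frac < multi_state_min:
        failures.append(
            f"multi-state fraction {multi_frac:.3f} < threshold {multi_state_min}"
        )
    if occupancy.max() > max_occupancy_factor / k:
        failures.append(
            f"max occupancy share {occupancy.max():.3f} > {max_occupancy_factor}/k"
        )
    return StateDiagnostics(
        multi_state_fraction=multi_frac,
        occupancy=occupancy,
        aggregates=agg,
        centers_pca=centers_pca,
        passed=not failures,
        failures=failures,
    )


def plot_state_map(diag: StateDiagnostics, overlay: str = "mortality", ax=None):
    """Scatter the 2-D center projection, colored/sized by a per-state aggregate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = diag.aggregates[overlay].to_numpy()
    sc = ax.scatter(
        diag.centers_pca[:, 0], diag.centers_pca[:, 1], c=vals, s=40 + 200 * diag.occupancy
    )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.figure.colorbar(sc, ax=ax, label=overlay)
    return ax
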