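"""Embedding-space neighborhood analysis.

Given per-sequence embeddings f(s_i) in R^d aligned to metadata (mutated
position, mutant amino acid, species, label), the k-neighborhood of a
query is the set of k sequences whose embeddings are nearest to it, self
excluded. Two statistics probe how an embedding space organizes a
single-mutation scan:

* **position distance** — |pos(query) - pos(neighbor)| over the
  neighborhood: small medians mean the space clusters by mutated
  position;
* **mutant-amino-acid accuracy** — fraction of the neighborhood sharing
  the query's mutant amino acid, compared against the exact expectation
  under a uniformly random arrangement of embeddings.

Euclidean distance is the default metric; cosine is available for
parity. Ties are broken by ascending row index so reports are fully
deterministic. The module also provides mean pooling, joint (two-model)
embedding concatenation and a minimal linear regression head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score

__all__ = [
    "EmbeddingSet",
    "NeighborhoodReport",
    "PositionDistanceStats",
    "AminoAcidAccuracy",
    "LinearHead",
    "aa_accuracy",
    "joint_concat",
    "knn",
    "k_sweep",
    "mean_pool",
    "permutation_null_accuracies",
    "position_distance_stats",
    "random_baseline_accuracy",
]


@dataclass
class EmbeddingSet:
    """An N x d embedding matrix aligned to per-row metadata.

    ``metadata`` is a DataFrame with one row per id (in order); typical
    columns are ``mutated_position``, ``mutant_aa``, ``species``,
    ``label``.
    """

    ids: list[str]
    matrix: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be 2-D with d >= 1")
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("ids must be unique")
        if self.matrix.shape[0] != n or len(self.metadata) != n:
            raise ValueError("ids, matrix and metadata row counts disagree")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        if name not in self.metadata.columns:
            raise KeyError(f"metadata column {name!r} missing")
        col = self.metadata[name].to_numpy()
        if pd.isna(col).any():
            raise ValueError(f"metadata column {name!r} has missing values")
        return col


@dataclass
class NeighborhoodReport:
    """k-nearest-neighbor indices per query row.

    ``neighbor_indices[q]`` lists the k row indices nearest to query q
    (self excluded), in ascending distance with index tie-breaks.
    """

    k: int
    metric: str
    neighbor_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.neighbor_indices)
        if idx.ndim != 2 or idx.shape[1] != self.k:
            raise ValueError("neighbor_indices must be N x k")
        rows = np.arange(idx.shape[0])[:, None]
        if (idx == rows).any():
            raise ValueError("a query appears in its own neighbor list")
        for q in range(idx.shape[0]):
            if len(set(idx[q])) != self.k:
                raise ValueError(f"duplicate neighbor index in row {q}")
        self.neighbor_indices = idx

    def to_frame(self, ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        cols = {f"nn{j + 1}": self.neighbor_indices[:, j] for j in range(self.k)}
        df = pd.DataFrame(cols)
        if ids is not None:
            df.insert(0, "id", list(ids))
        return df


def mean_pool(token_embeddings: np.ndarray) -> np.ndarray:
    """Mean of per-token embeddings over the sequence: T x d -> d."""
    m = np.asarray(token_embeddings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("expected a nonempty T x d matrix")
    return m.mean(axis=0)


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(X, X, metric="euclidean")
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = int(np.argmax(norms == 0))
            raise ValueError(f"zero-norm row {bad} under cosine metric")
        return cdist(X, X, metric="cosine")
    raise ValueError(f"unknown metric {metric!r}")


def knn(E: EmbeddingSet, k: int, metric: str = "euclidean") -> NeighborhoodReport:
    """k-nearest neighbors of every row, self excluded.

    Exhaustive all-pairs distances with deterministic tie-breaking: equal
    distances are ordered by ascending row index (stable sort on the
    distance matrix).
    """
    if not 1 <= k <= E.n - 1:
        raise ValueError(f"k must be in [1, N-1] = [1, {E.n - 1}], got {k}")
    D = _distance_matrix(E.matrix, metric)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return NeighborhoodReport(k=k, metric=metric, neighbor_indices=order[:, :k])


@dataclass
class PositionDistanceStats:
    """|pos(query) - pos(neighbor)| over each neighborhood.

    Both the median of the pooled N*k distances and the median of the
    per-query medians are reported, since a scan summary may reasonably
    use either.
    """

    distances: np.ndarray  # N x k
    pooled_median: float
    per_query_medians: np.ndarray
    median_of_query_medians: float
    pooled_mean: float


def position_distance_stats(
    E: EmbeddingSet, report: NeighborhoodReport, column: str = "mutated_position"
) -> PositionDistanceStats:
    """Distance in mutated position between each query and its neighbors."""
    pos = E.column(column).astype(float)
    idx = report.neighbor_indices
    dist = np.abs(pos[:, None] - pos[idx])
    per_query = np.median(dist, axis=1)
    return PositionDistanceStats(
        distances=dist,
        pooled_median=float(np.median(dist)),
        per_query_medians=per_query,
        median_of_query_medians=float(np.median(per_query)),
        pooled_mean=float(dist.mean()),
    )


@dataclass
class AminoAcidAccuracy:
    """Per-query fraction of neighbors sharing the mutant amino acid."""

    per_query: np.ndarray
    mean: float


def aa_accuracy(
    E: EmbeddingSet, report: NeighborhoodReport, column: str = "mutant_aa"
) -> AminoAcidAccuracy:
    """Fraction of each neighborhood sharing the query's mutant amino acid."""
    labels = E.column(column)
    idx = report.neighbor_indices
    hits = labels[idx] == labels[:, None]
    per_query = hits.mean(axis=1)
    return AminoAcidAccuracy(per_query=per_query, mean=float(per_query.mean()))


def random_baseline_accuracy(labels: Sequence, k: int = 1) -> float:
    """Exact expected accuracy under uniformly random embeddings.

    If each query's k neighbors were k uniform draws without replacement
    from the other N-1 rows, the expected fraction sharing the query's
    label is mean over queries q of (n_label(q) - 1) / (N - 1), where
    n_a counts rows with label a. The value is independent of k.
    """
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two rows")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, N-1], got {k}")
    counts: dict = {}
    for a in labels:
        counts[a] = counts.get(a, 0) + 1
    return float(np.mean([(counts[a] - 1) / (n - 1) for a in labels]))


def permutation_null_accuracies(
    labels: Sequence,
    report: NeighborhoodReport,
    n_trials: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo null for the mean neighborhood label accuracy.

    Shuffles the label vector ``n_trials`` times while keeping the
    neighbor graph fixed and returns the trial means — the distribution
    of :func:`aa_accuracy`'s mean when labels are arranged at random.
    """
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    idx = report.neighbor_indices
    out = np.empty(n_trials)
    for t in range(n_trials):
        perm = lab[rng.permutation(lab.size)]
        out[t] = (perm[idx] == perm[: idx.shape[0], None]).mean()
    return out


def k_sweep(
    E: EmbeddingSet,
    ks: Sequence[int],
    metric: str = "euclidean",
    position_column: str = "mutated_position",
    aa_column: str = "mutant_aa",
) -> pd.DataFrame:
    """Neighborhood summaries across neighborhood sizes.

    One distance matrix is computed; each row of the result gives, for
    one k, the pooled median position distance and the mean mutant-amino-
    acid accuracy (plus the k-independent random baseline).
    """
    kmax = max(ks)
    full = knn(E, kmax, metric=metric)
    have_pos = position_column in E.metadata.columns
    have_aa = aa_column in E.metadata.columns
    rows = []
    for k in sorted(ks):
        sub = NeighborhoodReport(
            k=k, metric=metric, neighbor_indices=full.neighbor_indices[:, :k]
        )
        row: dict = {"k": k}
        if have_pos:
            row["median_position_distance"] = position_distance_stats(
                E, sub, position_column
            ).pooled_median
        if have_aa:
            row["mean_aa_accuracy"] = aa_accuracy(E, sub, aa_column).mean
            row["baseline_aa_accuracy"] = random_baseline_accuracy(
                E.column(aa_column), k
            )
        rows.append(row)
    return pd.DataFrame(rows)


def joint_concat(E1: EmbeddingSet, E2: EmbeddingSet) -> EmbeddingSet:
    """Concatenate two pooled embedding sets row-wise by id.

    The id sets must coincide; rows of ``E2`` are realigned to ``E1``'s
    order. Metadata columns are merged; a column present in both must
    agree on every id, otherwise a ValueError names the offending id.
    """
    if set(E1.ids) != set(E2.ids):
        missing = sorted(set(E1.ids) ^ set(E2.ids))[:5]
        raise ValueError(f"id sets differ (e.g. {missing})")
    pos2 = {i: j for j, i in enumerate(E2.ids)}
    perm = [pos2[i] for i in E1.ids]
    m2 = E2.matrix[perm]
    meta2 = E2.metadata.iloc[perm].reset_index(drop=True)
    meta = E1.metadata.copy()
    for col in meta2.columns:
        if col in meta.columns:
            a, b = meta[col].to_numpy(), meta2[col].to_numpy()
            both = ~(pd.isna(a) | pd.isna(b))
            bad = np.nonzero(both & (a != b))[0]
            if bad.size:
                raise ValueError(
                    f"metadata conflict in column {col!r} for id"
                    f" {E1.ids[int(bad[0])]!r}"
                )
        else:
            meta[col] = meta2[col]
    return EmbeddingSet(
        ids=list(E1.ids),
        matrix=np.hstack([E1.matrix, m2]),
        metadata=meta,
    )


class LinearHead:
    """Single-layer (linear) regression head over pooled embeddings.

    Ordinary least squares when ``ridge == 0`` (requires N_train > d),
    otherwise ridge regression with penalty ``ridge``. ``score`` returns
    the coefficient of determination R^2 and Spearman's rho — the two
    standard metrics for sequence-level regression benchmarks.
    """

    def __init__(self, ridge: float = 0.0):
        if ridge < 0:
            raise ValueError("ridge penalty must be nonnegative")
        self.ridge = ridge
        self._model = None

    def fit(self, train: EmbeddingSet, label_column: str = "label") -> "LinearHead":
        y = train.column(label_column).astype(float)
        if self.ridge == 0:
            if train.n <= train.d:
                raise ValueError(
                    f"singular system: N={train.n} <= d={train.d} with ridge 0"
                )
            self._model = LinearRegression()
        else:
            self._model = Ridge(alpha=self.ridge)
        self._model.fit(train.matrix, y)
        return self

    def predict(self, E: EmbeddingSet) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("head is not fitted")
        return self._model.predict(E.matrix)

    def score(self, E: EmbeddingSet, label_column: str = "label") -> dict[str, float]:
        y = E.column(label_column).astype(float)
        yhat = self.predict(E)
        rho = spearmanr(y, yhat).statistic
        return {"r2": float(r2_score(y, yhat)), "spearman": float(rho)}
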