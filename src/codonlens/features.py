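"""Global CDS features and embedding augmentation.

A nucleotide sequence carries two cheap global signals that its protein
does not: GC-content and the species-specific codon-usage fingerprint.
This module turns both into feature blocks that can be appended to
pooled sequence embeddings before a prediction head, and provides a
transparent nearest-centroid species classifier over 64-dimensional
codon-frequency vectors as a desk-scale probe of how much species signal
a CDS corpus contains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    CODONS,
    STANDARD_CODE,
    CdsRecord,
    GeneticCode,
    codon_frequency_vector,
    gc_content,
)
from .embedspace import EmbeddingSet

__all__ = [
    "FeatureBlock",
    "SpeciesCentroids",
    "augment",
    "classify_species",
    "fit_species_centroids",
    "gc_feature",
    "one_hot_species",
]


@dataclass
class SpeciesCentroids:
    """Mean per-sequence codon-frequency vector for each species."""

    centroids: dict[str, np.ndarray]
    n_train: dict[str, int]

    def __post_init__(self) -> None:
        for sp, v in self.centroids.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (64,):
                raise ValueError(f"centroid for {sp!r} must be a 64-vector")
            if not np.isclose(v.sum(), 1.0):
                raise ValueError(f"centroid for {sp!r} does not sum to 1")
            self.centroids[sp] = v

    @property
    def species(self) -> list[str]:
        return sorted(self.centroids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {sp: self.centroids[sp] for sp in self.species}, index=list(CODONS)
        ).T
        df.index.name = "species"
        return df


def fit_species_centroids(
    train: Sequence[CdsRecord], code: GeneticCode = STANDARD_CODE
) -> SpeciesCentroids:
    """Fit per-species codon-usage centroids from labeled CDS.

    Each centroid is the mean of the per-sequence codon-frequency
    vectors of that species (so every sequence weighs equally regardless
    of length). Records must carry a species.
    """
    by_sp: dict[str, list[np.ndarray]] = {}
    for rec in train:
        if rec.species is None:
            raise ValueError(f"record {rec.id!r} has no species")
        by_sp.setdefault(rec.species, []).append(
            codon_frequency_vector(rec, code=code)
        )
    if not by_sp:
        raise ValueError("no training sequences")
    return SpeciesCentroids(
        centroids={sp: np.mean(vs, axis=0) for sp, vs in by_sp.items()},
        n_train={sp: len(vs) for sp, vs in by_sp.items()},
    )


def classify_species(
    cds: CdsRecord | str,
    centroids: SpeciesCentroids,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[str, dict[str, float]]:
    """Nearest-centroid species call for one CDS.

    Returns the species whose centroid is closest in Euclidean distance
    to the sequence's codon-frequency vector, plus the full distance
    vector. Ties break to the lexicographically first species name.
    """
    v = codon_frequency_vector(cds, code=code)
    dists = {
        sp: float(np.linalg.norm(v - centroids.centroids[sp]))
        for sp in centroids.species
    }
    best = min(centroids.species, key=lambda sp: (dists[sp], sp))
    return best, dists


@dataclass
class FeatureBlock:
    """A named N x f feature matrix aligned to sequence ids."""

    name: str
    ids: list[str]
    matrix: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != len(self.ids):
            raise ValueError("row count must match ids")
        if not self.columns:
            self.columns = [f"{self.name}_{j}" for j in range(self.matrix.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.columns)
        df.insert(0, "id", self.ids)
        return df


def gc_feature(
    records: Sequence[CdsRecord],
    train_records: Optional[Sequence[CdsRecord]] = None,
) -> FeatureBlock:
    """Normalized (z-scored) GC-content as an N x 1 feature block.

    Normalization statistics come from ``train_records`` (default: the
    records themselves) so the test split never leaks into the scaler.
    The population convention (ddof=0) is used; a constant-GC training
    split yields all-zero features.
    """
    gcs = np.array([gc_content(r.sequence) for r in records])
    ref = (
        gcs
        if train_records is None
        else np.array([gc_content(r.sequence) for r in train_records])
    )
    mu, sd = ref.mean(), ref.std()
    z = np.zeros_like(gcs) if sd == 0 else (gcs - mu) / sd
    return FeatureBlock(
        name="gc", ids=[r.id for r in records], matrix=z[:, None], columns=["gc_z"]
    )


def one_hot_species(
    records: Sequence[CdsRecord],
    train_records: Optional[Sequence[CdsRecord]] = None,
) -> FeatureBlock:
    """One-hot species indicator block with train-fixed category order.

    Category order is the sorted species set of ``train_records``
    (default: the records themselves). A species unseen at training time
    yields an all-zero row and a warning.
    """
    ref = records if train_records is None else train_records
    cats = sorted({r.species for r in ref if r.species is not None})
    if not cats:
        raise ValueError("no species present in training records")
    col = {sp: j for j, sp in enumerate(cats)}
    m = np.zeros((len(records), len(cats)))
    for i, r in enumerate(records):
        j = col.get(r.species)
        if j is None:
            warnings.warn(
                f"species {r.species!r} of record {r.id!r} unseen at fit time;"
                " emitting all-zero row",
                stacklevel=2,
            )
        else:
            m[i, j] = 1.0
    return FeatureBlock(
        name="species",
        ids=[r.id for r in records],
        matrix=m,
        columns=[f"species={sp}" for sp in cats],
    )


def augment(embeddings: EmbeddingSet, blocks: Sequence[FeatureBlock]) -> EmbeddingSet:
    """Append feature blocks column-wise to an embedding set.

    Blocks are realigned to the embedding id order (ids must coincide);
    the output dimension is d plus the sum of block widths, in argument
    order. Row count, id order and metadata are untouched. An empty
    block list returns an equivalent embedding set.
    """
    parts = [embeddings.matrix]
    for b in blocks:
        if set(b.ids) != set(embeddings.ids):
            missing = sorted(set(embeddings.ids) ^ set(b.ids))[:5]
            raise ValueError(
                f"feature block {b.name!r} ids misaligned (e.g. {missing})"
            )
        pos = {i: j for j, i in enumerate(b.ids)}
        parts.append(b.matrix[[pos[i] for i in embeddings.ids]])
    return EmbeddingSet(
        ids=list(embeddings.ids),
        matrix=np.hstack(parts),
        metadata=embeddings.metadata.copy(),
    )
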