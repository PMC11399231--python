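"""Translation-preserving codon sampling strategies.

Two transforms that replace a true CDS with a surrogate encoding the same
protein:

* **permutation** — within one sequence, shuffle the codons occupying the
  positions of each amino acid; the per-sequence codon multiset (hence
  codon usage and GC-content) is exactly preserved, only local order is
  destroyed.
* **uniform** — replace every codon independently by a uniform draw from
  its synonym set; both local order and usage bias are destroyed.

``true_cds`` (identity) completes the trio. Seeding is hierarchical: a
dataset-level master seed plus a stable hash of each record id, so
per-record output is independent of dataset order.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

from .seqcore import CdsRecord, GeneticCode, STANDARD_CODE, codons_of

__all__ = ["permute_synonymous", "sample_uniform", "apply_strategy", "STRATEGIES"]

STRATEGIES = ("true_cds", "permutation", "uniform")

_ALIASES = {
    "true": "true_cds",
    "true_cds": "true_cds",
    "permute": "permutation",
    "permutation": "permutation",
    "uniform": "uniform",
}


def record_rng(master_seed: int, record_id: str) -> np.random.Generator:
    """Per-record RNG derived from a master seed and a stable id hash."""
    digest = hashlib.sha256(record_id.encode()).digest()
    h = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


def _transform(
    cds: CdsRecord,
    rng: np.random.Generator,
    code: GeneticCode,
    kind: str,
    freeze_terminal_stop: bool,
) -> CdsRecord:
    cods = codons_of(cds.sequence)
    n = len(cods)
    frozen_tail = (
        freeze_terminal_stop and n > 0 and code.table[cods[-1]] == "*"
    )
    active = n - 1 if frozen_tail else n

    if kind == "permutation":
        positions: dict[str, list[int]] = {}
        for i in range(active):
            positions.setdefault(code.table[cods[i]], []).append(i)
        new = list(cods)
        for aa in sorted(positions):  # sorted: stable rng consumption order
            idx = positions[aa]
            if len(idx) > 1:
                perm = rng.permutation(len(idx))
                for slot, src in zip(idx, perm):
                    new[slot] = cods[idx[src]]
    else:  # uniform
        new = list(cods)
        for i in range(active):
            syn = sorted(code.synonym_sets[code.table[cods[i]]])
            new[i] = syn[int(rng.integers(len(syn)))]

    return CdsRecord(
        id=cds.id,
        sequence="".join(new),
        species=cds.species,
        label=cds.label,
        mutation=cds.mutation,
    )


def permute_synonymous(
    cds: CdsRecord,
    seed: int,
    code: GeneticCode = STANDARD_CODE,
    freeze_terminal_stop: bool = True,
) -> CdsRecord:
    """Shuffle same-amino-acid codons within one sequence.

    For each amino acid, the multiset of codons at its positions is
    preserved exactly; their arrangement is a uniform random permutation.
    Translation, per-sequence codon counts and GC-content are unchanged.
    Stop codons permute among stop positions only; the terminal stop is
    left in place by default to preserve terminality.
    """
    rng = record_rng(seed, cds.id)
    return _transform(cds, rng, code, "permutation", freeze_terminal_stop)


def sample_uniform(
    cds: CdsRecord,
    seed: int,
    code: GeneticCode = STANDARD_CODE,
    freeze_terminal_stop: bool = True,
) -> CdsRecord:
    """Replace each codon by a uniform draw from its synonym set.

    Translation is preserved; codon-usage bias is not. Single-codon amino
    acids (Met, Trp) are fixed points.
    """
    rng = record_rng(seed, cds.id)
    return _transform(cds, rng, code, "uniform", freeze_terminal_stop)


def apply_strategy(
    dataset: Sequence[CdsRecord],
    strategy: str,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> list[CdsRecord]:
    """Apply a codon sampling strategy record-wise to a dataset.

    ``true_cds`` returns the input unchanged. Per-record seeds derive
    from ``seed`` and each record's id, so output does not depend on
    dataset order. Metadata (species, label, mutation) is preserved.
    """
    canon = _ALIASES.get(strategy)
    if canon is None:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {sorted(set(_ALIASES))}"
        )
    if canon == "true_cds":
        return list(dataset)
    fn = permute_synonymous if canon == "permutation" else sample_uniform
    return [fn(r, seed, code=code) for r in dataset]
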