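"""Degeneracy-aware dataset construction for mutation-scan corpora.

The genetic code is degenerate, so an all-single-codon-substitution scan
of a gene contains many coding sequences that translate to the same
protein. Training nucleotide models on such data while testing protein
models demands care: a protein-identical ("degenerate") pair split across
train and test leaks labels. This module provides the two standard
constructions —

* **Complete set** — keep every training CDS except those degenerate with
  any test CDS;
* **Unique set** — keep a random, maximal subset of pairwise-nondegenerate
  CDS (one per distinct protein), retaining each survivor's raw label;

— plus translation-match filtering, single-codon mutation application,
and the count-weighted fitness summary used for antibiotic-selection
scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .seqcore import (
    STANDARD_CODE,
    CdsRecord,
    GeneticCode,
    ProteinRecord,
    CODONS,
    codons_of,
    translate,
    validate_pair,
)

__all__ = [
    "MutationDescriptor",
    "MutationScanDataset",
    "FitnessRecord",
    "apply_codon_mutation",
    "build_complete_set",
    "build_unique_set",
    "dedupe_degenerate_test",
    "enumerate_codon_substitutions",
    "filter_translation_mismatch",
    "fitness_weighted_average",
    "group_degenerate",
    "normalize_fitness",
    "degeneracy_key",
]


class ReferenceInconsistencyError(ValueError):
    """Descriptor's reference codon disagrees with the reference sequence."""


@dataclass(frozen=True)
class MutationDescriptor:
    """A single-codon substitution at a 1-based codon position."""

    position: int
    ref_codon: str
    alt_codon: str
    code: GeneticCode = field(default=STANDARD_CODE, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.ref_codon == self.alt_codon:
            raise ValueError("ref_codon and alt_codon must differ")
        for c in (self.ref_codon, self.alt_codon):
            if c not in self.code.table:
                raise ValueError(f"invalid codon {c!r}")
        if self.position < 1:
            raise ValueError("codon positions are 1-based")

    @property
    def ref_aa(self) -> str:
        return self.code.table[self.ref_codon]

    @property
    def alt_aa(self) -> str:
        return self.code.table[self.alt_codon]

    @property
    def is_synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    def __str__(self) -> str:
        # protein-level display, e.g. "A42G"
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class FitnessRecord:
    """Raw and wildtype-normalized fitness of one allele.

    ``w > 1`` flags a variant more fit than wildtype.
    """

    f: float
    f_wt: float

    @property
    def w(self) -> float:
        return normalize_fitness(self.f, self.f_wt)

    @property
    def more_fit_than_wt(self) -> bool:
        return self.w > 1.0


def degeneracy_key(rec: CdsRecord | str, code: GeneticCode = STANDARD_CODE) -> str:
    """Protein string used to compare CDS for degeneracy.

    Case-insensitive (sequences are uppercased on ingestion), ignores the
    terminal stop, and renders internal stops as ``'*'`` so that
    stop-codon variants group by their (truncating) translation.
    """
    return translate(rec, code=code, mode="strict", drop_terminal_stop=True,
                     allow_internal_stop=True)


def filter_translation_mismatch(
    pairs: Iterable[tuple[CdsRecord, ProteinRecord]],
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[tuple[CdsRecord, ProteinRecord]], list[dict]]:
    """Keep CDS/protein pairs whose translation matches exactly.

    Mirrors the curation rule for database-retrieved CDS: any pair whose
    CDS does not translate to its protein is dropped. Frame and alphabet
    errors become rejections rather than exceptions. Returns
    ``(kept, rejection_log)``; each log entry has ``id`` and ``reason``.
    """
    kept: list[tuple[CdsRecord, ProteinRecord]] = []
    log: list[dict] = []
    for cds, prot in pairs:
        try:
            ok, report = validate_pair(cds, prot, code=code)
        except ValueError as exc:
            log.append({"id": cds.id, "reason": f"{type(exc).__name__}: {exc}"})
            continue
        if ok:
            kept.append((cds, prot))
        else:
            log.append(
                {
                    "id": cds.id,
                    "reason": (
                        f"translation mismatch at residue {report['position']}"
                        f" ({report['translated']!r} != {report['expected']!r})"
                    ),
                }
            )
    return kept, log


def group_degenerate(
    cds_list: Sequence[CdsRecord], code: GeneticCode = STANDARD_CODE
) -> dict[str, list[CdsRecord]]:
    """Partition CDS records by translated protein.

    Two CDS share a group iff they are degenerate (identical translation,
    terminal stop ignored). Group keys are the shared protein strings.
    """
    groups: dict[str, list[CdsRecord]] = {}
    for rec in cds_list:
        groups.setdefault(degeneracy_key(rec, code), []).append(rec)
    return groups


def build_complete_set(
    train: Sequence[CdsRecord],
    test: Sequence[CdsRecord],
    code: GeneticCode = STANDARD_CODE,
) -> list[CdsRecord]:
    """All training CDS except those degenerate with any test CDS.

    The test set is untouched; the returned list preserves train order.
    """
    test_proteins = {degeneracy_key(r, code) for r in test}
    return [r for r in train if degeneracy_key(r, code) not in test_proteins]


def build_unique_set(
    cds_list: Sequence[CdsRecord],
    seed: int,
    code: GeneticCode = STANDARD_CODE,
) -> list[CdsRecord]:
    """A random, maximal subset of pairwise-nondegenerate CDS.

    Exactly one CDS is kept per degeneracy group, chosen uniformly at
    random with ``seed``; survivors keep their raw (unaveraged) labels.
    Output size equals the number of distinct proteins; order follows
    first appearance of each group in the input.
    """
    rng = np.random.default_rng(seed)
    groups = group_degenerate(cds_list, code)
    out: list[CdsRecord] = []
    for key in groups:  # insertion order = first appearance
        members = groups[key]
        out.append(members[int(rng.integers(len(members)))])
    return out


def dedupe_degenerate_test(
    test: Sequence[CdsRecord],
    seed: int,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[CdsRecord], list[CdsRecord]]:
    """Remove random members of degenerate groups so the set is unique.

    The rule used for mostly-nondegenerate test sets: within each
    degeneracy group one member is kept (uniformly at random, seeded) and
    the rest removed. Returns ``(kept, removed)`` with input order
    preserved in ``kept``.
    """
    keep = {id(r) for r in build_unique_set(test, seed, code)}
    kept = [r for r in test if id(r) in keep]
    removed = [r for r in test if id(r) not in keep]
    return kept, removed


def apply_codon_mutation(
    reference: CdsRecord,
    m: MutationDescriptor,
    variant_id: Optional[str] = None,
) -> CdsRecord:
    """Apply a single-codon substitution to a reference CDS.

    The reference codon at ``m.position`` must equal ``m.ref_codon``;
    otherwise a :class:`ReferenceInconsistencyError` is raised. The
    returned record differs from the reference only over the mutated
    codon's three nucleotides and carries the descriptor.
    """
    cods = codons_of(reference.sequence)
    if not (1 <= m.position <= len(cods)):
        raise IndexError(
            f"codon position {m.position} out of range 1..{len(cods)}"
        )
    found = cods[m.position - 1]
    if found != m.ref_codon:
        raise ReferenceInconsistencyError(
            f"reference has {found} at codon {m.position}, descriptor says"
            f" {m.ref_codon}"
        )
    cods[m.position - 1] = m.alt_codon
    return CdsRecord(
        id=variant_id or f"{reference.id}:{m.position}:{m.alt_codon}",
        sequence="".join(cods),
        species=reference.species,
        mutation=m,
    )


def enumerate_codon_substitutions(
    reference: CdsRecord,
    position: int,
    include_stops: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> list[CdsRecord]:
    """All single-codon variants of ``reference`` at one position.

    With stops included there are exactly 63 variants (64 codons minus
    the reference codon); ``include_stops=False`` drops alt codons that
    translate to ``'*'``.
    """
    ref_codon = codons_of(reference.sequence)[position - 1]
    out = []
    for alt in CODONS:
        if alt == ref_codon:
            continue
        if not include_stops and code.table[alt] == "*":
            continue
        m = MutationDescriptor(position=position, ref_codon=ref_codon,
                               alt_codon=alt, code=code)
        out.append(apply_codon_mutation(reference, m))
    return out


@dataclass
class MutationScanDataset:
    """A reference CDS plus its single-codon variants with fitness labels."""

    reference: CdsRecord
    variants: list[CdsRecord]
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def __post_init__(self) -> None:
        ref_cods = codons_of(self.reference.sequence)
        for v in self.variants:
            m = v.mutation
            if m is None:
                raise ValueError(f"variant {v.id} lacks a mutation descriptor")
            diff = [
                i
                for i, (a, b) in enumerate(
                    zip(ref_cods, codons_of(v.sequence)), start=1
                )
                if a != b
            ]
            if diff != [m.position]:
                raise ValueError(
                    f"variant {v.id} differs from reference at codons {diff},"
                    f" descriptor says {m.position}"
                )

    @property
    def degeneracy_groups(self) -> dict[str, list[CdsRecord]]:
        """Partition of reference + variants by translated protein."""
        return group_degenerate([self.reference, *self.variants], self.code)

    def __len__(self) -> int:
        return len(self.variants)


def fitness_weighted_average(
    counts: Sequence[float],
    concentrations: Sequence[float],
    log_fn: Callable[[np.ndarray], np.ndarray] = np.log10,
) -> float:
    """Count-weighted mean of log-concentration across selection plates.

    For an allele sequenced on plates with antibiotic concentrations
    ``A_p`` and read counts ``c_p``, the unnormalized fitness is

        f = sum_p c_p * log10(A_p) / sum_p c_p.

    ``log_fn`` is injectable because selection pipelines differ in their
    log base and per-plate normalization.
    """
    c = np.asarray(counts, dtype=float)
    a = np.asarray(concentrations, dtype=float)
    if c.shape != a.shape:
        raise ValueError("counts and concentrations must have equal length")
    if (a <= 0).any():
        raise ValueError("concentrations must be strictly positive")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ValueError("undefined fitness: zero total count")
    return float((c * log_fn(a)).sum() / total)


def normalize_fitness(f: float, f_wt: float) -> float:
    """Normalize allele fitness by wildtype fitness: ``w = f / f_wt``."""
    if f_wt == 0:
        raise ZeroDivisionError("wildtype fitness is zero")
    return f / f_wt
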