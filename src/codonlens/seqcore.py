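"""Genetic-code arithmetic for coding sequences.

Translation, CDS/protein consistency checks, GC-content, codon-usage
profiles and the k-mer-token to residue map used when a nucleotide model
tokenizes more than one codon per token.

All sequence input is case-insensitive and RNA-tolerant: sequences are
uppercased and ``U`` is mapped to ``T`` on ingestion. The standard nuclear
genetic code is the default everywhere; a custom :class:`GeneticCode` can
be injected into any operation that consults the code table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "AlphabetError",
    "CdsRecord",
    "CodonUsageProfile",
    "FrameError",
    "GeneticCode",
    "PrematureStopError",
    "ProteinRecord",
    "CODONS",
    "CODON_INDEX",
    "STANDARD_CODE",
    "codon_usage",
    "codons_of",
    "gc_content",
    "kmer_token_residue_map",
    "normalize_dna",
    "translate",
    "validate_pair",
]

#: The 64 codons in lexicographic (A<C<G<T) order; fixed vector layout for
#: every 64-dimensional codon-count/frequency vector in the package.
CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP = "*"


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the expected alphabet."""


class PrematureStopError(ValueError):
    """A stop codon occurs before the final codon in strict mode."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table plus its synonym-set partition.

    ``table`` maps each of the 64 codons to one of the 20 standard amino
    acids or ``'*'`` for stop. ``synonym_sets`` inverts it: amino acid ->
    frozenset of codons encoding it.
    """

    table: Mapping[str, str]
    synonym_sets: Mapping[str, frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            raise ValueError("genetic code table must cover exactly the 64 codons")
        syn: dict[str, set[str]] = {}
        for codon, aa in self.table.items():
            syn.setdefault(aa, set()).add(codon)
        object.__setattr__(
            self,
            "synonym_sets",
            {aa: frozenset(cs) for aa, cs in syn.items()},
        )

    @property
    def amino_acids(self) -> tuple[str, ...]:
        """Sorted amino-acid symbols, stop last."""
        aas = sorted(a for a in self.synonym_sets if a != STOP)
        return tuple(aas) + ((STOP,) if STOP in self.synonym_sets else ())


def _standard_code() -> GeneticCode:
    t = CodonTable.unambiguous_dna_by_id[1]
    table = dict(t.forward_table)
    for c in t.stop_codons:
        table[c] = STOP
    return GeneticCode(table=table)


STANDARD_CODE = _standard_code()
assert sum(1 for a in STANDARD_CODE.table.values() if a == STOP) == 3
assert len(set(STANDARD_CODE.table.values()) - {STOP}) == 20


def normalize_dna(seq: str) -> str:
    """Uppercase and map U->T. Does not validate the alphabet."""
    return seq.upper().replace("U", "T")


@dataclass
class CdsRecord:
    """A coding DNA sequence with optional species, label and mutation.

    ``label`` is a task-dependent real value (melting point in deg C,
    normalized fitness, log10 stability, ...). ``mutation`` is a
    :class:`codonlens.curation.MutationDescriptor` when the record is a
    single-codon variant of a reference gene.
    """

    id: str
    sequence: str
    species: Optional[str] = None
    label: Optional[float] = None
    mutation: Optional[object] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_dna(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """An amino-acid sequence (20 standard letters, optional terminal '*')."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()


def codons_of(seq: str) -> list[str]:
    """Split a frame-valid DNA string into its codons."""
    s = normalize_dna(seq)
    if len(s) % 3 != 0:
        raise FrameError(f"length {len(s)} is not a multiple of 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def translate(
    cds: str | CdsRecord,
    code: GeneticCode = STANDARD_CODE,
    mode: str = "strict",
    drop_terminal_stop: bool = True,
    allow_internal_stop: bool = False,
) -> str:
    """Translate a frame-valid CDS into amino acids.

    Parameters
    ----------
    mode
        ``"strict"`` requires a pure-ACGT sequence and (unless
        ``allow_internal_stop``) no stop codon before the last position.
        ``"lenient"`` renders any codon containing a non-ACGT character as
        ``'X'`` and permits internal stops.
    drop_terminal_stop
        When True (default) a trailing stop codon is omitted from the
        returned protein, matching the convention of protein databases;
        otherwise it is rendered ``'*'``.

    Raises
    ------
    FrameError, AlphabetError, PrematureStopError
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    seq = cds.sequence if isinstance(cds, CdsRecord) else normalize_dna(cds)
    aas: list[str] = []
    for codon in codons_of(seq):
        aa = code.table.get(codon)
        if aa is None:
            if mode == "strict":
                raise AlphabetError(f"non-ACGT codon {codon!r}")
            aa = "X"
        aas.append(aa)
    if mode == "strict" and not allow_internal_stop:
        if STOP in aas[:-1]:
            pos = aas.index(STOP) + 1
            raise PrematureStopError(f"internal stop at codon {pos}")
    if aas and aas[-1] == STOP and drop_terminal_stop:
        aas.pop()
    return "".join(aas)


def validate_pair(
    cds: CdsRecord | str,
    protein: ProteinRecord | str,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[bool, Optional[dict]]:
    """Check that a CDS translates exactly to the given protein.

    The terminal stop is ignored on both sides. Returns ``(ok, report)``;
    on mismatch ``report`` carries the first differing residue (1-based)
    and the two symbols. Frame errors propagate from :func:`translate`.
    """
    prot = protein.sequence if isinstance(protein, ProteinRecord) else protein.upper()
    prot = prot.rstrip(STOP)
    if not prot or not (cds.sequence if isinstance(cds, CdsRecord) else cds):
        raise ValueError("both records must be nonempty")
    trans = translate(cds, code=code, mode="strict", drop_terminal_stop=True,
                      allow_internal_stop=True)
    if trans == prot:
        return True, None
    n = min(len(trans), len(prot))
    pos = next((i for i in range(n) if trans[i] != prot[i]), n)
    return False, {
        "position": pos + 1,
        "translated": trans[pos] if pos < len(trans) else "",
        "expected": prot[pos] if pos < len(prot) else "",
        "reason": "length mismatch" if pos == n else "residue mismatch",
    }


def gc_content(seq: str) -> float:
    """Fraction of G or C among the ACGT bases of ``seq``.

    Case-insensitive; characters outside ACGT (after U->T mapping) are
    excluded from numerator and denominator alike.
    """
    s = normalize_dna(seq)
    if not s:
        raise ValueError("empty sequence has no GC-content")
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise AlphabetError("no ACGT bases in sequence")
    return (s.count("G") + s.count("C")) / acgt


@dataclass
class CodonUsageProfile:
    """Aggregate codon counts/frequencies over a CDS collection.

    ``counts`` follows the :data:`CODONS` layout. ``per_aa_frequencies``
    conditions on the encoded amino acid and only lists amino acids that
    occur; each conditional vector sums to one.
    """

    counts: np.ndarray
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must be a 64-vector")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(64)
        return self.counts / self.total

    @property
    def per_aa_frequencies(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for aa, codons in self.code.synonym_sets.items():
            idx = sorted(CODON_INDEX[c] for c in codons)
            sub = self.counts[idx]
            tot = sub.sum()
            if tot > 0:
                out[aa] = {
                    CODONS[i]: self.counts[i] / tot
                    for i in idx
                    if self.counts[i] > 0
                }
        return out

    def to_frame(self) -> pd.DataFrame:
        """64-row table: codon, amino_acid, count, frequency."""
        return pd.DataFrame(
            {
                "codon": CODONS,
                "amino_acid": [self.code.table[c] for c in CODONS],
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


def codon_usage(
    seqs: Iterable[CdsRecord | str], code: GeneticCode = STANDARD_CODE
) -> CodonUsageProfile:
    """Aggregate codon usage across frame-valid sequences."""
    counts = np.zeros(64, dtype=np.int64)
    for s in seqs:
        for codon in codons_of(s.sequence if isinstance(s, CdsRecord) else s):
            i = CODON_INDEX.get(codon)
            if i is None:
                raise AlphabetError(f"non-ACGT codon {codon!r}")
            counts[i] += 1
    return CodonUsageProfile(counts=counts, code=code)


def codon_frequency_vector(
    seq: CdsRecord | str, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Per-sequence 64-vector of codon frequencies (sums to 1)."""
    return codon_usage([seq], code=code).frequencies


def kmer_token_residue_map(k: int, n_tokens: int) -> list[tuple[int, ...]]:
    """Map k-mer token indices to the residue indices they cover.

    A nucleotide model tokenizing on k-mers (k a multiple of 3) covers
    k/3 residues per token: token ``t`` maps to residues
    ``[t*k/3, (t+1)*k/3)``. For k=6 every token yields two residue
    predictions; for k=3 the map is the identity.
    """
    if k <= 0 or k % 3 != 0:
        raise ValueError(f"k must be a positive multiple of 3, got {k}")
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    per = k // 3
    return [tuple(range(t * per, (t + 1) * per)) for t in range(n_tokens)]
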