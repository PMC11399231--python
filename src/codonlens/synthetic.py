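"""Synthetic data with planted ground truth.

Three generators, each a pure function of its seed:

* :func:`gen_species_corpus` — a multi-species CDS collection in which
  each species has its own Dirichlet-sampled per-amino-acid codon usage
  and its own label profile (melting-point-like: distinct species means,
  a GC slope, Gaussian noise);
* :func:`gen_mutation_scan` — an all-single-codon-substitution scan of a
  random reference gene, including degenerate synonymous variants, with
  fitness drawn from a planted position- or amino-acid-effect model and
  normalized so wildtype sits at 1;
* :func:`gen_structured_embeddings` — embedding matrices whose local
  neighborhoods are organized by mutated position, by mutant amino acid,
  or not at all, so the neighborhood protocol's discrimination can be
  tested against known structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    CODONS,
    STANDARD_CODE,
    CdsRecord,
    GeneticCode,
    gc_content,
)
from .curation import (
    MutationDescriptor,
    MutationScanDataset,
    apply_codon_mutation,
)
from .embedspace import EmbeddingSet

__all__ = [
    "SpeciesModel",
    "EmbeddingStructureSpec",
    "gen_mutation_scan",
    "gen_species_corpus",
    "gen_structured_embeddings",
    "make_species_models",
    "random_cds",
]


@dataclass
class SpeciesModel:
    """Codon-usage and label profile of one synthetic species.

    ``usage`` maps each amino acid to a probability vector over its
    synonym set (sorted codon order). ``label_mean``/``label_sd`` shape a
    melting-point-like label (deg C); ``gc_slope`` couples the label to
    the sequence's GC-content deviation from the corpus mean.
    """

    name: str
    usage: dict[str, np.ndarray]
    label_mean: float = 55.0
    label_sd: float = 2.0
    gc_slope: float = 20.0

    def __post_init__(self) -> None:
        for aa, v in self.usage.items():
            v = np.asarray(v, dtype=float)
            if not np.isclose(v.sum(), 1.0):
                raise ValueError(f"usage for {aa!r} does not sum to 1")
            self.usage[aa] = v


def make_species_models(
    n_species: int = 5,
    alpha: float = 0.5,
    seed: int = 0,
    label_means: Optional[Sequence[float]] = None,
    label_sd: float = 2.0,
    gc_slope: float = 20.0,
    code: GeneticCode = STANDARD_CODE,
) -> list[SpeciesModel]:
    """Draw species codon-usage models from a symmetric Dirichlet.

    Small ``alpha`` gives peaky, well-separated usage (easy species
    identification); large ``alpha`` approaches uniform usage
    (identification near chance). Default label means are spread over
    45–65 deg C so species have distinct label profiles.
    """
    rng = np.random.default_rng(seed)
    if label_means is None:
        label_means = np.linspace(45.0, 65.0, n_species)
    models = []
    for i in range(n_species):
        usage = {}
        for aa in code.amino_acids:
            syn = sorted(code.synonym_sets[aa])
            usage[aa] = rng.dirichlet(np.full(len(syn), alpha))
        models.append(
            SpeciesModel(
                name=f"sp{i + 1}",
                usage=usage,
                label_mean=float(label_means[i]),
                label_sd=label_sd,
                gc_slope=gc_slope,
            )
        )
    return models


_SENSE_AAS = tuple(a for a in STANDARD_CODE.amino_acids if a != "*")


def _encode_protein(
    protein: str, usage: dict[str, np.ndarray], rng: np.random.Generator,
    code: GeneticCode,
) -> str:
    cods = []
    for aa in protein:
        syn = sorted(code.synonym_sets[aa])
        cods.append(syn[int(rng.choice(len(syn), p=usage[aa]))])
    return "".join(cods)


def gen_species_corpus(
    models: Sequence[SpeciesModel],
    n_per_species: int = 200,
    protein_length: int = 120,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> list[CdsRecord]:
    """Generate a species-labeled CDS corpus with planted usage bias.

    Proteins are uniform random over the 20 amino acids (Met start);
    codons are drawn from the record's species usage; labels are
    ``label_mean + gc_slope * (gc - corpus_mean_gc) + N(0, label_sd)``.
    """
    rng = np.random.default_rng(seed)
    recs: list[CdsRecord] = []
    for m in models:
        for j in range(n_per_species):
            aas = rng.choice(len(_SENSE_AAS), size=protein_length - 1)
            protein = "M" + "".join(_SENSE_AAS[a] for a in aas)
            seq = _encode_protein(protein, m.usage, rng, code)
            recs.append(
                CdsRecord(id=f"{m.name}_{j:04d}", sequence=seq, species=m.name)
            )
    gcs = np.array([gc_content(r.sequence) for r in recs])
    mean_gc = gcs.mean()
    i = 0
    for m in models:
        for _ in range(n_per_species):
            r = recs[i]
            r.label = float(
                m.label_mean
                + m.gc_slope * (gcs[i] - mean_gc)
                + rng.normal(0.0, m.label_sd)
            )
            i += 1
    return recs


def random_cds(
    length_codons: int, seed: int, code: GeneticCode = STANDARD_CODE
) -> CdsRecord:
    """A random stop-free reference CDS starting with ATG."""
    if length_codons < 2:
        raise ValueError("need at least two codons")
    rng = np.random.default_rng(seed)
    sense = sorted(c for c in CODONS if code.table[c] != "*")
    body = [sense[int(i)] for i in rng.integers(len(sense), size=length_codons - 1)]
    return CdsRecord(id="WT", sequence="ATG" + "".join(body))


def gen_mutation_scan(
    reference_length_codons: int = 100,
    fitness_model: str = "position_effect",
    seed: int = 0,
    include_stops: bool = True,
    noise_sd: float = 0.05,
    code: GeneticCode = STANDARD_CODE,
) -> MutationScanDataset:
    """All single-codon substitutions of a random reference, with fitness.

    Every position contributes 63 variants (64 codons minus the
    reference codon); degenerate synonymous entries are therefore
    abundant. Planted fitness: wildtype w = 1; synonymous variants are
    neutral (w ~ 1 + noise); nonsynonymous variants get a per-position
    (``position_effect``) or per-mutant-amino-acid (``aa_effect``) effect
    drawn Uniform(0.05, 1.10) — so most variants fall below wildtype but
    some exceed it — plus Gaussian noise of sd ``noise_sd`` on the
    normalized scale.
    """
    if fitness_model not in ("position_effect", "aa_effect"):
        raise ValueError(f"unknown fitness model {fitness_model!r}")
    rng = np.random.default_rng(seed)
    reference = random_cds(reference_length_codons, seed=int(rng.integers(2**31)),
                           code=code)
    reference.label = 1.0

    L = reference_length_codons
    pos_effect = rng.uniform(0.05, 1.10, size=L)
    aa_keys = sorted(set(code.table.values()))
    aa_effect = dict(zip(aa_keys, rng.uniform(0.05, 1.10, size=len(aa_keys))))

    variants: list[CdsRecord] = []
    ref_cods = [reference.sequence[i : i + 3] for i in range(0, 3 * L, 3)]
    for pos in range(1, L + 1):
        ref_codon = ref_cods[pos - 1]
        for alt in CODONS:
            if alt == ref_codon:
                continue
            if not include_stops and code.table[alt] == "*":
                continue
            m = MutationDescriptor(position=pos, ref_codon=ref_codon,
                                   alt_codon=alt, code=code)
            v = apply_codon_mutation(
                reference, m, variant_id=f"v{pos:04d}_{alt}"
            )
            if m.is_synonymous:
                w = 1.0
            elif fitness_model == "position_effect":
                w = pos_effect[pos - 1]
            else:
                w = aa_effect[m.alt_aa]
            v.label = float(w + rng.normal(0.0, noise_sd))
            variants.append(v)
    return MutationScanDataset(reference=reference, variants=variants, code=code)


@dataclass
class EmbeddingStructureSpec:
    """How to plant local structure into synthetic embeddings.

    ``principle`` selects the organizing key: ``position`` clusters rows
    by mutated codon position, ``amino_acid`` by mutant amino acid,
    ``random`` plants nothing. Rows are
    ``cluster_scale * c(key) + N(0, noise_sd I_d)`` with ``c`` a fixed
    random map from key to a d-vector; the cluster_scale : noise_sd
    ratio is the separability dial.
    """

    principle: str = "position"
    cluster_scale: float = 10.0
    noise_sd: float = 1.0
    d: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.principle not in ("position", "amino_acid", "random"):
            raise ValueError(f"unknown principle {self.principle!r}")
        if self.cluster_scale < 0 or self.noise_sd < 0:
            raise ValueError("cluster_scale and noise_sd must be >= 0")
        if self.d < 1:
            raise ValueError("d must be >= 1")


def gen_structured_embeddings(
    records: MutationScanDataset | Sequence[CdsRecord],
    spec: EmbeddingStructureSpec,
) -> EmbeddingSet:
    """Embed mutation-scan records with planted neighborhood structure.

    Accepts a :class:`MutationScanDataset` (its variants are embedded)
    or any sequence of variant records carrying mutation descriptors.
    Metadata columns: ``mutated_position``, ``mutant_aa``, ``label``.
    """
    if isinstance(records, MutationScanDataset):
        recs = list(records.variants)
    else:
        recs = list(records)
    if not recs:
        raise ValueError("no records to embed")
    for r in recs:
        if r.mutation is None:
            raise ValueError(f"record {r.id!r} lacks a mutation descriptor")

    rng = np.random.default_rng(spec.seed)
    positions = np.array([r.mutation.position for r in recs])
    aas = np.array([r.mutation.alt_aa for r in recs])
    keys = positions if spec.principle == "position" else aas

    matrix = rng.normal(0.0, spec.noise_sd, size=(len(recs), spec.d))
    if spec.principle != "random":
        centers = {
            k: rng.standard_normal(spec.d) for k in sorted(set(keys.tolist()))
        }
        matrix += spec.cluster_scale * np.stack([centers[k] for k in keys.tolist()])

    meta = pd.DataFrame(
        {
            "mutated_position": positions,
            "mutant_aa": aas,
            "label": [r.label for r in recs],
        }
    )
    return EmbeddingSet(ids=[r.id for r in recs], matrix=matrix, metadata=meta)
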