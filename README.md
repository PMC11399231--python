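# codonlens

Codon-level machinery for comparing nucleotide- and protein-based sequence
models on protein tasks: CDS curation and degeneracy-aware dataset
construction, synonymous-codon sampling strategies, codon-usage/GC/species
features, and a k-nearest-neighbor protocol for probing how an embedding
space organizes single-mutation scans.

## The problem

A coding DNA sequence (CDS) carries strictly more information than the
protein it encodes: because the genetic code is degenerate (61 sense codons
for 20 amino acids), one protein admits many CDS, and the choice among
synonymous codons — codon usage bias — is species- and gene-specific.
Benchmarking nucleotide models against protein models therefore raises
dataset questions with sharp answers:

- **Curation.** A retrieved CDS must translate exactly to its protein; any
  mismatch is filtered out.
- **Degeneracy.** An all-single-codon-substitution scan of a gene (e.g. a
  deep mutational scan measuring fitness *w_i = f_i / f_WT*, with *w_i* > 1
  meaning fitter than wildtype) contains many degenerate CDS — distinct DNA,
  identical protein. Splitting them carelessly across train and test leaks
  labels. Two constructions avoid this: the **Complete set** (drop every
  training CDS degenerate with any test CDS) and the **Unique set** (a
  random, maximal subset with pairwise-distinct translations, keeping raw
  labels).
- **Sampling.** When the true CDS is unknown it is tempting to synthesize
  one. Two translation-preserving surrogates bracket the information loss:
  **permutation** (shuffle same-amino-acid codons within the sequence —
  codon usage preserved, local order destroyed) and **uniform** (each codon
  drawn uniformly from its synonym set — usage destroyed too).
- **Interpretation.** Given per-sequence embeddings *f(s_i) ∈ R^d*, the
  k-neighborhood NN_k(s_i) is the set of k sequences minimizing
  ‖f(s_i) − f(s_j)‖ (self excluded). For a mutation scan, two statistics
  reveal the organizing principle: the distribution of
  |pos(query) − pos(neighbor)| over mutated positions, and the fraction of
  neighbors sharing the query's mutant amino acid, compared to its exact
  expectation under a random arrangement,
  mean_q (n_label(q) − 1)/(N − 1).

Every stage is exercised end-to-end on seeded synthetic data with planted
ground truth: species corpora with Dirichlet-sampled codon usage, full
single-codon mutation scans with planted fitness, and embeddings clustered
by position, by mutant amino acid, or not at all.

## Worked example

```python
from codonlens.synthetic import (gen_mutation_scan, gen_structured_embeddings,
                                 EmbeddingStructureSpec)
from codonlens.curation import build_unique_set
from codonlens.embedspace import (knn, aa_accuracy, position_distance_stats,
                                  random_baseline_accuracy)

scan = gen_mutation_scan(reference_length_codons=60, seed=42)
print(f"variants: {len(scan.variants)}")
unique = build_unique_set(scan.variants, seed=42)
print(f"unique (nondegenerate) subset: {len(unique)}")

spec = EmbeddingStructureSpec(principle="amino_acid", cluster_scale=10.0,
                              noise_sd=1.0, d=16, seed=43)
E = gen_structured_embeddings(unique, spec)
report = knn(E, k=10)
print(f"mean mutant-aa accuracy: {aa_accuracy(E, report).mean:.3f}")
print(f"random baseline:         {random_baseline_accuracy(E.column('mutant_aa'), k=10):.3f}")
print(f"median position distance: {position_distance_stats(E, report).pooled_median:.1f}")
```

prints

```
variants: 3780
unique (nondegenerate) subset: 1201
mean mutant-aa accuracy: 1.000
random baseline:         0.047
median position distance: 18.0
```

A 60-codon gene yields 63 × 60 = 3780 single-codon variants collapsing to
1201 distinct proteins. With embeddings planted to cluster by mutant amino
acid (separation 10× the noise), every 10-neighborhood is pure — accuracy
1.0 against an expected 0.047 under a random arrangement — while the
mutated *positions* of neighbors are unrelated (median distance 18 of a
possible 0–59), showing the two statistics discriminate the organizing
principle.

A command-line interface exposes the same operations
(`codonlens translate | validate | curate | sample | features |
analyze-embeddings | simulate`); every run writes a JSON manifest with its
full parameterization.

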