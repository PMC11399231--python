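# Methods

## Genetic-code conventions

The standard nuclear genetic code (61 sense codons, 3 stops) is the default
throughout and is taken from Biopython's codon tables; any operation that
consults the code accepts an injected `GeneticCode` for non-standard codes.
Input is case-insensitive and RNA-tolerant (uppercased, U→T on ingestion).
Strict translation — the default for curation — demands pure ACGT and no
internal stop; lenient translation renders ambiguous codons as `X`. The
terminal stop codon is kept in the CDS but dropped from the translated
protein, matching protein-database convention, so CDS/protein validation
and degeneracy comparison both ignore it. Stop-codon variants inside a
mutation scan are retained by default (they are among the 63 possible
substitutions at a codon) and translate with `*`, so they form their own
degeneracy groups; a flag excludes them.

## Degeneracy-aware curation

Two CDS are *degenerate* when their translations are identical (terminal
stop ignored). The **Complete** rule removes from the training split every
CDS degenerate with any test CDS, leaving the test split untouched; the
**Unique** rule keeps exactly one CDS per degeneracy group, chosen
uniformly at random from a seeded generator, and retains the survivor's
raw label rather than a group average — synonymous variants of one protein
can carry different measured fitness, and averaging would erase exactly the
codon-level signal one wants to study. For mostly-nondegenerate test sets
the same mechanism removes random members of each degenerate group so the
set becomes unique.

Fitness for selection-scan data is summarized as the count-weighted mean of
log10 antibiotic concentration across selection plates,
f = Σ_p c_p·log10(A_p) / Σ_p c_p, then normalized by wildtype (w = f/f_WT,
w > 1 ⇒ fitter than wildtype). Published selection pipelines differ in log
base and per-plate depth normalization, so the log function is injectable;
the count-weighted log10 reading is the package default.

Codon positions are 1-based in descriptors and I/O ("S26C" style protein
display), 0-based internally; nucleotide spans are half-open.

## Sampling strategies

Permutation operates *within one sequence*: for each amino acid, the codons
at its positions are redistributed by a uniform random permutation. This
preserves the per-sequence codon multiset — hence codon usage, GC-content
and translation — exactly, and destroys only local codon order. Uniform
resampling replaces each codon independently by a uniform draw from its
synonym set, destroying usage bias as well. Stop codons permute only among
stop positions, and the terminal stop is frozen by default to preserve
terminality. Seeding is hierarchical — a master seed combined with a SHA-256
hash of the record id — so per-record output is independent of dataset
order and reproducible record-by-record.

A consequence used by the tests: any classifier over per-sequence codon
*frequencies* is exactly invariant under permutation, while uniform
resampling reduces species identification to chance.

## Features and augmentation

The species classifier is a nearest-centroid rule over 64-dimensional
per-sequence codon-frequency vectors (centroid = unweighted mean over a
species' training sequences; Euclidean distance; ties broken by species
name). It was chosen over a multinomial likelihood scorer for transparency;
the likelihood scorer is a natural extension point. "Normalized
GC-content" is implemented as a z-score with statistics from the training
split only (population convention, ddof = 0). Species enter as a one-hot
block whose category order is fixed by the training split; unseen species
yield an all-zero row plus a warning. Augmentation is plain column-wise
concatenation onto pooled embeddings, aligned by id — appending before the
prediction head, which is where a global scalar/indicator can act without
re-training the encoder.

## Neighborhood protocol

Embeddings are compared with Euclidean distance by default (cosine is
provided for parity but is not a true metric and degrades in high
dimension). Neighborhoods are computed from the exhaustive all-pairs
distance matrix with a stable argsort, so equal distances resolve to the
ascending row index and reports are fully deterministic; the test suite
checks exact agreement with an independent pure-Python all-pairs sort,
including planted duplicate rows. Position-distance summaries report both
the median of the pooled N·k distances and the median of per-query medians
(the two defensible readings of "median neighborhood distance"); the
random-arrangement baseline for label agreement is the exact expectation
mean_q (n_label(q) − 1)/(N − 1), which is independent of k, and is
validated against a label-shuffle Monte-Carlo null. A k-sweep utility
recomputes the summaries across neighborhood sizes from one distance
matrix.

The linear head is ordinary least squares (or ridge when a penalty is
given) over pooled embeddings, scored by R² and Spearman's ρ. Joint
embeddings are the id-aligned concatenation of two pooled embedding sets
with metadata-conflict detection.

## Synthetic generators

All generators are pure functions of their seed.

**Species corpus.** Each species draws, per amino acid, a codon-usage
vector from a symmetric Dirichlet with concentration α; α is the single
separability dial (α = 0.5 default gives peaky, well-separated usage;
α → ∞ approaches uniform usage and chance-level identification). Proteins
are uniform random over the 20 amino acids with a forced Met start
(length 120 by default, 200 sequences per species, 5 species). Labels
emulate melting points: species means spaced 45–65 °C (sd 2 °C) plus a GC
slope of 20 °C per unit GC-content deviation from the corpus mean. For the
augmentation-additivity experiment specifically, the corpus is generated
with label sd 1 °C and GC slope 100 °C/unit so that, by variance budgeting,
the GC term carries roughly 10 % of label variance and both augmentation
gaps are resolvable above noise; this is an experimental design choice made
up front, not a property of the default corpus.

**Mutation scan.** A random stop-free reference (ATG start) of L codons
yields all 63 single-codon substitutions at every position (63·L variants,
collapsing to 20·L + 1 distinct proteins). Planted fitness on the
normalized scale: wildtype 1; synonymous variants neutral; nonsynonymous
variants get a per-position or per-mutant-amino-acid effect drawn
Uniform(0.05, 1.10) plus N(0, 0.05) noise — so most variants fall below
wildtype while some exceed it, the shape real scans show.

**Structured embeddings.** Row i is cluster_scale·c(key_i) + N(0, σ²I_d)
with c a fixed seeded map from key (mutated position, mutant amino acid, or
nothing) to a standard-normal d-vector. The cluster_scale : σ ratio
controls recoverability; recovery is monotone in it, which the suite
checks over a seeded grid.

What the generators deliberately do *not* emulate: real protein structure
or thermodynamics, within-gene positional codon bias, phylogenetic
correlation between species, and the actual geometry of learned language
model embeddings. Passing tests therefore certify the correctness of the
dataset constructions and the discrimination power of the protocol on
planted structure — not any claim about real models or real data.

## Problem sizes and numerical choices

The end-to-end checks run at: 1000 random CDS for sampling invariance; 50
nearest-neighbor instances with N ≤ 500, d ≤ 32 under both metrics; a
length-100 scan (6300 variants, 2001-protein unique subset, k = 10,
separation ratio 10) for planted-structure recovery with a 200-shuffle
null interval; a 10⁴-draw Monte-Carlo oracle for baseline calibration
(agreement within 3 standard errors); 5 species × 200 sequences for the
species-signal experiment; and 5 seeds × 500 held-out sequences for
augmentation additivity. These sizes keep the whole pipeline at seconds of
runtime while leaving comfortable statistical margins.

Chi-square goodness-of-fit checks on sampling uniformity use α = 0.01.
Distance ties break to the ascending row index everywhere; species ties to
the lexicographically first name. Degenerate inputs fail loudly: empty
sequences, frame violations, non-ACGT codons in strict mode, zero total
counts in fitness weighting, zero-norm rows under cosine, singular OLS
systems (N ≤ d with no ridge).

## Known limitations

- The nearest-centroid species classifier is a transparent stand-in; it is
  not a language model and its accuracies are not comparable to fine-tuned
  model accuracies on real corpora.
- The neighborhood protocol materializes the full N×N distance matrix;
  fine for N up to a few tens of thousands, not for millions of rows.
- Only the standard genetic code is bundled; alternative codes must be
  supplied explicitly.
- The fitness-weighting formula is one reading of under-specified
  selection-pipeline conventions (see above) and is injectable for that
  reason.
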