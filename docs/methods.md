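# Methods

`tetrabin` bins assembled metagenomic contigs by clustering a fused feature
representation: a learned, context-aware embedding of each contig produced by
a span-masked language model over 4-mer tokens, concatenated with a compact,
non-negative decomposition of the contig's canonical tetranucleotide
frequencies. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic test bed does and does not show.

## Signal model and assumptions

Contigs from the same genome share oligonucleotide usage ("genomic
signature"), and double-strandedness makes a 4-mer and its reverse complement
the same observation. The method assumes this compositional signal (plus
whatever longer-range sequence regularities the language model can pick up)
suffices to group contigs by source genome. Abundance/coverage information is
deliberately not used. Contigs shorter than 2000 bp are discarded before any
processing (`min_length`, configurable): below that, 4-mer statistics are too
noisy to support binning.

## Contig embedding branch

**Tokenization.** A stride-1 sliding window turns a contig of L bases into
L−3 overlapping 4-mer tokens (`ATTCGA` → `ATTC, TTCG, TCGA`). The vocabulary
is fixed and deterministic: the 256 4-mers in lexicographic order followed by
`[CLS] [SEP] [PAD] [MASK] [UNK]`, 261 entries in all. Any window touching an
ambiguous base (normalized to `N` on input) maps to `[UNK]`; this preserves
positional continuity instead of silently deleting tokens. Token streams are
packed into consecutive, non-overlapping segments of 510 content tokens,
wrapped as `[CLS] … [SEP]` and right-padded with `[PAD]` to a fixed model
length of 512.

**Span masking.** Because adjacent 4-mers overlap in 3 bases, masking a
single token leaves it trivially recoverable from its neighbours; spans are
masked instead. Per segment, span centers are drawn uniformly without
replacement from content positions (never `[UNK]`), each span's length is
drawn uniformly from the multi-scale set {1, 2, 4}, centered and clipped to
the content region; candidates overlapping an accepted span are rejected.
Drawing stops as soon as covered tokens reach 15% of the content length, so
the realized budget can overshoot by at most one span (empirically ≈15.3%
mean coverage on full segments). Each span is then processed 80% of the time
by replacement with `[MASK]`, 10% by replacement with uniformly random
4-mers, and 10% left unchanged; cross-entropy loss is computed at all
in-span positions against the original ids. Budget accounting is by tokens,
span-wise branching, first-reach stopping — choices that had to be fixed
where the procedure is underdetermined.

**Encoder.** A BERT-style bidirectional transformer (learned token +
absolute position embeddings summed, multi-head self-attention with padding
masks, GELU feed-forward blocks, post-residual LayerNorm) implemented in
NumPy with hand-derived backpropagation, trained with AdamW (decoupled weight
decay 0.01, constant learning rate 2 × 10⁻⁵ by default, optional linear
warmup) and no next-sentence objective. The default geometry is deliberately
small — 2 layers, width 64, 2 heads — because the mechanism, not the scale,
is what the package implements and tests; BERT-base geometry is reachable
purely through `MLMConfig`. Every parameter's gradient is validated against
central finite differences in the test suite.

**Pooling and reduction.** A contig's vector is the unweighted mean of its
segments' final-layer `[CLS]` vectors (a heavily padded final segment counts
equally; pooling is permutation-invariant). The N × hidden matrix is reduced
to c = 24 dimensions with UMAP (n_neighbors 15, min_dist 0.1, Euclidean,
fixed seed). Note that UMAP's layout optimization does not map duplicate
input rows to bitwise-identical outputs — duplicates land close together,
which is what the tests assert.

## Decomposed tetranucleotide frequency branch

Collapsing the 256 4-mers by reverse-complement identity leaves 136 classes
(16 palindromic singletons + 120 pairs); the representative is the
lexicographically smaller member and columns are sorted. Counting is done on
the original strand only — canonical collapse already makes rows strand
invariant — with N-containing windows skipped, and each row is divided by
its own sum, so rows are comparable across contig lengths.

The transposed matrix V = Tᵀ (136 × n) is factored as V ≈ WH by Euclidean
multiplicative updates at rank s = 10 (default), initialized with NNDSVD.
Numerical choices: denominators carry a 1e-10 stabilizer; NNDSVD's exact
zeros are floored at 1e-6 × mean(V) because a multiplicative update can
never move an entry off exact zero, which otherwise locks the iteration into
the initial sparsity pattern and blocks convergence on exactly low-rank
inputs; iteration stops at `max_iter` (200) or when the relative objective
decrease falls below 1e-4. The per-contig feature block is Hᵀ (n × s). A
`rank_scan` utility reports relative reconstruction error over candidate
ranks; the default s = 10 sits in the flat region of that curve for
TNF-like inputs.

## Feature fusion and clustering

The reduced embedding block (first) and the NMF coefficient block are
concatenated into an N × (c+s) matrix — N × 34 under defaults. Single-feature
modes (`TNF`, `Dec_TNF`, `embedding`) pass the corresponding block through
unchanged for ablation comparisons.

DBSCAN's two parameters are chosen from the data:

* **Eps** — for every point, the distance to its k-th nearest neighbour
  (default k = 15, the median of the MinPts grid, matching the usual
  k ≈ MinPts heuristic) is found with an in-package random-projection-tree
  forest (15 trees, Euclidean metric; hyperplanes equidistant from two
  random points; margin-ordered descent with a candidate budget, default
  `n_trees × k × 50`, exact when the budget reaches n). The sorted curve's
  knee is detected Kneedle-style: normalize both axes to [0, 1] and take the
  point with maximum vertical distance to the chord joining the endpoints.
  A constant curve has no knee and raises; a manual `eps` bypasses
  detection. This automates what is otherwise a human read of the plotted
  curve, so a rendered curve remains available for inspection.
* **MinPts** — grid search over {5, 10, 15, 20, 25}: each candidate is
  clustered with DBSCAN (neighbourhoods from the same index) and scored by
  the mean silhouette of non-noise points **minus the noise fraction**;
  candidates with fewer than 2 clusters or more than 90% noise are invalid,
  and ties go to the smallest MinPts. The noise penalty matters: bare
  silhouette improves monotonically as cluster fringes are discarded into
  noise, so without it the search drifts to the largest MinPts and throws
  away up to ~10% of points on clean data.

The DBSCAN expansion itself follows the standard density-reachability
semantics (a point counts in its own neighbourhood) and is verified
label-for-label against scikit-learn's implementation under exhaustive
neighbourhood search. Noise is always label −1 and never mixed with cluster
ids.

## Evaluation

Contig level: each bin is matched to the genome contributing the plurality
of its contigs (ties broken lexicographically), then P = TP/(TP+FP),
R = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN) per bin, with both macro (mean over
bins) and micro (pooled counts) summaries reported, since either averaging
convention is defensible. Noise contigs are unassigned and count as FN for
their genome.

Base-pair level: for each (genome, bin) pair, bp-recall is the overlapping
base pairs over the genome size and bp-precision over the bin size; a genome
counts as recovered at recall threshold r if some bin reaches bp-recall ≥ r
with bp-precision ≥ 0.95 (the near-complete convention is recall 0.9,
precision 0.95). By default genome size means the summed length of the
genome's evaluated contigs — the base pairs a binner could possibly recover —
with the true genome sizes available as an option. If the truth provides
genome → species/genus labels, genomes sharing a label can be merged before
counting, giving coarser taxonomic-level tables.

## Synthetic communities

Each genome is an order-2 Markov chain over {A,C,G,T} whose 16 context rows
are drawn from Dirichlet(α); α (default 0.1) controls how divergent the
genomes' 4-mer spectra are, and the generator's difficulty ordering is itself
tested (higher divergence → higher reference-clusterer ARI, on average over
seeds). Defaults: 3 genomes of 80–120 kbp, 50 contigs each (150 total),
log-normal contig lengths (median 3000 bp, σ_log 0.4, floor 2000 bp),
substitution noise 0.5% — a desk-scale community with unambiguous
compositional structure. Substitutions only, no indels: coordinates stay
trivial and indels add nothing for composition-based binning. What passing
tests on this bed demonstrate is that the pipeline recovers compositional
structure end to end; they say nothing about repeats, strain mixtures,
uneven coverage, or assembly chimerism in real data.

## Problem sizes and determinism

The default pipeline profile trains the tiny encoder for 2 epochs on at most
512 segments (subsampled reproducibly when the corpus is larger) with batch
size 16 — about 3–4 minutes end to end for a 150-contig community on one CPU
core, which is the scale the test suite and the reproduction script
exercise. All randomness (simulation, masking, training order, UMAP, tree
construction) derives from explicit seeds; reruns from a cached checkpoint
reproduce identical bins and artifact hashes.

## Known limitations

* No abundance features; single-sample composition only, by design.
* The desk-scale encoder is far below BERT-base capacity; with 2 epochs on
  small corpora its embeddings carry mostly compositional (not long-range
  semantic) information.
* Knee detection assumes one dominant inflection in the k-distance curve;
  pathological curves (constant, multi-knee) need the manual `eps` override.
* NMF multiplicative updates converge slowly near the optimum; the defaults
  target feature extraction, not high-precision factorization (tests that
  require near-exact recovery raise `max_iter` accordingly).
* The RP-forest index is exact only when the candidate budget reaches the
  point count; production-size inputs trade accuracy for speed exactly as
  the budget dictates.
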