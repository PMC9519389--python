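# Methods

`nlrmotifs` re-creates, end to end and on synthetic data, a per-residue
machine-learning pipeline for annotating the conserved sequence motifs of
plant NLR immune receptors (nucleotide-binding, leucine-rich-repeat
receptors), together with the post-processing rules that turn raw per-residue
probabilities into motif calls, domain layouts and receptor classes, and the
downstream unsupervised analyses of motif variability. This note documents
the models, the parameters that matter, the synthetic data the package tests
itself on, and the numerical choices made where the design was open.

## The prediction model

### Motif registry

Seventeen motif classes are defined: the extended EDVID motif of the CC
domain alpha3 helix (consensus `RDbbbDbEDbbD`, L=12), six TIR structural
elements (betaA, alphaA, betaC, alphaC, betaD-alphaD1, alphaD3), nine NBS
(NB-ARC) motifs in fixed canonical order (VG < P-loop < RNBS-A < Walker-B <
RNBS-B < RNBS-C < GLPL < RNBS-D < MHD) and the LxxLxL repeat-start motif of
the LRR domain. Consensus strings use `b` for the hydrophobic class
{A,V,L,I,M,F,W,Y,C} and `x` for any residue.

Where the literature prints a consensus (EDVID, P-loop `GbGGbGKTT`, Walker-B
`KRFbbbbDDbW`, RNBS-B `KbbbTTR`, RNBS-C `LxxxExWxLF`, RNBS-D `CFbYCxLFP`,
the `bbVG` frame, `LxxLxL`) it is used verbatim. The TIR elements and RNBS-A
have no published consensus string; the registry ships synthetic defaults
anchored on the conserved positions that are described for them (the
catalytic Glu and neighbouring Cys at alphaC positions 1 and 4, Phe/Pro at
betaD-alphaD1 positions 4 and 9, Phe@0 and Trp@5 for RNBS-A). All lengths
and consensi are overridable through `default_registry(overrides=...)`; a
model archive records the length it was trained for and refuses to run
against a conflicting registry.

### Per-residue features

For a query sequence, each residue i is described by the negative natural
log of the match-emission probabilities to the 20 amino acids, for two
successive iterations of a profile search of the query against a small
focused database — a 2x20 block per residue. The reference search engine is
an internal iterative PSSM search:

1. **Iteration 1** finds gapless local alignments of the query against every
   database sequence, seeded by exact 4-mer matches and extended to the
   maximum-scoring segment on each diagonal under BLOSUM62 scoring. The
   score threshold is derived from the requested E-value cutoff (default
   1e-5) via ungapped Karlin–Altschul statistics.
2. Aligned residues are collected into query-anchored columns. Emissions are
   Henikoff-weighted residue frequencies mixed with substitution-profile
   pseudocounts (mass 1 relative to the observed count mass; the pseudocount
   profile is the observed column frequency vector pushed through the
   BLOSUM62 conditional substitution matrix).
3. **Iteration 2** repeats the search with the iteration-1 position-specific
   scoring matrix (log-odds against the background) and rebuilds emissions
   from the new hit set.

The query sequence is always a row of its own profile, as in iterative HMM
search where the first model is seeded from the query. Consequently a query
with no homologs in the database still yields informative features — its own
substitution profile — rather than a constant background block. The
`include_query=False` switch restores pure hit-based profiles (background
fill at uncovered positions). Probabilities are floored at 1e-9 before the
log; background frequencies are the BLOSUM62 marginals.

An optional second engine (`engine="pyhmmer"`) performs iteration 1 with
phmmer and iteration 2 with a query-anchored profile HMM (hand architecture,
one match state per query position) searched by hmmsearch; its alignments
feed the same emission machinery, so the engines are exchangeable and are
cross-checked against each other in the tests.

### Windows and classifiers

A candidate start at position p for a motif of length L is described by the
concatenated feature blocks of positions [p-5, p+L+5), i.e.
20 x 2 x (5 + L + 5) = 40(L+10) features (640 for LxxLxL, 880 for EDVID).
Out-of-sequence positions are padded with the background block, so every
residue of every sequence is scoreable. Feature order is fixed
(position-major, then iteration, then alphabetical amino acid) and stamped
into model archives.

Each motif has its own binary classifier, a multilayer perceptron with
hidden layers (250, 125, 100), ReLU activations, Adam at a constant learning
rate of 0.001, and L2 penalty (default alpha 1e-4, per-motif configurable).
The classifier standardizes its input features internally (mean/std learned
during fit, stored on the estimator): the raw -ln-emission features are
all-positive with heterogeneous scales, and without standardization Adam
intermittently stalls in an all-negative-class plateau on rare-positive data
(~1 positive per 250 windows). Training stops when the training loss stops
improving by more than 1e-5 for 10 consecutive epochs (cap 500 epochs).
sklearn's built-in validation early stopping monitors *accuracy*, which is
uninformative at this prevalence, so loss-based stopping is used instead.
Negative examples are all non-start positions of the training sequences; no
resampling or class weighting is applied.

### Evaluation protocol

Sequences are split into five equal groups (deterministic given a seed).
Groups 1–4 serve a fourfold cross-validation; the final model is refit on
all four and the fifth group is touched exactly once for the test report.
Metrics are position-level: precision, recall, specificity,
F1, and G = sqrt(precision x recall) (a `g_mode` switch provides the
sqrt(recall x specificity) variant; the default is preferred because the
alternative is degenerate under extreme class imbalance, where specificity
is ~1 regardless of model quality). Evaluation scores exact positions by
default; a tolerance of +-k residues is configurable for border-ambiguity
studies.

## Post-processing rules

* **Calling:** one call per local probability maximum strictly above 0.80
  (plateaus call their leftmost position).
* **Satellites:** competing same-motif calls closer than 15 residues are
  resolved when their probabilities differ by more than 20 percentage points
  (keep the stronger); otherwise both survive, flagged ambiguous. The
  conservative keep-and-flag branch for small differences is our choice; the
  resolution rule only specifies the >20% case.
* **NBS layout:** valid iff all nine NBS motifs occur exactly once with
  strictly increasing starts in canonical order; violations carry
  machine-readable reasons (`missing:X`, `duplicated:X`, `disordered:X|Y`).
* **LRR ladders:** accepted iff the first LxxLxL start lies less than 50 aa
  downstream of the MHD end (motif end = start + L), consecutive starts are
  15–50 aa apart, and at least 9 repeats are present (5 in CNL-oriented
  analyses). The last repeat is open-ended.
* **Classes:** TNL = all six TIR motifs in order upstream of a valid NBS;
  CNL = extended-EDVID upstream of a valid NBS; NL = valid NBS without
  either; everything else `other`. TIR takes precedence over CC when both
  fire (flagged). An EDVID call downstream of the NBS flags a shuffled
  layout. RPW8-type (RNL) receptors have no trained detector and are not
  auto-classified — a documented limitation.

## Motif analytics

Chimeras concatenate each motif of an analysis complement (9 NBS; 6 TIR + 9
NBS; or EDVID + 9 NBS + first five LxxLxL) with 5 flanking residues per
side, 'X'-padded at sequence borders. Because chimeras of one layout have
equal length, pairwise identity is exact ungapped matching, and clustering
is connected components over the >=threshold identity graph. Column
conservation is relative entropy (bits) against the BLOSUM62 background;
logo matrices scale per-column frequencies by that relative entropy.

LRR motifs embed into 18 dimensions: Kyte–Doolittle hydropathy, formal
charge (K/R +1, D/E -1, H +0.1) and Zamyatnin residue volume for each of
the six frame positions, z-scored across the dataset (all three scales are
swappable). Clustering uses OPTICS with Xi extraction (defaults
min_samples=20, xi=0.05) under the Euclidean (Minkowski-2) metric.
Ladder-position distributions report, per cluster, the percentage of motifs
at each 1-based position of the repeat ladder, columns normalized to 100%.

## Coevolution analysis

Mutual information between alignment columns is computed from
Henikoff-weighted joint counts (gaps and 'X' excluded, weights rescaled so
one row carries one count). Profile pseudocounts are mixed in with mass
`m * Ki * Kj` for the joint of columns i and j, where Ki and Kj are the
numbers of distinct residues observed in the columns and m defaults to 1.
Scaling the mass with the observed cardinalities is deliberate: the
finite-sample MI inflation of a column pair grows as (Ki-1)(Kj-1)/2N, so
sparse high-cardinality joints (the noise) are shrunk strongly toward the
product profile while concentrated low-cardinality signals are essentially
untouched. Pair significance is a Z-score against the empirical
off-diagonal MI distribution, cut at Z >= 3.5 (boundary inclusive).
Cumulative MI sums a column's significant MI; proximity MI averages
cumulative MI over a column's 3D-contact neighbours when a contact table
(plain TSV of i, j, distance; 5 Å default cutoff) is supplied. No APC
correction and no Potts/DCA modelling — by design.

## Synthetic data: what it emulates, and what it does not

All tests and benchmarks run on generated data with exact ground truth.

* **Motif training sets** plant one consensus-conforming window per
  background sequence (background = BLOSUM62 marginals) at a uniform random
  position. Hydrophobic `b` positions are sampled from {L,I,V,M,F}; LRR
  repeats sample leucine with probability 0.7. Noise `mu` perturbs each
  non-anchor position independently and *class-preservingly*: a `b` position
  is redrawn uniformly from the nine hydrophobics, an `x` position from the
  background. Fixed anchors never change, so every labeled motif matches its
  consensus at any mu — as in curated motif sets, which only contain
  delineated, conforming motifs. What mu erodes is the learnable statistical
  bias at non-anchor positions.
* **Synthetic NLRs** concatenate an N-terminal region (EDVID for CNL, the
  six TIR motifs in order for TNL, padding for NL), the nine NBS motifs with
  15–35 aa spacers, a <50 aa linker, and an LRR ladder of 9–14 repeats
  (15–50 aa each). Repeats carry the canonical extended context
  `LxxLxLxx[N/T/S]xL` beyond the 6-mer; optional satellite decoys place a
  second conforming 6-mer 6–14 aa into a repeat at a configurable rate.
* **Focused databases** (default 150 NLR-like sequences >=500 aa plus 100
  LRR-only sequences >=200 aa) are noisy copies (20% per-residue mutation)
  of a small set of archetypes, giving profile searches real families to
  find.
* **Planted LRR classes** for clustering tests put one charged residue at
  one exposed position (K@1, D@4, E@2, R@1, K@4, R@2) on an otherwise fixed
  template; sigma is the per-window probability of one random residue
  jitter.
* **Covarying alignments** plant one binary covarying column pair (coupling
  c in [0,1]) in an otherwise i.i.d. background alignment.

What the generators do **not** emulate: real phylogenetic correlation
between sequences, taxonomic composition, domain-length distributions of
real NLR families, insertion/deletion variation inside motifs, and
integrated decoy domains. Passing benchmarks on this synthetic data
therefore demonstrates that the pipeline's machinery — features, training
protocol, rules, analytics — works and is internally consistent; it does
not certify accuracy on real proteomes.

## Benchmark problem sizes

The self-contained benchmark script (`scripts/acceptance.py`) trains on
scaled-down editions of the synthetic benchmarks so a full run fits a single
CPU: 240 sequences for the EDVID (length 300, mu 0.15) and P-loop (length
400, mu 0.10) benchmarks, 120 sequences per TIR motif (length 250, mu 0.05),
and 160 NL proteins for the LxxLxL benchmark (9–14 repeats of 15–40 aa, mu
0.15, satellite rate 0.2). The focused database keeps its full default size
(150 + 100). The benchmark script skips the four diagnostic CV fold fits
(the final model and held-out metric are unchanged by them) and caps
training at 150 epochs, which the loss-plateau rule undercuts in practice.

## Known limitations

* The internal PSSM engine is gapless; diverged homologs with indels
  fragment into multiple anchor segments rather than one gapped alignment.
* Per-motif L2 alphas are exposed but default to a single value (1e-4); no
  hyperparameter search is bundled.
* Identity clustering is exact-layout only; free-length inputs require an
  external clustering tool.
* The MI Z-null is the empirical off-diagonal distribution; column-shuffle
  permutation nulls are not implemented.
* RNL receptors are not auto-classified (no RPW8 motif model).
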