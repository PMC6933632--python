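# Methods

## The problem and the model

Topologically associating domains (TADs) partition interphase chromatin into
self-interacting blocks; the bins separating adjacent TADs — TAD boundaries —
are enriched for the insulator protein CTCF and carry characteristic histone
modification patterns. `tadbound` frames boundary detection as binary
classification: given a genomic bin, decide from locally aggregated chromatin
signals and the bin's DNA sequence whether it is a TAD boundary.

A locus is represented by its **context window**: the bin-grid bin containing
its midpoint plus `bin_number` bins on each side, spanning

```
len(region) = bin_size * (2 * bin_number + 1)
```

bases (840 kb at the default `bin_size = 40 kb`, `bin_number = 10`). For each
of the nine marks (CTCF, H3K4me1, H3K4me2, H3K4me3, H3K9ac, H3K9me3,
H3K27ac, H3K27me3, H3K36me3, in this fixed order) the per-bin mean coverage
is computed, giving a `9 * (2*bin_number + 1)` signal vector (189 / 153 / 117
features at bin_number 10 / 8 / 6). Optionally the center bin's sequence
contributes all 4^k k-mer frequencies (64 features at k = 3), appended after
the signal block in lexicographic word order.

Negatives are not arbitrary background: for each boundary one non-boundary
bin is drawn at random whose Hi-C interaction frequency matches the
boundary's, removing contact intensity as a confounder. The design is always
balanced (one negative per boundary).

Two classifiers are fitted to the resulting design matrix:

* a **random forest** (500 trees, sqrt(M) features per split, otherwise
  library defaults), whose Gini importances are reshaped to a marks-by-bins
  table to localise which context bins carry the discriminative signal;
* a **multilayer perceptron** with four hidden layers —
  512 identity units (dropout 0.6975), 256 softplus units (input batch-norm,
  dropout 0.5153), 512 identity units (input batch-norm, dropout 0.4252),
  1024 hard-sigmoid units — and a single sigmoid output neuron computing
  `S(x) = 1 / (1 + exp(-x))`; a probability above the 0.5 threshold calls a
  boundary.

Performance is estimated by stratified k-fold cross-validation (default 10
folds), reporting AUC, AUPR, accuracy and F-score on held-out predictions.

## Conventions and numerical choices

* **Coordinates** are 0-based half-open everywhere; BED input needs no
  shifting. Chromosome names are matched exactly (no `chr` normalisation).
* **Missing signal** defaults to 0.0: uncovered bases contribute zero to bin
  means, the usual coverage-track semantics. The policy is configurable per
  track.
* **Center-bin rule**: the center bin of a locus is the genome-grid bin
  (`[i*bin_size, (i+1)*bin_size)`) containing the locus midpoint
  (`(start+end)//2`).
* **Edge handling**: a locus whose context window exits the chromosome is
  dropped with a logged warning, not zero-padded — padding would fabricate
  context signal. Negative sampling can exclude near-edge candidates up
  front so the balanced design survives extraction.
* **k-mer denominator** is always `m - k + 1` for a length-`m` bin, even when
  windows containing `N` are skipped; frequencies therefore sum to exactly 1
  only for N-free sequences. Counting is forward-strand only, without
  reverse-complement collapsing, matching the lexicographic 4^k feature
  layout. k is supported in 1..5.
* **z-scoring by factor** (used for the similarity diagnostic) standardises
  each sample's per-mark block to mean 0, sd 1 using the sample standard
  deviation (ddof = 1); zero-variance blocks map to zeros. Classifiers
  consume raw bin means by default — the z-scored variant exists for
  diagnostics and experimentation.
* **Negative matching** interprets "similar interaction frequency" as a
  greedy, seeded, without-replacement draw among candidate bins whose
  frequency differs from the boundary's by at most a tolerance (default 10%
  relative; absolute mode available), processed in a random boundary order.
  Sampled negatives must additionally lie at least one `bin_size` (the
  default exclusion margin) from every boundary. An unmatched boundary is an
  error naming the locus, so the caller can widen the tolerance explicitly.
* **Similarity diagnostic**: cosine similarity of per-mark z-scored blocks on
  randomly sampled pairs (default 2000 per class; half of the intra pairs
  from each class) rather than all O(n^2) pairs; intra vs inter distributions
  are compared per mark with a two-sided Wilcoxon rank-sum test (exact below
  50 samples per group, normal approximation otherwise). Both per-mark and
  pooled (all marks concatenated) outputs are reported.
* **MLP training**: binary cross-entropy minimised by back-propagation with
  Adam (learning rate 1e-3), default 100 epochs and batch size 32, Glorot
  initialisation from the model seed. Batch normalisation applies to a
  layer's *input* (as the architecture table specifies), using batch
  statistics during training and running averages (momentum 0.9) at
  inference; dropout is inverted and disabled at inference, so predictions
  are deterministic. "Identity" hidden layers are taken at face value; the
  hard-sigmoid is the piecewise-linear `clip(0.2x + 0.5, 0, 1)`. A
  non-finite training loss raises a divergence error suggesting a smaller
  learning rate.
* **Cross-validation folds** default to 10 (the headline protocol); 5-fold
  is exposed as well since both protocols are in circulation for this task.
  All randomness — fold shuffling, forest bootstraps, MLP initialisation and
  dropout, negative sampling — descends from explicit integer seeds.

## The synthetic data generator

`tadbound.simulate` produces download-free datasets exhibiting exactly the
structure the classifier assumes, and nothing more:

* per-mark **context shapes** around planted boundaries — enrichment peaking
  at the center bin (`center_peak`: CTCF, H3K4me2/3, H3K9ac, H3K27ac,
  H3K36me3), depletion at the center (`center_depletion`: H3K9me3), flanking
  enrichment dipping at the center (`flanking_peak`: H3K4me1, H3K27me3), or
  an effect confined to the center bin (`center_delta`, used to test
  importance localisation). Shapes ride on a baseline of 1.0 with Gaussian
  noise (sd 1.0 by default), clipped at zero as coverage must be;
* **boundary placement** on the bin grid with at least two context-window
  lengths of separation, so windows never overlap;
* **contact frequencies** drawn i.i.d. uniform on [5, 15] for boundary and
  background bins alike, so frequency matching is always feasible and the
  contact table carries no class information;
* **sequence**: i.i.d. bases at 41% GC, with several copies (default 8) of a
  CTCF-core consensus motif (degenerate positions resolved to A) planted
  across each boundary center bin with probability 0.9 — emulating the
  clustering of insulator binding sites at real boundaries, which is what
  makes k-mer features informative at the reduced bin size.

Defaults are desk-scale: 2 chromosomes, 2 kb bins, 5 flanking bins, 24
boundaries, effect size 3.0. The named benchmark conditions in
`tadbound.benchmarks` (strong / null / weak / center_delta) fix the sample
sizes used throughout the tests and the acceptance script: 60 boundaries
(120 design rows) for the strong, weak and center-delta conditions, 150
boundaries (300 rows) for the null, where a stable chance-level estimate
needs more data. The random forest is evaluated with 10-fold
cross-validation; the MLP with 5-fold and 60 epochs, trading a little fold
granularity for the slower back-end.

What the generator does **not** emulate: spatially correlated noise,
mappability and GC biases, ChIP efficiency differences between marks,
distance-dependent Hi-C contact decay, boundary-strength heterogeneity, and
genuine motif grammar (only exact-copy planting). Passing tests on these
fixtures therefore demonstrate that the pipeline recovers planted structure
of the assumed form — they do not certify real-data accuracy, which depends
on the quality of the input tracks and boundary calls.

## Design choices that were genuinely open

* The bigWig dialect is supported behind a flag, but bedGraph is the
  reference track format so the whole test surface runs on plain text.
* The interaction-frequency table is a plain 4-column TSV
  (chrom, start, end, frequency): no standard carrier exists for this
  artifact, and TSV keeps it inspectable.
* Matching tolerance has no published value; 10% relative is the default and
  it is a required, visible knob rather than a hidden constant.
* The MLP is implemented directly in numpy (dense layers, batch norm,
  dropout, Adam); the architecture is small enough that a hand-rolled
  implementation is simpler to audit than a framework dependency, and its
  forward pass is verified against an independent per-neuron oracle in the
  tests.
* `BoundaryModel.fit()` returns a `BoundaryResults` object (estimates,
  per-fold metric dispersion, importances, `summary()`), following the
  model/results convention of statistical modelling libraries.

## Known limitations

* Real-data benchmarks (ENCODE/Roadmap tracks, published boundary calls)
  are out of scope; no downloading or liftover is performed.
* Motif *discovery* at boundaries is not implemented; the generator only
  plants a known motif.
* Greedy matching does not globally optimise the frequency pairing; with a
  tight tolerance and few candidates it can fail where an optimal assignment
  would succeed (the error message says which boundary was unmatched).
* The MLP implementation is single-threaded numpy; it is adequate for
  thousands of samples, not millions.
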