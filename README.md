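# tadbound

Classify genomic loci as **TAD boundary vs non-boundary** from the chromatin
context: per-bin CTCF and histone-mark coverage around each locus, plus
k-mer frequencies of the center-bin DNA sequence. For people working on 3D
genome organisation who have boundary calls, signal tracks and a genome, but
no appetite for new Hi-C experiments.

## The model

A locus is reduced to the bin-grid bin containing its midpoint and described
by its context window of `2 * bin_number + 1` bins,

```
len(region) = bin_size * (2 * bin_number + 1)        # 840 kb at 40 kb x 10
```

For nine marks (CTCF, H3K4me1, H3K4me2, H3K4me3, H3K9ac, H3K9me3, H3K27ac,
H3K27me3, H3K36me3) the mean coverage per bin gives a
`9 * (2*bin_number+1)`-dimensional signal vector (189 at the default
geometry); the center bin's sequence optionally adds all 4^k k-mer
frequencies (64 at k = 3), each word counted over `m - k + 1` sliding
windows. Negatives are sampled one-per-boundary from bins with a matching
Hi-C interaction frequency, so contact intensity cannot drive the
classifier. Two back-ends are provided: a 500-tree random forest (with
per-bin Gini importance maps) and a 6-layer MLP
(512 linear / 256 softplus / 512 linear / 1024 hard-sigmoid hidden units
with dropout and batch normalisation, sigmoid output), both evaluated by
stratified cross-validation with AUC, AUPR, accuracy and F-score. A
cosine-similarity diagnostic checks that same-class signal profiles look
more alike than cross-class ones (Wilcoxon rank-sum test per mark).

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Everything below runs on synthetic data generated by the package itself:

```python
import tadbound as tb

fx = tb.generate_fixture(tb.FixtureConfig(
    n_boundaries=60, n_chromosomes=2, chrom_length=1_500_000, seed=1))
matrix = tb.extract_features(
    fx.tracks, fx.boundaries, fx.contacts, fx.config.bin_config,
    genome=fx.genome, kmer=tb.KmerSpec(3))
results = tb.BoundaryModel(matrix, "rf").fit(folds=10, seed=0)
print(results.summary())
```

```
Boundary classification results
===============================================
backend: rf    folds: 10    seed: 0
samples: 120 (boundary 60, non-boundary 60)
features: 163
-----------------------------------------------
metric            mean        sd
auc             1.0000    0.0000
aupr            1.0000    0.0000
accuracy        1.0000    0.0000
f_score         1.0000    0.0000
===============================================
```

120 rows are the 60 planted boundaries plus 60 frequency-matched negatives;
163 features are 9 marks x 11 context bins plus 64 3-mer frequencies. At
this effect size (signal peak 3.0 vs noise sd 1.0) held-out AUC is 1.0 —
the classes are fully separable; at effect size 0 the same pipeline returns
chance-level AUC (~0.5). `results.bin_importance()` reshapes the forest's
Gini importances into a 9 x 11 marks-by-bins table;
`results.predict_table(matrix)` scores loci with probabilities and calls.

The same workflow is available from the shell:

```sh
tadbound make-fixture --out fx --n-boundaries 60 --chrom-length 1500000 --seed 1
tadbound extract --loci fx/boundaries.bed --contacts fx/contacts.tsv \
    --genome fx/genome.fasta --track CTCF=fx/CTCF.bedgraph \
    ... \
    --bin-size 2000 --bin-number 5 --kmer 3 --out matrix.tsv
tadbound train-eval --matrix matrix.tsv --model both --folds 10 --out run/
tadbound similarity --matrix matrix.tsv --out run/sim
tadbound predict --checkpoint run/rf.checkpoint.pkl --matrix matrix.tsv --out calls.tsv
```

Real inputs drop in the same way: BED boundary calls, bedGraph / fixed-step
WIG / bigWig coverage tracks, a FASTA genome and a 4-column TSV of per-bin
interaction frequencies.

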