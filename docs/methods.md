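# Methods

## Gaussian sequence representation

A protein sequence is tokenized into all overlapping subsequences of
length *l_s* (a length-*l* sequence yields *L = l − (l_s − 1)* tokens;
0-based, half-open offsets). Each token is mapped to a *d*-dimensional
embedding vector; tokens absent from the embedding table (for example
tokens containing the ambiguity letters B, J, O, U, X, Z) are skipped
and counted rather than zero-imputed, because a zero row would distort
the covariance estimate. A sequence must retain at least one embeddable
token.

The embedded tokens are modelled as i.i.d. draws from a multivariate
normal 𝒩(μ, Σ). The sequence is summarized by the maximum-likelihood
moments: the empirical mean and the empirical covariance with divisor
1/L. The 1/L divisor is deliberate — numeric libraries default to the
unbiased 1/(L−1) and the implementation does not use that default. A
single-token sequence is legal and has Σ̃ = 0.

The i.i.d. assumption is knowingly wrong for overlapping k-mers
(adjacent tokens share k−1 residues); the Gaussian is used only as a
summary statistic whose moments feed a similarity, never as a density.

## Similarity kernel

Sequence similarity is the convex combination

sim(sᵢ, sⱼ) = α·cos(μ̃ᵢ, μ̃ⱼ) + (1−α)·⟨Σ̃ᵢ, Σ̃ⱼ⟩_F / (‖Σ̃ᵢ‖_F ‖Σ̃ⱼ‖_F).

Both components are inner products of unit-normalized objects (vectors
in ℝᵈ, matrices in ℝ^{d²}), so each component Gram matrix — and any
convex combination — is positive semi-definite; the kernel is passed to
the SVM unclipped and unshifted. Degenerate inputs (zero mean vector,
zero covariance from single-token sequences) contribute similarity 0
instead of raising, keeping short sequences usable. α is accepted on
the closed interval [0, 1]: α = 1 is mean-cosine only, α = 0 is
covariance-similarity only, and the default α = 0.3 is the value at
which held-out micro-AUPR peaks. Square kernels are symmetrized as
(K + Kᵀ)/2 to remove floating-point asymmetry.

## Embedding tables

Tables load from the plain-text one-token-per-line convention (token
followed by d floats; an optional integer "vocab d" header is
tolerated). Training uses skip-gram with negative sampling implemented
directly in numpy (single-threaded, fully seeded, run-to-run
identical). Hyperparameters follow the word2vec lineage — window 5 (in
token units), 5 negative samples, min_count 1, 5 epochs, linear
learning-rate decay from 0.025 — and are all exposed in
`TrainingParams`. The default corpus construction feeds each sequence
as one overlapping-token stream; the classic shifted non-overlapping
construction (k phase-shifted streams per sequence) is available via
`corpus_style="shifted"`. This trainer is meant for desk-scale corpora
(thousands of tokens); it is not optimized for proteome-scale training.

## Classification and nested cross-validation

One binary SVM per binding mode consumes the shared precomputed kernel
(One-vs-Rest). A label column that is single-class in a training fold
cannot be fit and becomes a flagged constant predictor — necessary
because the rarest mode has 3 positives. Binary predictions use
sign(decision value); ranking metrics use the raw decision values.

Nested cross-validation: outer folds (default 10) estimate performance,
inner folds (default 10) drive a grid search over *l_s*, α and the SVM
C, scored on inner micro-AUPR with ties broken toward smaller C then
smaller *l_s* (simpler models). Folds are built by greedy iterative
multilabel stratification (rarest remaining label first, dealt to the
fold most deficient in it); partitions are pure functions of the seed.
Metrics per outer fold are aggregated as mean ± sd; pooled
outer-test predictions are also retained so binary classifiers can
report pooled accuracy, MCC and micro-AUPR. Folds in which a rare label
has no positives are tolerated by the pooled micro-level metrics. No
class weighting is applied by default.

Baselines (logistic regression, k-nearest neighbours, SVM with
standard kernels, random forest) use the mean of the feature matrix as
a d-vector representation and are tuned by grid search on their
conventional grids (LR: penalty {none, L1, L2, elastic-net} ×
regularization {100, 10, 1, 0.1, 0.01}; kNN: neighbours {1, 3, …, 21} ×
{uniform, distance} × {Euclidean, Manhattan, Minkowski}; SVM: kernel
{linear, polynomial, RBF, sigmoid} × C {50, 10, 1, 0.1, 0.01}; RF:
max-features {sqrt, log2} × trees {10, 100, 200, 500, 1000}), with the
subsequence length swept at the featurization layer.

## Metrics

Subset accuracy is the fraction of samples whose whole predicted label
set matches exactly; on one label it reduces to ordinary accuracy.
Micro-AUPR flattens the n×m truth and score arrays and integrates the
precision–recall curve by step-wise precision-at-recall-change
summation, with tied scores entering together. MCC follows the standard
four-count formula with the convention MCC = 0 when any denominator
factor is zero. Note that with this convention a degenerate
all-positive predictor scores 0 even when its accuracy is high — the
reason MCC is reported alongside accuracy for imbalanced test sets.

## Nucleosome occupancy

Reads are reduced to their 5′ anchor (for minus-strand reads, the
rightmost aligned base) and extended to 147 bp — one nucleosomal
footprint — in the 5′→3′ direction, clipped at position 0 and at
chromosome ends. Per-base fragment coverage is normalized by the
genome-wide mean (total fragment-base mass over total declared genome
length), making the genome average exactly 1. Profiles are the
positionwise mean of the normalized track over ±1000 bp windows at peak
centres (windows truncated by chromosome boundaries contribute only
their defined offsets, with per-offset denominators), then smoothed by
a 61-bp centered moving average whose window shrinks at array edges (no
padding). Smoothing is applied to the final averaged profile, not the
genome-wide track (a config choice; smoothing the track first and
averaging after would commute only approximately at boundaries).

Categorization compares the mean occupancy of the central ±150 bp
against the mean over |offset| ∈ [500, 1000]: central below 0.9× flank
is dip-at-centre, above 1.1× is peak-at-centre, otherwise questionable.
The ±150 bp halfwidth (one footprint), the [500, 1000] flank band and
the 10% band are this package's operational definition of the three
published profile shapes, whose exact decision rule was never specified;
all three are exposed as parameters. The E-MI (enriched-sequence
mutual information, lig147) end-preference rule is the strict threshold
E-MI < 20.

Peak centres from interval files use floor((start+end)/2), or
start + summit when a narrowPeak summit column is present and
non-negative. All coordinates are 0-based half-open; BAM/SAM input is
supported through pysam (only chromosome, 5′ position and strand are
used — no MAPQ or duplicate filtering, which the occupancy definition
does not include).

## Synthetic data

Generators are pure functions of `SimConfig` (one seeded generator per
invocation, no global state; fixed seed ⇒ byte-identical files).

* Proteomes: uniform residues over the 20 standard amino acids —
  deliberately ignoring real amino-acid composition, which the kernel
  does not depend on.
* Embedding tables: i.i.d. standard-normal vectors for the full 20^k
  vocabulary (k ≤ 3), or corpus-restricted beyond that.
* Labelled datasets: each label owns disjoint k-mer motifs whose
  vectors are shifted by `motif_signal_strength` (default 5, a strong
  planted signal) along a label-specific unit direction; positive
  sequences receive 8 motif insertions at random positions. Requested
  label prevalences are hit exactly and every sequence keeps ≥ 1 label
  (default prevalences decline geometrically and sum to 1.2 so
  coverage is feasible). Because the signal lives in the embedding
  vectors, motif presence shifts both μ̃ and Σ̃, so both kernel
  components are informative.
* MNase read sets: 147-bp footprints at uniform density emitted as
  36-bp reads anchored at either footprint end (so 5′→3′ extension
  reconstructs the footprint exactly); at dip centres footprints
  overlapping the central ±150 bp are thinned by `dip_depth`, at peak
  centres the same window is enriched by the matching factor. The
  default background density of 2000 reads/kb (2 footprint starts per
  bp, comparable to deep merged MNase libraries) keeps per-base
  coverage noise in the central window well below the 10% decision
  band, so individual planted centres are recoverable; at sparser
  densities, reliable categorization requires averaging over many peak
  centres, exactly as with real ChIP peak sets.

Passing tests on these fixtures demonstrates correctness of the
machinery (estimators, kernel geometry, CV hygiene, signal recovery,
coordinate arithmetic), not real-data performance: real TF datasets are
smaller per label, far noisier, and their embedding signal is learned
rather than planted.

## Numerical and design choices

* Covariances are symmetrized as (A + Aᵀ)/2; PSD checks use the
  tolerance min-eigenvalue ≥ −1e−8 × scale.
* Gaussian representations persist losslessly to .npz containers;
  kernel matrices export as tab-delimited text with id headers.
* Duplicate FASTA records collapse on (id, residues); records sharing
  an id with different residues are all kept under suffixed ids
  ("id.1", "id.2") so no distinct sequence is silently dropped.
* Sequences shorter than *l_s* fail loudly at featurization rather
  than being silently removed, keeping dataset bookkeeping explicit.
* Problem sizes in the test-suite and acceptance script (40–120
  synthetic sequences, d = 10–20, 5–10 outer folds, 20 occupancy
  centres) were chosen as the smallest sizes at which the planted
  effects are unambiguous.

## Known limitations

* The skip-gram trainer is desk-scale; proteome-scale embedding
  training would need an optimized implementation.
* The inner-CV grid for α and C is configurable but defaults to a
  small set; the published optimum α = 0.3 is the package default.
* The dip/peak/questionable rule is an operational reconstruction (see
  above) and its thresholds are conventions, not fitted values.
* Published baseline MCC/accuracy figures for the occupancy test set
  are mutually inconsistent with their printed confusion matrices for
  every method except the kernel classifier; the metrics here follow
  the MCC formula exactly and make no attempt to reproduce those rows.
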