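# protgauss

Predicting how transcription factors (TFs) engage nucleosomes — end
binding, periodic binding, groove binding, dyad binding, gyre spanning,
orientational binding, and nucleosome (de)stabilization — directly from
their amino-acid sequences. Measuring these interaction modes
experimentally is expensive, the modes are not mutually exclusive, and
the available annotations are extremely imbalanced (a mode may have 3
positives among 167 TFs), so the problem is cast as multi-label
classification with ranking-based evaluation.

`protgauss` implements a Gaussian sequence representation with a
similarity kernel:

1. A protein of length *l* is split into *L = l − (l_s − 1)* overlapping
   subsequences of length *l_s* ("biological words", default *l_s* = 4).
2. Each word is embedded by a skip-gram word-embedding table into
   **x** ∈ ℝᵈ (default *d* = 100), giving a feature matrix *X* ∈ ℝ^{L×d}.
3. The rows of *X* are modelled as i.i.d. draws from 𝒩(μ, Σ); the
   sequence is summarized by the maximum-likelihood estimates
   μ̃ = (1/L) Σᵢ xᵢ and Σ̃ = (1/L) Σᵢ (xᵢ − μ̃)(xᵢ − μ̃)ᵀ (divisor 1/L,
   not 1/(L−1)).
4. Two sequences are compared by a convex combination of the cosine of
   their means and a normalized Frobenius inner product of their
   covariances:

   sim(sᵢ, sⱼ) = α·(μ̃ᵢ·μ̃ⱼ)/(‖μ̃ᵢ‖‖μ̃ⱼ‖) + (1−α)·⟨Σ̃ᵢ, Σ̃ⱼ⟩_F/(‖Σ̃ᵢ‖_F‖Σ̃ⱼ‖_F)

   with α ∈ [0, 1] (default 0.3). The resulting matrix is positive
   semi-definite and is fed to a One-vs-Rest SVM as a precomputed
   kernel.
5. Hyperparameters (*l_s*, α, C) are tuned by nested cross-validation
   (10 outer / 10 inner folds, multilabel-stratified), scored on
   micro-averaged AUPR; subset accuracy and MCC are also reported.

An independent validation pipeline computes nucleosome occupancy around
TF binding sites: MNase-seq reads are extended to 147 bp (the
nucleosomal footprint) in the 5′→3′ direction, piled up, normalized by
the genome-wide mean, averaged over ±1000 bp windows around ChIP-seq
peak centres, smoothed with a 61-bp moving average, and categorized as
dip-at-centre / peak-at-centre / questionable. TFs that prefer
nucleosome ends (E-MI penetration < 20) tend to show the dip-at-centre
shape.

A seeded synthetic-data module (`protgauss.simulate`) generates random
proteomes, embedding tables, planted-motif multi-label datasets, and
MNase-like read sets with planted occupancy shapes, so the entire
pipeline is testable without external downloads.

## Worked example

Generate a planted 40-sequence, 3-mode dataset and train the kernel SVM
with nested cross-validation:

```sh
protgauss simulate --kind labeled --seed 3 --n-sequences 40 --out sim
# wrote 40 sequences, 8000 vectors, 3 labels to sim

protgauss train --fasta sim/sequences.fasta --labels sim/labels.tsv \
    --embeddings sim/embeddings.txt --outer-folds 5 --inner-folds 3 \
    --alpha-grid 0.0,0.3,1.0 --c-grid 1.0 --seed 0 --out run
# {
#   "micro_aupr": "0.9948 +- 0.0067",
#   "subset_accuracy": "0.8742 +- 0.0797"
# }
```

`micro_aupr` is the outer-fold mean ± sd of the area under the pooled
precision–recall curve (1.0 = every positive label ranked above every
negative); `subset_accuracy` is the fraction of sequences whose entire
predicted mode set is exactly right. The strong planted motif signal is
recovered almost perfectly; per-fold selections and fold assignments
are in `run/report.json`.

Occupancy profiling on synthetic reads with planted dips:

```sh
protgauss simulate --kind mnase --seed 4 --n-centers 8 \
    --category dip-at-centre --out mn
protgauss occupancy --reads mn/reads.bed --peaks mn/peaks.bed \
    --tf-id DEMO --out occ
# DEMO: dip-at-centre (central 0.532, flank 1.065)
```

The central ±150 bp occupancy (0.53× genome average) is well below the
distal-flank occupancy (1.07×), so the profile is called dip-at-centre
— the signature of a TF binding nucleosome-depleted sites. The full
±1000 bp profile is written to `occ/profile.tsv`.

The same functionality is available as a library
(`protgauss.kernel.build_kernel_matrix`, `protgauss.classify.nested_cv`,
`protgauss.occupancy.profile_around_peaks`, ...).

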