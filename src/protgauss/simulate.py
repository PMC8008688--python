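"""Seeded synthetic fixtures for every stage of the pipeline.

Generates random proteomes, k-mer embedding tables, multi-label
datasets with planted motif signal, and MNase-seq-like read sets with
planted occupancy dips or peaks — in the same dialects the real
pipeline reads (FASTA, token+floats embedding text, delimited label
tables, BED). All generators are pure functions of their
:class:`SimConfig`: a fixed seed gives byte-identical output.

The planted label signal lives at the embedding level: each label owns
a few k-mer motifs whose embedding vectors are shifted along a
label-specific direction, and positive sequences carry several copies
of those motifs. Motif presence therefore moves both the mean and the
covariance of a sequence's Gaussian representation, so both kernel
components carry information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .classify import MultiLabelDataset
from .embeddings import EmbeddingTable
from .errors import ValidationError
from .occupancy import NUCLEOSOME_BP
from .seqio import AMINO_ACIDS, ProteinSequence


@dataclass
class SimConfig:
    """Knobs of all generators; defaults are the desk-scale study conditions."""

    seed: int = 0
    n_sequences: int = 120
    length_range: tuple[int, int] = (100, 200)
    k: int = 3
    d: int = 20
    n_labels: int = 3
    motifs_per_label: int = 2
    motif_signal_strength: float = 5.0
    motif_copies: int = 8
    prevalences: tuple[float, ...] | None = None  # default: (0.5, 0.35, 0.25)-style
    reads_per_kb: float = 2000.0
    read_length: int = 36
    dip_depth: float = 0.5

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.k < 1 or self.d < 1 or self.n_labels < 1:
            raise ValidationError("all counts must be >= 1")
        if not 0.0 <= self.dip_depth <= 1.0:
            raise ValidationError("dip_depth must be in [0, 1]")


def random_sequences(cfg: SimConfig) -> list[ProteinSequence]:
    """Uniform-random sequences over the 20 standard amino acids."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    letters = np.array(list(AMINO_ACIDS))
    out = []
    for i in range(cfg.n_sequences):
        length = int(rng.integers(lo, hi + 1))
        out.append(ProteinSequence(id=f"seq{i:04d}", residues="".join(rng.choice(letters, size=length))))
    return out


def synthetic_embedding_table(cfg: SimConfig, corpus: list[ProteinSequence] | None = None
                              ) -> EmbeddingTable:
    """Standard-normal vectors for every k-mer (or the corpus's k-mers).

    The full 20^k vocabulary is enumerated when it has at most 20,000
    tokens; beyond that a corpus must be supplied to bound the table.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if 20 ** cfg.k <= 20_000:
        tokens = ["".join(p) for p in product(AMINO_ACIDS, repeat=cfg.k)]
    elif corpus is not None:
        seen = set()
        for seq in corpus:
            for i in range(len(seq) - cfg.k + 1):
                seen.add(seq.residues[i : i + cfg.k])
        tokens = sorted(seen)
    else:
        raise ValidationError(f"20^{cfg.k} tokens is too many without a corpus")
    vectors = {t: rng.standard_normal(cfg.d) for t in tokens}
    return EmbeddingTable(k=cfg.k, d=cfg.d, vectors=vectors)


def _exact_count_memberships(n: int, quotas: list[int], rng: np.random.Generator) -> np.ndarray:
    """Binary n x m membership with exact column sums and >= 1 per row.

    First pass deals one label to every row (consuming quota roughly in
    proportion to what remains), then leftover quota is spread over rows
    not yet positive for that label.
    """
    m = len(quotas)
    if sum(quotas) < n:
        raise ValidationError("prevalences too small to give every sample a label")
    Y = np.zeros((n, m), dtype=int)
    remaining = np.array(quotas, dtype=float)
    for i in rng.permutation(n):
        p = remaining / remaining.sum()
        j = int(rng.choice(m, p=p))
        Y[i, j] = 1
        remaining[j] -= 1
        if remaining.sum() == 0:  # degenerate: quotas exactly n
            remaining = np.array(quotas, dtype=float) - Y.sum(axis=0)
            remaining = np.maximum(remaining, 0)
            if remaining.sum() == 0:
                break
    for j in range(m):
        deficit = quotas[j] - int(Y[:, j].sum())
        if deficit > 0:
            candidates = np.where(Y[:, j] == 0)[0]
            chosen = rng.choice(candidates, size=deficit, replace=False)
            Y[chosen, j] = 1
    return Y


def synthetic_labeled_dataset(cfg: SimConfig
                              ) -> tuple[list[ProteinSequence], EmbeddingTable, MultiLabelDataset]:
    """Sequences, embedding table and labels with planted motif signal.

    Each label owns ``motifs_per_label`` disjoint k-mers whose embedding
    vectors are shifted by ``motif_signal_strength`` along a random
    label-specific unit direction; positive sequences get
    ``motif_copies`` motif insertions at random positions. Label
    prevalences are met exactly and every sequence has >= 1 label.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    seqs = random_sequences(cfg)
    table = synthetic_embedding_table(cfg)

    prev = cfg.prevalences
    if prev is None:
        # declining imbalanced prevalences, rescaled so the union can
        # cover every sequence (sum 1.2), each clamped to at most 1
        weights = np.array([0.7 ** j for j in range(cfg.n_labels)])
        prev = tuple(np.minimum(1.0, 1.2 * weights / weights.sum()))
    if len(prev) != cfg.n_labels:
        raise ValidationError("one prevalence per label required")
    quotas = [int(round(p * cfg.n_sequences)) for p in prev]
    Y = _exact_count_memberships(cfg.n_sequences, quotas, rng)

    # disjoint motifs per label
    all_tokens = sorted(table.vectors)
    motif_idx = rng.choice(len(all_tokens), size=cfg.n_labels * cfg.motifs_per_label, replace=False)
    motifs = [
        [all_tokens[motif_idx[j * cfg.motifs_per_label + t]] for t in range(cfg.motifs_per_label)]
        for j in range(cfg.n_labels)
    ]
    for j in range(cfg.n_labels):
        u = rng.standard_normal(cfg.d)
        u /= np.linalg.norm(u)
        for tok in motifs[j]:
            table.vectors[tok] = table.vectors[tok] + cfg.motif_signal_strength * u

    planted = []
    for i, seq in enumerate(seqs):
        residues = list(seq.residues)
        for j in range(cfg.n_labels):
            if Y[i, j] != 1:
                continue
            for _ in range(cfg.motif_copies):
                tok = motifs[j][int(rng.integers(cfg.motifs_per_label))]
                pos = int(rng.integers(0, len(residues) - cfg.k + 1))
                residues[pos : pos + cfg.k] = list(tok)
        planted.append(ProteinSequence(id=seq.id, residues="".join(residues)))

    dataset = MultiLabelDataset(
        ids=[s.id for s in planted],
        labels=Y,
        label_names=[f"mode{j}" for j in range(cfg.n_labels)],
    )
    return planted, table, dataset


@dataclass
class MnaseTruth:
    """Planted occupancy shapes for one synthetic MNase experiment."""

    centers: list[tuple[str, int]]
    categories: list[str]
    reads: list = field(default_factory=list)
    peaks: list = field(default_factory=list)


def synthetic_mnase(centers: list[tuple[str, int]], categories: list[str],
                    cfg: SimConfig) -> MnaseTruth:
    """Uniform background reads with planted dips/peaks at given centres.

    Fragments are conceived as 147-bp nucleosome footprints; each is
    emitted as a short read anchored at one end (plus strand at the
    fragment start, or minus strand at the fragment's 3' end) so that
    147-bp 5'->3' extension reconstructs the footprint exactly. At a dip
    centre, footprints overlapping the central +-150 bp are thinned by
    ``dip_depth``; at a peak centre the same window is enriched by the
    matching factor; ``questionable`` centres are untouched.
    """
    if len(centers) != len(categories):
        raise ValidationError("one category per centre required")
    for cat in categories:
        if cat not in ("dip-at-centre", "peak-at-centre", "questionable"):
            raise ValidationError(f"unknown planted category {cat!r}")
    rng = np.random.default_rng(cfg.seed + 3)
    chroms: dict[str, int] = {}
    for chrom, pos in centers:
        chroms[chrom] = max(chroms.get(chrom, 0), pos + 3000)

    frag = NUCLEOSOME_BP
    truth = MnaseTruth(centers=list(centers), categories=list(categories))
    for chrom in sorted(chroms):
        length = chroms[chrom]
        n_reads = int(round(cfg.reads_per_kb * length / 1000.0))
        starts = np.sort(rng.integers(0, length - frag, size=n_reads))
        keep = np.ones(starts.size, dtype=bool)
        extra_starts: list[int] = []
        for (c, pos), cat in zip(centers, categories):
            if c != chrom or cat == "questionable":
                continue
            lo, hi = pos - 150 - (frag - 1), pos + 150
            in_window = (starts >= lo) & (starts < hi)
            if cat == "dip-at-centre":
                keep &= ~(in_window & (rng.random(starts.size) < cfg.dip_depth))
            else:  # peak-at-centre: symmetric enrichment
                n_extra = int(round(in_window.sum() * cfg.dip_depth))
                extra_starts.extend(int(x) for x in rng.integers(max(0, lo), hi, size=n_extra))
        final = np.sort(np.concatenate([starts[keep], np.array(extra_starts, dtype=int)]))
        for s in final:
            if rng.random() < 0.5:
                truth.reads.append((chrom, int(s), int(s) + cfg.read_length, "+"))
            else:
                e = int(s) + frag
                truth.reads.append((chrom, e - cfg.read_length, e, "-"))
    truth.reads.sort()
    truth.peaks = [(c, p - 50, p + 50) for c, p in centers]
    return truth


def write_mnase(truth: MnaseTruth, out_dir) -> dict[str, Path]:
    """Write reads.bed, peaks.bed and truth.tsv; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads_bed = out / "reads.bed"
    with open(reads_bed, "w") as fh:
        for i, (chrom, s, e, strand) in enumerate(truth.reads):
            fh.write(f"{chrom}\t{s}\t{e}\tread{i}\t0\t{strand}\n")
    peaks_bed = out / "peaks.bed"
    with open(peaks_bed, "w") as fh:
        for i, (chrom, s, e) in enumerate(truth.peaks):
            fh.write(f"{chrom}\t{s}\t{e}\tpeak{i}\n")
    truth_tsv = out / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("peak_id\tchrom\tcenter\tcategory\n")
        for i, ((chrom, pos), cat) in enumerate(zip(truth.centers, truth.categories)):
            fh.write(f"peak{i}\t{chrom}\t{pos}\t{cat}\n")
    return {"reads": reads_bed, "peaks": peaks_bed, "truth": truth_tsv}
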