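"""Nucleosome occupancy profiles around TF binding sites.

MNase-seq reads are extended to the nucleosomal footprint of 147 bp in
the 5' to 3' direction, piled up into per-base fragment coverage,
normalized by the genome-wide average coverage (so the genome mean is
1), averaged positionwise over +-1000 bp windows around ChIP-seq peak
centres, and smoothed with a 61-bp centered moving average. Each
averaged profile is then categorized as dip-at-centre, peak-at-centre
or questionable by comparing the mean occupancy of the central +-150 bp
(one nucleosome footprint) against the mean over the distal flanks
(|offset| in [500, 1000]).

All coordinates are 0-based half-open. For a minus-strand read the 5'
end is the rightmost aligned base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

NUCLEOSOME_BP = 147
#: E-MI penetration (lig147) below this value marks a nucleosome-end binder.
EMI_END_THRESHOLD = 20.0


@dataclass(frozen=True)
class ReadAlignment:
    """A read reduced to its 5' anchor: chromosome, 5' position, strand."""

    chrom: str
    start: int  # 5' end coordinate (rightmost aligned base for '-')
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError("read start must be >= 0")
        if self.strand not in "+-":
            raise ValidationError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"bad interval [{self.start}, {self.end})")


@dataclass
class CoverageTrack:
    """Per-base fragment counts per chromosome, plus the genome mean."""

    counts: dict[str, np.ndarray]
    genome_mean: float


@dataclass
class OccupancyProfile:
    """Average normalized occupancy at offsets -flank..+flank from peaks."""

    tf_id: str
    offsets: np.ndarray
    values: np.ndarray
    n_peaks: int


@dataclass(frozen=True)
class ProfileCategory:
    category: str  # dip-at-centre | peak-at-centre | questionable
    central_mean: float
    flank_mean: float


def extend_reads(reads: list[ReadAlignment], length: int = NUCLEOSOME_BP) -> list[GenomicInterval]:
    """Extend each read to ``length`` bp in its 5' to 3' direction.

    A plus-strand read anchored at s covers [s, s+length); a minus-strand
    read whose 5' end is e covers [e-length+1, e+1). Fragments running
    past position 0 are clipped.
    """
    if length < 1:
        raise ValidationError("extension length must be >= 1")
    out = []
    for r in reads:
        if r.strand == "+":
            start, end = r.start, r.start + length
        else:
            start, end = r.start - length + 1, r.start + 1
        out.append(GenomicInterval(chrom=r.chrom, start=max(0, start), end=end))
    return out


def coverage(fragments: list[GenomicInterval], chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Per-base count of overlapping fragments via a difference array.

    The genome mean is total fragment-base coverage divided by the total
    length of all declared chromosomes. Fragments running past a
    chromosome end are clipped.
    """
    counts = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    diffs = {c: np.zeros(n + 1, dtype=float) for c, n in chrom_lengths.items()}
    for frag in fragments:
        if frag.chrom not in chrom_lengths:
            raise ValidationError(f"fragment chromosome {frag.chrom!r} not declared")
        n = chrom_lengths[frag.chrom]
        start, end = min(frag.start, n), min(frag.end, n)
        if start >= end:
            continue
        diffs[frag.chrom][start] += 1
        diffs[frag.chrom][end] -= 1
    total_mass = 0.0
    total_len = 0
    for c in counts:
        counts[c] = np.cumsum(diffs[c][:-1])
        total_mass += counts[c].sum()
        total_len += chrom_lengths[c]
    if total_len == 0:
        raise ValidationError("empty genome")
    return CoverageTrack(counts=counts, genome_mean=total_mass / total_len)


def normalize_occupancy(track: CoverageTrack) -> CoverageTrack:
    """Divide every per-base count by the genome-wide mean coverage."""
    if track.genome_mean <= 0:
        raise ValidationError("genome mean coverage is zero; cannot normalize")
    return CoverageTrack(
        counts={c: v / track.genome_mean for c, v in track.counts.items()},
        genome_mean=1.0,
    )


def smooth(values: np.ndarray, window: int = 61) -> np.ndarray:
    """Centered moving average with an odd window.

    Near the array edges the window shrinks to the available span (no
    padding), so a constant array is left exactly unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    v = np.asarray(values, dtype=float)
    if window == 1:
        return v.copy()
    h = window // 2
    n = v.size
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(0, np.arange(n) - h)
    hi = np.minimum(n, np.arange(n) + h + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def profile_around_peaks(track: CoverageTrack, peaks: list[tuple[str, int]],
                         flank: int = 1000, smooth_window: int = 61,
                         tf_id: str = "") -> OccupancyProfile:
    """Average the (normalized) track over +-flank windows at peak centres.

    Peaks truncated by chromosome boundaries contribute only their
    defined offsets, with per-offset denominators; the positionwise
    average is then smoothed.
    """
    if not peaks:
        raise ValidationError("no peaks supplied")
    width = 2 * flank + 1
    acc = np.zeros(width)
    denom = np.zeros(width)
    n_used = 0
    for chrom, center in peaks:
        if chrom not in track.counts:
            continue
        arr = track.counts[chrom]
        lo, hi = center - flank, center + flank + 1
        s, e = max(0, lo), min(arr.size, hi)
        if s >= e:
            continue
        acc[s - lo : e - lo] += arr[s:e]
        denom[s - lo : e - lo] += 1
        n_used += 1
    if n_used == 0:
        raise ValidationError("all peaks fall outside the covered genome")
    values = np.divide(acc, denom, out=np.zeros(width), where=denom > 0)
    return OccupancyProfile(
        tf_id=tf_id,
        offsets=np.arange(-flank, flank + 1),
        values=smooth(values, smooth_window),
        n_peaks=n_used,
    )


def categorize_profile(p: OccupancyProfile, central_halfwidth: int = 150,
                       rel_threshold: float = 0.1, flank_range: tuple[int, int] = (500, 1000),
                       ) -> ProfileCategory:
    """Dip/peak/questionable call from the central-vs-flank occupancy ratio.

    central < (1 - t) * flank  -> dip-at-centre
    central > (1 + t) * flank  -> peak-at-centre
    otherwise questionable.
    """
    off = p.offsets
    central = p.values[np.abs(off) <= central_halfwidth].mean()
    lo, hi = flank_range
    flank = p.values[(np.abs(off) >= lo) & (np.abs(off) <= hi)].mean()
    if central < (1.0 - rel_threshold) * flank:
        cat = "dip-at-centre"
    elif central > (1.0 + rel_threshold) * flank:
        cat = "peak-at-centre"
    else:
        cat = "questionable"
    return ProfileCategory(category=cat, central_mean=float(central), flank_mean=float(flank))


def emi_end_preference(emi: float) -> bool:
    """True iff the E-MI penetration value indicates nucleosome-end binding."""
    return emi < EMI_END_THRESHOLD


# ---------------------------------------------------------------------------
# Text / alignment I/O
# ---------------------------------------------------------------------------


def read_reads_bed(path) -> list[ReadAlignment]:
    """Read 6-column BED reads; the 5' anchor is strand dependent."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValidationError(f"{path}:{lineno}: need 6 BED columns for stranded reads")
            chrom, start, end, _, _, strand = parts[:6]
            start, end = int(start), int(end)
            anchor = start if strand == "+" else end - 1
            reads.append(ReadAlignment(chrom=chrom, start=anchor, strand=strand))
    return reads


def read_reads_bam(path) -> list[ReadAlignment]:
    """Read mapped reads from BAM/SAM; only chrom, 5' position, strand are used."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if rec.is_reverse:
                reads.append(ReadAlignment(rec.reference_name, rec.reference_end - 1, "-"))
            else:
                reads.append(ReadAlignment(rec.reference_name, rec.reference_start, "+"))
    return reads


def read_peaks(path) -> list[tuple[str, int]]:
    """Peak centres from BED or narrowPeak.

    narrowPeak rows with a non-negative summit offset (column 10) use
    start + summit; otherwise the midpoint floor((start + end) / 2).
    """
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if len(parts) >= 10 and parts[9].lstrip("-").isdigit() and int(parts[9]) >= 0:
                center = start + int(parts[9])
            else:
                center = (start + end) // 2
            peaks.append((chrom, center))
    return peaks


def write_profile(p: OccupancyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\toccupancy\n")
        for o, v in zip(p.offsets, p.values):
            fh.write(f"{o}\t{float(v)!r}\n")


def write_categories(rows: list[tuple[str, ProfileCategory]], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_id\tcategory\tcentral_mean\tflank_mean\n")
        for tf_id, c in rows:
            fh.write(f"{tf_id}\t{c.category}\t{float(c.central_mean)!r}\t{float(c.flank_mean)!r}\n")
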