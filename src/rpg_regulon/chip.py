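"""Binned ChIP coverage, Poisson significance, metagenes and occupancy calls.

Reads are counted by their strand-aware 5' ends into fixed-width bins
(RPM-normalizable), per-bin significance is a Poisson tail against
max(global, local) background rate (MACS-style lambda floor), and per-gene
occupancy is the maximum significance within a +/-500 bp promoter window
around the TSS.  Binding matrices over many promoters can be clustered with
seeded k-means, occupancy call sets intersected across datasets, and
divergent (bidirectional) promoter pairs detected from TSS annotation.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans

__all__ = [
    "GenomicInterval",
    "TSSAnchor",
    "CoverageTrack",
    "SignificanceTrack",
    "MetageneProfile",
    "OccupancyCall",
    "coverage_rpm",
    "poisson_track",
    "metagene_profile",
    "call_occupancy",
    "cluster_binding",
    "overlap_sets",
    "bidirectional_pairs",
]

DEFAULT_THETA = 5.0          # -log10 p occupancy threshold
DEFAULT_PROMOTER_WINDOW = 500
DEFAULT_LOCAL_WINDOW = 10_000


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def five_prime(self) -> int:
        return self.start if self.strand != "-" else self.end - 1


@dataclass(frozen=True)
class TSSAnchor:
    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("TSS position must be non-negative")
        if self.strand not in "+-":
            raise ValueError("TSS strand must be + or -")


@dataclass
class CoverageTrack:
    bin_width: int
    counts: dict            # chrom -> int array of per-bin counts
    library_size: int

    def per_chrom(self):
        return self.counts

    def rpm(self) -> dict:
        if self.library_size == 0:
            raise ValueError("library size is zero")
        return {c: v * 1e6 / self.library_size for c, v in self.counts.items()}

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.counts.values())


@dataclass
class SignificanceTrack:
    bin_width: int
    values: dict            # chrom -> float array of -log10 Poisson p per bin
    lambda_global: float

    def per_chrom(self):
        return self.values


@dataclass
class MetageneProfile:
    offsets: np.ndarray     # bin-centre offsets relative to the TSS
    matrix: np.ndarray      # genes x bins, NaN where off-chromosome
    mean_curve: np.ndarray
    gene_ids: list


@dataclass(frozen=True)
class OccupancyCall:
    gene_id: str
    factor: str
    score: float
    bound: bool
    threshold: float

    def __post_init__(self):
        if self.bound != (self.score >= self.threshold):
            raise ValueError("bound flag inconsistent with score/threshold")


def coverage_rpm(reads, bin_width: int, chrom_sizes: dict,
                 library_size: int | None = None) -> CoverageTrack:
    """Bin reads by strand-aware 5' end; RPM view via ``CoverageTrack.rpm``."""
    reads = list(reads)
    if not reads:
        raise ValueError("empty read set")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts = {c: np.zeros(-(-size // bin_width), dtype=np.int64)
              for c, size in chrom_sizes.items()}
    assigned = 0
    for read in reads:
        pos = read.five_prime()
        if read.chrom not in counts:
            raise ValueError(f"read on unknown chromosome {read.chrom}")
        if pos >= chrom_sizes[read.chrom]:
            raise ValueError(f"read beyond chromosome end at {read.chrom}:{pos}")
        counts[read.chrom][pos // bin_width] += 1
        assigned += 1
    return CoverageTrack(bin_width, counts,
                         library_size if library_size is not None else assigned)


def poisson_track(track: CoverageTrack,
                  local_window: int = DEFAULT_LOCAL_WINDOW) -> SignificanceTrack:
    """Per-bin -log10 Poisson tail p-value with a local/global lambda floor.

    lambda is the larger of the genome-wide mean bin count and the mean over
    ``local_window`` centred on the bin (the bin itself excluded); the
    significance of count k is -log10 P(X >= k | lambda), 0 for k = 0.
    """
    if local_window < track.bin_width:
        raise ValueError("local_window must cover at least one bin")
    if track.n_bins == 0:
        raise ValueError("empty track")
    lam_global = sum(int(v.sum()) for v in track.counts.values()) / track.n_bins
    half = max(1, local_window // (2 * track.bin_width))
    values = {}
    for chrom, k in track.counts.items():
        k = k.astype(float)
        csum = np.concatenate([[0.0], np.cumsum(k)])
        idx = np.arange(len(k))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, len(k))
        window_sum = csum[hi] - csum[lo] - k   # bin itself excluded
        window_n = (hi - lo - 1).astype(float)
        lam_local = np.divide(window_sum, window_n,
                              out=np.zeros_like(k), where=window_n > 0)
        lam = np.maximum(lam_global, lam_local)
        with np.errstate(divide="ignore"):
            v = -np.log10(sps.poisson.sf(k - 1, lam))
        v[k == 0] = 0.0
        values[chrom] = v
    return SignificanceTrack(track.bin_width, values, lam_global)


def _track_values(track) -> tuple[int, dict]:
    if isinstance(track, SignificanceTrack):
        return track.bin_width, track.values
    if isinstance(track, CoverageTrack):
        return track.bin_width, track.rpm()
    raise TypeError("expected a SignificanceTrack or CoverageTrack")


def metagene_profile(track, anchors, offset: int = 3000,
                     bin_width: int | None = None) -> MetageneProfile:
    """TSS-anchored profile over +/-offset bp; minus-strand rows are flipped
    so negative offsets are always upstream.  Off-chromosome bins are NaN and
    excluded from the mean curve."""
    anchors = list(anchors)
    if not anchors:
        raise ValueError("empty anchor list")
    track_bin, values = _track_values(track)
    if bin_width is None:
        bin_width = track_bin
    if bin_width != track_bin:
        raise ValueError("metagene bin width must equal the track bin width")
    n_side = offset // bin_width
    n_bins = 2 * n_side + 1
    offsets = (np.arange(n_bins) - n_side) * bin_width
    matrix = np.full((len(anchors), n_bins), np.nan)
    for i, a in enumerate(anchors):
        if a.chrom not in values:
            raise ValueError(f"anchor {a.gene_id} on uncovered chromosome")
        chrom_vals = values[a.chrom]
        b0 = a.pos // bin_width
        lo, hi = b0 - n_side, b0 + n_side + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(chrom_vals))
        row = np.full(n_bins, np.nan)
        row[src_lo - lo: src_hi - lo] = chrom_vals[src_lo:src_hi]
        if a.strand == "-":
            row = row[::-1]
        matrix[i] = row
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(matrix, axis=0)
    return MetageneProfile(offsets, matrix, mean_curve,
                           [a.gene_id for a in anchors])


def call_occupancy(sig: SignificanceTrack, anchor: TSSAnchor,
                   window: int = DEFAULT_PROMOTER_WINDOW,
                   threshold: float = DEFAULT_THETA,
                   factor: str = "", upstream_only: bool = False) -> OccupancyCall:
    """Bound/unbound call from the max significance within the promoter window."""
    if anchor.chrom not in sig.values:
        raise ValueError(f"anchor {anchor.gene_id} off any covered chromosome")
    vals = sig.values[anchor.chrom]
    if upstream_only:
        if anchor.strand == "+":
            lo, hi = anchor.pos - window, anchor.pos
        else:
            lo, hi = anchor.pos, anchor.pos + window
    else:
        lo, hi = anchor.pos - window, anchor.pos + window
    b_lo = max(lo // sig.bin_width, 0)
    b_hi = min(hi // sig.bin_width + 1, len(vals))
    if b_lo >= b_hi:
        raise ValueError("promoter window not covered by the track")
    score = float(vals[b_lo:b_hi].max())
    return OccupancyCall(anchor.gene_id, factor, score, score >= threshold,
                         threshold)


def cluster_binding(matrix: np.ndarray, k: int, restarts: int = 10,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Euclidean k-means on log(1+x) binding rows.

    Returns 1-based labels and per-cluster mean profiles (original scale of
    the log rows), clusters renumbered by descending mean signal so cluster 1
    is always the high-occupancy group.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("binding matrix must be finite")
    n = matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    logm = np.log1p(matrix)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(logm)
    order = np.argsort(-np.array([
        logm[raw == c].mean() if (raw == c).any() else -np.inf
        for c in range(k)
    ]), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    profiles = np.vstack([
        logm[labels == c].mean(axis=0) if (labels == c).any()
        else np.full(matrix.shape[1], np.nan)
        for c in range(1, k + 1)
    ])
    return labels, profiles


def overlap_sets(call_sets: dict) -> dict:
    """Venn partition of named bound-gene sets over a shared universe.

    ``call_sets`` maps dataset name -> {gene_id: bound}.  Returns a mapping
    from the tuple of dataset names a gene is bound in (sorted) to the sorted
    gene list of that exclusive region; the empty tuple collects genes bound
    nowhere.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    universes = [frozenset(calls) for calls in call_sets.values()]
    if len(set(universes)) != 1:
        raise ValueError("call sets cover inconsistent gene universes")
    names = sorted(call_sets)
    regions: dict[tuple, list] = {}
    for gene in sorted(universes[0]):
        key = tuple(nm for nm in names if call_sets[nm][gene])
        regions.setdefault(key, []).append(gene)
    return regions


def bidirectional_pairs(anchors, max_gap: int = 500) -> list[tuple]:
    """Divergent promoter pairs: a '-' gene at most ``max_gap`` bp left of a
    '+' gene, so the two transcribe away from each other."""
    pairs = []
    by_chrom: dict[str, list] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom_anchors in by_chrom.values():
        minus = sorted((a for a in chrom_anchors if a.strand == "-"),
                       key=lambda a: a.pos)
        plus = sorted((a for a in chrom_anchors if a.strand == "+"),
                      key=lambda a: a.pos)
        for g1 in minus:
            for g2 in plus:
                if g1.pos <= g2.pos <= g1.pos + max_gap:
                    pairs.append((g1, g2))
    return pairs
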