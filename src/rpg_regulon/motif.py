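"""PWM scanning of promoters and peaks for the TCTCGCGAGA-class motifs.

The palindromic TCTCGCGAGA element marks the subset of ribosomal-protein-gene
(RPG) promoters that recruit DYRK1A; this module builds a position weight
matrix (PWM) for it (or for any IUPAC consensus / aligned site set), scans
sequences on both strands, and converts scores to *exact* tail p-values
under an i.i.d. background.  Exactness comes from a dynamic program over a
discretized score lattice (default granularity 1e-4 bits); scanning scores
windows on the same lattice, so the p-value attached to a hit is the exact
probability that a background sequence scores at least as high.

Promoters are classified into three conservation tiers from the best-hit
p-value (bona fide / poorly conserved / absent), peak sets are tested for
central motif enrichment (a fixed-ladder CentriMo-style binomial test), and
TSS-anchored windows are matched against the polypyrimidine TCT initiator
consensus YC(+1)TYTYY.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PWM",
    "MotifHit",
    "CentralEnrichmentResult",
    "build_pwm",
    "background_from_sequences",
    "ScorePValueTable",
    "scan_sequence",
    "classify_promoter_motif",
    "central_enrichment",
    "tct_match",
    "DYRK1A_CONSENSUS",
]

DYRK1A_CONSENSUS = "TCTCGCGAGA"

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: classification thresholds on the best-hit p-value
BONA_FIDE_P = 1e-4
POORLY_CONSERVED_P = 3e-4

#: candidate central-window widths (bp) for the enrichment ladder
CENTRAL_WINDOW_LADDER = (50, 100, 150, 200, 250)

MAX_EXACT_LENGTH = 14


@dataclass(frozen=True)
class PWM:
    """Probability matrix over A,C,G,T with an i.i.d. background model."""

    probs: np.ndarray          # length x 4
    background: np.ndarray     # 4-vector
    pseudocount: float

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be a length x 4 matrix")
        if not np.all(probs > 0) or not np.all(bg > 0):
            raise ValueError("all probabilities must be strictly positive")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """Per-position log2(p / background) in bits."""
        return np.log2(self.probs / self.background)

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1]
        return PWM(rc, self.background[_COMPLEMENT_INDEX], self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int                # 0-based from sequence start
    strand: str                # '+' or '-'
    score: float               # log-odds in bits
    p_value: float
    motif_class: str | None = None


@dataclass(frozen=True)
class CentralEnrichmentResult:
    bin_width: int
    bin_centers: np.ndarray
    counts: np.ndarray
    best_window: int
    p_central: float
    n_peaks: int


def build_pwm(consensus: str | None = None, sites=None,
              pseudocount: float = 0.01, background=None) -> PWM:
    """Build a PWM from an IUPAC consensus or a list of aligned sites.

    For a consensus, each allowed base at a position shares probability
    ``1 - (4 - k) * eps`` equally (k allowed bases, eps = pseudocount), and
    every disallowed base receives ``eps``; rows are renormalized.  For a
    site list, base counts plus the pseudocount are normalized per column.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if (consensus is None) == (sites is None):
        raise ValueError("provide exactly one of consensus or sites")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    if consensus is not None:
        if not consensus:
            raise ValueError("empty consensus")
        eps = pseudocount
        rows = []
        for ch in consensus.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC character {ch!r}")
            allowed = IUPAC[ch]
            k = len(allowed)
            row = np.full(4, eps)
            row[[_BASE_INDEX[b] for b in allowed]] = (1.0 - (4 - k) * eps) / k
            rows.append(row / row.sum())
        probs = np.vstack(rows)
    else:
        sites = [s.upper() for s in sites]
        if not sites:
            raise ValueError("empty site list")
        lengths = {len(s) for s in sites}
        if len(lengths) != 1:
            raise ValueError("sites must be equal length")
        (L,) = lengths
        counts = np.zeros((L, 4))
        for s in sites:
            for i, ch in enumerate(s):
                if ch not in _BASE_INDEX:
                    raise ValueError(f"invalid base {ch!r} in site")
                counts[i, _BASE_INDEX[ch]] += 1
        probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(probs, background, pseudocount)


def background_from_sequences(sequences, symmetrize: bool = True) -> np.ndarray:
    """Base frequencies of a sequence set (N ignored).

    With ``symmetrize`` the complement strands are pooled, so the background
    is strand-symmetric and one score lattice serves both strands.
    """
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode(seq)
        valid = codes[codes >= 0]
        counts += np.bincount(valid, minlength=4)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in sequence set")
    if symmetrize:
        counts = counts + counts[_COMPLEMENT_INDEX]
    return counts / counts.sum()


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


class ScorePValueTable:
    """Exact tail probabilities of PWM scores under the background model.

    Per-position log-odds are rounded to an integer lattice (``granularity``
    bits per unit); the full score distribution is then an L-fold convolution
    of four-point distributions, computed by dynamic programming.  Windows
    scored on the same lattice get exact p-values: ``pvalue(s)`` is the
    probability that an i.i.d. background window reaches lattice score >= s.
    """

    def __init__(self, pwm: PWM, granularity: float = 1e-4,
                 allow_long: bool = False):
        if pwm.length > MAX_EXACT_LENGTH and not allow_long:
            raise ValueError(
                f"exact table limited to length <= {MAX_EXACT_LENGTH}; "
                "pass allow_long=True to override"
            )
        self.pwm = pwm
        self.granularity = float(granularity)
        logodds = pwm.log_odds()
        self.int_scores = np.round(logodds / self.granularity).astype(np.int64)
        row_min = self.int_scores.min(axis=1)
        row_max = self.int_scores.max(axis=1)
        self.min_score = int(row_min.sum())
        self.max_score = int(row_max.sum())
        span = self.max_score - self.min_score
        dist = np.zeros(span + 1)
        dist[0] = 1.0
        filled = 0
        for i in range(pwm.length):
            nxt = np.zeros(span + 1)
            width = filled + (row_max[i] - row_min[i])
            for b in range(4):
                off = self.int_scores[i, b] - row_min[i]
                nxt[off: off + filled + 1] += pwm.background[b] * dist[: filled + 1]
            dist = nxt
            filled = width
        self._dist = dist
        # tail[i] = P(score >= min_score + i)
        self._tail = np.cumsum(dist[::-1])[::-1]

    def lattice_score(self, codes: np.ndarray) -> int:
        """Lattice score of one encoded window (must be N-free)."""
        L = self.pwm.length
        if codes.shape[0] != L or np.any(codes < 0):
            raise ValueError("window must be N-free and match PWM length")
        return int(self.int_scores[np.arange(L), codes].sum())

    def pvalue(self, lattice_score: int) -> float:
        """Exact P(score >= lattice_score) under the background."""
        idx = int(lattice_score) - self.min_score
        if idx <= 0:
            return 1.0
        if idx >= len(self._tail):
            idx = len(self._tail) - 1
        return float(max(self._tail[idx], np.nextafter(0, 1)))

    def pvalues(self, lattice_scores: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(lattice_scores) - self.min_score,
                      0, len(self._tail) - 1)
        return np.maximum(self._tail[idx], np.nextafter(0, 1))


def _window_scores(codes: np.ndarray, int_matrix: np.ndarray):
    """Lattice scores of every window; windows containing N are masked."""
    L = int_matrix.shape[0]
    n_win = codes.shape[0] - L + 1
    if n_win <= 0:
        raise ValueError("sequence shorter than motif")
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(wins >= 0, axis=1)
    scores = np.zeros(n_win, dtype=np.int64)
    if valid.any():
        v = wins[valid].astype(np.int64)
        scores[valid] = int_matrix[np.arange(L)[None, :], v].sum(axis=1)
    return scores, valid


def _strand_scores(codes: np.ndarray, table: ScorePValueTable):
    """Forward and reverse-strand lattice scores for every window start."""
    fwd = table.int_scores
    rev = fwd[::-1][:, _COMPLEMENT_INDEX]
    sf, vf = _window_scores(codes, fwd)
    sr, vr = _window_scores(codes, rev)
    return sf, sr, vf & vr


def scan_sequence(pwm: PWM, sequence: str, sequence_id: str = "",
                  both_strands: bool = True, p_threshold: float | None = None,
                  table: ScorePValueTable | None = None
                  ) -> tuple[MotifHit | None, list[MotifHit]]:
    """Scan a sequence; return the best hit and all hits with p <= threshold.

    Windows containing N are unscored.  At each window the better strand
    wins, '+' on ties (a perfect palindrome scores identically on both
    strands).  The best hit over the sequence is the highest score; offset
    ties break to the leftmost.  Returns ``(None, [])`` when every window
    contains an N.
    """
    if table is None:
        table = ScorePValueTable(pwm)
    codes = encode(sequence)
    if codes.shape[0] < pwm.length:
        raise ValueError("sequence shorter than motif")
    sf, sr, valid = _strand_scores(codes, table)
    if not both_strands:
        sr = np.full_like(sf, np.iinfo(np.int64).min)
    if not valid.any():
        return None, []
    best_per_win = np.where(sr > sf, sr, sf)
    strand_per_win = np.where(sr > sf, "-", "+")

    logodds = pwm.log_odds()
    rc_logodds = logodds[::-1][:, _COMPLEMENT_INDEX]

    def float_score(offset: int, strand: str) -> float:
        mat = logodds if strand == "+" else rc_logodds
        win = codes[offset: offset + pwm.length]
        return float(mat[np.arange(pwm.length), win].sum())

    masked = np.where(valid, best_per_win, np.iinfo(np.int64).min)
    best_off = int(np.argmax(masked))  # argmax returns the leftmost maximum
    best_strand = str(strand_per_win[best_off])
    best = MotifHit(sequence_id, best_off, best_strand,
                    float_score(best_off, best_strand),
                    table.pvalue(int(masked[best_off])))

    hits: list[MotifHit] = []
    if p_threshold is not None:
        pvals = table.pvalues(best_per_win)
        for off in np.nonzero(valid & (pvals <= p_threshold))[0]:
            st = str(strand_per_win[off])
            hits.append(MotifHit(sequence_id, int(off), st,
                                 float_score(int(off), st),
                                 float(pvals[off])))
    return best, hits


def classify_promoter_motif(best_p: float,
                            bona_fide_p: float = BONA_FIDE_P,
                            poorly_conserved_p: float = POORLY_CONSERVED_P) -> str:
    """Tier a promoter by its best-hit p-value.

    bona_fide: p < 1e-4; poorly_conserved: 1e-4 <= p < 3e-4; absent
    otherwise.  Both boundaries go to the weaker class (strict '<' rules).
    """
    if not (0.0 < best_p <= 1.0):
        raise ValueError(f"p-value {best_p} outside (0, 1]")
    if best_p < bona_fide_p:
        return "bona_fide"
    if best_p < poorly_conserved_p:
        return "poorly_conserved"
    return "absent"


def central_enrichment(peak_records, pwm: PWM, bin_width: int = 10,
                       table: ScorePValueTable | None = None,
                       ladder=CENTRAL_WINDOW_LADDER) -> CentralEnrichmentResult:
    """Positional distribution of the best motif site across equal-width peaks.

    Per peak the best site (either strand) is located; ties break to the
    site centre nearest the peak centre, then '+', then leftmost.  Site
    centres are histogrammed in ``bin_width`` bins around the peak centre.
    For each central window in the ladder, a binomial tail probability is
    computed against uniform best-site placement; the smallest, Bonferroni
    corrected for the ladder size, is reported.
    """
    records = list(peak_records)
    if not records:
        raise ValueError("empty peak set")
    widths = {len(seq) for _, seq in records}
    if len(widths) != 1:
        raise ValueError("peak sequences must have equal width")
    (w,) = widths
    L = pwm.length
    if w < L:
        raise ValueError("peaks shorter than motif")
    if table is None:
        table = ScorePValueTable(pwm)

    half_site = (L - 1) / 2.0
    peak_centre = (w - 1) / 2.0
    rel_positions = []
    for _, seq in records:
        codes = encode(seq)
        sf, sr, valid = _strand_scores(codes, table)
        if not valid.any():
            continue
        best_per_win = np.where(sr > sf, sr, sf)
        strand_pref = np.where(sr > sf, 1, 0)  # 0 = '+', preferred on ties
        masked = np.where(valid, best_per_win, np.iinfo(np.int64).min)
        top = masked.max()
        cand = np.nonzero(masked == top)[0]
        rel = cand + half_site - peak_centre
        order = np.lexsort((cand, strand_pref[cand], np.abs(rel)))
        rel_positions.append(rel[order[0]])
    if not rel_positions:
        raise ValueError("no peak had a scoreable (N-free) window")
    rel_positions = np.asarray(rel_positions)
    n = len(rel_positions)

    half_w = w / 2.0
    edges = np.arange(-half_w, half_w + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(rel_positions, bins=edges)
    bin_centers = (edges[:-1] + edges[1:]) / 2.0

    n_starts = w - L + 1
    starts = np.arange(n_starts)
    start_rel = starts + half_site - peak_centre
    best_p, best_window = 1.0, ladder[0]
    for win in ladder:
        k = int(np.sum(np.abs(start_rel) <= win / 2.0))
        p0 = min(1.0, k / n_starts)
        x = int(np.sum(np.abs(rel_positions) <= win / 2.0))
        p = float(sps.binom.sf(x - 1, n, p0))
        if p < best_p:
            best_p, best_window = p, win
    p_central = float(min(1.0, len(ladder) * best_p))
    p_central = max(p_central, np.nextafter(0, 1))
    return CentralEnrichmentResult(bin_width, bin_centers, counts,
                                   best_window, p_central, n)


# the TCT initiator consensus YC(+1)TYTYY at positions -1, +1..+6
_TCT_PATTERN = ("CT", "C", "T", "CT", "T", "CT", "CT")


def tct_match(window: str, tss_index: int = 1, max_tss_shift: int = 0
              ) -> tuple[bool, int | None]:
    """Match the TCT initiator consensus around an annotated TSS.

    ``tss_index`` is the index in ``window`` of the +1 base (first
    transcribed base; there is no position 0, so the pattern occupies the 7
    consecutive bases starting one left of +1).  Candidate TSSs within
    ``max_tss_shift`` bp of the annotation are tried, nearest first ('+'
    direction preferred on ties); returns (matched, shift) with the shift of
    the matching TSS, or (False, None).
    """
    window = window.upper()
    if tss_index < 1 or tss_index + 6 > len(window):
        raise ValueError("window must cover at least [-1, +6] around the TSS")
    shifts = sorted(range(-max_tss_shift, max_tss_shift + 1),
                    key=lambda s: (abs(s), 0 if s >= 0 else 1))
    for shift in shifts:
        i = tss_index + shift
        if i < 1 or i + 6 > len(window):
            continue
        seg = window[i - 1: i + 6]
        if all(base in allowed for base, allowed in zip(seg, _TCT_PATTERN)):
            return True, shift
    return False, None
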