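"""PWM scanning with normalized bit scores, calibrated thresholds and
shuffle-based empirical e-values.

Scores are *normalized* bit scores: the log2-likelihood of a word under
the motif minus the log2-likelihood of the consensus word, so the best
possible match scores exactly 0 and every other word is negative.  A
per-motif significance threshold is calibrated by binning window scores
into 1-bit intervals and testing each high-scoring interval for
over-representation against an i.i.d. background model (one-sided
binomial).  A single empirical e-value per motif is obtained by shuffling
the scanned sequence and asking how often a shuffle's best window ties or
beats the observed best window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .io_core import MotifMatrix, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "Background",
    "ScanCalibration",
    "EmpiricalEvalue",
    "encode_sequence",
    "normalized_bit_score",
    "scan_sequence",
    "estimate_background",
    "calibrate_threshold",
    "empirical_evalue",
    "mask_low_complexity",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode_sequence(seq: str) -> np.ndarray:
    """Map A/C/G/T/N to integer codes 0..4 (N = 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """A scored window: 0-based start on the forward sequence, '+'/'-' strand."""

    motif: str
    position: int
    strand: str
    score_bits: float


@dataclass
class Background:
    """Order-0 or order-1 model of the unmasked scanned sequence.

    ``probs`` are mononucleotide probabilities over (A,C,G,T); for
    order 1, ``transition[i, j]`` is P(next = j | current = i).
    """

    order: int
    probs: np.ndarray
    transition: np.ndarray | None = None

    def sample(self, n_words: int, length: int, rng: np.random.Generator) -> np.ndarray:
        if self.order == 0:
            return rng.choice(4, size=(n_words, length), p=self.probs)
        words = np.empty((n_words, length), dtype=np.int64)
        words[:, 0] = rng.choice(4, size=n_words, p=self.probs)
        for i in range(1, length):
            u = rng.random(n_words)
            cum = np.cumsum(self.transition, axis=1)
            words[:, i] = (u[:, None] > cum[words[:, i - 1]]).sum(axis=1)
        return words


@dataclass
class ScanCalibration:
    """Per-motif threshold calibration over 1-bit score intervals.

    Bin ``k`` covers the half-open interval (upper_edges[k] - width,
    upper_edges[k]] with upper_edges[0] = 0 so that the consensus score
    falls in the top bin.  ``threshold_bits`` is the lower edge of the
    least-scoring significant bin in the accepted high-score run, or None
    when no bin is significantly enriched.
    """

    motif: str
    bin_width_bits: float
    upper_edges: np.ndarray
    observed_counts: np.ndarray
    expected_counts: np.ndarray
    binomial_p: np.ndarray
    n_windows: int
    threshold_bits: float | None
    significant_hits: list[MotifHit] = field(default_factory=list)


@dataclass
class EmpiricalEvalue:
    observed_max_bits: float
    n_shuffles: int
    n_better_or_equal: int

    @property
    def e_value(self) -> float:
        return self.n_better_or_equal / self.n_shuffles


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _normalized_log_tables(motif: MotifMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-position log2-frequency lookup tables, consensus-normalized.

    Forward table L[i, c]: contribution of base code c at motif column i,
    with the column maximum subtracted so a full window sum is the
    normalized bit score.  Reverse table gives, for the base observed at
    forward offset i, the contribution to the reverse-strand score.
    """
    lf = motif.log2_frequencies
    colmax = lf.max(axis=1, keepdims=True)
    fwd = lf - colmax
    # reverse-strand window starting at j: column i reads complement of
    # base at forward offset (m-1-i)
    rev = fwd[::-1, ::-1].copy()
    return np.ascontiguousarray(fwd), np.ascontiguousarray(rev)


def normalized_bit_score(motif: MotifMatrix, word: str) -> float:
    """Score a word of motif length; 0 iff the word is a consensus word."""
    if len(word) != motif.length:
        raise ValueError(f"word length {len(word)} != motif length {motif.length}")
    codes = encode_sequence(word.upper())
    if np.any(codes > 3):
        raise ValueError("word contains N or invalid characters; window not scorable")
    fwd, _ = _normalized_log_tables(motif)
    return float(fwd[np.arange(motif.length), codes].sum())


def _window_scores(motif: MotifMatrix, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores of every window on both strands plus a validity mask.

    Returns (scores_fwd, scores_rev, valid) arrays of length
    n - m + 1; windows containing N are invalid (scores NaN).
    """
    m = motif.length
    n = codes.size
    if n < m:
        return np.empty(0), np.empty(0), np.zeros(0, dtype=bool)
    fwd, rev = _normalized_log_tables(motif)
    nw = n - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    valid = ~(windows > 3).any(axis=1)
    safe = np.where(windows > 3, 0, windows)
    cols = np.arange(m)
    sf = fwd[cols, safe].sum(axis=1)
    sr = rev[cols, safe].sum(axis=1)
    sf[~valid] = np.nan
    sr[~valid] = np.nan
    return sf, sr, valid


def scan_sequence(motif: MotifMatrix, seq: SequenceRecord,
                  both_strands: bool = True) -> list[MotifHit]:
    """Score every N-free window of the sequence on one or both strands.

    Hit positions are 0-based starts on the forward sequence regardless
    of strand.  A sequence shorter than the motif yields no hits (with a
    warning).
    """
    if seq.length < motif.length:
        logger.warning("sequence %s shorter than motif %s; no windows scanned",
                       seq.id, motif.name)
        return []
    codes = encode_sequence(seq.sequence)
    sf, sr, valid = _window_scores(motif, codes)
    hits: list[MotifHit] = []
    for j in np.flatnonzero(valid):
        hits.append(MotifHit(motif.name, int(j), "+", float(sf[j])))
        if both_strands:
            hits.append(MotifHit(motif.name, int(j), "-", float(sr[j])))
    return hits


# ---------------------------------------------------------------------------
# Background estimation
# ---------------------------------------------------------------------------

def estimate_background(seq: SequenceRecord, order: int = 0,
                        pseudocount: float = 0.01) -> Background:
    """Estimate an order-0 (or order-1) background from unmasked bases."""
    if order not in (0, 1):
        raise ValueError("background order must be 0 or 1")
    codes = encode_sequence(seq.sequence)
    unmasked = codes[codes < 4]
    if unmasked.size == 0:
        raise ValueError("no unmasked bases to estimate a background from")
    counts = np.bincount(unmasked, minlength=4).astype(float) + pseudocount
    probs = counts / counts.sum()
    if order == 0:
        return Background(0, probs)
    trans = np.full((4, 4), pseudocount)
    a, b = codes[:-1], codes[1:]
    ok = (a < 4) & (b < 4)
    np.add.at(trans, (a[ok], b[ok]), 1.0)
    trans /= trans.sum(axis=1, keepdims=True)
    return Background(1, probs, trans)


# ---------------------------------------------------------------------------
# Threshold calibration (1-bit intervals, binomial enrichment)
# ---------------------------------------------------------------------------

def _enumerate_word_scores(motif: MotifMatrix, background: Background
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact per-word scores and background probabilities by enumeration.

    Returns (scores_fwd, scores_rev, probs) over all 4**m words; only
    feasible for short motifs (m <= 10).
    """
    fwd, rev = _normalized_log_tables(motif)
    logp = np.log(background.probs)
    s_f = np.zeros(1)
    s_r = np.zeros(1)
    lp = np.zeros(1)
    for i in range(motif.length):
        s_f = (s_f[:, None] + fwd[i][None, :]).ravel()
        s_r = (s_r[:, None] + rev[i][None, :]).ravel()
        lp = (lp[:, None] + logp[None, :]).ravel()
    return s_f, s_r, np.exp(lp)


def _bin_index(scores: np.ndarray, width: float) -> np.ndarray:
    """Index of the 1-bit interval holding each score.

    Interval k spans scores in (-(k+1)w, -kw], with the top interval
    (k = 0) also containing the consensus score 0; a small tolerance
    keeps scores sitting exactly on an edge in the higher interval.
    """
    return np.floor(-np.asarray(scores) / width - 1e-9).astype(int).clip(min=0)


def expected_bin_probabilities(motif: MotifMatrix, background: Background,
                               n_bins: int, bin_width_bits: float = 1.0,
                               mc_draws: int = 100_000,
                               rng: np.random.Generator | None = None,
                               both_strands: bool = True) -> np.ndarray:
    """Per-window probability of scoring inside each interval under the background.

    Exact enumeration over all words for motifs of <= 10 columns with an
    order-0 background; Monte Carlo sampling from the background model
    otherwise.  With both strands the probability is averaged over the
    forward and reverse-strand scores of a background word.
    """
    if motif.length <= 10 and background.order == 0:
        s_f, s_r, probs = _enumerate_word_scores(motif, background)
    else:
        rng = rng or np.random.default_rng(0)
        words = background.sample(mc_draws, motif.length, rng)
        fwd, rev = _normalized_log_tables(motif)
        cols = np.arange(motif.length)
        s_f = fwd[cols, words].sum(axis=1)
        s_r = rev[cols, words].sum(axis=1)
        probs = np.full(mc_draws, 1.0 / mc_draws)
    q = np.zeros(n_bins)
    for scores, weight in ((s_f, 0.5 if both_strands else 1.0),
                           (s_r, 0.5 if both_strands else 0.0)):
        if weight == 0.0:
            continue
        idx = _bin_index(scores, bin_width_bits)
        idx = np.minimum(idx, n_bins - 1)
        q += weight * np.bincount(idx, weights=probs, minlength=n_bins)
    return q


def calibrate_threshold(motif: MotifMatrix, seq: SequenceRecord,
                        background: Background | None = None,
                        bin_width_bits: float = 1.0, alpha: float = 0.05,
                        both_strands: bool = True,
                        mc_draws: int = 100_000,
                        rng: np.random.Generator | None = None) -> ScanCalibration:
    """Calibrate a per-motif bit-score significance threshold.

    Window scores are binned into 1-bit intervals; each interval's
    observed count is tested (one-sided binomial, greater) against the
    expected per-window probability under the background model.  The
    accepted region is the maximal run of significant intervals
    extending down from the highest-scoring occupied interval; any
    non-significant interval terminates the run.  The threshold is the
    lower edge of the lowest interval in the run; when even the top
    occupied interval is not enriched the motif is reported
    non-significant (no threshold, no significant hits).
    """
    if background is None:
        background = estimate_background(seq)
    codes = encode_sequence(seq.sequence)
    sf, sr, valid = _window_scores(motif, codes)
    scores = []
    hits_meta = []
    for j in np.flatnonzero(valid):
        scores.append(sf[j])
        hits_meta.append((int(j), "+"))
        if both_strands:
            scores.append(sr[j])
            hits_meta.append((int(j), "-"))
    scores = np.asarray(scores)
    n_windows = scores.size
    if n_windows == 0:
        raise ValueError("no scorable windows; cannot calibrate")

    idx = _bin_index(scores, bin_width_bits)
    n_bins = int(idx.max()) + 1
    observed = np.bincount(idx, minlength=n_bins).astype(int)
    q = expected_bin_probabilities(motif, background, n_bins, bin_width_bits,
                                   mc_draws=mc_draws, rng=rng,
                                   both_strands=both_strands)
    expected = n_windows * q
    pvals = np.ones(n_bins)
    for k in range(n_bins):
        if observed[k] > 0:
            pvals[k] = float(stats.binom.sf(observed[k] - 1, n_windows, min(q[k], 1.0)))

    threshold: float | None = None
    started = False
    for k in range(n_bins):
        if not started and observed[k] == 0:
            continue  # above the highest occupied interval
        if pvals[k] < alpha:
            started = True
            threshold = -(k + 1) * bin_width_bits
        else:
            break

    significant: list[MotifHit] = []
    if threshold is not None:
        for s, (pos, strand) in zip(scores, hits_meta):
            if s >= threshold:
                significant.append(MotifHit(motif.name, pos, strand, float(s)))
    upper_edges = -bin_width_bits * np.arange(n_bins)
    return ScanCalibration(motif.name, bin_width_bits, upper_edges, observed,
                           expected, pvals, n_windows, threshold, significant)


# ---------------------------------------------------------------------------
# Empirical e-value by sequence shuffling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _batch_max_scores(batch, fwd, rev, both_strands):
    K, n = batch.shape
    m = fwd.shape[0]
    out = np.full(K, -np.inf)
    nw = n - m + 1
    for k in range(K):
        best = -np.inf
        for j in range(nw):
            ok = True
            s_f = 0.0
            s_r = 0.0
            for i in range(m):
                c = batch[k, j + i]
                if c > 3:
                    ok = False
                    break
                s_f += fwd[i, c]
                s_r += rev[i, c]
            if ok:
                if s_f > best:
                    best = s_f
                if both_strands and s_r > best:
                    best = s_r
        out[k] = best
    return out


def empirical_evalue(motif: MotifMatrix, seq: SequenceRecord,
                     n_shuffles: int = 100_000, seed: int = 0,
                     both_strands: bool = True,
                     chunk: int = 200) -> EmpiricalEvalue:
    """Empirical e-value of the best observed window score.

    The unmasked bases of the sequence are permuted uniformly (N
    positions stay fixed), the shuffled sequence is re-scanned on both
    strands, and the e-value is the fraction of shuffles whose maximum
    score ties or beats the observed maximum.  Deterministic for a fixed
    seed.
    """
    if n_shuffles < 100:
        logger.warning("n_shuffles=%d is too coarse to resolve e-values near 0.05",
                       n_shuffles)
    codes = encode_sequence(seq.sequence)
    sf, sr, valid = _window_scores(motif, codes)
    if not valid.any():
        raise ValueError("no scorable window; observed maximum undefined")
    observed = float(np.nanmax(sf[valid]))
    if both_strands:
        observed = max(observed, float(np.nanmax(sr[valid])))

    fwd, rev = _normalized_log_tables(motif)
    unmasked_pos = np.flatnonzero(codes < 4)
    bases = codes[unmasked_pos]
    rng = np.random.default_rng(seed)
    n_ge = 0
    tol = 1e-9
    done = 0
    while done < n_shuffles:
        k = min(chunk, n_shuffles - done)
        tile = np.broadcast_to(bases, (k, bases.size)).copy()
        shuffled = rng.permuted(tile, axis=1)
        batch = np.broadcast_to(codes, (k, codes.size)).copy()
        batch[:, unmasked_pos] = shuffled
        maxima = _batch_max_scores(batch, fwd, rev, both_strands)
        n_ge += int((maxima >= observed - tol).sum())
        done += k
    return EmpiricalEvalue(observed, n_shuffles, n_ge)


# ---------------------------------------------------------------------------
# Low-complexity masking (DUST-like triplet filter)
# ---------------------------------------------------------------------------

def _dust_score(codes: np.ndarray) -> float:
    """Triplet-coincidence score of a window: sum c_t(c_t-1)/2 over the
    counts of each ACGT triplet, divided by (#triplets - 1)."""
    n = codes.size
    if n < 4:
        return 0.0
    trip = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    ok = (codes[:-2] < 4) & (codes[1:-1] < 4) & (codes[2:] < 4)
    trip = trip[ok]
    if trip.size < 2:
        return 0.0
    counts = np.bincount(trip, minlength=64)
    pairs = (counts * (counts - 1) // 2).sum()
    return float(pairs) / (trip.size - 1)


def mask_low_complexity(seq: SequenceRecord, window: int = 64,
                        threshold: float = 2.0) -> SequenceRecord:
    """Replace low-complexity windows by N (simple DUST-like filter).

    Windows (stepped by half the window size, plus a terminal window) whose
    triplet-coincidence score exceeds the threshold are fully masked.
    Idempotent: masking an already-masked sequence changes nothing,
    because N triplets never contribute to the score.
    """
    codes = encode_sequence(seq.sequence)
    n = codes.size
    if n == 0:
        return SequenceRecord(seq.id, seq.sequence)
    step = max(1, window // 2)
    starts = list(range(0, max(1, n - window + 1), step))
    if starts[-1] != max(0, n - window):
        starts.append(max(0, n - window))
    to_mask = np.zeros(n, dtype=bool)
    for s in starts:
        w = codes[s:s + window]
        if _dust_score(w) > threshold:
            to_mask[s:s + window] = True
    if not to_mask.any():
        return SequenceRecord(seq.id, seq.sequence)
    out = np.array(list(seq.sequence))
    out[to_mask] = "N"
    return SequenceRecord(seq.id, "".join(out))


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def hits_to_bed(hits: list[MotifHit], seq_id: str, motif_length: int) -> str:
    """BED-like text (seq, start, end, motif, score, strand), 0-based half-open."""
    lines = []
    for h in hits:
        lines.append(f"{seq_id}\t{h.position}\t{h.position + motif_length}\t"
                     f"{h.motif}\t{h.score_bits:.4f}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
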