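"""Raw pairwise similarity evidence between contigs.

Three kinds of evidence feed the binner:

* **TNF** — tetranucleotide composition. Counts over the 136 canonical
  tetramers (reverse-complement classes of the 256 4-mers) are turned into
  frequencies, and a pair of contigs is scored by a logistic map of the
  Euclidean distance between their frequency vectors, with a
  length-dependent midpoint: short contigs have noisier composition
  estimates, so the distance at which two contigs stop looking related
  grows as lengths shrink.
* **ABD** — abundance. Per sample, each contig's read depth is modelled as
  a normal with the observed mean and variance; the score for a pair is the
  shared area of the two densities, combined across *effective* samples
  (those where at least one contig has depth above ``min_cv``) by geometric
  mean.
* **COR** — abundance correlation. Pearson correlation of the two mean-depth
  profiles across samples, defined only with three or more samples.

Scalar forms (`tnf_raw_score`, `abd_score`, `cor_score`) implement the
definitions; `*_matrix` forms vectorise them over all contig pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import ndtr

__all__ = [
    "canonical_tetramers",
    "compute_tnf",
    "tnf_matrix",
    "tnf_distance_matrix",
    "tnf_raw_score",
    "tnf_score_matrix",
    "abd_score",
    "abd_matrix",
    "cor_score",
    "cor_matrix",
    "TNFVector",
    "PairEvidence",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def canonical_tetramers() -> list[str]:
    """The 136 canonical tetramers: each 4-mer and its reverse complement
    collapse to the lexicographically smaller of the two (16 palindromes
    plus 120 two-member classes). Sorted, stable across runs."""
    reps = {min(kmer, _revcomp(kmer)) for kmer in map("".join, product("ACGT", repeat=4))}
    return sorted(reps)


_CANONICAL = canonical_tetramers()
_CANONICAL_INDEX = {k: i for i, k in enumerate(_CANONICAL)}

# 256-entry lookup: 4-mer code (base-4, A=0 C=1 G=2 T=3) -> canonical slot
_CODE2SLOT = np.empty(256, dtype=np.int16)
for _kmer in map("".join, product("ACGT", repeat=4)):
    _code = 0
    for _c in _kmer:
        _code = _code * 4 + "ACGT".index(_c)
    _CODE2SLOT[_code] = _CANONICAL_INDEX[min(_kmer, _revcomp(_kmer))]

# sequence byte -> base code; N (and anything else) -> 4 marks invalid windows
_BYTE2CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BYTE2CODE[ord(_c)] = _i


@dataclass
class TNFVector:
    """Canonical-tetramer frequencies of one contig."""

    freq: np.ndarray  # (136,), sums to 1 when n_kmers > 0
    n_kmers: int  # valid (N-free) 4-bp windows counted


@dataclass
class PairEvidence:
    """Raw evidence for one contig pair.

    NaN marks undefined evidence: ``abd`` when no sample is effective
    (``n_abd`` is then 0), ``cor`` with fewer than three samples or a
    zero-variance profile.
    """

    tnf_raw: float
    abd: float
    cor: float
    n_abd: int


def _window_slots(seq: str) -> np.ndarray:
    """Canonical slot of every valid 4-bp window of ``seq``."""
    codes = _BYTE2CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        return np.empty(0, dtype=np.int16)
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
    window = (
        c0.astype(np.int32) * 64
        + c1.astype(np.int32) * 16
        + c2.astype(np.int32) * 4
        + c3.astype(np.int32)
    )
    return _CODE2SLOT[window[valid]]


def compute_tnf(seq: str) -> TNFVector:
    """Slide a 4-bp window (step 1) over ``seq``; windows containing N are
    skipped; counts accumulate on canonical representatives and are
    normalised to frequencies. Strand-symmetric by construction."""
    slots = _window_slots(seq)
    counts = np.bincount(slots, minlength=136).astype(float)
    n = int(slots.size)
    freq = counts / n if n else counts
    return TNFVector(freq=freq, n_kmers=n)


def tnf_matrix(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Stack compute_tnf over contigs -> (freq matrix (N,136), n_kmers (N,))."""
    n = len(sequences)
    freq = np.zeros((n, 136))
    kmers = np.zeros(n, dtype=np.int64)
    for i, s in enumerate(sequences):
        v = compute_tnf(s)
        freq[i] = v.freq
        kmers[i] = v.n_kmers
    return freq, kmers


def tnf_distance_matrix(freq: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance between TNF frequency rows."""
    sq = np.einsum("ij,ij->i", freq, freq)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (freq @ freq.T)
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


# Logistic map of TNF distance to a relatedness score. The midpoint distance
# grows for short contigs as d0(L)^2 = TNF_A / L_h + TNF_B, where L_h is the
# harmonic mean of the pair's lengths (4-mer frequency sampling noise has
# variance ~ 1/L), and the slope scales with the midpoint (k = TNF_K0 / d0)
# so the score curve keeps its shape across lengths. Coefficients were fitted
# once on simulated communities (scripts/calibrate_tnf.py, seed 20240601)
# from same-genome vs different-genome fragment pairs at 1-50 kb and are
# frozen here.
TNF_A = 2.207
TNF_B = 6.969e-04
TNF_K0 = 5.37


def _tnf_midpoint(len_a, len_b):
    lh = 2.0 / (1.0 / np.asarray(len_a, dtype=float) + 1.0 / np.asarray(len_b, dtype=float))
    return np.sqrt(TNF_A / lh + TNF_B)


def _logistic_score(dist, d0):
    # normalised so the score is exactly 1 at zero distance
    g = 1.0 / (1.0 + np.exp(np.minimum(TNF_K0 * (dist / d0 - 1.0), 500.0)))
    g0 = 1.0 / (1.0 + np.exp(-TNF_K0))
    return g / g0


def tnf_raw_score(a: TNFVector, b: TNFVector, len_a: int, len_b: int) -> float:
    """Relatedness of two contigs from composition alone, in [0, 1].

    1 at zero distance, decreasing in the Euclidean distance between the
    frequency vectors, symmetric in the pair. Returns NaN (undefined
    evidence) if either contig had no valid tetramer window.
    """
    if a.n_kmers == 0 or b.n_kmers == 0:
        return float("nan")
    d = float(np.linalg.norm(a.freq - b.freq))
    return float(_logistic_score(d, _tnf_midpoint(len_a, len_b)))


def tnf_score_matrix(freq: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Pairwise TNF raw scores for all contigs (diagonal = 1)."""
    d = tnf_distance_matrix(freq)
    lengths = np.asarray(lengths, dtype=float)
    d0 = _tnf_midpoint(lengths[:, None], lengths[None, :])
    return _logistic_score(d, d0)


_VAR_FLOOR = 1e-4  # guards zero-variance depth rows


def _normal_overlap(m1, v1, m2, v2):
    """Shared area of N(m1,v1) and N(m2,v2); 1 iff identical. Vectorised."""
    m1, v1, m2, v2 = np.broadcast_arrays(
        np.asarray(m1, float), np.asarray(v1, float),
        np.asarray(m2, float), np.asarray(v2, float),
    )
    v1 = np.maximum(v1, _VAR_FLOOR)
    v2 = np.maximum(v2, _VAR_FLOOR)
    # orient so sigma1 <= sigma2: density 1 then dominates between the two
    # intersection points and the overlap is two tails of 1 plus a slab of 2
    swap = v1 > v2
    m1s = np.where(swap, m2, m1)
    v1s = np.where(swap, v2, v1)
    m2s = np.where(swap, m1, m2)
    v2s = np.where(swap, v1, v2)

    equal = np.isclose(v1s, v2s, rtol=1e-9, atol=1e-12)
    sd = np.sqrt(v1s)
    out_equal = 2.0 * ndtr(-np.abs(m1s - m2s) / (2.0 * np.where(sd > 0, sd, 1.0)))

    # intersection points of the log-densities: A x^2 + B x + C = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        A = 0.5 / v2s - 0.5 / v1s  # < 0 when v1 < v2
        B = m1s / v1s - m2s / v2s
        C = m2s**2 / (2 * v2s) - m1s**2 / (2 * v1s) + 0.5 * np.log(v2s / v1s)
        disc = B * B - 4 * A * C
        sq = np.sqrt(np.maximum(disc, 0.0))
        x_lo = (-B + sq) / (2 * A)  # A < 0 flips the usual ordering
        x_hi = (-B - sq) / (2 * A)
        s1 = np.sqrt(v1s)
        s2 = np.sqrt(v2s)
        out_gen = (
            ndtr((x_hi - m2s) / s2)
            - ndtr((x_lo - m2s) / s2)
            + ndtr((x_lo - m1s) / s1)
            + 1.0
            - ndtr((x_hi - m1s) / s1)
        )
    # no real intersection: the narrow density sits entirely under the wide
    # one only in the identical limit; overlap -> 1
    out_gen = np.where(disc <= 0, 1.0, out_gen)
    out = np.where(equal, out_equal, out_gen)
    return np.clip(out, 0.0, 1.0)


def abd_score(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    min_cv: float = 1.0,
) -> tuple[float, int]:
    """Abundance similarity of a contig pair across samples.

    A sample is *effective* iff at least one of the two contigs has mean
    depth above ``min_cv`` (default 1). Per effective sample the score is
    the shared area of the two depth normals; scores combine across
    effective samples by geometric mean. Returns ``(score, nABD)``;
    ``(nan, 0)`` when no sample is effective.
    """
    mean_a = np.asarray(mean_a, float)
    mean_b = np.asarray(mean_b, float)
    if mean_a.shape != mean_b.shape:
        raise ValueError("mismatched sample counts")
    eff = (mean_a > min_cv) | (mean_b > min_cv)
    n_abd = int(eff.sum())
    if n_abd == 0:
        return float("nan"), 0
    ov = _normal_overlap(mean_a[eff], np.asarray(var_a, float)[eff],
                         mean_b[eff], np.asarray(var_b, float)[eff])
    score = float(np.exp(np.mean(np.log(np.maximum(ov, 1e-300)))))
    return min(score, 1.0), n_abd


def abd_matrix(
    mean: np.ndarray,
    var: np.ndarray,
    min_cv: float = 1.0,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise ABD scores and effective-sample counts for all contigs.

    Returns ``(score (N,N) with NaN where nABD == 0, nABD (N,N) int)``.
    Row-chunked to bound peak memory at O(chunk * N * samples).
    """
    n, s = mean.shape
    score = np.full((n, n), np.nan)
    n_abd = np.zeros((n, n), dtype=np.int32)
    above = mean > min_cv
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        eff = above[lo:hi, None, :] | above[None, :, :]  # (c, n, s)
        cnt = eff.sum(axis=2)
        logsum = np.zeros((hi - lo, n))
        for j in range(s):
            ov = _normal_overlap(
                mean[lo:hi, None, j], var[lo:hi, None, j],
                mean[None, :, j], var[None, :, j],
            )
            logsum += np.where(eff[:, :, j], np.log(np.maximum(ov, 1e-300)), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sc = np.exp(logsum / cnt)
        score[lo:hi] = np.where(cnt > 0, np.minimum(sc, 1.0), np.nan)
        n_abd[lo:hi] = cnt
    return score, n_abd


def cor_score(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Pearson correlation of two mean-depth profiles across samples.

    Undefined (NaN) with fewer than 3 samples or when either profile has
    zero variance; undefined is a value, not an error.
    """
    a = np.asarray(mean_a, float)
    b = np.asarray(mean_b, float)
    if a.shape != b.shape:
        raise ValueError("mismatched sample counts")
    if a.size < 3:
        return float("nan")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cor_matrix(mean: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of depth profiles; NaN where undefined."""
    n, s = mean.shape
    if s < 3:
        return np.full((n, n), np.nan)
    centred = mean - mean.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centred, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centred / norm[:, None]
        r = z @ z.T
    r[norm == 0, :] = np.nan
    r[:, norm == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)
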