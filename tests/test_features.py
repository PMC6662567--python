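"""Raw pairwise evidence: canonical tetramers, TNF, ABD overlap, COR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tetrabin import features
from tetrabin.features import (
    abd_score,
    canonical_tetramers,
    compute_tnf,
    cor_score,
    tnf_raw_score,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP.get(c, "N") for c in reversed(s))


class TestCanonicalTetramers:
    def test_enumeration_oracle(self):
        # independent enumeration: merge the 256 tetramers into
        # reverse-complement classes
        from itertools import product

        classes = set()
        for kmer in map("".join, product("ACGT", repeat=4)):
            classes.add(frozenset({kmer, revcomp(kmer)}))
        assert len(classes) == 136
        palindromes = [c for c in classes if len(c) == 1]
        assert len(palindromes) == 16
        assert canonical_tetramers() == sorted(min(c) for c in classes)

    def test_lexicographic_representative_and_palindrome(self):
        tets = canonical_tetramers()
        assert "AAAA" in tets and "TTTT" not in tets
        assert "ACGT" in tets  # its own reverse complement

    def test_stable_and_sorted(self):
        assert canonical_tetramers() == canonical_tetramers()
        assert canonical_tetramers() == sorted(canonical_tetramers())


class TestComputeTnf:
    def test_single_class_run(self):
        v = compute_tnf("AAAAA")
        assert v.n_kmers == 2
        assert v.freq[canonical_tetramers().index("AAAA")] == 1.0

    def test_reverse_complement_folding(self):
        v = compute_tnf("TTTT")
        assert v.freq[canonical_tetramers().index("AAAA")] == 1.0

    def test_windows_with_n_skipped(self):
        v = compute_tnf("AANAAAA")  # only the final 4 windows of AAAA region
        assert v.n_kmers == 1

    def test_too_short_gives_empty_vector(self):
        v = compute_tnf("ACG")
        assert v.n_kmers == 0 and not v.freq.any()

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=4, max_size=200))
    def test_strand_symmetry(self, seq):
        a = compute_tnf(seq)
        b = compute_tnf(revcomp(seq))
        assert a.n_kmers == b.n_kmers
        np.testing.assert_array_equal(a.freq, b.freq)

    def test_frequencies_sum_to_one(self):
        v = compute_tnf("ACGTACGGTTACGATCG" * 10)
        assert v.freq.sum() == pytest.approx(1.0)


class TestTnfRawScore:
    def test_identical_vectors_score_one(self):
        v = compute_tnf("ACGTTGCAAT" * 500)
        assert tnf_raw_score(v, v, 5000, 5000) == pytest.approx(1.0)

    def test_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(136))
        vecs = []
        for eps in [0.0, 0.005, 0.02, 0.08]:
            f = base + eps * rng.dirichlet(np.ones(136))
            f = f / f.sum()
            vecs.append(features.TNFVector(freq=f, n_kmers=1000))
        scores = [tnf_raw_score(vecs[0], v, 10000, 10000) for v in vecs]
        assert scores == sorted(scores, reverse=True)
        assert len(set(scores)) == len(scores)  # strictly decreasing
        for v in vecs[1:]:
            assert tnf_raw_score(vecs[0], v, 8000, 3000) == pytest.approx(
                tnf_raw_score(v, vecs[0], 3000, 8000)
            )

    def test_shorter_contigs_get_more_slack(self):
        # same compositional distance is judged more leniently at short lengths
        rng = np.random.default_rng(1)
        f1 = rng.dirichlet(np.ones(136))
        f2 = f1 + 0.01 * rng.dirichlet(np.ones(136))
        f2 /= f2.sum()
        a = features.TNFVector(freq=f1, n_kmers=100)
        b = features.TNFVector(freq=f2, n_kmers=100)
        assert tnf_raw_score(a, b, 1500, 1500) > tnf_raw_score(a, b, 50000, 50000)

    def test_zero_kmer_vector_is_undefined(self):
        v = compute_tnf("ACGTACGT" * 100)
        empty = features.TNFVector(freq=np.zeros(136), n_kmers=0)
        assert np.isnan(tnf_raw_score(v, empty, 800, 800))


def numeric_overlap(m1, v1, m2, v2):
    """Independent oracle: integrate min of the two normal densities."""

    def f(x):
        d1 = np.exp(-((x - m1) ** 2) / (2 * v1)) / np.sqrt(2 * np.pi * v1)
        d2 = np.exp(-((x - m2) ** 2) / (2 * v2)) / np.sqrt(2 * np.pi * v2)
        return min(d1, d2)

    lo = min(m1 - 10 * np.sqrt(v1), m2 - 10 * np.sqrt(v2))
    hi = max(m1 + 10 * np.sqrt(v1), m2 + 10 * np.sqrt(v2))
    val, _ = quad(f, lo, hi, limit=300)
    return val


class TestAbdScore:
    def test_identical_distributions_score_one(self):
        m = np.array([10.0, 25.0, 3.0])
        v = np.array([4.0, 9.0, 1.0])
        score, n = abd_score(m, v, m, v)
        assert score == pytest.approx(1.0)
        assert n == 3

    def test_distant_means_score_tiny(self):
        score, n = abd_score([10.0], [4.0], [10000.0], [400.0])
        assert n == 1
        assert score < 0.01

    def test_below_threshold_means_give_no_evidence(self):
        score, n = abd_score([0.5], [0.5], [0.5], [0.5])
        assert n == 0
        assert np.isnan(score)

    @pytest.mark.parametrize(
        "m1,v1,m2,v2",
        [
            (10.0, 4.0, 12.0, 4.0),  # equal variances
            (10.0, 4.0, 12.0, 25.0),  # unequal variances
            (5.0, 1.0, 5.0, 16.0),  # same mean, different spread
            (3.0, 0.5, 30.0, 40.0),  # far apart
        ],
    )
    def test_matches_numeric_overlap_oracle(self, m1, v1, m2, v2):
        score, _ = abd_score([m1], [v1], [m2], [v2])
        assert score == pytest.approx(numeric_overlap(m1, v1, m2, v2), abs=1e-6)

    def test_scale_consistency(self):
        # doubling means and quadrupling variances leaves overlap unchanged
        m1, v1, m2, v2 = 10.0, 4.0, 14.0, 9.0
        s1, _ = abd_score([m1], [v1], [m2], [v2])
        s2, _ = abd_score([2 * m1], [4 * v1], [2 * m2], [4 * v2])
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_geometric_mean_across_effective_samples(self):
        s1, _ = abd_score([10.0], [4.0], [12.0], [4.0])
        s2, _ = abd_score([30.0], [9.0], [31.0], [9.0])
        both, n = abd_score([10.0, 30.0], [4.0, 9.0], [12.0, 31.0], [4.0, 9.0])
        assert n == 2
        assert both == pytest.approx(np.sqrt(s1 * s2))

    def test_effective_sample_counting(self):
        # a sample counts when either contig is above the threshold
        _, n = abd_score([0.5, 5.0, 0.2], [1, 1, 1], [2.0, 0.1, 0.3], [1, 1, 1])
        assert n == 2

    def test_mismatched_sample_counts_fatal(self):
        with pytest.raises(ValueError):
            abd_score([1.0, 2.0], [1, 1], [1.0], [1])

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        mean = rng.lognormal(2, 1, (12, 3))
        var = mean + (0.3 * mean) ** 2
        score, n_abd = features.abd_matrix(mean, var)
        for i in range(12):
            for j in range(12):
                s, n = abd_score(mean[i], var[i], mean[j], var[j])
                assert n_abd[i, j] == n
                assert score[i, j] == pytest.approx(s, rel=1e-9)


class TestCorScore:
    def test_perfect_linearity(self):
        assert cor_score([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert cor_score([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        assert np.isnan(cor_score([5, 5, 5], [1, 2, 3]))

    def test_fewer_than_three_samples_undefined(self):
        assert np.isnan(cor_score([1, 2], [2, 4]))

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(4)
        mean = rng.lognormal(2, 1, (8, 4))
        mat = features.cor_matrix(mean)
        for i in range(8):
            for j in range(8):
                assert mat[i, j] == pytest.approx(
                    cor_score(mean[i], mean[j]), abs=1e-9
                )
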