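"""String-kernel values: k-mer products, naive vs dynamic-programming
agreement, normalization, the induced metric, and the length-only limit."""

import itertools
import math

import numpy as np
import pytest

from seqkernel import (
    AminoAlphabet,
    KernelParams,
    ProteinSequence,
    RatioMatrix,
    correlation_kernel,
    identity_matrix,
    k2,
    k3_naive,
    k3_recursive,
    kernel_distance,
    limit_semikernel,
    ones_matrix,
    pairwise_matrix,
)
from seqkernel.kernel import KernelOverflowError, SequenceError
from seqkernel.synthdata import random_sequence

from conftest import make_random_sequences

AB = AminoAlphabet(("A", "B"))


def seq(text, alphabet, sid="s"):
    return ProteinSequence.from_string(sid, text, alphabet)


@pytest.fixture(scope="module")
def toy_params(toy_k1):
    return KernelParams(toy_k1, beta=1.0, k_max=10)


class TestKmerKernel:
    def test_single_residue_is_k1_entry(self, toy_params):
        assert k2([0], [1], toy_params) == 1.0
        assert k2([0], [0], toy_params) == 4.0

    def test_identity_matrix_is_exact_match_indicator(self):
        params = KernelParams(identity_matrix(AB), beta=1.0, k_max=5)
        assert k2([0, 1, 0], [0, 1, 0], params) == 1.0
        assert k2([0, 1, 0], [0, 0, 0], params) == 0.0

    def test_hand_product(self, toy_params):
        # u=AB, v=AA: K1(A,A)*K1(B,A) = 4*1
        assert k2([0, 1], [0, 0], toy_params) == 4.0

    def test_length_mismatch_rejected(self, toy_params):
        with pytest.raises(SequenceError, match="mismatch"):
            k2([0, 1], [0], toy_params)


class TestNaiveKernel:
    def test_single_residue_pair(self, toy_params):
        s = seq("A", AB)
        assert k3_naive(s, s, toy_params).k3 == 4.0

    def test_matches_independent_enumeration(self, toy_params, rng):
        """Cross-check against a from-scratch k-mer enumeration written here."""
        four = AminoAlphabet(("A", "B", "C", "D"))
        vals = np.array(
            [
                [3.0, 1.0, 0.5, 1.0],
                [1.0, 2.0, 1.0, 0.5],
                [0.5, 1.0, 4.0, 1.0],
                [1.0, 0.5, 1.0, 2.0],
            ]
        )
        params = KernelParams(RatioMatrix(vals, four, 1.0), beta=1.0, k_max=3)
        s = random_sequence(8, rng, "s", four)
        t = random_sequence(8, rng, "t", four)
        expected = 0.0
        for k in (1, 2, 3):
            for i, j in itertools.product(range(8 - k + 1), repeat=2):
                prod = 1.0
                for off in range(k):
                    prod *= vals[s.residues[i + off], t.residues[j + off]]
                expected += prod
        assert k3_naive(s, t, params).k3 == pytest.approx(expected, rel=1e-12)

    def test_all_ones_matrix_reproduces_length_formula(self, rng):
        params = KernelParams(ones_matrix(), beta=1.0, k_max=6)
        s = make_random_sequences(1, rng, 10, 30)[0]
        t = make_random_sequences(1, rng, 10, 30, prefix="t")[0]
        assert k3_naive(s, t, params).k3 == pytest.approx(
            limit_semikernel(len(s), len(t), 6), rel=1e-12
        )


class TestRecursiveKernel:
    def test_agrees_with_naive_on_randomized_suite(self, sm2, rng):
        matrices = [sm2, identity_matrix()]
        for case in range(40):
            params = KernelParams(
                matrices[case % 2],
                beta=float(rng.uniform(0.05, 1.5)),
                k_max=int(rng.integers(1, 9)),
            )
            s = random_sequence(int(rng.integers(3, 40)), rng, "s")
            t = random_sequence(int(rng.integers(3, 40)), rng, "t")
            naive = k3_naive(s, t, params)
            rec = k3_recursive(s, t, params)
            assert rec.k3 == pytest.approx(naive.k3, rel=1e-9)
            np.testing.assert_allclose(rec.k3_by_k, naive.k3_by_k, rtol=1e-9)

    def test_kmax_one_single_layer(self, toy_k1):
        params = KernelParams(toy_k1, beta=1.0, k_max=1)
        s, t = seq("AAB", AB), seq("BA", AB, "t")
        assert k3_recursive(s, t, params).k3 == k3_naive(s, t, params).k3

    def test_symmetric_in_arguments(self, default_params, rng):
        s = random_sequence(25, rng, "s")
        t = random_sequence(31, rng, "t")
        assert k3_recursive(s, t, default_params).k3 == pytest.approx(
            k3_recursive(t, s, default_params).k3, rel=1e-12
        )

    def test_breakdown_sums_to_total_and_is_nonnegative(self, default_params, rng):
        s = random_sequence(40, rng, "s")
        t = random_sequence(35, rng, "t")
        value = k3_recursive(s, t, default_params)
        assert np.all(value.k3_by_k >= 0)
        assert value.k3 == pytest.approx(value.k3_by_k.sum())
        assert len(value.k3_by_k) == default_params.effective_p(40, 35)

    def test_monotone_in_kmax(self, sm2, rng):
        s = random_sequence(30, rng, "s")
        t = random_sequence(30, rng, "t")
        values = [
            k3_recursive(s, t, KernelParams(sm2, beta=0.2, k_max=k)).k3
            for k in (1, 3, 5, 10)
        ]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_overflow_raises(self):
        huge = RatioMatrix(np.full((2, 2), 1e300), AB, beta_applied=1.0)
        params = KernelParams(huge, beta=1.0, k_max=5)
        s = seq("ABABAB", AB)
        with pytest.raises(KernelOverflowError, match="beta or k_max"):
            k3_recursive(s, s, params)


class TestCorrelationKernel:
    def test_self_similarity_is_exactly_one(self, default_params, rng):
        for s in make_random_sequences(10, rng):
            assert correlation_kernel(s, s, default_params) == 1.0

    def test_equal_length_pairs_under_ones_matrix(self, rng):
        params = KernelParams(ones_matrix(), beta=1.0, k_max=10)
        s = random_sequence(60, rng, "s")
        t = random_sequence(60, rng, "t")
        assert correlation_kernel(s, t, params) == 1.0

    def test_disjoint_residues_under_identity_matrix(self):
        params = KernelParams(identity_matrix(), beta=1.0, k_max=5)
        s = ProteinSequence.from_string("s", "AAAA")
        t = ProteinSequence.from_string("t", "CCCC")
        assert correlation_kernel(s, t, params) == 0.0

    def test_small_beta_approaches_length_only_limit(self, sm2, rng):
        """As beta -> 0 the kernel sees only lengths: equal-length pairs -> 1."""
        params = KernelParams(sm2, beta=1e-6, k_max=10)
        for _ in range(5):
            n = int(rng.integers(40, 120))
            s = random_sequence(n, rng, "s")
            t = random_sequence(n, rng, "t")
            assert correlation_kernel(s, t, params) == pytest.approx(1.0, abs=1e-3)


class TestKernelDistance:
    @pytest.mark.parametrize(
        "khat,expected", [(1.0, 0.0), (0.0, math.sqrt(2)), (0.5, 1.0)]
    )
    def test_closed_forms(self, khat, expected):
        assert kernel_distance(khat) == pytest.approx(expected, abs=1e-12)

    def test_rejects_broken_kernel_values(self):
        with pytest.raises(ValueError, match="broken kernel"):
            kernel_distance(1.0 + 1e-6)

    def test_clamps_roundoff_excess(self):
        assert kernel_distance(1.0 + 1e-12) == 0.0

    def test_triangle_inequality_on_random_triples(self, default_params, rng):
        seqs = make_random_sequences(12, rng, 20, 60)
        dist = pairwise_matrix(seqs, default_params, output="distance").values
        n = len(seqs)
        for _ in range(100):
            i, j, k = rng.choice(n, size=3, replace=False)
            assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-12


class TestLimitSemikernel:
    def test_unit_lengths(self):
        assert limit_semikernel(1, 1, 10) == 1.0

    def test_hand_sum(self):
        assert limit_semikernel(5, 5, 5) == 55.0  # 25+16+9+4+1

    def test_matches_ones_matrix_kernel(self, rng):
        params = KernelParams(ones_matrix(), beta=1.0, k_max=10)
        for _ in range(5):
            s = make_random_sequences(1, rng, 5, 50)[0]
            t = make_random_sequences(1, rng, 5, 50, prefix="t")[0]
            assert k3_recursive(s, t, params).k3 == pytest.approx(
                limit_semikernel(len(s), len(t), 10), rel=1e-12
            )


class TestPairwiseMatrix:
    def test_identical_sequences_all_ones(self, default_params, rng):
        base = random_sequence(30, rng, "a")
        seqs = [
            ProteinSequence(sid, base.residues, base.alphabet)
            for sid in ("a", "b", "c")
        ]
        sim = pairwise_matrix(seqs, default_params)
        np.testing.assert_array_equal(sim.values, np.ones((3, 3)))

    def test_distance_diagonal_is_zero(self, default_params, rng):
        seqs = make_random_sequences(4, rng, 20, 40)
        dist = pairwise_matrix(seqs, default_params, output="distance")
        np.testing.assert_array_equal(np.diag(dist.values), np.zeros(4))
        assert np.max(dist.values) <= math.sqrt(2) + 1e-12

    def test_matches_pairwise_correlation_kernel(self, default_params, rng):
        seqs = make_random_sequences(5, rng, 20, 40)
        sim = pairwise_matrix(seqs, default_params)
        for i, j in itertools.combinations(range(5), 2):
            expected = correlation_kernel(seqs[i], seqs[j], default_params)
            assert sim.values[i, j] == pytest.approx(expected, rel=1e-12)
        assert np.max(np.abs(sim.values - sim.values.T)) < 1e-12

    def test_duplicate_ids_rejected(self, default_params, rng):
        seqs = make_random_sequences(2, rng, 20, 30)
        dup = ProteinSequence(seqs[0].id, seqs[1].residues, seqs[1].alphabet)
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_matrix([seqs[0], dup], default_params)
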