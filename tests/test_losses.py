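"""Loss math: softmax, cross-entropy, KL divergence, stream weighting.

Every closed-form value asserted here was computed independently (by
hand or with a brute-force per-class summation oracle) before being
frozen into the test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tsml import (ConfigurationError, InvalidInputError, cross_entropy,
                  kl_divergence, mutual_stream_loss, softmax_probs,
                  stream_loss, student_loss)

# ---------------------------------------------------------------------------
# brute-force oracles

def ce_oracle(p, true_idx):
    """-sum_c y_c log p_c with an explicit loop."""
    total = 0.0
    for c, pc in enumerate(p):
        y_c = 1.0 if c == true_idx else 0.0
        total -= y_c * np.log(max(pc, 1e-12))
    return total


def kl_oracle(a, b):
    """sum_c a_c log(a_c / b_c) with an explicit loop."""
    total = 0.0
    for ac, bc in zip(a, b):
        ac, bc = max(ac, 1e-12), max(bc, 1e-12)
        total += ac * np.log(ac / bc)
    return total


def random_probs(rng, C):
    p = rng.random(C) + 1e-3
    return p / p.sum()


# ---------------------------------------------------------------------------
# softmax

class TestSoftmax:
    def test_uniform_logits_give_uniform_probs(self):
        np.testing.assert_allclose(softmax_probs([0.0] * 6), np.full(6, 1 / 6))

    def test_two_class_value(self):
        # e/(e+1), 1/(e+1) evaluated directly
        np.testing.assert_allclose(
            softmax_probs([1.0, 0.0]), [0.73105858, 0.26894142], atol=1e-4
        )

    def test_shift_invariance(self):
        z = np.array([0.3, -1.2, 4.0, 0.0])
        np.testing.assert_allclose(softmax_probs(z), softmax_probs(z + 123.5),
                                   rtol=1e-12)

    @pytest.mark.parametrize("bad", [[np.nan, 0.0], [np.inf, 1.0]])
    def test_nonfinite_logits_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            softmax_probs(bad)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            softmax_probs([1.0])

    @settings(deadline=None, max_examples=100)
    @given(arrays(np.float64, st.integers(2, 12),
                  elements=st.floats(-50, 50)))
    def test_output_is_a_distribution(self, z):
        p = softmax_probs(z)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-6

    @settings(deadline=None, max_examples=50)
    @given(arrays(np.float64, 5, elements=st.floats(-20, 20)),
           st.floats(-100, 100))
    def test_shift_invariance_property(self, z, k):
        np.testing.assert_allclose(softmax_probs(z), softmax_probs(z + k),
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# cross entropy

class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.zeros(4)
        p[2] = 1.0
        assert cross_entropy(p, 2) == 0.0

    def test_uniform_six_classes_is_ln6(self):
        assert cross_entropy(np.full(6, 1 / 6), 3) == pytest.approx(
            1.7918, abs=1e-4
        )

    def test_quarter_probability(self):
        assert cross_entropy([0.25, 0.75], 0) == pytest.approx(1.3863, abs=1e-4)

    def test_zero_probability_clamped_finite(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="tsml.losses"):
            val = cross_entropy([0.0, 1.0], 0)
        assert np.isfinite(val)
        assert val == pytest.approx(-np.log(1e-12))
        assert any("clamped" in r.message for r in caplog.records)

    def test_batch_mean_reduction(self):
        p = np.array([[0.25, 0.75], [0.5, 0.5]])
        y = np.array([0, 1])
        expected = (ce_oracle(p[0], 0) + ce_oracle(p[1], 1)) / 2
        assert cross_entropy(p, y) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_entropy([0.5, 0.5], 2)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            C = int(rng.integers(2, 10))
            p = random_probs(rng, C)
            k = int(rng.integers(C))
            assert cross_entropy(p, k) == pytest.approx(
                ce_oracle(p, k), abs=1e-9
            )


# ---------------------------------------------------------------------------
# KL divergence

class TestKLDivergence:
    def test_identity_is_zero(self):
        p = [0.2, 0.3, 0.5]
        assert kl_divergence(p, p) == 0.0

    def test_hand_value(self):
        # 0.5 ln 2 + 0.5 ln(2/3) by hand
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.1438, abs=1e-4
        )

    def test_asymmetry(self):
        a, b = [0.9, 0.1], [0.5, 0.5]
        assert kl_divergence(a, b) != pytest.approx(kl_divergence(b, a), abs=1e-6)

    def test_mismatched_length_rejected(self):
        with pytest.raises(InvalidInputError):
            kl_divergence([0.5, 0.5], [0.2, 0.3, 0.5])

    def test_nonnegative_and_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            C = int(rng.integers(2, 10))
            a, b = random_probs(rng, C), random_probs(rng, C)
            val = kl_divergence(a, b)
            assert val >= 0.0  # Gibbs' inequality
            assert val == pytest.approx(kl_oracle(a, b), abs=1e-9)


# ---------------------------------------------------------------------------
# student and stream losses

class TestStudentLoss:
    def test_perfect_agreeing_students_zero_loss(self):
        p = np.zeros(6)
        p[1] = 1.0
        out = student_loss(p, p, 1)
        assert out.total == 0.0

    def test_uniform_pair_reduces_to_ln6(self):
        p = np.full(6, 1 / 6)
        out = student_loss(p, p, 0)
        assert out.kl == 0.0
        assert out.total == pytest.approx(1.7918, abs=1e-4)

    def test_sum_of_component_oracles(self):
        out = student_loss([0.25, 0.75], [0.5, 0.5], 0)
        assert out.ce == pytest.approx(1.3863, abs=1e-3)
        assert out.kl == pytest.approx(0.1438, abs=1e-3)
        assert out.total == pytest.approx(1.5301, abs=1e-3)

    def test_kl_weight_zero_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(3)
        p_self, p_peer = random_probs(rng, 5), random_probs(rng, 5)
        out = student_loss(p_self, p_peer, 2, kl_weight=0.0)
        assert out.total == cross_entropy(p_self, 2)
        assert out.kl == 0.0

    def test_direction_flag_changes_the_kl_term(self):
        rng = np.random.default_rng(5)
        a, b = random_probs(rng, 4), random_probs(rng, 4)
        fwd = student_loss(a, b, 0, kl_direction="peer_to_self")
        rev = student_loss(a, b, 0, kl_direction="self_to_peer")
        assert fwd.kl == pytest.approx(kl_oracle(b, a), abs=1e-9)
        assert rev.kl == pytest.approx(kl_oracle(a, b), abs=1e-9)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ConfigurationError):
            student_loss([0.5, 0.5], [0.5, 0.5], 0, kl_direction="sideways")


class TestStreamLoss:
    def test_midpoint(self):
        assert stream_loss(2.0, 4.0, 0.5) == 3.0

    @pytest.mark.parametrize("alpha,expected", [(0.0, 2.0), (1.0, 4.0)])
    def test_endpoints_exact(self, alpha, expected):
        assert stream_loss(2.0, 4.0, alpha) == expected

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            stream_loss(1.0, 1.0, 1.5)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0, 1))
    def test_linearity(self, l1, l2, alpha):
        assert stream_loss(l1, l2, alpha) == pytest.approx(
            (1 - alpha) * l1 + alpha * l2, abs=1e-12
        )

    def test_breakdown_invariants(self):
        rng = np.random.default_rng(11)
        p1, p2 = random_probs(rng, 6), random_probs(rng, 6)
        br = mutual_stream_loss(p1, p2, 2, alpha=0.3)
        assert br.student1.total == br.student1.ce + br.student1.kl
        assert br.stream == pytest.approx(
            0.7 * br.student1.total + 0.3 * br.student2.total, abs=1e-12
        )
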