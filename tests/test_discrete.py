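"""Unit and property tests for the finite-alphabet probability core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unionpid import (
    JointPMF,
    compose_ci,
    conditional_channel,
    conditional_mutual_information,
    entropy,
    marginalize,
    merge_variables,
    mutual_information,
)
from unionpid.zoo import make_distribution, random_joint

TOL = 1e-9


class TestJointPMF:
    def test_rejects_bad_mass(self):
        with pytest.raises(ValueError, match="sum"):
            JointPMF(("A",), {"A": (0, 1)}, np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="negative"):
            JointPMF(("A",), {"A": (0, 1)}, np.array([1.2, -0.2]))

    def test_rejects_symbol_outside_alphabet(self):
        with pytest.raises(KeyError):
            JointPMF.from_outcomes(
                ("A", "B"), {(0, 2): 1.0},
                alphabets={"A": (0, 1), "B": (0, 1)},
            )


class TestMarginalize:
    def test_xor_single_source_is_uniform(self, xor):
        m = marginalize(xor, "Y1")
        assert np.allclose(m.probs, [0.5, 0.5])

    def test_target_marginal_of_copy_channel_system(self, t_eq_y1):
        m = marginalize(t_eq_y1, "T")
        assert np.allclose(m.probs, [0.5, 0.5])

    def test_keep_all_is_identity(self, boom):
        m = marginalize(boom, boom.variables)
        assert np.allclose(m.probs, boom.probs)

    def test_unknown_variable_raises(self, xor):
        with pytest.raises(KeyError):
            marginalize(xor, "nope")


class TestConditionalChannel:
    def test_identity_channel_when_target_copies_source(self, t_eq_y1):
        K = conditional_channel(t_eq_y1, "T", "Y1")
        assert np.allclose(K.matrix, np.eye(2))

    def test_xor_channels_are_uniform(self, xor):
        K = conditional_channel(xor, "T", "Y1")
        assert np.allclose(K.matrix, 0.25 + 0.25 * np.ones((2, 2)))

    def test_boom_k1_rows(self, boom):
        K = conditional_channel(boom, "T", "Y1")
        expected = np.array([[1, 0, 0], [0.5, 0.5, 0], [1 / 3, 0, 2 / 3]])
        assert np.allclose(K.matrix, expected)

    def test_zero_probability_row_excluded(self):
        pmf = JointPMF.from_outcomes(
            ("T", "Y"), {(0, 0): 0.5, (0, 1): 0.5, (1, 0): 0.0},
            alphabets={"T": (0, 1), "Y": (0, 1)},
        )
        K = conditional_channel(pmf, "T", "Y")
        assert K.row_labels == (0,)


class TestInformation:
    def test_entropy_closed_forms(self, xor):
        assert entropy(xor, "Y1") == pytest.approx(1.0, abs=TOL)
        det = JointPMF.from_outcomes(("A",), {(0,): 1.0}, alphabets={"A": (0, 1)})
        assert entropy(det, "A") == pytest.approx(0.0, abs=TOL)
        u3 = JointPMF(("A",), {"A": (0, 1, 2)}, np.full(3, 1 / 3))
        assert entropy(u3, "A") == pytest.approx(math.log2(3), abs=TOL)

    @pytest.mark.parametrize(
        "name,A,expected",
        [
            ("XOR", ("Y1", "Y2"), 1.0),
            ("AND", ("Y1", "Y2"), 0.8112781244591328),
            ("TWEAKED_COPY", ("Y1", "Y2"), math.log2(3)),
            ("TWEAKED_COPY", ("Y1",), 0.9182958340544896),
        ],
    )
    def test_mutual_information_printed_values(self, name, A, expected):
        pmf = make_distribution(name)
        assert mutual_information(pmf, A, "T") == pytest.approx(expected, abs=1e-9)

    def test_cmi_xor_bijection(self, xor):
        # given Y1, the map Y2 -> T is a bijection
        assert conditional_mutual_information(xor, ("Y2",), ("T",), ("Y1",)) \
            == pytest.approx(1.0, abs=TOL)

    def test_cmi_vanishes_under_conditional_independence(self, t_eq_y1):
        # Y2 is independent noise: I(Y2; T | Y1) = 0
        assert conditional_mutual_information(t_eq_y1, ("Y2",), ("T",), ("Y1",)) \
            == pytest.approx(0.0, abs=TOL)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_chain_rule_and_symmetry_random(self, seed):
        pmf = random_joint([2, 3, 2], seed=seed, concentration=1.0)
        lhs = mutual_information(pmf, ("Y1", "Y2"), "T")
        rhs = mutual_information(pmf, "Y1", "T") + conditional_mutual_information(
            pmf, ("Y2",), ("T",), ("Y1",)
        )
        assert lhs == pytest.approx(rhs, abs=TOL)
        assert mutual_information(pmf, "Y1", ("T", "Y2")) == pytest.approx(
            mutual_information(pmf, ("T", "Y2"), "Y1"), abs=TOL
        )
        i = mutual_information(pmf, "Y1", "T")
        assert -TOL <= i <= min(entropy(pmf, "Y1"), entropy(pmf, "T")) + TOL

    def test_overlap_rejected(self, xor):
        with pytest.raises(ValueError, match="overlap"):
            mutual_information(xor, ("Y1",), ("Y1", "T"))


class TestComposeCI:
    def test_adapted_reducedor_matches_printed_q(self):
        # the composed q is independent of r and has masses (1/2, 1/8 x4)
        for r in (0.0, 0.5, 1.0):
            pmf = make_distribution("ADAPTED_REDUCEDOR", r=r)
            q = compose_ci(pmf, [("Y1",), ("Y2",)])
            expected = {
                (0, 0, 0): 0.5,
                (1, 0, 0): 0.125, (1, 0, 1): 0.125,
                (1, 1, 0): 0.125, (1, 1, 1): 0.125,
            }
            got = dict(q.outcomes())
            assert set(got) == set(expected)
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, abs=1e-12)

    def test_ci_distribution_is_fixed_point(self, t_eq_y1):
        # Y1 and Y2 already conditionally independent given T: q = p
        q = compose_ci(t_eq_y1, [("Y1",), ("Y2",)])
        assert np.allclose(q.probs, t_eq_y1.probs, atol=1e-12)

    def test_xor_composition_is_uniform(self, xor):
        q = compose_ci(xor, [("Y1",), ("Y2",)])
        assert np.allclose(q.probs, 1 / 8)

    def test_single_full_block_recovers_joint(self, boom):
        q = compose_ci(boom, [("Y1", "Y2")])
        ref = marginalize(boom, ("T", "Y1", "Y2"))
        assert np.allclose(q.probs, ref.probs, atol=1e-12)

    def test_target_marginal_preserved_and_normalized(self):
        pmf = random_joint([3, 2, 2], seed=7, concentration=0.5)
        q = compose_ci(pmf, [("Y1",), ("Y2",)])
        assert q.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(
            marginalize(q, "T").probs, marginalize(pmf, "T").probs, atol=1e-12
        )

    def test_overlapping_blocks_rejected(self, xor):
        with pytest.raises(ValueError, match="more than one block"):
            compose_ci(xor, [("Y1",), ("Y1", "Y2")])


class TestMergeVariables:
    def test_merge_preserves_information(self):
        t4 = make_distribution("TARGETMONO_A")
        merged = merge_variables(t4, ("T", "Z"), "TZ")
        assert mutual_information(merged, ("Y1", "Y2"), "TZ") == pytest.approx(
            mutual_information(t4, ("Y1", "Y2"), ("T", "Z")), abs=TOL
        )
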