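"""Tests for the conditional-independence union information and synergy."""

import numpy as np
import pytest

from unionpid import (
    SourceCollection,
    admissible_partitions,
    bivariate_atoms_ci,
    compose_ci,
    duplicate_variable,
    make_distribution,
    marginalize,
    merge_variables,
    mutual_information,
    normalize_sources,
    random_joint,
    synergy_ci,
    union_information_ci,
)

ABS = 1e-9


class TestNormalizeSources:
    def test_duplicate_variable_source_removed(self):
        pmf = make_distribution("ANDDUPLICATE")
        out = normalize_sources(pmf, SourceCollection.of("Y1", "Y2", "Y3"))
        assert out.sources == (frozenset({"Y1"}), frozenset({"Y2"}))

    def test_subset_source_removed(self, xor):
        out = normalize_sources(xor, SourceCollection.of("Y1", ("Y1", "Y2")))
        assert out.sources == (frozenset({"Y1", "Y2"}),)

    def test_independent_sources_unchanged(self, xor):
        coll = SourceCollection.of("Y1", "Y2")
        assert normalize_sources(xor, coll).sources == coll.sources

    def test_overlapping_coalitions_kept(self):
        # each coalition is reconstructible from the union of the others, but
        # none is a function of any single other source: all must survive
        pmf = random_joint([2, 2, 2, 2], seed=5)
        coll = SourceCollection.of(("Y1", "Y2"), ("Y1", "Y3"), ("Y2", "Y3"))
        assert normalize_sources(pmf, coll).sources == coll.sources

    def test_coalition_source_not_removed_when_jointly_determined(self):
        # Y3 = Y1 xor Y2 is a function of the PAIR only; it stays
        pmf = make_distribution("XORLOSES")
        coll = SourceCollection.of("Y1", "Y2", "Y3")
        assert normalize_sources(pmf, coll).sources == coll.sources


class TestAdmissiblePartitions:
    def test_coalition_plus_singleton_gives_two(self):
        fam = admissible_partitions(SourceCollection.of(("Y1", "Y2"), "Y3"))
        assert len(fam.partitions) == 2

    def test_pairwise_coalitions_give_four(self):
        fam = admissible_partitions(
            SourceCollection.of(("Y1", "Y2"), ("Y1", "Y3"), ("Y2", "Y3"))
        )
        assert len(fam.partitions) == 4

    def test_singletons_give_one(self):
        fam = admissible_partitions(SourceCollection.of("Y1", "Y2"))
        assert fam.partitions == ((frozenset({"Y1"}), frozenset({"Y2"})),)


class TestUnionInformation:
    def test_and_value(self, and_dist):
        res = union_information_ci(and_dist, SourceCollection.of("Y1", "Y2"))
        assert res.value == pytest.approx(0.5408520829727554, abs=1e-9)
        assert not res.clipped

    def test_reducedor_clips_at_true_information(self):
        pmf = make_distribution("ADAPTED_REDUCEDOR", r=0.75)
        res = union_information_ci(pmf, SourceCollection.of("Y1", "Y2"))
        assert res.clipped
        assert res.value == pytest.approx(
            mutual_information(pmf, ("Y1", "Y2"), "T"), abs=ABS
        )

    def test_single_source_is_self_redundancy(self, and_dist):
        res = union_information_ci(and_dist, SourceCollection.of("Y1"))
        assert res.value == pytest.approx(
            mutual_information(and_dist, "Y1", "T"), abs=ABS
        )


class TestSynergy:
    @pytest.mark.parametrize(
        "name,expected",
        [("XOR", 1.0), ("COPY", 0.0), ("AND", 0.2704260414863775)],
    )
    def test_printed_synergies(self, name, expected):
        assert synergy_ci(make_distribution(name)) == pytest.approx(expected, abs=1e-9)

    def test_markov_chain_targets(self):
        ch = make_distribution("COPYXOR_CHAIN")
        p1 = marginalize(ch, ("T1", "Y1", "Y2")).with_target("T1")
        p2 = marginalize(ch, ("T2", "Y1", "Y2")).with_target("T2")
        assert synergy_ci(p1) == pytest.approx(0.0, abs=ABS)
        assert synergy_ci(p2) == pytest.approx(1.0, abs=ABS)

    def test_duplicate_source_handled_by_normalization(self):
        pmf = make_distribution("ANDDUPLICATE")
        naive_q = compose_ci(pmf, [("Y1",), ("Y2",), ("Y3",)])
        naive = mutual_information(naive_q, ("Y1", "Y2", "Y3"), "T")
        assert naive == pytest.approx(0.6810015706843329, abs=1e-9)
        assert synergy_ci(pmf) == pytest.approx(0.2704260414863775, abs=1e-9)

    def test_single_source_synergy_is_cmi(self):
        # S(Y1 -> T) = I(Y2; T | Y1) via self-redundancy and the chain rule
        pmf = random_joint([2, 2, 3], seed=11)
        from unionpid import conditional_mutual_information

        s = synergy_ci(pmf, SourceCollection.of("Y1"))
        assert s == pytest.approx(
            conditional_mutual_information(pmf, ("Y2",), ("T",), ("Y1",)), abs=ABS
        )


class TestBivariateAtoms:
    def test_xor_pure_synergy(self, xor):
        atoms = bivariate_atoms_ci(xor)
        assert (atoms.R, atoms.U1, atoms.U2, atoms.S) == pytest.approx(
            (0, 0, 0, 1), abs=ABS
        )

    def test_and_atoms_from_union_system(self, and_dist):
        atoms = bivariate_atoms_ci(and_dist)
        assert atoms.S == pytest.approx(0.2704260414863775, abs=1e-9)
        assert atoms.U1 == pytest.approx(0.2295739585136225, abs=1e-9)
        assert atoms.U2 == pytest.approx(atoms.U1, abs=ABS)
        assert atoms.R == pytest.approx(0.0817041659455104, abs=1e-9)
        assert atoms.total == pytest.approx(
            mutual_information(and_dist, ("Y1", "Y2"), "T"), abs=ABS
        )

    def test_unique_information_channel(self, t_eq_y1):
        atoms = bivariate_atoms_ci(t_eq_y1)
        assert (atoms.R, atoms.U1, atoms.U2, atoms.S) == pytest.approx(
            (0, 1, 0, 0), abs=ABS
        )

    def test_atoms_nonnegative_on_random_fixtures(self):
        for seed in range(25):
            pmf = random_joint([2, 2, 2], seed=seed, concentration=0.8)
            atoms = bivariate_atoms_ci(pmf)
            for v in (atoms.R, atoms.U1, atoms.U2, atoms.S):
                assert v >= -1e-9
            assert atoms.total == pytest.approx(
                mutual_information(pmf, ("Y1", "Y2"), "T"), abs=ABS
            )


class TestProperties:
    def test_conditional_independence_implies_zero_synergy(self):
        # compose any fixture's own CI surrogate: its synergy must vanish
        for seed in range(10):
            pmf = random_joint([2, 3, 2], seed=seed)
            q = compose_ci(pmf, [("Y1",), ("Y2",)])
            assert synergy_ci(q) == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_predictor_invariance(self):
        for seed in range(10):
            pmf = random_joint([2, 2, 3], seed=seed, concentration=0.7)
            base = synergy_ci(pmf)
            aug = duplicate_variable(pmf, "Y2", "Y3")
            assert synergy_ci(aug) == pytest.approx(base, abs=1e-9)

    def test_target_monotonicity_counterexample(self):
        t5 = make_distribution("TARGETMONO_B")
        u_t = union_information_ci(
            marginalize(t5, ("T", "Y1", "Y2")).with_target("T"),
            SourceCollection.of("Y1", "Y2"),
        ).value
        u_tz = union_information_ci(
            merge_variables(t5, ("T", "Z"), "TZ").with_target("TZ"),
            SourceCollection.of("Y1", "Y2"),
        ).value
        assert u_t == pytest.approx(0.91, abs=0.005)
        assert u_tz == pytest.approx(0.90, abs=0.005)
        assert u_t > u_tz
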