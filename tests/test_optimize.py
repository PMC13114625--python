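import numpy as np
import pytest

from mininf import DiscreteJointDistribution, VariableSet
from mininf.optimize import (MarginalFamily, MinInfTerm, brute_force_mininf,
                             extend_with_conditional, extend_with_cpt, mininf,
                             unique_information, verify_dp_mininf)

from conftest import make_xor, random_distribution


def make_copy_target() -> DiscreteJointDistribution:
    """Target (Z1, Z2) = (D1, D2) with D1, D2 independent uniform bits."""
    p = np.zeros((2, 2, 2, 2))
    for d1 in range(2):
        for d2 in range(2):
            p[d1, d2, d1, d2] = 0.25
    return DiscreteJointDistribution(
        VariableSet(["Z1", "Z2", "D1", "D2"], [2, 2, 2, 2]), p)


class TestCompositionHelpers:
    def test_extend_with_cpt_reproduces_enumeration(self, rng):
        base = random_distribution(["A", "B"], rng)
        cpt = rng.dirichlet(np.ones(2), size=(2, 2))
        joint = extend_with_cpt(base, "C", 2, ["A", "B"], cpt)
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    assert joint.probs[a, b, c] == pytest.approx(
                        base.probs[a, b] * cpt[a, b, c])

    def test_extend_with_conditional_preserves_joint_marginal(self, rng):
        base = random_distribution(["A", "B"], rng)
        source = random_distribution(["A", "C"], rng)
        joint = extend_with_conditional(base, source, ["C"], ["A"])
        assert joint.marginalize(["A", "B"]).allclose(base)
        # C drawn from P(C|A) only, so C ⊥ B | A by construction
        assert joint.is_conditionally_independent(["C"], ["B"], ["A"])


class TestMarginalFamily:
    def test_redundant_subsets_collapsed(self, rng):
        d = random_distribution(["A", "B", "C"], rng)
        fam = MarginalFamily(d, [["A", "B"], ["A"], ["A", "B", "C"]])
        assert fam.preserved == [frozenset({"A", "B", "C"})]
        assert fam.is_singleton

    def test_reference_is_feasible(self, rng):
        d = random_distribution(["A", "B", "C"], rng)
        fam = MarginalFamily(d, [["A", "B"], ["B", "C"]])
        assert fam.violation(fam.reference_member().probs.ravel()) < 1e-12

    def test_ipf_projection_hits_the_constraints(self, rng):
        d = random_distribution(["A", "B", "C"], rng)
        fam = MarginalFamily(d, [["A", "B"], ["B", "C"]])
        q = fam.ipf_project(rng.dirichlet(np.ones(8)))
        assert fam.violation(q) < 1e-8

    def test_scope_must_be_covered(self, rng):
        d = random_distribution(["A", "B"], rng)
        with pytest.raises(ValueError):
            MarginalFamily(d, [["A", "Q"]])


class TestMinInf:
    def test_singleton_family_returns_reference_information(self, rng):
        d = random_distribution(["A", "B", "C"], rng)
        fam = MarginalFamily(d, [["A", "B", "C"]])
        res = mininf(MinInfTerm(fam, ["A"], ["B"], ["C"]))
        assert res.value == pytest.approx(
            d.conditional_mutual_information(["A"], ["B"], ["C"]), abs=1e-12)
        assert res.status == "convex-certified"
        assert res.argmin.allclose(d)

    def test_only_single_marginals_preserved_reaches_zero(self, rng):
        d = random_distribution(["Z", "D"], rng)
        fam = MarginalFamily(d, [["Z"], ["D"]])
        res = mininf(MinInfTerm(fam, ["Z"], ["D"]))
        assert res.value == 0.0  # the product member is feasible

    def test_result_invariants(self, rng):
        for k in range(10):
            d = random_distribution(["Z", "D1", "D2"], rng)
            fam = MarginalFamily(d, [["Z", "D1"], ["Z", "D2"]])
            term = MinInfTerm(fam, ["Z"], ["D1"], ["D2"])
            res = mininf(term, seed=k)
            ref_value = d.conditional_mutual_information(["Z"], ["D1"], ["D2"])
            assert res.constraint_violation <= 1e-8
            assert res.value <= ref_value + 1e-8
            assert res.value >= -1e-10

    def test_solver_matches_oracle_on_random_instances(self, rng):
        for k in range(6):
            d = random_distribution(["Z", "D1", "D2"], rng)
            fam = MarginalFamily(d, [["Z", "D1"], ["Z", "D2"]])
            term = MinInfTerm(fam, ["Z"], ["D1"], ["D2"])
            solved = mininf(term, seed=k).value
            oracle = brute_force_mininf(term, samples=20_000, seed=k)
            assert solved == pytest.approx(oracle, abs=1e-3)
            assert oracle >= solved - 1e-6  # oracle upper-bounds the min

    def test_oracle_monotone_in_samples(self, rng):
        d = random_distribution(["Z", "D1", "D2"], rng)
        fam = MarginalFamily(d, [["Z", "D1"], ["Z", "D2"]])
        term = MinInfTerm(fam, ["Z"], ["D1"], ["D2"])
        v_small = brute_force_mininf(term, samples=2_000, seed=7)
        v_large = brute_force_mininf(term, samples=8_000, seed=7)
        assert v_large <= v_small + 1e-12

    def test_oracle_scope_limit(self, rng):
        d = random_distribution(list("ABCDE"), rng)
        fam = MarginalFamily(d, [list("ABCD"), list("BCDE")])
        with pytest.raises(ValueError):
            brute_force_mininf(MinInfTerm(fam, ["A"], ["E"]), samples=10)


class TestUniqueInformation:
    def test_full_redundancy_is_zero(self):
        # D1 = D2 = Z: the preserved marginals force the copies in every
        # member, so the conditional information vanishes
        p = np.zeros((2, 2, 2))
        p[0, 0, 0] = p[1, 1, 1] = 0.5
        d = DiscreteJointDistribution(VariableSet(["Z", "D1", "D2"], [2] * 3), p)
        res = unique_information(d, ["Z"], ["D1"], ["D2"])
        assert res.value == pytest.approx(0.0, abs=1e-9)

    def test_xor_has_no_unique_information(self):
        res = unique_information(make_xor(("Z", "D1", "D2")),
                                 ["Z"], ["D1"], ["D2"])
        assert res.value == pytest.approx(0.0, abs=1e-9)

    def test_copy_carries_one_unique_bit(self):
        res = unique_information(make_copy_target(), ["Z1", "Z2"],
                                 ["D1"], ["D2"])
        assert res.value == pytest.approx(1.0, abs=1e-7)
        assert res.status == "convex-certified"

    def test_sandwich_bounds_on_random_distributions(self, rng):
        for k in range(15):
            names = ["Z", "D1", "D2"] + (["O"] if k % 2 else [])
            d = random_distribution(names, rng)
            o1 = ["O"] if "O" in names else []
            res = unique_information(d, ["Z"], ["D1"], ["D2"], o1, seed=k)
            hi = min(d.conditional_mutual_information(["Z"], ["D1"], o1),
                     d.conditional_mutual_information(["Z"], ["D1"],
                                                      ["D2"] + o1))
            assert -1e-10 <= res.value <= hi + 2e-6

    def test_monotone_in_predictor_argument(self, rng):
        # Lemma-style monotonicity: UI(Z; {D,D'} \\ D2) >= UI(Z; D \\ D2),
        # checked by seeding the smaller problem with the projected argmin
        for k in range(8):
            d = random_distribution(["Z", "D", "Dp", "D2"], rng)
            big = unique_information(d, ["Z"], ["D", "Dp"], ["D2"], seed=k)
            small = unique_information(
                d, ["Z"], ["D"], ["D2"], seed=k,
                extra_starts=[big.argmin.marginalize(["Z", "D", "D2"])])
            assert big.value >= small.value - 2e-6


class TestDataProcessing:
    def _markov_instance(self, rng):
        base = random_distribution(["Z", "D", "O", "F"], rng)
        kern = random_distribution(["D", "O", "Dp"], rng)
        return extend_with_conditional(base, kern, ["Dp"], ["D", "O"])

    def test_unique_information_dp_equality_and_inequality(self, rng):
        # Lemma: Z ⊥ D' | D,O1 gives UI(Z;{D,D'}\\D2|O1) == UI(Z;D\\D2|O1)
        #        >= UI(Z;D'\\D2|O1); here O1 = O and D2 = F
        for k in range(5):
            p = self._markov_instance(rng)
            small = unique_information(p, ["Z"], ["D"], ["F"], ["O"], seed=k)
            lift = extend_with_conditional(small.argmin, p, ["Dp"], ["D", "O"])
            big = unique_information(p, ["Z"], ["D", "Dp"], ["F"], ["O"],
                                     seed=k, extra_starts=[lift])
            # cross-seed both ways so the equality is checked at solver
            # accuracy rather than at the mercy of either local solve
            small = unique_information(
                p, ["Z"], ["D"], ["F"], ["O"], seed=k,
                extra_starts=[small.argmin,
                              big.argmin.marginalize(["Z", "D", "F", "O"])])
            lift = extend_with_conditional(small.argmin, p, ["Dp"], ["D", "O"])
            big = unique_information(p, ["Z"], ["D", "Dp"], ["F"], ["O"],
                                     seed=k,
                                     extra_starts=[lift, big.argmin])
            other = unique_information(
                p, ["Z"], ["Dp"], ["F"], ["O"], seed=k,
                extra_starts=[lift.marginalize(["Z", "Dp", "F", "O"])])
            assert big.value == pytest.approx(small.value, abs=2e-6)
            assert other.value <= small.value + 2e-6

    def test_verify_dp_mininf_on_constructed_distributions(self, rng):
        for k in range(5):
            p = self._markov_instance(rng)
            rep = verify_dp_mininf(p, "Z", "D", "Dp", E=("O",), E2=("F",),
                                   O=[("O",)], seed=k)
            assert rep.equality_holds and rep.dp_holds

    def test_exact_copy_gives_equal_minima(self, rng):
        base = random_distribution(["Z", "D", "O"], rng)
        copy_cpt = np.eye(2).reshape(2, 2)
        p = extend_with_cpt(base, "Dp", 2, ["D"], copy_cpt)
        rep = verify_dp_mininf(p, "Z", "D", "Dp", E=("O",), O=[("O",)])
        assert rep.min_dd == pytest.approx(rep.min_d, abs=2e-6)
        assert rep.min_dp == pytest.approx(rep.min_d, abs=2e-6)

    def test_constant_dp_gives_zero_third_minimum(self, rng):
        base = random_distribution(["Z", "D", "O"], rng)
        const_cpt = np.tile([1.0, 0.0], (2, 1)).reshape(2, 2)
        p = extend_with_cpt(base, "Dp", 2, ["D"], const_cpt)
        rep = verify_dp_mininf(p, "Z", "D", "Dp", E=("O",), O=[("O",)])
        assert rep.min_dp == pytest.approx(0.0, abs=1e-9)
        assert rep.min_dp <= rep.min_d + 2e-6

    def test_precondition_failure_reports_the_violation(self, rng):
        d = random_distribution(["Z", "D", "Dp", "O"], rng)
        with pytest.raises(ValueError, match="precondition"):
            verify_dp_mininf(d, "Z", "D", "Dp", E=("O",), O=[("O",)])

    def test_family_nesting_monotonicity(self, rng):
        # more preserved marginals -> a larger (or equal) minimum
        for k in range(5):
            d = random_distribution(["Z", "D1", "D2"], rng)
            loose = MarginalFamily(d, [["Z", "D1"]])
            tight = MarginalFamily(d, [["Z", "D1"], ["Z", "D2"]],
                                   scope=["Z", "D1", "D2"])
            t_loose = MinInfTerm(loose, ["Z"], ["D1"])
            t_tight = MinInfTerm(tight, ["Z"], ["D1"], ["D2"])
            v_tight = mininf(t_tight, seed=k).value
            # seed the looser problem with the tight argmin's projection
            v_loose = mininf(
                MinInfTerm(MarginalFamily(d, [["Z", "D1"]],
                                          scope=["Z", "D1", "D2"]),
                           ["Z"], ["D1"], ["D2"]),
                seed=k, extra_starts=[mininf(t_tight, seed=k).argmin]).value
            assert v_tight >= v_loose - 1e-8
            del t_loose
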