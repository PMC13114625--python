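import numpy as np
import pytest

from mininf import (ChainPartition, Group, GroupCollection, ICScenario,
                    InstrumentalSpec, MechanismSpec, build_chain_decomposition,
                    eval_combined, eval_gd1, eval_ic,
                    eval_mininf_instrumental, eval_standard_instrumental,
                    eval_unique_instrumental, figure_structure,
                    plan_from_independencies, sample_scm,
                    violating_distribution)

from conftest import make_independent_bits, random_distribution


def scm_draw(figname, seed):
    fig = figure_structure(figname)
    joint = sample_scm(fig.dag, MechanismSpec(seed=seed))
    obs = joint.marginalize([n for n in joint.variables.names
                             if n not in fig.dag.hidden])
    return fig, joint, obs


def spec_of(fig):
    roles = {k: v for k, v in fig.roles.items()
             if k in ("z", "x", "y", "b0", "b1", "b2", "u", "y1", "y2", "ybar")}
    return InstrumentalSpec(**roles)


class TestStandardInstrumental:
    def test_independent_variables_leave_full_entropy_slack(self, rng):
        d = make_independent_bits(("Z", "X", "Y"))
        r = eval_standard_instrumental(
            d, InstrumentalSpec(z=("Z",), x=("X",), y=("Y",)))
        assert r.slack == pytest.approx(1.0)  # H(X)
        assert not r.violated

    def test_two_bit_relay_violates_by_one_bit(self):
        case = violating_distribution("two-bit-relay")
        r = case.evaluate()
        assert r.upper_bound == pytest.approx(1.0)
        assert [t.value for t in r.terms] == pytest.approx([1.0, 1.0])
        assert r.slack == pytest.approx(-1.0)
        assert r.violated

    def test_causally_fulfilled_on_fig1A_draws(self):
        for seed in range(15):
            fig, _, obs = scm_draw("fig1A", seed)
            r = eval_standard_instrumental(obs, spec_of(fig))
            assert r.slack >= -1e-9

    def test_role_overlap_rejected(self):
        with pytest.raises(ValueError):
            InstrumentalSpec(z=("Z",), x=("Z",), y=("Y",))


class TestUniqueInstrumental:
    def test_empty_reference_reduces_to_standard(self, rng):
        d = random_distribution(["Z", "X", "Y", "W"], rng)
        spec_u = InstrumentalSpec(z=("Z",), x=("X",), y=("Y",), b0=("W",),
                                  b1=("W",), b2=())
        spec_s = InstrumentalSpec(z=("Z",), x=("X",), y=("Y",), b0=("W",))
        ru = eval_unique_instrumental(d, spec_u)
        rs = eval_standard_instrumental(d, spec_s)
        assert ru.slack == pytest.approx(rs.slack, abs=1e-8)

    def test_relay_with_independent_reference_still_violates(self):
        case = violating_distribution("two-bit-relay-W")
        r = case.evaluate()
        assert r.slack <= -1.0 + 1e-6
        assert r.violated

    def test_causally_fulfilled_on_fig1B_draws(self):
        for seed in range(10):
            fig, _, obs = scm_draw("fig1B", seed)
            r = eval_unique_instrumental(obs, spec_of(fig))
            assert r.slack >= -1e-5

    def test_subsumption_by_multivariate_instrument_on_fig1B(self):
        # H(X|Z,W) >= I(Z;Y|X) is tighter than both the B0=∅ standard test
        # and the B0=W unique-information test
        for seed in range(8):
            fig, _, obs = scm_draw("fig1B", seed)
            i_zy_x = obs.conditional_mutual_information(["Z"], ["Y"], ["X"])
            slack15 = obs.conditional_entropy(["X"], ["Z", "W"]) - i_zy_x
            slack8 = obs.conditional_entropy(["X"], ["Z"]) - i_zy_x
            ui = eval_unique_instrumental(obs, spec_of(fig))
            slack11 = ui.slack
            assert slack15 <= slack8 + 1e-10
            assert slack15 <= slack11 + 2e-6

    def test_upper_bound_invariant_under_instrument_exchange(self, rng):
        d = random_distribution(["Z", "X", "Y", "W"], rng)
        h1 = d.conditional_entropy(["X"], ["Z", "W"])
        # standard with B0=W minus I(Z;X|W) equals H(X|Z,W) too
        r = eval_standard_instrumental(
            d, InstrumentalSpec(z=("Z",), x=("X",), y=("Y",), b0=("W",)))
        assert r.upper_bound - r.terms[0].value == pytest.approx(h1, abs=1e-12)

    def test_causally_fulfilled_on_fig1C_draws(self):
        for seed in range(8):
            fig, _, obs = scm_draw("fig1C", seed)
            r = eval_unique_instrumental(obs, spec_of(fig))
            assert r.slack >= -1e-5


class TestChainDecomposition:
    def test_single_part_degenerate(self):
        fig, joint, _ = scm_draw("fig1A", 0)
        spec = spec_of(fig)
        terms = build_chain_decomposition(joint, spec, ChainPartition([("Z",)]))
        assert len(terms) == 2
        assert terms[1].value == pytest.approx(
            joint.conditional_mutual_information(["Z"], ["U"], ["W", "X"]),
            abs=1e-12)

    @pytest.mark.parametrize("figname,b0", [("fig2A", ("W1",)),
                                            ("fig2C", ("W3",))])
    def test_partition_order_does_not_change_the_sum(self, figname, b0):
        for seed in range(5):
            fig, joint, _ = scm_draw(figname, seed)
            spec = InstrumentalSpec(z=("Z", "W2"), x=("X",), b0=b0, u=("U",))
            total = joint.conditional_mutual_information(
                ["Z", "W2"], ["U"], tuple(b0) + ("X",))
            for parts in ([("Z",), ("W2",)], [("W2",), ("Z",)]):
                terms = build_chain_decomposition(joint, spec,
                                                  ChainPartition(parts))
                s = sum(t.value for t in terms[1:])
                assert s == pytest.approx(total, abs=1e-10)

    def test_fully_blocked_instrument_gives_zero_terms(self, rng):
        # Z ⊥ U: independent blocks
        from mininf import CausalDAG
        g = CausalDAG(["Z", "X", "U"], [("Z", "X"), ("U", "X")], hidden=["U"])
        joint = sample_scm(g, MechanismSpec(seed=1))
        spec = InstrumentalSpec(z=("Z",), x=("X",), u=("U",))
        terms = build_chain_decomposition(joint, spec, ChainPartition([("Z",)]))
        # I(Z;U|X) need not vanish (X is a collider); but I(Z;U) does and the
        # chain identity still holds
        assert terms[1].value == pytest.approx(
            joint.conditional_mutual_information(["Z"], ["U"], ["X"]),
            abs=1e-12)

    def test_hidden_required_in_simulation_mode(self):
        fig, _, obs = scm_draw("fig1A", 0)
        with pytest.raises(ValueError):
            build_chain_decomposition(obs, spec_of(fig),
                                      ChainPartition([("Z",)]))


class TestCombined:
    def test_empty_y2_reduces_to_standard(self, rng):
        d = random_distribution(["Z", "X", "Y1", "W1", "W2"], rng)
        spec_c = InstrumentalSpec(z=("Z",), x=("X",), y=("Y1",),
                                  b0=("W1", "W2"), b1=("W1",), b2=("W2",),
                                  y1=("Y1",), y2=(), ybar=())
        spec_s = InstrumentalSpec(z=("Z",), x=("X",), y=("Y1",),
                                  b0=("W1", "W2"))
        rc = eval_combined(d, spec_c)
        rs = eval_standard_instrumental(d, spec_s)
        assert rc.slack == pytest.approx(rs.slack, abs=1e-8)

    def test_ybar_outside_y1_rejected(self):
        with pytest.raises(ValueError):
            InstrumentalSpec(z=("Z",), x=("X",), y=("Y1", "Y2"),
                             y1=("Y1",), y2=("Y2",), ybar=("Y2",))

    @pytest.mark.parametrize("figname", ["fig2A", "fig2B"])
    def test_causally_fulfilled_on_fig2_draws(self, figname):
        for seed in range(8):
            fig, _, obs = scm_draw(figname, seed)
            r = eval_combined(obs, spec_of(fig))
            assert r.slack >= -1e-5


class TestMinInfInstrumental:
    def _fig2c_setup(self, obs=None):
        fig = figure_structure("fig2C")
        spec = spec_of(fig)
        partition = ChainPartition([spec.z])
        plan = plan_from_independencies(fig.dag, spec,
                                        fig.roles["plan_inserts"])
        return fig, spec, partition, plan

    def test_single_full_conditioning_step_equals_standard(self, rng):
        fig = figure_structure("fig1A")
        spec = spec_of(fig)
        _, _, obs = scm_draw("fig1A", 3)
        plan = plan_from_independencies(fig.dag, spec, [(("Y",), ("X", "W"))])
        r = eval_mininf_instrumental(obs, spec, ChainPartition([("Z",)]),
                                     [plan])
        rs = eval_standard_instrumental(obs, spec)
        assert r.slack == pytest.approx(rs.slack, abs=1e-8)

    def test_causally_fulfilled_on_fig2C_draws(self):
        fig, spec, partition, plan = self._fig2c_setup()
        for seed in range(6):
            _, _, obs = scm_draw("fig2C", seed)
            r = eval_mininf_instrumental(obs, spec, partition, [plan],
                                         restarts=4)
            assert r.slack >= -1e-5

    def test_three_term_bound_at_least_as_tight_as_y1_only(self):
        # the added minInf terms are nonnegative: the Eq-25-style lower bound
        # dominates the standard bound restricted to Y1
        fig, spec, partition, plan = self._fig2c_setup()
        for seed in range(4):
            _, _, obs = scm_draw("fig2C", seed)
            r3 = eval_mininf_instrumental(obs, spec, partition, [plan],
                                          restarts=4)
            r1 = eval_standard_instrumental(
                obs, InstrumentalSpec(z=spec.z, x=spec.x, y=("Y1",),
                                      b0=spec.b0))
            sum3 = sum(t.value for t in r3.terms)
            sum1 = sum(t.value for t in r1.terms)
            assert sum3 >= sum1 - 1e-6

    def test_breaker_rejected_only_by_the_mininf_bound(self):
        case = violating_distribution("fig2C-breaker")
        r = case.evaluate()
        assert r.violated and r.slack <= -1.0 + 1e-5
        standard = eval_standard_instrumental(
            case.dist, InstrumentalSpec(z=("Z",), x=("X",), y=("Y1",),
                                        b0=("W2", "W3")))
        assert standard.slack >= -1e-9

    def test_plan_with_wrong_base_conditioning_rejected(self):
        fig, spec, partition, plan = self._fig2c_setup()
        bad_spec = InstrumentalSpec(z=("Z",), x=("X",), b0=("W2",), u=("U",))
        _, _, obs = scm_draw("fig2C", 0)
        with pytest.raises(ValueError, match="expected"):
            eval_mininf_instrumental(obs, bad_spec, partition, [plan])


class TestGD1:
    def test_single_observable_group_is_a_shannon_bound(self, rng):
        d = random_distribution(["Y", "Z", "B"], rng)
        gc = GroupCollection(("Y",), ("Z",), [Group(("B",))])
        r = eval_gd1(d, gc)
        assert r.slack >= -1e-10

    def test_two_disjoint_copy_groups_saturate(self):
        # Y = (B1, B2) with independent uniform bits: H(Y) = 2,
        # I(Y;B1) = I(Y;B2) = 1
        p = np.zeros((2, 2, 4))
        for b1 in range(2):
            for b2 in range(2):
                p[b1, b2, 2 * b1 + b2] = 0.25
        from mininf import DiscreteJointDistribution, VariableSet
        d = DiscreteJointDistribution(
            VariableSet(["B1", "B2", "Y"], [2, 2, 4]), p)
        gc = GroupCollection(("Y",), (), [Group(("B1",)), Group(("B2",))])
        r = eval_gd1(d, gc)
        assert r.upper_bound == pytest.approx(2.0)
        assert [t.value for t in r.terms] == pytest.approx([1.0, 1.0])
        assert r.slack == pytest.approx(0.0, abs=1e-10)

    def test_causally_fulfilled_on_fig3A_draws(self):
        fig = figure_structure("fig3A")
        gc = GroupCollection(fig.roles["y"], fig.roles["z"],
                             [Group(m, proxy=p) for m, p in
                              fig.roles["groups"]],
                             hidden=fig.dag.hidden)
        for seed in range(10):
            joint = sample_scm(fig.dag, MechanismSpec(seed=seed))
            r = eval_gd1(joint, gc, testable_only=True)
            assert r.slack >= -1e-9

    def test_failed_group_independence_raises(self, rng):
        d = random_distribution(["Y", "Z", "B1", "B2"], rng)
        gc = GroupCollection(("Y",), ("Z",), [Group(("B1",)), Group(("B2",))])
        with pytest.raises(ValueError, match="group independence"):
            eval_gd1(d, gc)

    def test_overlap_degree(self):
        gc = GroupCollection(("Y",), (), [Group(("A", "B")), Group(("B", "C")),
                                          Group(("D",))])
        assert gc.overlap_degree(0) == 2
        assert gc.overlap_degree(2) == 1


class TestInformationCausality:
    def test_single_independent_round_has_full_entropy_slack(self):
        d = make_independent_bits(("X1", "M", "Y1"))
        scn = ICScenario.from_joint(d, ("X1",), ("M",), ("Y1",))
        r = eval_ic(scn)
        assert r.slack == pytest.approx(1.0)  # H(M)

    def test_perfect_one_bit_protocol_saturates(self):
        # M = X1, Y1 = M: upper 1.0, terms I(X1;M)=1 and I(X1;Y1|M)=0
        p = np.zeros((2, 2, 2))
        p[0, 0, 0] = p[1, 1, 1] = 0.5
        from mininf import DiscreteJointDistribution, VariableSet
        d = DiscreteJointDistribution(
            VariableSet(["X1", "M", "Y1"], [2, 2, 2]), p)
        r = eval_ic(ICScenario.from_joint(d, ("X1",), ("M",), ("Y1",)))
        assert r.upper_bound == pytest.approx(1.0)
        assert [t.value for t in r.terms] == pytest.approx([1.0, 0.0])
        assert r.slack == pytest.approx(0.0, abs=1e-10)

    def test_causally_fulfilled_on_fig3B_draws(self):
        fig = figure_structure("fig3B")
        for seed in range(10):
            joint = sample_scm(fig.dag, MechanismSpec(seed=seed))
            obs = joint.marginalize([n for n in joint.variables.names
                                     if n != "U"])
            scn = ICScenario.from_joint(obs, fig.roles["x"], fig.roles["m"],
                                        fig.roles["y"])
            r = eval_ic(scn)
            assert r.slack >= -1e-9

    def test_inconsistent_marginals_rejected(self, rng):
        d1 = random_distribution(["X1", "M", "Y1"], rng)
        d2 = random_distribution(["X1", "M", "Y2"], rng)
        with pytest.raises(ValueError, match="disagree"):
            ICScenario(("X1",), ("M",), ("Y1", "Y2"), [d1, d2])

    def test_simulation_mode_exposes_hidden_terms(self):
        fig = figure_structure("fig3B")
        joint = sample_scm(fig.dag, MechanismSpec(seed=2))
        scn = ICScenario.from_joint(joint, fig.roles["x"], fig.roles["m"],
                                    fig.roles["y"], u=("U",))
        r = eval_ic(scn, include_hidden=True)
        hidden_terms = [t for t in r.terms if t.status == "nonestimable"]
        assert len(hidden_terms) == 2
        assert all(t.value >= 0 for t in hidden_terms)
        assert r.slack >= -1e-9
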