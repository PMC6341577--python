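"""DEC/DEC+J state space, rates, cladogenesis, likelihood and marginals."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from phyloseed.biogeography import (
    DEFAULT_AREAS,
    build_anagenetic_Q,
    build_state_space,
    cladogenesis_table,
    dec_loglik,
    fit_dec,
    likelihood_ratio_test,
    node_marginals,
)
from phyloseed.biogeography import _state_index
from phyloseed.tree import Chronogram

A3 = ("A", "B", "C")


class TestStateSpace:
    @pytest.mark.parametrize(
        "n_areas,max_range,expected",
        [(6, 2, 21), (2, 2, 3), (6, 6, 63), (4, 1, 4)],
    )
    def test_counts(self, n_areas, max_range, expected):
        areas = tuple("ABCDEF"[:n_areas])
        assert len(build_state_space(areas, max_range)) == expected

    def test_ordering_by_size_then_lexicographic(self):
        states = build_state_space(A3, 2)
        sizes = [len(s) for s in states]
        assert sizes == sorted(sizes)
        singletons = [sorted(s)[0] for s in states[:3]]
        assert singletons == ["A", "B", "C"]

    def test_invalid_max_range_rejected(self):
        with pytest.raises(ValueError):
            build_state_space(A3, 0)


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self):
        states = build_state_space(A3, 2)
        assert np.allclose(build_anagenetic_Q(states, 0.0, 0.0, areas=A3), 0.0)

    def test_expansion_rate_definition(self):
        states = build_state_space(("A", "B"), 2)
        idx = _state_index(states)
        Q = build_anagenetic_Q(states, d=0.7, e=0.0, areas=("A", "B"))
        assert Q[idx[frozenset("A")], idx[frozenset("AB")]] == pytest.approx(0.7)

    def test_multipliers_scale_expansions(self):
        states = build_state_space(("A", "B"), 2)
        idx = _state_index(states)
        m = np.array([[1.0, 0.25], [0.25, 1.0]])
        Q = build_anagenetic_Q(states, d=1.0, e=0.0, multipliers=m, areas=("A", "B"))
        assert Q[idx[frozenset("A")], idx[frozenset("AB")]] == pytest.approx(0.25)

    def test_contraction_and_null_absorption(self):
        states = build_state_space(("A", "B"), 2)
        idx = _state_index(states)
        Q = build_anagenetic_Q(states, d=0.0, e=0.3, areas=("A", "B"))
        assert Q[idx[frozenset("AB")], idx[frozenset("A")]] == pytest.approx(0.3)
        assert Q[idx[frozenset("A")], 0] == pytest.approx(0.3)  # to null
        assert np.allclose(Q[0], 0.0)  # null absorbing

    @pytest.mark.parametrize("seed", range(3))
    def test_rows_sum_to_zero(self, seed, rng):
        states = build_state_space(DEFAULT_AREAS, 2)
        d, e = rng.uniform(0, 1, 2)
        Q = build_anagenetic_Q(states, d, e)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12


class TestCladogenesis:
    def test_singleton_parent_pure_sympatry(self):
        table = cladogenesis_table(build_state_space(A3, 2), "DEC", areas=A3)
        events = table[frozenset("A")]
        assert len(events) == 1
        ev = events[0]
        assert ev.left == ev.right == frozenset("A")
        assert ev.weight == pytest.approx(1.0)

    def test_two_area_parent_enumeration(self):
        """Subset sympatry and vicariance enumerated; weights sum to 1."""
        table = cladogenesis_table(build_state_space(A3, 2), "DEC", areas=A3)
        events = table[frozenset("AB")]
        kinds = {ev.kind for ev in events}
        assert kinds == {"subset", "vicariance"}
        unordered = {frozenset((ev.left, ev.right)) for ev in events}
        # subset: (AB, A), (AB, B); vicariance: (A, B)
        assert unordered == {
            frozenset({frozenset("AB"), frozenset("A")}),
            frozenset({frozenset("AB"), frozenset("B")}),
            frozenset({frozenset("A"), frozenset("B")}),
        }
        assert sum(ev.weight for ev in events) == pytest.approx(1.0)

    def test_jump_targets_outside_parent(self):
        table = cladogenesis_table(build_state_space(A3, 2), "DECJ", j=0.5, areas=A3)
        parent = frozenset("A")
        founders = [ev for ev in table[parent] if ev.kind == "founder"]
        assert founders
        for ev in founders:
            jumped = ev.left if ev.left != parent else ev.right
            assert jumped.isdisjoint(parent)

    def test_j_zero_table_equals_dec(self):
        states = build_state_space(A3, 2)
        dec = cladogenesis_table(states, "DEC", areas=A3)
        decj = cladogenesis_table(states, "DECJ", j=0.0, areas=A3)
        for parent in dec:
            a = sorted((e.left, e.right, e.kind, e.weight) for e in dec[parent])
            b = sorted((e.left, e.right, e.kind, e.weight) for e in decj[parent])
            assert a == b

    def test_invalid_j_rejected(self):
        states = build_state_space(A3, 2)
        with pytest.raises(ValueError):
            cladogenesis_table(states, "DECJ", j=3.0, areas=A3)
        with pytest.raises(ValueError):
            cladogenesis_table(states, "DEC", j=0.5, areas=A3)


class TestLikelihood:
    def test_single_tip_no_events(self):
        t = Chronogram.from_newick("(X:1,Y:1):0;").prune_to_species({"X": "X"})
        ll = dec_loglik(t, {"X": {"A"}}, d=0.0, e=0.0, areas=A3)
        assert ll == pytest.approx(np.log(1.0 / 6.0))  # flat prior over 6 states

    def test_matches_enumeration_oracle_two_tips(self):
        tree = Chronogram.from_newick("(X:2,Y:2):0;")
        tips = {"X": {"A"}, "Y": {"B", "C"}}
        states = build_state_space(A3, 2)
        idx = _state_index(states)
        Q = build_anagenetic_Q(states, 0.03, 0.01, areas=A3)
        table = cladogenesis_table(states, "DEC", areas=A3)
        P = expm(Q * 2.0)
        total = 0.0
        for s in states:
            for ev in table[s]:
                total += (
                    ev.weight
                    / len(states)
                    * P[idx[ev.left], idx[frozenset(tips["X"])]]
                    * P[idx[ev.right], idx[frozenset(tips["Y"])]]
                )
        ll = dec_loglik(tree, tips, 0.03, 0.01, areas=A3)
        assert ll == pytest.approx(np.log(total), abs=1e-8)

    def test_matches_enumeration_oracle_three_tips(self):
        tree = Chronogram.from_newick("((X:1,Y:1):1,Z:2):0;")
        tips = {"X": {"A"}, "Y": {"A", "B"}, "Z": {"C"}}
        states = build_state_space(A3, 2)
        idx = _state_index(states)
        d, e = 0.05, 0.02
        Q = build_anagenetic_Q(states, d, e, areas=A3)
        table = cladogenesis_table(states, "DEC", areas=A3)
        P1 = expm(Q * 1.0)
        total = 0.0
        for root_state in states:
            for ev_r in table[root_state]:
                # left corner evolves 1 My to the inner node, then splits
                inner = 0.0
                for inner_state in states:
                    p_reach = P1[idx[ev_r.left], idx[inner_state]]
                    if p_reach == 0:
                        continue
                    for ev_i in table[inner_state]:
                        inner += (
                            p_reach
                            * ev_i.weight
                            * P1[idx[ev_i.left], idx[frozenset(tips["X"])]]
                            * P1[idx[ev_i.right], idx[frozenset(tips["Y"])]]
                        )
                z = expm(Q * 2.0)[idx[ev_r.right], idx[frozenset(tips["Z"])]]
                total += ev_r.weight / len(states) * inner * z
        ll = dec_loglik(tree, tips, d, e, areas=A3)
        assert ll == pytest.approx(np.log(total), abs=1e-8)

    def test_decj_at_zero_equals_dec(self, yule8):
        from phyloseed.simulate import simulate_dec_ranges

        sim = simulate_dec_ranges(
            yule8, d=0.3, e=0.05, seed=1, areas=A3, root_state=frozenset("A")
        )
        a = dec_loglik(yule8, sim.tip_ranges, 0.1, 0.02, model="DEC", areas=A3)
        b = dec_loglik(yule8, sim.tip_ranges, 0.1, 0.02, j=0.0, model="DECJ", areas=A3)
        assert b == pytest.approx(a, abs=1e-9)

    def test_decj_never_below_dec_after_fit(self, yule8):
        from phyloseed.simulate import simulate_dec_ranges

        sim = simulate_dec_ranges(
            yule8, d=0.3, e=0.05, j=0.3, seed=2, areas=A3, root_state=frozenset("A")
        )
        dec = fit_dec(yule8, sim.tip_ranges, "DEC", areas=A3, n_starts=2, seed=0)
        decj = fit_dec(yule8, sim.tip_ranges, "DECJ", areas=A3, n_starts=2, seed=0)
        assert decj.loglik_ >= dec.loglik_ - 1e-6

    def test_invariant_to_zero_length_polytomy_resolution(self):
        tips = {"X": {"A"}, "Y": {"B"}, "Z": {"C"}}
        t1 = Chronogram.from_newick("(X:2,Y:2,Z:2):0;")
        t2 = Chronogram.from_newick("(Z:2,Y:2,X:2):0;")
        a = dec_loglik(t1, tips, 0.1, 0.05, areas=A3)
        b = dec_loglik(t2, tips, 0.1, 0.05, areas=A3)
        assert a == pytest.approx(b, abs=1e-10)

    def test_unknown_tip_range_rejected(self, cherry):
        with pytest.raises(ValueError, match="state space"):
            dec_loglik(cherry, {"A": {"A", "B", "C"}, "B": {"A"}}, 0.1, 0.1, areas=A3)


class TestFitAndLRT:
    def test_identical_tip_ranges_drive_rates_to_bound(self):
        tree = Chronogram.from_newick("((X:1,Y:1):1,Z:2):0;")
        fit = fit_dec(
            tree, {t: {"A"} for t in "XYZ"}, "DEC", areas=A3, n_starts=2, seed=0
        )
        assert fit.d_ <= 1e-8
        assert fit.e_ <= 1e-8

    def test_published_lrt_values(self):
        """LRT on the printed DEC/DEC+J log likelihoods."""
        res = likelihood_ratio_test(-46.67, -27.26, df=1)
        assert res.statistic == pytest.approx(38.82, abs=0.005)
        assert res.p_value == pytest.approx(4.7e-10, rel=0.05)

    def test_equal_likelihoods(self):
        res = likelihood_ratio_test(-5.0, -5.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_quantile(self):
        res = likelihood_ratio_test(0.0, 3.8415 / 2.0, df=1)
        assert res.p_value == pytest.approx(0.05, abs=1e-4)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-2.0, -1.0, df=0)


class TestMarginals:
    def test_no_events_all_mass_on_observed_area(self):
        tree = Chronogram.from_newick("((X:1,Y:1):1,Z:2):0;")
        nodes, corners = node_marginals(
            tree, {t: {"A"} for t in "XYZ"}, d=0.0, e=0.0, areas=A3
        )
        assert np.allclose(nodes["A"], 1.0)

    def test_rows_sum_to_one(self, yule8):
        from phyloseed.simulate import simulate_dec_ranges

        sim = simulate_dec_ranges(
            yule8, d=0.3, e=0.05, seed=3, areas=A3, root_state=frozenset("A")
        )
        nodes, corners = node_marginals(yule8, sim.tip_ranges, d=0.2, e=0.05, areas=A3)
        assert np.allclose(nodes.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(corners.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_exhaustive_joint_reconstruction(self):
        """Root marginal equals brute-force marginalization over histories."""
        tree = Chronogram.from_newick("((X:1,Y:1):1,Z:2):0;")
        tips = {"X": {"A"}, "Y": {"B"}, "Z": {"C"}}
        d, e = 0.1, 0.03
        states = build_state_space(A3, 2)
        idx = _state_index(states)
        Q = build_anagenetic_Q(states, d, e, areas=A3)
        table = cladogenesis_table(states, "DEC", areas=A3)
        P1, P2 = expm(Q * 1.0), expm(Q * 2.0)
        joint_root = {}
        for root_state in states:
            tot = 0.0
            for ev_r in table[root_state]:
                inner = 0.0
                for inner_state in states:
                    p = P1[idx[ev_r.left], idx[inner_state]]
                    for ev_i in table[inner_state]:
                        inner += (
                            p
                            * ev_i.weight
                            * P1[idx[ev_i.left], idx[frozenset(tips["X"])]]
                            * P1[idx[ev_i.right], idx[frozenset(tips["Y"])]]
                        )
                tot += ev_r.weight * inner * P2[idx[ev_r.right], idx[frozenset(tips["Z"])]]
            joint_root[s_name(root_state)] = tot / len(states)
        z = sum(joint_root.values())
        nodes, _ = node_marginals(tree, tips, d=d, e=e, areas=A3)
        root_id = nodes.index.max()  # root is last in postorder
        for name, val in joint_root.items():
            assert nodes.loc[root_id, name] == pytest.approx(val / z, abs=1e-8)


def s_name(s):
    return "+".join(sorted(s))
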