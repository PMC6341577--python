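"""Generators: Yule trees, trait simulators, DEC histories, seed datasets,
and the in-text fixture."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from phyloseed.fixture import (
    BINARY_TRAITS,
    TIP_RANGES,
    fixture_plukenetiinae,
    reconstruct_seed_measurements,
)
from phyloseed.morphometrics import cluster_seed_sizes
from phyloseed.simulate import (
    default_seed_classes,
    generate_seed_dataset,
    simulate_continuous,
    simulate_dec_ranges,
    simulate_liability_pair,
    simulate_yule_tree,
)


class TestYule:
    def test_two_tips_single_cherry(self):
        t = simulate_yule_tree(2, seed=0)
        assert t.n_tips == 2
        assert t.root_age > 0

    def test_fixed_seed_identical_newick(self):
        a = simulate_yule_tree(10, seed=5).to_newick()
        b = simulate_yule_tree(10, seed=5).to_newick()
        assert a == b

    def test_requested_root_age_honoured(self):
        t = simulate_yule_tree(12, seed=1, root_age=30.0)
        assert t.root_age == pytest.approx(30.0, rel=1e-9)

    def test_no_zero_length_tip_edges(self):
        t = simulate_yule_tree(40, seed=2)
        lengths = t.edge_lengths[t.tip_ids]
        assert np.all(lengths > 0)

    def test_waiting_time_scaling(self):
        """Root age shrinks like 1/birth_rate: time to go 2 -> n lineages is
        sum of Exp(k*rate) waits, so mean root age scales inversely."""
        ages_slow = [simulate_yule_tree(10, seed=s, birth_rate=0.5).root_age for s in range(300)]
        ages_fast = [simulate_yule_tree(10, seed=s, birth_rate=2.0).root_age for s in range(300)]
        assert np.mean(ages_slow) / np.mean(ages_fast) == pytest.approx(4.0, rel=0.15)

    def test_calibrated_root_age_near_calibration(self):
        ages = [
            simulate_yule_tree(8, seed=s, calibrated=True).root_age for s in range(200)
        ]
        assert np.mean(ages) == pytest.approx(36.43, abs=1.0)


class TestContinuous:
    def test_zero_rate_all_tips_at_root_state(self, yule8):
        x = simulate_continuous(yule8, "BM", {"sigma2": 0.0, "z0": 2.5}, seed=0)
        assert all(v == 2.5 for v in x.values())

    def test_star_variance_matches_closed_form(self):
        from phyloseed.tree import Chronogram

        star = Chronogram.from_newick("(A:2,B:2,C:2,D:2,E:2):0;")
        draws = np.array(
            [
                list(simulate_continuous(star, "BM", {"sigma2": 1.5}, seed=s).values())
                for s in range(4000)
            ]
        )
        # each tip is N(0, sigma2*T) independently
        assert np.allclose(draws.var(axis=0), 3.0, rtol=0.1)
        assert abs(np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]) < 0.05

    def test_tip_covariance_matches_tree(self, yule8):
        C = yule8.covariance().matrix
        draws = np.array(
            [
                [
                    simulate_continuous(yule8, "BM", {"sigma2": 1.0}, seed=s)[t]
                    for t in yule8.tip_labels
                ]
                for s in range(3000)
            ]
        )
        emp = np.cov(draws.T)
        assert np.allclose(emp, C, atol=0.15 * C.max())


class TestLiabilityPair:
    def test_degenerate_full_correlation(self, yule8):
        cont, binv, liab = simulate_liability_pair(
            yule8, r=1.0, seed=3, return_liability=True
        )
        for t in yule8.tip_labels:
            assert binv[t] == int(cont[t] > 0)

    def test_zero_correlation_on_average(self, yule8):
        cors = []
        for s in range(300):
            cont, _, liab = simulate_liability_pair(
                yule8, r=0.0, seed=s, return_liability=True
            )
            x = np.array(list(cont.values()))
            l = np.array([liab[t] for t in cont])
            cors.append(np.corrcoef(x, l)[0, 1])
        assert -0.1 <= np.mean(cors) <= 0.1

    def test_fixed_seed_determinism(self, yule8):
        assert simulate_liability_pair(yule8, 0.5, seed=9) == simulate_liability_pair(
            yule8, 0.5, seed=9
        )


class TestDECSimulation:
    def test_no_events_everything_stays_at_root(self, yule8):
        sim = simulate_dec_ranges(
            yule8, d=0.0, e=0.0, j=0.0, seed=0, root_state=frozenset({"AMZ"})
        )
        assert all(r == frozenset({"AMZ"}) for r in sim.tip_ranges.values())
        assert sim.n_restarts == 0

    def test_event_counts_scale_with_dispersal_rate(self):
        """Fraction of multi-area tips grows with d (Poisson-like in d*t)."""
        tree = simulate_yule_tree(40, seed=4, root_age=5.0)
        fracs = []
        for d in (0.01, 0.05):
            multi = 0
            total = 0
            for s in range(40):
                sim = simulate_dec_ranges(
                    tree, d=d, e=0.0, seed=s, root_state=frozenset({"AMZ"})
                )
                multi += sum(len(r) > 1 for r in sim.tip_ranges.values())
                total += len(sim.tip_ranges)
            fracs.append(multi / total)
        assert fracs[1] > fracs[0] > 0

    def test_true_history_recorded_for_all_nodes(self, yule8):
        sim = simulate_dec_ranges(
            yule8, d=0.2, e=0.02, j=0.1, seed=5, root_state=frozenset({"AMZ"})
        )
        assert len(sim.node_states) == yule8.n_nodes
        assert all(1 <= len(s) <= 2 for s in sim.node_states.values())

    def test_founder_fraction_increases_with_j(self):
        """Higher j scatters daughters into new areas more often."""
        tree = simulate_yule_tree(40, seed=6, root_age=2.0)

        def scatter(j):
            out = 0
            for s in range(30):
                sim = simulate_dec_ranges(
                    tree, d=0.001, e=0.0, j=j, seed=s, root_state=frozenset({"AMZ"})
                )
                out += sum(r != frozenset({"AMZ"}) for r in sim.tip_ranges.values())
            return out

        assert scatter(1.0) > scatter(0.1)


class TestSeedDataset:
    def test_zero_spread_identical_records(self):
        from phyloseed.simulate import SeedClassSpec

        spec = [SeedClassSpec("only", 1.0, sd_size=0.0, sd_shape=0.0, n=5)]
        records, labels = generate_seed_dataset(spec, seed=0)
        dims = {(r.length, r.width, r.thickness) for r in records}
        assert len(dims) == 1
        assert labels == ["only"] * 5

    def test_default_five_classes_recovered_by_clustering(self):
        records, labels = generate_seed_dataset(seed=123)
        res = cluster_seed_sizes(records, cut_height=0.35)
        assert res.n_clusters == 5
        assert adjusted_rand_score(labels, res.assignments) >= 0.95

    def test_max_class_volumes_inside_published_interval(self):
        from phyloseed.morphometrics import estimate_volume

        records, labels = generate_seed_dataset(seed=7)
        vols = [
            estimate_volume(r.length, r.width, r.thickness).volume
            for r, lab in zip(records, labels)
            if lab == "Max"
        ]
        inside = np.mean([(26000 <= v <= 38000) for v in vols])
        assert inside >= 0.95

    def test_determinism(self):
        a, la = generate_seed_dataset(seed=11)
        b, lb = generate_seed_dataset(seed=11)
        assert la == lb
        assert [(r.length, r.width, r.thickness) for r in a] == [
            (r.length, r.width, r.thickness) for r in b
        ]


class TestFixture:
    def test_tip_count_and_root_age(self, plukfix):
        assert plukfix.tree.n_tips == 21
        assert plukfix.tree.root_age == pytest.approx(31.94, abs=1e-6)

    def test_printed_node_ages_honoured(self, plukfix):
        t = plukfix.tree
        assert t.mrca_age("Romanoa_tamnoides", "P_serrata") == pytest.approx(28.71, abs=1e-6)
        assert t.mrca_age("P_serrata", "P_polyadenia") == pytest.approx(19.1, abs=1e-6)
        assert t.mrca_age("P_polyadenia", "P_conophora") == pytest.approx(17.39, abs=1e-6)
        assert t.mrca_age("P_africana", "P_ankaranensis") == pytest.approx(9.4, abs=1e-6)
        assert t.mrca_age("P_africana", "P_corniculata") == pytest.approx(4.5, abs=1e-6)

    def test_polyadenia_mean_log_volume(self, plukfix):
        assert plukfix.trait["P_polyadenia"] == pytest.approx(np.log10(30684), abs=1e-9)

    def test_africana_savanna_biome_coding(self, plukfix):
        assert plukfix.binary_traits["biome"]["P_africana"] == 1
        assert plukfix.binary_traits["fire_tolerance"]["P_africana"] == 1

    def test_ranges_single_area_and_marked_approximate(self, plukfix):
        assert all(len(r) == 1 for r in plukfix.tip_ranges.values())
        assert plukfix.metadata["approximate"] is True

    def test_reconstruction_matches_summary_counts(self, reconstructed_seeds):
        by_taxon = {}
        for r in reconstructed_seeds:
            by_taxon.setdefault(r.taxon, []).append(r)
        assert len(by_taxon["P_stipellata"]) == 47
        assert len(by_taxon["P_polyadenia"]) == 19
        Ls = [r.length for r in by_taxon["P_volubilis"]]
        assert min(Ls) == pytest.approx(13.0)
        assert max(Ls) == pytest.approx(22.0)
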