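"""BM/OU/EB likelihoods and fits, model comparison, phylogenetic signal."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phyloseed.simulate import simulate_continuous, simulate_yule_tree
from phyloseed.trait_models import (
    TraitModelML,
    akaike_weights,
    blomberg_k,
    bm_loglik,
    compare_models,
    fit_trait_model,
    lambda_profile_loglik,
    pagel_lambda,
)
from phyloseed.tree import Chronogram


class TestBMLoglik:
    def test_two_tip_star_two_independent_normals(self, cherry):
        # sigma2*T = 1, values (0, 2) around z0=1: each deviates by 1
        ll = bm_loglik(cherry, {"A": 0.0, "B": 2.0}, sigma2=1.0, z0=1.0)
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn_oracle(self, seed, yule8):
        x = simulate_continuous(yule8, "BM", {"sigma2": 1.3, "z0": 0.5}, seed=seed)
        xv = np.array([x[t] for t in yule8.tip_labels])
        oracle = multivariate_normal(
            mean=0.5 * np.ones(8), cov=1.3 * yule8.covariance().matrix
        ).logpdf(xv)
        assert bm_loglik(yule8, x, 1.3, 0.5) == pytest.approx(oracle, abs=1e-8)

    def test_invalid_sigma2_rejected(self, cherry):
        with pytest.raises(ValueError):
            bm_loglik(cherry, {"A": 0.0, "B": 1.0}, sigma2=0.0, z0=0.0)


class TestFitting:
    def test_bm_gls_closed_form_and_recovery(self, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0, "z0": 2.0}, seed=1)
        fit = fit_trait_model(yule50, trait, "BM")
        # closed-form GLS estimates maximize the likelihood: profile check
        assert 0.7 <= fit.sigma2 <= 1.4
        for s2 in (fit.sigma2 * 0.9, fit.sigma2 * 1.1):
            assert bm_loglik(yule50, trait, s2, fit.z0) <= fit.loglik + 1e-10
        for dz in (-0.1, 0.1):
            assert (
                bm_loglik(yule50, trait, fit.sigma2, fit.z0 + dz) <= fit.loglik + 1e-10
            )
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    @pytest.mark.parametrize("model", ["OU", "EB"])
    def test_nesting_limits_reach_bm(self, model, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=2)
        bm = fit_trait_model(yule50, trait, "BM")
        other = fit_trait_model(yule50, trait, model)
        assert other.loglik >= bm.loglik - 1e-6
        assert other.k == 3

    def test_eb_simulated_at_zero_rate_equals_bm_data(self, yule50):
        trait = simulate_continuous(yule50, "EB", {"sigma2": 1.0, "eb_rate": 0.0}, seed=3)
        bm = fit_trait_model(yule50, trait, "BM")
        eb = fit_trait_model(yule50, trait, "EB")
        assert eb.loglik == pytest.approx(bm.loglik, abs=1e-4)

    def test_too_few_tips_rejected(self, cherry):
        with pytest.raises(ValueError):
            fit_trait_model(cherry, {"A": 0.0, "B": 1.0}, "BM")


class TestComparison:
    def test_equal_aic_equal_weights(self):
        w = akaike_weights([10.0, 10.0, 10.0])
        assert np.allclose(w, 1 / 3)

    def test_delta_two_textbook_weights(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.731, abs=0.001)
        assert w[1] == pytest.approx(0.269, abs=0.001)

    def test_weights_sum_to_one_and_best_is_modal(self, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=4)
        fits = [fit_trait_model(yule50, trait, m) for m in ("BM", "OU", "EB")]
        comp = compare_models(fits)
        assert sum(comp.weights) == pytest.approx(1.0, abs=1e-12)
        assert min(comp.delta_aic) == 0.0
        best = comp.best()
        w = dict(zip(comp.models, comp.weights))
        assert w[best] == max(comp.weights)

    def test_bm_is_modal_best_model_on_bm_data(self, yule50):
        """BM data should usually select BM over OU/EB by AIC."""
        wins = 0
        for rep in range(30):
            trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=500 + rep)
            fits = [fit_trait_model(yule50, trait, m) for m in ("BM", "OU", "EB")]
            if compare_models(fits).best() == "BM":
                wins += 1
        assert wins >= 16


class TestSignal:
    def test_k_near_one_under_bm(self, yule50):
        ks = [
            blomberg_k(
                yule50,
                simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=1000 + rep),
                n_perm=0,
            ).estimate
            for rep in range(100)
        ]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_k_permutation_p_reproducible_and_valid(self, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=6)
        a = blomberg_k(yule50, trait, n_perm=199, seed=42)
        b = blomberg_k(yule50, trait, n_perm=199, seed=42)
        assert a.p_value == b.p_value
        assert 1 / 200 <= a.p_value <= 1.0

    def test_constant_trait_rejected(self, yule8):
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(yule8, {t: 1.0 for t in yule8.tip_labels})

    def test_lambda_identity_at_one(self, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=7)
        bm = fit_trait_model(yule50, trait, "BM")
        assert lambda_profile_loglik(yule50, trait, 1.0) == pytest.approx(
            bm.loglik, abs=1e-8
        )

    def test_lambda_zero_is_iid_star(self, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=8)
        x = np.array([trait[t] for t in yule50.tip_labels])
        n = len(x)
        iid_lnl = -0.5 * n * (
            math.log(2 * math.pi) + math.log(x.var()) + 1.0
        )
        assert lambda_profile_loglik(yule50, trait, 0.0) == pytest.approx(
            iid_lnl, abs=1e-8
        )

    def test_lambda_profile_continuous(self, yule50):
        trait = simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=9)
        grid = np.linspace(0.0, 1.0, 101)
        vals = [lambda_profile_loglik(yule50, trait, g) for g in grid]
        assert np.max(np.abs(np.diff(vals))) < 5.0  # no jumps

    def test_lambda_near_one_on_bm_data(self, yule50):
        lams = [
            pagel_lambda(
                yule50,
                simulate_continuous(yule50, "BM", {"sigma2": 1.0}, seed=2000 + rep),
            ).estimate
            for rep in range(50)
        ]
        assert np.median(lams) >= 0.95


class TestRCrossCheck:
    """Independent oracle: the same statistics from R (ape/phytools)."""

    def test_phylosig_matches_phytools(self, yule8, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        trait = simulate_continuous(yule8, "BM", {"sigma2": 1.0, "z0": 1.0}, seed=11)
        newick = yule8.to_newick()
        vals = ",".join(f"{trait[t]!r}" for t in yule8.tip_labels)
        names = ",".join(f"'{t}'" for t in yule8.tip_labels)
        script = tmp_path / "sig.R"
        script.write_text(
            f"""
            suppressMessages(library(phytools))
            tree <- ape::read.tree(text="{newick}")
            x <- c({vals}); names(x) <- c({names})
            k <- phylosig(tree, x, method="K")
            l <- phylosig(tree, x, method="lambda")
            cat(sprintf("%.10f %.10f\\n", as.numeric(k), l$lambda))
            """
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        k_r, lam_r = map(float, out.stdout.split())
        k_py = blomberg_k(yule8, trait, n_perm=0).estimate
        lam_py = pagel_lambda(yule8, trait).estimate
        assert k_py == pytest.approx(k_r, rel=1e-4)
        assert lam_py == pytest.approx(lam_r, abs=1e-3)
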