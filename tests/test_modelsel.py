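"""Candidate sets, information criteria, weights, averaging, GOF."""

import numpy as np
import pytest

from gardenhunt.modelsel import (
    GofResult,
    aicc,
    akaike_weights,
    apply_overdispersion,
    build_model_table,
    enumerate_models,
    gof_bootstrap,
    model_average,
    qaicc,
    support_label,
    variable_importance,
)
from gardenhunt.rn import RNDesign, RNFit, RNSpec, fit_rn
from gardenhunt.simulate import simulate_species_history


class TestEnumerate:
    def test_cardinalities(self):
        assert len(enumerate_models(allow_quadratic=False)) == 32
        assert len(enumerate_models(allow_quadratic=True)) == 48

    def test_effort_always_present_and_hierarchy(self):
        for quad in (False, True):
            specs = enumerate_models(allow_quadratic=quad)
            assert len(set(specs)) == len(specs)
            for s in specs:
                assert "effort" in s.detection_terms
                if "tree_buffer2" in s.site_terms:
                    assert "tree_buffer" in s.site_terms

    def test_contains_null_and_full(self):
        specs = enumerate_models(allow_quadratic=False)
        assert RNSpec("", ("effort",), ()) in specs
        assert RNSpec(
            "", ("effort", "date", "tracks_dens"),
            ("tree_buffer", "dist_river", "dist_conuco"),
        ) in specs


class TestCriteria:
    def test_aicc_worked_example(self):
        # -2(-100) + 2*3 + 2*3*4/(54-4) = 200 + 6 + 0.48
        assert aicc(-100, 3, 54) == pytest.approx(206.48)

    def test_aicc_approaches_aic(self):
        aic = -2 * (-100) + 2 * 3
        assert aicc(-100, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_aicc_small_sample_guard(self):
        with pytest.raises(ValueError, match="sample too small"):
            aicc(-10, 5, 6)

    def test_qaicc_counts_chat_as_parameter(self):
        # at c_hat = 1 the only difference from AICc is the extra parameter
        got = qaicc(-100, 3, 54, 1.0)
        assert got == pytest.approx(aicc(-100, 4, 54))

    def test_weights_examples(self):
        np.testing.assert_allclose(
            akaike_weights([0.0, 2.0]), [0.731, 0.269], atol=5e-4
        )
        np.testing.assert_allclose(akaike_weights([0.0, 0.0]), [0.5, 0.5])
        w = akaike_weights(np.random.default_rng(0).uniform(0, 20, 17))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def dummy_fit(det=(), site=(), loglik=-100.0, coefs=None, variances=None):
    """Hand-built RNFit for table-level machinery tests."""
    spec = RNSpec("sp", det, site)
    n_a, n_b = 1 + len(det), 1 + len(site)
    params = np.zeros(n_a + n_b) if coefs is None else np.asarray(coefs, float)
    vcov = np.diag(np.zeros(n_a + n_b) if variances is None
                   else np.asarray(variances, float))
    design = RNDesign(
        y=np.zeros((1, 1)), W=np.zeros((1, 1, n_a)), X=np.zeros((1, n_b)),
        det_names=("(Intercept)",) + det, site_names=("(Intercept)",) + site,
    )
    return RNFit(spec=spec, alpha=params[:n_a], beta=params[n_a:],
                 loglik=loglik, K=50, vcov=vcov, n_sites=54,
                 converged=True, design=design)


class TestModelTable:
    def test_sorted_weights_sum_one(self):
        fits = [dummy_fit(loglik=ll) for ll in (-100, -95, -102)]
        mt = build_model_table(fits)
        assert mt.table["delta"].iloc[0] == 0.0
        assert mt.table["AICc"].is_monotonic_increasing
        assert mt.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_ranking_invariant_to_loglik_shift(self):
        lls = [-100.0, -97.5, -103.2]
        mt1 = build_model_table([dummy_fit(loglik=ll) for ll in lls])
        mt2 = build_model_table([dummy_fit(loglik=ll + 37.0) for ll in lls])
        np.testing.assert_allclose(mt1.table["delta"], mt2.table["delta"],
                                   atol=1e-9)
        np.testing.assert_allclose(mt1.table["weight"], mt2.table["weight"],
                                   atol=1e-9)

    def test_qaicc_used_when_overdispersed(self):
        mt = build_model_table([dummy_fit()], c_hat=1.5)
        assert mt.criterion == "QAICc"

    def test_nonconverged_dropped(self):
        bad = dummy_fit(loglik=-90)
        bad.converged = False
        with pytest.warns(UserWarning, match="non-converged"):
            mt = build_model_table([dummy_fit(loglik=-100), bad])
        assert len(mt) == 1


class TestImportance:
    def test_support_scale_boundaries(self):
        assert support_label(0.95) == "very strong"
        assert support_label(0.9) == "strong"
        assert support_label(0.61) == "strong"
        assert support_label(0.6) == "moderate"
        assert support_label(0.31) == "moderate"
        assert support_label(0.3) == "low"
        assert support_label(0.0) == "low"

    def test_term_in_every_or_no_model(self):
        fits = [dummy_fit(det=("effort",), site=s)
                for s in ((), ("tree_buffer",))]
        mt = build_model_table(fits)
        assert variable_importance(mt, "effort") == (pytest.approx(1.0),
                                                     "very strong")
        assert variable_importance(mt, "dist_conuco") == (0.0, "low")

    def test_equal_weight_split(self):
        fits = [dummy_fit(site=("tree_buffer",), loglik=-100.0),
                dummy_fit(site=("dist_river",), loglik=-100.0)]
        mt = build_model_table(fits)
        sow, label = variable_importance(mt, "tree_buffer")
        assert sow == pytest.approx(0.5, abs=1e-12)
        assert label == "moderate"

    def test_matches_brute_force_tally(self, std_covariates):
        from gardenhunt.modelsel import fit_candidate_set

        h, _ = simulate_species_history(
            std_covariates, {"intercept": -1.0, "effort": 0.5},
            {"intercept": 0.7, "tree_buffer": 1.0}, np.random.default_rng(21),
        )
        mt = fit_candidate_set(h, std_covariates, n_starts=1, seed=0)
        for term in ("date", "tracks_dens", "tree_buffer", "dist_conuco"):
            sow, _ = variable_importance(mt, term)
            brute = sum(
                w for f, w in zip(mt.fits, mt.table["weight"])
                if term in f.spec.detection_terms + f.spec.site_terms
            )
            assert sow == pytest.approx(brute, abs=1e-12)


class TestModelAverage:
    def test_two_model_hand_example(self):
        # equal weights, estimates 1 and 3, zero variance:
        # estimate 2, SE = sum w*sqrt(0 + (b-2)^2) = 1
        fits = [
            dummy_fit(site=("tree_buffer",), coefs=[0, 0, 1.0],
                      variances=[0, 0, 0]),
            dummy_fit(site=("tree_buffer",), coefs=[0, 0, 3.0],
                      variances=[0, 0, 0]),
        ]
        mt = build_model_table(fits)
        avg = model_average(mt).set_index("term")
        row = avg.loc["lam:tree_buffer"]
        assert row["estimate"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(1.0)
        assert row["lo95"] == pytest.approx(2 - 1.96)

    def test_single_model_passthrough_with_inflation(self):
        fit = dummy_fit(site=("tree_buffer",), coefs=[0, 0, 1.5],
                        variances=[0, 0, 0.04])
        mt = build_model_table([fit], c_hat=4.0)
        row = model_average(mt).set_index("term").loc["lam:tree_buffer"]
        assert row["estimate"] == pytest.approx(1.5)
        assert row["se"] == pytest.approx(0.2)
        # CI half-width inflated by sqrt(c_hat) = 2
        assert row["hi95"] - row["estimate"] == pytest.approx(1.96 * 0.2 * 2.0)

    def test_averaged_predictions_in_envelope(self, std_covariates):
        from gardenhunt.modelsel import fit_candidate_set
        from gardenhunt.rn import predict_lambda

        h, _ = simulate_species_history(
            std_covariates, {"intercept": -1.0, "effort": 0.5},
            {"intercept": 0.7, "tree_buffer": 1.0}, np.random.default_rng(2),
        )
        mt = fit_candidate_set(h, std_covariates, n_starts=1, seed=0)
        keep = mt.table["delta"].to_numpy() <= 10
        w = mt.table["weight"].to_numpy()[keep]
        w = w / w.sum()
        preds = np.array([
            predict_lambda(f, std_covariates)["lambda"].to_numpy()
            for f, k in zip(mt.fits, keep) if k
        ])
        avg = (w[:, None] * preds).sum(axis=0)
        assert np.all(avg <= preds.max(axis=0) + 1e-12)
        assert np.all(avg >= preds.min(axis=0) - 1e-12)


class TestGof:
    def test_c_hat_ratio_definition(self):
        g = GofResult(chi2_obs=120.0, boot_samples=np.array([90.0, 100.0, 110.0]))
        assert g.boot_mean == pytest.approx(100.0)
        assert g.c_hat == pytest.approx(1.2)

    def test_degenerate_bootstrap_gives_p_one(self):
        g = GofResult(chi2_obs=77.0, boot_samples=np.full(10, 77.0))
        assert g.p_value == 1.0

    def test_seeded_bootstrap_bit_reproducible(self, std_covariates):
        h, spec = simulate_species_history(
            std_covariates, {"intercept": -1.0, "effort": 0.5},
            {"intercept": 0.7, "tree_buffer": 0.8}, np.random.default_rng(4),
        )
        fit = fit_rn(spec, h, std_covariates, n_starts=2, seed=0)
        g1 = gof_bootstrap(fit, B=25, seed=123)
        g2 = gof_bootstrap(fit, B=25, seed=123)
        np.testing.assert_array_equal(g1.boot_samples, g2.boot_samples)
        assert g1.chi2_obs == g2.chi2_obs
        assert 0.0 <= g1.p_value <= 1.0 and g1.c_hat > 0


class TestOverdispersion:
    @pytest.mark.parametrize("se,c_hat,expected",
                             [(0.1, 4.0, 0.2), (0.1, 0.5, 0.1), (0.1, 1.0, 0.1)])
    def test_inflation_rule(self, se, c_hat, expected):
        assert apply_overdispersion([se], c_hat)[0] == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            apply_overdispersion([0.1], 0.0)
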