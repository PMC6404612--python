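"""AI-REML solver correctness: closed forms, oracles, and contracts."""

import numpy as np
import pandas as pd
import pytest

import subgblup as sg
from subgblup.reml import FitError, fitted_decomposition

from conftest import covariance_at, restricted_loglik_bruteforce


def _identity_kernel(n, label="G"):
    ids = tuple(f"l{i}" for i in range(n))
    return sg.GeneticKernel(np.eye(n), ids, label, c=float(n), nugget=0.0)


def _one_trial_pheno(y_by_line_rep):
    """records (line i, rep j) all in a single trial -> intercept-only X."""
    rows = [
        (f"l{i}", "t1", y)
        for i, reps in enumerate(y_by_line_rep)
        for y in np.atleast_1d(reps)
    ]
    return sg.PhenoTable(pd.DataFrame(rows, columns=["line", "trial", "y"]))


class TestClosedForms:
    def test_balanced_one_way_matches_anova_reml(self):
        # balanced one-way random effects: REML == ANOVA estimators
        # sigma_e^2 = MSE, sigma_g^2 = (MSA - MSE) / r
        rng = np.random.default_rng(42)
        a, r = 100, 3
        g = rng.normal(0, 1.0, a)
        y = g[:, None] + rng.normal(0, 1.0, (a, r))
        pheno = _one_trial_pheno(y)
        fit = sg.fit_reml(pheno, sg.ModelSpec("y", [("G", _identity_kernel(a))]), tol=1e-10)
        line_means = y.mean(axis=1)
        msa = r * np.sum((line_means - y.mean()) ** 2) / (a - 1)
        mse = np.sum((y - line_means[:, None]) ** 2) / (a * (r - 1))
        assert fit.sigma2["residual"] == pytest.approx(mse, abs=1e-6)
        assert fit.sigma2["G"] == pytest.approx((msa - mse) / r, abs=1e-6)

    def test_single_record_ridge_identity(self):
        # one record per line, intercept only: g = h^2-shrunk centered y
        rng = np.random.default_rng(43)
        n = 120
        y = rng.normal(0, 1, n) + rng.normal(0, 1, n)
        pheno = _one_trial_pheno([[v] for v in y])
        fit = sg.fit_reml(pheno, sg.ModelSpec("y", [("G", _identity_kernel(n))]), tol=1e-10)
        h2 = fit.sigma2["G"] / (fit.sigma2["G"] + fit.sigma2["residual"])
        expected = h2 * (y - y.mean())
        np.testing.assert_allclose(fit.blups["G"].to_numpy(), expected, atol=1e-8)

    def test_blup_shrinkage_scales_with_record_count(self):
        # balanced r records/line: shrinkage = r sg2 / (r sg2 + se2)
        rng = np.random.default_rng(44)
        n, r = 80, 4
        g = rng.normal(0, 1.0, n)
        y = g[:, None] + rng.normal(0, 1.0, (n, r))
        pheno = _one_trial_pheno(y)
        fit = sg.fit_reml(pheno, sg.ModelSpec("y", [("G", _identity_kernel(n))]), tol=1e-10)
        sg2, se2 = fit.sigma2["G"], fit.sigma2["residual"]
        shrink = r * sg2 / (r * sg2 + se2)
        means = y.mean(axis=1)
        expected = shrink * (means - _gls_grand_mean(means, sg2 + se2 / r))
        np.testing.assert_allclose(fit.blups["G"].to_numpy(), expected, atol=1e-6)


def _gls_grand_mean(means, _var):
    return means.mean()  # balanced design: GLS mean = arithmetic mean


class TestLoglikOracle:
    def test_solver_loglik_matches_error_contrast_density(self, small_fit):
        V = covariance_at(small_fit)
        d = small_fit.design
        assert small_fit.loglik == pytest.approx(
            restricted_loglik_bruteforce(d.y, d.X, V), abs=1e-8
        )

    def test_loglik_oracle_on_multi_trial_unbalanced_fit(self, small_sim):
        ks = sg.model_kernels(small_sim.marker_set, "GxG")
        ph = sg.standardize_phenotypes(small_sim.pheno, ["yield"])
        fit = sg.fit_reml(ph, sg.ModelSpec("yield", list(zip(("G", "I"), ks))))
        V = covariance_at(fit)
        assert fit.loglik == pytest.approx(
            restricted_loglik_bruteforce(fit.design.y, fit.design.X, V), abs=1e-8
        )


class TestNullSignal:
    def test_boundary_mass_matches_asymptotic_half(self):
        # with zero genetic signal the REML estimate has ~50% point mass at
        # the boundary; the non-boundary estimates stay small
        cfg = sg.SimConfig(n_lines=150, m_per_subgenome=(40, 40, 20),
                           sigma2_A=0, sigma2_B=0, sigma2_D=0, seed=2)
        ms, _ = sg.simulate_genotypes(cfg)
        kg = sg.vanraden_kernel(ms)
        rng = np.random.default_rng(7)
        n_boundary, estimates = 0, []
        reps = 40
        for _ in range(reps):
            ph = sg.PhenoTable(pd.DataFrame({
                "line": list(ms.line_ids), "trial": "t1", "y": rng.standard_normal(150),
            }))
            fit = sg.fit_reml(ph, sg.ModelSpec("y", [("G", kg)]))
            n_boundary += fit.boundary["G"]
            estimates.append(fit.sigma2["G"])
        se = np.sqrt(0.25 / reps)
        assert abs(n_boundary / reps - 0.5) < 3 * se + 0.05
        assert np.mean(estimates) < 0.15  # well below the residual variance of 1


class TestVarianceRecovery:
    def test_abd_component_ranks_recovered(self):
        # sigma2 A:B:D = 0.3:0.4:0.1 -> fitted components usually rank B>A>D
        hits = 0
        reps = 10
        for s in range(reps):
            cfg = sg.SimConfig(n_lines=250, m_per_subgenome=(80, 90, 50), seed=100 + s)
            data = sg.simulate_dataset(cfg)
            ks = sg.model_kernels(data.marker_set, "ABD")
            spec = sg.ModelSpec("yield", list(zip(("A", "B", "D"), ks)))
            fit = sg.fit_reml(data.pheno, spec)
            if fit.sigma2["B"] > fit.sigma2["A"] > fit.sigma2["D"]:
                hits += 1
        assert hits >= 7


class TestModelComparison:
    def test_aic_deterministic_on_refit(self, small_sim, small_fit):
        ks = sg.model_kernels(small_sim.marker_set, "ABD")
        ph = sg.standardize_phenotypes(small_sim.pheno, ["yield"])
        refit = sg.fit_reml(ph, sg.ModelSpec("yield", list(zip(("A", "B", "D"), ks))))
        assert sg.model_aic(refit) == pytest.approx(small_fit.aic, abs=1e-8)
        assert refit.aic == pytest.approx(-2 * refit.loglik + 2 * 4)

    def test_aic_prefers_true_model_class(self):
        # data without epistasis: the additive model usually wins on AIC;
        # with strong epistasis the epistatic model usually wins
        wins_null, wins_epi = 0, 0
        reps = 8
        for s in range(reps):
            for epi, counter in ((0.0, "null"), (0.5, "epi")):
                cfg = sg.SimConfig(n_lines=200, m_per_subgenome=(60, 70, 40),
                                   sigma2_AB=epi, records_per_line=2, seed=500 + s)
                data = sg.simulate_dataset(cfg)
                ph = data.pheno
                add = sg.fit_reml(ph, _spec(data, "ABD"))
                full = sg.fit_reml(ph, _spec(data, "ABDxABD"))
                if counter == "null" and add.aic <= full.aic:
                    wins_null += 1
                if counter == "epi" and full.aic < add.aic:
                    wins_epi += 1
        assert wins_null > reps / 2
        assert wins_epi > reps / 2

    def test_compare_aic_warns_on_different_fixed_designs(self, small_fit):
        other_pheno = _one_trial_pheno([[0.3], [1.2], [-0.5], [0.9]] * 10)
        other = sg.fit_reml(other_pheno, sg.ModelSpec("y", [("G", _identity_kernel(40))]))
        with pytest.warns(UserWarning, match="fixed-effect designs"):
            sg.compare_aic([small_fit, other])


def _spec(data, model):
    ks = sg.model_kernels(data.marker_set, model)
    return sg.ModelSpec("yield", list(zip(sg.MODEL_TERMS[model], ks)))


class TestLikelihoodRatioTest:
    def test_identical_fits_give_zero_statistic(self, small_fit):
        res = sg.likelihood_ratio_test(small_fit, small_fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_invariant_to_term_order(self, small_sim):
        ph = sg.standardize_phenotypes(small_sim.pheno, ["yield"])
        ks = sg.model_kernels(small_sim.marker_set, "ABD")
        fwd = sg.fit_reml(ph, sg.ModelSpec("yield", list(zip(("A", "B", "D"), ks))))
        rev = sg.fit_reml(ph, sg.ModelSpec("yield", list(zip(("D", "B", "A"), ks[::-1]))))
        assert fwd.loglik == pytest.approx(rev.loglik, abs=1e-6)

    def test_non_nested_models_rejected(self, small_sim, small_fit):
        ph = sg.standardize_phenotypes(small_sim.pheno, ["yield"])
        kg = sg.model_kernels(small_sim.marker_set, "G")
        gfit = sg.fit_reml(ph, sg.ModelSpec("yield", [("G", kg[0])]))
        with pytest.raises(FitError, match="nested"):
            sg.likelihood_ratio_test(small_fit, gfit)

    def test_boundary_mixture_halves_pvalue(self, small_sim):
        ph = sg.standardize_phenotypes(small_sim.pheno, ["yield"])
        full = sg.fit_reml(ph, _spec_on(small_sim, ("A", "B", "D")))
        red = sg.fit_reml(ph, _spec_on(small_sim, ("A", "B")))
        mix = sg.likelihood_ratio_test(full, red)
        plain = sg.likelihood_ratio_test(full, red, boundary_mixture=False)
        if mix.statistic > 0:
            assert mix.p_value == pytest.approx(plain.p_value / 2)
        assert mix.df == 1


def _spec_on(data, labels):
    sub = sg.subgenome_kernels(data.marker_set, nugget=0.0)
    return sg.ModelSpec("yield", [(l, sub[l].with_nugget()) for l in labels])


class TestSamplingCorrelations:
    def test_single_component_is_unit(self):
        rng = np.random.default_rng(50)
        n = 60
        y = rng.normal(size=n)
        ph = _one_trial_pheno([[v] for v in y])
        fit = sg.fit_reml(ph, sg.ModelSpec("y", [("G", _identity_kernel(n))]))
        # variance parameters: G + residual -> 2x2 with unit diagonal
        corr = sg.sampling_correlations(fit)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)

    def test_disjoint_line_blocks_give_near_zero_correlation(self):
        # two kernels living on disjoint halves of the population: their
        # variance estimates draw on disjoint data -> near-orthogonal AI
        rng = np.random.default_rng(51)
        n = 200
        half = n // 2
        ids = tuple(f"l{i}" for i in range(n))
        K1 = np.zeros((n, n)); K1[:half, :half] = np.eye(half)
        K2 = np.zeros((n, n)); K2[half:, half:] = np.eye(half)
        g = np.concatenate([rng.normal(0, 1, half), rng.normal(0, 1.2, half)])
        # two records per line so residual and line variances are separable
        y = g[:, None] + rng.normal(0, 1, (n, 2))
        ph = _one_trial_pheno(y)
        spec = sg.ModelSpec("y", [
            ("first", sg.GeneticKernel(K1, ids, "first", c=1.0)),
            ("second", sg.GeneticKernel(K2, ids, "second", c=1.0)),
        ])
        fit = sg.fit_reml(ph, spec)
        corr = sg.sampling_correlations(fit)
        assert abs(corr.loc["first", "second"]) < 0.2


class TestContracts:
    def test_reconstruction_identity(self, small_fit):
        dec = fitted_decomposition(small_fit)
        resid = dec["y"] - dec.drop(columns="y").sum(axis=1)
        assert float(np.abs(resid).max()) < 1e-8

    def test_boundary_terms_have_zero_blups(self, small_sim):
        cfg = sg.SimConfig(n_lines=120, m_per_subgenome=(40, 50, 20), seed=1)
        data = sg.simulate_dataset(cfg)  # epistasis truly zero
        fit = sg.fit_reml(data.pheno, _spec(data, "ABDxABD"))
        for term, is_boundary in fit.boundary.items():
            if term != "residual" and is_boundary:
                assert fit.sigma2[term] == 0.0
                np.testing.assert_array_equal(sg.blup_effects(fit)[term].to_numpy(), 0.0)

    def test_aliased_fixed_design_names_columns(self, small_sim):
        # a structure covariate identical to a trial contrast is aliased
        ms = small_sim.marker_set
        basis = sg.decompose_structure(ms, k=1)
        recs = pd.DataFrame({
            "line": list(ms.line_ids),
            "trial": ["t1" if i < 60 else "t2" for i in range(ms.n_lines)],
            "y": np.arange(ms.n_lines, dtype=float) % 7,
        })
        dup = np.where(np.arange(ms.n_lines) < 60, 0.0, 1.0)
        bad_basis = sg.StructureBasis(
            Q=dup[:, None], singular_values=np.array([1.0]), k=1,
            m_tilde=basis.m_tilde, line_ids=ms.line_ids, column_means=basis.column_means,
        )
        kg = sg.vanraden_kernel(ms)
        with pytest.raises(FitError, match="aliased"):
            sg.fit_reml(sg.PhenoTable(recs), sg.ModelSpec("y", [("G", kg)], structure=bad_basis))

    def test_records_for_unknown_lines_rejected(self):
        ph = _one_trial_pheno([[0.1], [0.2], [0.3]])
        with pytest.raises(FitError, match="absent"):
            sg.fit_reml(ph, sg.ModelSpec("y", [("G", _identity_kernel(2))]))
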