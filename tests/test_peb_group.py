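"""Group-level machinery: PEB, Bayesian model reduction, BMA, contrasts."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from dcmpeb.peb_group import (OFF_VARIANCE, PEBDesign, bayes_factor_null,
                              bayesian_contrast, bmr_evidence, fit_peb,
                              greedy_search, make_peb_design,
                              posterior_probability)
from dcmpeb.synthetic_cohort import (CohortSpec, behavior_table,
                                     generate_cohort, synthetic_posteriors)
from dcmpeb.variational_inversion import PosteriorEstimate, PriorSpec


def _posterior(mean, cov, priors):
    return PosteriorEstimate(
        mean=np.asarray(mean, float), cov=np.asarray(cov, float),
        free_energy=0.0, f_trace=np.array([0.0]), converged=True,
        noise_log_precisions=np.zeros(4), param_map=priors.param_map,
        prior=priors)


@pytest.fixture(scope="module")
def b_cohort(short_paradigm):
    spec = CohortSpec(n_subjects=30, n_female=15, master_seed=5)
    subs = generate_cohort(spec, short_paradigm)
    priors = PriorSpec.default()
    posts = synthetic_posteriors(subs, priors, error_sd=0.05, seed=9)
    return subs, posts, priors


class TestBMR:
    @pytest.fixture(scope="class")
    @staticmethod
    def gaussian_toy():
        rng = np.random.default_rng(1)
        n, p = 30, 5
        X = rng.normal(size=(n, p))
        y = X @ (rng.normal(size=p) * 0.5) + rng.normal(0, 0.3, n)
        sig2 = 0.09
        v0 = np.full(p, 0.5)
        P = X.T @ X / sig2 + np.diag(1 / v0)
        S = np.linalg.inv(P)
        mu = S @ (X.T @ y / sig2)
        def evidence(v):
            C = sig2 * np.eye(n) + (X * v) @ X.T
            return multivariate_normal.logpdf(y, np.zeros(n), C)
        return X, y, sig2, v0, mu, S, evidence

    def test_identity_reduction_changes_nothing(self, gaussian_toy):
        _, _, _, v0, mu, S, _ = gaussian_toy
        dF, mur, Sr = bmr_evidence(np.zeros(5), np.diag(v0), mu, S,
                                   np.zeros(5), np.diag(v0))
        assert abs(dF) < 1e-10
        assert np.allclose(mur, mu)
        assert np.allclose(Sr, S)

    def test_matches_explicit_refit_evidence(self, gaussian_toy):
        X, y, sig2, v0, mu, S, evidence = gaussian_toy
        for off in ([0], [1, 3], [0, 2, 4]):
            vr = v0.copy()
            vr[off] = OFF_VARIANCE
            dF, mur, _ = bmr_evidence(np.zeros(5), np.diag(v0), mu, S,
                                      np.zeros(5), np.diag(vr))
            refit = evidence(vr) - evidence(v0)
            assert abs(dF - refit) < 1e-8
            # reduced posterior matches the explicitly refit posterior
            Pr = X.T @ X / sig2 + np.diag(1 / vr)
            mur_exact = np.linalg.solve(Pr, X.T @ y / sig2)
            assert np.allclose(mur, mur_exact, atol=1e-8)

    def test_removing_a_supported_parameter_costs_evidence(self, gaussian_toy):
        _, _, _, v0, mu, S, _ = gaussian_toy
        j = int(np.argmax(np.abs(mu) / np.sqrt(np.diag(S))))
        vr = v0.copy()
        vr[j] = OFF_VARIANCE
        dF, _, _ = bmr_evidence(np.zeros(5), np.diag(v0), mu, S,
                                np.zeros(5), np.diag(vr))
        assert dF < 0


class TestFitPEB:
    def test_identical_subjects_intercept_only(self):
        priors = PriorSpec.default()
        pm = priors.param_map
        shared = np.zeros(len(pm))
        idx = [k for k, a in enumerate(pm.addresses) if a[0] == "C"]
        shared[idx] = 0.15
        cov = np.eye(len(pm)) * 1e-6
        posts = [_posterior(shared, cov, priors) for _ in range(12)]
        design = PEBDesign(np.ones((12, 1)), ("mean",), np.array(idx))
        peb = fit_peb(posts, design)
        assert np.allclose(peb.beta_mean[0], 0.15, atol=1e-3)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        X[:, 1] = 0.0
        with pytest.raises(ValueError):
            PEBDesign(X, ("mean", "junk"), np.arange(3))

    def test_sex_effect_sign_recovered_across_replications(self, short_paradigm):
        priors = PriorSpec.default()
        pm = priors.param_map
        idx = [k for k, a in enumerate(pm.addresses) if a[0] == "A"]
        labels = [pm.addresses[k] for k in idx]
        j = labels.index(("A", 2, 3))
        hits = 0
        for rep in range(20):
            spec = CohortSpec(n_subjects=30, n_female=15, master_seed=1000 + rep)
            subs = generate_cohort(spec, short_paradigm)
            posts = synthetic_posteriors(subs, priors, error_sd=0.05,
                                         seed=500 + rep)
            design = make_peb_design(behavior_table(subs), pm, matrix="A")
            peb = fit_peb(posts, design)
            if peb.beta_mean[1, j] < 0:   # configured female-male shift -0.1
                hits += 1
        assert hits >= 18   # >= 90% of replications

    def test_null_cohort_covariate_effects_center_on_zero(self, short_paradigm):
        priors = PriorSpec.default()
        pm = priors.param_map
        zs = []
        for rep in range(6):
            spec = CohortSpec(n_subjects=24, n_female=12, subject_sd=0.05,
                              sex_effects={}, performance_slopes={},
                              master_seed=2000 + rep)
            subs = generate_cohort(spec, short_paradigm)
            posts = synthetic_posteriors(subs, priors, error_sd=0.05,
                                         seed=700 + rep)
            design = make_peb_design(behavior_table(subs), pm, matrix="B")
            peb = fit_peb(posts, design)
            zs.append(peb.effect_z()[1:].ravel())   # covariate rows only
        zs = np.concatenate(zs)
        frac = np.mean(np.abs(zs) > 1.96)
        assert abs(zs.mean()) < 0.2
        assert frac < 0.12   # ~5% nominal, binomial + shrinkage slack


class TestGreedySearchAndBMA:
    def test_final_iteration_averages_256_models(self, b_cohort):
        _, posts, priors = b_cohort
        design = PEBDesign(np.ones((len(posts), 1)), ("mean",),
                           np.array([k for k, a in
                                     enumerate(priors.param_map.addresses)
                                     if a[0] == "B"]))
        peb = fit_peb(posts, design)
        bma = greedy_search(peb)
        assert bma.in_play.size == 8
        assert bma.n_models == 256
        assert abs(bma.model_probabilities.sum() - 1.0) < 1e-10

    def test_fewer_than_eight_candidates_shrinks_model_space(self, b_cohort):
        _, posts, priors = b_cohort
        idx = np.array([k for k, a in enumerate(priors.param_map.addresses)
                        if a[0] == "B"])
        design = PEBDesign(np.ones((len(posts), 1)), ("mean",), idx)
        peb = fit_peb(posts, design)
        bma = greedy_search(peb, candidates=np.arange(5))
        assert bma.n_models <= 2 ** 5

    def test_strongly_supported_parameters_survive(self, b_cohort):
        subs, posts, priors = b_cohort
        pm = priors.param_map
        idx = np.array([k for k, a in enumerate(pm.addresses) if a[0] == "B"])
        labels = [pm.addresses[k] for k in idx]
        design = PEBDesign(np.ones((len(posts), 1)), ("mean",), idx,
                           tuple(labels))
        peb = fit_peb(posts, design)
        bma = greedy_search(peb)
        # the large configured NoGo modulations carry strong evidence
        for addr in [("B", 1, 1, 0), ("B", 1, 3, 0)]:
            assert posterior_probability(bma, ("mean", addr)) > 0.95
        # BMA means stay close to the full PEB estimate for them
        for addr in [("B", 1, 1, 0), ("B", 1, 3, 0)]:
            j = labels.index(addr)
            assert abs(bma.mean[j] - peb.beta_mean[0, j]) < 0.05

    def test_true_zero_modulations_get_pruned(self, short_paradigm):
        # entries never touched by the template, effects, or scatter are
        # switched off with high sensitivity
        priors = PriorSpec.default()
        pm = priors.param_map
        spec = CohortSpec(n_subjects=30, n_female=15, subject_sd=0.0,
                          sex_effects={}, performance_slopes={},
                          master_seed=3)
        subs = generate_cohort(spec, short_paradigm)
        posts = synthetic_posteriors(subs, priors, error_sd=0.05, seed=11)
        idx = np.array([k for k, a in enumerate(pm.addresses) if a[0] == "B"])
        labels = [pm.addresses[k] for k in idx]
        design = PEBDesign(np.ones((len(posts), 1)), ("mean",), idx,
                           tuple(labels))
        peb = fit_peb(posts, design)
        bma = greedy_search(peb)
        template_B = subs[0].true_params.B
        true_zero = [j for j, (_, k, i, l) in enumerate(labels)
                     if template_B[k, i, l] == 0]
        pp_zero = bma.pp[true_zero]
        assert np.mean(pp_zero < 0.5) >= 0.8


class TestContrastsAndBayesFactors:
    def _trivial_bma(self, mean, var, prior_var=1.0):
        from dcmpeb.peb_group import BMAResult
        n = len(mean)
        return BMAResult(
            model_masks=np.ones((1, 0), dtype=int),
            model_free_energies=np.zeros(1),
            model_probabilities=np.ones(1),
            in_play=np.array([], dtype=int), pruned=np.array([], dtype=int),
            mean=np.asarray(mean, float), cov=np.diag(var),
            pp=np.ones(n), prior_mean=np.zeros(n),
            prior_variance=np.full(n, prior_var),
            covariate_names=("mean",),
            parameter_labels=tuple(str(i) for i in range(n)))

    def test_directional_probability_matches_normal_cdf(self):
        bma = self._trivial_bma([-0.3], [0.01])
        ct = bayesian_contrast(bma, np.array([1.0]))
        assert ct["pp_negative"] == pytest.approx(norm.cdf(3.0), abs=1e-10)

    def test_zero_contrast_flagged(self):
        bma = self._trivial_bma([0.1, 0.2], [0.01, 0.01])
        with pytest.raises(ValueError):
            bayesian_contrast(bma, np.zeros(2))

    def test_bayes_factor_unchanged_posterior_is_one(self):
        bma = self._trivial_bma([0.0], [1.0], prior_var=1.0)
        assert bayes_factor_null(bma, 0) == pytest.approx(1.0)

    def test_bayes_factor_worked_example(self):
        # prior N(0,1), posterior N(1, 0.25): phi(0;0,1)/phi(0;1,0.25)
        bma = self._trivial_bma([1.0], [0.25], prior_var=1.0)
        expected = norm.pdf(0, 0, 1) / norm.pdf(0, 1, 0.5)
        assert bayes_factor_null(bma, 0) == pytest.approx(expected)
        assert bayes_factor_null(bma, 0) == pytest.approx(3.6945, abs=1e-3)

    def test_displaced_posterior_gives_large_bayes_factor(self):
        bma = self._trivial_bma([0.8], [0.01])
        assert bayes_factor_null(bma, 0) > 100
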