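import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import capturebayes as cb
from capturebayes.domain import CaptureDataset, build_design_matrix
from capturebayes.model import (ModelSpec, ParameterState, evidence_threshold,
                                inclusion_probabilities, linear_predictor,
                                log_likelihood, log_prior, posterior_summary,
                                prepare_model_data, run_mcmc)

from _oracles import bernoulli_expanded_loglik, quadrature_selection_posterior
from conftest import make_visit


def _state_for(data, **kw):
    J = data.X.shape[1]
    defaults = dict(
        alpha=np.zeros(len(data.years)), beta=np.zeros(J),
        gamma=np.ones(J), eps_forest=np.zeros(len(data.forest_ids)),
        eps_site=np.zeros(len(data.site_ids)),
        sigma_beta=1.0, sigma_forest=1.0, sigma_site=1.0)
    defaults.update(kw)
    return ParameterState(**defaults)


@pytest.fixture
def two_site_data():
    visits = [
        make_visit(site="s0", forest="f0", x=0.0, traps=5, nights=2,
                   counts={"total": 2, "females": 2}),
        make_visit(site="s1", forest="f1", x=1000.0, traps=5, nights=1,
                   counts={"total": 1, "females": 1}),
    ]
    ds = CaptureDataset(visits=visits)
    return prepare_model_data(ds, ModelSpec(covariates=("Condition",)))


class TestLikelihood:
    def test_all_zero_parameters_give_half_probability(self):
        from capturebayes.model import ModelData
        data = ModelData(
            y=np.array([0]), n=np.array([10]), X=np.zeros((1, 0)),
            years=(2004,), year_idx=np.array([0]), forest_ids=("f0",),
            forest_idx=np.array([0]), site_ids=("s0",),
            site_idx=np.array([0]), site_coords=np.zeros((1, 2)),
            corr_chol=np.eye(1))
        st = _state_for(data)
        assert log_likelihood(st, data) == pytest.approx(10 * np.log(0.5))

    def test_excluded_covariates_contribute_nothing(self, two_site_data):
        st_off = _state_for(two_site_data, beta=np.array([2.5]),
                            gamma=np.array([0.0]))
        st_zero = _state_for(two_site_data, beta=np.array([0.0]),
                             gamma=np.array([1.0]))
        assert log_likelihood(st_off, two_site_data) == pytest.approx(
            log_likelihood(st_zero, two_site_data))

    def test_matches_bernoulli_expansion_up_to_constant(self, tiny_dataset):
        data = prepare_model_data(tiny_dataset, ModelSpec())
        rng = np.random.default_rng(1)
        st = _state_for(data, alpha=rng.normal(size=len(data.years)),
                        beta=rng.normal(scale=0.5, size=data.X.shape[1]))
        eta = linear_predictor(st, data)
        p = 1 / (1 + np.exp(-eta))
        expanded = bernoulli_expanded_loglik(data.y, data.n, p)
        from scipy.special import gammaln
        const = np.sum(gammaln(data.n + 1) - gammaln(data.y + 1)
                       - gammaln(data.n - data.y + 1))
        assert log_likelihood(st, data) == pytest.approx(expanded + const)

    def test_invariant_under_visit_permutation(self, small_dataset):
        ds, _ = small_dataset
        data = prepare_model_data(ds, ModelSpec())
        rng = np.random.default_rng(2)
        st = _state_for(data, alpha=rng.normal(size=len(data.years)),
                        beta=rng.normal(scale=0.3, size=data.X.shape[1]),
                        eps_forest=rng.normal(size=len(data.forest_ids)),
                        eps_site=rng.normal(size=len(data.site_ids)))
        ll = log_likelihood(st, data)
        perm = rng.permutation(len(ds.visits))
        ds2 = CaptureDataset(visits=[ds.visits[i] for i in perm],
                             availability_mask=ds.availability_mask)
        data2 = prepare_model_data(ds2, ModelSpec())
        st2 = _state_for(
            data2,
            alpha=st.alpha[[data2.years.index(y) for y in data2.years]],
            beta=st.beta,
            eps_forest=np.array([st.eps_forest[data.forest_ids.index(f)]
                                 for f in data2.forest_ids]),
            eps_site=np.array([st.eps_site[data.site_ids.index(s)]
                               for s in data2.site_ids]))
        assert log_likelihood(st2, data2) == pytest.approx(ll)


class TestPrior:
    def test_sigma_beta_outside_support(self, two_site_data):
        st = _state_for(two_site_data, sigma_beta=2.5)
        assert log_prior(st, ModelSpec(covariates=("Condition",)),
                         two_site_data) == -np.inf

    def test_inclusion_prior_is_half(self, two_site_data):
        spec = ModelSpec(covariates=("Condition",))
        st1 = _state_for(two_site_data, gamma=np.array([1.0]))
        st0 = _state_for(two_site_data, gamma=np.array([0.0]))
        # equal joint density either way => marginal Pr(gamma=1) = 0.5
        assert log_prior(st1, spec, two_site_data) == pytest.approx(
            log_prior(st0, spec, two_site_data))

    def test_matches_term_by_term_hand_computation(self, two_site_data):
        spec = ModelSpec(covariates=("Condition",))
        rng = np.random.default_rng(3)
        st = _state_for(two_site_data,
                        alpha=rng.normal(size=len(two_site_data.years)),
                        beta=np.array([0.4]), gamma=np.array([1.0]),
                        eps_forest=np.array([0.1, -0.2]),
                        eps_site=np.array([0.05, -0.1]),
                        sigma_beta=0.8, sigma_forest=0.6, sigma_site=0.7)
        d = 1000.0
        rho = cb.disc_correlation(d, spec.range_m)
        cov = 0.7**2 * np.array([[1 + 1e-8, rho], [rho, 1 + 1e-8]])
        expected = (
            norm.logpdf(st.alpha, 0, 10).sum()
            + np.log(0.5)
            + norm.logpdf(0.4, 0, 0.8)
            + np.log(1 / 2.0) + 2 * np.log(1 / 5.0)
            + norm.logpdf(st.eps_forest, 0, 0.6).sum()
            + multivariate_normal.logpdf(st.eps_site, np.zeros(2), cov)
        )
        assert log_prior(st, spec, two_site_data) == pytest.approx(
            expected, rel=1e-9)


class TestEvidenceThreshold:
    @pytest.mark.parametrize("prior_odds,fold,expected",
                             [(1, 3, 0.75), (1, 1, 0.5), (2, 3, 6 / 7)])
    def test_odds_identity(self, prior_odds, fold, expected):
        assert evidence_threshold(prior_odds, fold) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            evidence_threshold(0.0, 3.0)


class TestSampler:
    def test_same_seed_gives_identical_draws(self, tiny_dataset):
        spec = ModelSpec(chains=2, iterations=400, burn_in=100, seed=9,
                         covariates=("Condition",))
        s1 = run_mcmc(tiny_dataset, spec)
        s2 = run_mcmc(tiny_dataset, spec)
        np.testing.assert_array_equal(s1.alpha, s2.alpha)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.gamma, s2.gamma)
        np.testing.assert_array_equal(s1.eps_site, s2.eps_site)

    def test_draw_count_contract(self, tiny_dataset):
        spec = ModelSpec(chains=2, iterations=600, burn_in=200, thin=2,
                         seed=1, covariates=("Condition",))
        s = run_mcmc(tiny_dataset, spec)
        assert s.alpha.shape[:2] == (2, 200)

    def test_null_data_downweights_covariate(self):
        # no captures in many trap-nights: the covariate should not be
        # favoured over the null model
        visits = [make_visit(site=f"s{i}", forest=f"f{i}", x=i * 1000.0,
                             traps=6, nights=5, counts={"total": 0},
                             covariates={"Condition": float(i)})
                  for i in range(4)]
        ds = CaptureDataset(visits=visits)
        spec = ModelSpec(covariates=("Condition",), chains=2,
                         iterations=8000, burn_in=2000, seed=4,
                         include_site_effects=False,
                         include_forest_effects=False)
        samples = run_mcmc(ds, spec)
        pr = inclusion_probabilities(samples)["Condition"]
        design = build_design_matrix(ds)
        j = design.covariate_names.index("Condition")
        oracle = quadrature_selection_posterior(
            samples.data.y, samples.data.n, design.X[:, [j]])
        assert pr < 0.5
        assert pr == pytest.approx(float(oracle["pr_include"][0]), abs=0.05)


class TestSummaries:
    def _dummy_samples(self, data, spec, beta, gamma):
        C, D, J = 1, beta.shape[0], beta.shape[1]
        return cb.PosteriorSamples(
            spec=spec, data=data,
            alpha=np.zeros((1, D, len(data.years))),
            beta=beta[None, :, :], gamma=gamma[None, :, :],
            sigma_beta=np.ones((1, D)), sigma_forest=np.ones((1, D)),
            sigma_site=np.ones((1, D)),
            eps_forest=np.zeros((1, D, len(data.forest_ids))),
            eps_site=np.zeros((1, D, len(data.site_ids))))

    def test_inclusion_probability_is_indicator_mean(self, two_site_data):
        spec = ModelSpec(covariates=("Condition",))
        gamma = np.array([[1.0], [1.0], [0.0], [0.0]])
        s = self._dummy_samples(two_site_data, spec,
                                np.ones((4, 1)), gamma)
        assert inclusion_probabilities(s)["Condition"] == 0.5

    def test_degenerate_zero_draws(self, two_site_data):
        spec = ModelSpec(covariates=("Condition",))
        s = self._dummy_samples(two_site_data, spec, np.zeros((4, 1)),
                                np.zeros((4, 1)))
        tab = posterior_summary(s)
        assert (tab["mean"] == 0).all() and (tab["sd"] == 0).all()

    def test_effective_coefficient_is_mixture_mean(self, two_site_data):
        # two-point sample set: included draws at beta=2, excluded at beta=5
        spec = ModelSpec(covariates=("Condition",))
        beta = np.array([[2.0], [2.0], [2.0], [5.0]])
        gamma = np.array([[1.0], [1.0], [1.0], [0.0]])
        s = self._dummy_samples(two_site_data, spec, beta, gamma)
        tab = posterior_summary(s).set_index("parameter")
        # Pr(gamma=1) * E[beta | gamma=1] = 0.75 * 2
        assert tab.loc["Condition", "mean"] == pytest.approx(1.5)
        assert tab.loc["Condition", "pr_nonzero"] == pytest.approx(0.75)

    def test_summary_row_order_follows_covariate_order(self, strong_signal_fit):
        _, _, samples = strong_signal_fit
        tab = posterior_summary(samples)
        assert list(tab["parameter"][:3]) == ["alpha_2004", "alpha_2005",
                                              "alpha_2011"]
        assert list(tab["parameter"][3:]) == list(cb.COVARIATE_NAMES)

    def test_strong_signal_flags_true_covariates(self, strong_signal_fit):
        _, truth, samples = strong_signal_fit
        tab = posterior_summary(samples).set_index("parameter")
        for name in truth.nonzero_covariates():
            assert tab.loc[name, "strong"]
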