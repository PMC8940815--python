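"""FOCE engine tests: analytic exactness, degenerate recovery, strategies."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pulmodeconv.models import (
    AbsorptionVariant,
    ConfigurationError,
    ParameterSet,
    Route,
)
from pulmodeconv.nlme import (
    NlmeConfig,
    Strategy,
    _FoceProblem,
    _marshal,
    _Occasion,
    _Subject,
    fit_iv_stage,
    fit_nlme,
    fit_nlme_config,
)
from pulmodeconv.simulate import (
    Occasion,
    StudyArm,
    TrialDesign,
    VariabilityModel,
    simulate_trial,
    single_dose_occasion,
)


class _LinearToyProblem(_FoceProblem):
    """A model *linear* in eta with additive error, for which the Laplace
    (FOCE) marginal likelihood is exact: y = a + b*eta + eps."""

    def __init__(self, cfg, subjects, a, b):
        super().__init__(cfg, subjects)
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)

    def occasion_params(self, base, subj, re_vec):
        return [re_vec]

    def predict(self, subj, params_per_occ):
        eta = params_per_occ[0]
        value = eta[0] if len(eta) else 0.0
        return self.a + self.b * value


class TestFoceExactness:
    def test_matches_closed_form_marginal_likelihood(self):
        """On a linear-in-eta additive-error toy model the FOCE objective
        equals the closed-form Gaussian marginal -2 log-likelihood."""
        rng = np.random.default_rng(0)
        a = np.array([1.0, 2.0, 3.0, 2.5])
        b = np.array([0.5, 1.0, -0.3, 0.8])
        omega, sigma = 0.4, 0.2
        y = a + b * rng.normal(0, omega) + rng.normal(0, sigma, 4)

        base = ParameterSet(cl=1.0, v1=1.0)
        cfg = NlmeConfig(
            variant=None, base=base, theta=(), eta=("cl",),
            omega_init={"cl": omega}, sigma_init=sigma,
            error_model="additive",
        )
        subj = _Subject(1, [_Occasion(Route.IV, 1, [(0.0, 1.0)],
                                      np.arange(4.0), y)])
        problem = _LinearToyProblem(cfg, [subj], a, b)
        foce = problem.per_subject_neg2ll(problem.pack_initial())[0]

        cov = sigma**2 * np.eye(4) + omega**2 * np.outer(b, b)
        resid = y - a
        sign, logdet = np.linalg.slogdet(cov)
        exact = 4 * math.log(2 * math.pi) + logdet + resid @ np.linalg.solve(cov, resid)
        assert foce == pytest.approx(exact, abs=1e-6)


class TestDegenerateRecovery:
    def test_zero_variability_reduces_to_naive_fit(self):
        """With no random effects and no residual noise, the joint (ALL)
        fit recovers the population parameters to optimizer tolerance."""
        variant = AbsorptionVariant.from_name("I")
        params = ParameterSet(cl=10.0, v1=20.0, f_pul=0.5, k_fast=0.15)
        sampling = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)
        design = TrialDesign(
            arms=(
                StudyArm(Route.IV, 4, (single_dose_occasion(50.0, sampling),)),
                StudyArm(Route.INHALED, 4, (single_dose_occasion(100.0, sampling),)),
            ),
            crossover=True,
        )
        ds, _ = simulate_trial(variant, params, design, VariabilityModel.none(), seed=0)
        # start away from the truth
        start = replace(params, cl=14.0, v1=15.0, f_pul=0.35, k_fast=0.3)
        cfg = NlmeConfig(
            variant=variant, base=start, theta=("cl", "v1", "f_pul", "k_fast"),
            eta=(), sigma_init=0.1, fix_sigma=True, strategy="ALL",
        )
        fit = fit_nlme_config(ds, cfg, seed=1)
        assert fit.converged
        assert fit.params.cl == pytest.approx(10.0, rel=0.02)
        assert fit.params.v1 == pytest.approx(20.0, rel=0.02)
        assert fit.params.f_pul == pytest.approx(0.5, rel=0.02)
        assert fit.params.k_fast == pytest.approx(0.15, rel=0.02)


@pytest.fixture(scope="module")
def crossover_fit_inputs():
    variant = AbsorptionVariant.from_name("I")
    params = ParameterSet(cl=20.0, v1=25.0, q2=15.0, v2=80.0,
                          f_pul=0.5, k_fast=0.1)
    sampling = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0)
    design = TrialDesign(
        arms=(
            StudyArm(Route.IV, 8, (single_dose_occasion(50.0, sampling),)),
            StudyArm(Route.INHALED, 8, (single_dose_occasion(200.0, sampling),)),
        ),
        crossover=True,
    )
    variability = VariabilityModel(iiv={"cl": 0.2, "f_pul": 0.2},
                                   residual_proportional_sd=0.1)
    ds, _ = simulate_trial(variant, params, design, variability, seed=4)
    return variant, params, ds


class TestStrategies:

    def test_ppp_ipp_all_give_comparable_exposure(self, crossover_fit_inputs):
        """The three data-combination strategies agree on the inferred
        pulmonary exposure for a well-specified model on cross-over data."""
        variant, params, ds = crossover_fit_inputs
        prior = fit_iv_stage(ds, params, iiv=["cl"], sigma_init=0.1, seed=7)
        assert prior.converged

        ratios = {}
        for strategy in (Strategy.PPP, Strategy.IPP, Strategy.ALL):
            fit = fit_nlme(ds, variant, params, strategy,
                           iiv=["cl", "f_pul"], prior=prior,
                           sigma_init=0.1, seed=8)
            assert fit.converged, strategy
            truth_exposure = params.f_pul / params.k_fast
            ratios[strategy] = (fit.params.f_pul / fit.params.k_fast) / truth_exposure
        for strategy, ratio in ratios.items():
            assert 0.7 < ratio < 1.4, (strategy, ratio)
        values = list(ratios.values())
        assert max(values) / min(values) < 1.35

    def test_ipp_requires_crossover(self):
        variant = AbsorptionVariant.from_name("I")
        params = ParameterSet(cl=20.0, v1=25.0, f_pul=0.5, k_fast=0.1)
        sampling = (0.5, 2.0, 8.0, 24.0, 48.0)
        design = TrialDesign(
            arms=(
                StudyArm(Route.IV, 3, (single_dose_occasion(50.0, sampling),)),
                StudyArm(Route.INHALED, 3, (single_dose_occasion(100.0, sampling),)),
            ),
            crossover=False,  # disjoint subjects
        )
        variability = VariabilityModel(iiv={"cl": 0.1}, residual_proportional_sd=0.05)
        ds, _ = simulate_trial(variant, params, design, variability, seed=2)
        prior = fit_iv_stage(ds, params, iiv=["cl"], sigma_init=0.05, seed=3)
        with pytest.raises(ConfigurationError, match="same subjects"):
            fit_nlme(ds, variant, params, Strategy.IPP, iiv=["cl", "f_pul"],
                     prior=prior, seed=4)

    def test_ppp_requires_prior(self, crossover_fit_inputs):
        variant, params, ds = crossover_fit_inputs
        with pytest.raises(ConfigurationError, match="prior"):
            fit_nlme(ds, variant, params, Strategy.PPP, iiv=["cl"], prior=None)


class TestConsistency:
    def test_estimates_improve_with_more_subjects(self):
        """Population estimates tighten as the cohort grows (omega, sigma
        fixed): mean absolute log-error at n=96 is below n=8."""
        variant = AbsorptionVariant.from_name("I")
        params = ParameterSet(cl=12.0, v1=30.0)
        sampling = (0.5, 1.0, 3.0, 8.0, 24.0)
        errors = {}
        for n in (8, 96):
            errs = []
            for rep in range(2):
                design = TrialDesign(
                    arms=(StudyArm(Route.IV, n, (single_dose_occasion(50.0, sampling),)),)
                )
                variability = VariabilityModel(iiv={"cl": 0.25},
                                               residual_proportional_sd=0.15)
                ds, _ = simulate_trial(variant, params, design, variability,
                                       seed=100 + rep)
                fit = fit_iv_stage(ds, params, iiv=["cl"], sigma_init=0.15,
                                   seed=rep)
                assert fit.converged
                errs.append(abs(math.log(fit.params.cl / 12.0))
                            + abs(math.log(fit.params.v1 / 30.0)))
            errors[n] = np.mean(errs)
        assert errors[96] < errors[8]


class TestMarshalling:
    def test_subjects_and_occasions_extracted(self, model_ii, small_crossover_design,
                                              mild_variability):
        variant, params = model_ii
        ds, _ = simulate_trial(variant, params, small_crossover_design,
                               mild_variability, seed=1)
        subjects = _marshal(ds)
        assert len(subjects) == 8
        assert all(len(s.occasions) == 2 for s in subjects)  # iv + inhaled
        routes = {o.route for s in subjects for o in s.occasions}
        assert routes == {Route.IV, Route.INHALED}
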