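import numpy as np
import pytest
from scipy import optimize, stats

from birthspacing.data_model import (
    CovariateSet,
    GapRecord,
    encode_covariates,
    expand_to_strata,
)
from birthspacing.pwp import (
    PWPError,
    fit_pwp_gt,
    partial_loglik,
    wald_table,
)
from birthspacing.simulate import SimulationConfig, simulate_cohort
from oracles import brute_force_partial_loglik, random_tiny_stratum


def _cov(employment="unemployed", age=20.0):
    return CovariateSet(
        woman_age_at_marriage=age,
        woman_education="secondary",
        woman_employment=employment,
        husband_age=26.0,
        husband_education="secondary",
        husband_employment="employed",
        stillbirth="no",
        age_first_pregnancy_band=">18",
        income_band="<=135",
    )


def _gap(wid, time, event, cov):
    return GapRecord(wid, 1, time, event, cov)


class TestPartialLoglik:
    def test_two_subjects_distinct_events_at_beta_zero(self):
        gaps = [_gap("a", 5.0, 1, _cov()), _gap("b", 9.0, 1, _cov())]
        ll, grad, hess = partial_loglik([0.0], gaps, 1, variables=["woman_employment"])
        # risk sets of size 2 then 1
        assert ll == pytest.approx(-np.log(2.0))

    def test_single_subject_loglik_zero_at_any_beta(self):
        gaps = [_gap("a", 5.0, 1, _cov())]
        for b in (-2.0, 0.0, 1.7):
            ll, _, _ = partial_loglik([b], gaps, 1, variables=["woman_employment"])
            assert ll == pytest.approx(0.0)

    def test_beta_zero_equals_sum_of_log_risk_set_sizes(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            gaps = random_tiny_stratum(rng)
            p = len(encode_covariates(gaps[0].covariates))
            ll, _, _ = partial_loglik(np.zeros(p), gaps, 1)
            expected = -sum(
                np.log(sum(1 for l in gaps if l.gap_time >= g.gap_time))
                for g in gaps
                if g.event
            )
            assert ll == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_agrees_with_brute_force_enumeration(self, ties):
        """Oracle equality on 200 random tiny cohorts, including tied gap
        times, at several coefficient vectors."""
        rng = np.random.default_rng(2024)
        for k in range(200):
            gaps = random_tiny_stratum(rng)
            p = len(encode_covariates(gaps[0].covariates))
            beta = rng.normal(scale=0.5, size=p)
            ll, _, _ = partial_loglik(beta, gaps, 1, ties=ties)
            oracle = brute_force_partial_loglik(beta, gaps, 1, ties=ties)
            assert ll == pytest.approx(oracle, abs=1e-10), f"cohort {k}"

    def test_gradient_and_hessian_match_finite_differences(self):
        rng = np.random.default_rng(5)
        gaps = random_tiny_stratum(rng, max_subjects=8)
        p = len(encode_covariates(gaps[0].covariates))
        beta = rng.normal(scale=0.3, size=p)

        def f(b):
            return partial_loglik(b, gaps, 1)[0]

        ll, grad, hess = partial_loglik(beta, gaps, 1)
        num_grad = optimize.approx_fprime(beta, f, 1e-6)
        assert np.allclose(grad, num_grad, atol=1e-4)
        num_hess_col = optimize.approx_fprime(
            beta, lambda b: partial_loglik(b, gaps, 1)[1][0], 1e-6
        )
        assert np.allclose(hess[0], num_hess_col, atol=1e-4)

    def test_zero_events_is_error_not_minus_inf(self):
        gaps = [_gap("a", 5.0, 0, _cov()), _gap("b", 9.0, 0, _cov())]
        with pytest.raises(PWPError, match="no events"):
            partial_loglik([0.0], gaps, 1, variables=["woman_employment"])

    def test_empty_stratum_is_error(self):
        with pytest.raises(PWPError, match="empty"):
            partial_loglik([0.0], [], 1, variables=["woman_employment"])


class TestFit:
    def test_mle_matches_brute_force_1d_maximum(self, tiny8):
        gaps = expand_to_strata(tiny8, 1)
        fit = fit_pwp_gt(gaps, strata=[1], variables=["woman_employment"])
        sf = fit.strata[1]

        neg = lambda b: -brute_force_partial_loglik(
            [b], gaps, 1, variables=["woman_employment"]
        )
        brute = optimize.minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                                         options={"xatol": 1e-8})
        assert sf.beta[0] == pytest.approx(brute.x, abs=1e-4)
        assert sf.converged and sf.score_norm < 1e-8

    def test_constant_covariate_dropped_baseline_loglik(self):
        gaps = [_gap("a", 5.0, 1, _cov()), _gap("b", 9.0, 1, _cov())]
        fit = fit_pwp_gt(gaps, strata=[1], variables=["woman_employment"])
        sf = fit.strata[1]
        assert sf.names == [] and sf.dropped == ["woman_employment[unemployed]"]
        assert sf.loglik == pytest.approx(-np.log(2.0))

    def test_hessian_negative_definite_and_score_small_at_optimum(self):
        records = simulate_cohort(SimulationConfig(n_women=400, seed=3))
        gaps = expand_to_strata(records, 2)
        fit = fit_pwp_gt(gaps, strata=[1, 2])
        for sf in fit.strata.values():
            assert sf.converged and sf.score_norm < 1e-8
            # observed information positive definite: SEs finite and positive
            assert np.all(np.isfinite(sf.se)) and np.all(sf.se > 0)

    def test_gap_time_scale_invariance(self):
        """The partial likelihood is rank-based: rescaling all gap times by
        a positive constant leaves the coefficients unchanged."""
        records = simulate_cohort(SimulationConfig(n_women=300, seed=9))
        gaps = expand_to_strata(records, 2)
        scaled = [
            GapRecord(g.woman_id, g.stratum, g.gap_time * 7.3, g.event, g.covariates)
            for g in gaps
        ]
        f1 = fit_pwp_gt(gaps, strata=[1, 2])
        f2 = fit_pwp_gt(scaled, strata=[1, 2])
        for s in (1, 2):
            assert np.allclose(f1.strata[s].beta, f2.strata[s].beta, atol=1e-8)

    def test_agrees_with_statsmodels_stratified_cox(self):
        """Independent cross-check: statsmodels PHReg with Breslow ties on
        the same per-stratum designs agrees to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        records = simulate_cohort(SimulationConfig(n_women=400, seed=77))
        gaps = expand_to_strata(records, 4)
        fit = fit_pwp_gt(gaps, strata=[1, 2, 3, 4])
        from birthspacing.data_model import encoded_covariate_names

        names = encoded_covariate_names()
        for s, sf in fit.strata.items():
            rows = [g for g in gaps if g.stratum == s]
            t = np.array([g.gap_time for g in rows])
            ev = np.array([g.event for g in rows])
            X = np.array(
                [list(encode_covariates(g.covariates).values()) for g in rows]
            )
            idx = [names.index(nm) for nm in sf.names]
            res = sm.PHReg(t, X[:, idx], status=ev, ties="breslow").fit(disp=False)
            assert np.allclose(res.params, sf.beta, atol=1e-6)
            assert np.allclose(res.bse, sf.se, atol=1e-6)

    def test_efron_agrees_with_lifelines_on_tied_data(self):
        """lifelines implements Efron ties; integer-rounded gap times force
        heavy ties and both routes must agree."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        records = simulate_cohort(SimulationConfig(n_women=250, seed=13))
        gaps = [
            GapRecord(g.woman_id, g.stratum, float(int(g.gap_time // 6)) + 1.0,
                      g.event, g.covariates)
            for g in expand_to_strata(records, 1)
        ]
        fit = fit_pwp_gt(gaps, strata=[1], ties="efron",
                         variables=["woman_employment", "age_first_pregnancy_band"])
        sf = fit.strata[1]
        df = pd.DataFrame(
            {
                "t": [g.gap_time for g in gaps],
                "e": [g.event for g in gaps],
                **{
                    nm: [encode_covariates(g.covariates)[nm] for g in gaps]
                    for nm in sf.names
                },
            }
        )
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e",
                fit_options={"precision": 1e-9})
        assert np.allclose(cph.params_[sf.names].to_numpy(), sf.beta, atol=1e-5)

    def test_separation_flagged(self):
        # employment perfectly orders the gap times -> monotone likelihood
        gaps = [
            _gap("a", 1.0, 1, _cov("unemployed")),
            _gap("b", 2.0, 1, _cov("unemployed")),
            _gap("c", 3.0, 1, _cov("employed")),
            _gap("d", 4.0, 1, _cov("employed")),
        ]
        fit = fit_pwp_gt(gaps, strata=[1], variables=["woman_employment"])
        sf = fit.strata[1]
        assert sf.separated and not sf.converged

    def test_shared_coefficients_option(self):
        records = simulate_cohort(SimulationConfig(n_women=300, seed=31))
        gaps = expand_to_strata(records, 2)
        fit = fit_pwp_gt(gaps, strata=[1, 2], shared_coefficients=True,
                         variables=["woman_employment"])
        assert fit.shared_coefficients and list(fit.strata) == [0]
        assert fit.strata[0].converged


class TestWaldTable:
    def test_reference_rows_print_unit_hazard(self):
        records = simulate_cohort(SimulationConfig(n_women=300, seed=4))
        gaps = expand_to_strata(records, 2)
        fit = fit_pwp_gt(gaps, strata=[1, 2])
        table = wald_table(fit)
        ref = table[(table.variable == "woman_education")
                    & (table.level == "illiterate/primary")]
        assert ref["stratum1_HR"].iloc[0] == 1.0
        assert np.isnan(ref["stratum1_SE"].iloc[0])
        assert np.isnan(ref["stratum1_p"].iloc[0])

    def test_wald_p_matches_normal_cdf(self):
        records = simulate_cohort(SimulationConfig(n_women=400, seed=6))
        gaps = expand_to_strata(records, 1)
        fit = fit_pwp_gt(gaps, strata=[1], variables=["woman_employment"])
        sf = fit.strata[1]
        z = sf.beta[0] / sf.se[0]
        assert sf.p_values[0] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)
        assert sf.hazard_ratios[0] == pytest.approx(np.exp(sf.beta[0]), abs=1e-15)

    def test_table_covers_all_variables_and_levels(self):
        records = simulate_cohort(SimulationConfig(n_women=300, seed=4))
        gaps = expand_to_strata(records, 1)
        fit = fit_pwp_gt(gaps, strata=[1])
        table = wald_table(fit)
        # 2 continuous rows + one row per categorical level
        from birthspacing.data_model import CATEGORICAL_LEVELS

        expected = 2 + sum(len(v) for v in CATEGORICAL_LEVELS.values())
        assert len(table) == expected
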