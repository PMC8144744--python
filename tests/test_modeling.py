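import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import phase4d as p4
from phase4d._coxutils import fit_cox_fast, harrell_cindex
from phase4d.modeling import (
    bootstrap_cindex,
    clinical_design,
    concordance_index,
    fit_cox,
    fraction_new_information,
)


def breslow_negloglik(beta, time, event, X):
    """Independent Breslow partial log-likelihood via direct summation."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(event):
        risk_set = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk_set]).sum())
    return -ll


def toy_data(n=10, p=2, seed=0):
    """Tie-free survival data."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    t = rng.exponential(np.exp(-X[:, 0]))
    t += np.linspace(0, 1e-6, n)          # guarantee unique times
    d = (rng.random(n) < 0.7).astype(float)
    d[:2] = 1                              # at least two events
    return X, t, d


class TestFastCoxOracle:
    def test_beta_matches_scipy_optimiser(self):
        X, t, d = toy_data(10, 2, seed=1)
        fit = fit_cox_fast(t, d, X)
        res = minimize(breslow_negloglik, np.zeros(2), args=(t, d, X),
                       method="BFGS", tol=1e-12)
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-9)

    def test_null_loglik_matches_direct_sum(self):
        X, t, d = toy_data(12, 1, seed=2)
        fit = fit_cox_fast(t, d, X)
        assert fit.loglik_null == pytest.approx(
            -breslow_negloglik(np.zeros(1), t, d, X), abs=1e-9)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter
        X, t, d = toy_data(40, 3, seed=3)
        fit = fit_cox_fast(t, d, X)
        df = pd.DataFrame(X, columns=list("abc"))
        df["time"], df["event"] = t, d
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=1e-5)
        assert fit.lr_chi2 == pytest.approx(
            cph.log_likelihood_ratio_test().test_statistic, abs=1e-6)


class TestConcordance:
    def test_pair_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1, 6) + np.arange(6) * 1e-9
        d = np.array([1, 0, 1, 1, 0, 1.0])
        risk = rng.normal(size=6)
        conc = disc = ties = 0
        for i in range(6):
            if d[i] == 0:
                continue
            for j in range(6):
                if t[j] > t[i]:
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] < risk[j]:
                        disc += 1
                    else:
                        ties += 1
        oracle = (conc + 0.5 * ties) / (conc + disc + ties)
        assert harrell_cindex(t, d, risk) == pytest.approx(oracle)
        assert concordance_index(t, d, risk) == pytest.approx(oracle)

    def test_perfect_and_random(self):
        t = np.arange(1.0, 11)
        d = np.ones(10)
        assert harrell_cindex(t, d, -t) == pytest.approx(1.0)
        assert harrell_cindex(t, d, np.zeros(10)) == pytest.approx(0.5)

    def test_fast_matches_lifelines(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 50)
        d = (rng.random(50) < 0.6).astype(float)
        d[0] = 1
        risk = rng.normal(size=50)
        assert harrell_cindex(t, d, risk) == pytest.approx(
            concordance_index(t, d, risk))

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_cindex(np.array([1.0, 2.0]), np.array([0.0, 0.0]),
                           np.array([0.1, 0.2]))


class TestFitCox:
    def test_missing_values_raise(self):
        X, t, d = toy_data(20, 2, seed=6)
        design = pd.DataFrame(X, columns=["a", "b"])
        design.iloc[3, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_cox(design, t, d)

    def test_more_covariates_than_patients_raises(self):
        rng = np.random.default_rng(7)
        design = pd.DataFrame(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            fit_cox(design, np.arange(1.0, 5), np.ones(4))

    def test_hazard_ratio_sign(self):
        X, t, d = toy_data(100, 1, seed=8)
        fit = fit_cox(pd.DataFrame(X, columns=["x"]), t, d)
        assert fit.hazard_ratios["x"] > 1.0     # x raises hazard
        assert fit.lr_chi2 > 0


class TestBootstrap:
    def test_seed_bit_identical(self):
        X, t, d = toy_data(60, 2, seed=9)
        design = pd.DataFrame(X, columns=["a", "b"])
        a = bootstrap_cindex(design, t, d, B=20, seed=3)
        b = bootstrap_cindex(design, t, d, B=20, seed=3)
        c = bootstrap_cindex(design, t, d, B=20, seed=4)
        assert a == b
        assert a != c

    def test_noise_model_centred_at_half(self):
        rng = np.random.default_rng(10)
        n = 80
        design = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(1, n)
        d = (rng.random(n) < 0.6).astype(float)
        med, lo, hi = bootstrap_cindex(design, t, d, B=50, seed=0)
        assert 0.4 < med < 0.6
        assert lo <= med <= hi

    def test_invalid_B(self):
        with pytest.raises(ValueError):
            bootstrap_cindex(pd.DataFrame({"x": [1.0, 2]}),
                             np.array([1.0, 2]), np.array([1.0, 1]), B=1)


class TestFractionNewInformation:
    def _fits(self, beta_extra, seed=11):
        rng = np.random.default_rng(seed)
        n = 150
        c0 = rng.normal(size=n)
        f = rng.normal(size=n)
        lp = 0.8 * c0 + beta_extra * f
        t = rng.exponential(np.exp(-lp))
        cc = rng.uniform(0, 2, n)
        time, d = np.minimum(t, cc), (t <= cc).astype(float)
        clin = pd.DataFrame({"c0": c0})
        both = pd.DataFrame({"c0": c0, "f": f})
        return fit_cox(clin, time, d), fit_cox(both, time, d)

    def test_identity_from_lr_values(self):
        cfit, crfit = self._fits(1.0)
        comp = fraction_new_information(cfit, crfit, "test")
        assert comp.adequacy == pytest.approx(cfit.lr_chi2 / crfit.lr_chi2)
        assert comp.fraction_new == pytest.approx(1.0 - comp.adequacy)
        assert comp.lr_clinical == cfit.lr_chi2

    def test_uninformative_addition_near_zero(self):
        cfit, crfit = self._fits(0.0)
        comp = fraction_new_information(cfit, crfit)
        assert comp.fraction_new < 0.15

    def test_strong_addition_dominates(self):
        cfit, crfit = self._fits(2.0)
        comp = fraction_new_information(cfit, crfit)
        assert comp.fraction_new > 0.5

    def test_half_fraction_example(self):
        # synthetic LR values 10 and 20 give fraction_new exactly 0.5
        class _Stub:
            params_ = pd.Series(dtype=float)
            summary = pd.DataFrame({"p": []})

        a = p4.modeling.FittedCox(model=_Stub(), covariates=["c"], loglik=0.0,
                                  lr_chi2=10.0)
        b = p4.modeling.FittedCox(model=_Stub(), covariates=["c", "f"],
                                  loglik=0.0, lr_chi2=20.0)
        comp = fraction_new_information(a, b)
        assert comp.adequacy == pytest.approx(0.5)
        assert comp.fraction_new == pytest.approx(0.5)

    def test_not_nested_raises(self):
        a = p4.modeling.FittedCox(model=None, covariates=["c", "x"],
                                  loglik=0.0, lr_chi2=10.0)
        b = p4.modeling.FittedCox(model=None, covariates=["c", "f"],
                                  loglik=0.0, lr_chi2=20.0)
        with pytest.raises(ValueError, match="nested"):
            fraction_new_information(a, b)


class TestClinicalDesign:
    def _clin(self):
        return pd.DataFrame({
            "patient": ["a", "b", "c", "d"],
            "sex": ["male", "female", "male", "female"],
            "age": [70.0, 65.0, 80.0, 75.0],
            "t_stage": ["T1", "T2", "T1", "T1"],
            "ecog": ["0+1", "0+1", "2", "3"],
            "lobe": ["lower", "upper+middle", "lower", "upper+middle"],
            "tumour_volume": [4.0, 10.0, 2.0, 6.0],
            "motion_amplitude": [5.0, 3.0, 8.0, 2.0]})

    def test_dummy_coding_drops_reference(self):
        design = clinical_design(self._clin())
        assert "tumour_volume" in design.columns
        assert "age" in design.columns
        # binary categoricals contribute exactly one column each
        assert sum(c.startswith("sex_") for c in design.columns) == 1
        assert sum(c.startswith("lobe_") for c in design.columns) == 1
        assert sum(c.startswith("ecog_") for c in design.columns) == 2
        assert design.index.tolist() == ["a", "b", "c", "d"]
        assert design.dtypes.eq(float).all()

    def test_motion_amplitude_not_a_covariate(self):
        design = clinical_design(self._clin())
        assert "motion_amplitude" not in design.columns
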