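import numpy as np
import pytest

from photoqtl import (HDEECurveModel, decompose_proportions, estimate_group_perturbations,
                      fit_mean_curve, select_growth_model)
from photoqtl.growth import HDEEParams, eval_growth, eval_hdee


def test_noiseless_composite_recovery(grid11, etr_params, etr_mean):
    fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
    assert fit.rss < 1e-10
    for name in ("K", "a", "b", "c", "d"):
        est, true = getattr(fit.params, name), getattr(etr_params, name)
        assert abs(est - true) / abs(true) < 1e-3
    # fitted curve reproduces the data at every grid point
    assert np.allclose(fit.predict(), etr_mean, atol=1e-8)


def test_noiseless_qp_and_qn_forms_recovered(grid11):
    cases = [("mitscherlich", HDEEParams(K=0.2, a=-4.0, b=0.6, c=0.3, d=-0.5)),
             ("korf", HDEEParams(K=0.95, a=30.0, b=2.5, c=0.1, d=-1.5))]
    for family, p in cases:
        y = eval_hdee(family, p, grid11.log_levels)
        fit = fit_mean_curve(y, grid11, family, True)
        assert fit.rss < 1e-9, family
        assert np.allclose(fit.predict(), y, atol=1e-7)


def test_flat_trajectory_degenerates_to_K(grid11):
    y = np.full(grid11.L, 7.5)
    fit = fit_mean_curve(y, grid11, "logistic", True, n_restarts=5)
    assert fit.rss < 1e-12
    assert fit.predict() == pytest.approx(y, abs=1e-6)


def test_noisy_asymptote_recovered_within_five_percent(grid11):
    """Fitting the 98-sample mean trajectory (per-sample noise sd 5% of K)
    recovers the asymptote to a few percent when the composite's components
    occupy complementary parts of the light axis."""
    p = HDEEParams(K=0.9, a=104.0, b=4.4, c=0.12, d=0.95)
    mean = eval_hdee("korf", p, grid11.log_levels)
    rng = np.random.default_rng(2)
    errs = []
    for _ in range(30):
        Y = mean + rng.normal(0, 0.05 * p.K, size=(98, grid11.L))
        fit = fit_mean_curve(Y.mean(axis=0), grid11, "korf", True, n_restarts=10)
        errs.append(abs(fit.params.K - p.K) / p.K)
    assert np.median(errs) < 0.05


def test_generating_family_wins_model_selection(grid11, etr_mean):
    best, table = select_growth_model(etr_mean, grid11, ["logistic", "gompertz"], True)
    assert best.family == "logistic"
    assert set(table.index) == {"logistic", "gompertz"}
    assert {"aic", "bic", "aicc"} <= set(table.columns)


def test_single_candidate_returned_unconditionally(grid11, etr_mean):
    best, table = select_growth_model(etr_mean, grid11, ["gompertz"], True)
    assert best.family == "gompertz"
    assert len(table) == 1


def test_composite_beats_pure_growth_when_disturbance_present(grid11, etr_mean):
    # data carry a genuine c*l^d component: composite must win on all criteria
    composite = fit_mean_curve(etr_mean, grid11, "logistic", True)
    pure = fit_mean_curve(etr_mean, grid11, "logistic", False)
    for ic in ("aic", "bic", "aicc"):
        assert composite.ic[ic] < pure.ic[ic]


def test_too_few_levels_rejected(grid11):
    with pytest.raises(ValueError):
        HDEECurveModel(np.ones(4), type(grid11)(raw_levels=grid11.raw_levels[:4]),
                       "logistic", True)


def test_summary_reports_fit_quality(grid11, etr_mean):
    fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
    text = fit.summary()
    assert "rss" in text and "BIC" in text and "logistic" in text


class TestProportionDecomposition:
    def test_pure_growth_gives_full_autogenic_share(self, grid11, etr_mean):
        fit = fit_mean_curve(eval_growth("logistic", HDEEParams(30, 8, 1.2),
                                         grid11.log_levels), grid11, "logistic", False)
        df = decompose_proportions(fit)
        assert np.allclose(df["autogenic_share"], 1.0)
        assert np.allclose(df["disturbance_share"], 0.0)

    def test_equal_components_split_evenly(self, grid11):
        fit = fit_mean_curve(np.full(grid11.L, 2.0), grid11, "logistic", False)
        fit.params = fit.params.with_(K=1.0, a=0.0, c=1.0, d=0.0)  # phi == omega == 1
        fit.family = "gompertz"  # K e^0 = 1 exactly
        df = decompose_proportions(fit)
        assert np.allclose(df["autogenic_share"], 0.5)

    def test_pure_disturbance_gives_full_environmental_share(self, grid11):
        fit = fit_mean_curve(np.full(grid11.L, 2.0), grid11, "logistic", False)
        fit.params = fit.params.with_(K=0.0, c=0.5, d=-1.0)
        df = decompose_proportions(fit)
        assert np.allclose(df["disturbance_share"], 1.0)

    def test_shares_sum_to_one_wherever_defined(self, grid11, etr_mean):
        fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
        df = decompose_proportions(fit)
        s = df["autogenic_share"] + df["disturbance_share"]
        assert np.allclose(s[~s.isna()], 1.0)


class TestGroupPerturbations:
    def _make(self, grid11, etr_mean, rng, shift_group=None, delta=0.0, n=96, groups=6):
        from photoqtl.simulate import _ar1_noise

        labels = np.repeat(np.arange(groups), n // groups)
        Y = etr_mean + _ar1_noise(rng, n, grid11.L, 2.25, 0.6)
        if shift_group is not None:
            Y[labels == shift_group] += delta
        return Y, labels

    def test_null_rejection_rate_near_alpha(self, grid11, etr_mean):
        fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
        rej = 0
        n_rep = 200
        for r in range(n_rep):
            rng = np.random.default_rng(5000 + r)
            Y, labels = self._make(grid11, etr_mean, rng)
            pert = estimate_group_perturbations(Y, grid11, fit, labels)
            rej += pert.kw_pvalue < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_large_shift_detected(self, grid11, etr_mean):
        fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
        rng = np.random.default_rng(9)
        Y, labels = self._make(grid11, etr_mean, rng, shift_group=2, delta=5.0)
        pert = estimate_group_perturbations(Y, grid11, fit, labels)
        assert pert.kw_pvalue < 0.01
        assert pert.anova_pvalue < 0.01
        # the shifted group's mean offset reflects the planted shift
        assert pert.group_epsilon[2] == pytest.approx(5.0, abs=1.0)

    def test_single_group_skips_tests_but_returns_offsets(self, grid11, etr_mean):
        fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
        rng = np.random.default_rng(1)
        Y, _ = self._make(grid11, etr_mean, rng, n=12, groups=6)
        pert = estimate_group_perturbations(Y, grid11, fit, np.zeros(12, dtype=int))
        assert np.isnan(pert.kw_pvalue)
        assert pert.epsilon.shape == (12,)

    def test_tiny_groups_excluded_with_warning(self, grid11, etr_mean):
        fit = fit_mean_curve(etr_mean, grid11, "logistic", True)
        rng = np.random.default_rng(1)
        Y, labels = self._make(grid11, etr_mean, rng, n=12, groups=6)
        labels = labels.copy()
        labels[0] = 99  # singleton group
        labels[1] = 0
        with pytest.warns(UserWarning):
            pert = estimate_group_perturbations(Y, grid11, fit, labels)
        assert 99 in pert.excluded_groups
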