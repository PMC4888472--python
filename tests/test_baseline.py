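"""Curve-fit baseline classifier and Cohen's kappa."""
import numpy as np
import pytest

from nsdlsm.baseline import (
    ConfusionMatrix,
    CurveFitResult,
    classify_by_aic,
    cohen_kappa,
    fit_curve_suite,
    run_comparison,
)
from nsdlsm.hmm import FitConfig
from nsdlsm.simulate import simulate_batch

from _util import make_series


def series_from_curve(y):
    return make_series(np.asarray(y, dtype=float))


class TestFitCurveSuite:
    def test_constant_series_exact_fit(self):
        res = fit_curve_suite(series_from_curve(np.full(120, 0.4)))
        by_name = {r.model_name: r for r in res}
        assert by_name["constant"].rss == pytest.approx(0.0, abs=1e-20)
        best = min((r for r in res if r.converged), key=lambda r: r.aic)
        assert best.model_name == "constant"

    def test_noiseless_logistic_recovered(self):
        t = np.arange(1, 366, dtype=float)
        y = 1.0 / (1.0 + np.exp((180.0 - t) / 10.0))
        res = fit_curve_suite(series_from_curve(y))
        sig = next(r for r in res if r.model_name == "sigmoid")
        assert sig.converged
        assert sig.params["delta"] == pytest.approx(1.0, abs=1e-4)
        assert sig.params["theta"] == pytest.approx(180.0, abs=1e-3)
        assert sig.params["phi"] == pytest.approx(10.0, abs=1e-3)
        by_name = {r.model_name: r for r in res}
        assert sig.aic < by_name["linear"].aic
        assert sig.aic < by_name["constant"].aic

    def test_aic_formula_cross_check(self):
        rng = np.random.default_rng(0)
        y = np.clip(0.5 + 0.1 * rng.normal(size=150), 0, 1)
        res = fit_curve_suite(series_from_curve(y))
        n = 150
        for r in res:
            if r.converged and r.rss > 0:
                k = r.k
                assert r.aic == pytest.approx(
                    n * np.log(r.rss / n) + 2 * k, abs=1e-9
                )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_curve_suite(series_from_curve(np.full(30, 0.2)))


class TestClassifyByAIC:
    def test_only_constant_converged(self):
        res = [
            CurveFitResult("constant", {"c": 0.2}, 1.0, -100.0, True),
            CurveFitResult("linear", {}, np.inf, np.inf, False),
            CurveFitResult("sigmoid", {}, np.inf, np.inf, False),
            CurveFitResult("double_sigmoid", {}, np.inf, np.inf, False),
        ]
        assert classify_by_aic(res) == "sedentary"

    def test_tie_broken_toward_fewer_parameters(self):
        res = [
            CurveFitResult("linear", {"beta": 1e-3}, 1.0, -50.0, True),
            CurveFitResult("sigmoid", {}, 1.0, -50.0, True),
        ]
        assert classify_by_aic(res) == "nomadic"

    def test_no_converged_rejected(self):
        with pytest.raises(ValueError):
            classify_by_aic(
                [CurveFitResult("linear", {}, np.inf, np.inf, False)]
            )


class TestCohenKappa:
    def test_perfect_agreement(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[10.0, 0.0], [0.0, 10.0]]))
        assert cohen_kappa(cm) == pytest.approx(1.0)

    def test_hand_example(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[20.0, 5.0], [10.0, 15.0]]))
        assert cohen_kappa(cm) == pytest.approx(0.4, abs=1e-12)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 4, size=10000)
        pred = rng.integers(0, 4, size=10000)
        cm = ConfusionMatrix.from_labels(
            [str(t) for t in true], [str(p) for p in pred]
        )
        assert abs(cohen_kappa(cm)) < 0.05

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        true = rng.integers(0, 3, size=500)
        pred = np.where(rng.random(500) < 0.7, true, rng.integers(0, 3, size=500))
        cm = ConfusionMatrix.from_labels(
            [str(t) for t in true], [str(p) for p in pred],
            labels=("0", "1", "2"),
        )
        assert cohen_kappa(cm) == pytest.approx(
            cohen_kappa_score(true, pred), abs=1e-12
        )

    def test_permutation_invariance(self):
        counts = np.array([[20.0, 5.0, 1.0], [10.0, 15.0, 2.0], [0.0, 3.0, 9.0]])
        cm = ConfusionMatrix(("a", "b", "c"), counts)
        perm = [2, 0, 1]
        cm2 = ConfusionMatrix(
            ("c", "a", "b"), counts[np.ix_(perm, perm)]
        )
        assert cohen_kappa(cm2) == pytest.approx(cohen_kappa(cm))

    def test_correct_addition_never_decreases_kappa(self):
        counts = np.array([[20.0, 5.0], [10.0, 15.0]])
        base = cohen_kappa(ConfusionMatrix(("a", "b"), counts))
        bumped = counts.copy()
        bumped[0, 0] += 1
        assert cohen_kappa(ConfusionMatrix(("a", "b"), bumped)) >= base

    def test_single_cell_convention(self):
        cm = ConfusionMatrix(("a", "b"), np.array([[10.0, 0.0], [0.0, 0.0]]))
        assert cohen_kappa(cm) == 0.0


@pytest.fixture(scope="module")
def small_report():
    ds = simulate_batch(3, seed=2)
    return run_comparison(ds, FitConfig())


class TestRunComparison:

    def test_confusions_account_for_every_trajectory(self, small_report):
        assert small_report.latent_cm.total == 12
        assert small_report.baseline_cm.total == 12

    def test_proportions_rows_sum_to_one(self, small_report):
        for which in ("latent", "baseline"):
            props = small_report.proportions(which)
            for true_lab, row in props.items():
                assert sum(row.values()) == pytest.approx(1.0)

    def test_kappa_consistency_with_labels(self, small_report):
        from nsdlsm.baseline import COMPARISON_LABELS

        cm = ConfusionMatrix.from_labels(
            small_report.true_labels, small_report.latent_labels,
            labels=COMPARISON_LABELS,
        )
        assert cohen_kappa(cm) == pytest.approx(small_report.latent_kappa)

    def test_identical_predictions_give_identical_kappa(self):
        from nsdlsm.baseline import COMPARISON_LABELS

        true = ["dispersal", "migration", "nomadic", "sedentary"] * 5
        cm1 = ConfusionMatrix.from_labels(true, true, labels=COMPARISON_LABELS)
        cm2 = ConfusionMatrix.from_labels(true, true, labels=COMPARISON_LABELS)
        assert cohen_kappa(cm1) == cohen_kappa(cm2) == pytest.approx(1.0)
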