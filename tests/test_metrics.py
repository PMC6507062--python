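import numpy as np
import pytest

from oehr import (
    SimulationScenario,
    crossvalidated_performance,
    generate_dataset,
    gonen_heller_cpe,
    harrell_cindex,
    integrated_brier_score,
    r2_d,
    r2_pm,
)
from oehr.datasets import SurvivalDataset
from oehr.metrics import brier_score

from _oracles import brute_cindex, brute_cpe


class TestCindex:
    def test_perfect_ordering_is_one(self):
        t = np.arange(1.0, 21.0)
        risk = -t  # higher risk, shorter survival
        assert harrell_cindex(t, np.ones(20, int), risk) == 1.0

    def test_matches_brute_force_under_censoring(self, rng):
        n = 50
        t = rng.exponential(size=n)
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        risk = rng.standard_normal(n)
        assert harrell_cindex(t, e, risk) == pytest.approx(
            brute_cindex(t, e, risk), abs=1e-12
        )

    def test_null_predictor_is_half_on_average(self):
        vals = []
        for s in range(50):
            rng = np.random.default_rng(900 + s)
            t = rng.exponential(size=200)
            risk = rng.standard_normal(200)
            vals.append(harrell_cindex(t, np.ones(200, int), risk))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)


class TestCPE:
    def test_all_equal_is_half_by_convention(self):
        assert gonen_heller_cpe(np.zeros(10)) == 0.5

    def test_sign_flip_invariance_and_range(self, rng):
        lp = rng.standard_normal(40)
        c = gonen_heller_cpe(lp)
        assert 0.5 <= c <= 1.0
        assert gonen_heller_cpe(-lp) == pytest.approx(c, abs=1e-12)

    def test_matches_double_summation(self, rng):
        lp = rng.standard_normal(50)
        assert gonen_heller_cpe(lp) == pytest.approx(brute_cpe(lp), abs=1e-12)


class TestBrierScore:
    def test_constant_half_prediction_without_censoring(self, rng):
        n = 200
        t = rng.exponential(size=n)
        d = SurvivalDataset(t, np.ones(n, int), rng.standard_normal(n))
        times = np.quantile(t, [0.2, 0.4, 0.6, 0.8])
        probs = np.full((n, len(times)), 0.5)
        bs = brier_score(d, d, probs, times)
        assert bs == pytest.approx(np.full(len(times), 0.25), abs=1e-12)
        assert integrated_brier_score(d, d, probs, times) == pytest.approx(0.25)

    def test_oracle_predictions_drive_score_to_zero(self, rng):
        n = 100
        t = rng.exponential(size=n)
        d = SurvivalDataset(t, np.ones(n, int), rng.standard_normal(n))
        times = np.quantile(t, [0.3, 0.6])
        probs = (t[:, None] > times[None, :]).astype(float)
        assert integrated_brier_score(d, d, probs, times) == pytest.approx(0.0)

    def test_matches_scikit_survival_under_censoring(self, rng):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        n = 300
        t = rng.exponential(size=n)
        e = rng.integers(0, 2, size=n).astype(bool)
        d = SurvivalDataset(t, e.astype(int), rng.standard_normal(n))
        times = np.quantile(t, [0.2, 0.5])
        probs = rng.uniform(size=(n, len(times)))
        y = Surv.from_arrays(event=e, time=t)
        _, expected = sks_brier(y, y, probs, times)
        assert brier_score(d, d, probs, times) == pytest.approx(expected, abs=1e-10)

    def test_informative_model_beats_null_model(self):
        sc = SimulationScenario(-4 / 3, 4, 1, n=400, reps=10, seed=47)
        wins = 0
        for r in range(10):
            d = generate_dataset(sc, r)
            times = np.quantile(d.time, np.linspace(0.05, 0.9, 30))
            # null: Kaplan-Meier-style marginal survival for everyone
            from oehr._cox import breslow_baseline, predict_survival, prepare

            sd = prepare(np.zeros((d.n, 1)), d.time, d.status)
            kt, H0 = breslow_baseline(sd, np.array([0.0]))
            null_probs = predict_survival(kt, H0, np.zeros(d.n), times)
            from oehr import fit_categorical_cox
            from oehr.cutpoints import categorize, dummy_design

            res = fit_categorical_cox(d, -0.4, 1.5)
            X = dummy_design(categorize(d.x, -0.4, 1.5), True)
            sd2 = prepare(X, d.time, d.status)
            from oehr._cox import newton_fit

            fit = newton_fit(sd2)
            kt2, H02 = breslow_baseline(sd2, fit.beta)
            probs = predict_survival(kt2, H02, X @ fit.beta, times)
            wins += (integrated_brier_score(d, d, probs, times)
                     <= integrated_brier_score(d, d, null_probs, times))
        assert wins >= 9


class TestExplainedVariation:
    def test_r2_pm_closed_forms(self, rng):
        assert r2_pm(np.zeros(30)) == 0.0
        lp = rng.standard_normal(2000)
        lp = (lp - lp.mean()) / lp.std(ddof=1) * np.sqrt(np.pi**2 / 6)
        assert r2_pm(lp) == pytest.approx(0.5, abs=1e-12)
        assert r2_pm(2.0 * lp) > r2_pm(lp)

    def test_r2_d_affine_invariance_and_null(self, rng):
        n = 300
        t = rng.exponential(size=n)
        e = np.ones(n, int)
        lp = rng.standard_normal(n)
        base = r2_d(t, e, lp)
        assert r2_d(t, e, 3.0 * lp + 2.0) == pytest.approx(base, abs=1e-10)
        # null predictor: no explained variation beyond noise
        null_vals = [
            r2_d(t, e, np.random.default_rng(s).standard_normal(n))
            for s in range(10)
        ]
        assert np.mean(null_vals) < 0.05

    def test_r2_d_monotone_in_signal_strength(self):
        meds = []
        for scale in (1.0, 2.0):
            vals = []
            for s in range(8):
                rng = np.random.default_rng(1100 + s)
                n = 300
                x = rng.standard_normal(n)
                t = -np.log(rng.uniform(size=n)) / np.exp(scale * np.abs(x))
                vals.append(r2_d(t, np.ones(n, int), np.abs(x) * scale))
            meds.append(np.median(vals))
        assert meds[1] > meds[0]


class TestCrossValidation:
    def test_deterministic_and_row_order_invariant(self, severe_data):
        rep1 = crossvalidated_performance(severe_data, "q1q3", seed=5)
        rep2 = crossvalidated_performance(severe_data, "q1q3", seed=5)
        assert rep1.means == rep2.means
        perm = np.random.default_rng(0).permutation(severe_data.n)
        shuffled = severe_data.subset(perm)
        rep3 = crossvalidated_performance(shuffled, "q1q3", seed=5)
        for m in rep1.means:
            assert rep1.means[m] == pytest.approx(rep3.means[m], abs=1e-12)

    def test_two_fold_and_five_fold_layouts(self, severe_data):
        rep = crossvalidated_performance(severe_data, "median", n_folds=2)
        assert len(rep.per_fold) == 2
        rep5 = crossvalidated_performance(severe_data, "median", n_folds=5,
                                          n_repeats=2, seed=3)
        assert len(rep5.per_fold) == 10
        for m in rep.MEASURES:
            assert 0.0 <= rep.means[m] <= 1.0
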