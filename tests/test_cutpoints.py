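import numpy as np
import pytest

from oehr import (
    SimulationScenario,
    candidate_equal_hr_pairs,
    fit_categorical_cox,
    generate_dataset,
    median_cutpoint,
    minp_logrank_cutpoint,
    oehr_cutpoints,
    quartile_cutpoints,
)
from oehr.cutpoints import EQUAL_HR_TOL, categorize
from oehr.datasets import SurvivalDataset

from _oracles import brute_max_logrank_split


class TestSimpleSplits:
    def test_median_small_list_and_sort_oracle(self, rng):
        assert median_cutpoint([1, 2, 3]).cut1 == 2
        x = rng.uniform(size=101)
        assert median_cutpoint(x).cut1 == np.sort(x)[50]
        with pytest.raises(ValueError):
            median_cutpoint(np.ones(10))

    def test_quartiles_small_list_and_closed_form(self, rng):
        r = quartile_cutpoints([1, 2, 3, 4])
        assert (r.cut1, r.cut2) == (np.percentile([1, 2, 3, 4], 25),
                                    np.percentile([1, 2, 3, 4], 75))
        x = rng.standard_normal(100_000)
        r = quartile_cutpoints(x)
        assert r.cut1 == pytest.approx(-0.6745, abs=0.02)
        assert r.cut2 == pytest.approx(0.6745, abs=0.02)

    def test_standard_normal_sampling_distribution(self):
        # across replicates the mean selected cuts match the known quantiles
        sc = SimulationScenario(-2, 2, 0, n=500, reps=100, seed=17)
        med, q1, q3 = [], [], []
        for r in range(100):
            x = generate_dataset(sc, r).x
            med.append(median_cutpoint(x).cut1)
            rq = quartile_cutpoints(x)
            q1.append(rq.cut1)
            q3.append(rq.cut2)
        assert np.mean(med) == pytest.approx(0.0, abs=0.02)
        assert np.mean(q1) == pytest.approx(-0.68, abs=0.02)
        assert np.mean(q3) == pytest.approx(0.67, abs=0.02)


class TestMinP:
    def test_equals_brute_force_maximum(self):
        sc = SimulationScenario(-8 / 5, 8 / 3, 0.5, pc=0.25, n=150, reps=1, seed=29)
        d = generate_dataset(sc, 0)
        res = minp_logrank_cutpoint(d)
        cut, stat = brute_max_logrank_split(d.time, d.status, d.x)
        assert res.cut1 == pytest.approx(cut, abs=1e-12)
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.naive_p is not None and "multiplicity" in " ".join(res.notes)

    def test_recovers_a_step_hazard_threshold(self):
        # single true step at x = 0.3 with a large effect
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(400 + s)
            n = 500
            x = rng.standard_normal(n)
            lp = np.where(x > 0.3, 1.5, 0.0)
            t = -np.log(rng.uniform(size=n)) / np.exp(lp)
            d = SurvivalDataset(t, np.ones(n, dtype=int), x)
            hits += abs(minp_logrank_cutpoint(d).cut1 - 0.3) <= 0.1
        assert hits >= 9


class TestCategoricalCox:
    def test_aic_bic_definitional(self, severe_data):
        res = fit_categorical_cox(severe_data, -0.4, 1.5)
        k = 2  # two dummies, no covariates
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * k)
        assert res.bic == pytest.approx(
            -2 * res.loglik + np.log(severe_data.n_events) * k
        )
        assert res.group_counts.sum() == severe_data.n
        assert res.hrs == pytest.approx(np.exp(res.coefficients))

    def test_equal_hazard_construction_gives_equal_hrs(self):
        # symmetric V truth cut at +-0.9: both groups share the same hazard
        sc = SimulationScenario(-2, 2, 0, n=500, reps=20, seed=31)
        ratios, oks = [], 0
        for r in range(20):
            d = generate_dataset(sc, r)
            res = fit_categorical_cox(d, -0.9, 0.9)
            if np.all(res.hrs > 1):
                oks += 1
        assert oks >= 18

    def test_null_data_type_one_sanity(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(600 + s)
            n = 300
            x = rng.standard_normal(n)
            t = -np.log(rng.uniform(size=n))
            d = SurvivalDataset(t, np.ones(n, dtype=int), x)
            res = fit_categorical_cox(d, -0.7, 0.7)
            se = np.abs(res.coefficients / _z_from_p(res.p_values))
            hits += np.all(np.abs(res.coefficients) <= 2 * se + 1e-12)
        assert hits >= 18

    def test_tiny_group_rejected_with_name(self, severe_data):
        with pytest.raises(ValueError, match="group"):
            fit_categorical_cox(severe_data, severe_data.x.min() + 1e-6, 0.5)


def _z_from_p(p):
    from scipy.stats import norm

    return norm.isf(np.asarray(p) / 2)


class TestCandidatePairs:
    def test_constraint_percentiles_and_count(self, symmetric_fit, symmetric_data):
        pairs = candidate_equal_hr_pairs(symmetric_fit, symmetric_data)
        assert 0 < len(pairs) <= 91
        for p in pairs:
            assert abs(p.loglam1 - p.loglam2) <= EQUAL_HR_TOL
            assert p.x1 < p.x2
            assert 5 <= p.percentile_index <= 95
            assert symmetric_data.x.min() < p.x1 < p.x2 < symmetric_data.x.max()

    def test_symmetric_truth_gives_nearly_mirrored_pairs(self, symmetric_fit,
                                                         symmetric_data):
        pairs = candidate_equal_hr_pairs(symmetric_fit, symmetric_data)
        asym = np.median([abs(p.x1 + p.x2) for p in pairs])
        assert asym < 0.25


class TestOEHR:
    def test_returned_pair_minimizes_aic_exhaustively(self, severe_fit, severe_data):
        res = oehr_cutpoints(severe_data, severe_fit)
        pairs = candidate_equal_hr_pairs(severe_fit, severe_data)
        for p in pairs:
            try:
                other = fit_categorical_cox(severe_data, p.x1, p.x2,
                                            method_label="oehr")
            except ValueError:
                continue
            assert res.aic <= other.aic + 1e-9

    def test_cuts_inside_support_and_equal_height(self, severe_fit, severe_data):
        from oehr import predict_log_relative_hazard

        res = oehr_cutpoints(severe_data, severe_fit)
        assert severe_data.x.min() < res.cut1 < res.cut2 < severe_data.x.max()
        y1, y2 = predict_log_relative_hazard(severe_fit,
                                             np.array([res.cut1, res.cut2]))
        assert abs(y1 - y2) <= EQUAL_HR_TOL + 1e-9

    def test_discretization_conserves_rows_and_events(self, severe_fit, severe_data):
        res = oehr_cutpoints(severe_data, severe_fit)
        codes = categorize(severe_data.x, res.cut1, res.cut2)
        assert len(codes) == severe_data.n
        assert res.group_counts.sum() == severe_data.n

    def test_aic_and_bic_selections_usually_agree(self):
        sc = SimulationScenario(-2, 2, 0, n=500, reps=10, seed=57)
        agree = 0
        for r in range(sc.reps):
            d = generate_dataset(sc, r)
            from oehr import select_smoothing_by_aic

            fit = select_smoothing_by_aic(d)
            a = oehr_cutpoints(d, fit, criterion="aic", require_u_shape=False)
            b = oehr_cutpoints(d, fit, criterion="bic", require_u_shape=False)
            agree += (a.cut1, a.cut2) == (b.cut1, b.cut2)
        assert agree >= 9

    def test_equal_height_recovery_matches_v_truth(self):
        # |k1| (a - cut1) and k2 (cut2 - a) estimate the same height
        sc = SimulationScenario(-4 / 3, 4, 1, n=500, reps=15, seed=71)
        lefts, rights = [], []
        for r in range(sc.reps):
            d = generate_dataset(sc, r)
            from oehr import select_smoothing_by_aic

            fit = select_smoothing_by_aic(d)
            res = oehr_cutpoints(d, fit, require_u_shape=False)
            lefts.append((4 / 3) * (1 - res.cut1))
            rights.append(4 * (res.cut2 - 1))
        diff = np.mean(lefts) - np.mean(rights)
        sd = np.std(np.array(lefts) - np.array(rights), ddof=1) / np.sqrt(len(lefts))
        assert abs(diff) < 2.5 * max(sd, 0.05)
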