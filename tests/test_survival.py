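"""Survival statistics: hand-computed product-limit and log-rank
fixtures, lifelines cross-checks, and screen behavior."""

import numpy as np
import pandas as pd
import pytest

from kdsig.errors import ConfigError
from kdsig.simulate import SimSurvivalConfig, simulate_survival
from kdsig.survival import (dichotomize, hazard_ratio, km_estimate,
                            logrank_test, screen_genes, summarize_screen)


class TestKaplanMeier:
    def test_all_events(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.empty

    def test_hand_computed_mixed_censoring(self):
        """Six subjects, censoring at t=2 and t=5.

        t=1: 6 at risk, 1 event -> 5/6
        t=3: 4 at risk, 1 event -> 5/6 * 3/4 = 0.625
        t=4: 3 at risk, 1 event -> 0.625 * 2/3
        t=6: 1 at risk, 1 event -> 0
        """
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        assert km["time"].tolist() == [1, 3, 4, 6]
        assert km["survival"].to_numpy() == pytest.approx([5 / 6, 0.625, 0.625 * 2 / 3, 0.0])
        assert km["n_at_risk"].tolist() == [6, 4, 3, 1]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=200).round(3)
        km = km_estimate(t, np.ones(200, dtype=int))
        for _, row in km.iloc[::20].iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(t, e)
        assert np.all(np.diff(km["survival"]) <= 1e-12)

    def test_lifelines_cross_check(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(5, 150)
        e = rng.integers(0, 2, 150)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km["time"]).to_numpy()
        assert np.allclose(km["survival"], theirs, atol=1e-10)


class TestLogRank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_six_subjects(self):
        """High: (1,1) (4,1) (5,0); low: (2,1) (3,1) (6,1).

        Risk-set table (t, d1, d, n1, n):
          1: 1 1 3 6 | 2: 0 1 2 5 | 3: 0 1 2 4 | 4: 1 1 2 3 | 6: 0 1 0 1
        O-E = 2 - (1/2 + 2/5 + 1/2 + 2/3) = -1/15
        V   = 1/4 + 6/25 + 1/4 + 2/9
        """
        o_minus_e = 2 - (0.5 + 0.4 + 0.5 + 2 / 3)
        v = 0.25 + 0.24 + 0.25 + 2 / 9
        chi2, p = logrank_test([1, 4, 5], [1, 1, 0], [2, 3, 6], [1, 1, 1])
        assert chi2 == pytest.approx(o_minus_e ** 2 / v, abs=1e-12)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        t1, t2 = rng.exponential(5, 40), rng.exponential(9, 50)
        e1, e2 = rng.integers(0, 2, 40), rng.integers(0, 2, 50)
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a == pytest.approx(b)

    def test_lifelines_cross_check(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        t1, t2 = rng.exponential(5, 60), rng.exponential(9, 70)
        e1 = rng.integers(0, 2, 60)
        e2 = rng.integers(0, 2, 70)
        chi2, p = logrank_test(t1, e1, t2, e2)
        ref = ll_logrank(t1, t2, e1, e2)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = hazard_ratio(t, e, t, e)
        assert res.hr == pytest.approx(1.0, abs=1e-8)

    def test_label_swap_inverts(self):
        rng = np.random.default_rng(5)
        t1, t2 = rng.exponential(5, 50), rng.exponential(10, 50)
        e1 = np.ones(50, int)
        e2 = rng.integers(0, 2, 50)
        a = hazard_ratio(t1, e1, t2, e2)
        b = hazard_ratio(t2, e2, t1, e1)
        assert a.hr == pytest.approx(1 / b.hr, rel=1e-8)

    def test_lifelines_cross_check_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        # integer times force ties, exercising the Efron correction
        t1 = np.maximum(1, rng.poisson(8, 80))
        t2 = np.maximum(1, rng.poisson(12, 90))
        e1, e2 = rng.integers(0, 2, 80), rng.integers(0, 2, 90)
        ours = hazard_ratio(t1, e1, t2, e2)
        df = pd.DataFrame({
            "t": np.concatenate([t1, t2]),
            "e": np.concatenate([e1, e2]),
            "x": np.concatenate([np.ones(80), np.zeros(90)]),
        })
        cph = CoxPHFitter().fit(df, "t", "e")
        assert ours.log_hr == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert ours.se_log_hr == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-6)

    def test_zero_events_flagged(self):
        res = hazard_ratio([1, 2], [0, 0], [1, 2], [1, 1])
        assert res.hr == 0.0
        assert res.flag == "no_events_high"
        res = hazard_ratio([1, 2], [1, 1], [1, 2], [0, 0])
        assert res.hr == np.inf
        assert res.flag == "no_events_low"

    def test_no_events_at_all_rejected(self):
        with pytest.raises(ConfigError):
            hazard_ratio([1.0], [0], [2.0], [0])


class TestDichotomize:
    def test_median_split_ties_low(self):
        d = dichotomize([1.0, 2.0, 3.0, 4.0])
        assert d.high.tolist() == [False, False, True, True]
        d = dichotomize([1.0, 2.0, 2.0, 4.0])  # median 2: ties go low
        assert d.high.tolist() == [False, False, False, True]

    def test_all_equal_rejected(self):
        with pytest.raises(ConfigError, match="no split"):
            dichotomize([3.0, 3.0, 3.0, 3.0])

    def test_best_cutoff_recovers_true_threshold(self):
        """Step hazard at the 0.6 quantile; the scan should land within
        one 0.05-quantile step on most seeds."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 600
            x = rng.normal(size=n)
            cut = np.quantile(x, 0.6)
            rate = 0.03 * np.where(x > cut, 3.0, 1.0)
            te = rng.exponential(1 / rate)
            tc = rng.exponential(1 / 0.005, n)
            t, e = np.minimum(te, tc), (te <= tc).astype(int)
            d = dichotomize(x, "best_cutoff", times=t, events=e)
            q = d.scan.loc[d.scan["logrank_p"].idxmin(), "quantile"]
            hits += abs(q - 0.6) <= 0.05 + 1e-9
        assert hits >= 0.8 * n_seeds

    def test_best_cutoff_needs_survival_data(self):
        with pytest.raises(ConfigError):
            dichotomize([1.0, 2.0, 3.0, 4.0], "best_cutoff")


class TestScreen:
    def _cohort_with_planted(self, seed, n=800, n_null=20):
        rng = np.random.default_rng(seed)
        x_hit = rng.normal(size=n)
        rate = 0.03 * np.exp(np.log(2) * (x_hit > np.median(x_hit)))
        te = rng.exponential(1 / rate)
        tc = rng.exponential(1 / 0.01, n)
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "time": np.minimum(te, tc),
            "event": (te <= tc).astype(int),
            "HIT": x_hit,
        })
        for k in range(n_null):
            cohort[f"NULL{k}"] = rng.normal(size=n)
        return cohort

    def test_planted_gene_ranks_first(self):
        wins = 0
        for seed in range(5):
            cohort = self._cohort_with_planted(seed)
            genes = [c for c in cohort.columns if c not in ("subject_id", "time", "event")]
            screen = screen_genes(cohort, genes)
            wins += screen.iloc[0]["gene"] == "HIT"
        assert wins >= 4

    def test_ranked_by_hr_descending(self):
        screen = screen_genes(self._cohort_with_planted(0), ["HIT", "NULL0", "NULL1"])
        assert np.all(np.diff(screen["hr"]) <= 1e-12)
        assert (screen["n_high"] + screen["n_low"] == 800).all()

    def test_empty_gene_list(self):
        screen = screen_genes(self._cohort_with_planted(1), [])
        assert screen.empty

    def test_missing_gene_rejected(self):
        with pytest.raises(ConfigError, match="NOPE"):
            screen_genes(self._cohort_with_planted(2), ["NOPE"])

    def test_summary_counts(self):
        screen = pd.DataFrame({"hr": [2.0, 1.5, 0.5, 1.1],
                               "logrank_p": [0.01, 0.2, 0.01, 0.04]})
        s = summarize_screen(screen)
        assert s == {"n_genes": 4, "n_hr_gt_1": 3, "n_hr_gt_1_significant": 2}


def test_per_unit_hazard_ratio_recovered_from_log_linear_cohort():
    """beta = log 2 per expression unit: the per-unit HR implied by a
    median split (log HR scaled by the observed between-group mean
    expression difference) recovers ~2, with the slight downward
    attenuation expected of a marginal fit."""
    vals = []
    for seed in range(20):
        coh = simulate_survival(SimSurvivalConfig(
            n_subjects=2000, baseline_hazard=0.02, log_hr_per_unit=np.log(2),
            censor_rate=0.01, seed=seed), "G")
        x = coh["G"].to_numpy()
        d = dichotomize(x)
        t, e = coh["time"].to_numpy(), coh["event"].to_numpy()
        r = hazard_ratio(t[d.high], e[d.high], t[~d.high], e[~d.high])
        dx = x[d.high].mean() - x[~d.high].mean()
        vals.append(np.exp(np.log(r.hr) / dx))
    assert sum(1.7 <= v <= 2.35 for v in vals) >= 18


def test_generating_model_yields_uniform_logrank_p_under_null():
    """beta = 0: log-rank p across seeds is uniform (KS at alpha=0.01)."""
    from scipy import stats

    ps = []
    for seed in range(100):
        coh = simulate_survival(SimSurvivalConfig(
            n_subjects=80, baseline_hazard=0.03, censor_rate=0.01, seed=seed), "G")
        d = dichotomize(coh["G"].to_numpy())
        t, e = coh["time"].to_numpy(), coh["event"].to_numpy()
        ps.append(logrank_test(t[d.high], e[d.high], t[~d.high], e[~d.high])[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01
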