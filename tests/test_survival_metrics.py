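import numpy as np
import pandas as pd
import pytest

from protsig import (best_cutpoint_maxstat, bootstrap_ci, cox_ph,
                     horizon_classification, km_estimate, logrank_test,
                     median_cutpoint, per_marker_km_screen, roc_auc,
                     time_dependent_roc, youden_best_point)
from protsig.survival_metrics import _logrank_z


def brute_force_auc(scores, labels):
    """Concordant-pair counting: (wins + half-ties) / (n1 * n0)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_all_tied_scores_give_half(self):
        r = roc_auc(np.ones(10), np.r_[np.ones(4), np.zeros(6)].astype(int))
        assert r.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        r = roc_auc(np.r_[np.ones(5), np.zeros(5)],
                    np.r_[np.ones(5), np.zeros(5)].astype(int))
        assert r.auc == 1.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.choice(np.arange(8.0), size=20)  # force ties
            labels = rng.integers(0, 2, 20)
            if labels.sum() in (0, 20):
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc \
            == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, int))

    def test_curve_is_monotone_step_from_origin_to_one(self):
        rng = np.random.default_rng(5)
        r = roc_auc(rng.normal(size=40), rng.integers(0, 2, 40))
        assert r.fpr[0] == r.tpr[0] == 0.0
        assert r.fpr[-1] == r.tpr[-1] == 1.0
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()


class TestYouden:
    def exhaustive_best(self, scores, labels):
        cuts = np.r_[np.inf, np.unique(scores)[::-1]]
        best = None
        for c in cuts:
            pred = scores >= c
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            key = (round(j, 12), round(spec, 12), c)
            if best is None or key > best:
                best = key
        return best[0]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            scores = rng.choice(np.arange(10.0), 30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() in (0, 30):
                continue
            bp = youden_best_point(roc_auc(scores, labels))
            assert bp.youden_j == pytest.approx(
                self.exhaustive_best(scores, labels), abs=1e-9)

    def test_perfect_separation_j_one(self):
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        bp = youden_best_point(roc_auc(np.r_[np.ones(5), np.zeros(5)], labels),
                               n_pos=5, n_neg=5)
        assert bp.youden_j == pytest.approx(1.0)
        assert bp.sensitivity == bp.specificity == 1.0
        assert bp.ppv == bp.npv == 1.0

    def test_identical_distributions_j_zero(self):
        scores = np.tile(np.arange(5.0), 2)
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        bp = youden_best_point(roc_auc(scores, labels))
        assert bp.youden_j == pytest.approx(0.0, abs=1e-12)


class TestBootstrap:
    def test_degenerate_metric_gives_point_interval(self):
        scores = np.r_[np.ones(30), np.zeros(30)]
        labels = scores.astype(int)
        lo, hi = bootstrap_ci(lambda s, l: roc_auc(s, l).auc, scores, labels,
                              n=200, seed=0)
        assert lo == hi == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        ci1 = bootstrap_ci(lambda s, l: roc_auc(s, l).auc, scores, labels,
                           n=300, seed=5)
        ci2 = bootstrap_ci(lambda s, l: roc_auc(s, l).auc, scores, labels,
                           n=300, seed=5)
        assert ci1 == ci2

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=80) + 0.8 * rng.integers(0, 2, 80)
        labels = (scores > scores.mean()).astype(int)
        auc = roc_auc(scores, labels).auc
        lo, hi = bootstrap_ci(lambda s, l: roc_auc(s, l).auc, scores, labels,
                              n=500, seed=1)
        assert lo <= auc <= hi


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        km = km_estimate(np.array([1.0, 2.0]), np.array([0, 0]))
        assert km.survival_at(5.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(10)
        times = rng.exponential(10, 40)
        km = km_estimate(times, np.ones(40, int))
        for t in np.quantile(times, [0.2, 0.5, 0.9]):
            assert km.survival_at(t) == pytest.approx((times > t).mean(),
                                                      abs=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        times = np.r_[np.arange(1.0, 7.0), np.arange(1.0, 7.0)]
        events = np.ones(12, int)
        group = np.r_[np.zeros(6), np.ones(6)].astype(int)
        stat, p = logrank_test(times, events, group)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_o_e_v_table(self):
        """Small instance worked through the hypergeometric O-E/V table."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 0, 1])
        group = np.array([1, 0, 1, 0, 1, 0])
        # risk sets: t=1 (3v3) d in g1; t=2 (2v3) d in g0; t=3 (2v2) d in g1;
        # t=4 (1v2) d in g0; t=6 (0v1) d in g0
        o = 2.0
        e = 3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 0.0
        v = (3 * 3) / (6 * 6 * 5) * 5 + (2 * 3) / (5 * 5 * 4) * 4 \
            + (2 * 2) / (4 * 4 * 3) * 3 + (1 * 2) / (3 * 3 * 2) * 2 + 0.0
        expected = (o - e) ** 2 / v
        stat, _ = logrank_test(times, events, group)
        assert stat == pytest.approx(expected, abs=1e-9)
        # the standardized form must square to the same statistic
        z = _logrank_z(times, events, group.astype(bool))
        assert z ** 2 == pytest.approx(expected, abs=1e-9)

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(5, 30) + 0.1
        events = rng.integers(0, 2, 30)
        events[0] = 1
        group = rng.integers(0, 2, 30)
        group[:2] = [0, 1]
        s1, _ = logrank_test(times, events, group)
        s2, _ = logrank_test(np.log1p(times), events, group)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestCoxPH:
    def test_binary_covariate_hr_recovery(self):
        rng = np.random.default_rng(12)
        n = 1000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n) / np.exp(np.log(2.0) * g)
        cov = pd.DataFrame({"age_years": g})  # single numeric covariate
        res = cox_ph(t, np.ones(n, int), cov, multivariate=True)
        assert 1.7 <= res.hr.iloc[0] <= 2.35

    def test_unpenalized_cox_routes_agree(self):
        """lifelines-based PH fit vs the package's own partial-likelihood
        maximizer at zero penalty, on a shared instance."""
        from protsig._solvers import CoxData, cox_lasso_fit
        rng = np.random.default_rng(13)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n) / np.exp(0.5 * x)
        cov = pd.DataFrame({"age_years": x})
        res = cox_ph(t, np.ones(n, int), cov, multivariate=True)
        beta = cox_lasso_fit(CoxData(x[:, None], t, np.ones(n, int)), 0.0,
                             tol=1e-12)
        assert np.log(res.hr.iloc[0]) == pytest.approx(beta[0], abs=1e-6)

    def test_univariate_mode_loops_covariates(self, small_cohort_table):
        clin = small_cohort_table.clinical
        cov = clin[["age_years", "stage", "asa", "adjuvant_chemo",
                    "ca199_uml"]]
        res = cox_ph(clin.os_months.to_numpy(), clin.event.to_numpy(), cov,
                     multivariate=False)
        assert (res.model == "univariate").all()
        assert {"age_years", "stage", "log2_ca199"} <= set(res.covariate)

    def test_zero_variance_covariate_named(self):
        cov = pd.DataFrame({"age_years": np.ones(30)})
        with pytest.raises(ValueError, match="age_years"):
            cox_ph(np.arange(1.0, 31.0), np.ones(30, int), cov)


class TestTimeDependentROC:
    def test_reduces_to_static_roc_without_censoring(self):
        rng = np.random.default_rng(14)
        n = 60
        scores = rng.normal(size=n)
        times = rng.exponential(12, n) + 0.5
        events = np.ones(n, int)
        for t in (6.0, 12.0):
            res = time_dependent_roc(scores, times, events, t)
            static = roc_auc(scores, (times <= t).astype(int)).auc
            assert res.auc == pytest.approx(static, abs=1e-12)

    def test_perfect_ranking_score(self):
        rng = np.random.default_rng(15)
        times = rng.exponential(12, 50) + 0.5
        res = time_dependent_roc(-times, times, np.ones(50, int),
                                 float(np.median(times)))
        assert res.auc == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(600 + seed)
            n = 273
            times = rng.exponential(15, n)
            events = (rng.random(n) < 0.85).astype(int)
            events[np.argmax(times)] = 1
            aucs.append(time_dependent_roc(rng.normal(size=n), times, events,
                                           12.0).auc)
        assert all(0.40 <= a <= 0.60 for a in aucs)

    def test_no_cases_or_controls_rejected(self):
        times = np.array([10.0, 12.0, 15.0])
        with pytest.raises(ValueError, match="no cases"):
            time_dependent_roc(np.arange(3.0), times, np.ones(3, int), 5.0)
        with pytest.raises(ValueError, match="no controls"):
            time_dependent_roc(np.arange(3.0), times, np.ones(3, int), 20.0)


class TestHorizonClassification:
    def test_all_alive_all_predicted_alive(self):
        scores = np.zeros(10)
        times = np.full(10, 30.0)
        table = horizon_classification(scores, times, np.zeros(10, int),
                                       cutoff=1.0, horizons=(12.0,))
        row = table.iloc[0]
        assert row.tp == 10 and row.fn == 0 and row.sensitivity == 1.0

    def test_orientation_flip_complements_table(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=40)
        times = rng.exponential(15, 40) + 0.1
        events = np.ones(40, int)
        a = horizon_classification(scores, times, events, 0.0,
                                   horizons=(12.0,), risk_oriented=True)
        b = horizon_classification(scores, times, events, 0.0,
                                   horizons=(12.0,), risk_oriented=False)
        assert a.iloc[0].tp == b.iloc[0].fn and a.iloc[0].tn == b.iloc[0].fp

    def test_matches_per_sample_enumeration(self):
        rng = np.random.default_rng(17)
        n = 50
        scores = rng.normal(size=n)
        times = rng.exponential(15, n) + 0.1
        events = rng.integers(0, 2, n)
        cutoff = float(np.median(scores))
        t = 12.0
        table = horizon_classification(scores, times, events, cutoff,
                                       horizons=(t,))
        tp = fp = tn = fn = 0
        for s, ti, e in zip(scores, times, events):
            if ti <= t and e == 0:
                continue  # censored before the horizon
            alive = ti > t
            pred = s < cutoff
            tp += pred and alive
            fp += pred and not alive
            tn += (not pred) and (not alive)
            fn += (not pred) and alive
        assert (table.iloc[0][["tp", "fp", "tn", "fn"]].tolist()
                == [tp, fp, tn, fn])


class TestCutpoints:
    @staticmethod
    def _scored_survival(seed=18, n=120):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        hazard = np.where(scores > 0.2, 3.0, 1.0)
        t = rng.exponential(1.0, n) / hazard
        c = rng.exponential(3.0, n)
        return scores, np.minimum(t, c), (t <= c).astype(int)

    def test_maxstat_matches_exhaustive_scan(self):
        scores, times, events = self._scored_survival(n=30)
        res = best_cutpoint_maxstat(scores, times, events)
        lo, hi = np.quantile(scores, [0.1, 0.9])
        inside = np.unique(scores[(scores >= lo) & (scores <= hi)])
        cands = (inside[:-1] + inside[1:]) / 2
        zs = [abs(_logrank_z(times, events, scores > c)) for c in cands]
        assert res.cutoff == pytest.approx(cands[int(np.argmax(zs))])
        assert res.p_selection_biased

    def test_cutoff_respects_quantile_bounds(self):
        for seed in range(5):
            scores, times, events = self._scored_survival(seed=30 + seed)
            res = best_cutpoint_maxstat(scores, times, events)
            lo, hi = np.quantile(scores, [0.1, 0.9])
            assert lo <= res.cutoff <= hi

    def test_median_cutpoint_splits_at_median(self):
        scores, times, events = self._scored_survival()
        res = median_cutpoint(scores, times, events)
        assert res.cutoff == pytest.approx(np.median(scores))
        assert res.n_low + res.n_high == len(scores)
        assert not res.p_selection_biased

    def test_changepoint_recovery(self):
        hits = 0
        for seed in range(5):
            scores, times, events = self._scored_survival(seed=50 + seed,
                                                          n=300)
            res = best_cutpoint_maxstat(scores, times, events)
            pct = (scores <= res.cutoff).mean()
            true_pct = (scores <= 0.2).mean()
            hits += abs(pct - true_pct) <= 0.10
        assert hits >= 4


class TestPerMarkerScreen:
    def test_returns_all_markers_and_flags_planted_effect(self):
        from protsig import SimulationConfig, simulate_cohort
        sim = SimulationConfig(n_resectable=150, n_unresectable=2,
                               survival_betas={"P020": 0.8}, seed=19)
        cohort, _ = simulate_cohort(sim)
        table = per_marker_km_screen(
            cohort, cohort.clinical.resectable.to_numpy())
        assert len(table) == 93
        assert bool(table.set_index("marker").loc["P020", "flagged"])
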