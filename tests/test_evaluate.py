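import math

import numpy as np
import pytest

from ogscreen.evaluate import (
    harrell_cindex,
    rmse,
    run_benchmark,
    selection_metrics,
    td_auc,
    univariate_cox_screen,
)
from ogscreen.evaluate import test_set_tests as prognostic_tests  # avoid pytest collection
from ogscreen.pipeline import OgsConfig
from tests.conftest import make_survival_data


class TestRmse:
    def test_exact_recovery(self):
        theta = np.arange(5.0)
        assert rmse(theta, theta) == 0.0

    def test_single_unit_error(self):
        t = np.zeros(3005)
        h = t.copy()
        h[17] = 1.0
        assert rmse(h, t) == pytest.approx(math.sqrt(1 / 3005), abs=1e-9)

    def test_sign_flip_symmetry(self, rng):
        t = rng.standard_normal(50)
        e = rng.standard_normal(50)
        assert rmse(t + e, t) == pytest.approx(rmse(t - e, t))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))


class TestSelectionMetrics:
    UNIVERSE = tuple(f"f{i}" for i in range(3005))
    TRUTH = tuple(f"f{i}" for i in range(91))
    TRUE_INT = tuple(f"f{i}" for i in range(85, 91))

    def test_perfect_selection(self):
        p_int, sen, spe, size = selection_metrics(
            self.TRUTH, self.TRUTH, self.UNIVERSE, self.TRUE_INT
        )
        assert (p_int, sen, spe, size) == (1.0, 1.0, 1.0, 91)

    def test_empty_selection(self):
        p_int, sen, spe, size = selection_metrics(
            (), self.TRUTH, self.UNIVERSE, self.TRUE_INT
        )
        assert (p_int, sen, spe, size) == (0.0, 0.0, 1.0, 0)

    def test_nine_false_positives(self):
        selected = self.TRUTH + tuple(f"f{i}" for i in range(91, 100))
        _, sen, spe, size = selection_metrics(
            selected, self.TRUTH, self.UNIVERSE, self.TRUE_INT
        )
        assert sen == 1.0
        assert spe == pytest.approx(2905 / 2914)
        assert size == 100

    def test_two_route_agreement(self, rng):
        # set algebra vs confusion-matrix counting
        sel = set(rng.choice(self.UNIVERSE, 120, replace=False))
        p_int, sen, spe, size = selection_metrics(
            sel, self.TRUTH, self.UNIVERSE, self.TRUE_INT
        )
        truth = set(self.TRUTH)
        tp = sum(1 for f in self.UNIVERSE if f in sel and f in truth)
        tn = sum(1 for f in self.UNIVERSE if f not in sel and f not in truth)
        fn = sum(1 for f in self.UNIVERSE if f not in sel and f in truth)
        fp = sum(1 for f in self.UNIVERSE if f in sel and f not in truth)
        assert sen == tp / (tp + fn)
        assert spe == tn / (tn + fp)
        assert size == tp + fp


class TestHarrellCindex:
    def test_perfectly_anti_monotone(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        pi = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert harrell_cindex(pi, t, np.ones(5, int)) == 1.0

    def test_reversed(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        pi = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        assert harrell_cindex(pi, t, np.ones(5, int)) == 0.0

    def test_hand_example_with_censoring(self):
        # times 1,2,3,4,5; subject 2 (time 2) censored
        # usable pairs: earlier member has an event
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        d = np.array([1, 0, 1, 1, 1])
        pi = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
        # pairs from subj1 (pi=5): vs 2,3,4,5 -> all concordant (4)
        # subj2 censored: no pairs as earlier member
        # subj3 (pi=4): vs 4,5 -> concordant, concordant (2)
        # subj4 (pi=2): vs 5 (pi=3) -> discordant (0)
        # total usable 7, concordant 6
        assert harrell_cindex(pi, t, d) == pytest.approx(6 / 7)

    def test_complement_under_negation(self, rng):
        n = 40
        pi = rng.standard_normal(n)
        t = rng.exponential(1.0, n)
        d = np.ones(n, int)
        assert harrell_cindex(pi, t, d) == pytest.approx(
            1 - harrell_cindex(-pi, t, d)
        )


class TestTdAuc:
    def test_perfect_separation_no_censoring(self):
        t = np.linspace(1, 10, 40)
        pi = -t
        auc = td_auc(pi, t, np.ones(40, int))
        assert auc == 1.0

    def test_rank_invariance(self, rng):
        n = 60
        pi = rng.standard_normal(n)
        T = rng.exponential(1.0, n)
        C = rng.uniform(0, 3, n)
        t = np.minimum(T, C) + 1e-9
        d = (T <= C).astype(int)
        a1 = td_auc(pi, t, d)
        a2 = td_auc(np.exp(pi) * 3 + 1, t, d)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_null_centered_at_half(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(60):
            n = 150
            pi = rng.standard_normal(n)
            T = rng.exponential(1.0, n)
            C = rng.uniform(0, 3, n)
            t = np.minimum(T, C) + 1e-9
            d = (T <= C).astype(int)
            aucs.append(td_auc(pi, t, d))
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se


class TestTestSetTests:
    def test_median_split_balance(self, rng):
        n = 100
        pi = rng.standard_normal(n)
        med = np.median(pi)
        assert abs((pi > med).sum() - (pi <= med).sum()) <= 1 if n % 2 == 0 else 1

    def test_constant_pi_flagged(self, rng):
        data = make_survival_data(rng, n=40, q=1)
        dev, cox_p, lr_p = prognostic_tests(np.ones(40), data.time, data.event)
        assert cox_p == 1.0
        assert dev == 0.0

    def test_prognostic_pi_negative_deviance(self, rng):
        n = 120
        E = rng.standard_normal((n, 1))
        lp = 2.0 * E[:, 0]
        T = rng.exponential(1.0, n) / np.exp(lp)
        t = np.clip(T, 1e-9, None)
        d = np.ones(n, int)
        dev, cox_p, lr_p = prognostic_tests(lp, t, d)
        assert dev < 0
        assert cox_p < 1e-6
        assert lr_p < 1e-4

    def test_null_pi_p_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(150):
            n = 60
            pi = rng.standard_normal(n)
            t = rng.exponential(1.0, n) + 1e-9
            ps.append(prognostic_tests(pi, t, np.ones(n, int))[1])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestUnivariateCoxScreen:
    def test_matches_single_fits(self, rng):
        from ogscreen.coxcore import _newton_cox, _score_info

        data = make_survival_data(rng, n=100, q=1, p=4, alpha=[0.5],
                                  beta=[1.0, 0, 0, 0])
        Z = np.hstack([data.E, data.X])
        wald_p, wald_z = univariate_cox_screen(data.time, data.event, Z)
        for j in range(Z.shape[1]):
            z = (Z[:, j] - Z[:, j].mean()) / Z[:, j].std()
            beta, _, _, _ = _newton_cox(data.time, data.event, z[:, None])
            _, _, info = _score_info(data.time, data.event, z[:, None],
                                     z * beta[0])
            ref_z = beta[0] * np.sqrt(info[0, 0])
            assert wald_z[j] == pytest.approx(ref_z, abs=1e-4)

    def test_sis_retention_count(self):
        assert math.floor(300 / math.log(300)) == 52


class TestRunBenchmark:
    def test_single_replicate_medians_equal_values(self, small_sim_config):
        report = run_benchmark(
            small_sim_config,
            methods=("ordinary_lasso",),
            replicates=1,
            seed=4,
            ogs_config=OgsConfig(folds=3, n_lambdas_group=15,
                                 n_lambdas_final=15, permutations=5),
            folds=3,
        )
        row = report.per_replicate.iloc[0]
        assert report.summary.loc["ordinary_lasso", "sen"] == row["sen"]
        assert report.summary.loc["ordinary_lasso", "c_index"] == row["c_index"]
        assert report.failures == {"ordinary_lasso": 0}

    def test_replicate_order_invariance(self, small_sim_config):
        kw = dict(
            methods=("ordinary_lasso",), replicates=3, seed=11,
            ogs_config=OgsConfig(folds=3, n_lambdas_group=10,
                                 n_lambdas_final=10, permutations=3),
            folds=3,
        )
        rep = run_benchmark(small_sim_config, **kw)
        med1 = rep.summary.loc["ordinary_lasso", "sen"]
        shuffled = rep.per_replicate.sample(frac=1, random_state=0)
        med2 = shuffled.groupby("method")["sen"].median()["ordinary_lasso"]
        assert med1 == med2

    def test_unknown_method_rejected(self, small_sim_config):
        with pytest.raises(ValueError):
            run_benchmark(small_sim_config, methods=("nope",), replicates=1,
                          seed=0)
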