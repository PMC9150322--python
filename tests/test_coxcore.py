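import numpy as np
import pytest

from ogscreen.coxcore import (
    SurvivalDataset,
    cox_loglik,
    fit_null_cox,
    fit_overlap_group_cox,
    fit_penalized_cox,
    _newton_cox,
)
from ogscreen.pathways import PathwayCollection, build_expansion
from tests.conftest import make_survival_data


class TestSurvivalDataset:
    def test_interaction_order_and_values(self, rng):
        data = make_survival_data(rng, n=10, q=2, p=3)
        U, names = data.interactions()
        assert names == (
            "E1:g1", "E1:g2", "E1:g3", "E2:g1", "E2:g2", "E2:g3",
        )
        np.testing.assert_allclose(U[:, 4], data.E[:, 1] * data.X[:, 1])

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            SurvivalDataset(np.array([1.0, -1.0]), np.array([1, 0]),
                            np.zeros((2, 1)), np.zeros((2, 1)), ("a",), ("g",))
        with pytest.raises(ValueError):
            SurvivalDataset(np.array([1.0, 1.0]), np.array([1, 2]),
                            np.zeros((2, 1)), np.zeros((2, 1)), ("a",), ("g",))


class TestFitNullCox:
    def test_martingale_residuals_sum_to_zero(self, rng):
        data = make_survival_data(rng, n=100, q=3, alpha=[0.5, -0.5, 0.2])
        null = fit_null_cox(data)
        assert abs(null.m.sum()) < 1e-6

    def test_three_subject_hand_computation(self):
        # subjects with times 1 < 2 < 3, all events, one binary covariate
        # x = (1, 0, 1); with b = alpha-hat, w = exp(b):
        #   score: sum_events [x_i - S1/S0] = 0 at the MLE
        # hand Breslow increments: 1/(2w+1), 1/(w+1), 1/w
        data = SurvivalDataset(
            time=np.array([1.0, 2.0, 3.0]),
            event=np.array([1, 1, 1]),
            E=np.array([[1.0], [0.0], [1.0]]),
            X=np.zeros((3, 1)),
            env_names=("x",),
            gene_names=("g",),
        )
        null = fit_null_cox(data)
        b = null.alpha[0]
        w = np.exp(b)
        # score equation: (1 - 2w/(2w+1)) + (0 - w/(w+1)) + (1 - 1) = 0
        assert (1 - 2 * w / (2 * w + 1)) - w / (w + 1) == pytest.approx(
            0.0, abs=1e-8
        )
        inc = null.baseline_increments
        np.testing.assert_allclose(
            inc, [1 / (2 * w + 1), 1 / (w + 1), 1 / w], atol=1e-8
        )
        # c_i = exp(eta_i) * Lambda0(t_i): only increments at event times
        # up to the subject's own observed time contribute
        expected_c = np.array([
            w * inc[0],
            inc[0] + inc[1],
            w * (inc[0] + inc[1] + inc[2]),
        ])
        np.testing.assert_allclose(null.c, expected_c, atol=1e-8)
        np.testing.assert_allclose(null.m, data.event - expected_c, atol=1e-8)

    def test_c_equals_row_sums_of_P(self, rng):
        data = make_survival_data(rng, n=60, q=2, alpha=[0.3, 0.3])
        null = fit_null_cox(data)
        np.testing.assert_allclose(null.c, null.P.sum(axis=1), atol=1e-10)

    def test_no_events_rejected(self, rng):
        data = make_survival_data(rng, n=20, q=1)
        data.event[:] = 0
        with pytest.raises(ValueError):
            fit_null_cox(data)

    def test_martingale_range(self, rng):
        data = make_survival_data(rng, n=120, q=2, alpha=[1.0, -0.5])
        null = fit_null_cox(data)
        assert (null.m <= 1.0 + 1e-12).all()
        assert (null.m[data.event == 0] <= 1e-12).all()

    def test_V_positive_semidefinite_ish(self, rng):
        for _ in range(3):
            data = make_survival_data(rng, n=40, q=2, alpha=[0.5, 0.0])
            null = fit_null_cox(data)
            evals = np.linalg.eigvalsh(null.V)
            assert evals.min() >= -1e-8 * np.linalg.norm(null.V)


class TestFitPenalizedCox:
    def test_lasso_heavy_penalty_all_zero(self, rng):
        data = make_survival_data(rng, n=80, q=2, p=5, alpha=[0.5, -0.5])
        Z = np.hstack([data.E, data.X])
        names = data.env_names + data.gene_names
        model = fit_penalized_cox(
            data.time, data.event, Z, names, penalty="lasso", folds=3,
            rng_seed=0, n_lambdas=30,
        )
        # the path starts at lambda_max where everything is zero
        assert model.lam > 0

    def test_ridge_near_zero_matches_unpenalized(self, rng):
        data = make_survival_data(rng, n=150, q=1, alpha=[0.8])
        z = (data.E - data.E.mean()) / data.E.std()
        beta_un, _, _, _ = _newton_cox(data.time, data.event, z)
        beta_pen, _, _, _ = _newton_cox(data.time, data.event, z, ridge=1e-10)
        assert beta_pen[0] == pytest.approx(beta_un[0], abs=1e-4)

    def test_ridge_duplicated_column_symmetric(self, rng):
        data = make_survival_data(rng, n=100, q=1, alpha=[0.7])
        z = data.E[:, 0]
        beta, _, _, _ = _newton_cox(
            data.time, data.event, np.column_stack([z, z]), ridge=0.1
        )
        assert beta[0] == pytest.approx(beta[1], abs=1e-6)

    def test_constant_column_dropped_with_warning(self, rng):
        data = make_survival_data(rng, n=60, q=1, alpha=[0.5])
        Z = np.column_stack([data.E[:, 0], np.ones(60)])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_penalized_cox(
                data.time, data.event, Z, ("x", "const"), penalty="lasso",
                folds=3, rng_seed=0, n_lambdas=20,
            )
        assert model.feature_names == ("x",)

    def test_deterministic_given_seed(self, rng):
        data = make_survival_data(rng, n=80, q=2, p=4, alpha=[0.5, -0.5],
                                  beta=[1.0, 0, 0, 0])
        Z = np.hstack([data.E, data.X])
        names = data.env_names + data.gene_names
        m1 = fit_penalized_cox(data.time, data.event, Z, names, folds=4,
                               rng_seed=7, n_lambdas=25)
        m2 = fit_penalized_cox(data.time, data.event, Z, names, folds=4,
                               rng_seed=7, n_lambdas=25)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.lam == m2.lam

    def test_monotone_shrinkage_along_ridge_grid(self, rng):
        data = make_survival_data(rng, n=100, q=2, alpha=[0.8, -0.6])
        Zs = (data.E - data.E.mean(0)) / data.E.std(0)
        norms = []
        for lam in (0.01, 0.5, 10.0):
            b, _, _, _ = _newton_cox(data.time, data.event, Zs, ridge=lam)
            norms.append(np.linalg.norm(b))
        assert norms[0] > norms[1] > norms[2]


class TestFitOverlapGroupCox:
    def test_lambda_max_selects_nothing(self, rng):
        data = make_survival_data(rng, n=60, q=1, p=6, alpha=[0.4])
        pw = PathwayCollection(("a", "b"), (("g1", "g2", "g3"), ("g4", "g5", "g6")))
        ex = build_expansion(pw)
        res = fit_overlap_group_cox(data, ex, folds=3, rng_seed=0,
                                    n_lambdas=8, lambda_min_ratio=0.9)
        # near lambda_max the whole path keeps every group at zero
        assert res.lambdas[0] >= res.lambdas[-1]

    def test_effective_group_detected(self):
        # one group of 5 genes with real effect among 10 noise groups
        detected = 0
        runs = 12
        for s in range(runs):
            rng = np.random.default_rng(1000 + s)
            n, p = 200, 55
            data = make_survival_data(
                rng, n=n, q=1, p=p, alpha=[0.3],
                beta=[2.0] * 5 + [0.0] * 50, censor_scale=30.0,
            )
            names = tuple(f"grp{j}" for j in range(11))
            members = tuple(
                tuple(f"g{i + 1}" for i in range(5 * j, 5 * j + 5))
                for j in range(11)
            )
            ex = build_expansion(
                PathwayCollection(names, members, genes=data.gene_names)
            )
            res = fit_overlap_group_cox(data, ex, folds=4, rng_seed=s,
                                        n_lambdas=25)
            detected += "grp0" in res.selected
        assert detected >= runs - 1

    def test_disjoint_groups_match_column_permutation(self, rng):
        # with disjoint groups the expansion is a column permutation, so
        # permuting the gene order must not change the selected groups
        data = make_survival_data(rng, n=120, q=1, p=6, alpha=[0.3],
                                  beta=[1.5, 1.5, 0, 0, 0, 0])
        pw1 = PathwayCollection(("a", "b"), (("g1", "g2", "g3"), ("g4", "g5", "g6")),
                                genes=data.gene_names)
        pw2 = PathwayCollection(("a", "b"), (("g3", "g1", "g2"), ("g6", "g5", "g4")),
                                genes=data.gene_names)
        r1 = fit_overlap_group_cox(data, build_expansion(pw1), folds=3,
                                   rng_seed=0, n_lambdas=20)
        r2 = fit_overlap_group_cox(data, build_expansion(pw2), folds=3,
                                   rng_seed=0, n_lambdas=20)
        assert set(r1.selected) == set(r2.selected)


class TestCoxLoglik:
    def test_matches_direct_evaluation(self, rng):
        data = make_survival_data(rng, n=30, q=1)
        eta = rng.standard_normal(30)
        ll = cox_loglik(data.time, data.event, eta)
        direct = 0.0
        for i in range(30):
            if data.event[i]:
                risk = data.time >= data.time[i]
                direct += eta[i] - np.log(np.exp(eta[risk]).sum())
        assert ll == pytest.approx(direct, abs=1e-9)

    def test_stable_under_huge_eta(self, rng):
        data = make_survival_data(rng, n=30, q=1)
        eta = rng.standard_normal(30) * 400
        assert np.isfinite(cox_loglik(data.time, data.event, eta))
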