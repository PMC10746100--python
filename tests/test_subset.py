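import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methyldiet.errors import CollinearityError, EmptyModelError, InputError
from methyldiet.subset import (
    choose_subset,
    leaps_and_bounds,
    refit_and_prune,
    variance_inflation,
    _criterion_value,
)


def brute_force_best(X, y, k_max):
    """Exhaustive per-size best subsets by independent least squares."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    best = {}
    for k in range(1, k_max + 1):
        best_rss, best_set = np.inf, None
        for S in itertools.combinations(range(X.shape[1]), k):
            b, *_ = np.linalg.lstsq(Xc[:, S], yc, rcond=None)
            rss = float(((yc - Xc[:, S] @ b) ** 2).sum())
            if rss < best_rss:
                best_rss, best_set = rss, S
        best[k] = (best_set, best_rss)
    return best


class TestLeapsAndBounds:
    def test_orthogonal_columns_closed_form(self):
        """With mutually orthogonal centered columns the best size-k subset
        is the top-k columns by squared correlation with y."""
        rng = np.random.default_rng(0)
        n, p = 50, 6
        Q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(n, p + 1)))
        # Gram-Schmidt on centered columns keeps every column centered
        base = rng.normal(size=(n, p))
        base -= base.mean(axis=0)
        Q, _ = np.linalg.qr(base)
        y = rng.normal(size=n)
        yc = y - y.mean()
        scores = (Q.T @ yc) ** 2
        ranked = list(np.argsort(-scores))
        res = leaps_and_bounds(Q, y)
        for k in range(1, p + 1):
            assert set(res.subsets[k]) == set(ranked[:k])

    def test_full_model_rss_equals_ols(self):
        rng = np.random.default_rng(2)
        n, p = 40, 7
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        res = leaps_and_bounds(X, y)
        import statsmodels.api as sm

        full = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.rss[p] == pytest.approx(full.ssr)
        # RSS is non-increasing in subset size
        rss_seq = [res.rss[k] for k in sorted(res.rss)]
        assert all(a >= b - 1e-10 for a, b in zip(rss_seq, rss_seq[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_identical_to_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 45, 9
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[rng.choice(p, 3, replace=False)] = rng.normal(0, 2, 3)
        y = X @ beta + rng.normal(size=n)
        res = leaps_and_bounds(X, y)
        oracle = brute_force_best(X, y, p)
        for k in oracle:
            assert tuple(res.subsets[k]) == tuple(sorted(oracle[k][0]))
            assert res.rss[k] == pytest.approx(oracle[k][1], rel=1e-9)

    def test_bound_actually_prunes(self):
        rng = np.random.default_rng(4)
        n, p = 80, 12
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 3 + rng.normal(size=n)
        res = leaps_and_bounds(X, y)
        assert res.n_evaluated < res.n_total_subsets

    def test_dataframe_input_returns_probe_ids(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("dcba"))
        y = frame["a"].to_numpy() + rng.normal(0, 0.1, 30)
        res = leaps_and_bounds(frame, y)
        assert res.subsets[1] == ("a",)

    def test_exact_collinearity_names_offender(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(CollinearityError):
            leaps_and_bounds(X, rng.normal(size=30), predictor_ids=list("abcd"))

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(20), np.random.default_rng(0).normal(size=20)])
        with pytest.raises(InputError, match="constant"):
            leaps_and_bounds(X, np.random.default_rng(1).normal(size=20))

    def test_k_max_at_least_n_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(InputError):
            leaps_and_bounds(rng.normal(size=(10, 4)), rng.normal(size=10), k_max=10)


class TestChooseSubset:
    def test_single_size_returned_under_every_criterion(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        res = leaps_and_bounds(X, y, k_max=1)
        for crit in ("AIC", "BIC", "AICc", "adjR2"):
            assert choose_subset(res, n=30, criterion=crit) == res.subsets[1]

    def test_bic_recovers_true_support(self):
        """Strong 3-predictor signal among 10 candidates at n = 200: the
        BIC choice always contains the true support, and matches it
        exactly in most replicates (best-subset search maximises the
        spurious-fit advantage of noise predictors, so occasional
        one-variable overselection is expected even for BIC)."""
        exact = contains = 0
        n_reps = 100
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            n, p = 200, 10
            X = rng.normal(size=(n, p))
            true = (0, 1, 2)
            y = X[:, true] @ np.array([2.0, -1.5, 1.0]) + rng.normal(size=n)
            res = leaps_and_bounds(X, y, k_max=6)
            chosen = tuple(choose_subset(res, n=n, criterion="BIC"))
            exact += chosen == true
            contains += set(true) <= set(chosen)
        assert contains >= 0.95 * n_reps
        assert exact >= 0.7 * n_reps

    def test_criterion_values_recomputable_from_rss(self):
        rng = np.random.default_rng(3)
        n, p = 60, 5
        X = rng.normal(size=(n, p))
        y = X[:, 0] + rng.normal(size=n)
        res = leaps_and_bounds(X, y)
        for k, rss in res.rss.items():
            assert _criterion_value("AIC", rss, res.tss, n, k) == pytest.approx(
                n * np.log(rss / n) + 2 * (k + 1)
            )
            assert _criterion_value("BIC", rss, res.tss, n, k) == pytest.approx(
                n * np.log(rss / n) + np.log(n) * (k + 1)
            )
            adj = 1 - (rss / (n - k - 1)) / (res.tss / (n - 1))
            assert _criterion_value("adjR2", rss, res.tss, n, k) == pytest.approx(-adj)


class TestRefitAndPrune:
    def test_noop_when_all_strong_and_uncorrelated(self):
        rng = np.random.default_rng(0)
        n = 100
        X = rng.normal(size=(n, 3))
        y = X @ np.array([3.0, -2.0, 1.5]) + rng.normal(0, 0.5, n)
        fit = refit_and_prune(X, y, subset=[0, 1, 2])
        assert fit.predictor_ids == [0, 1, 2]
        assert (fit.vif <= 10).all()

    def test_duplicated_column_removed_by_vif(self):
        rng = np.random.default_rng(1)
        n = 80
        x = rng.normal(size=n)
        X = np.column_stack([x, x + rng.normal(0, 1e-8, n), rng.normal(size=n)])
        y = 2 * x + X[:, 2] + rng.normal(0, 0.5, n)
        fit = refit_and_prune(X, y, subset=[0, 1, 2], p_keep=1.0)
        assert len(fit.predictor_ids) == 2
        assert 2 in fit.predictor_ids
        assert sum(j in fit.predictor_ids for j in (0, 1)) == 1

    def test_single_predictor_matches_textbook_t_test(self):
        """Slope, SE and two-sided p on a 6-point dataset against the
        closed-form simple-regression formulas with n - 2 df."""
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([1.0, 2, 1, 3, 2, 4])
        fit = refit_and_prune(x[:, None], y, subset=[0], p_keep=1.0)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt((resid**2).sum() / 4 / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), df=4)
        assert fit.coefficients[0] == pytest.approx(slope)
        assert fit.standard_errors[0] == pytest.approx(se)
        assert fit.p_values[0] == pytest.approx(p)
        assert fit.vif[0] == 1.0

    def test_prune_is_idempotent(self):
        rng = np.random.default_rng(2)
        n, p = 90, 6
        X = rng.normal(size=(n, p))
        y = X[:, :2] @ np.array([2.0, -2.0]) + rng.normal(size=n)
        fit1 = refit_and_prune(X, y, subset=list(range(p)))
        fit2 = refit_and_prune(X, y, subset=fit1.predictor_ids)
        assert fit2.predictor_ids == fit1.predictor_ids
        pd.testing.assert_series_equal(fit1.coefficients, fit2.coefficients)

    def test_all_pruned_raises_empty_model(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        with pytest.raises(EmptyModelError):
            refit_and_prune(X, y, subset=[0, 1, 2], p_keep=1e-12)

    def test_vif_of_independent_columns_near_one(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        vif = variance_inflation(frame)
        assert ((vif >= 1.0) & (vif < 1.2)).all()
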