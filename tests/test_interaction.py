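import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methyldiet import (
    DietResponseModel,
    DietResponseResults,
    fit_interaction_model,
)
from methyldiet.errors import InputError

from conftest import make_phenotypes


def simulate_rows(n=120, seed=0, beta=None, noise_sd=2.0, with_cov=True):
    """Raw arrays from the interaction data-generating process.

    beta = (const, diet, score, diet:score, age, sex) with diet MHP = 0
    and sex female = 0."""
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = (-8.0, -1.5, 0.3, -0.6, 0.02, 0.8)
    diet = np.where(rng.random(n) < 0.5, "MHP", "LF")
    score = rng.normal(0.0, 2.0, n)
    age = rng.uniform(20, 65, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    d = (diet == "LF").astype(float)
    s = (sex == "male").astype(float)
    mean = beta[0] + beta[1] * d + beta[2] * score + beta[3] * d * score
    if with_cov:
        mean = mean + beta[4] * age + beta[5] * s
    y = mean + rng.normal(0.0, noise_sd, n)
    return dict(pct_bmil=y, total_score=score, diet=diet, age=age, sex=sex)


class TestModelConstruction:
    def test_design_matrix_layout(self):
        data = simulate_rows(n=30, seed=1)
        model = DietResponseModel(**data)
        assert list(model.design.columns) == [
            "const", "diet", "score", "diet:score", "age", "sex",
        ]
        d = model.design
        np.testing.assert_array_equal(
            d["diet"], (np.asarray(data["diet"]) == "LF").astype(float)
        )
        np.testing.assert_allclose(d["diet:score"], d["diet"] * d["score"])

    def test_unadjusted_model_has_four_columns(self):
        data = simulate_rows(n=30, seed=2)
        model = DietResponseModel(
            data["pct_bmil"], data["total_score"], data["diet"]
        )
        assert list(model.design.columns) == ["const", "diet", "score", "diet:score"]

    def test_single_arm_rejected(self):
        data = simulate_rows(n=20, seed=3)
        with pytest.raises(InputError, match="both diet arms"):
            DietResponseModel(
                data["pct_bmil"], data["total_score"], ["MHP"] * 20
            )

    def test_too_few_rows_rejected(self):
        with pytest.raises(InputError):
            DietResponseModel(
                np.zeros(5), np.arange(5.0), ["MHP", "LF", "MHP", "LF", "MHP"]
            )

    def test_constant_score_rejected(self):
        with pytest.raises(InputError, match="constant"):
            DietResponseModel(
                np.arange(10.0), np.ones(10), ["MHP", "LF"] * 5
            )

    def test_unknown_sex_label_rejected(self):
        data = simulate_rows(n=20, seed=4)
        data["sex"] = ["F"] * 20
        with pytest.raises(InputError, match="sex"):
            DietResponseModel(**data)

    def test_from_frames_aligns_on_id(self):
        data = simulate_rows(n=40, seed=5)
        pheno = make_phenotypes(
            data["diet"], data["pct_bmil"], age=data["age"], sex=data["sex"]
        )
        ids = pheno.ids
        # shuffled score table must still align by id
        order = np.random.default_rng(0).permutation(40)
        scores = pd.DataFrame(
            {"total": np.asarray(data["total_score"])[order]},
            index=pd.Index(np.asarray(ids)[order], name="id"),
        )
        model = DietResponseModel.from_frames(scores, pheno)
        np.testing.assert_allclose(model.design["score"], data["total_score"])

    def test_from_frames_missing_score_raises(self):
        data = simulate_rows(n=20, seed=6)
        pheno = make_phenotypes(data["diet"], data["pct_bmil"])
        scores = pd.DataFrame(
            {"total": data["total_score"][:-1]},
            index=pd.Index(pheno.ids[:-1], name="id"),
        )
        with pytest.raises(InputError, match="missing"):
            DietResponseModel.from_frames(scores, pheno)


class TestFit:
    def test_noiseless_exact_recovery(self):
        beta = (-7.952, -1.179, 0.238, -0.453, 0.013, 1.5)
        data = simulate_rows(n=80, seed=7, beta=beta, noise_sd=0.0)
        res = DietResponseModel(**data).fit()
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-8)
        assert res.rsquared == pytest.approx(1.0)

    def test_normal_equations_oracle_small_dataset(self):
        """12-row fit checked against (X'X)^{-1} X'y and the classical
        covariance s^2 (X'X)^{-1} computed by hand."""
        data = simulate_rows(n=12, seed=8)
        model = DietResponseModel(**data)
        res = model.fit()
        X = model.design.to_numpy()
        y = np.asarray(data["pct_bmil"], dtype=float)
        XtX_inv = np.linalg.inv(X.T @ X)
        beta_hat = XtX_inv @ X.T @ y
        resid = y - X @ beta_hat
        s2 = resid @ resid / (12 - X.shape[1])
        np.testing.assert_allclose(res.params.to_numpy(), beta_hat, rtol=1e-10)
        np.testing.assert_allclose(res.cov.to_numpy(), s2 * XtX_inv, rtol=1e-8)
        np.testing.assert_allclose(
            res.bse.to_numpy(), np.sqrt(np.diag(s2 * XtX_inv)), rtol=1e-8
        )
        # two-sided t p-values with n - k df
        t = beta_hat / np.sqrt(np.diag(s2 * XtX_inv))
        np.testing.assert_allclose(
            res.pvalues.to_numpy(), 2 * stats.t.sf(np.abs(t), df=12 - X.shape[1]),
            rtol=1e-8,
        )

    def test_reference_swap_flips_diet_terms_only(self):
        """Recoding LF as the reference negates beta_D and beta_DT, maps
        const -> const + beta_D and score -> score + beta_DT, and leaves
        every fitted value identical."""
        data = simulate_rows(n=90, seed=9)
        res_m = DietResponseModel(**data, diet_ref="MHP").fit()
        res_l = DietResponseModel(**data, diet_ref="LF").fit()
        p_m, p_l = res_m.params, res_l.params
        assert p_l["diet"] == pytest.approx(-p_m["diet"])
        assert p_l["diet:score"] == pytest.approx(-p_m["diet:score"])
        assert p_l["const"] == pytest.approx(p_m["const"] + p_m["diet"])
        assert p_l["score"] == pytest.approx(p_m["score"] + p_m["diet:score"])
        assert p_l["age"] == pytest.approx(p_m["age"])
        for t in (-3.0, 0.0, 2.5):
            for diet in ("MHP", "LF"):
                xm = res_m._design_row(t, diet)
                xl = res_l._design_row(t, diet)
                assert xm @ p_m.to_numpy() == pytest.approx(xl @ p_l.to_numpy())

    def test_interaction_term_against_statsmodels_formula(self):
        import statsmodels.formula.api as smf

        data = simulate_rows(n=100, seed=10)
        res = DietResponseModel(**data).fit()
        frame = pd.DataFrame(
            {
                "y": data["pct_bmil"],
                "score": data["total_score"],
                "diet": data["diet"],
                "age": data["age"],
                "sex": data["sex"],
            }
        )
        ref = smf.ols(
            "y ~ C(diet, Treatment('MHP')) * score + age "
            "+ C(sex, Treatment('female'))",
            data=frame,
        ).fit()
        assert res.params["diet:score"] == pytest.approx(
            ref.params["C(diet, Treatment('MHP'))[T.LF]:score"]
        )
        assert res.bse["diet:score"] == pytest.approx(
            ref.bse["C(diet, Treatment('MHP'))[T.LF]:score"]
        )

    def test_mixed_fit_reports_zero_random_intercept_variance(self):
        """One observation per participant leaves the variance split
        unidentified; the diagnostic reports the boundary value 0."""
        data = simulate_rows(n=60, seed=11)
        res = DietResponseModel(**data).fit(method="mixed")
        assert res.random_intercept_var == 0.0
        ols = DietResponseModel(**data).fit()
        pd.testing.assert_series_equal(res.params, ols.params)

    def test_unknown_method_rejected(self):
        data = simulate_rows(n=20, seed=12)
        with pytest.raises(InputError):
            DietResponseModel(**data).fit(method="reml")


class TestMarginals:
    def test_prediction_values_by_hand(self):
        data = simulate_rows(n=80, seed=13)
        res = DietResponseModel(**data).fit()
        grid = np.array([-2.0, 0.0, 3.0])
        marg = res.predict_marginals(grid)
        b = res.params
        age_bar = res.covariate_means["age"]
        sex_bar = res.covariate_means["sex"]
        for i, t in enumerate(grid):
            mhp = b["const"] + b["score"] * t + b["age"] * age_bar + b["sex"] * sex_bar
            lf = mhp + b["diet"] + b["diet:score"] * t
            assert marg.pred_mhp[i] == pytest.approx(mhp)
            assert marg.pred_lf[i] == pytest.approx(lf)

    def test_se_matches_monte_carlo_delta_method(self):
        """Point SE equals the SD of x'beta under beta ~ N(beta_hat, Cov),
        estimated from 200k multivariate normal draws."""
        data = simulate_rows(n=70, seed=14)
        res = DietResponseModel(**data).fit()
        rng = np.random.default_rng(99)
        draws = rng.multivariate_normal(
            res.params.to_numpy(), res.cov.to_numpy(), size=200_000
        )
        for t in (-1.0, 2.0):
            for diet in ("MHP", "LF"):
                x = res._design_row(t, diet)
                _, se = res._pred_se(x[None, :])
                mc = (draws @ x).std(ddof=1)
                assert se[0] == pytest.approx(mc, rel=0.02)

    def test_default_grid_spans_observed_scores(self):
        data = simulate_rows(n=50, seed=15)
        res = DietResponseModel(**data).fit()
        marg = res.predict_marginals()
        assert len(marg.grid) == 50
        assert marg.grid[0] == pytest.approx(res.score_range[0])
        assert marg.grid[-1] == pytest.approx(res.score_range[1])
        frame = marg.to_frame()
        assert list(frame.columns) == ["score", "pred_mhp", "se_mhp", "pred_lf", "se_lf"]

    def test_extrapolation_warns(self):
        data = simulate_rows(n=50, seed=16)
        res = DietResponseModel(**data).fit()
        lo, hi = res.score_range
        with pytest.warns(UserWarning, match="extrapolation"):
            res.predict_marginals(np.array([lo, hi + 10 * (hi - lo)]))

    def test_se_minimised_near_covariate_center(self):
        """Prediction SE grows away from the center of the observed score
        distribution (classic hyperbolic confidence band shape)."""
        data = simulate_rows(n=200, seed=17)
        res = DietResponseModel(**data).fit()
        center = float(np.mean(data["total_score"]))
        spread = float(np.std(data["total_score"]))
        grid = np.array([center - 4 * spread, center, center + 4 * spread])
        marg = res.predict_marginals(grid)
        assert marg.se_mhp[1] < marg.se_mhp[0]
        assert marg.se_mhp[1] < marg.se_mhp[2]


class TestSerialization:
    def test_roundtrip_preserves_predictions_exactly(self, tmp_path):
        data = simulate_rows(n=60, seed=18)
        res = fit_interaction_model(
            pd.DataFrame(
                {"total": data["total_score"]},
                index=pd.Index([f"S{i:04d}" for i in range(60)], name="id"),
            ),
            make_phenotypes(
                data["diet"], data["pct_bmil"], age=data["age"], sex=data["sex"]
            ),
        )
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = DietResponseResults.from_json(path)
        pd.testing.assert_series_equal(res.params, back.params)
        pd.testing.assert_frame_equal(res.cov, back.cov)
        grid = np.linspace(*res.score_range, 7)
        a, b = res.predict_marginals(grid), back.predict_marginals(grid)
        np.testing.assert_array_equal(a.pred_mhp, b.pred_mhp)
        np.testing.assert_array_equal(a.se_lf, b.se_lf)

    def test_summary_mentions_codings_and_terms(self):
        data = simulate_rows(n=40, seed=19)
        text = DietResponseModel(**data).fit().summary()
        for token in ("diet:score", "MHP = 0", "female = 0", "P>|t|"):
            assert token in text
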