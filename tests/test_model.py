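"""Weight learning (OLS / ridge), penalty selection, and the index transform."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfni.errors import (
    DegenerateFormulaError,
    SingularDesignError,
    ValidationError,
)
from cfni.model import (
    DEFAULT_LAMBDA_GRID,
    _ridge_beta,
    cfni_score,
    cfni_scores,
    effective_df,
    fit_ols,
    fit_ridge,
    select_penalty_cv,
    select_penalty_ic,
    to_index_formula,
)
from cfni.types import FittedLinearModel, IndexFormula


def make_tables(g, r, hei):
    n = len(g)
    ids = [f"c{i}" for i in range(n)]
    summaries = pd.DataFrame(
        {"cart_id": ids, "pct_green": g, "pct_yellow": 100 - np.asarray(g) - np.asarray(r),
         "pct_red": r}
    )
    scores = pd.DataFrame({"cart_id": ids, "total": hei})
    return summaries, scores


@pytest.fixture
def noiseless_data(rng):
    """503 compositions on the generating plane HEI = 56.72 + 0.270G - 0.278R."""
    g = rng.uniform(10, 90, 503)
    r = np.minimum(rng.uniform(0, 60, 503), 100 - g)
    hei = 56.72 + 0.270 * g - 0.278 * r
    return make_tables(g, r, hei)


class TestOLS:
    def test_exact_recovery_on_noiseless_data(self, noiseless_data):
        model = fit_ols(*noiseless_data)
        assert model.constant == pytest.approx(56.72, rel=1e-8)
        assert model.coef_green == pytest.approx(0.270, rel=1e-8)
        assert model.coef_red == pytest.approx(-0.278, rel=1e-8)
        assert model.penalty == 0.0 and model.method == "model3_ols"

    def test_constant_outcome(self):
        summaries, scores = make_tables([10, 40, 70, 20], [5, 30, 10, 50], [63.0] * 4)
        model = fit_ols(summaries, scores)
        assert model.coef_green == pytest.approx(0.0, abs=1e-10)
        assert model.coef_red == pytest.approx(0.0, abs=1e-10)
        assert model.constant == pytest.approx(63.0)

    def test_saturated_fit_has_zero_residuals(self):
        summaries, scores = make_tables([10, 50, 30], [20, 10, 60], [55.0, 70.0, 40.0])
        model = fit_ols(summaries, scores)
        pred = model.predict(summaries["pct_green"], summaries["pct_red"])
        assert np.allclose(pred, scores["total"], atol=1e-9)

    def test_rank_deficient_design_rejected(self):
        summaries, scores = make_tables([30, 30, 30, 30], [10, 20, 30, 40], [60, 61, 62, 63])
        with pytest.raises(SingularDesignError):
            fit_ols(summaries, scores)


class TestRidge:
    def test_single_predictor_closed_form(self):
        """Centered x=(-1,0,1), y=(-2,0,2), lambda=2: slope x'y/(x'x+lambda)
        = 4/(2+2) = 1 on the sample-SD-standardized scale."""
        X = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([-2.0, 0.0, 2.0])
        _, beta = _ridge_beta(X, y, 2.0)
        assert beta[0] == pytest.approx(1.0)
        _, beta0 = _ridge_beta(X, y, 0.0)
        assert beta0[0] == pytest.approx(2.0)

    def test_lambda_zero_equals_ols(self, noiseless_data):
        ridge = fit_ridge(*noiseless_data, penalty=0.0)
        ols = fit_ols(*noiseless_data)
        assert ridge.coef_green == pytest.approx(ols.coef_green, abs=1e-10)
        assert ridge.coef_red == pytest.approx(ols.coef_red, abs=1e-10)
        assert ridge.constant == pytest.approx(ols.constant, abs=1e-10)

    def test_large_lambda_shrinks_to_mean(self, noiseless_data):
        summaries, scores = noiseless_data
        model = fit_ridge(summaries, scores, penalty=1e12)
        assert model.coef_green == pytest.approx(0.0, abs=1e-6)
        assert model.coef_red == pytest.approx(0.0, abs=1e-6)
        assert model.constant == pytest.approx(scores["total"].mean(), abs=1e-4)

    def test_negative_lambda_rejected(self, noiseless_data):
        with pytest.raises(ValidationError):
            fit_ridge(*noiseless_data, penalty=-1.0)

    def test_coefficient_norm_nonincreasing_in_lambda(self, rng):
        g = rng.uniform(10, 90, 200)
        r = np.minimum(rng.uniform(0, 60, 200), 100 - g)
        hei = 56.72 + 0.27 * g - 0.278 * r + rng.normal(0, 9, 200)
        summaries, scores = make_tables(g, r, hei)
        norms = []
        for lam in DEFAULT_LAMBDA_GRID:
            m = fit_ridge(summaries, scores, penalty=lam)
            norms.append(np.hypot(m.coef_green, m.coef_red))
        assert np.all(np.diff(norms) <= 1e-12)

    def test_matches_sklearn_ridge(self, rng):
        """Independent oracle: scikit-learn Ridge on the standardized design."""
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        g = rng.uniform(10, 90, 150)
        r = np.minimum(rng.uniform(0, 60, 150), 100 - g)
        hei = 56.72 + 0.27 * g - 0.278 * r + rng.normal(0, 9, 150)
        summaries, scores = make_tables(g, r, hei)
        X = summaries[["pct_green", "pct_red"]].to_numpy()
        sd = X.std(axis=0, ddof=1)
        Z = (X - X.mean(axis=0)) / sd
        for lam in (0.5, 10.0, 500.0):
            ours = fit_ridge(summaries, scores, penalty=lam)
            ref = sklearn_linear.Ridge(alpha=lam, fit_intercept=True).fit(Z, hei)
            assert ours.coef_green == pytest.approx(ref.coef_[0] / sd[0], rel=1e-8)
            assert ours.coef_red == pytest.approx(ref.coef_[1] / sd[1], rel=1e-8)


class TestPenaltySelection:
    def test_ic_noiseless_selects_smallest_lambda(self, noiseless_data):
        model = select_penalty_ic(*noiseless_data)
        assert model.penalty == pytest.approx(min(DEFAULT_LAMBDA_GRID))
        assert model.method == "model1_ridge_ic"

    def test_ic_singleton_grid_zero_is_ols(self, noiseless_data):
        model = select_penalty_ic(*noiseless_data, lambda_grid=[0.0])
        ols = fit_ols(*noiseless_data)
        assert model.coef_green == pytest.approx(ols.coef_green, abs=1e-10)
        assert model.penalty == 0.0

    def test_effective_df_matches_eigenvalue_formula(self, rng):
        """df(lambda) = sum d_i^2/(d_i^2 + lambda) + 1, via explicit hat trace."""
        X = rng.uniform(0, 100, size=(60, 2))
        sd = X.std(axis=0, ddof=1)
        Z = (X - X.mean(axis=0)) / sd
        for lam in (0.0, 1.0, 37.5, 4000.0):
            hat = Z @ np.linalg.solve(Z.T @ Z + lam * np.eye(2), Z.T)
            assert effective_df(X, lam) == pytest.approx(np.trace(hat) + 1.0, abs=1e-10)
        assert effective_df(X, 0.0) == pytest.approx(3.0)
        dfs = [effective_df(X, lam) for lam in DEFAULT_LAMBDA_GRID]
        assert np.all(np.diff(dfs) < 0)

    def test_cv_noiseless_selects_near_minimum_and_is_deterministic(self, noiseless_data):
        m1 = select_penalty_cv(*noiseless_data, folds=10, seed=42)
        m2 = select_penalty_cv(*noiseless_data, folds=10, seed=42)
        assert m1.penalty == m2.penalty
        # held-out MSE at the chosen lambda is essentially zero
        assert min(m1.diagnostics["cv_mse"]) < 1e-6
        assert m1.penalty <= DEFAULT_LAMBDA_GRID[5]

    def test_cv_leave_one_out_runs(self, rng):
        g = rng.uniform(10, 90, 12)
        r = np.minimum(rng.uniform(0, 60, 12), 100 - g)
        hei = 56.72 + 0.27 * g - 0.278 * r + rng.normal(0, 5, 12)
        summaries, scores = make_tables(g, r, hei)
        model = select_penalty_cv(summaries, scores, folds=12, seed=0)
        assert np.all(np.isfinite(model.diagnostics["cv_mse"]))


class TestIndexTransform:
    def test_published_model1_values_reproduce_printed_formula(self):
        model = FittedLinearModel("model1_ridge_ic", 0.185, -0.217, 59.23, 1.0)
        f = to_index_formula(model)
        assert round(f.coef_green_3v, 4) == 0.7773
        assert round(f.coef_yellow_3v, 4) == 0.5923
        assert round(f.coef_red_3v, 4) == 0.3753
        assert round(f.offset, 2) == 37.53
        assert round(f.scale, 2) == 40.20

    def test_hand_arithmetic_case(self):
        f = to_index_formula(FittedLinearModel("model3_ols", 1.0, -1.0, 0.0, 0.0))
        assert f.weights() == (1.0, 0.0, -1.0)
        assert f.offset == -100.0 and f.scale == 200.0

    def test_degenerate_weights_rejected(self):
        with pytest.raises(DegenerateFormulaError):
            to_index_formula(FittedLinearModel("model3_ols", 0.0, 0.0, 60.0, 0.0))

    @settings(max_examples=100, deadline=None)
    @given(
        const=st.floats(10, 90),
        bg=st.floats(0.01, 1.0),
        br=st.floats(-1.0, -0.01),
        g=st.floats(0, 100),
        frac=st.floats(0, 1),
    )
    def test_transform_identity(self, const, bg, br, g, frac):
        """The index is the exact affine rescaling of predicted HEI."""
        model = FittedLinearModel("model3_ols", bg, br, const, 0.0)
        f = to_index_formula(model)
        r = (100 - g) * frac
        y = 100 - g - r
        pred = const + bg * g + br * r
        lo = 100 * min(f.weights())
        hi = 100 * max(f.weights())
        expected = (pred - lo) / (hi - lo) * 100
        got = cfni_score(f, {"pct_green": g, "pct_yellow": y, "pct_red": r})
        assert got == pytest.approx(expected, abs=1e-10)
        assert -1e-9 <= got <= 100 + 1e-9


class TestCfniScore:
    @pytest.fixture
    def published(self):
        return IndexFormula(0.7773, 0.5923, 0.3753, 37.53, 40.20)

    @pytest.mark.parametrize(
        "comp,expected",
        [((100, 0, 0), 100.0), ((0, 0, 100), 0.0), ((50, 26, 24), 64.03)],
    )
    def test_published_anchor_scores(self, published, comp, expected):
        g, y, r = comp
        score = cfni_score(published, {"pct_green": g, "pct_yellow": y, "pct_red": r})
        assert score == pytest.approx(expected, abs=0.005)

    def test_off_simplex_rejected(self, published):
        with pytest.raises(ValidationError):
            cfni_score(published, {"pct_green": 50, "pct_yellow": 10, "pct_red": 10})

    def test_linearity_in_mixtures(self, published, rng):
        """The score of a weight-weighted mixture equals the weighted mean
        of the component scores."""
        g = rng.uniform(0, 100, 20)
        r = (100 - g) * rng.uniform(0, 1, 20)
        y = 100 - g - r
        w = rng.uniform(0.1, 5, 20)
        w /= w.sum()
        mix = {"pct_green": w @ g, "pct_yellow": w @ y, "pct_red": w @ r}
        singles = [
            cfni_score(published, {"pct_green": gi, "pct_yellow": yi, "pct_red": ri})
            for gi, yi, ri in zip(g, y, r)
        ]
        assert cfni_score(published, mix) == pytest.approx(w @ singles, abs=1e-9)

    def test_rank_agreement_with_predicted_hei(self, rng):
        """Rescaling is order-preserving: index ranks carts like predicted HEI."""
        model = FittedLinearModel("model3_ols", 0.270, -0.278, 56.72, 0.0)
        f = to_index_formula(model)
        g = rng.uniform(0, 100, 100)
        r = (100 - g) * rng.uniform(0, 1, 100)
        df = pd.DataFrame({"pct_green": g, "pct_yellow": 100 - g - r, "pct_red": r})
        idx = cfni_scores(f, df)
        pred = model.predict(g, r)
        assert np.array_equal(np.argsort(idx), np.argsort(pred))
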