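"""The maximum-entropy model: fitting, prediction, importance, curves.

The fitting oracle is an independent nested grid search over the
coefficients, refined by zooming; on tiny discrete problems the convex
optimizer must agree with it to high precision.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from maxsdm.model import MaxEnt, MaxEntResults, sample_background


def brute_force_fit(F_p, F_b, lam, span=20.0, steps=41, rounds=7):
    """Nested grid search over beta for the penalized objective.

    Independent of the package optimizer: evaluates the objective on a
    coarse grid and zooms around the best point until the grid spacing is
    tiny; the convex objective makes the zoom safe.
    """
    m = F_p.shape[1]
    fbar = F_p.mean(axis=0)

    def obj(beta):
        return (-fbar @ beta + logsumexp(F_b @ beta)
                + np.abs(lam * beta).sum())

    center = np.zeros(m)
    width = span
    best = center.copy()
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, steps) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        betas = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.array([obj(b) for b in betas])
        best = betas[vals.argmin()]
        center = best
        width = 3.0 * width / (steps - 1)  # keep 1.5 grid steps of slack
    return best, obj(best)


class TestSampleBackground:
    def test_all_cells_once(self, stack2):
        n_valid = int((~stack2.mask).sum())
        bg = sample_background(stack2, n_valid, seed=0)
        assert len(bg) == n_valid
        row, col = stack2.grid.cell_of(bg["x"].to_numpy(),
                                       bg["y"].to_numpy())
        assert len(set(zip(row, col))) == n_valid

    def test_too_many_rejected(self, stack2):
        with pytest.raises(ValueError, match="background"):
            sample_background(stack2, 10**7, seed=0)

    def test_deterministic(self, stack2):
        a = sample_background(stack2, 100, seed=5)
        b = sample_background(stack2, 100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_background_mean_near_landscape_mean(self, stack2):
        # CLT: the background mean of each layer sits within 3 standard
        # errors of the landscape mean
        bg = sample_background(stack2, 5000, seed=1)
        for name in stack2.continuous:
            vals = stack2[name].values
            vals = vals[np.isfinite(vals)]
            se = vals.std() / np.sqrt(len(bg))
            assert abs(bg[name].mean() - vals.mean()) < 3 * se


class TestFit:
    def test_no_signal_coefficients_shrink(self):
        # presences identical to the background distribution: the zero
        # vector satisfies the optimality condition exactly (the penalty
        # dominates a zero mean-feature gap), so every coefficient is 0
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 2000),
                           "b": rng.uniform(0, 1, 2000)})
        res = MaxEnt(bg, bg, classes="LQ", reg_mult=1.0).fit()
        assert np.all(res.beta == 0.0)

    def test_no_signal_subsample_stays_near_uniform(self):
        # presences subsampled from the background: sampling noise in the
        # feature means exceeds the default penalty, so coefficients need
        # not vanish — but the fitted distribution stays near uniform
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 2000),
                           "b": rng.uniform(0, 1, 2000)})
        pres = bg.sample(300, random_state=3)
        res = MaxEnt(pres, bg, classes="LQ", reg_mult=1.0).fit()
        raw = res.predict(bg, mode="raw")
        assert raw.max() / raw.min() < 1.5

    def test_oracle_binary_feature(self):
        # 4-cell background, one binary feature, presences only where the
        # feature is 1: the fit must match the brute-force maximizer
        bg = pd.DataFrame({"f": [0.0, 0.0, 1.0, 1.0]})
        pres = pd.DataFrame({"f": [1.0] * 8})
        model = MaxEnt(pres, bg, classes="L", reg_mult=0.01)
        res = model.fit()
        F_p = res.features.transform(model.presence)
        F_b = res.features.transform(model.background)
        beta_star, obj_star = brute_force_fit(F_p, F_b, res.lam)
        assert abs(res.objective - obj_star) < 1e-6
        raw_fit = res.predict(bg, mode="raw")
        eta = F_b @ beta_star
        raw_star = np.exp(eta - logsumexp(eta))
        np.testing.assert_allclose(raw_fit, raw_star, atol=1e-3)

    def test_oracle_two_features_six_cells(self):
        rng = np.random.default_rng(4)
        bg = pd.DataFrame({"u": rng.uniform(0, 1, 6),
                           "v": rng.uniform(0, 1, 6)})
        pres = bg.iloc[[0, 1, 1, 2]].reset_index(drop=True)
        model = MaxEnt(pres, bg, classes="L", reg_mult=0.5)
        res = model.fit()
        F_p = res.features.transform(model.presence)
        F_b = res.features.transform(model.background)
        _, obj_star = brute_force_fit(F_p, F_b, res.lam)
        assert res.objective <= obj_star + 1e-6

    def test_huge_penalty_gives_uniform_raw(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 50)})
        pres = bg.iloc[:10]
        res = MaxEnt(pres, bg, classes="LQ", reg_mult=1e4).fit()
        assert np.all(res.beta == 0.0)
        np.testing.assert_allclose(res.predict(bg, mode="raw"), 1 / 50,
                                   atol=1e-12)

    def test_shrinkage_monotone_in_multiplier(self):
        rng = np.random.default_rng(6)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 500)})
        pres = pd.DataFrame({"a": rng.beta(5, 2, 100)})
        norms = []
        for mult in [0.5, 1.0, 2.0, 4.0]:
            res = MaxEnt(pres, bg, classes="LQ", reg_mult=mult).fit()
            norms.append(np.abs(res.beta).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_reg_mult_must_be_positive(self):
        bg = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError):
            MaxEnt(bg, bg, reg_mult=0.0)


@pytest.fixture(scope="module")
def fitted(stack2, presences2):
    model = MaxEnt.from_stack(stack2, presences2, n_background=3000,
                              seed=7, classes="LQ")
    return model.fit()


class TestPredict:
    def test_zero_model_uniform_cloglog(self):
        # all beta = 0 over N cells: raw = 1/N, H = ln N, and the cloglog
        # output equals 1 - 1/e everywhere
        rng = np.random.default_rng(8)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 64)})
        res = MaxEnt(bg.iloc[:5], bg, classes="L", reg_mult=1e4).fit()
        np.testing.assert_allclose(res.entropy, np.log(64))
        np.testing.assert_allclose(res.predict(bg, mode="cloglog"),
                                   1 - np.exp(-1), atol=1e-12)

    def test_raw_sums_to_one_over_background(self, fitted):
        raw = fitted.predict(fitted.model.background, mode="raw")
        assert abs(raw.sum() - 1.0) < 1e-9

    def test_cloglog_monotone_in_raw(self, fitted):
        bg = fitted.model.background
        raw = fitted.predict(bg, mode="raw")
        clog = fitted.predict(bg, mode="cloglog")
        order = np.argsort(raw)
        assert np.all(np.diff(clog[order]) >= 0)
        assert clog.min() > 0.0 and clog.max() < 1.0

    def test_predict_stack_shape_and_mask(self, fitted, stack2):
        out = fitted.predict_stack(stack2, mode="cloglog")
        assert out.shape == stack2.grid.shape
        assert not out.mask.any()

    def test_missing_variable_rejected(self, fitted):
        with pytest.raises(KeyError):
            fitted.predict(pd.DataFrame({"nope": [1.0]}))

    def test_serialization_roundtrip(self, fitted, stack2, tmp_path):
        path = tmp_path / "model.json"
        fitted.to_json(path)
        back = MaxEntResults.from_json(path)
        table, _, _ = stack2.table()
        np.testing.assert_allclose(back.predict(table, mode="cloglog"),
                                   fitted.predict(table, mode="cloglog"))


class TestInterpretation:
    def test_single_variable_importance_is_100(self):
        rng = np.random.default_rng(9)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 800)})
        pres = pd.DataFrame({"a": rng.beta(6, 2, 150)})
        res = MaxEnt(pres, bg, classes="LQ").fit()
        imp = res.variable_importance(n_permutations=2, seed=0)
        assert imp["percent_contribution"].iloc[0] == pytest.approx(100)
        assert imp["permutation_importance"].iloc[0] == pytest.approx(100)

    def test_signal_variable_beats_noise(self):
        rng = np.random.default_rng(10)
        bg = pd.DataFrame({"signal": rng.uniform(0, 1, 2000),
                           "noise": rng.uniform(0, 1, 2000)})
        pres = pd.DataFrame({"signal": rng.beta(8, 2, 300),
                             "noise": rng.uniform(0, 1, 300)})
        res = MaxEnt(pres, bg, classes="LQ").fit()
        imp = res.variable_importance(n_permutations=3, seed=1) \
            .set_index("variable")
        assert (imp.loc["signal", "permutation_importance"]
                > imp.loc["noise", "permutation_importance"])

    def test_linear_model_monotone_curve(self):
        rng = np.random.default_rng(11)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 800)})
        pres = pd.DataFrame({"a": rng.beta(8, 1.5, 200)})
        res = MaxEnt(pres, bg, classes="L", reg_mult=0.5).fit()
        assert res.params.iloc[0] > 0
        curve = res.response_curve("a", n_steps=50)
        assert np.all(np.diff(curve["cloglog"]) > 0)

    def test_lq_curve_peaks_at_vertex(self):
        # with features L + Q and beta_Q < 0, the response curve peaks at
        # the scaled vertex -beta_L / (2 beta_Q)
        rng = np.random.default_rng(12)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 3000)})
        pres = pd.DataFrame({"a": np.clip(rng.normal(0.55, 0.1, 600),
                                          0, 1)})
        res = MaxEnt(pres, bg, classes="LQ", reg_mult=0.5).fit()
        bl = res.params["L(a)"]
        bq = res.params["Q(a)"]
        assert bq < 0
        vertex = np.clip(-bl / (2 * bq), 0, 1)
        curve = res.response_curve("a", n_steps=401)
        lo, hi = res.features.scales["a"]
        peak_scaled = ((curve.loc[curve["cloglog"].idxmax(), "value"] - lo)
                       / (hi - lo))
        assert abs(peak_scaled - vertex) < 0.01

    def test_importance_needs_permutations(self, stack2, presences2):
        res = MaxEnt.from_stack(stack2, presences2, n_background=500,
                                seed=0).fit()
        with pytest.raises(ValueError):
            res.variable_importance(n_permutations=0)

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(13)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 100)})
        res = MaxEnt(bg.iloc[:20], bg, classes="L").fit()
        text = res.summary()
        assert "entropy" in text and "reg. multiplier" in text
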