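"""Block CV, AUC, AICc and the Continuous Boyce Index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maxsdm.evaluate import (
    UndefinedCBIError,
    aicc_score,
    assign_blocks,
    auc_score,
    boyce_index,
    tune_and_select,
)
from maxsdm.model import MaxEnt


class TestAssignBlocks:
    def test_four_tight_clusters(self):
        centers = [(0, 0), (10, 0), (0, 10), (10, 10)]
        rng = np.random.default_rng(0)
        px, py = [], []
        for cx, cy in centers:
            px += list(cx + rng.normal(0, 0.1, 10))
            py += list(cy + rng.normal(0, 0.1, 10))
        fa = assign_blocks((np.array(px), np.array(py)),
                           (np.array(px), np.array(py)), k=4)
        blocks = fa.presence_block.reshape(4, 10)
        assert all(len(set(b)) == 1 for b in blocks)
        assert len({b[0] for b in blocks}) == 4

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        pxy = (rng.uniform(0, 100, 101), rng.uniform(0, 100, 101))
        bxy = (rng.uniform(0, 100, 500), rng.uniform(0, 100, 500))
        fa = assign_blocks(pxy, bxy, k=4)
        assert fa.presence_block.size == 101
        assert fa.background_block.size == 500
        assert set(fa.presence_block) <= {1, 2, 3, 4}

    def test_median_split_balance(self):
        # odd count: the median split leaves side counts within 1 per axis
        rng = np.random.default_rng(2)
        px = rng.uniform(0, 100, 101)
        py = rng.uniform(0, 100, 101)
        fa = assign_blocks((px, py), (px, py), k=4)
        left = np.isin(fa.presence_block, [1, 3]).sum()
        right = np.isin(fa.presence_block, [2, 4]).sum()
        assert abs(left - right) <= 1

    def test_empty_block_rejected(self):
        # all presences in one tight cluster: quadrant split on identical
        # coordinates leaves blocks empty
        px = np.full(20, 5.0)
        py = np.full(20, 5.0)
        with pytest.raises(ValueError, match="smaller k"):
            assign_blocks((px, py), (px, py), k=4)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_enumerated_pairs(self):
        # presences {0.9, 0.4}, background {0.5, 0.1}:
        # (0.9>0.5) + (0.9>0.1) + (0.4<0.5 -> 0) + (0.4>0.1) = 3/4
        assert auc_score([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_identical_distributions(self):
        v = np.linspace(0, 1, 50)
        assert auc_score(v, v) == 0.5

    def test_ties_count_half(self):
        assert auc_score([0.5], [0.5]) == 0.5

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=2, max_size=30),
           st.lists(st.integers(0, 100), min_size=2, max_size=30))
    def test_invariant_under_monotone_transform(self, p, b):
        p = np.asarray(p) / 100.0
        b = np.asarray(b) / 100.0
        base = auc_score(p, b)
        trans = auc_score(np.exp(3 * p), np.exp(3 * b))
        assert base == pytest.approx(trans)


class TestAICc:
    @staticmethod
    def uniform_results(n_cells=10, n_pres=5):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, n_cells)})
        pres = pd.DataFrame({"a": rng.uniform(0, 1, n_pres)})
        return MaxEnt(pres, bg, classes="L", reg_mult=1e4).fit()

    def test_uniform_closed_form(self):
        # uniform raw over 10 cells, 5 presences, k = 0:
        # AICc = -2 * 5 * ln(0.1) ~ 23.026
        res = self.uniform_results()
        aicc = aicc_score(res)
        assert aicc == pytest.approx(-2 * 5 * np.log(0.1), abs=1e-9)

    def test_zero_coefficients_do_not_count(self):
        res = self.uniform_results()
        assert res.n_params == 0

    def test_blowup_when_k_too_large(self):
        rng = np.random.default_rng(4)
        bg = pd.DataFrame({
            "a": rng.uniform(0, 1, 200), "b": rng.uniform(0, 1, 200),
            "c": rng.uniform(0, 1, 200)})
        pres = pd.DataFrame({
            "a": rng.beta(5, 1, 4), "b": rng.beta(1, 5, 4),
            "c": rng.beta(5, 1, 4)})
        res = MaxEnt(pres, bg, classes="LQ", reg_mult=0.05).fit()
        if res.n_params >= len(pres) - 1:
            assert aicc_score(res) == np.inf

    def test_decomposition_reproducible(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 300)})
        pres = pd.DataFrame({"a": rng.beta(4, 2, 50)})
        res = MaxEnt(pres, bg, classes="LQ").fit()
        raw = res.predict(res.model.presence, mode="raw")
        k = res.n_params
        n = len(res.model.presence)
        lnL = np.log(raw).sum()
        expected = 2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1)
        assert aicc_score(res) == pytest.approx(expected)


@pytest.fixture(scope="module")
def reference(truth2):
    suit = truth2.suitability
    return suit.values[~suit.mask].ravel()


class TestBoyceIndex:
    def test_calibrated_predictions_near_one(self, truth2, reference):
        from maxsdm.synth import sample_presences

        occ = sample_presences(truth2, 1000, seed=21, jitter=False)
        suit = truth2.suitability
        row, col = suit.cell_of(*occ.xy)
        pred_p = suit.values[row, col]
        assert boyce_index(pred_p, reference) >= 0.95

    def test_inverted_predictions_near_minus_one(self, truth2, reference):
        from maxsdm.synth import sample_presences

        occ = sample_presences(truth2, 1000, seed=21, jitter=False)
        suit = truth2.suitability
        row, col = suit.cell_of(*occ.xy)
        assert boyce_index(1 - suit.values[row, col],
                           1 - reference) <= -0.95

    def test_uninformative_predictions_near_zero(self, reference):
        # presences placed uniformly at random, scored by the landscape
        # suitability: the mean CBI over replicates is near zero
        vals = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            idx = rng.integers(0, reference.size, 1000)
            vals.append(boyce_index(reference[idx], reference))
        assert abs(np.mean(vals)) < 0.3

    def test_sign_flip_on_rank_reversal(self, truth2, reference):
        from maxsdm.synth import sample_presences

        occ = sample_presences(truth2, 500, seed=22, jitter=False)
        suit = truth2.suitability
        row, col = suit.cell_of(*occ.xy)
        pred_p = suit.values[row, col]
        fwd = boyce_index(pred_p, reference)
        rev = boyce_index(1 - pred_p, 1 - reference)
        assert fwd == pytest.approx(-rev)

    def test_constant_reference_undefined(self):
        with pytest.raises(UndefinedCBIError):
            boyce_index([0.5, 0.6], np.full(100, 0.5))


@pytest.fixture(scope="module")
def data(stack2, presences2):
    from maxsdm.model import sample_background
    from maxsdm.occ import dedup_to_grid

    occ = dedup_to_grid(presences2, stack2.grid)
    x, y = occ.xy
    pres = stack2.extract(x, y).dropna()
    bg = sample_background(stack2, 800, seed=30)
    return pres, bg, (x, y), (bg["x"].to_numpy(), bg["y"].to_numpy())


class TestTuneAndSelect:
    def test_single_candidate_selected(self, data):
        pres, bg, pxy, bxy = data
        table, selected = tune_and_select(
            pres, bg, pxy, bxy, classes_grid=["LQ"], mult_grid=[1.0],
            categorical=["soil"], n_knots=4)
        assert len(table) == 1
        assert selected["classes"] == "LQ"
        assert selected["reg_mult"] == 1.0

    def test_table_columns_and_ranking(self, data):
        pres, bg, pxy, bxy = data
        table, selected = tune_and_select(
            pres, bg, pxy, bxy, classes_grid=["L", "LQ"],
            mult_grid=[1.0, 2.0], categorical=["soil"], n_knots=4)
        assert len(table) == 4
        assert table["aicc"].is_monotonic_increasing
        assert {"auc_diff", "cbi", "aicc_rank"} <= set(table.columns)
        # the selected candidate minimizes auc_diff in the table
        assert selected["auc_diff"] == pytest.approx(table["auc_diff"].min())
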