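"""LSTM cell/forward/gradients, training sanity, GBT importance and reduced subset."""

import numpy as np
import pytest

from preictal.dataset import class_weights
from preictal.evaluate import roc_auc
from preictal.features import feature_dim
from preictal.models import (
    GbtConfig,
    ImportanceReport,
    LstmConfig,
    LstmParams,
    aggregate_importance,
    flatten_samples,
    gbt_predict,
    init_lstm_params,
    lstm_forward,
    lstm_loss_and_grads,
    lstm_param_count,
    lstm_step,
    predict_proba,
    select_reduced_features,
    train_gbt,
    train_lstm,
)
from preictal.synth import simulate_feature_timeline

import pandas as pd


def zero_params(F, C):
    return LstmParams(
        Wx=np.zeros((F, 4 * C)),
        Wh=np.zeros((C, 4 * C)),
        b=np.zeros(4 * C),
        D=np.zeros((C, 2)),
        d=np.zeros(2),
    )


class TestParamCount:
    @pytest.mark.parametrize("F,C,expected", [(96, 3, 1208), (960, 3, 11576), (0, 1, 12)])
    def test_formula(self, F, C, expected):
        assert lstm_param_count(F, C) == expected

    @pytest.mark.parametrize("F,C", [(5, 3), (96, 3), (960, 3), (17, 2)])
    def test_enumerated_parameters_match_formula(self, F, C):
        p = init_lstm_params(F, C, seed=0)
        assert p.n_params == lstm_param_count(F, C)

    def test_gate_views_have_printed_shapes(self):
        p = init_lstm_params(7, 3)
        for g in ("f", "i", "o", "c"):
            assert p.W(g).shape == (3, 7)
            assert p.U(g).shape == (3, 3)
            assert p.b_gate(g).shape == (3,)


class TestStep:
    def test_zero_params_zero_state_stay_zero(self):
        p = zero_params(4, 3)
        h, c = lstm_step(np.ones(4), np.zeros(3), np.zeros(3), p)
        assert np.allclose(h, 0.0) and np.allclose(c, 0.0)

    def test_zero_params_halve_previous_cell_state(self):
        # forget gate sigma(0)=0.5, candidate tanh(0)=0 -> c = 0.5 * c_prev
        p = zero_params(4, 3)
        h, c = lstm_step(np.zeros(4), np.zeros(3), np.ones(3), p)
        assert np.allclose(c, 0.5)

    def test_dimension_mismatch_rejected(self):
        p = zero_params(4, 3)
        with pytest.raises(ValueError):
            lstm_step(np.ones(5), np.zeros(3), np.zeros(3), p)

    def test_matches_handwritten_scalar_recurrence(self, rng):
        """Vectorized cell vs an independent elementwise loop, to 1e-12."""
        F, C, T = 5, 3, 4
        p = init_lstm_params(F, C, seed=7)
        X = rng.standard_normal((T, F))

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        h = np.zeros(C)
        c = np.zeros(C)
        for t in range(T):
            f = np.array([sig(p.W("f")[k] @ X[t] + p.U("f")[k] @ h + p.b_gate("f")[k]) for k in range(C)])
            i = np.array([sig(p.W("i")[k] @ X[t] + p.U("i")[k] @ h + p.b_gate("i")[k]) for k in range(C)])
            o = np.array([sig(p.W("o")[k] @ X[t] + p.U("o")[k] @ h + p.b_gate("o")[k]) for k in range(C)])
            g = np.array([np.tanh(p.W("c")[k] @ X[t] + p.U("c")[k] @ h + p.b_gate("c")[k]) for k in range(C)])
            c = f * c + i * g
            h = o * np.tanh(c)
        hv, cv = np.zeros(C), np.zeros(C)
        for t in range(T):
            hv, cv = lstm_step(X[t], hv, cv, p)
        assert np.allclose(hv, h, atol=1e-12)
        assert np.allclose(cv, c, atol=1e-12)

    def test_gate_bound_invariants(self, rng):
        """|h| <= 1 entrywise; |c_t| <= t from zero initial state."""
        p = init_lstm_params(4, 3, seed=3)
        h, c = np.zeros(3), np.zeros(3)
        for t in range(1, 20):
            h, c = lstm_step(rng.standard_normal(4) * 5, h, c, p)
            assert np.all(np.abs(h) <= 1.0)
            assert np.all(np.abs(c) <= t + 1e-12)


class TestForward:
    def test_zero_params_give_coin_flip(self, rng):
        p = zero_params(6, 3)
        probs = lstm_forward(p, rng.standard_normal((5, 4, 6)))
        assert np.allclose(probs, 0.5)

    def test_probabilities_normalized(self, rng):
        p = init_lstm_params(6, 3, seed=1)
        probs = lstm_forward(p, rng.standard_normal((8, 10, 6)))
        assert np.all((probs > 0) & (probs < 1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_state_reset_between_samples(self, rng):
        """Each history is scored from a zero state: duplicates score identically."""
        p = init_lstm_params(6, 3, seed=2)
        x = rng.standard_normal((1, 5, 6))
        probs = lstm_forward(p, np.concatenate([x, x]))
        assert np.allclose(probs[0], probs[1], atol=1e-15)


class TestGradients:
    def test_bptt_matches_finite_differences(self, rng):
        F, C, T, B = 4, 3, 3, 2
        p = init_lstm_params(F, C, seed=5)
        X = rng.standard_normal((B, T, F))
        y = np.array([0, 1])
        w = np.array([1.0, 3.0])
        loss, grads = lstm_loss_and_grads(p, X, y, w)
        eps = 1e-6
        for name, arr in p.arrays().items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp, _ = lstm_loss_and_grads(p, X, y, w)
                arr[ix] = orig - eps
                lm, _ = lstm_loss_and_grads(p, X, y, w)
                arr[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestTraining:
    def make_data(self, effect, n=400, seed=0):
        tl = simulate_feature_timeline(n, 6, effect, seed=seed, interictal_block=60, preictal_block=30)
        from preictal.dataset import make_samples

        s = make_samples(tl, 5, "train")
        return s.tensor(tl), s.label.astype(int)

    def test_separable_data_learned(self):
        X, y = self.make_data(3.0)
        cfg = LstmConfig(epochs=25, seed=0)
        p, losses = train_lstm(X, y, class_weights(y), cfg)
        assert losses[-1] < losses[0]
        assert roc_auc(predict_proba(p, X), y) > 0.95

    def test_fixed_seed_reproducible(self):
        X, y = self.make_data(1.0, n=200)
        cfg = LstmConfig(epochs=5, seed=3)
        _, l1 = train_lstm(X, y, None, cfg)
        _, l2 = train_lstm(X, y, None, cfg)
        assert l1 == l2

    def test_higher_preictal_weight_does_not_reduce_recall(self):
        X, y = self.make_data(1.0, n=600, seed=4)
        recalls = []
        for wp in (1.0, 4.0, 16.0):
            p, _ = train_lstm(X, y, {0: 1.0, 1: wp}, LstmConfig(epochs=15, seed=1))
            scores = predict_proba(p, X)
            recalls.append(float((scores[y == 1] > 0.5).mean()))
        assert recalls[0] <= recalls[1] + 0.05 and recalls[1] <= recalls[2] + 0.05

    def test_bad_labels_rejected(self):
        X = np.zeros((4, 3, 2))
        with pytest.raises(ValueError):
            train_lstm(X, np.array([0, 1, 2, 1]))


class TestGbt:
    def test_planted_feature_carries_top_importance(self, rng):
        n, F = 600, 51
        X = rng.standard_normal((n, F))
        y = (rng.uniform(size=n) < 0.3).astype(int)
        X[y == 1, 7] += 3.0
        names = [f"cnt|c{i}" for i in range(F)]
        _, rep = train_gbt(X, y, names, GbtConfig(rounds=40))
        imp = rep.table.set_index("feature")["importance"]
        assert imp.idxmax() == "cnt|c7"
        assert imp.sum() == pytest.approx(1.0)

    def test_null_importance_not_concentrated(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((300, 20))
            y = (r.uniform(size=300) < 0.3).astype(int)
            _, rep = train_gbt(X, y, [f"cnt|c{i}" for i in range(20)], GbtConfig(rounds=20, seed=seed))
            hits += rep.table["importance"].max() > 3.0 / 20
        assert hits <= 1  # >=90% of seeds stay near-uniform

    def test_predictions_learn_separable_data(self, rng):
        X = rng.standard_normal((400, 5))
        y = (X[:, 0] > 0).astype(int)
        names = [f"cnt|c{i}" for i in range(5)]
        booster, _ = train_gbt(X, y, names, GbtConfig(rounds=30))
        assert roc_auc(gbt_predict(booster, X, names), y) > 0.99

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_gbt(rng.standard_normal((10, 2)), np.zeros(10, dtype=int), ["cnt|c0", "cnt|c1"])

    def test_flatten_samples_names_windows(self):
        X = np.arange(24.0).reshape(2, 3, 4)
        Xf, names = flatten_samples(X, ["a", "b", "c", "d"])
        assert Xf.shape == (2, 12)
        assert names[0] == "a@t0" and names[-1] == "d@t2"
        assert np.array_equal(Xf[0, :4], X[0, 0])


class TestImportanceAggregation:
    def make_report(self, weights):
        table = pd.DataFrame(
            {
                "feature": list(weights),
                "base_feature": list(weights),
                "importance": np.array(list(weights.values()), dtype=float),
            }
        )
        return ImportanceReport(table)

    def test_single_band_takes_all(self):
        rep = self.make_report({"pow|b3|c0": 0.7, "pow|b3|c1": 0.3})
        agg = aggregate_importance(rep, "band")
        assert agg[3] == pytest.approx(1.0)
        assert agg.sum() == pytest.approx(1.0)

    def test_uniform_over_bands(self):
        rep = self.make_report({f"pow|b{b}|c0": 0.1 for b in range(10)})
        agg = aggregate_importance(rep, "band")
        assert np.allclose(agg.values, 0.1)

    def test_site_map_ranked_to_unit_max(self):
        rep = self.make_report({"cnt|c5": 0.8, "cnt|c2": 0.2})
        from preictal.preprocess import default_channel_grid

        grid = aggregate_importance(rep, "site", default_channel_grid(16, 4))
        assert grid.max() == 1.0
        assert grid[5 // 4, 5 % 4] == 1.0
        assert grid[2 // 4, 2 % 4] == pytest.approx(0.25)

    def test_group_aggregate_normalized(self):
        rep = self.make_report({"cnt|c0": 0.5, "pow|b1|c0": 1.5})
        agg = aggregate_importance(rep, "group")
        assert agg["mua_count"] == pytest.approx(0.25)
        assert agg.sum() == pytest.approx(1.0)


class TestReducedSubset:
    def full_columns(self, ch):
        from preictal.features import (
            _names_lfp_coherence,
            _names_lfp_power,
            _names_mua_correlation,
            _names_mua_count,
        )

        return (
            _names_lfp_power(ch)
            + _names_lfp_coherence(ch)
            + _names_mua_count(ch)
            + _names_mua_correlation(ch)
        )

    def test_dimension_is_six_times_channels(self):
        for ch in (16, 96):
            sel = select_reduced_features(self.full_columns(ch))
            assert len(sel) == 6 * ch

    def test_subset_of_full_and_band_restriction(self):
        cols = self.full_columns(8)
        sel = select_reduced_features(cols)
        assert set(sel) <= set(cols)
        from preictal.features import parse_feature_name

        for c in sel:
            t = parse_feature_name(c)
            if t["band"] is not None:
                assert t["band"] in {0, 6, 7, 9}

    def test_missing_group_rejected(self):
        from preictal.features import _names_lfp_power

        with pytest.raises(ValueError):
            select_reduced_features(_names_lfp_power(4))
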