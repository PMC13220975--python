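"""State-decoding tests: block shuffle, bagged trees, ROC pooling,
asymptotic fits and the control analyses."""

import numpy as np
import pandas as pd
import pytest

import motistate as ms
from motistate import config as cfg
from motistate import features as feat
from motistate import labeling
from motistate import prediction as P


def mann_whitney_auc(scores, labels):
    """Pairwise-comparison oracle: P(score+ > score-) with tie credit."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBlockShuffle:
    def test_single_block_identity(self):
        df = pd.DataFrame({"a": range(10)})
        out = P.block_shuffle(df, block=25, rng=0)
        assert (out["a"] == df["a"]).all()

    def test_block_one_full_permutation(self):
        idx = P.block_shuffle_indices(200, 1, rng=3)
        assert sorted(idx) == list(range(200))
        assert (idx != np.arange(200)).any()

    def test_adjacency_preserved_within_blocks(self):
        n, block = 100, 25
        idx = P.block_shuffle_indices(n, block, rng=5)
        assert sorted(idx) == list(range(n))
        # within-block successors stay adjacent in the output
        pos = np.argsort(idx)
        for i in range(n - 1):
            if i % block != block - 1:
                assert pos[i + 1] == pos[i] + 1

    def test_invalid_block(self):
        with pytest.raises(ValueError):
            P.block_shuffle_indices(10, 0, rng=0)


class TestTrainPredict:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(0)
        y = np.array(["persistent", "disengaged", "attentive"],
                     dtype=object)[rng.integers(0, 3, 600)]
        X = pd.DataFrame({v: rng.normal(size=600)
                          for v in cfg.NONPERFORMANCE_VARS})
        code = pd.Series(y).map({"persistent": 0, "disengaged": 1,
                                 "attentive": 2}).to_numpy(float)
        X["prestim_lick_rate"] = code      # perfectly informative feature
        return X, y

    def test_perfect_feature_auc_one(self, toy):
        X, y = toy
        run = P.train_predict(X, y, ["prestim_lick_rate"], seed=1)
        for state in cfg.STATES:
            assert P.pooled_roc([run], y, state).auc > 0.999

    def test_each_trial_scored_once(self, toy):
        X, y = toy
        run = P.train_predict(X, y, seed=2)
        assert len(run.scores) == len(y)
        assert np.allclose(run.scores.sum(axis=1), 1.0)

    def test_determinism(self, toy):
        X, y = toy
        r1 = P.train_predict(X, y, seed=9)
        r2 = P.train_predict(X, y, seed=9)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)

    def test_permuted_labels_chance_auc(self, toy):
        X, y = toy
        yp = np.random.default_rng(7).permutation(y)
        runs = [P.train_predict(X, yp, seed=s) for s in range(5)]
        for state in cfg.STATES:
            assert abs(P.pooled_roc(runs, yp, state).auc - 0.5) < 0.05

    def test_empty_pool_error(self, toy):
        X, y = toy
        with pytest.raises(ValueError):
            P.train_predict(X, y, [], seed=0)


class TestPooledRoc:
    def test_perfect_scores(self):
        y = np.array(["attentive"] * 5 + ["persistent"] * 5, dtype=object)
        scores = pd.DataFrame({"attentive": [1.0] * 5 + [0.0] * 5,
                               "persistent": [0.0] * 5 + [1.0] * 5})
        run = P.PredictionRun(scores, y, ["x"], 0)
        assert P.pooled_roc([run], y, "attentive").auc == 1.0

    def test_mann_whitney_oracle_small_examples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 11)
            lab = rng.random(n) < 0.5
            if lab.all() or not lab.any():
                continue
            sc = np.round(rng.random(n), 1)     # provoke ties
            y = np.where(lab, "attentive", "persistent").astype(object)
            run = P.PredictionRun(
                pd.DataFrame({"attentive": sc, "persistent": 1 - sc}),
                y, ["x"], 0)
            roc = P.pooled_roc([run], y, "attentive")
            assert np.isclose(roc.auc, mann_whitney_auc(sc, lab))

    def test_chance_level_uniform_scores(self):
        rng = np.random.default_rng(1)
        y = np.where(rng.random(20000) < 0.5, "attentive",
                     "persistent").astype(object)
        sc = rng.random(20000)
        run = P.PredictionRun(
            pd.DataFrame({"attentive": sc, "persistent": 1 - sc}),
            y, ["x"], 0)
        assert abs(P.pooled_roc([run], y, "attentive").auc - 0.5) < 0.02

    def test_no_positives_flagged(self):
        y = np.array(["persistent"] * 10, dtype=object)
        run = P.PredictionRun(
            pd.DataFrame({"persistent": np.ones(10)}), y, ["x"], 0)
        roc = P.pooled_roc([run], y, "attentive")
        assert roc.flagged and np.isnan(roc.auc)


class TestAsymptoticFit:
    def test_noiseless_recovery(self):
        x = np.arange(1, 9, dtype=float)
        y = 0.9 - 0.4 * np.exp(-0.8 * x)
        fit = P.fit_asymptotic(x, y)
        assert abs(fit.a - 0.9) < 1e-6
        assert abs(fit.b - 0.4) < 1e-6
        assert abs(fit.k - 0.8) < 1e-6
        assert fit.r_squared > 1 - 1e-9

    def test_constant_curve_flagged(self):
        fit = P.fit_asymptotic(np.arange(1, 9), np.full(8, 0.7))
        assert fit.flagged and fit.p_k is None

    def test_noisy_k_recovery(self):
        """k recovered within 20% of truth at sigma = 0.01 noise."""
        rng = np.random.default_rng(0)
        x = np.arange(1, 9, dtype=float)
        ks = []
        for _ in range(25):
            y = 0.9 - 0.4 * np.exp(-0.8 * x) + rng.normal(0, 0.01, 8)
            ks.append(P.fit_asymptotic(x, y).k)
        assert abs(np.median(ks) - 0.8) < 0.2 * 0.8

    def test_strong_trend_small_p(self):
        x = np.arange(1, 9, dtype=float)
        y = 0.9 - 0.4 * np.exp(-0.8 * x)
        fit = P.fit_asymptotic(x, y + np.random.default_rng(1).normal(
            0, 0.005, 8))
        assert fit.p_k < 0.01


class TestSingleVariableRank:
    def test_planted_coupling_ranks_first(self):
        """When only prestimulus licking couples to state, it wins."""
        c = ms.MouseConfig(mouse_id="m", n_sessions=3,
                           trials_per_session=300, seed=4)
        for var, coup in c.feature_coupling.items():
            if var != "prestim_lick_rate":
                coup.means = {s: 1.0 for s in coup.means}
                coup.drift = {}
        tl = ms.gen_state_timeline(c)
        tr = ms.gen_trials(tl, c)
        table = ms.gen_feature_table(tl, tr, c, rng=1)
        table["mouse"] = "m"
        sm = feat.smooth_per_session(table, list(cfg.NONPERFORMANCE_VARS))
        y = table["latent_state"].to_numpy()
        rank = P.single_variable_rank(sm, y, n_iterations=3, seed=0)
        assert rank["variable"].iloc[0] == "prestim_lick_rate"

    def test_uninformative_features_flagged(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({v: rng.normal(size=400)
                          for v in cfg.NONPERFORMANCE_VARS})
        y = np.array(["persistent", "disengaged", "attentive"],
                     dtype=object)[rng.integers(0, 3, 400)]
        with pytest.warns(UserWarning, match="chance"):
            rank = P.single_variable_rank(X, y, n_iterations=2, seed=1)
        assert (rank["mean_auc"] < 0.6).all()


class TestControls:
    def test_row_shuffle_preserves_decodability(self, labeled_session_table):
        _, smoothed, labels = labeled_session_table
        y = labels.labels["state"].to_numpy()
        res = P.control_predictions("row_shuffle", smoothed, y, seed=0,
                                    n_iterations=3)
        assert (res["auc"] > 0.8).all()

    def test_unknown_mode_error(self):
        with pytest.raises(ValueError, match="unknown control mode"):
            P.control_predictions("bogus")

    def test_cross_mouse_needs_two_mice(self):
        with pytest.raises(ValueError, match=">= 2 mice"):
            P.cross_mouse_auc({"m1": (None, None)})

    def test_subset_modes_restrict_pools(self, labeled_session_table):
        _, smoothed, labels = labeled_session_table
        y = labels.labels["state"].to_numpy()
        res = P.control_predictions("subset_physio", smoothed, y, seed=0,
                                    n_iterations=2)
        assert res["pool_size"].max() == 4


class TestRegressionControls:
    def test_planted_signal_dominates(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({v: rng.normal(size=800)
                          for v in cfg.NONPERFORMANCE_VARS})
        resp = 2.0 * X["wheel_speed"].to_numpy() + rng.normal(0, 0.5, 800)
        y = np.array(["persistent"] * 800, dtype=object)
        res = P.regression_controls(X, y, "correctness", resp, seed=0)
        med = res.t_real.groupby("predictor")["t"].apply(
            lambda t: np.median(np.abs(t)))
        assert med.idxmax() == "wheel_speed"
        assert res.friedman_p < 0.01

    def test_shuffled_response_null_t(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({v: rng.normal(size=800)
                          for v in cfg.NONPERFORMANCE_VARS})
        resp = rng.normal(size=800)
        y = np.array(["persistent"] * 800, dtype=object)
        res = P.regression_controls(X, y, "correctness", resp, seed=1)
        med = res.t_shuffled.groupby("predictor")["t"].median()
        assert (med.abs() < 2.0).all()

    def test_mnr_detects_state_coupling(self, labeled_session_table):
        _, smoothed, labels = labeled_session_table
        y = labels.labels["state"].to_numpy()
        sub = smoothed.iloc[::4].reset_index(drop=True)
        res = P.regression_controls(sub, y[::4], "states", seed=0)
        assert set(res.friedman["scope"]) == set(cfg.STATES)
        assert (res.friedman["p"] < 0.01).any()
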