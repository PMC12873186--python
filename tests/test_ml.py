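"""Multivariable stage: pruning, LOSO random forest, Shapley importance."""

import numpy as np
import pandas as pd
import pytest

from autonomics import ml_analysis as ml
from autonomics._treeshap import forest_shap


def _toy_table(n_subjects=20, effect=2.0, n_noise=3, seed=0, feature0="f0"):
    """REST/MIST rows with one informative feature and noise features."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for phase, shift in (("REST", 0.0), ("MIST", effect)):
            row = {"subject": f"s{i}", "group": "STRESS" if i % 2 else "CONTROL",
                   "phase": phase, feature0: rng.normal(shift, 1.0)}
            for k in range(n_noise):
                row[f"noise{k}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestPruneFeatures:
    def test_identical_columns_one_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        df = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.normal(size=40)})
        kept = ml.prune_features(df, ["A", "B", "C"])
        assert kept in (["A", "C"], ["B", "C"])
        assert len(kept) == 2

    def test_uncorrelated_panel_untouched(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("ABCD"))
        assert ml.prune_features(df, list("ABCD")) == list("ABCD")

    def test_greedy_chain_drops_middle(self):
        # a three-column chain where B is highly correlated with both A and
        # C while A-C stays below threshold: B has the highest mean
        # absolute correlation and is dropped first.  (Note r(A,B) = 0.9,
        # r(B,C) = 0.9 with r(A,C) = 0.1 is not a valid correlation matrix;
        # 0.85/0.85/0.45 is the same chain at feasible values.)
        target = np.array([[1.0, 0.85, 0.45], [0.85, 1.0, 0.85],
                           [0.45, 0.85, 1.0]])
        L = np.linalg.cholesky(target)
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4000, 3)) @ L.T
        df = pd.DataFrame(data, columns=["A", "B", "C"])
        corr = df.corr().abs()
        assert corr.loc["A", "B"] > 0.75 and corr.loc["B", "C"] > 0.75
        assert corr.loc["A", "C"] < 0.75
        assert ml.prune_features(df, ["A", "B", "C"]) == ["A", "C"]


class TestLosoRF:
    def test_separable_toy_perfect_accuracy(self):
        table = _toy_table(n_subjects=16, effect=8.0)
        acc = ml.loso_rf(table, "MIST", seed=0,
                         features=("f0", "noise0", "noise1", "noise2"))
        assert acc == 1.0

    def test_deterministic_under_fixed_seed(self):
        table = _toy_table(n_subjects=12, effect=0.8, seed=3)
        feats = ("f0", "noise0", "noise1", "noise2")
        a1 = ml.loso_rf(table, "MIST", seed=7, features=feats)
        a2 = ml.loso_rf(table, "MIST", seed=7, features=feats)
        assert a1 == a2

    def test_label_permutation_near_chance(self):
        rng = np.random.default_rng(0)
        table = _toy_table(n_subjects=20, effect=0.0, seed=4)
        feats = ("f0", "noise0", "noise1", "noise2")
        accs = [ml.loso_rf(table, "MIST", seed=s, features=feats)
                for s in range(10)]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.08)

    def test_subject_missing_a_phase_excluded(self):
        table = _toy_table(n_subjects=10, effect=5.0)
        table = table.drop(table[(table.subject == "s0")
                                 & (table.phase == "MIST")].index)
        X, y, groups = ml._contrast_frame(table, "MIST", ("f0", "noise0"))
        assert "s0" not in set(groups)
        assert np.unique(groups).size == 9

    def test_leakage_guard(self):
        # duplicating the held-out rows into training inflates null accuracy;
        # the LOSO splitter must not do that
        rng = np.random.default_rng(5)
        table = _toy_table(n_subjects=20, effect=0.0, seed=5)
        feats = ("f0", "noise0", "noise1", "noise2")
        X, y, groups = ml._contrast_frame(table, "MIST", feats)
        honest = ml.LosoForestClassifier(random_state=1).fit(X, y, groups).accuracy_

        from sklearn.ensemble import RandomForestClassifier
        leaky_preds = np.empty(y.size, dtype=int)
        for g in np.unique(groups):
            test = groups == g
            rf = RandomForestClassifier(n_estimators=100, random_state=1)
            rf.fit(X, y)  # deliberately trained on everything
            leaky_preds[test] = rf.predict(X[test])
        leaky = np.mean(leaky_preds == y)
        assert leaky > 0.9  # memorization
        assert honest < 0.75  # the honest splitter stays near chance


class TestRepeatAndSummarize:
    def test_separable_toy_zero_sd(self):
        table = _toy_table(n_subjects=12, effect=8.0)
        res = ml.repeat_and_summarize(table, "MIST", n_repeats=5,
                                      features=("f0", "noise0", "noise1"))
        assert res.accuracy_mean == 1.0
        assert res.accuracy_sd == 0.0

    def test_single_repeat_sd_missing(self):
        table = _toy_table(n_subjects=10, effect=2.0)
        res = ml.repeat_and_summarize(table, "MIST", n_repeats=1,
                                      features=("f0", "noise0"))
        assert np.isnan(res.accuracy_sd)

    def test_reproducible_under_master_seed(self):
        table = _toy_table(n_subjects=10, effect=0.8, seed=6)
        feats = ("f0", "noise0", "noise1")
        r1 = ml.repeat_and_summarize(table, "MIST", n_repeats=3, master_seed=9,
                                     features=feats)
        r2 = ml.repeat_and_summarize(table, "MIST", n_repeats=3, master_seed=9,
                                     features=feats)
        assert r1.accuracy_mean == r2.accuracy_mean
        assert r1.importance_mean == r2.importance_mean


class TestShapImportance:
    def test_local_accuracy_of_attributions(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + 0.5 * X[:, 3] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        phi, base = forest_shap(rf, X[:15])
        pred = rf.predict_proba(X[:15])[:, 1]
        assert np.max(np.abs(phi.sum(1) + base - pred)) < 1e-6

    def test_informative_feature_ranks_first(self):
        top = 0
        for seed in range(10):
            table = _toy_table(n_subjects=14, effect=2.0, seed=seed)
            imp = ml.shap_importance(table, "MIST", seed=seed,
                                     features=("f0", "noise0", "noise1", "noise2"))
            top += max(imp, key=imp.get) == "f0"
        assert top >= 9

    def test_all_noise_importances_comparable(self):
        table = _toy_table(n_subjects=20, effect=0.0, seed=8)
        imps = []
        for seed in range(8):
            imp = ml.shap_importance(table, "MIST", seed=seed,
                                     features=("f0", "noise0", "noise1", "noise2"))
            imps.append([imp[k] for k in ("f0", "noise0", "noise1", "noise2")])
        means = np.mean(imps, axis=0)
        # no feature dominates: spread within a factor ~2 of the mean level
        assert means.max() / means.min() < 2.0

    def test_equal_additive_signals_comparable_importance(self):
        # two features carrying the same additive effect receive comparable
        # mean importance once the finite-sample draw variability is
        # averaged over cohort realizations
        g1s, g2s = [], []
        for data_seed in range(4):
            rng = np.random.default_rng(100 + data_seed)
            rows = []
            for i in range(30):
                for phase, shift in (("REST", 0.0), ("MIST", 1.5)):
                    rows.append({"subject": f"s{i}", "group": "STRESS",
                                 "phase": phase,
                                 "g1": rng.normal(shift, 1.0),
                                 "g2": rng.normal(shift, 1.0),
                                 "noise": rng.normal()})
            table = pd.DataFrame(rows)
            imp = ml.shap_importance(table, "MIST", seed=data_seed,
                                     features=("g1", "g2", "noise"))
            g1s.append(imp["g1"])
            g2s.append(imp["g2"])
        assert 0.5 < np.mean(g1s) / np.mean(g2s) < 2.0
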