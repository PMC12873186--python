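"""Multivariable stage: correlation pruning, z-scoring, binary Random
Forest models with leave-one-subject-out cross-validation, repetition over
seeds, and Shapley feature-importance ranking.

Three binary contrasts are evaluated (REST vs MIST, REST vs MGT,
REST vs VS).  Each model is a 100-tree random forest; accuracy is the
fraction of correctly classified held-out rows pooled over subjects, and
importance is the mean absolute Shapley attribution of the held-out
predictions, averaged across folds and repeats.

Features are z-scored on the training fold and the scaler applied to the
held-out subject (global pre-CV scaling is available via
``scaling="global"`` for strict protocol fidelity; fold-wise scaling
avoids train/test leakage and is the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from ._treeshap import forest_shap

__all__ = [
    "DEFAULT_FEATURES", "CONTRASTS", "MLResult",
    "prune_features", "LosoForestClassifier", "loso_rf",
    "repeat_and_summarize", "shap_importance",
]

#: default candidate panel (the indices retained by the univariate stage)
DEFAULT_FEATURES = ("nSCR", "AmpSum", "meanRR", "meanBB", "PCOH",
                    "PNCOH_PCOH", "SamEn", "SD1_SD2")

CONTRASTS = ("MIST", "MGT", "VS")  # each versus REST


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------

def prune_features(table, features=None, threshold=0.75):
    """Greedy removal of highly correlated features.

    While any pair exceeds ``|Pearson r| > threshold``, the member of the
    worst pair with the higher mean absolute correlation to all remaining
    features is dropped (ties keep the earlier column).  Returns the
    retained feature names in their original order.
    """
    feats = list(features if features is not None else
                 [c for c in table.columns if c not in ("subject", "group", "phase")])
    data = table[feats].astype(float)
    keep = [f for f in feats if data[f].notna().sum() >= 3 and data[f].std() > 0]
    while True:
        if len(keep) < 2:
            break
        corr = data[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_i = corr[i].mean()
        mean_j = corr[j].mean()
        drop = keep[i] if mean_i > mean_j else keep[j] if mean_j > mean_i else keep[max(i, j)]
        keep.remove(drop)
    return keep


# ---------------------------------------------------------------------------
# LOSO random forest
# ---------------------------------------------------------------------------

def _contrast_frame(table, contrast, features):
    """Rows of REST and the task phase, one label per row (task = 1)."""
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    sub = table[table["phase"].isin(["REST", contrast])].copy()
    sub = sub.dropna(subset=list(features))
    # keep only subjects contributing both phases
    counts = sub.groupby("subject")["phase"].nunique()
    complete = counts[counts == 2].index
    sub = sub[sub["subject"].isin(complete)]
    if sub.empty:
        raise ValueError(f"no complete subjects for contrast REST vs {contrast}")
    y = (sub["phase"] == contrast).astype(int).to_numpy()
    X = sub[list(features)].to_numpy(dtype=float)
    groups = sub["subject"].to_numpy()
    return X, y, groups


class LosoForestClassifier(BaseEstimator):
    """Random-forest evaluator under leave-one-subject-out CV.

    Parameters
    ----------
    n_estimators : trees per forest (100 by default).
    scaling : "fold" (z-score fit on the training subjects) or "global"
        (z-score the full table before CV).
    random_state : forest seed.
    compute_shap : attach exact Shapley attributions of the held-out
        predictions.

    Attributes (after :meth:`fit`)
    ------------------------------
    accuracy_ : pooled held-out accuracy
    shap_values_ : (n_rows, n_features) attributions (if requested)
    base_values_, y_true_, y_pred_, groups_
    """

    def __init__(self, n_estimators=100, scaling="fold", random_state=None,
                 compute_shap=False):
        self.n_estimators = n_estimators
        self.scaling = scaling
        self.random_state = random_state
        self.compute_shap = compute_shap

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = np.asarray(groups)
        if self.scaling not in ("fold", "global"):
            raise ValueError("scaling must be 'fold' or 'global'")
        if self.scaling == "global":
            X = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        preds = np.empty(y.size, dtype=int)
        shap_vals = np.zeros_like(X) if self.compute_shap else None
        base_vals = np.zeros(y.size) if self.compute_shap else None
        for g in np.unique(groups):
            test = groups == g
            train = ~test
            Xtr, Xte = X[train], X[test]
            if self.scaling == "fold":
                mu, sd = Xtr.mean(0), Xtr.std(0)
                sd = np.where(sd > 0, sd, 1.0)
                Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
            rf = RandomForestClassifier(n_estimators=self.n_estimators,
                                        random_state=self.random_state)
            rf.fit(Xtr, y[train])
            preds[test] = rf.predict(Xte)
            if self.compute_shap:
                phi, base = forest_shap(rf, Xte)
                shap_vals[test] = phi
                base_vals[test] = base
        self.accuracy_ = float(np.mean(preds == y))
        self.y_true_, self.y_pred_, self.groups_ = y, preds, groups
        self.shap_values_ = shap_vals
        self.base_values_ = base_vals
        return self


def loso_rf(table, contrast, seed=None, features=DEFAULT_FEATURES,
            n_estimators=100, scaling="fold"):
    """Pooled LOSO accuracy of one binary contrast (thin wrapper)."""
    X, y, groups = _contrast_frame(table, contrast, features)
    est = LosoForestClassifier(n_estimators=n_estimators, scaling=scaling,
                               random_state=seed).fit(X, y, groups)
    return est.accuracy_


# ---------------------------------------------------------------------------
# repetition and summary
# ---------------------------------------------------------------------------

@dataclass
class MLResult:
    contrast: str
    features: tuple
    n_subjects: int
    n_repeats: int
    accuracy_mean: float
    accuracy_sd: float  # NaN for a single repeat
    importance_mean: dict = field(default_factory=dict)  # feature -> mean |SHAP|
    importance_sd: dict = field(default_factory=dict)
    ranking: tuple = ()  # features in descending mean importance


def _repeat_seeds(master_seed, n_repeats):
    """Documented master-seed derivation: the first ``n_repeats`` states of
    ``numpy.random.SeedSequence(master_seed)``, right-shifted below 2^31."""
    return [int(s) for s in
            (np.random.SeedSequence(master_seed).generate_state(n_repeats) >> 1)]


def repeat_and_summarize(table, contrast, n_repeats=100, master_seed=0,
                         features=DEFAULT_FEATURES, n_estimators=100,
                         scaling="fold", shap_repeats=None):
    """Repeat the LOSO evaluation over derived seeds and summarize.

    Shapley attributions are aggregated over ``shap_repeats`` repeats (all
    by default); accuracy over all repeats.
    """
    X, y, groups = _contrast_frame(table, contrast, features)
    seeds = _repeat_seeds(master_seed, n_repeats)
    n_shap = n_repeats if shap_repeats is None else min(shap_repeats, n_repeats)
    accs, imps = [], []
    for k, s in enumerate(seeds):
        est = LosoForestClassifier(n_estimators=n_estimators, scaling=scaling,
                                   random_state=s,
                                   compute_shap=(k < n_shap)).fit(X, y, groups)
        accs.append(est.accuracy_)
        if est.shap_values_ is not None:
            imps.append(np.abs(est.shap_values_).mean(axis=0))
    accs = np.asarray(accs)
    imps = np.asarray(imps)
    imp_mean = dict(zip(features, imps.mean(0))) if imps.size else {}
    imp_sd = dict(zip(features, imps.std(0, ddof=1) if len(imps) > 1
                      else np.full(len(features), np.nan))) if imps.size else {}
    ranking = tuple(sorted(imp_mean, key=imp_mean.get, reverse=True)) if imp_mean else ()
    return MLResult(
        contrast=contrast, features=tuple(features),
        n_subjects=int(np.unique(groups).size), n_repeats=n_repeats,
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)) if n_repeats > 1 else float("nan"),
        importance_mean={k: float(v) for k, v in imp_mean.items()},
        importance_sd={k: float(v) for k, v in imp_sd.items()},
        ranking=ranking,
    )


def shap_importance(table, contrast, features=DEFAULT_FEATURES, seed=0,
                    n_estimators=100, scaling="fold"):
    """Mean absolute held-out Shapley importance of a single LOSO run."""
    X, y, groups = _contrast_frame(table, contrast, features)
    est = LosoForestClassifier(n_estimators=n_estimators, scaling=scaling,
                               random_state=seed, compute_shap=True).fit(X, y, groups)
    imp = np.abs(est.shap_values_).mean(axis=0)
    return dict(zip(features, (float(v) for v in imp)))
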