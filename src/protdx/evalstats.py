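"""Classification metrics, model-comparison statistics, cross-validation and
leave-one-site-out orchestration, and the two-model probability ensemble.

Balanced classification accuracy (BCA, mean of sensitivity and specificity)
is the primary metric because the six conditions are heavily imbalanced; the
rank-based AUC is reported alongside.  Models fitted on overlapping resampled
splits are compared with the variance-corrected resampled t-test
t = mean(d) / sqrt((1/k + n_test/n_train) * var(d)), df = k - 1.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohortio import CONDITIONS, Cohort, SplitPlan
from .featselect import FeaturePanel, select_features
from .preprocess import ZScoreTransform
from . import jointnet
from .jointnet import JointModelSpec, TrainedJointModel, select_thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "balanced_accuracy",
    "auc",
    "corrected_resampled_ttest",
    "bh_fdr",
    "ensemble_search",
    "ensemble_apply",
    "run_cross_validation",
    "CVResult",
    "FoldResult",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(calls: np.ndarray, labels: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 over observed labels."""
    calls = np.asarray(calls, dtype=float)
    labels = np.asarray(labels, dtype=float)
    obs = ~np.isnan(labels)
    calls, labels = calls[obs], labels[obs]
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("balanced accuracy needs both classes among observed labels")
    sens = float((calls[pos] == 1).mean())
    spec = float((calls[neg] == 0).mean())
    return (sens + spec) / 2.0


def auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties receive half credit."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    obs = ~np.isnan(labels)
    p, y = probabilities[obs], labels[obs]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes among observed labels")
    r = stats.rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def corrected_resampled_ttest(
    diffs: np.ndarray, test_train_ratio: float
) -> TTestResult:
    """Variance-corrected resampled t-test on per-split score differences.

    ``test_train_ratio`` is n_test / n_train of the resampling scheme (1/9 for
    a 9-1-1 ten-fold design, counting the validation fold on the training
    side).  All-zero differences give t = 0, p = 1; nonzero constant
    differences are flagged degenerate with p = 0.
    """
    d = np.asarray(diffs, dtype=float)
    k = len(d)
    if k < 2:
        raise ValueError("need >= 2 splits for the corrected resampled t-test")
    if test_train_ratio < 0:
        raise ValueError("test_train_ratio must be >= 0")
    mean = d.mean()
    var = d.var(ddof=1)
    df = k - 1
    if var == 0:
        if mean == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(np.inf if mean > 0 else -np.inf, df, 0.0, degenerate=True)
    t = mean / np.sqrt((1.0 / k + test_train_ratio) * var)
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def ensemble_apply(w: float, probs_a: np.ndarray, probs_b: np.ndarray) -> np.ndarray:
    return w * np.asarray(probs_a, dtype=float) + (1 - w) * np.asarray(probs_b, dtype=float)


def ensemble_search(
    val_probs_a: np.ndarray,
    val_probs_b: np.ndarray,
    val_labels: np.ndarray,
    step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-condition grid search over mixture weights w in {0, step, ..., 1}
    maximizing validation BCA of w*p_A + (1-w)*p_B at a re-selected F1
    threshold (ties -> smallest w).

    Returns (weights, thresholds), one per condition.  Because the grid
    contains both endpoints, the selected mixture's validation BCA can never
    fall below either component's.
    """
    a = np.asarray(val_probs_a, dtype=float)
    b = np.asarray(val_probs_b, dtype=float)
    y = np.asarray(val_labels, dtype=float)
    n_cond = a.shape[1]
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    weights = np.zeros(n_cond)
    thresholds = np.full(n_cond, 0.5)
    for c in range(n_cond):
        obs = ~np.isnan(y[:, c])
        yc = y[obs, c]
        if len(np.unique(yc)) < 2:
            warnings.warn(f"condition {c}: single-class validation labels; w = 0",
                          stacklevel=2)
            continue
        best_bca, best_w, best_t = -1.0, 0.0, 0.5
        for w in grid:
            mix = ensemble_apply(w, a[obs, c], b[obs, c])
            t = select_thresholds(mix[:, None], yc[:, None])[0]
            bca = balanced_accuracy((mix >= t).astype(float), yc)
            if bca > best_bca:  # strict: ties keep the smallest w
                best_bca, best_w, best_t = bca, w, t
        weights[c], thresholds[c] = best_w, best_t
    return weights, thresholds


# ---------------------------------------------------------------------------
# XGBoost per-condition baseline (ensemble partner)
# ---------------------------------------------------------------------------

_XGB_PARAMS = {
    "objective": "binary:logistic",
    "tree_method": "hist",
    "max_depth": 4,
    "eta": 0.1,
    "subsample": 0.8,
    "max_bin": 63,
    "nthread": 1,
    "verbosity": 0,
}


def fit_xgb_baselines(
    cohort: Cohort,
    panel: list[str],
    train_ids: pd.Index,
    val_ids: pd.Index,
    seed: int = 0,
    n_rounds: int = 150,
) -> tuple[list[xgb.Booster | None], ZScoreTransform, np.ndarray]:
    """One boosted-tree classifier per condition on training-split z-scored
    panel proteins, with F1 thresholds from the validation split."""
    zs = ZScoreTransform.fit(cohort.abundance.loc[pd.Index(train_ids), panel])
    X_tr = zs.apply(cohort.abundance.loc[pd.Index(train_ids), panel]).to_numpy()
    X_va = zs.apply(cohort.abundance.loc[pd.Index(val_ids), panel]).to_numpy()
    y_tr = cohort.labels.loc[pd.Index(train_ids)].to_numpy(dtype=float)
    y_va = cohort.labels.loc[pd.Index(val_ids)].to_numpy(dtype=float)
    boosters: list[xgb.Booster | None] = []
    thresholds = np.full(len(CONDITIONS), 0.5)
    val_probs = np.full((len(val_ids), len(CONDITIONS)), 0.5)
    for c in range(len(CONDITIONS)):
        m = ~np.isnan(y_tr[:, c])
        if len(np.unique(y_tr[m, c])) < 2:
            boosters.append(None)
            continue
        dtrain = xgb.QuantileDMatrix(X_tr[m], label=y_tr[m, c],
                                     max_bin=_XGB_PARAMS["max_bin"])
        bst = xgb.train(dict(_XGB_PARAMS, seed=seed + c), dtrain,
                        num_boost_round=n_rounds)
        boosters.append(bst)
        val_probs[:, c] = bst.predict(xgb.DMatrix(X_va))
    thresholds = select_thresholds(val_probs, y_va)
    return boosters, zs, thresholds


def xgb_predict(
    boosters: list[xgb.Booster | None],
    zs: ZScoreTransform,
    cohort: Cohort,
    panel: list[str],
    ids: pd.Index,
) -> np.ndarray:
    X = zs.apply(cohort.abundance.loc[pd.Index(ids), panel]).to_numpy()
    out = np.full((len(ids), len(CONDITIONS)), 0.5)
    dm = xgb.DMatrix(X)
    for c, bst in enumerate(boosters):
        if bst is not None:
            out[:, c] = bst.predict(dm)
    return out


# ---------------------------------------------------------------------------
# Cross-validation orchestration
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Everything downstream interpretation needs from one rotation."""

    fold: int
    panel: FeaturePanel
    model: TrainedJointModel
    test_ids: pd.Index
    val_ids: pd.Index
    X_test: np.ndarray              # preprocessed network input, test rows
    y_test: np.ndarray
    test_probs: np.ndarray
    test_calls: np.ndarray
    test_embeddings: np.ndarray
    val_probs: np.ndarray
    y_val: np.ndarray
    xgb_test_probs: np.ndarray | None = None
    xgb_val_probs: np.ndarray | None = None
    xgb_thresholds: np.ndarray | None = None
    ensemble_weights: np.ndarray | None = None
    ensemble_thresholds: np.ndarray | None = None


@dataclass
class CVResult:
    metrics: pd.DataFrame           # long format: fold, condition, model, metric, value
    folds: list[FoldResult] = field(default_factory=list)

    def median_metric(self, model: str, metric: str) -> pd.Series:
        m = self.metrics
        sel = m[(m["model"] == model) & (m["metric"] == metric)]
        return sel.groupby("condition")["value"].median()


def panel_hash(panel: FeaturePanel) -> str:
    return hashlib.sha256("|".join(panel.proteins).encode()).hexdigest()


def _fold_metrics(
    rows: list[dict], fold: int, model: str,
    probs: np.ndarray, calls: np.ndarray, y: np.ndarray,
) -> None:
    for c, cond in enumerate(CONDITIONS):
        m = ~np.isnan(y[:, c])
        if len(np.unique(y[m, c])) < 2:
            warnings.warn(
                f"fold {fold}, condition {cond}: single-class test labels; "
                "metrics reported missing",
                stacklevel=2,
            )
            continue
        rows.append({"fold": fold, "condition": cond, "model": model,
                     "metric": "bca",
                     "value": balanced_accuracy(calls[m, c], y[m, c])})
        rows.append({"fold": fold, "condition": cond, "model": model,
                     "metric": "auc", "value": auc(probs[m, c], y[m, c])})


def run_cross_validation(
    cohort: Cohort,
    plan: SplitPlan,
    spec: JointModelSpec | None = None,
    seed: int = 0,
    include_xgboost: bool = True,
    include_ensemble: bool = True,
    featselect_kwargs: dict | None = None,
    keep_folds: bool = True,
) -> CVResult:
    """Full pipeline per rotation: fresh feature panel from train+validation,
    fresh preprocessing chain and network from the training split, test
    metrics on the held-out fold.  Test rows never enter panel selection or
    transform fitting."""
    spec = spec or JointModelSpec()
    fs_kwargs = featselect_kwargs or {}
    rows: list[dict] = []
    folds: list[FoldResult] = []
    for f, (train_ids, val_ids, test_ids) in enumerate(plan.folds):
        train_ids, val_ids, test_ids = (
            pd.Index(train_ids), pd.Index(val_ids), pd.Index(test_ids)
        )
        trainval = train_ids.append(val_ids)
        panel = select_features(
            cohort, trainval, seed=seed + 17 * f, split_id=str(f), **fs_kwargs
        )
        fold_spec = jointnet.JointModelSpec(**{**spec.__dict__, "seed": spec.seed + f})
        model = jointnet.train(fold_spec, cohort, panel, (train_ids, val_ids, test_ids))

        X_test = model.transform(cohort, test_ids).to_numpy()
        probs, emb = model.forward_probs(X_test)
        calls = (probs >= model.thresholds).astype(int)
        y_test = cohort.labels.loc[test_ids].to_numpy(dtype=float)
        _fold_metrics(rows, f, "joint", probs, calls, y_test)

        X_val = model.transform(cohort, val_ids).to_numpy()
        val_probs, _ = model.forward_probs(X_val)
        y_val = cohort.labels.loc[val_ids].to_numpy(dtype=float)

        fr = FoldResult(
            fold=f, panel=panel, model=model, test_ids=test_ids, val_ids=val_ids,
            X_test=X_test, y_test=y_test, test_probs=probs, test_calls=calls,
            test_embeddings=emb, val_probs=val_probs, y_val=y_val,
        )

        if include_xgboost:
            boosters, zs, xthr = fit_xgb_baselines(
                cohort, panel.proteins, train_ids, val_ids, seed=seed + f
            )
            x_test_probs = xgb_predict(boosters, zs, cohort, panel.proteins, test_ids)
            x_val_probs = xgb_predict(boosters, zs, cohort, panel.proteins, val_ids)
            _fold_metrics(rows, f, "xgboost", x_test_probs,
                          (x_test_probs >= xthr).astype(int), y_test)
            fr.xgb_test_probs, fr.xgb_val_probs, fr.xgb_thresholds = (
                x_test_probs, x_val_probs, xthr
            )
            if include_ensemble:
                w, ethr = ensemble_search(val_probs, x_val_probs, y_val)
                mix_test = w * probs + (1 - w) * x_test_probs
                _fold_metrics(rows, f, "ensemble", mix_test,
                              (mix_test >= ethr).astype(int), y_test)
                fr.ensemble_weights, fr.ensemble_thresholds = w, ethr

        if keep_folds:
            folds.append(fr)
        logger.info("fold %d done (panel size %d)", f, len(panel))
    return CVResult(pd.DataFrame(rows), folds)
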