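"""Two-stage feature selection: per-protein association models plus a
gradient-boosted-tree consensus, run on train+validation participants only.

Stage 1 fits, per protein and condition, ordinary least squares of natural-log
abundance on the condition indicator, age, sex and the participant's average
protein level (mean log abundance over all proteins).  The condition
coefficient is reported as a multiplicative fold change exp(beta); proteins
with fold change > 2 or < 0.5 survive the filter and the top 5 by
Benjamini-Hochberg-adjusted p value are kept per condition.

Stage 2 resplits train+validation into ten stratified subfolds, trains one
boosted-tree classifier per rotation (the held-out subfold tunes a small
depth/subsample grid on the first rotation) and keeps the proteins used for at
least one split by every rotation's model.

The union over the six conditions and both stages forms the split's feature
panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohortio import CONDITIONS, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "FeaturePanel",
    "glm_association",
    "select_by_association",
    "gbt_predictive_selection",
    "build_panel",
    "select_features",
]


@dataclass
class AssociationResult:
    """Per-protein association statistics for one condition."""

    condition: str
    table: pd.DataFrame  # index protein; columns beta, fold_change, p, p_adj


@dataclass
class FeaturePanel:
    """Ordered selected proteins with per-stage provenance."""

    proteins: list[str]
    provenance: pd.DataFrame  # index protein; columns association, predictive, conditions
    split_id: str | None = None

    def __len__(self) -> int:
        return len(self.proteins)


def _log_abundance(cohort: Cohort, ids: pd.Index) -> np.ndarray:
    """Natural-log abundance with per-protein mean fill of missing cells
    (computed within ``ids``); association models need a complete response."""
    x = np.log(cohort.abundance.loc[ids].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(x, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(x))
    x[nan_rows, nan_cols] = col_mean[nan_cols]
    return x


def glm_association(cohort: Cohort, condition: str, ids: pd.Index) -> AssociationResult:
    """OLS of log abundance on condition + age + sex + average protein level,
    for every protein at once, restricted to ``ids`` with an observed label."""
    ids = pd.Index(ids)
    y_lab = cohort.labels.loc[ids, condition]
    ids = ids[y_lab.notna()]
    y_lab = y_lab.loc[ids].to_numpy(dtype=float)
    if (y_lab == 1).sum() < 2 or (y_lab == 0).sum() < 2:
        raise ValueError(
            f"condition {condition!r} needs >= 2 positives and >= 2 negatives "
            "with observed labels"
        )

    logx = _log_abundance(cohort, ids)
    avg_level = logx.mean(axis=1)
    age = cohort.phenotypes.loc[ids, "age"].to_numpy(dtype=float)
    sex = cohort.phenotypes.loc[ids, "sex"].to_numpy(dtype=float)

    X = np.column_stack([np.ones(len(ids)), y_lab, age, sex, avg_level])
    names = ["intercept", "condition", "age", "sex", "avg_protein_level"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sds = X[:, 1:].std(axis=0)
        degenerate = [n for n, s in zip(names[1:], sds) if s == 0]
        raise ValueError(
            f"rank-deficient design for {condition!r}; collinear/constant "
            f"terms: {degenerate or names}"
        )

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ logx)               # 5 x p
    resid = logx - X @ beta
    dof = len(ids) - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(xtx_inv[1, 1] * sigma2)
    b = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "beta": b,
            "fold_change": np.exp(b),
            "p": p,
            "p_adj": p_adj,
        },
        index=cohort.proteins,
    )
    return AssociationResult(condition, table)


def select_by_association(
    assoc: AssociationResult,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    top_n: int = 5,
) -> list[str]:
    """Fold-change filter (> fc_hi or < fc_lo) then top ``top_n`` smallest
    adjusted p among survivors (all survivors when fewer)."""
    t = assoc.table
    survivors = t[(t["fold_change"] > fc_hi) | (t["fold_change"] < fc_lo)]
    if survivors.empty:
        return []
    return survivors.nsmallest(top_n, "p_adj").index.tolist()


# ---------------------------------------------------------------------------
# Predictive (boosted-tree consensus) stage
# ---------------------------------------------------------------------------

_GBT_GRID: tuple[dict, ...] = (
    {"max_depth": 3, "subsample": 0.8},
    {"max_depth": 4, "subsample": 1.0},
)

# Slow learning rate plus aggressive per-tree column subsampling keeps split
# gradients alive on easily separable (rare) conditions and spreads splits
# across the whole informative pool, which the all-rotations intersection
# rule needs to retain redundant markers.
_GBT_BASE = {
    "objective": "binary:logistic",
    "tree_method": "hist",
    "max_bin": 63,
    "eta": 0.1,
    "colsample_bytree": 0.1,
    "nthread": 1,
    "verbosity": 0,
}


def _stratified_subfolds(
    y: np.ndarray, n_subfolds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign indices to subfolds, separately shuffling positives and
    negatives so every subfold carries both classes whenever possible."""
    fold = np.empty(len(y), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % n_subfolds
    return fold


def gbt_predictive_selection(
    cohort: Cohort,
    condition: str,
    ids: pd.Index,
    n_subfolds: int = 10,
    seed: int = 0,
    n_rounds: int = 200,
    screen_top_n: int | None = 250,
    extra_params: dict | None = None,
) -> list[str]:
    """Boosted-tree consensus: a protein is kept iff every subfold-rotation
    model used it in at least one split.

    ``screen_top_n`` restricts the candidate proteins to the strongest by
    univariate association evidence before any tree is grown (None = all
    proteins); this is a computational device for single-CPU runs and leaves
    strongly informative proteins untouched.
    """
    rng = np.random.default_rng(seed)
    ids = pd.Index(ids)
    y_all = cohort.labels.loc[ids, condition]
    ids = ids[y_all.notna()]
    y = y_all.loc[ids].to_numpy(dtype=float)
    if (y == 1).sum() < n_subfolds:
        raise ValueError(
            f"condition {condition!r}: fewer positives than subfolds; "
            "stratified subfolding impossible"
        )

    proteins = cohort.proteins
    X = cohort.abundance.loc[ids].to_numpy(dtype=np.float32)
    if screen_top_n is not None and screen_top_n < len(proteins):
        # univariate two-sample t screen on log abundance (missing ignored)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lx = np.log(X.astype(float))
            m1 = np.nanmean(lx[y == 1], axis=0)
            m0 = np.nanmean(lx[y == 0], axis=0)
            v1 = np.nanvar(lx[y == 1], axis=0) / max((y == 1).sum(), 1)
            v0 = np.nanvar(lx[y == 0], axis=0) / max((y == 0).sum(), 1)
        score = np.abs(m1 - m0) / np.sqrt(v1 + v0 + 1e-12)
        score = np.where(np.isfinite(score), score, 0.0)
        keep = np.sort(np.argsort(-score)[:screen_top_n])
        proteins = proteins[keep]
        X = X[:, keep]

    fold = _stratified_subfolds(y, n_subfolds, rng)
    feat_names = list(proteins)

    def fit_model(train_mask: np.ndarray, params: dict) -> xgb.Booster:
        dtrain = xgb.QuantileDMatrix(
            X[train_mask], label=y[train_mask], max_bin=_GBT_BASE["max_bin"],
            feature_names=feat_names,
        )
        full = dict(_GBT_BASE, **(extra_params or {}), **params,
                    seed=int(rng.integers(2**31)))
        return xgb.train(full, dtrain, num_boost_round=n_rounds)

    # tune the small grid on the first rotation's held-out subfold
    val_mask0 = fold == 0
    best_params, best_ll = None, np.inf
    boosters: dict[int, xgb.Booster] = {}
    for params in _GBT_GRID:
        bst = fit_model(~val_mask0, params)
        dval = xgb.DMatrix(X[val_mask0], feature_names=feat_names)
        p = np.clip(bst.predict(dval), 1e-7, 1 - 1e-7)
        yv = y[val_mask0]
        ll = -np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p))
        if ll < best_ll:
            best_ll, best_params, boosters[0] = ll, params, bst

    selected: set[str] | None = None
    for r in range(n_subfolds):
        bst = boosters.get(r)
        if bst is None:
            val_mask = fold == r
            if y[~val_mask].sum() == 0 or y[~val_mask].sum() == (~val_mask).sum():
                raise ValueError(
                    f"degenerate single-class training set in subfold rotation {r}"
                )
            bst = fit_model(~val_mask, best_params)
        used = set(bst.get_score(importance_type="weight"))
        selected = used if selected is None else (selected & used)
        if not selected:
            break
    return [p for p in proteins if p in (selected or set())]


def build_panel(
    association_picks: dict[str, list[str]],
    predictive_picks: dict[str, list[str]],
    protein_order: pd.Index,
    split_id: str | None = None,
) -> FeaturePanel:
    """Union of both stages over all conditions, deduplicated, ordered by the
    cohort's protein order, with provenance flags."""
    rows: dict[str, dict] = {}
    for stage, picks in (("association", association_picks),
                         ("predictive", predictive_picks)):
        for cond, prots in picks.items():
            for p in prots:
                row = rows.setdefault(
                    p, {"association": False, "predictive": False, "conditions": set()}
                )
                row[stage] = True
                row["conditions"].add(cond)
    ordered = [p for p in protein_order if p in rows]
    prov = pd.DataFrame(
        {
            "association": [rows[p]["association"] for p in ordered],
            "predictive": [rows[p]["predictive"] for p in ordered],
            "conditions": [",".join(sorted(rows[p]["conditions"])) for p in ordered],
        },
        index=pd.Index(ordered, name="protein"),
    )
    return FeaturePanel(ordered, prov, split_id)


def select_features(
    cohort: Cohort,
    trainval_ids: pd.Index,
    seed: int = 0,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    top_n: int = 5,
    n_subfolds: int = 10,
    conditions: tuple[str, ...] = CONDITIONS,
    screen_top_n: int | None = 250,
    n_rounds: int = 200,
    split_id: str | None = None,
) -> FeaturePanel:
    """Run both stages for every condition and assemble the split's panel."""
    assoc_picks: dict[str, list[str]] = {}
    pred_picks: dict[str, list[str]] = {}
    for i, cond in enumerate(conditions):
        assoc = glm_association(cohort, cond, trainval_ids)
        assoc_picks[cond] = select_by_association(assoc, fc_hi, fc_lo, top_n)
        pred_picks[cond] = gbt_predictive_selection(
            cohort, cond, trainval_ids, n_subfolds=n_subfolds,
            seed=seed + 1000 * i, screen_top_n=screen_top_n, n_rounds=n_rounds,
        )
    return build_panel(assoc_picks, pred_picks, cohort.proteins, split_id)
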