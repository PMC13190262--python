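"""Model interpretation: permutation feature importance, embedding covariance
importance, embedding-specific protein signatures, the 2-D diagnostic
probability map, within-diagnosis clustering and cluster differential
abundance.

Permutation importance (PermFIT-style) shuffles one network input column at a
time across test participants and records the per-condition cross-entropy
increase; over repeated shuffles the mean/sd yield a z statistic and a
one-sided normal p value (importance means the loss went *up*).  Permutation
happens on the model's input representation, after preprocessing: permuting
raw values and re-imputing would entangle the imputer with the feature under
test.

Embedding importance follows the activation-pattern (Haufe) argument: for a
linear readout, the covariance between a latent dimension and the predicted
probability is a more faithful importance measure than the readout weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats, special
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .cohortio import CONDITIONS, Cohort
from .evalstats import bh_fdr
from .jointnet import TrainedJointModel, _CLIP

logger = logging.getLogger(__name__)

__all__ = [
    "permfit",
    "aggregate_importance",
    "haufe_importance",
    "embedding_protein_signature",
    "probability_map",
    "project_onto_map",
    "cluster_map",
    "cluster_differential_abundance",
    "ProbabilityMap",
]


# ---------------------------------------------------------------------------
# PermFIT
# ---------------------------------------------------------------------------

def _cross_entropy_per_condition(
    probs: np.ndarray, y: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Unsmoothed BCE per condition over observed labels."""
    p = np.clip(probs, _CLIP, 1 - _CLIP)
    yv = np.where(mask, np.nan_to_num(y), 0.0)
    ll = yv * np.log(p) + (1 - yv) * np.log(1 - p)
    with np.errstate(invalid="ignore"):
        out = -(ll * mask).sum(axis=0) / mask.sum(axis=0)
    return out


def permfit(
    model: TrainedJointModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of every panel protein for every condition.

    ``X_test`` is the preprocessed network input (rows = test participants).
    Returns a long frame indexed by (protein, condition) with columns mean,
    sd, z, p, p_adj (BH within condition across proteins).
    """
    rng = np.random.default_rng(seed)
    mask = ~np.isnan(y_test)
    base = _cross_entropy_per_condition(
        model.forward_probs(X_test)[0], y_test, mask
    )
    n, d = X_test.shape
    n_cond = y_test.shape[1]

    # single-precision forward pass; only the first layer depends on the
    # permuted column, so its pre-activation is updated with a rank-1 term
    net = model.net
    W = [w.astype(np.float32) for w in net.W]
    b = [v.astype(np.float32) for v in net.b]
    We, be = net.We.astype(np.float32), net.be.astype(np.float32)
    Wo, bo = net.Wo.astype(np.float32), net.bo.astype(np.float32)
    X32 = X_test.astype(np.float32)
    Z1_base = X32 @ W[0] + b[0]
    Z1_tiled = np.tile(Z1_base, (n_perm, 1))  # shared base, tiled once

    from ._mlp import gelu

    def tail_probs(z1_big: np.ndarray) -> np.ndarray:
        h = gelu(z1_big)
        for Wl, bl in zip(W[1:], b[1:]):
            h = gelu(h @ Wl + bl)
        logits = (h @ We + be) @ Wo + bo
        return special.expit(logits.astype(float))

    records = np.empty((d, n_cond, 2))  # mean, sd of CE increase
    for f in range(d):
        # all permutations of one column evaluated as one stacked batch
        perms = np.stack(
            [rng.permutation(X32[:, f]) for _ in range(n_perm)]
        )  # n_perm x n
        delta = (perms - X32[:, f]).reshape(-1, 1)          # (n_perm*n) x 1
        z1 = Z1_tiled + delta * W[0][f]
        probs = tail_probs(z1).reshape(n_perm, n, n_cond)
        diffs = np.empty((n_perm, n_cond))
        for r in range(n_perm):
            diffs[r] = _cross_entropy_per_condition(probs[r], y_test, mask) - base
        records[f, :, 0] = diffs.mean(axis=0)
        records[f, :, 1] = diffs.std(axis=0, ddof=1)

    rows = []
    for ci, cond in enumerate(CONDITIONS):
        mean = records[:, ci, 0]
        sd = records[:, ci, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, mean / sd, 0.0)
        p = np.where(sd > 0, special.ndtr(-z), 0.5)  # one-sided: increase
        p_adj = bh_fdr(p)[0]
        for fi, prot in enumerate(model.panel):
            rows.append(
                {"protein": prot, "condition": cond, "mean": mean[fi],
                 "sd": sd[fi], "z": z[fi], "p": p[fi], "p_adj": p_adj[fi],
                 "sd_zero": sd[fi] == 0}
            )
    return pd.DataFrame(rows).set_index(["protein", "condition"])


def aggregate_importance(
    reports: list[pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Combine per-split permutation reports into fold counts (splits with
    BH-adjusted p < alpha) and the mean z over the splits in which the protein
    was on the panel.  Proteins never on any panel are simply absent."""
    frames = []
    for i, rep in enumerate(reports):
        f = rep[["z", "p_adj"]].copy()
        f["split"] = i
        frames.append(f.reset_index())
    allf = pd.concat(frames, ignore_index=True)
    out = (
        allf.groupby(["protein", "condition"])
        .agg(
            fold_count=("p_adj", lambda s: int((s < alpha).sum())),
            mean_z=("z", "mean"),
            n_panels=("split", "nunique"),
        )
    )
    return out


# ---------------------------------------------------------------------------
# Haufe covariance importance for embeddings
# ---------------------------------------------------------------------------

def haufe_importance(embeddings: np.ndarray, probabilities: np.ndarray) -> np.ndarray:
    """Sample covariance between each embedding dimension and each condition's
    predicted probability over a reference population (dims x conditions)."""
    e = np.asarray(embeddings, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if len(e) != len(p):
        raise ValueError("embeddings and probabilities must share rows")
    ec = e - e.mean(axis=0)
    pc = p - p.mean(axis=0)
    return ec.T @ pc / (len(e) - 1)


# ---------------------------------------------------------------------------
# Embedding-specific protein signatures
# ---------------------------------------------------------------------------

def embedding_protein_signature(
    panel_abundance: pd.DataFrame,
    embedding_values: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    gain_threshold: float = 50.0,
    seed: int = 0,
    n_rounds: int = 150,
) -> list[str]:
    """Boosted-tree regression of one embedding dimension on the panel
    proteins (validation-tuned over a small depth grid by MSE); proteins with
    cumulative split gain above ``gain_threshold`` form the signature.

    The gain threshold is on the booster's native total-gain scale and is not
    guaranteed comparable across refits with different targets; it is exposed
    for that reason.
    """
    X = panel_abundance.to_numpy(dtype=float)
    z = np.asarray(embedding_values, dtype=float)
    dtrain = xgb.DMatrix(X[train_idx], label=z[train_idx],
                         feature_names=list(panel_abundance.columns))
    dval = xgb.DMatrix(X[val_idx], label=z[val_idx],
                       feature_names=list(panel_abundance.columns))
    best, best_mse = None, np.inf
    for depth in (3, 5):
        params = {"objective": "reg:squarederror", "max_depth": depth,
                  "eta": 0.1, "subsample": 0.8, "tree_method": "hist",
                  "nthread": 1, "seed": seed, "verbosity": 0}
        # early stopping on validation MSE keeps gains honest: a target the
        # proteins cannot predict stops within a few rounds
        bst = xgb.train(
            params, dtrain, num_boost_round=n_rounds,
            evals=[(dval, "val")], early_stopping_rounds=20,
            verbose_eval=False,
        )
        mse = float(np.mean(
            (bst.predict(dval, iteration_range=(0, bst.best_iteration + 1))
             - z[val_idx]) ** 2
        ))
        if mse < best_mse:
            best, best_mse = bst, mse
    best = best[: best.best_iteration + 1]
    gains = best.get_score(importance_type="total_gain")
    return [p for p in panel_abundance.columns if gains.get(p, 0.0) > gain_threshold]


# ---------------------------------------------------------------------------
# Probability map
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityMap:
    """2-D stochastic-neighbour embedding of 6-D diagnostic probabilities."""

    coords: pd.DataFrame           # participants x (x, y)
    diagnosis: pd.Series           # single positive diagnosis per participant
    reference_probs: pd.DataFrame  # the 6-D vectors the map was fit on
    perplexity: float
    seed: int
    contours: dict[str, list[np.ndarray]] = field(default_factory=dict)
    clusters: dict[str, pd.Series] = field(default_factory=dict)


def eligible_single_diagnosis(
    probabilities: pd.DataFrame, labels: pd.DataFrame
) -> pd.Series:
    """Participants with exactly one positive among the six conditions; the
    all-negative and multi-positive are excluded from the map."""
    y = labels.to_numpy(dtype=float)
    pos_count = np.nansum(y == 1, axis=1)
    keep = pos_count == 1
    idx = labels.index[keep]
    diag = labels.loc[idx].apply(lambda r: r.index[r == 1][0], axis=1)
    return diag


def probability_map(
    probabilities: pd.DataFrame,
    diagnosis: pd.Series,
    perplexity: float = 1000.0,
    seed: int = 0,
    kde_threshold: float = 0.01,
    compute_contours: bool = False,
) -> ProbabilityMap:
    """t-SNE of the 6-D probability vectors of single-diagnosis participants.

    Perplexity is capped at n/4 (the headline value of 1,000 assumes a
    consortium-scale population) and auto-shrunk below n with a warning.
    Density contours per diagnosis are cut from a Gaussian KDE (Scott's rule)
    at ``kde_threshold``.
    """
    if len(probabilities) < 50:
        raise ValueError("need >= 50 eligible participants for a stable map")
    n = len(probabilities)
    perp = min(perplexity, n / 4)
    if perp >= n:
        warnings.warn("perplexity >= n; shrinking", stacklevel=2)
        perp = max((n - 1) / 3.0, 2.0)
    ts = TSNE(
        n_components=2, perplexity=perp, random_state=seed, init="pca",
        max_iter=1000,
    )
    coords = ts.fit_transform(probabilities.to_numpy(dtype=float))
    coords_df = pd.DataFrame(coords, index=probabilities.index, columns=["x", "y"])
    pmap = ProbabilityMap(
        coords=coords_df,
        diagnosis=diagnosis.loc[probabilities.index],
        reference_probs=probabilities.copy(),
        perplexity=float(perp),
        seed=seed,
    )
    if compute_contours:
        pmap.contours = _kde_contours(coords_df, pmap.diagnosis, kde_threshold)
    return pmap


def _kde_contours(
    coords: pd.DataFrame, diagnosis: pd.Series, level: float, grid_n: int = 120
) -> dict[str, list[np.ndarray]]:
    from skimage import measure

    out: dict[str, list[np.ndarray]] = {}
    x, y = coords["x"].to_numpy(), coords["y"].to_numpy()
    pad_x = 0.1 * np.ptp(x) + 1e-9
    pad_y = 0.1 * np.ptp(y) + 1e-9
    gx = np.linspace(x.min() - pad_x, x.max() + pad_x, grid_n)
    gy = np.linspace(y.min() - pad_y, y.max() + pad_y, grid_n)
    mesh = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2).T
    for diag in sorted(diagnosis.unique()):
        pts = coords[diagnosis == diag].to_numpy().T
        if pts.shape[1] < 5:
            continue
        try:
            kde = stats.gaussian_kde(pts)  # Scott bandwidth
        except np.linalg.LinAlgError:
            continue
        dens = kde(mesh).reshape(grid_n, grid_n)
        polys = []
        for contour in measure.find_contours(dens, level):
            xi = np.interp(contour[:, 1], np.arange(grid_n), gx)
            yi = np.interp(contour[:, 0], np.arange(grid_n), gy)
            polys.append(np.column_stack([xi, yi]))
        out[diag] = polys
    return out


def project_onto_map(
    pmap: ProbabilityMap, new_probs: pd.DataFrame, k: int = 10
) -> pd.DataFrame:
    """Out-of-sample projection: distance-weighted average of the map
    coordinates of the k nearest reference participants in probability space."""
    ref = pmap.reference_probs.to_numpy(dtype=float)
    ref_xy = pmap.coords.to_numpy(dtype=float)
    q = new_probs.to_numpy(dtype=float)
    k = min(k, len(ref))
    out = np.empty((len(q), 2))
    d2 = ((q[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    for i in range(len(q)):
        nn = np.argpartition(d2[i], k - 1)[:k]
        w = 1.0 / (np.sqrt(d2[i, nn]) + 1e-9)
        out[i] = (ref_xy[nn] * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame(out, index=new_probs.index, columns=["x", "y"])


def cluster_map(
    pmap: ProbabilityMap,
    diagnosis: str,
    k_range: range = range(2, 11),
    seed: int = 0,
    min_cluster_size: int = 5,
) -> tuple[pd.Series, int]:
    """Centroid clustering of one diagnosis's map coordinates for each k in
    ``k_range``; the k with the highest silhouette wins.

    Clusters below ``min_cluster_size`` members are treated as map outliers:
    their members are excluded from the returned labeling and the silhouette
    is computed over the remaining clusters (silhouette otherwise rewards
    isolating a handful of extreme points, and a cluster that small supports
    no downstream differential abundance).  The returned k is the number of
    retained clusters; solutions with fewer than two are skipped.
    """
    pts = pmap.coords[pmap.diagnosis == diagnosis].to_numpy(dtype=float)
    ids = pmap.coords.index[pmap.diagnosis == diagnosis]
    if len(pts) < 3 or np.allclose(pts, pts[0]):
        raise ValueError(
            f"coordinates for {diagnosis!r} are degenerate; clustering is not meaningful"
        )
    best: tuple | None = None
    best_sil = -np.inf
    n_dropped = 0
    for k in k_range:
        if k >= len(pts):
            break
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(pts)
        sizes = np.bincount(labels, minlength=k)
        big = np.flatnonzero(sizes >= min_cluster_size)
        if len(big) < 2:
            continue
        keep = np.isin(labels, big)
        renum = {c: i for i, c in enumerate(big)}
        kept_labels = np.array([renum[c] for c in labels[keep]])
        sil = silhouette_score(pts[keep], kept_labels)
        if sil > best_sil:
            best_sil = sil
            best = (kept_labels, keep, len(big))
            n_dropped = int((~keep).sum())
    if best is None:
        raise ValueError("no valid clustering found in k_range")
    kept_labels, keep, k_eff = best
    if n_dropped:
        warnings.warn(
            f"{n_dropped} {diagnosis!r} participant(s) fell into clusters below "
            f"{min_cluster_size} members and were excluded as map outliers",
            stacklevel=2,
        )
    series = pd.Series(kept_labels, index=ids[keep], name="cluster")
    pmap.clusters[diagnosis] = series
    return series, k_eff


# ---------------------------------------------------------------------------
# Cluster differential abundance
# ---------------------------------------------------------------------------

def cluster_differential_abundance(
    cohort: Cohort,
    diagnosis: str,
    cluster_labels: pd.Series,
    min_cluster_size: int = 5,
) -> pd.DataFrame:
    """Per-protein linear model of log abundance on cluster indicators plus
    age, sex, site and average protein level, restricted to the diagnosis's
    positives carrying a cluster label.

    Returns a frame indexed by protein with, per non-reference cluster,
    columns ``logFC_c{k}``, ``p_c{k}`` and BH-adjusted ``p_adj_c{k}``
    (adjustment across proteins within cluster).
    """
    sizes = cluster_labels.value_counts()
    small = sizes[sizes < min_cluster_size].index.tolist()
    if small:
        warnings.warn(f"cluster(s) {small} with < {min_cluster_size} members excluded",
                      stacklevel=2)
    keep_clusters = sorted(sizes[sizes >= min_cluster_size].index)
    if len(keep_clusters) < 2:
        raise ValueError("need >= 2 usable clusters for differential abundance")
    lab = cluster_labels[cluster_labels.isin(keep_clusters)]
    ids = pd.Index(lab.index)

    logx = np.log(cohort.abundance.loc[ids].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(logx, axis=0)
    nr, nc = np.where(np.isnan(logx))
    logx[nr, nc] = col_mean[nc]
    avg = logx.mean(axis=1)

    ph = cohort.phenotypes.loc[ids]
    cols = [np.ones(len(ids))]
    names = ["intercept"]
    ref = keep_clusters[0]
    for c in keep_clusters[1:]:
        cols.append((lab == c).to_numpy(dtype=float))
        names.append(f"c{c}")
    cols += [ph["age"].to_numpy(dtype=float), ph["sex"].to_numpy(dtype=float)]
    names += ["age", "sex"]
    sites = sorted(ph["site"].unique())
    for s in sites[1:]:
        cols.append((ph["site"] == s).to_numpy(dtype=float))
        names.append(f"site_{s}")
    cols.append(avg)
    names.append("avg_protein_level")
    X = np.column_stack(cols)
    # drop exactly collinear columns (e.g. a site fully confounded with a cluster)
    q = np.linalg.matrix_rank(X)
    if q < X.shape[1]:
        keep_cols, r = [], 0
        for j in range(X.shape[1]):
            cand = X[:, keep_cols + [j]]
            if np.linalg.matrix_rank(cand) > r:
                keep_cols.append(j)
                r += 1
        X = X[:, keep_cols]
        names = [names[j] for j in keep_cols]

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ logx)
    resid = logx - X @ beta
    dof = len(ids) - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof

    out = pd.DataFrame(index=cohort.proteins)
    for c in keep_clusters[1:]:
        name = f"c{c}"
        if name not in names:
            continue
        jj = names.index(name)
        b = beta[jj]
        se = np.sqrt(xtx_inv[jj, jj] * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b / se, 0.0)
        p = 2 * stats.t.sf(np.abs(t), dof)
        out[f"logFC_c{c}"] = b
        out[f"p_c{c}"] = p
        out[f"p_adj_c{c}"] = bh_fdr(p)[0]
    out.attrs["reference_cluster"] = ref
    out.attrs["diagnosis"] = diagnosis
    return out
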