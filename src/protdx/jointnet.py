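"""The multi-task joint diagnostic network and its loss functions.

Six dementia-associated conditions are predicted simultaneously from a
selected protein panel by a shared multilayer perceptron whose last hidden
representation (the *embedding*, default 32 dimensions) is combined linearly
into six sigmoid heads.  A multi-task rather than multi-class design lets
every participant contribute to exactly the tasks for which they carry an
observed label: missing labels are masked out of the loss, never imputed.

The training objective is a label-smoothed binary cross-entropy plus a
pairwise hinge rank loss weighted by lambda:

    L = L_BCE(alpha) + lambda * L_rank(epsilon)

For a participant k and conditions i < j with both labels observed, the rank
term penalises max(0, (p_ki - p_kj) (y_kj - y_ki) + epsilon): a positive
condition's probability must exceed a negative one's by the margin epsilon
(default 0.25).  Pairs with equal labels contribute the constant epsilon and
carry zero gradient — the literal form is kept so the loss value matches its
definition exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from ._mlp import MLP, Adam
from .cohortio import CONDITIONS, Cohort
from .preprocess import DeepChain, fit_deep_chain
from .featselect import FeaturePanel

logger = logging.getLogger(__name__)

__all__ = [
    "JointModelSpec",
    "TrainedJointModel",
    "PredictionSet",
    "bce_smoothed",
    "rank_loss",
    "total_loss",
    "loss_gradient",
    "train",
    "select_thresholds",
    "tune_hyperparameters",
    "predict",
    "extract_embeddings",
    "predict_with_dropout",
    "normalize_probability",
    "save_model",
    "load_model",
]

_CLIP = 1e-7  # probability clipping before logarithms


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _as_mask(y: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        mask = ~np.isnan(y)
    return mask.astype(bool)


def bce_smoothed(
    y: np.ndarray, p: np.ndarray, mask: np.ndarray | None = None, alpha: float = 0.0
) -> float:
    """Label-smoothed binary cross-entropy averaged over observed entries.

    The smoothed target is y(1 - alpha) + alpha/2; the denominator is the
    count of observed (participant, condition) entries so the loss scale is
    comparable across missingness patterns.
    """
    mask = _as_mask(y, mask)
    if not mask.any():
        raise ValueError("no observed labels; BCE undefined")
    p = np.clip(p, _CLIP, 1 - _CLIP)
    yv = np.where(mask, np.nan_to_num(y), 0.0)
    t = yv * (1 - alpha) + alpha / 2.0
    ll = t * np.log(p) + (1 - t) * np.log(1 - p)
    return float(-(ll * mask).sum() / mask.sum())


def rank_loss(
    y: np.ndarray, p: np.ndarray, mask: np.ndarray | None = None, eps: float = 0.25
) -> float:
    """Pairwise hinge rank loss, mean over participants with >= 1 observed
    label, of the sum over condition pairs with both labels observed."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    mask = _as_mask(y, mask)
    rows = mask.any(axis=1)
    if not rows.any():
        return 0.0
    n_rank = int(rows.sum())
    yv = np.nan_to_num(y)
    total = 0.0
    k = y.shape[1]
    for i, j in combinations(range(k), 2):
        both = mask[:, i] & mask[:, j]
        if not both.any():
            continue
        s = yv[:, j] - yv[:, i]
        h = (p[:, i] - p[:, j]) * s + eps
        total += float(np.maximum(0.0, h)[both].sum())
    return total / n_rank


def total_loss(
    y: np.ndarray,
    p: np.ndarray,
    mask: np.ndarray | None = None,
    alpha: float = 0.0,
    eps: float = 0.25,
    lam: float = 1.0,
) -> float:
    """Combined objective: smoothed BCE + lambda * rank loss."""
    out = bce_smoothed(y, p, mask, alpha)
    if lam != 0.0:
        out += lam * rank_loss(y, p, mask, eps)
    return out


def loss_gradient(
    y: np.ndarray,
    p: np.ndarray,
    mask: np.ndarray | None = None,
    alpha: float = 0.0,
    eps: float = 0.25,
    lam: float = 1.0,
) -> np.ndarray:
    """d(total loss)/d(logits) for sigmoid heads (analytic, vectorized)."""
    mask = _as_mask(y, mask)
    yv = np.where(mask, np.nan_to_num(y), 0.0)
    t = yv * (1 - alpha) + alpha / 2.0
    m_count = mask.sum()
    dbce_dlogit = (p - t) * mask / m_count  # (p - target) is BCE-on-logits grad

    dp = np.zeros_like(p)
    rows = mask.any(axis=1)
    n_rank = max(int(rows.sum()), 1)
    if lam != 0.0:
        k = y.shape[1]
        for i, j in combinations(range(k), 2):
            both = mask[:, i] & mask[:, j]
            if not both.any():
                continue
            s = yv[:, j] - yv[:, i]
            active = ((p[:, i] - p[:, j]) * s + eps > 0) & both
            dp[:, i] += np.where(active, s, 0.0)
            dp[:, j] -= np.where(active, s, 0.0)
        dp = dp * (lam / n_rank)
    drank_dlogit = dp * p * (1 - p)
    return dbce_dlogit + drank_dlogit


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class JointModelSpec:
    """Architecture and optimization hyperparameters of the joint network."""

    hidden: tuple[int, ...] = (256, 64)
    embedding_dim: int = 32
    dropout: float = 0.1
    alpha: float = 0.1          # label smoothing
    eps: float = 0.25           # rank-loss margin
    lam: float = 1.0            # rank-loss weight
    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def validate(self, panel_size: int) -> None:
        if not 0 <= self.alpha < 0.5:
            raise ValueError("label smoothing alpha must lie in [0, 0.5)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.embedding_dim >= panel_size:
            raise ValueError("embedding dimension must be smaller than the panel size")
        if self.lam < 0 or self.eps < 0:
            raise ValueError("lam and eps must be non-negative")


@dataclass
class PredictionSet:
    """Per-participant probabilities, binary calls and embeddings."""

    probabilities: pd.DataFrame         # participants x conditions
    calls: pd.DataFrame                 # participants x conditions, 0/1
    embeddings: pd.DataFrame            # participants x embedding dims
    intervals: pd.DataFrame | None = None  # (condition, lo|hi) columns


@dataclass
class TrainedJointModel:
    """Fitted network plus the preprocessing chain and per-task thresholds."""

    spec: JointModelSpec
    net: MLP
    chain: DeepChain
    panel: list[str]
    thresholds: np.ndarray              # 6 probabilities in (0, 1)
    conditions: tuple[str, ...] = CONDITIONS
    training_log: list[dict] = field(default_factory=list)

    def transform(self, cohort: Cohort, ids: pd.Index | None = None) -> pd.DataFrame:
        ab = cohort.abundance if ids is None else cohort.abundance.loc[pd.Index(ids)]
        return self.chain.apply(ab)

    def forward_probs(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits, emb, _ = self.net.forward(X, training=False)
        return _sigmoid(logits), emb


def _sigmoid(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

def _f1(y: np.ndarray, calls: np.ndarray) -> float:
    tp = float(((calls == 1) & (y == 1)).sum())
    fp = float(((calls == 1) & (y == 0)).sum())
    fn = float(((calls == 0) & (y == 1)).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def select_thresholds(
    probabilities: np.ndarray, labels: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per task, sweep midpoints of sorted unique validation probabilities and
    return the threshold with maximal F1 (ties -> larger threshold).

    Tasks whose validation labels are single-class fall back to 0.5 with a
    warning.
    """
    mask = _as_mask(labels, mask)
    n_tasks = probabilities.shape[1]
    out = np.full(n_tasks, 0.5)
    for i in range(n_tasks):
        m = mask[:, i]
        y = labels[m, i]
        p = probabilities[m, i]
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"task {i}: validation labels single-class; threshold defaults to 0.5",
                stacklevel=2,
            )
            continue
        uniq = np.unique(p)
        if len(uniq) == 1:
            continue
        cands = (uniq[:-1] + uniq[1:]) / 2.0
        best_f1, best_t = -1.0, 0.5
        for t in cands:
            f1 = _f1(y, (p >= t).astype(float))
            if f1 > best_f1 or (f1 == best_f1 and t > best_t):
                best_f1, best_t = f1, t
        out[i] = best_t
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _prep_split(
    cohort: Cohort,
    panel: list[str],
    train_ids: pd.Index,
    val_ids: pd.Index,
    knn_k: int = 10,
) -> tuple[DeepChain, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    chain = fit_deep_chain(cohort.abundance.loc[pd.Index(train_ids)], panel, k=knn_k)
    X_tr = chain.apply(cohort.abundance.loc[pd.Index(train_ids)]).to_numpy()
    X_va = chain.apply(cohort.abundance.loc[pd.Index(val_ids)]).to_numpy()
    y_tr = cohort.labels.loc[pd.Index(train_ids)].to_numpy(dtype=float)
    y_va = cohort.labels.loc[pd.Index(val_ids)].to_numpy(dtype=float)
    return chain, X_tr, y_tr, X_va, y_va


def train(
    spec: JointModelSpec,
    cohort: Cohort,
    panel: FeaturePanel | list[str],
    split: tuple,
    knn_k: int = 10,
) -> TrainedJointModel:
    """Fit the joint network on one train/validation/test triple.

    The preprocessing chain is fit on the training ids only; optimization is
    mini-batch Adam on the combined loss with early stopping on the validation
    loss; per-task thresholds are selected on validation predictions before
    any test-set use.  Deterministic given ``spec.seed``.
    """
    panel_ids = panel.proteins if isinstance(panel, FeaturePanel) else list(panel)
    spec.validate(len(panel_ids))
    train_ids, val_ids = pd.Index(split[0]), pd.Index(split[1])
    chain, X_tr, y_tr, X_va, y_va = _prep_split(cohort, panel_ids, train_ids, val_ids, knn_k)

    rng = np.random.default_rng(spec.seed)
    net = MLP(len(panel_ids), spec.hidden, spec.embedding_dim, len(CONDITIONS),
              spec.dropout, rng)
    params = net.parameters()
    n_w = len(net.W)
    decay_mask = [True] * n_w + [False] * n_w + [True, False, True, False]
    opt = Adam(params, lr=spec.lr, weight_decay=spec.weight_decay,
               decay_mask=decay_mask)

    mask_tr = ~np.isnan(y_tr)
    keep = mask_tr.any(axis=1)  # all-missing rows contribute nothing
    X_fit, y_fit = X_tr[keep], y_tr[keep]
    n = len(X_fit)
    best_val = np.inf
    best_params = [p.copy() for p in params]
    best_epoch = -1
    log: list[dict] = []
    stale = 0
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb, yb = X_fit[idx], y_fit[idx]
            logits, _, cache = net.forward(xb, training=True, rng=rng)
            p = _sigmoid(logits)
            dlogits = loss_gradient(yb, p, None, spec.alpha, spec.eps, spec.lam)
            grads = net.backward(dlogits, cache)
            opt.step(params, grads)
        val_logits, _, _ = net.forward(X_va, training=False)
        val_loss = total_loss(y_va, _sigmoid(val_logits), None,
                              spec.alpha, spec.eps, spec.lam)
        log.append({"epoch": epoch, "val_loss": val_loss})
        if val_loss < best_val - 1e-4:
            best_val, best_epoch, stale = val_loss, epoch, 0
            best_params = [p.copy() for p in params]
        else:
            stale += 1
            if stale >= spec.patience:
                break
    net.set_parameters(best_params)

    val_logits, _, _ = net.forward(X_va, training=False)
    thresholds = select_thresholds(_sigmoid(val_logits), y_va)
    return TrainedJointModel(
        spec=spec, net=net, chain=chain, panel=panel_ids,
        thresholds=thresholds,
        training_log=log + [{"best_epoch": best_epoch, "best_val_loss": best_val}],
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(
    model: TrainedJointModel, cohort: Cohort, ids: pd.Index | None = None
) -> PredictionSet:
    """Deterministic forward pass through the fitted chain and network."""
    ids = cohort.participants if ids is None else pd.Index(ids)
    X = model.transform(cohort, ids).to_numpy()
    probs, emb = model.forward_probs(X)
    probs = np.clip(probs, _CLIP, 1 - _CLIP)
    calls = (probs >= model.thresholds).astype(int)
    cols = list(model.conditions)
    return PredictionSet(
        probabilities=pd.DataFrame(probs, index=ids, columns=cols),
        calls=pd.DataFrame(calls, index=ids, columns=cols),
        embeddings=pd.DataFrame(
            emb, index=ids, columns=[f"E{d:02d}" for d in range(emb.shape[1])]
        ),
    )


def extract_embeddings(
    model: TrainedJointModel, cohort: Cohort, ids: pd.Index | None = None
) -> pd.DataFrame:
    """Pre-head activations (the learned low-dimensional proteomic summary)."""
    return predict(model, cohort, ids).embeddings


def predict_with_dropout(
    model: TrainedJointModel,
    cohort: Cohort,
    ids: pd.Index | None = None,
    reps: int = 100,
    seed: int = 0,
    dropout: float | None = None,
) -> PredictionSet:
    """Stochastic forward passes with dropout active at inference.

    Reports the median probability and (2.5, 97.5) percentile interval over
    ``reps`` passes; interval width is a proxy for model instability.
    """
    ids = cohort.participants if ids is None else pd.Index(ids)
    X = model.transform(cohort, ids).to_numpy()
    rng = np.random.default_rng(seed)
    rate = model.spec.dropout if dropout is None else dropout
    draws = np.empty((reps, len(ids), len(model.conditions)))
    for r in range(reps):
        logits, _, _ = model.net.forward(
            X, training=True, rng=rng, dropout_override=rate
        )
        draws[r] = _sigmoid(logits)
    med = np.median(draws, axis=0)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    cols = list(model.conditions)
    det_probs, emb = model.forward_probs(X)
    intervals = pd.concat(
        {
            "lo": pd.DataFrame(lo, index=ids, columns=cols),
            "hi": pd.DataFrame(hi, index=ids, columns=cols),
        },
        axis=1,
    )
    return PredictionSet(
        probabilities=pd.DataFrame(med, index=ids, columns=cols),
        calls=pd.DataFrame(
            (med >= model.thresholds).astype(int), index=ids, columns=cols
        ),
        embeddings=pd.DataFrame(
            emb, index=ids, columns=[f"E{d:02d}" for d in range(emb.shape[1])]
        ),
        intervals=intervals,
    )


def normalize_probability(
    p: np.ndarray | float, threshold: np.ndarray | float, log: bool = False
) -> np.ndarray | float:
    """Threshold-normalized score p / threshold (1.0 at the decision
    boundary); ``log=True`` gives the zero-centred report form log(p/t)."""
    score = np.asarray(p, dtype=float) / np.asarray(threshold, dtype=float)
    out = np.log(score) if log else score
    return float(out) if np.isscalar(p) and np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MODEL_SCHEMA = 1


def save_model(model: TrainedJointModel, out_dir: str | Path) -> None:
    """Write a versioned model container: JSON manifest (spec, thresholds,
    panel), network weights and the fitted preprocessing chain."""
    from dataclasses import asdict
    import json
    from .preprocess import chain_to_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema": _MODEL_SCHEMA,
        "spec": {**asdict(model.spec), "hidden": list(model.spec.hidden)},
        "thresholds": model.thresholds.tolist(),
        "panel": model.panel,
        "conditions": list(model.conditions),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    params = model.net.parameters()
    np.savez(out / "weights.npz", **{f"p{i}": p for i, p in enumerate(params)})
    chain_to_json(model.chain, out / "chain.json")


def load_model(in_dir: str | Path) -> TrainedJointModel:
    import json
    from .preprocess import chain_from_json

    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("schema") != _MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {manifest.get('schema')}")
    spec_dict = dict(manifest["spec"])
    spec_dict["hidden"] = tuple(spec_dict["hidden"])
    spec = JointModelSpec(**spec_dict)
    panel = manifest["panel"]
    rng = np.random.default_rng(0)
    net = MLP(len(panel), spec.hidden, spec.embedding_dim,
              len(manifest["conditions"]), spec.dropout, rng)
    with np.load(d / "weights.npz") as z:
        net.set_parameters([z[f"p{i}"] for i in range(len(z.files))])
    return TrainedJointModel(
        spec=spec,
        net=net,
        chain=chain_from_json(d / "chain.json"),
        panel=panel,
        thresholds=np.asarray(manifest["thresholds"], dtype=float),
        conditions=tuple(manifest["conditions"]),
    )


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE: dict = {
    "hidden": [(64,), (128,), (256,), (256, 64), (512, 128), (128, 64, 32)],
    "dropout": (0.0, 0.5),
    "alpha": (0.0, 0.2),
    "lam": [0.0, 0.25, 0.5, 1.0, 2.0],
    "lr": (1e-4, 1e-2),  # log-uniform
}


def tune_hyperparameters(
    cohort: Cohort,
    panel: FeaturePanel | list[str],
    split: tuple,
    space: dict | None = None,
    budget: int = 50,
    seed: int = 0,
    base_spec: JointModelSpec | None = None,
) -> tuple[JointModelSpec, list[dict]]:
    """Seeded random search maximizing validation BCA averaged over tasks.

    Returns the winning spec and the full trial log.
    """
    from .evalstats import balanced_accuracy

    space = dict(DEFAULT_SEARCH_SPACE, **(space or {}))
    base = base_spec or JointModelSpec()
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    best_spec, best_score = None, -np.inf
    val_ids = pd.Index(split[1])
    y_val = cohort.labels.loc[val_ids].to_numpy(dtype=float)
    for trial in range(budget):
        lr_lo, lr_hi = space["lr"]
        cand = replace(
            base,
            hidden=tuple(space["hidden"][rng.integers(len(space["hidden"]))]),
            dropout=float(rng.uniform(*space["dropout"])),
            alpha=float(rng.uniform(*space["alpha"])),
            lam=float(space["lam"][rng.integers(len(space["lam"]))]),
            lr=float(np.exp(rng.uniform(np.log(lr_lo), np.log(lr_hi)))),
            seed=int(rng.integers(2**31)),
        )
        model = train(cand, cohort, panel, split)
        pred = predict(model, cohort, val_ids)
        scores = []
        for i, cond in enumerate(CONDITIONS):
            m = ~np.isnan(y_val[:, i])
            if len(np.unique(y_val[m, i])) == 2:
                scores.append(
                    balanced_accuracy(pred.calls.to_numpy()[m, i], y_val[m, i])
                )
        score = float(np.mean(scores)) if scores else 0.0
        trials.append({"trial": trial, "spec": cand, "val_bca": score})
        if score > best_score:
            best_score, best_spec = score, cand
    return best_spec, trials
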