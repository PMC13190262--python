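"""Clinical translation: K-shot transfer to new sites, progression
prediction from embeddings, two-cutoff probability calibration and the
per-individual diagnostic report.

The transfer premise is that the joint network's low-dimensional embedding
already captures neurodegeneration-related signal broadly, so a plain
logistic-regression head fit on K labelled participants from a new site
("FineTune") generalizes better than retraining on raw proteins ("Retrain")
at the same sample size.

The two-cutoff scheme converts a continuous probability into a three-way
triage: below the lower cutoff the derivation-set negative predictive value
meets its target, above the upper cutoff the positive predictive value does;
the zone between is reported indeterminate (confirmatory testing advised).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .cohortio import CONDITIONS, Cohort
from .evalstats import auc, balanced_accuracy
from .interpret import ProbabilityMap, project_onto_map
from .jointnet import TrainedJointModel, normalize_probability, predict

logger = logging.getLogger(__name__)

__all__ = [
    "kshot_transfer",
    "progression_task",
    "TwoCutoff",
    "fit_two_cutoff",
    "apply_two_cutoff",
    "shapley_attribution",
    "IndividualReport",
    "individual_report",
]


# ---------------------------------------------------------------------------
# K-shot transfer
# ---------------------------------------------------------------------------

def _stratified_sample(
    y: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a K-sample preserving the class ratio (at least one of each
    class when available)."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n = len(pos) + len(neg)
    k_pos = int(round(K * len(pos) / n))
    k_pos = min(max(k_pos, 1 if len(pos) else 0), len(pos), K - 1)
    k_neg = min(K - k_pos, len(neg))
    take = np.concatenate([
        rng.choice(pos, size=k_pos, replace=False),
        rng.choice(neg, size=k_neg, replace=False),
    ])
    return np.sort(take)


def kshot_transfer(
    model: TrainedJointModel,
    cohort: Cohort,
    new_site_ids: pd.Index,
    K: int = 100,
    repeats: int = 20,
    seed: int = 0,
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Adapt a frozen model to a new site with K labelled participants.

    Per repeat and condition, a logistic head (scikit-learn defaults) is fit
    on (a) the frozen network embeddings ("FineTune") and (b) the z-scored
    panel proteins ("Retrain") of a stratified K-sample, then evaluated on the
    remaining participants.  Returns a long frame (repeat, condition,
    approach, bca, auc); repeats with under-represented classes are skipped
    for that condition and logged.
    """
    new_site_ids = pd.Index(new_site_ids)
    pred = predict(model, cohort, new_site_ids)
    emb = pred.embeddings.to_numpy()
    Xraw = model.transform(cohort, new_site_ids).to_numpy()
    labels = cohort.labels.loc[new_site_ids]
    conds = conditions or CONDITIONS
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        for cond in conds:
            y_all = labels[cond].to_numpy(dtype=float)
            obs = np.flatnonzero(~np.isnan(y_all))
            y = y_all[obs]
            if len(obs) < K + 20:
                raise ValueError(
                    f"condition {cond!r}: need >= K + 20 labelled participants "
                    f"on the new site (have {len(obs)})"
                )
            take_local = _stratified_sample(y, K, rng)
            take = obs[take_local]
            rest = np.setdiff1d(obs, take)
            if (y_all[take] == 1).sum() < 2 or len(np.unique(y_all[rest])) < 2:
                logger.info("repeat %d, condition %s skipped (class shortage)",
                            rep, cond)
                continue
            for approach, X in (("FineTune", emb), ("Retrain", Xraw)):
                if approach == "Retrain":
                    sc = StandardScaler().fit(X[take])
                    X_tr, X_te = sc.transform(X[take]), sc.transform(X[rest])
                else:
                    X_tr, X_te = X[take], X[rest]
                lr = LogisticRegression(max_iter=1000)
                lr.fit(X_tr, y_all[take])
                p = lr.predict_proba(X_te)[:, 1]
                calls = (p >= 0.5).astype(float)
                rows.append({
                    "repeat": rep, "condition": cond, "approach": approach,
                    "bca": balanced_accuracy(calls, y_all[rest]),
                    "auc": auc(p, y_all[rest]),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Progression task
# ---------------------------------------------------------------------------

def progression_task(
    model: TrainedJointModel,
    cohort: Cohort,
    progression: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Ten-fold CV of a default logistic head on baseline embeddings to
    predict cognitive progression among eligible participants (baseline CDR 0,
    non-decreasing follow-up CDR)."""
    elig = progression[progression["eligible"] & progression["progressor"].notna()]
    ids = pd.Index(elig.index)
    y = elig["progressor"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("progression labels are single-class; task undefined")
    emb = predict(model, cohort, ids).embeddings.to_numpy()
    rng = np.random.default_rng(seed)
    fold = np.empty(len(ids), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = np.arange(len(idx)) % k
    from .jointnet import select_thresholds

    probs = np.empty(len(ids))
    calls = np.empty(len(ids))
    for f in range(k):
        te = fold == f
        lr = LogisticRegression(max_iter=1000)
        lr.fit(emb[~te], y[~te])
        # per-fold F1 threshold from training predictions (progressors are a
        # small minority; a fixed 0.5 cutoff would rarely call anyone)
        p_tr = lr.predict_proba(emb[~te])[:, 1]
        thr = select_thresholds(p_tr[:, None], y[~te][:, None])[0]
        probs[te] = lr.predict_proba(emb[te])[:, 1]
        calls[te] = (probs[te] >= thr).astype(float)
    return {
        "n": len(ids),
        "n_progressors": int(y.sum()),
        "bca": balanced_accuracy(calls, y),
        "auc": auc(probs, y),
    }


# ---------------------------------------------------------------------------
# Two-cutoff calibration
# ---------------------------------------------------------------------------

@dataclass
class TwoCutoff:
    """Probability cutoffs guaranteeing NPV below and PPV above on the
    derivation set; in between is the indeterminate zone."""

    lower: float | None
    upper: float | None
    target_npv: float
    target_ppv: float
    derivation_npv: float | None
    derivation_ppv: float | None
    coverage: float
    empty_indeterminate: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def fit_two_cutoff(
    probabilities: np.ndarray,
    labels: np.ndarray,
    target_npv: float = 0.9,
    target_ppv: float = 0.9,
) -> TwoCutoff:
    """Derive the two cutoffs on a derivation set.

    lower = the largest candidate threshold t with NPV(prob < t) >= target;
    upper = the smallest candidate with PPV(prob >= t) >= target; candidates
    are midpoints of sorted unique probabilities.  A side with no attaining
    threshold is reported unattainable (None).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    obs = ~np.isnan(y)
    p, y = p[obs], y[obs]
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("derivation set must contain both classes")
    uniq = np.unique(p)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])

    lower = upper = None
    npv_at = ppv_at = None
    for t in cands:  # ascending; keep the largest attaining NPV
        below = p < t
        if below.any():
            npv = float((y[below] == 0).mean())
            if npv >= target_npv:
                lower, npv_at = float(t), npv
    for t in cands:  # ascending; first attaining PPV is the smallest
        above = p >= t
        if above.any():
            ppv = float((y[above] == 1).mean())
            if ppv >= target_ppv:
                upper, ppv_at = float(t), ppv
                break
    empty = False
    if lower is not None and upper is not None and lower > upper:
        warnings.warn(
            "lower cutoff exceeds upper cutoff (fully separable probabilities); "
            "indeterminate zone is empty",
            stacklevel=2,
        )
        empty = True
    if lower is not None and upper is not None and not empty:
        covered = float(((p < lower) | (p >= upper)).mean())
    else:
        covered = float(((p < lower) if lower is not None else np.zeros_like(p, bool)).mean()
                        + ((p >= upper) if upper is not None else np.zeros_like(p, bool)).mean())
        covered = min(covered, 1.0)
    return TwoCutoff(lower, upper, target_npv, target_ppv, npv_at, ppv_at,
                     covered, empty)


def apply_two_cutoff(cutoffs: TwoCutoff, probabilities: np.ndarray) -> np.ndarray:
    """Classify probabilities into 'negative' / 'indeterminate' / 'positive';
    monotone in the probability."""
    p = np.asarray(probabilities, dtype=float)
    out = np.full(p.shape, "indeterminate", dtype=object)
    if cutoffs.empty_indeterminate and cutoffs.lower is not None:
        # separable case: a single effective boundary at the upper cutoff
        out[p < cutoffs.upper] = "negative"
        out[p >= cutoffs.upper] = "positive"
        return out
    if cutoffs.lower is not None:
        out[p < cutoffs.lower] = "negative"
    if cutoffs.upper is not None:
        out[p >= cutoffs.upper] = "positive"
    return out


# ---------------------------------------------------------------------------
# Shapley attribution and the individual report
# ---------------------------------------------------------------------------

def shapley_attribution(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    n_perm: int = 128,
    seed: int = 0,
) -> np.ndarray:
    """Sampling-based Shapley values of ``predict_fn`` (vectorized over rows,
    returning one value per row) for a single input ``x`` against a background
    population.

    Per permutation a random background row is drawn and features are switched
    from background to ``x`` in permutation order; the output increments are
    the marginal contributions.  Satisfies the efficiency property in
    expectation: contributions sum to f(x) - E_bg f(bg).
    """
    rng = np.random.default_rng(seed)
    d = len(x)
    phi = np.zeros(d)
    for _ in range(n_perm):
        bg = background[rng.integers(len(background))]
        order = rng.permutation(d)
        # rows[0] = bg, rows[t] = bg with first t features (in order) from x
        rows = np.tile(bg, (d + 1, 1))
        mask = np.zeros(d, dtype=bool)
        for t, f in enumerate(order):
            mask[f] = True
            rows[t + 1, mask] = x[mask]
        vals = predict_fn(rows)
        phi[order] += np.diff(vals)
    return phi / n_perm


@dataclass
class IndividualReport:
    """Self-contained per-participant diagnostic summary."""

    participant: str
    normalized_probabilities: dict[str, float]   # log(p / threshold), 0-centred
    probabilities: dict[str, float]
    calls: dict[str, int]
    top_positive: dict[str, list[tuple[str, float]]]
    top_negative: dict[str, list[tuple[str, float]]]
    map_location: tuple[float, float] | None = None
    traits: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def individual_report(
    model: TrainedJointModel,
    cohort: Cohort,
    participant: str,
    background_ids: pd.Index,
    pmap: ProbabilityMap | None = None,
    trait_table: pd.DataFrame | None = None,
    n_perm: int = 128,
    top_k: int = 10,
    seed: int = 0,
) -> IndividualReport:
    """Per-condition Shapley attribution of the predicted probability against
    the background (training) population, with the top +/- ``top_k``
    contributing proteins, zero-centred normalized probabilities and an
    optional map location and protein-trait annotation."""
    background_ids = pd.Index(background_ids)
    if len(background_ids) < 30:
        warnings.warn("background set < 30 rows; attribution variance will be high",
                      stacklevel=2)
    X_bg = model.transform(cohort, background_ids).to_numpy()
    x = model.transform(cohort, pd.Index([participant])).to_numpy()[0]
    probs, _ = model.forward_probs(x[None, :])
    probs = probs[0]

    top_pos: dict[str, list[tuple[str, float]]] = {}
    top_neg: dict[str, list[tuple[str, float]]] = {}
    for ci, cond in enumerate(model.conditions):
        fn = lambda rows, ci=ci: model.forward_probs(rows)[0][:, ci]
        phi = shapley_attribution(fn, x, X_bg, n_perm=n_perm, seed=seed + ci)
        order = np.argsort(-phi)
        pos = [(model.panel[j], float(phi[j])) for j in order if phi[j] > 0][:top_k]
        neg = [(model.panel[j], float(phi[j])) for j in order[::-1] if phi[j] < 0][:top_k]
        top_pos[cond] = pos
        top_neg[cond] = neg

    loc = None
    if pmap is not None:
        proj = project_onto_map(
            pmap,
            pd.DataFrame([probs], index=[participant], columns=list(model.conditions)),
        )
        loc = (float(proj.iloc[0, 0]), float(proj.iloc[0, 1]))

    traits: dict[str, list[str]] = {}
    if trait_table is not None:
        contributing = {p for lst in (*top_pos.values(), *top_neg.values())
                        for p, _ in lst}
        for prot in sorted(contributing):
            hits = trait_table[trait_table["protein"] == prot]["trait"].tolist()
            if hits:
                traits[prot] = hits

    return IndividualReport(
        participant=participant,
        normalized_probabilities={
            c: float(normalize_probability(probs[i], model.thresholds[i], log=True))
            for i, c in enumerate(model.conditions)
        },
        probabilities={c: float(probs[i]) for i, c in enumerate(model.conditions)},
        calls={c: int(probs[i] >= model.thresholds[i])
               for i, c in enumerate(model.conditions)},
        top_positive=top_pos,
        top_negative=top_neg,
        map_location=loc,
        traits=traits,
    )
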