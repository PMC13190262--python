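"""Fitted preprocessing transforms for the proteomics matrix.

Two chains are used downstream:

* the network chain — per-participant average-level normalization, 10-nearest-
  neighbour imputation and rank-based Gaussian normalization, fit on the
  training split only and applied unchanged to held-out data;
* the tree chain — training-split z-scoring, used by forest/boosted baselines.

Outlier masking (|z| > 6 per protein) is a one-off curation step applied
dataset-wide before any splitting, mirroring consortium-level data cleaning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special
from sklearn.impute import KNNImputer

__all__ = [
    "mask_outliers",
    "normalize_average_level",
    "KnnImputerTransform",
    "GaussianRankTransform",
    "ZScoreTransform",
    "DeepChain",
    "fit_deep_chain",
]


class TransformError(ValueError):
    pass


def _check_proteins(fitted: pd.Index, data: pd.DataFrame) -> None:
    if list(fitted) != list(data.columns):
        raise TransformError(
            "protein list of the data does not match the protein list the "
            "transform was fit on"
        )


def mask_outliers(abundance: pd.DataFrame, z_cut: float = 6.0) -> pd.DataFrame:
    """Set entries beyond ``z_cut`` standard deviations of their protein's
    mean (classical moments over non-missing entries) to missing.

    Single pass: statistics are computed once, not re-iterated after masking.
    Proteins with fewer than 3 non-missing values are left untouched.
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    x = abundance.to_numpy(dtype=float, copy=True)
    n_obs = np.sum(~np.isnan(x), axis=0)
    thin = n_obs < 3
    if thin.any():
        warnings.warn(
            f"{int(thin.sum())} protein(s) with < 3 non-missing values left "
            "untouched by outlier masking",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=0)
    z_ok = sd > 0
    mask = np.zeros_like(x, dtype=bool)
    cols = z_ok & ~thin
    with np.errstate(invalid="ignore"):
        mask[:, cols] = np.abs(x[:, cols] - mean[cols]) > z_cut * sd[cols]
    mask &= ~np.isnan(x)
    x[mask] = np.nan
    return pd.DataFrame(x, index=abundance.index, columns=abundance.columns)


def normalize_average_level(abundance: pd.DataFrame) -> pd.DataFrame:
    """Divide each participant's values by their mean over non-missing
    proteins; missing entries stay missing."""
    x = abundance.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(x), axis=1)
    if (n_obs == 0).any():
        bad = abundance.index[n_obs == 0].tolist()
        raise TransformError(f"participant(s) with all proteins missing: {bad[:10]}")
    row_mean = np.nanmean(x, axis=1, keepdims=True)
    return pd.DataFrame(x / row_mean, index=abundance.index, columns=abundance.columns)


@dataclass
class KnnImputerTransform:
    """k-nearest-neighbour imputation with the training split as donor pool.

    Distances are Euclidean over mutually observed proteins, rescaled by the
    number of shared proteins; a missing cell receives the mean of its protein
    over the k nearest training participants.
    """

    proteins: pd.Index
    imputer: KNNImputer
    k: int

    @classmethod
    def fit(cls, train: pd.DataFrame, k: int = 10) -> "KnnImputerTransform":
        if k > len(train):
            raise TransformError(f"k={k} exceeds the {len(train)} training participants")
        all_missing = train.columns[train.isna().all(axis=0)]
        if len(all_missing):
            raise TransformError(
                f"protein(s) never observed in training; cannot fit imputer: "
                f"{all_missing.tolist()[:10]}"
            )
        imp = KNNImputer(n_neighbors=k)
        imp.fit(train.to_numpy(dtype=float))
        return cls(train.columns, imp, k)

    def apply(self, abundance: pd.DataFrame) -> pd.DataFrame:
        _check_proteins(self.proteins, abundance)
        out = self.imputer.transform(abundance.to_numpy(dtype=float, copy=True))
        return pd.DataFrame(out, index=abundance.index, columns=abundance.columns)


@dataclass
class GaussianRankTransform:
    """Rank-based inverse-normal transform fit on the training split.

    Training values map to Phi^-1((r - 0.5)/n) with average ranks for ties;
    held-out values map through linear interpolation of the training empirical
    quantile function, clipped to the training probability range
    [0.5/n, (n - 0.5)/n].
    """

    proteins: pd.Index
    sorted_values: np.ndarray  # n_train x p, each column ascending
    n: int

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "GaussianRankTransform":
        x = train.to_numpy(dtype=float)
        if np.isnan(x).any():
            raise TransformError("Gaussian rank transform requires complete (imputed) input")
        const = np.ptp(x, axis=0) == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant training column(s); mapped to 0",
                stacklevel=2,
            )
        return cls(train.columns, np.sort(x, axis=0), len(train))

    def apply(self, abundance: pd.DataFrame) -> pd.DataFrame:
        _check_proteins(self.proteins, abundance)
        x = abundance.to_numpy(dtype=float)
        if np.isnan(x).any():
            raise TransformError("Gaussian rank transform requires complete (imputed) input")
        n = self.n
        grid = (np.arange(n) + 0.5) / n
        lo, hi = 0.5 / n, (n - 0.5) / n
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            sv = self.sorted_values[:, j]
            if sv[0] == sv[-1]:
                out[:, j] = 0.0
                continue
            probs = np.interp(x[:, j], sv, grid)
            out[:, j] = special.ndtri(np.clip(probs, lo, hi))
        return pd.DataFrame(out, index=abundance.index, columns=abundance.columns)

    def apply_training(self, train: pd.DataFrame) -> pd.DataFrame:
        """Exact rank transform of the training split itself (average ranks
        for ties), Phi^-1((r - 0.5)/n)."""
        _check_proteins(self.proteins, train)
        from scipy.stats import rankdata

        x = train.to_numpy(dtype=float)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            col = x[:, j]
            if np.ptp(col) == 0:
                out[:, j] = 0.0
            else:
                out[:, j] = special.ndtri((rankdata(col, method="average") - 0.5) / len(col))
        return pd.DataFrame(out, index=train.index, columns=train.columns)


@dataclass
class ZScoreTransform:
    """Column z-scoring with training-split mean and sd (for tree baselines)."""

    proteins: pd.Index
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "ZScoreTransform":
        x = train.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(x, axis=0)
            sd = np.nanstd(x, axis=0, ddof=0)
        if (sd == 0).any():
            warnings.warn(
                f"{int((sd == 0).sum())} zero-sd column(s); scaled to 0", stacklevel=2
            )
        return cls(train.columns, mean, sd)

    def apply(self, abundance: pd.DataFrame) -> pd.DataFrame:
        _check_proteins(self.proteins, abundance)
        x = abundance.to_numpy(dtype=float)
        sd = np.where(self.sd == 0, 1.0, self.sd)
        out = (x - self.mean) / sd
        out[:, self.sd == 0] = 0.0
        return pd.DataFrame(out, index=abundance.index, columns=abundance.columns)


@dataclass
class DeepChain:
    """Ordered network-input chain: average-level normalization (stateless,
    computed over the full protein set) -> panel subset -> kNN imputation ->
    Gaussian rank normalization.  Fit on training rows only; refuses
    application before fitting, which enforces the chain order by
    construction."""

    panel: list[str]
    imputer: KnnImputerTransform
    rank: GaussianRankTransform

    def apply(self, abundance: pd.DataFrame) -> pd.DataFrame:
        """``abundance`` is the full (outlier-masked) matrix; returns the
        transformed panel-column matrix ready for the network."""
        normed = normalize_average_level(abundance)[self.panel]
        return self.rank.apply(self.imputer.apply(normed))


def fit_deep_chain(
    train_abundance: pd.DataFrame, panel: list[str], k: int = 10
) -> DeepChain:
    """Fit the network chain on the training split.

    Row normalization uses each participant's mean over all proteins (not just
    the panel), matching the average-protein-level covariate convention; the
    imputer and rank normalizer are fit on the panel columns of the normalized
    training rows.
    """
    normed = normalize_average_level(train_abundance)[panel]
    imputer = KnnImputerTransform.fit(normed, k=k)
    complete = imputer.apply(normed)
    rank = GaussianRankTransform.fit(complete)
    return DeepChain(list(panel), imputer, rank)


# ---------------------------------------------------------------------------
# JSON serialization (schema-versioned)
# ---------------------------------------------------------------------------

_SCHEMA = 1


def chain_to_json(chain: DeepChain, path: str | Path) -> None:
    payload = {
        "schema": _SCHEMA,
        "panel": chain.panel,
        "k": chain.imputer.k,
        "imputer_reference": np.asarray(
            chain.imputer.imputer._fit_X, dtype=float
        ).tolist(),
        "rank_sorted": chain.rank.sorted_values.tolist(),
        "rank_n": chain.rank.n,
    }
    Path(path).write_text(json.dumps(payload))


def chain_from_json(path: str | Path) -> DeepChain:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _SCHEMA:
        raise TransformError(f"unsupported chain schema {payload.get('schema')}")
    panel = payload["panel"]
    ref = pd.DataFrame(np.asarray(payload["imputer_reference"], dtype=float),
                       columns=panel)
    imputer = KnnImputerTransform.fit(ref, k=payload["k"])
    rank = GaussianRankTransform(
        pd.Index(panel), np.asarray(payload["rank_sorted"], dtype=float),
        payload["rank_n"],
    )
    return DeepChain(panel, imputer, rank)
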