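"""Cohort data model, delimited-text I/O, cognition-derived labels and split plans.

A cohort couples three participant-aligned tables:

* ``abundance`` — participants x proteins, relative fluorescence units (RFU),
  strictly positive where observed, ``NaN`` for missing measurements;
* ``phenotypes`` — site id, age, sex, MMSE, CDR, APOE allele counts and an
  optional longitudinal CDR sequence per participant;
* ``labels`` — one ternary column per condition (1.0 positive, 0.0 negative,
  ``NaN`` missing / never assessed).

The condition order is fixed package-wide and never reordered.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed condition order used by every stage of the toolkit.
CONDITIONS: tuple[str, ...] = ("control", "AD", "PD", "FTD", "ALS", "stroke_TIA")

#: Token encoding for the ternary label states in labels.tsv.
_LABEL_TOKENS = {"positive": 1.0, "negative": 0.0, "": np.nan}
_LABEL_VALUES = {1.0: "positive", 0.0: "negative"}

PHENOTYPE_COLUMNS = (
    "site", "age", "sex", "mmse", "cdr", "apoe_e2", "apoe_e4", "cdr_visits",
)


class CohortError(ValueError):
    """Raised for malformed or misaligned cohort tables."""


@dataclass
class Cohort:
    """Participant-aligned proteomics matrix, phenotypes and ternary labels."""

    abundance: pd.DataFrame
    phenotypes: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.abundance.index
        for name, tab in (("phenotypes", self.phenotypes), ("labels", self.labels)):
            if not idx.equals(tab.index):
                missing = idx.symmetric_difference(tab.index).tolist()[:10]
                raise CohortError(
                    f"participant ids of abundance and {name} differ; "
                    f"offending ids (up to 10): {missing}"
                )
        if self.abundance.columns.has_duplicates:
            raise CohortError("duplicate protein ids in abundance matrix")
        if list(self.labels.columns) != list(CONDITIONS):
            raise CohortError(
                f"label columns must be {list(CONDITIONS)}, got {list(self.labels.columns)}"
            )
        mmse = self.phenotypes.get("mmse")
        if mmse is not None:
            bad = mmse.dropna()
            bad = bad[(bad < 0) | (bad > 30)]
            if len(bad):
                raise CohortError(f"MMSE outside [0, 30] for participants {bad.index.tolist()[:10]}")

    @property
    def participants(self) -> pd.Index:
        return self.abundance.index

    @property
    def proteins(self) -> pd.Index:
        return self.abundance.columns

    @property
    def n_participants(self) -> int:
        return len(self.abundance)

    @property
    def n_proteins(self) -> int:
        return self.abundance.shape[1]

    def subset(self, ids: Sequence[str]) -> "Cohort":
        ids = pd.Index(ids)
        return Cohort(
            self.abundance.loc[ids],
            self.phenotypes.loc[ids],
            self.labels.loc[ids],
        )


@dataclass
class SplitPlan:
    """Train/validation/test participant-id triples for one evaluation scheme."""

    scheme: str  # "stratified-kfold" | "leave-one-site-out"
    folds: list[tuple[list[str], list[str], list[str]]]
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, (tr, va, te) in enumerate(self.folds):
            s_tr, s_va, s_te = set(tr), set(va), set(te)
            if s_tr & s_va or s_tr & s_te or s_va & s_te:
                raise CohortError(f"fold {i}: train/validation/test sets overlap")

    def __len__(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "meta": self.meta,
            "folds": [
                {"train": list(tr), "validation": list(va), "test": list(te)}
                for tr, va, te in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        folds = [
            (f["train"], f["validation"], f["test"]) for f in payload["folds"]
        ]
        return cls(payload["scheme"], folds, payload.get("seed"), payload.get("meta", {}))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write abundance.tsv, phenotypes.tsv and labels.tsv (TSV, UTF-8, '.' decimal,
    empty cell = missing) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ab = cohort.abundance.copy()
    ab.index.name = "participant"
    ab.to_csv(out / "abundance.tsv", sep="\t", na_rep="", float_format="%.10g")
    ph = cohort.phenotypes.copy()
    ph.index.name = "participant"
    ph.to_csv(out / "phenotypes.tsv", sep="\t", na_rep="")
    lab = cohort.labels.copy()
    for c in lab.columns:
        lab[c] = lab[c].map(_LABEL_VALUES).fillna("")
    lab.index.name = "participant"
    lab.to_csv(out / "labels.tsv", sep="\t")


def _read_labels(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col="participant", dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        vals = raw[col].str.strip()
        unknown = sorted(set(vals) - set(_LABEL_TOKENS))
        if unknown:
            raise CohortError(
                f"labels column {col!r}: unknown state token(s) {unknown}; "
                f"expected one of {sorted(_LABEL_TOKENS)}"
            )
        out[col] = vals.map(_LABEL_TOKENS)
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; raises on id mismatch or
    non-numeric abundance cells."""
    d = Path(in_dir)
    ab = pd.read_csv(d / "abundance.tsv", sep="\t", index_col="participant")
    ab.columns.name = "protein"
    non_numeric = ab.select_dtypes(exclude="number").columns
    if len(non_numeric):
        for col in non_numeric:
            bad = ab[col][pd.to_numeric(ab[col], errors="coerce").isna() & ab[col].notna()]
            if len(bad):
                raise CohortError(
                    f"non-numeric abundance cell at participant {bad.index[0]!r}, "
                    f"protein {col!r}: {bad.iloc[0]!r}"
                )
        ab = ab.apply(pd.to_numeric)
    ph = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col="participant")
    if "cdr_visits" in ph.columns:
        ph["cdr_visits"] = ph["cdr_visits"].astype("string")
    lab = _read_labels(d / "labels.tsv")
    return Cohort(ab, ph.loc[ab.index] if ph.index.equals(ab.index) else ph, lab)


# ---------------------------------------------------------------------------
# Cognition-derived diagnostic classes
# ---------------------------------------------------------------------------

def derive_cognitive_labels(
    phenotypes: pd.DataFrame,
    dementia_mmse_cutoff: float = 19.0,
    cdr_precedence: bool = True,
) -> pd.Series:
    """Map participants without a primary diagnosis to a cognition-derived class.

    Classes: ``control`` (MMSE >= 26 or CDR 0), ``MCI-SCI`` (20 <= MMSE <= 25 or
    CDR 0.5), ``ComputedDementia`` (MMSE < ``dementia_mmse_cutoff`` or CDR >= 1)
    and ``Unknown`` (neither scale valid, or scores falling in no band).

    When MMSE and CDR disagree and ``cdr_precedence`` is set (default), the
    clinician-assigned CDR stage wins.
    """
    mmse = pd.to_numeric(phenotypes.get("mmse"), errors="coerce")
    cdr = pd.to_numeric(phenotypes.get("cdr"), errors="coerce")

    def classify(m: float, c: float) -> str:
        by_cdr = None
        if np.isfinite(c):
            if c == 0:
                by_cdr = "control"
            elif c == 0.5:
                by_cdr = "MCI-SCI"
            elif c >= 1:
                by_cdr = "ComputedDementia"
        by_mmse = None
        if np.isfinite(m):
            if m >= 26:
                by_mmse = "control"
            elif 20 <= m <= 25:
                by_mmse = "MCI-SCI"
            elif m < dementia_mmse_cutoff:
                by_mmse = "ComputedDementia"
        if by_cdr is not None and by_mmse is not None:
            return by_cdr if cdr_precedence else by_mmse
        for v in (by_cdr, by_mmse):
            if v is not None:
                return v
        return "Unknown"

    out = pd.Series(
        [classify(m, c) for m, c in zip(mmse.to_numpy(), cdr.to_numpy())],
        index=phenotypes.index,
        name="derived_class",
    )
    return out


# ---------------------------------------------------------------------------
# Split construction
# ---------------------------------------------------------------------------

def _site_fold_assignment(
    ids: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign one site's shuffled members to folds 0..k-1 as evenly as possible
    (round-robin after shuffling, so fold sizes differ by at most 1)."""
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    folds[perm] = np.arange(len(ids)) % k
    return folds


def make_stratified_kfold(cohort: Cohort, k: int = 10, seed: int = 0) -> SplitPlan:
    """Site-stratified k-fold plan with rotating (k-2)/1/1 train/validation/test
    fold assignment; every fold serves as the test split exactly once."""
    if k < 3:
        raise ValueError("k must be >= 3 (need train, validation and test folds)")
    rng = np.random.default_rng(seed)
    sites = cohort.phenotypes["site"]
    fold_of = pd.Series(index=cohort.participants, dtype=int)
    for site in sorted(sites.unique()):
        ids = cohort.participants[sites == site].to_numpy()
        if len(ids) < k:
            warnings.warn(
                f"site {site!r} has {len(ids)} < k={k} participants; "
                "members distributed round-robin across folds",
                stacklevel=2,
            )
        fold_of[ids] = _site_fold_assignment(ids, k, rng)
    folds = []
    for r in range(k):
        test_f, val_f = r, (r + 1) % k
        test = cohort.participants[fold_of == test_f].tolist()
        val = cohort.participants[fold_of == val_f].tolist()
        train = cohort.participants[(fold_of != test_f) & (fold_of != val_f)].tolist()
        folds.append((train, val, test))
    return SplitPlan("stratified-kfold", folds, seed, meta={"k": k})


def make_leave_one_site_out(
    cohort: Cohort,
    test_site: str,
    val_fraction: float = 1.0 / 9.0,
    seed: int = 0,
) -> SplitPlan:
    """Leave-one-site-out plan: the test split is exactly ``test_site``; the
    remaining participants are split site-stratified into train/validation."""
    sites = cohort.phenotypes["site"]
    if test_site not in set(sites):
        raise CohortError(f"unknown site id {test_site!r}")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test = cohort.participants[sites == test_site].tolist()
    train: list[str] = []
    val: list[str] = []
    for site in sorted(set(sites) - {test_site}):
        ids = cohort.participants[sites == site].to_numpy()
        perm = rng.permutation(len(ids))
        n_val = int(round(val_fraction * len(ids)))
        val.extend(ids[perm[:n_val]].tolist())
        train.extend(ids[perm[n_val:]].tolist())
    return SplitPlan(
        "leave-one-site-out",
        [(train, val, test)],
        seed,
        meta={"test_site": str(test_site), "val_fraction": val_fraction},
    )
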