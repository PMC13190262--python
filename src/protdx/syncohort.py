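"""Synthetic multi-site plasma-proteomics cohorts with known ground truth.

The generator emulates the structure of a consortium-style aptamer proteomics
release: participants contributed by 10-20 sites with multiplicative per-site
batch effects, six partially overlapping diagnostic conditions with imbalanced
prevalences and per-condition label missingness, a small set of "planted"
proteins per condition carrying multiplicative fold changes, age/sex covariate
effects, log-normal measurement noise and missing-completely-at-random matrix
entries.  Every distributional choice here is synthetic: the generator supplies
controlled ground truth for testing the pipeline, not a fitted model of any
real cohort.

Abundances are built additively on the natural-log scale (hence
multiplicatively on the RFU scale), so a planted effect of 3 means a 3x fold
change for positives of that condition — the same semantics the downstream
association filter uses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cohortio import CONDITIONS, Cohort

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "make_progression_labels",
    "plant_condition_subtypes",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


def _default_prevalence() -> dict[str, float]:
    # Imbalanced marginals echoing a dementia consortium: controls and AD
    # dominate, motor-neuron disease is rare.
    return {
        "control": 0.30,
        "AD": 0.20,
        "PD": 0.15,
        "FTD": 0.05,
        "ALS": 0.05,
        "stroke_TIA": 0.10,
    }


def _default_missing() -> dict[str, float]:
    return {c: 0.10 for c in CONDITIONS}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults define the standard study
    conditions used throughout the test-bench."""

    n_participants: int = 4000
    n_proteins: int = 2000
    n_sites: int = 10
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    planted_proteins_per_condition: int = 40
    fold_change_range: tuple[float, float] = (1.5, 3.0)
    site_shift_sd: float = 0.2
    site_scale_sd: float = 0.05
    label_missing_rate: dict[str, float] = field(default_factory=_default_missing)
    copathology_correlation: float = 0.1
    control_disease_correlation: float = -0.3
    age_effect_sd: float = 0.02
    sex_effect_sd: float = 0.05
    measurement_noise_sd: float = 0.3
    missing_value_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_participants", "n_proteins", "n_sites",
                     "planted_proteins_per_condition"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if set(self.prevalence) != set(CONDITIONS):
            raise ConfigurationError("prevalence must cover exactly the six conditions")
        for c, p in self.prevalence.items():
            if not 0 < p < 1:
                raise ConfigurationError(f"prevalence[{c!r}] must lie in (0, 1)")
        for c, p in self.label_missing_rate.items():
            if not 0 <= p < 1:
                raise ConfigurationError(f"label_missing_rate[{c!r}] must lie in [0, 1)")
        lo, hi = self.fold_change_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("fold_change_range must be positive with lo <= hi")
        if not 0 <= self.copathology_correlation < 1:
            raise ConfigurationError("copathology_correlation must lie in [0, 1)")
        if not -1 < self.control_disease_correlation <= 0:
            raise ConfigurationError(
                "control_disease_correlation must lie in (-1, 0]"
            )
        if np.linalg.eigvalsh(self._liability_cov()).min() <= 1e-10:
            raise ConfigurationError(
                "copathology_correlation / control_disease_correlation give a "
                "non-positive-definite liability covariance"
            )
        if not 0 <= self.missing_value_rate < 1:
            raise ConfigurationError("missing_value_rate must lie in [0, 1)")
        for name in ("site_shift_sd", "site_scale_sd", "age_effect_sd",
                     "sex_effect_sd", "measurement_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_proteins < 6 * self.planted_proteins_per_condition:
            raise ConfigurationError(
                "n_proteins must be >= 6 * planted_proteins_per_condition "
                "(planted sets are disjoint)"
            )

    def _liability_cov(self) -> np.ndarray:
        r = self.copathology_correlation
        cov = np.full((6, 6), r) + (1 - r) * np.eye(6)
        ctrl = CONDITIONS.index("control")
        cov[ctrl, :] = self.control_disease_correlation
        cov[:, ctrl] = self.control_disease_correlation
        cov[ctrl, ctrl] = 1.0
        return cov


@dataclass
class GroundTruth:
    """What the generator planted: multiplicative effects, site effects and the
    latent liabilities the labels were thresholded from."""

    effects: pd.DataFrame          # protein x condition, 1.0 = null
    site_shift: pd.DataFrame       # site x protein additive log-shift
    site_scale: pd.DataFrame       # site x protein multiplicative noise-scale
    liability: pd.DataFrame        # participant x condition latent normal
    planted: dict[str, list[str]]  # condition -> planted protein ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": self.planted,
            "effects": {
                "proteins": self.effects.index.tolist(),
                "conditions": self.effects.columns.tolist(),
                "values": self.effects.to_numpy().tolist(),
            },
            "site_shift": self.site_shift.to_dict(orient="split"),
            "site_scale": self.site_scale.to_dict(orient="split"),
            "liability": self.liability.to_dict(orient="split"),
        }
        Path(path).write_text(json.dumps(payload))


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_participants, config.n_proteins

    participants = pd.Index([f"P{i:06d}" for i in range(n)], name="participant")
    proteins = pd.Index([f"PROT{j:05d}" for j in range(p)], name="protein")

    # --- site assignment: mildly uneven contributor sizes -------------------
    site_names = [f"S{chr(65 + s)}" if config.n_sites <= 26 else f"S{s:02d}"
                  for s in range(config.n_sites)]
    site_probs = rng.dirichlet(np.full(config.n_sites, 10.0))
    site_idx = rng.choice(config.n_sites, size=n, p=site_probs)

    # --- covariates ---------------------------------------------------------
    age = np.clip(rng.normal(70.0, 8.0, n), 45.0, 90.0)
    sex = rng.integers(0, 2, n)  # 0 female, 1 male

    # --- labels from correlated latent liabilities: diseases mildly
    # co-occur (co-pathology), control runs against all of them ------------
    cov = config._liability_cov()
    liab = rng.multivariate_normal(np.zeros(6), cov, size=n, method="cholesky")
    prev = np.array([config.prevalence[c] for c in CONDITIONS])
    thresh = special.ndtri(1 - prev)
    y = (liab > thresh).astype(float)

    # --- planted multiplicative effects (disjoint sets) ---------------------
    planted_order = rng.permutation(p)
    effects = np.ones((p, 6))
    planted: dict[str, list[str]] = {}
    lo, hi = config.fold_change_range
    m = config.planted_proteins_per_condition
    for ci, cond in enumerate(CONDITIONS):
        idx = planted_order[ci * m:(ci + 1) * m]
        fc = rng.uniform(lo, hi, m)
        down = rng.random(m) < 0.5  # half the planted effects are decreases
        fc = np.where(down, 1.0 / fc, fc)
        effects[idx, ci] = fc
        planted[cond] = proteins[np.sort(idx)].tolist()

    # --- assemble log-abundance --------------------------------------------
    base = rng.normal(7.0, 1.0, p)                       # per-protein log level
    shift = rng.normal(0.0, config.site_shift_sd, (config.n_sites, p))
    scale = np.exp(rng.normal(0.0, config.site_scale_sd, (config.n_sites, p)))
    a_slope = rng.normal(0.0, config.age_effect_sd, p)   # per decade of age
    s_slope = rng.normal(0.0, config.sex_effect_sd, p)

    log_ab = np.tile(base, (n, 1))
    log_ab += y @ np.log(effects).T
    log_ab += shift[site_idx]
    log_ab += np.outer((age - 70.0) / 10.0, a_slope)
    log_ab += np.outer(sex.astype(float), s_slope)
    log_ab += rng.normal(0.0, config.measurement_noise_sd, (n, p)) * scale[site_idx]
    abundance = np.exp(log_ab)

    if config.missing_value_rate > 0:
        mcar = rng.random((n, p)) < config.missing_value_rate
        abundance[mcar] = np.nan

    # --- per-condition label missingness ------------------------------------
    labels = y.copy()
    for ci, cond in enumerate(CONDITIONS):
        rate = config.label_missing_rate[cond]
        if rate > 0:
            labels[rng.random(n) < rate, ci] = np.nan

    # --- cognition consistent with dementia status --------------------------
    dementing = (y[:, CONDITIONS.index("AD")] + y[:, CONDITIONS.index("FTD")]) > 0
    cdr = np.where(dementing, rng.choice([0.5, 1.0, 2.0], n, p=[0.3, 0.5, 0.2]), 0.0)
    blip = (~dementing) & (rng.random(n) < 0.05)
    cdr[blip] = 0.5
    mmse = np.clip(np.round(29.0 - 5.5 * cdr + rng.normal(0, 1.5, n)), 0, 30)
    mmse_missing = rng.random(n) < 0.05
    cdr_missing = rng.random(n) < 0.05
    mmse = np.where(mmse_missing, np.nan, mmse)
    cdr_obs = np.where(cdr_missing, np.nan, cdr)

    apoe_e4 = rng.binomial(2, 0.2 + 0.15 * y[:, CONDITIONS.index("AD")])
    apoe_e2 = rng.binomial(2, 0.07, n)

    phenotypes = pd.DataFrame(
        {
            "site": [site_names[s] for s in site_idx],
            "age": np.round(age, 1),
            "sex": sex,
            "mmse": mmse,
            "cdr": cdr_obs,
            "apoe_e2": apoe_e2,
            "apoe_e4": apoe_e4,
            "cdr_visits": pd.array([pd.NA] * n, dtype="string"),
        },
        index=participants,
    )
    cohort = Cohort(
        pd.DataFrame(abundance, index=participants, columns=proteins),
        phenotypes,
        pd.DataFrame(labels, index=participants, columns=list(CONDITIONS)),
    )
    truth = GroundTruth(
        effects=pd.DataFrame(effects, index=proteins, columns=list(CONDITIONS)),
        site_shift=pd.DataFrame(shift, index=site_names, columns=proteins),
        site_scale=pd.DataFrame(scale, index=site_names, columns=proteins),
        liability=pd.DataFrame(liab, index=participants, columns=list(CONDITIONS)),
        planted=planted,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Longitudinal progression labels
# ---------------------------------------------------------------------------

def make_progression_labels(
    cohort: Cohort,
    truth: GroundTruth,
    progression_fraction: float = 0.15,
    seed: int = 0,
    n_signal_proteins: int = 10,
    signal_coefficient: float = 0.8,
    n_visits: int = 3,
    blip_rate: float = 0.05,
) -> pd.DataFrame:
    """Flag a subset of baseline-CDR-0 participants as cognitive progressors.

    Progression probability follows a logistic link on the z-scored log
    abundance of the first ``n_signal_proteins`` proteins planted for AD, with
    coefficient ``signal_coefficient`` signed by each protein's planted effect
    direction (risk runs with the disease direction of the marker); the
    intercept is calibrated so the mean probability equals
    ``progression_fraction``.  Longitudinal CDR
    sequences are emitted consistently with the flags; a small fraction of
    stable participants receives a transient (non-monotone) CDR blip and is
    therefore excluded from the task, mirroring the non-decreasing-CDR
    eligibility rule.

    Returns a frame indexed by the baseline-CDR-0 participants with columns
    ``cdr_sequence`` (semicolon-joined), ``eligible`` and ``progressor``
    (NaN for excluded participants).
    """
    if not 0 <= progression_fraction < 1:
        raise ConfigurationError("progression_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    cdr = pd.to_numeric(cohort.phenotypes["cdr"], errors="coerce")
    base0 = cohort.participants[cdr == 0]
    if len(base0) == 0:
        raise ValueError("no participants with baseline CDR 0; progression task undefined")

    signal = truth.planted["AD"][:n_signal_proteins]
    x = np.log(cohort.abundance.loc[base0, signal].to_numpy())
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x)
    z = (x - col_mean) / np.nanstd(x, axis=0)
    direction = np.sign(np.log(truth.effects.loc[signal, "AD"].to_numpy()))
    score = (z * direction).sum(axis=1) * signal_coefficient

    if progression_fraction == 0:
        prob = np.zeros(len(base0))
    else:
        b0 = optimize.brentq(
            lambda b: special.expit(b + score).mean() - progression_fraction, -50, 50
        )
        prob = special.expit(b0 + score)
    progress = rng.random(len(base0)) < prob

    sequences = []
    for i in range(len(base0)):
        if progress[i]:
            step = rng.integers(1, n_visits)
            stage = rng.choice([0.5, 1.0], p=[0.7, 0.3])
            seq = [0.0] * step + [stage] * (n_visits - step)
        else:
            seq = [0.0] * n_visits
            if rng.random() < blip_rate and n_visits >= 3:
                j = rng.integers(1, n_visits - 1)
                seq[j] = 0.5  # transient blip -> non-monotone -> excluded
        sequences.append(seq)

    eligible = np.array([all(b >= a for a, b in zip(s, s[1:])) for s in sequences])
    out = pd.DataFrame(
        {
            "cdr_sequence": [";".join(f"{v:g}" for v in s) for s in sequences],
            "eligible": eligible,
            "progressor": np.where(eligible, progress.astype(float), np.nan),
        },
        index=base0,
    )
    return out


# ---------------------------------------------------------------------------
# Planted within-condition subtypes
# ---------------------------------------------------------------------------

def plant_condition_subtypes(
    cohort: Cohort,
    truth: GroundTruth,
    condition: str = "AD",
    cross_condition: str = "PD",
    n_cross_proteins: int = 16,
    n_extra_proteins: int = 8,
    shift: float = 2.5,
    seed: int = 0,
) -> tuple[Cohort, pd.Series, list[str]]:
    """Split one condition's positives into two proteomic subtypes.

    Subtype "B" (a random half of the positives) receives a multiplicative
    ``shift`` on ``n_cross_proteins`` proteins planted for ``cross_condition``,
    each applied in that protein's own disease direction (a coherent
    co-pathology-like profile, so the subtype's diagnostic probabilities move
    together), plus ``n_extra_proteins`` previously null proteins shifted
    upward.  Subtype B's ``cross_condition`` label is set missing — the
    co-pathology was never formally assessed, the label-missingness scenario
    the multi-task design exists for — so the trained model's
    ``cross_condition`` head responds freely to the planted profile.  Returns
    the modified cohort, the subtype assignment ('A'/'B' over the condition's
    positives) and the list of shifted protein ids.
    """
    rng = np.random.default_rng(seed)
    pos = cohort.participants[cohort.labels[condition] == 1.0]
    if len(pos) < 4:
        raise ValueError(f"too few positives for {condition!r} to plant subtypes")
    perm = rng.permutation(len(pos))
    b_ids = pos[np.sort(perm[: len(pos) // 2])]

    cross = truth.planted[cross_condition][:n_cross_proteins]
    planted_all = {pid for ids in truth.planted.values() for pid in ids}
    null_pool = [pid for pid in cohort.proteins if pid not in planted_all]
    extra = list(rng.choice(null_pool, size=n_extra_proteins, replace=False))
    shifted = list(cross) + extra

    ab = cohort.abundance.copy()
    cross_dir = np.sign(np.log(truth.effects.loc[cross, cross_condition].to_numpy()))
    factors = np.concatenate([shift ** cross_dir, np.full(len(extra), shift)])
    ab.loc[b_ids, shifted] = ab.loc[b_ids, shifted] * factors
    labels = cohort.labels.copy()
    labels.loc[b_ids, cross_condition] = np.nan
    subtype = pd.Series("A", index=pos, name="subtype")
    subtype.loc[b_ids] = "B"
    new = Cohort(ab, cohort.phenotypes, labels)
    return new, subtype, shifted
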