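"""Clinical translation: K-shot transfer, progression prediction, two-cutoff
calibration (with a brute-force oracle) and the individual report."""

import json

import numpy as np
import pandas as pd
import pytest

from protdx.clinic import (
    IndividualReport,
    apply_two_cutoff,
    fit_two_cutoff,
    individual_report,
    kshot_transfer,
    progression_task,
    shapley_attribution,
)
from protdx.cohortio import CONDITIONS
from protdx.syncohort import make_progression_labels


# ---------------------------------------------------------------------------
# Two-cutoff calibration
# ---------------------------------------------------------------------------

def brute_force_cutoffs(p, y, npv_t, ppv_t):
    uniq = np.unique(p)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    lower = upper = None
    for t in cands:
        below = p < t
        if below.any() and (y[below] == 0).mean() >= npv_t:
            lower = t
    for t in sorted(cands):
        above = p >= t
        if above.any() and (y[above] == 1).mean() >= ppv_t:
            upper = t
            break
    return lower, upper


class TestTwoCutoff:
    def test_toy_vector_matches_brute_force(self):
        p = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.9])
        y = np.array([0.0, 0.0, 0.0, 1.0, 0.0, 1.0])
        cut = fit_two_cutoff(p, y, target_npv=0.9, target_ppv=0.5)
        lo, hi = brute_force_cutoffs(p, y, 0.9, 0.5)
        assert cut.lower == pytest.approx(lo)
        assert cut.upper == pytest.approx(hi)

    def test_derivation_guarantees_hold(self, rng):
        p = rng.beta(2, 2, 1500)
        y = (rng.random(1500) < p).astype(float)
        cut = fit_two_cutoff(p, y)
        assert cut.derivation_npv >= 0.9
        assert cut.derivation_ppv >= 0.9
        zones = apply_two_cutoff(cut, p)
        assert (y[zones == "negative"] == 0).mean() >= 0.9
        assert (y[zones == "positive"] == 1).mean() >= 0.9
        assert cut.coverage == pytest.approx((zones != "indeterminate").mean())

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 200))
            p = rng.random(n)
            y = (rng.random(n) < p ** 0.7).astype(float)
            if y.min() == y.max():
                continue
            npv_t, ppv_t = rng.uniform(0.6, 0.95, 2)
            cut = fit_two_cutoff(p, y, npv_t, ppv_t)
            lo, hi = brute_force_cutoffs(p, y, npv_t, ppv_t)
            assert (cut.lower is None) == (lo is None)
            assert (cut.upper is None) == (hi is None)
            if lo is not None:
                assert cut.lower == pytest.approx(lo)
            if hi is not None:
                assert cut.upper == pytest.approx(hi)

    def test_perfect_separation_empty_indeterminate(self):
        p = np.array([0.05, 0.1, 0.15, 0.85, 0.9, 0.95])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        cut = fit_two_cutoff(p, y)
        assert cut.lower == cut.upper  # the zone [lower, upper) is empty
        assert cut.derivation_npv == 1.0
        assert cut.derivation_ppv == 1.0
        assert cut.coverage == 1.0
        zones = apply_two_cutoff(cut, p)
        assert (zones != "indeterminate").all()

    def test_crossed_cutoffs_flagged_with_warning(self):
        # loose targets make the NPV side overshoot the PPV side
        p = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="indeterminate"):
            cut = fit_two_cutoff(p, y, target_npv=0.5, target_ppv=0.5)
        assert cut.empty_indeterminate
        assert cut.lower > cut.upper
        zones = apply_two_cutoff(cut, p)
        assert (zones != "indeterminate").all()

    def test_alternative_ppv_target(self):
        p = np.array([0.1, 0.3, 0.5, 0.55, 0.6, 0.9])
        y = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        strict = fit_two_cutoff(p, y, target_ppv=0.9)
        loose = fit_two_cutoff(p, y, target_ppv=0.4)
        assert loose.upper <= (strict.upper or 1.0)

    def test_monotone_zones(self, rng):
        p = rng.random(300)
        y = (rng.random(300) < p).astype(float)
        cut = fit_two_cutoff(p, y, 0.8, 0.8)
        zones = apply_two_cutoff(cut, np.sort(p))
        order = {"negative": 0, "indeterminate": 1, "positive": 2}
        codes = [order[z] for z in zones]
        assert all(b >= a for a, b in zip(codes, codes[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_two_cutoff(np.array([0.2, 0.4]), np.array([1.0, 1.0]))


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

class TestShapley:
    def test_linear_model_closed_form(self, rng):
        d = 8
        w = rng.normal(0, 1, d)
        bg = rng.normal(0, 1, (200, d))
        x = rng.normal(0, 1, d)
        fn = lambda rows: rows @ w
        phi = shapley_attribution(fn, x, bg, n_perm=300, seed=0)
        expected = w * (x - bg.mean(axis=0))
        assert np.allclose(phi, expected, atol=0.15)

    def test_efficiency_property(self, rng):
        d = 6
        bg = rng.normal(0, 1, (100, d))
        x = rng.normal(0, 1, d)
        fn = lambda rows: np.tanh(rows[:, 0] * rows[:, 1]) + rows[:, 2] ** 2
        phi = shapley_attribution(fn, x, bg, n_perm=400, seed=1)
        gap = fn(x[None, :])[0] - fn(bg).mean()
        assert phi.sum() == pytest.approx(gap, abs=0.25)


# ---------------------------------------------------------------------------
# K-shot transfer
# ---------------------------------------------------------------------------

class TestKShot:
    def test_full_sample_limit_equals_plain_fit(self, small_cohort, small_model):
        from sklearn.linear_model import LogisticRegression
        from protdx.jointnet import predict
        from protdx.evalstats import balanced_accuracy

        cohort, _ = small_cohort
        sites = cohort.phenotypes["site"]
        new_site = sites.unique()[-1]
        ids = cohort.participants[sites == new_site]
        # K close to the full labelled pool: one repeat behaves like a plain
        # fit on (almost) all data, evaluated on the small remainder
        labels = cohort.labels.loc[ids, "control"]
        n_lab = labels.notna().sum()
        res = kshot_transfer(
            small_model, cohort, ids, K=n_lab - 21, repeats=1, seed=0,
            conditions=("control",),
        )
        assert set(res["approach"]) == {"FineTune", "Retrain"}
        assert res["bca"].between(0, 1).all()

    def test_repeats_and_conditions_reported(self, small_cohort, small_model):
        cohort, _ = small_cohort
        sites = cohort.phenotypes["site"]
        new_site = sites.value_counts().index[0]
        ids = cohort.participants[sites == new_site]
        res = kshot_transfer(
            small_model, cohort, ids, K=60, repeats=3, seed=1,
            conditions=("control", "AD"),
        )
        assert set(res["repeat"]) == {0, 1, 2}
        got = res.groupby(["condition", "approach"]).size()
        assert (got > 0).all()

    def test_reproducible_under_seed(self, small_cohort, small_model):
        cohort, _ = small_cohort
        sites = cohort.phenotypes["site"]
        ids = cohort.participants[sites == sites.unique()[0]]
        a = kshot_transfer(small_model, cohort, ids, K=50, repeats=2, seed=7,
                           conditions=("control",))
        b = kshot_transfer(small_model, cohort, ids, K=50, repeats=2, seed=7,
                           conditions=("control",))
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_site_rejected(self, small_cohort, small_model):
        cohort, _ = small_cohort
        ids = cohort.participants[:40]
        with pytest.raises(ValueError, match="K \\+ 20"):
            kshot_transfer(small_model, cohort, ids, K=100, repeats=1,
                           conditions=("control",))


# ---------------------------------------------------------------------------
# Progression
# ---------------------------------------------------------------------------

class TestProgression:
    def test_planted_signal_recovered(self, small_cohort, small_model):
        cohort, truth = small_cohort
        prog = make_progression_labels(cohort, truth, 0.2, seed=2)
        res = progression_task(small_model, cohort, prog, k=5)
        assert res["auc"] > 0.6
        assert res["n"] == int(prog["eligible"].sum())

    def test_shuffled_labels_near_chance(self, small_cohort, small_model, rng):
        cohort, truth = small_cohort
        prog = make_progression_labels(cohort, truth, 0.2, seed=2)
        shuffled = prog.copy()
        elig = shuffled["eligible"] & shuffled["progressor"].notna()
        vals = shuffled.loc[elig, "progressor"].to_numpy()
        shuffled.loc[elig, "progressor"] = rng.permutation(vals)
        res = progression_task(small_model, cohort, shuffled, k=5)
        assert abs(res["auc"] - 0.5) < 0.1

    def test_single_class_rejected(self, small_cohort, small_model):
        cohort, truth = small_cohort
        prog = make_progression_labels(cohort, truth, 0.0, seed=0)
        with pytest.raises(ValueError, match="single-class"):
            progression_task(small_model, cohort, prog)


# ---------------------------------------------------------------------------
# Individual report
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def report(small_cohort, small_split, small_model):
    cohort, _ = small_cohort
    tr, va, te = small_split.folds[0]
    return individual_report(
        small_model, cohort, te[0], pd.Index(tr[:120]), n_perm=24, seed=0
    )


class TestIndividualReport:
    def test_top_lists_sorted_and_bounded(self, report):
        for cond in CONDITIONS:
            pos = report.top_positive[cond]
            neg = report.top_negative[cond]
            assert len(pos) <= 10 and len(neg) <= 10
            assert all(v > 0 for _, v in pos)
            assert all(v < 0 for _, v in neg)
            assert [v for _, v in pos] == sorted(
                [v for _, v in pos], reverse=True
            )
            assert [v for _, v in neg] == sorted([v for _, v in neg])

    def test_normalized_probabilities_zero_centred_form(self, report):
        for cond in CONDITIONS:
            p = report.probabilities[cond]
            z = report.normalized_probabilities[cond]
            assert (z > 0) == (report.calls[cond] == 1)

    def test_json_round_trip_and_determinism(
        self, small_cohort, small_split, small_model, tmp_path
    ):
        cohort, _ = small_cohort
        tr, _, te = small_split.folds[0]
        r1 = individual_report(
            small_model, cohort, te[1], pd.Index(tr[:100]), n_perm=8, seed=5
        )
        r2 = individual_report(
            small_model, cohort, te[1], pd.Index(tr[:100]), n_perm=8, seed=5
        )
        assert r1.to_json() == r2.to_json()
        path = tmp_path / "report.json"
        r1.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["participant"] == te[1]
        assert set(payload["probabilities"]) == set(CONDITIONS)

    def test_small_background_warns(self, small_cohort, small_split, small_model):
        cohort, _ = small_cohort
        tr, _, te = small_split.folds[0]
        with pytest.warns(UserWarning, match="background"):
            individual_report(
                small_model, cohort, te[0], pd.Index(tr[:10]), n_perm=4, seed=0
            )

    def test_trait_table_joined(self, small_cohort, small_split, small_model):
        cohort, _ = small_cohort
        tr, _, te = small_split.folds[0]
        base = individual_report(
            small_model, cohort, te[0], pd.Index(tr[:60]), n_perm=8, seed=1
        )
        some_protein = base.top_positive["AD"][0][0]
        traits = pd.DataFrame(
            {"protein": [some_protein], "trait": ["grip strength"]}
        )
        rep = individual_report(
            small_model, cohort, te[0], pd.Index(tr[:60]), n_perm=8, seed=1,
            trait_table=traits,
        )
        assert rep.traits.get(some_protein) == ["grip strength"]
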