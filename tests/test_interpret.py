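"""Interpretation machinery: permutation importance, embedding covariance,
signatures, the probability map, clustering and cluster differential
abundance."""

import numpy as np
import pandas as pd
import pytest

from protdx.cohortio import CONDITIONS, Cohort
from protdx.interpret import (
    aggregate_importance,
    cluster_differential_abundance,
    cluster_map,
    eligible_single_diagnosis,
    embedding_protein_signature,
    haufe_importance,
    permfit,
    probability_map,
    project_onto_map,
)
from protdx import jointnet


@pytest.fixture(scope="module")
def fitted(small_cohort, small_split, small_model):
    cohort, truth = small_cohort
    _, _, te = small_split.folds[0]
    X_test = small_model.transform(cohort, pd.Index(te)).to_numpy()
    y_test = cohort.labels.loc[te].to_numpy(dtype=float)
    return cohort, truth, small_model, X_test, y_test


class TestPermfit:
    def test_only_panel_proteins_evaluated(self, fitted):
        cohort, _, model, X_test, y_test = fitted
        rep = permfit(model, X_test, y_test, n_perm=15, seed=0)
        evaluated = rep.index.get_level_values("protein").unique()
        assert set(evaluated) == set(model.panel)
        outside = set(cohort.proteins) - set(model.panel)
        assert not (set(evaluated) & outside)

    def test_planted_driver_significant_nulls_calibrated(self, fitted):
        cohort, truth, model, X_test, y_test = fitted
        rep = permfit(model, X_test, y_test, n_perm=60, seed=1)
        planted = {c: set(truth.planted[c]) for c in CONDITIONS}
        # strong planted proteins on the panel should surface for their own task
        hits, total = 0, 0
        for cond in CONDITIONS:
            on_panel = planted[cond] & set(model.panel)
            if not on_panel:
                continue
            sub = rep.xs(cond, level="condition").loc[sorted(on_panel)]
            hits += int((sub["p_adj"] < 0.05).sum())
            total += len(sub)
        assert total > 0 and hits / total > 0.5

    def test_ignored_column_has_no_importance(self, fitted):
        cohort, _, model, X_test, y_test = fitted
        import copy

        silenced = copy.deepcopy(model)
        silenced.net.W[0][0, :] = 0.0  # the network cannot see column 0
        rep = permfit(silenced, X_test, y_test, n_perm=10, seed=2)
        sub = rep.xs(model.panel[0], level="protein")
        assert np.allclose(sub["mean"], 0.0, atol=1e-5)

    def test_zero_sd_flagged(self, fitted):
        cohort, _, model, X_test, y_test = fitted
        X_const = X_test.copy()
        X_const[:, 3] = 1.23  # constant column: every permutation identical
        rep = permfit(model, X_const, y_test, n_perm=10, seed=3)
        sub = rep.xs(model.panel[3], level="protein")
        assert sub["sd_zero"].all()
        assert (sub["p"] == 0.5).all()


class TestAggregateImportance:
    def make_report(self, z, p_adj):
        idx = pd.MultiIndex.from_tuples(
            [("PR1", "AD")], names=["protein", "condition"]
        )
        return pd.DataFrame({"z": [z], "p_adj": [p_adj]}, index=idx)

    def test_fold_count_counts_significant_splits(self):
        reports = [self.make_report(2.0, 0.01) for _ in range(7)]
        reports += [self.make_report(0.1, 0.9) for _ in range(3)]
        agg = aggregate_importance(reports)
        row = agg.loc[("PR1", "AD")]
        assert row["fold_count"] == 7
        assert row["n_panels"] == 10

    def test_mean_z_over_panels_only(self):
        reports = [self.make_report(1.0, 0.5), self.make_report(3.0, 0.5)]
        agg = aggregate_importance(reports)
        assert agg.loc[("PR1", "AD"), "mean_z"] == pytest.approx(2.0)

    def test_absent_protein_absent_from_aggregate(self):
        agg = aggregate_importance([self.make_report(1.0, 0.5)])
        assert ("PR_OTHER", "AD") not in agg.index


class TestHaufe:
    def test_null_dimension_has_near_zero_covariance(self, rng):
        n = 4000
        emb = rng.standard_normal((n, 3))
        probs = 0.5 + 0.2 * np.tanh(emb[:, [0]])  # dim 1,2 unused
        h = haufe_importance(emb, probs)
        se = 1.0 * 0.2 / np.sqrt(n)
        assert abs(h[1, 0]) < 3 * se * 3
        assert abs(h[2, 0]) < 3 * se * 3
        assert h[0, 0] > 10 * se

    def test_linear_head_closed_form(self, rng):
        # purely linear single head: cov(z_j, w.z) = w_j var(z_j) for
        # independent dims
        n = 20000
        var = np.array([1.0, 4.0, 0.25])
        emb = rng.standard_normal((n, 3)) * np.sqrt(var)
        w = np.array([0.5, -0.2, 1.5])
        out = (emb @ w)[:, None]
        h = haufe_importance(emb, out)
        assert np.allclose(h[:, 0], w * var, rtol=0.1)
        assert np.all(np.sign(h[:, 0]) == np.sign(w))

    def test_bilinear_scaling(self, rng):
        emb = rng.standard_normal((500, 4))
        probs = rng.random((500, 2))
        h1 = haufe_importance(emb, probs)
        scaled = emb.copy()
        scaled[:, 2] *= 7.0
        h2 = haufe_importance(scaled, probs)
        assert np.allclose(h2[2], 7.0 * h1[2])


class TestEmbeddingSignature:
    def test_target_equal_to_one_protein_dominates(self, small_cohort, rng):
        # embeddings live on a roughly unit scale; the gain threshold assumes it
        cohort, _ = small_cohort
        panel = cohort.abundance.iloc[:, :30].fillna(
            cohort.abundance.iloc[:, :30].mean()
        )
        raw = panel.iloc[:, 7].to_numpy()
        target = (raw - raw.mean()) / raw.std()
        idx = np.arange(len(panel))
        sig = embedding_protein_signature(
            panel, target, idx[:450], idx[450:], gain_threshold=50.0
        )
        assert panel.columns[7] in sig
        assert len(sig) <= 5

    def test_noise_target_gives_tiny_signature(self, small_cohort, rng):
        cohort, _ = small_cohort
        panel = cohort.abundance.iloc[:, :30].fillna(
            cohort.abundance.iloc[:, :30].mean()
        )
        target = rng.standard_normal(len(panel))
        idx = np.arange(len(panel))
        sig = embedding_protein_signature(
            panel, target, idx[:450], idx[450:], gain_threshold=50.0
        )
        assert len(sig) <= 5


def synthetic_probability_frame(rng, n_per=120, sep=6.0):
    """Two diagnoses with disjoint probability supports."""
    rows, diags = [], []
    for d, cond in enumerate(("AD", "PD")):
        center = np.full(6, 0.2)
        center[d + 1] = 0.8  # AD and PD columns of CONDITIONS
        block = np.clip(center + rng.normal(0, 0.03, (n_per, 6)), 0.01, 0.99)
        rows.append(block)
        diags += [cond] * n_per
    probs = pd.DataFrame(
        np.vstack(rows),
        index=[f"P{i:04d}" for i in range(2 * n_per)],
        columns=list(CONDITIONS),
    )
    return probs, pd.Series(diags, index=probs.index)


class TestProbabilityMap:
    def test_disjoint_supports_separate(self, rng):
        probs, diag = synthetic_probability_frame(rng)
        pmap = probability_map(probs, diag, seed=0)
        from sklearn.metrics import silhouette_score

        sil = silhouette_score(
            pmap.coords.to_numpy(), (diag == "AD").astype(int).to_numpy()
        )
        assert sil > 0.5

    def test_fixed_seed_reproducible(self, rng):
        probs, diag = synthetic_probability_frame(rng, n_per=60)
        m1 = probability_map(probs, diag, seed=3)
        m2 = probability_map(probs, diag, seed=3)
        pd.testing.assert_frame_equal(m1.coords, m2.coords)

    def test_perplexity_capped_at_quarter_n(self, rng):
        probs, diag = synthetic_probability_frame(rng, n_per=60)
        pmap = probability_map(probs, diag, perplexity=1000.0, seed=0)
        assert pmap.perplexity == pytest.approx(len(probs) / 4)

    def test_too_few_participants_rejected(self, rng):
        probs, diag = synthetic_probability_frame(rng, n_per=20)
        with pytest.raises(ValueError, match="50"):
            probability_map(probs.iloc[:30], diag.iloc[:30], seed=0)

    def test_projection_lands_near_same_diagnosis(self, rng):
        probs, diag = synthetic_probability_frame(rng)
        pmap = probability_map(probs, diag, seed=0)
        new = probs.iloc[[0]] * 1.001  # essentially an AD-profile participant
        new.index = ["NEW"]
        proj = project_onto_map(pmap, new)
        ad_centroid = pmap.coords[diag == "AD"].mean()
        pd_centroid = pmap.coords[diag == "PD"].mean()
        d_ad = np.hypot(*(proj.iloc[0] - ad_centroid))
        d_pd = np.hypot(*(proj.iloc[0] - pd_centroid))
        assert d_ad < d_pd

    def test_eligibility_filter(self):
        labels = pd.DataFrame(
            [
                [1, 0, 0, 0, 0, 0],       # single positive -> eligible
                [0, 1, 1, 0, 0, 0],       # multi positive -> excluded
                [0, 0, 0, 0, 0, 0],       # all negative -> excluded
                [0, np.nan, 0, 1, 0, 0],  # single positive with missing -> eligible
            ],
            columns=list(CONDITIONS),
            index=["a", "b", "c", "d"],
        )
        diag = eligible_single_diagnosis(None, labels)
        assert diag.to_dict() == {"a": "control", "d": "FTD"}


class TestClusterMap:
    def test_two_planted_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        probs, diag = synthetic_probability_frame(rng)
        # split AD participants into two probability blobs (e.g. co-pathology)
        ad_idx = probs.index[diag == "AD"]
        half = ad_idx[: len(ad_idx) // 2]
        probs.loc[half, "stroke_TIA"] = np.clip(
            0.85 + rng.normal(0, 0.03, len(half)), 0.01, 0.99
        )
        pmap = probability_map(probs, diag, seed=1)
        labels, k = cluster_map(pmap, "AD", seed=0)
        assert k == 2
        truth = pd.Series(0, index=ad_idx)
        truth.loc[half] = 1
        assert adjusted_rand_score(truth[labels.index], labels) >= 0.8

    def test_degenerate_points_rejected(self):
        from protdx.interpret import ProbabilityMap

        coords = pd.DataFrame(
            np.ones((20, 2)), columns=["x", "y"],
            index=[f"P{i}" for i in range(20)],
        )
        diag = pd.Series(["AD"] * 20, index=coords.index)
        pmap = ProbabilityMap(coords, diag, coords, 5.0, 0)
        with pytest.raises(ValueError, match="degenerate"):
            cluster_map(pmap, "AD")


class TestClusterDifferentialAbundance:
    def build_cohort(self, rng, shift_proteins=(), shift=2.0):
        n, p = 240, 60
        idx = pd.Index([f"P{i:04d}" for i in range(n)])
        prots = [f"PR{j:02d}" for j in range(p)]
        ab = pd.DataFrame(rng.lognormal(5, 0.4, (n, p)), index=idx, columns=prots)
        clusters = pd.Series(np.repeat([0, 1], n // 2), index=idx)
        for prot in shift_proteins:
            ab.loc[clusters == 1, prot] *= shift
        ph = pd.DataFrame(
            {"site": rng.choice(["A", "B"], n), "age": rng.uniform(60, 80, n),
             "sex": rng.integers(0, 2, n)}, index=idx,
        )
        lab = pd.DataFrame(
            np.column_stack([np.zeros(n), np.ones(n)] + [np.zeros(n)] * 4),
            index=idx, columns=list(CONDITIONS),
        )
        return Cohort(ab, ph, lab), clusters

    def test_planted_cluster_shift_recovered(self, rng):
        shifted = [f"PR{j:02d}" for j in range(10)]
        cohort, clusters = self.build_cohort(rng, shifted, 2.0)
        res = cluster_differential_abundance(cohort, "AD", clusters)
        rec = (res.loc[shifted, "p_adj_c1"] < 0.05).mean()
        assert rec >= 0.8
        # multiplicative 2x; the average-protein-level covariate absorbs the
        # shared shift fraction m/p, so the expected coefficient is
        # log2 * (1 - 10/60)
        expected = np.log(2) * (1 - 10 / 60)
        assert np.median(res.loc[shifted, "logFC_c1"]) == pytest.approx(
            expected, abs=0.12
        )

    def test_permuted_labels_calibrated(self, rng):
        cohort, clusters = self.build_cohort(rng)
        permuted = pd.Series(
            rng.permutation(clusters.to_numpy()), index=clusters.index
        )
        res = cluster_differential_abundance(cohort, "AD", permuted)
        frac = (res["p_adj_c1"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res))

    def test_small_cluster_excluded(self, rng):
        cohort, clusters = self.build_cohort(rng)
        clusters.iloc[:3] = 2  # a 3-member cluster
        clusters.iloc[3:] = np.repeat([0, 1], (len(clusters) - 3) // 2 + 1)[: len(clusters) - 3]
        with pytest.warns(UserWarning, match="excluded"):
            res = cluster_differential_abundance(cohort, "AD", clusters)
        assert not any(c.endswith("_c2") for c in res.columns)
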