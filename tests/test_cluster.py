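"""PCA, conditional probabilities and silhouette-selected K-means."""

import numpy as np
import pandas as pd
import pytest

from emtime.cluster import (build_delta_profiles, build_median_profiles,
                            conditional_prob_high, kmeans_with_silhouette,
                            run_pca, top_contributors)
from emtime.scoring import (EMTScoreTable, GroupAssignment, compute_emt_score,
                            stratify_by_emt, GROUP_HIGH, GROUP_LOW)
from emtime.signatures import TimeMarkerTable


def _groups(labels, samples):
    return GroupAssignment(pd.Series(labels, index=samples), (0.0, 1.0))


def _table(values, markers, samples):
    df = pd.DataFrame(np.asarray(values, dtype=float), index=markers,
                      columns=samples)
    return TimeMarkerTable(df, pd.Series("cytokine", index=df.index))


def _balanced_groups(samples):
    n = len(samples)
    labels = (["low"] * (n // 4) + ["intermediate"] * (n // 2)
              + ["high"] * (n - n // 4 - n // 2))
    return _groups(labels, samples)


class TestMedianProfiles:
    def test_two_cohorts_three_groups_five_markers_shape(self, rng):
        samples = [f"s{i}" for i in range(12)]
        tables, groups = {}, {}
        for cid in ("A", "B"):
            tables[cid] = _table(rng.normal(size=(5, 12)),
                                 [f"m{i}" for i in range(5)], samples)
            groups[cid] = _balanced_groups(samples)
        med = build_median_profiles(tables, groups)
        assert med.shape == (6, 5)
        assert set(med.index.get_level_values("cohort")) == {"A", "B"}

    def test_constant_marker_cell_equals_the_constant(self):
        samples = [f"s{i}" for i in range(8)]
        tab = _table(np.full((1, 8), 3.5), ["m"], samples)
        med = build_median_profiles({"A": tab},
                                    {"A": _balanced_groups(samples)})
        assert (med["m"] == 3.5).all()

    def test_cells_match_sort_and_middle_median_oracle(self, rng):
        samples = [f"s{i}" for i in range(16)]
        vals = rng.normal(size=(3, 16))
        tab = _table(vals, ["x", "y", "z"], samples)
        grp = _balanced_groups(samples)
        med = build_median_profiles({"A": tab}, {"A": grp})
        for label in ("low", "intermediate", "high"):
            members = [samples.index(s) for s in grp.members(label)]
            for j, m in enumerate(("x", "y", "z")):
                col = np.sort(vals[j, members])
                k = len(col)
                oracle = (col[k // 2] if k % 2 else
                          0.5 * (col[k // 2 - 1] + col[k // 2]))
                assert med.loc[("A", label), m] == pytest.approx(oracle)

    def test_empty_group_error_names_cohort(self):
        samples = [f"s{i}" for i in range(8)]
        tab = _table(np.zeros((1, 8)), ["m"], samples)
        grp = _groups(["low"] * 4 + ["high"] * 4, samples)
        with pytest.raises(ValueError, match="cohort A.*intermediate"):
            build_median_profiles({"A": tab}, {"A": grp})

    def test_delta_profile_is_high_minus_low(self, rng):
        samples = [f"s{i}" for i in range(12)]
        tab = _table(rng.normal(size=(4, 12)),
                     [f"m{i}" for i in range(4)], samples)
        grp = _balanced_groups(samples)
        med = build_median_profiles({"A": tab}, {"A": grp})
        delta = build_delta_profiles({"A": tab}, {"A": grp})
        np.testing.assert_allclose(
            delta.loc["A"].to_numpy(),
            (med.loc[("A", "high")] - med.loc[("A", "low")]).to_numpy())


class TestPCA:
    def test_identical_columns_put_all_variance_on_pc1(self, rng):
        col = rng.normal(size=8)
        m = pd.DataFrame({"a": col, "b": col, "c": col})
        res = run_pca(m, standardize=True)
        assert res.explained_variance_pct.iloc[0] == pytest.approx(100.0)

    def test_2x2_matrix_matches_closed_form_eigenvalues(self):
        m = pd.DataFrame([[0.0, 0.0], [2.0, 1.0]], columns=["a", "b"])
        res = run_pca(m, standardize=False)
        # centered matrix [[-1,-.5],[1,.5]]; covariance [[2,1],[1,.5]];
        # eigenvalues 2.5 and 0
        assert res.explained_variance_pct.iloc[0] == pytest.approx(100.0)
        total_var = res.scores.var(ddof=1).sum()
        assert total_var == pytest.approx(2.5)

    def test_reconstruction_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(7, 4)),
                         columns=list("abcd"))
        res = run_pca(m, standardize=False)
        centered = m - m.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered.to_numpy(), atol=1e-10)

    def test_variance_pcts_nonincreasing_and_sum_100(self, rng):
        m = pd.DataFrame(rng.normal(size=(9, 5)))
        res = run_pca(m)
        pct = res.explained_variance_pct.to_numpy()
        assert np.all(np.diff(pct) <= 1e-9)
        assert pct.sum() == pytest.approx(100.0)
        np.testing.assert_allclose(res.contributions_pct.sum(axis=0), 100.0)

    def test_rows_with_missing_cells_dropped(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 3)))
        m.iloc[2, 1] = np.nan
        res = run_pca(m)
        assert len(res.scores) == 5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            run_pca(pd.DataFrame(np.ones((4, 3))), standardize=False)
        with pytest.raises(ValueError, match=">= 2"):
            run_pca(pd.DataFrame([[1.0, 2.0]]))


class TestTopContributors:
    def test_single_dominant_marker_ranks_first(self, rng):
        base = rng.normal(size=10)
        m = pd.DataFrame({"noise1": rng.normal(size=10) * 0.01,
                          "driver": base,
                          "noise2": rng.normal(size=10) * 0.01})
        res = run_pca(m, standardize=False)
        assert top_contributors(res, 1) == ["driver"]

    def test_full_ordering_matches_squared_loading_shares(self, rng):
        m = pd.DataFrame(rng.normal(size=(8, 6)),
                         columns=[f"m{i}" for i in range(6)])
        res = run_pca(m)
        order = top_contributors(res, 6)
        shares = (res.loadings["PC1"] ** 2 /
                  (res.loadings["PC1"] ** 2).sum() * 100)
        expected = sorted(shares.index, key=lambda k: (-shares[k], k))
        assert order == expected
        assert shares.loc[order].sum() == pytest.approx(100.0)

    def test_invalid_n_rejected(self, rng):
        res = run_pca(pd.DataFrame(rng.normal(size=(5, 3))))
        with pytest.raises(ValueError):
            top_contributors(res, 0)
        with pytest.raises(ValueError):
            top_contributors(res, 4)


class TestConditionalProb:
    def test_all_values_above_threshold_give_p1_everywhere(self):
        samples = [f"s{i}" for i in range(8)]
        marker = pd.Series(np.arange(8) + 10.0, index=samples, name="m")
        rows = conditional_prob_high(marker, _balanced_groups(samples),
                                     threshold=0.0)
        assert all(r.p_high_given_group == 1.0 for r in rows)

    def test_marker_equal_to_score_separates_groups_perfectly(self, rng):
        vals = rng.permutation(16).astype(float)
        scores = EMTScoreTable("X", pd.Series(
            vals, index=[f"s{i}" for i in range(16)]), 3, 13)
        groups = stratify_by_emt(scores)
        rows = {r.group: r for r in conditional_prob_high(
            scores.score.rename("m"), groups)}
        assert rows[GROUP_HIGH].p_high_given_group == 1.0
        assert rows[GROUP_LOW].p_high_given_group == 0.0

    def test_probabilities_match_exhaustive_counting(self, rng):
        samples = [f"s{i}" for i in range(20)]
        marker = pd.Series(rng.normal(size=20), index=samples, name="m")
        grp = _balanced_groups(samples)
        thr = float(np.median(marker))
        for r in conditional_prob_high(marker, grp):
            members = grp.members(r.group)
            oracle = sum(marker[s] >= thr for s in members) / len(members)
            assert r.p_high_given_group == pytest.approx(oracle)

    def test_law_of_total_probability_exact(self, rng):
        samples = [f"s{i}" for i in range(24)]
        marker = pd.Series(rng.normal(size=24), index=samples, name="m")
        grp = _balanced_groups(samples)
        rows = conditional_prob_high(marker, grp)
        total = sum(r.p_high_given_group * r.n_group / 24 for r in rows)
        overall = np.mean(marker >= rows[0].threshold_used)
        assert total == pytest.approx(overall, abs=1e-12)

    def test_empty_group_rejected(self, rng):
        samples = [f"s{i}" for i in range(8)]
        marker = pd.Series(rng.normal(size=8), index=samples, name="m")
        grp = _groups(["high"] * 4 + ["low"] * 4, samples)
        with pytest.raises(ValueError, match="intermediate"):
            conditional_prob_high(marker, grp)


def _blobs(rng, centers, n_per, n_markers=6, spread=1.0):
    rows, names = [], []
    for ci, c in enumerate(centers):
        for i in range(n_per):
            rows.append(c + rng.normal(0, spread, size=n_markers))
            names.append(f"C{ci}_{i}")
    return pd.DataFrame(rows, index=names,
                        columns=[f"m{i}" for i in range(n_markers)])


class TestKMeans:
    def test_two_planted_blobs_recovered(self, rng):
        centers = [np.zeros(6), np.full(6, 10.0)]  # 10 SD separation
        m = _blobs(rng, centers, n_per=11)
        res = kmeans_with_silhouette(m, seed=17)
        assert res.k_optimal == 2
        labels = res.assignments
        first = {c for c in labels.index if labels[c] == labels.iloc[0]}
        assert first in ({f"C0_{i}" for i in range(11)},
                         {f"C1_{i}" for i in range(11)})

    def test_three_planted_blobs_give_k3(self, rng):
        centers = [np.zeros(6), np.full(6, 10.0),
                   np.concatenate([np.full(3, -10.0), np.full(3, 10.0)])]
        m = _blobs(rng, centers, n_per=8)
        res = kmeans_with_silhouette(m, seed=17)
        assert res.k_optimal == 3

    def test_single_cloud_has_low_silhouette_and_stable_assignments(self, rng):
        m = _blobs(rng, [np.zeros(6)], n_per=20)
        r1 = kmeans_with_silhouette(m, seed=17)
        r2 = kmeans_with_silhouette(m, seed=99)
        assert r1.silhouette_by_k[2] < 0.3
        sil = [r1.silhouette_by_k[k] for k in sorted(r1.silhouette_by_k)]
        assert sil[0] == max(sil)  # silhouette decreases from K=2 upward
        assert r1.silhouette_by_k[2] == pytest.approx(
            r2.silhouette_by_k[2], abs=1e-9)

    def test_row_permutation_leaves_partition_invariant(self, rng):
        m = _blobs(rng, [np.zeros(4), np.full(4, 8.0)], n_per=6, n_markers=4)
        perm = m.sample(frac=1.0, random_state=3)
        r1 = kmeans_with_silhouette(m, seed=17)
        r2 = kmeans_with_silhouette(perm, seed=17)
        co1 = {frozenset(r1.assignments.index[r1.assignments == c])
               for c in set(r1.assignments)}
        co2 = {frozenset(r2.assignments.index[r2.assignments == c])
               for c in set(r2.assignments)}
        assert co1 == co2

    def test_k_range_must_start_at_2(self, rng):
        m = _blobs(rng, [np.zeros(4)], n_per=8, n_markers=4)
        with pytest.raises(ValueError, match=">= 2"):
            kmeans_with_silhouette(m, k_range=range(1, 4))
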