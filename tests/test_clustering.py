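import numpy as np
import pandas as pd
import pytest

from dichroma.clustering import (
    ClusterStats,
    cut_tree_k,
    detect_dichromatism,
    dichromatism_table,
    evaluate_cluster_criteria,
    remove_singletons,
    singleton_leaves,
    upgma,
)
from dichroma.errors import (
    DegenerateInputError,
    DegenerateRegionError,
    ParameterError,
)
from dichroma.visual_model import DistanceMatrix

from oracles import upgma_naive


def _random_metric(rng, n):
    pts = rng.uniform(0, 1, (n, 3))
    return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))


def _canonical_merges(Z, n):
    """Merge sequence as (frozenset of leaves, height) pairs."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_i, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_i] = merged
        out.append((merged, h))
    return out


def _dm(d, sexes, individuals=None, region="Abdomen", channel_dL=None):
    n = d.shape[0]
    individuals = individuals or [f"i{k}" for k in range(n)]
    meta = pd.DataFrame({
        "spectrum_id": [f"s{k}" for k in range(n)],
        "individual_id": individuals,
        "sex": list(sexes),
        "region": region,
        "patch_index": range(n),
    })
    return DistanceMatrix(ids=list(meta["spectrum_id"]), dS=d,
                          dL=d if channel_dL is None else channel_dL,
                          region=region, meta=meta)


class TestUpgma:
    def test_two_leaves_single_merge(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        Z = upgma(d)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.0)

    def test_three_leaf_hand_agglomeration(self):
        # d(A,B)=1, d(A,C)=4, d(B,C)=5: merge (A,B) at 1, then C at 4.5
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], float)
        Z = upgma(d)
        merges = _canonical_merges(Z, 3)
        assert merges[0] == (frozenset({0, 1}), pytest.approx(1.0))
        assert merges[1][0] == frozenset({0, 1, 2})
        assert merges[1][1] == pytest.approx(4.5)

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            d = _random_metric(rng, 8)
            Z = upgma(d)
            Zn = upgma_naive(d)
            got = _canonical_merges(Z, 8)
            want = _canonical_merges(Zn, 8)
            for (ga, gh), (wa, wh) in zip(got, want):
                assert ga == wa
                assert gh == pytest.approx(wh, rel=1e-10)

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(20)
        d = _random_metric(rng, 7)
        perm = rng.permutation(7)
        Z1 = _canonical_merges(upgma(d), 7)
        Z2 = _canonical_merges(upgma(d[np.ix_(perm, perm)]), 7)
        relabeled = [(frozenset(int(perm[i]) for i in s), h) for s, h in Z2]
        for (sa, ha), (sb, hb) in zip(Z1, relabeled):
            assert sa == sb
            assert ha == pytest.approx(hb, rel=1e-10)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ParameterError):
            upgma(d)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            Z = upgma(_random_metric(rng, 10))
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestCutTree:
    @pytest.fixture()
    def tree(self):
        rng = np.random.default_rng(22)
        d = _random_metric(rng, 5)
        return upgma(d), d

    def test_k1_all_one_cluster(self, tree):
        Z, _ = tree
        assert set(cut_tree_k(Z, 1)) == {0}

    def test_kn_all_singletons(self, tree):
        Z, _ = tree
        assert len(set(cut_tree_k(Z, 5))) == 5

    def test_k2_matches_last_merge(self, tree):
        Z, _ = tree
        labels = cut_tree_k(Z, 2)
        merges = _canonical_merges(Z, 5)
        # the two k=2 clusters are the children of the final merge
        penultimate = merges[-2][0]
        side = frozenset(np.flatnonzero(labels == labels[min(penultimate)]))
        assert side in (penultimate, frozenset(range(5)) - penultimate)

    def test_labels_contiguous_from_zero(self, tree):
        Z, _ = tree
        for k in range(1, 6):
            labels = cut_tree_k(Z, k)
            assert sorted(set(labels)) == list(range(k))

    def test_out_of_range_rejected(self, tree):
        Z, _ = tree
        with pytest.raises(ParameterError):
            cut_tree_k(Z, 0)
        with pytest.raises(ParameterError):
            cut_tree_k(Z, 6)


class TestSingletonRemoval:
    def _clustered_with_outliers(self, rng, outliers=()):
        # six tight triplets: every cut at k = 2..6 keeps groups intact,
        # so only planted far-away points can form singleton clusters
        centers = np.column_stack([np.arange(6) * 3.0, np.zeros(6)])
        pts = np.vstack([c + rng.normal(0, 0.01, (3, 2)) for c in centers])
        for k, i in enumerate(outliers):
            pts = np.insert(pts, i, [100.0 + 40 * k, 100.0], axis=0)
        return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))

    def test_single_outlier_excluded(self):
        rng = np.random.default_rng(23)
        d = self._clustered_with_outliers(rng, outliers=(3,))
        kept, excluded = remove_singletons(d)
        assert excluded == [3]
        assert kept.size == d.shape[0] - 1

    def test_no_singletons_identity(self):
        rng = np.random.default_rng(24)
        d = self._clustered_with_outliers(rng, outliers=())
        kept, excluded = remove_singletons(d)
        assert excluded == []
        assert kept.size == d.shape[0]

    def test_two_planted_outliers_both_excluded(self):
        rng = np.random.default_rng(25)
        d = self._clustered_with_outliers(rng, outliers=(2, 11))
        kept, excluded = remove_singletons(d)
        assert sorted(excluded) == [2, 11]

    def test_too_few_left_raises(self):
        # 5 points: 4 mutually close, 1 far; dropping >1 impossible here,
        # so shrink below 4 with a tiny all-spread matrix instead
        d = np.array([
            [0, 9, 9, 9],
            [9, 0, 9, 9],
            [9, 9, 0, 9],
            [9, 9, 9, 0.0],
        ])
        # every leaf is a singleton at k=4; removal would empty the region
        with pytest.raises(DegenerateRegionError):
            remove_singletons(d)


class TestCriteria:
    def _stats_for(self, jnd, pct_tot, pct_within, n=100):
        """Build a synthetic cut realising the given cluster statistics."""
        size = int(round(pct_tot / 100 * n))
        labels = np.array([0] * size + [1] * (n - size))
        n_major = int(round(pct_within / 100 * size))
        sexes = np.array(
            ["M"] * n_major + ["F"] * (size - n_major) + ["F"] * (n - size)
        )
        d = np.zeros((n, n))
        d[:size, size:] = jnd
        d[size:, :size] = jnd
        individuals = np.array([f"i{k}" for k in range(n)])
        stats = evaluate_cluster_criteria(labels, sexes, individuals, d)
        return stats[0]

    def test_qualifying_cluster(self):
        # strong male cluster: well separated, large, pure
        c = self._stats_for(jnd=5.91, pct_tot=47, pct_within=100)
        assert c.qualifies
        assert c.majority_sex == "M"
        assert c.jnd_to_rest == pytest.approx(5.91)

    def test_mixed_cluster_fails_purity(self):
        c = self._stats_for(jnd=3.88, pct_tot=65, pct_within=70)
        assert not c.qualifies
        assert c.pct_within == pytest.approx(70, abs=1)

    def test_small_cluster_fails_size(self):
        c = self._stats_for(jnd=10.0, pct_tot=5, pct_within=100)
        assert not c.qualifies

    def test_weak_separation_fails_jnd(self):
        c = self._stats_for(jnd=1.5, pct_tot=40, pct_within=100)
        assert not c.qualifies

    def test_inclusive_thresholds(self):
        c = self._stats_for(jnd=2.0, pct_tot=10, pct_within=90)
        assert c.qualifies

    def test_qualification_monotone_in_thresholds(self):
        rng = np.random.default_rng(26)
        n = 40
        labels = rng.integers(0, 3, n)
        sexes = np.where(rng.random(n) < 0.5, "M", "F")
        individuals = np.array([f"i{k % 7}" for k in range(n)])
        d = _random_metric(rng, n)
        base = evaluate_cluster_criteria(labels, sexes, individuals, d,
                                         thresholds=(80, 5, 0.2))
        stricter = evaluate_cluster_criteria(labels, sexes, individuals, d,
                                             thresholds=(90, 10, 0.4))
        for b, s in zip(base, stricter):
            if s.qualifies:
                assert b.qualifies

    def test_pct_males_counts_individuals_not_spectra(self):
        # 2 male individuals in region; only one contributes to cluster 0
        labels = np.array([0, 0, 1, 1])
        sexes = np.array(["M", "M", "M", "F"])
        individuals = np.array(["m1", "m1", "m2", "f1"])
        d = np.ones((4, 4)) - np.eye(4)
        stats = evaluate_cluster_criteria(labels, sexes, individuals, d)
        assert stats[0].pct_males == pytest.approx(50.0)


class TestDetector:
    def _planted_region(self, rng, n_per_sex=30, sep=6.0, frac_patch=0.3):
        """Male-only patch at `sep` JND from everything else."""
        n_patch = int(frac_patch * n_per_sex)
        pts = rng.normal(0, 0.15, (2 * n_per_sex, 1))
        pts[:n_patch] += sep  # first males carry the patch
        d = np.abs(pts - pts.T)
        sexes = ["M"] * n_per_sex + ["F"] * n_per_sex
        inds = [f"m{k % 5}" for k in range(n_per_sex)] + \
               [f"f{k % 5}" for k in range(n_per_sex)]
        return _dm(d, sexes, inds)

    def test_planted_male_patch_detected(self):
        rng = np.random.default_rng(27)
        dm = self._planted_region(rng)
        res = detect_dichromatism(dm, "dS")
        assert res.dichromatic
        assert res.cluster_sex == "M"
        assert res.best.pct_within == pytest.approx(100.0)
        assert res.tree_clust >= 2

    def test_null_region_not_flagged(self):
        rng = np.random.default_rng(28)
        flags = 0
        for _ in range(20):
            pts = rng.normal(0, 0.2, (40, 1))
            d = np.abs(pts - pts.T)
            dm = _dm(d, ["M"] * 20 + ["F"] * 20)
            flags += detect_dichromatism(dm, "dS").dichromatic
        assert flags <= 1

    def test_identical_spectra_classified_zero(self):
        d = np.zeros((12, 12))
        dm = _dm(d, ["M"] * 6 + ["F"] * 6)
        res = detect_dichromatism(dm, "dS", remove_outliers=False)
        assert res.tree_clust == 0

    def test_single_sex_region_rejected(self):
        rng = np.random.default_rng(29)
        d = _random_metric(rng, 8)
        dm = _dm(d, ["M"] * 8)
        with pytest.raises(DegenerateInputError):
            detect_dichromatism(dm, "dS")

    def test_reports_smallest_qualifying_k(self):
        rng = np.random.default_rng(30)
        dm = self._planted_region(rng, sep=8.0)
        res = detect_dichromatism(dm, "dS")
        assert res.tree_clust == min(c.k for c in res.all_qualifying)

    def test_report_table_schema(self):
        rng = np.random.default_rng(31)
        res = detect_dichromatism(self._planted_region(rng), "dS")
        table = dichromatism_table([res])
        assert list(table.columns) == [
            "region", "channel", "tree_clust", "JND",
            "pct_tot", "pct_within", "pct_males",
        ]
        assert table.loc[0, "tree_clust"] == res.tree_clust
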