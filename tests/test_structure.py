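"""Distances, UPGMA, PCoA and AMOVA against hand traces and independent
implementations (scipy average linkage, skbio PCoA, brute-force SS sums)."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

import corekit as ck
from conftest import random_genotypes


class TestBandMatrix:
    def test_heterozygote_bands(self, toy_genotypes):
        bands, cols = ck.band_matrix(toy_genotypes)
        assert cols == [("L1", 150), ("L1", 152), ("L1", 154)]
        assert bands[1].tolist() == [1, 1, 0]  # a2 = 150/152

    def test_homozygote_dosage_collapsed(self, toy_genotypes):
        bands, _ = ck.band_matrix(toy_genotypes)
        assert bands[0].tolist() == [1, 0, 0]  # a1 = 150/150

    def test_missing_call_flags_locus_columns_unknown(self):
        m = ck.MISSING
        calls = np.array([[[150, 152]], [[m, m]], [[150, 154]]], dtype=np.int64)
        gm = ck.GenotypeMatrix(("a", "b", "c"), ("L1",), calls)
        bands, _ = ck.band_matrix(gm)
        assert np.isnan(bands[1]).all()
        assert not np.isnan(bands[[0, 2]]).any()


class TestSimpleMatching:
    def test_identical_vectors(self):
        b = np.array([[1, 0, 1, 1], [1, 0, 1, 1]], dtype=float)
        d = ck.simple_matching_distance(b)
        assert d.values[0, 1] == 0.0

    def test_complementary_vectors(self):
        b = np.array([[1, 0, 1, 0, 1, 0], [0, 1, 0, 1, 0, 1]], dtype=float)
        assert ck.simple_matching_distance(b).values[0, 1] == 1.0

    def test_four_of_six_agree(self):
        b = np.array([[1, 1, 0, 0, 1, 0], [1, 1, 0, 0, 0, 1]], dtype=float)
        assert ck.simple_matching_distance(b).values[0, 1] == pytest.approx(1 - 4 / 6)

    def test_shared_absences_count_as_matches(self):
        b = np.array([[0, 0, 1], [0, 0, 1]], dtype=float)
        assert ck.simple_matching_distance(b).values[0, 1] == 0.0

    def test_unknown_columns_excluded_pairwise(self):
        b = np.array([[1, 0, np.nan], [1, 1, 0]])
        assert ck.simple_matching_distance(b).values[0, 1] == pytest.approx(0.5)

    def test_no_mutual_columns_is_error(self):
        b = np.array([[1, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="no known band columns"):
            ck.simple_matching_distance(b)

    def test_metric_bounded_on_complete_data(self):
        rng = np.random.default_rng(3)
        b = rng.integers(0, 2, size=(8, 20)).astype(float)
        d = ck.simple_matching_distance(b).values
        assert (d >= 0).all() and (d <= 1).all()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestUpgma:
    def test_two_leaves(self):
        d = ck.DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = ck.upgma(d)
        assert tree.root.height == pytest.approx(0.2)

    def test_three_point_hand_trace(self):
        # d(A,B)=0.2, d(A,C)=0.6, d(B,C)=0.4 -> (A,B) at 0.1, then C at 0.25
        vals = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.4], [0.6, 0.4, 0.0]])
        tree = ck.upgma(ck.DistanceMatrix(("A", "B", "C"), vals))
        assert tree.linkage[:, 2].tolist() == pytest.approx([0.2, 0.5])
        assert tree.root.height == pytest.approx(0.25)
        ab = next(c for c in tree.root.children if set(c.leaves()) == {"A", "B"})
        assert ab.height == pytest.approx(0.1)

    def test_tie_breaks_to_lowest_index_pair(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 0.2
        vals[2, 3] = vals[3, 2] = 0.2
        for i, j, v in [(0, 2, 0.8), (0, 3, 0.8), (1, 2, 0.8), (1, 3, 0.8)]:
            vals[i, j] = vals[j, i] = v
        tree = ck.upgma(ck.DistanceMatrix(("A", "B", "C", "D"), vals))
        assert tree.linkage[0, :2].tolist() == [0.0, 1.0]  # (A,B) merged first
        assert tree.linkage[1, :2].tolist() == [2.0, 3.0]

    def test_heights_non_decreasing_and_leafset(self, small_panel):
        tree = ck.upgma(ck.genetic_distance(small_panel))
        heights = tree.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert sorted(tree.root.leaves()) == sorted(small_panel.accession_ids)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(13)
        for n in (5, 8, 12):
            points = rng.normal(size=(n, 4))
            dv = pdist(points)
            ours = ck.upgma(
                ck.DistanceMatrix(tuple(f"s{i}" for i in range(n)), squareform(dv))
            )
            ref = linkage(dv, method="average")
            coph_ref = cophenet(ref)
            coph_ours = cophenet(ours.linkage)
            assert np.allclose(coph_ours, coph_ref, atol=1e-10)


class TestPcoa:
    def test_collinear_points_exact_embedding(self):
        coords = np.array([0.0, 1.0, 2.0])
        d = np.abs(coords[:, None] - coords[None, :])
        res = ck.pcoa(ck.DistanceMatrix(("a", "b", "c"), d))
        assert res.percent_explained[0] == pytest.approx(100.0)
        recovered = res.coordinates[:, 0]
        recovered = (recovered - recovered[0]) * np.sign(recovered[-1] - recovered[0])
        assert recovered == pytest.approx([0.0, 1.0, 2.0], abs=1e-9)

    def test_duplicated_accession_identical_coordinates(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 2]])
        d = squareform(pdist(pts))
        res = ck.pcoa(ck.DistanceMatrix(("a", "b", "b2", "c"), d))
        assert res.coordinates[1] == pytest.approx(res.coordinates[2], abs=1e-9)

    def test_three_dim_round_trip(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = ck.pcoa(ck.DistanceMatrix(tuple("abcdef"), d), n_axes=3)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d, atol=1e-9)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(7, 3))
        d2 = squareform(pdist(pts)) ** 2
        n = 7
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        res = ck.pcoa(ck.DistanceMatrix(tuple("abcdefg"), squareform(pdist(pts))))
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        ours = ck.pcoa(ck.DistanceMatrix(tuple("abcdefgh"), d), n_axes=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, list("abcdefgh")))
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1][:3], ref.eigvals.to_numpy()[:3], atol=1e-9
        )
        assert np.allclose(
            np.abs(ours.coordinates), np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-8
        )

    def test_n_axes_clipped_with_warning(self):
        d = squareform(pdist(np.arange(4.0)[:, None]))
        with pytest.warns(UserWarning, match="clipped"):
            ck.pcoa(ck.DistanceMatrix(tuple("abcd"), d), n_axes=10)


def brute_force_amova(d2, labels):
    """Direct-summation SS partition (independent of the implementation)."""
    n = len(labels)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in sorted(set(labels)):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]
        ) / len(idx)
    return ss_total - ss_within, ss_within


class TestAmova:
    def make(self, d2, ids):
        return ck.DistanceMatrix(ids, d2, "band_squared_euclidean")

    def test_fully_separated_populations(self):
        d2 = np.array(
            [
                [0, 0, 4, 4],
                [0, 0, 4, 4],
                [4, 4, 0, 0],
                [4, 4, 0, 0],
            ],
            dtype=float,
        )
        res = ck.amova(self.make(d2, ("a", "b", "c", "d")),
                       {"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        assert res.percent_among == pytest.approx(100.0)
        assert res.phi_pt == pytest.approx(1.0)

    def test_identical_individuals_degenerate(self):
        d2 = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="PhiPT reported as 0"):
            res = ck.amova(self.make(d2, ("a", "b", "c", "d")),
                           {"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        assert res.phi_pt == 0.0 and res.var_among == 0.0

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            pts = rng.normal(size=(6, 3))
            d2 = squareform(pdist(pts)) ** 2
            labels = ["p1", "p1", "p1", "p2", "p2", "p2"]
            res = ck.amova(self.make(d2, tuple("abcdef")), dict(zip("abcdef", labels)))
            ss_a, ss_w = brute_force_amova(d2, labels)
            assert res.ss_among == pytest.approx(ss_a, abs=1e-10)
            assert res.ss_within == pytest.approx(ss_w, abs=1e-10)
            assert res.percent_among + res.percent_within == pytest.approx(100.0)

    def test_unequal_sizes_match_brute_force(self):
        rng = np.random.default_rng(29)
        pts = rng.normal(size=(9, 2))
        d2 = squareform(pdist(pts)) ** 2
        labels = ["p1"] * 2 + ["p2"] * 3 + ["p3"] * 4
        ids = tuple(f"s{i}" for i in range(9))
        res = ck.amova(self.make(d2, ids), dict(zip(ids, labels)))
        ss_a, ss_w = brute_force_amova(d2, labels)
        assert res.ss_among == pytest.approx(ss_a, abs=1e-10)
        assert res.ss_within == pytest.approx(ss_w, abs=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(8, 2))
        d2 = squareform(pdist(pts)) ** 2
        ids = tuple(f"s{i}" for i in range(8))
        lab1 = dict(zip(ids, ["x"] * 4 + ["y"] * 4))
        lab2 = dict(zip(ids, ["north"] * 4 + ["south"] * 4))
        r1 = ck.amova(self.make(d2, ids), lab1)
        r2 = ck.amova(self.make(d2, ids), lab2)
        assert r1.phi_pt == pytest.approx(r2.phi_pt)

    def test_population_of_one_is_error(self):
        d2 = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="fewer than 2"):
            ck.amova(self.make(d2, ("a", "b", "c")), {"a": "p1", "b": "p1", "c": "p2"})

    def test_permutation_p_uniform_under_null(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(37)
        ids = tuple(f"s{i}" for i in range(16))
        pvals = []
        for rep in range(20):
            pts = rng.normal(size=(16, 3))
            d2 = squareform(pdist(pts)) ** 2
            labels = dict(zip(ids, rng.permutation(["p1"] * 8 + ["p2"] * 8)))
            res = ck.amova(self.make(d2, ids), labels, n_permutations=199, seed=rep)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPairwisePhiPt:
    def test_identical_populations_zero(self):
        base = np.array([[0, 1.0], [1.0, 0]])
        d2 = np.tile(base, (2, 2))
        np.fill_diagonal(d2, 0)
        ids = ("a1", "a2", "b1", "b2")
        dm = ck.DistanceMatrix(ids, d2, "band_squared_euclidean")
        with pytest.warns(UserWarning):
            out = ck.pairwise_phipt(dm, {"a1": "p1", "a2": "p1", "b1": "p2", "b2": "p2"})
        assert out.loc["p1", "p2"] == pytest.approx(0.0, abs=1e-9)

    def test_consistent_with_per_pair_amova(self, study_like_panel):
        gm = study_like_panel.genotypes.subset(
            study_like_panel.genotypes.accession_ids[::8]
        )
        pops = {a: study_like_panel.populations[a] for a in gm.accession_ids}
        dm = ck.genetic_distance(gm)
        table = ck.pairwise_phipt(dm, pops)
        pop_names = list(table.index)
        for i in range(len(pop_names)):
            for j in range(i + 1, len(pop_names)):
                ids = [a for a in gm.accession_ids
                       if pops[a] in (pop_names[i], pop_names[j])]
                res = ck.amova(dm.subset(ids), pops)
                assert table.loc[pop_names[i], pop_names[j]] == pytest.approx(res.phi_pt)
        assert np.allclose(table.to_numpy(), table.to_numpy().T)
        assert np.allclose(np.diag(table.to_numpy()), 0.0)
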