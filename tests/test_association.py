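import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu
from scipy.stats import rankdata

from tamkit.association import (LOWER, MIDDLE, UPPER, bulk_signature_scores,
                                composition_distance, dendrogram_to_newick,
                                hierarchical_cluster_means,
                                mann_whitney_u,
                                marker_percentile_membership, pcoa,
                                quartile_split, sample_signature_score,
                                spearman_cooccurrence)
from tamkit.core import GeneSignature
from tamkit.proportions import ProportionTable

from conftest import make_adata


class TestSampleSignatureScore:
    def test_constant_scores_pass_through(self):
        scores = pd.Series([0.3] * 6, index=[f"c{i}" for i in range(6)])
        samples = pd.Series(["s1"] * 3 + ["s2"] * 3, index=scores.index)
        out = sample_signature_score(scores, samples)
        assert np.allclose(out, 0.3)

    def test_two_sample_arithmetic(self):
        scores = pd.Series([0.0, 1.0, 1.0, 1.0],
                           index=[f"c{i}" for i in range(4)])
        samples = pd.Series(["a", "a", "b", "b"], index=scores.index)
        out = sample_signature_score(scores, samples)
        assert out["a"] == 0.5 and out["b"] == 1.0

    def test_median_statistic(self):
        scores = pd.Series([0.0, 0.1, 1.0], index=list("xyz"))
        samples = pd.Series(["s"] * 3, index=scores.index)
        assert sample_signature_score(scores, samples,
                                      statistic="median")["s"] == 0.1

    def test_bulk_mode_top_ranked_signature_scores_one(self):
        expr = pd.DataFrame([[9.0, 8.0, 1.0, 0.5, 0.2]],
                            index=["s1"],
                            columns=[f"g{i}" for i in range(5)])
        sig = GeneSignature("s", ("g0", "g1"))
        out = bulk_signature_scores(expr, sig, r_max=4)
        assert out["s1"] == 1.0


class TestQuartileSplit:
    def test_one_to_eight(self):
        scores = pd.Series(np.arange(1.0, 9.0),
                           index=[f"s{i}" for i in range(8)])
        strata = quartile_split(scores)
        # quantiles: q25 = 2.75, q75 = 6.25
        assert set(scores.index[strata == LOWER]) == {"s0", "s1"}
        assert set(scores.index[strata == UPPER]) == {"s6", "s7"}

    def test_all_equal_warns_with_empty_extremes(self):
        scores = pd.Series([2.0] * 6, index=[f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="equal"):
            strata = quartile_split(scores)
        assert (strata == MIDDLE).all()

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=20),
                           index=[f"s{i}" for i in range(20)])
        a = quartile_split(scores)
        b = quartile_split(scores + 17.3)
        assert (a == b).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            quartile_split(pd.Series([1.0, 2.0, 3.0]))


def enumerate_exact_p(x, y, u_obs):
    """Oracle: exact two-sided p by enumerating all group labellings."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    us = [sum(c) - n1 * (n1 + 1) / 2
          for c in itertools.combinations(ranks, n1)]
    us = np.array(us)
    p_ge = (us >= u_obs - 1e-9).mean()
    p_le = (us <= u_obs + 1e-9).mean()
    return min(1.0, 2 * min(p_ge, p_le))


class TestMannWhitneyU:
    def test_complete_separation(self):
        U, W, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert W == 6.0  # ranks 1+2+3
        # exact two-sided: 2 * 1/C(6,3) = 0.1
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0]
        U, W, p = mann_whitney_u(x, x)
        assert U == len(x) ** 2 / 2
        assert p == 1.0

    def test_exact_matches_independent_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.integers(0, 5, size=6).astype(float)
            y = rng.integers(0, 5, size=6).astype(float)
            U, W, p = mann_whitney_u(x, y)
            assert p == pytest.approx(enumerate_exact_p(x, y, U), abs=1e-12)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1, size=25)
        U, W, p = mann_whitney_u(x, y)
        ref = scipy_mwu(x, y, alternative="two-sided", method="asymptotic")
        assert U == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, _, p_exact = mann_whitney_u(x, y)
            _, _, p_norm = mann_whitney_u(x, y, exact_max_n=0)
            assert abs(p_exact - p_norm) < 0.02

    def test_one_sided_directions(self):
        _, _, p_greater = mann_whitney_u([4, 5, 6], [1, 2, 3],
                                         alternative="greater")
        _, _, p_less = mann_whitney_u([4, 5, 6], [1, 2, 3],
                                      alternative="less")
        assert p_greater < 0.1 < p_less

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _props(rows, clusters):
    samples = [f"s{i}" for i in range(len(rows))]
    frac = pd.DataFrame(rows, index=samples, columns=clusters)
    return ProportionTable(frac, pd.Series("x", index=samples),
                           pd.Series(100, index=samples))


class TestSpearmanCooccurrence:
    def test_monotone_relation_gives_unit_rho(self):
        rows = [[0.1, 0.2, 0.7], [0.2, 0.3, 0.5], [0.3, 0.4, 0.3],
                [0.35, 0.45, 0.2]]
        rho = spearman_cooccurrence(_props(rows, ["A", "B", "C"]))
        assert rho.loc["A", "B"] == pytest.approx(1.0)
        assert rho.loc["A", "C"] == pytest.approx(-1.0)

    def test_unit_diagonal(self):
        rng = np.random.default_rng(5)
        raw = rng.dirichlet(np.ones(4), size=6)
        rho = spearman_cooccurrence(_props(raw.tolist(), list("ABCD")))
        assert np.allclose(np.diag(rho), 1.0)

    def test_four_sample_toy_against_rank_oracle(self):
        rows = [[0.5, 0.5], [0.4, 0.6], [0.7, 0.3], [0.2, 0.8]]
        rho = spearman_cooccurrence(_props(rows, ["A", "B"]))
        a = rankdata([r[0] for r in rows])
        b = rankdata([r[1] for r in rows])
        expected = np.corrcoef(a, b)[0, 1]
        assert rho.loc["A", "B"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_cluster_warns_nan(self):
        rows = [[0.5, 0.2, 0.3], [0.5, 0.3, 0.2], [0.5, 0.25, 0.25]]
        with pytest.warns(UserWarning, match="zero-variance"):
            rho = spearman_cooccurrence(_props(rows, ["A", "B", "C"]))
        assert np.isnan(rho.loc["A", "B"])
        assert rho.loc["A", "A"] == 1.0


class TestPcoa:
    def test_recovers_planted_two_d_configuration(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(7, 2)) * 3
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, evals = pcoa(pd.DataFrame(D), n_axes=2)
        emb = coords.to_numpy()
        D_emb = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        assert np.allclose(D_emb, D, atol=1e-8)
        assert evals[evals < -1e-8].size == 0  # Euclidean-realizable

    def test_two_points_embed_at_plus_minus_half_distance(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        coords, _ = pcoa(D, n_axes=2)
        vals = sorted(coords.iloc[:, 0].tolist())
        assert vals == pytest.approx([-2.0, 2.0], abs=1e-10)

    def test_four_point_toy_against_eigen_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, evals = pcoa(D, n_axes=3)
        n = 4
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        ref_evals = np.sort(np.linalg.eigvalsh(B))[::-1]
        assert np.allclose(np.sort(evals)[::-1][:3], ref_evals[:3],
                           atol=1e-10)
        # embedded inner products reconstruct the centred Gram matrix
        assert np.allclose(coords.to_numpy() @ coords.to_numpy().T, B,
                           atol=1e-8)

    def test_matches_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours, evals = pcoa(D, n_axes=2)
        ref = skbio_pcoa(D, number_of_dimensions=2)
        assert np.allclose(np.abs(ours.to_numpy()),
                           np.abs(ref.samples.to_numpy()), atol=1e-8)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.zeros((3, 3)))


class TestHierarchicalClusterMeans:
    def test_identical_clusters_merge_at_zero(self):
        counts = np.tile([[5, 1, 0, 2]], (20, 1))
        adata = make_adata(counts, clusters=["a"] * 10 + ["b"] * 10)
        Z, labels = hierarchical_cluster_means(adata)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_line_geometry_first_merge(self):
        # cluster means on a line at 0, 1, 10 -> first merge joins {0, 1}
        counts = np.zeros((30, 1), dtype=int)
        counts[10:20] = 1
        counts[20:] = 10
        adata = make_adata(counts, clusters=["z0"] * 10 + ["z1"] * 10
                           + ["z9"] * 10, normalize=False)
        adata.layers["lognorm"] = counts.astype(float)
        Z, labels = hierarchical_cluster_means(adata)
        first = {labels[int(Z[0, 0])], labels[int(Z[0, 1])]}
        assert first == {"z0", "z1"}

    def test_four_cluster_merge_sequence_vs_bruteforce(self):
        rng = np.random.default_rng(9)
        means = rng.normal(size=(4, 6)) * 2
        counts = np.zeros((40, 6), dtype=int)
        adata = make_adata(counts, clusters=[f"k{i}" for i in range(4)
                                             for _ in range(10)],
                           normalize=False)
        layer = np.repeat(means, 10, axis=0)
        adata.layers["lognorm"] = layer
        Z, labels = hierarchical_cluster_means(adata, method="complete")

        # brute-force complete-linkage agglomeration oracle
        active = {i: [i] for i in range(4)}
        dist = {(i, j): np.linalg.norm(means[i] - means[j])
                for i in range(4) for j in range(i + 1, 4)}
        heights = []
        next_id = 4
        members = {i: [i] for i in range(4)}
        while len(active) > 1:
            best = min(((i, j) for i in active for j in active if i < j),
                       key=lambda ij: max(
                           np.linalg.norm(means[a] - means[b])
                           for a in members[ij[0]] for b in members[ij[1]]))
            h = max(np.linalg.norm(means[a] - means[b])
                    for a in members[best[0]] for b in members[best[1]])
            heights.append(h)
            members[next_id] = members.pop(best[0]) + members.pop(best[1])
            active.pop(best[0]); active.pop(best[1])
            active[next_id] = True
            next_id += 1
        assert np.allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-10)

    def test_newick_serialisation_is_wellformed(self):
        counts = np.random.default_rng(10).poisson(3, size=(30, 8))
        adata = make_adata(counts, clusters=["a"] * 10 + ["b"] * 10
                           + ["c"] * 10)
        Z, labels = hierarchical_cluster_means(adata)
        nwk = dendrogram_to_newick(Z, labels)
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
        for lab in labels:
            assert lab in nwk


class TestMarkerPercentileMembership:
    def _adata(self, expr_col, clusters):
        n = len(expr_col)
        counts = np.zeros((n, 2), dtype=int)
        adata = make_adata(counts, clusters=clusters, normalize=False)
        layer = np.zeros((n, 2))
        layer[:, 0] = expr_col
        adata.layers["lognorm"] = layer
        return adata

    def test_exclusive_marker_gives_pure_bins(self):
        expr = [0.0] * 10 + list(np.linspace(1, 2, 10))
        clusters = ["other"] * 10 + ["c"] * 10
        adata = self._adata(expr, clusters)
        out = marker_percentile_membership(adata, "g0", n_bins=5)
        assert np.allclose(out["c"], 1.0)

    def test_ordered_clusters_split_top_and_bottom(self):
        expr = list(np.linspace(0.1, 1, 10)) + list(np.linspace(5, 6, 10))
        clusters = ["low"] * 10 + ["high"] * 10
        out = marker_percentile_membership(self._adata(expr, clusters),
                                           "g0", n_bins=4)
        assert out.iloc[0]["low"] == 1.0
        assert out.iloc[-1]["high"] == 1.0

    def test_twenty_cell_interleaved_enumeration(self):
        # alternating clusters with strictly increasing expression: each
        # 2-cell bin holds one cell of each cluster
        expr = np.arange(1, 21, dtype=float)
        clusters = ["a", "b"] * 10
        out = marker_percentile_membership(self._adata(expr, clusters),
                                           "g0", n_bins=10)
        assert len(out) == 10
        assert np.allclose(out["a"], 0.5) and np.allclose(out["b"], 0.5)
        assert (out["n_cells"] == 2).all()

    def test_ties_collapse_into_lower_bin(self):
        expr = [1.0] * 6 + [2.0, 3.0]
        clusters = ["a"] * 6 + ["b", "b"]
        out = marker_percentile_membership(self._adata(expr, clusters),
                                           "g0", n_bins=4)
        # the six tied cells all fall into the first bin
        assert out["n_cells"].iloc[0] == 6

    def test_pooled_composition_matches_positive_cells(self):
        rng = np.random.default_rng(11)
        expr = np.round(rng.random(200) * rng.integers(0, 2, 200), 2)
        clusters = rng.choice(["a", "b", "c"], 200).tolist()
        adata = self._adata(expr, clusters)
        out = marker_percentile_membership(adata, "g0", n_bins=10)
        pooled = (out[["a", "b", "c"]].multiply(out["n_cells"], axis=0)
                  .sum() / out["n_cells"].sum())
        pos_mask = expr > 0
        ref = pd.Series(np.array(clusters)[pos_mask]) \
            .value_counts(normalize=True)
        for cl in ref.index:
            assert pooled[cl] == pytest.approx(ref[cl], abs=1e-12)
        assert np.allclose(out[["a", "b", "c"]].sum(axis=1), 1.0)

    def test_few_positive_cells_reduce_bins(self):
        expr = [0.0] * 18 + [1.0, 2.0]
        clusters = ["a"] * 19 + ["b"]
        with pytest.warns(UserWarning, match="reducing bins"):
            out = marker_percentile_membership(self._adata(expr, clusters),
                                               "g0", n_bins=100)
        assert len(out) == 2

    def test_unexpressed_gene_rejected(self):
        adata = self._adata([0.0, 0.0], ["a", "b"])
        with pytest.raises(ValueError, match="not expressed"):
            marker_percentile_membership(adata, "g0")


class TestCompositionDistance:
    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(12)
        raw = rng.dirichlet(np.ones(3), size=5)
        props = _props(raw.tolist(), list("ABC"))
        D = composition_distance(props)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
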