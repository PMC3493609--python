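"""Spearman matrices, MDS embedding, Hotelling ellipses, network builds."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidcohort.core import ValidationError
from lipidcohort.networks import (
    build_pathway_graph,
    build_pcn,
    correlation_distance,
    heatmap_matrix,
    hotelling_ellipse,
    mds_embed,
    rigid_align,
    spearman_exact,
    spearman_pair,
)
from tests.conftest import make_table


def _pairwise(coords):
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(-1))


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = np.arange(1.0, 11.0)
        t = make_table({"A": x, "B": np.exp(x)}, ["g0"] * 5 + ["g1"] * 5)
        pair = spearman_pair(t)
        assert pair.rho_group0.loc["A", "B"] == pytest.approx(1.0)
        assert pair.rho_group1.loc["A", "B"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(1.0, 9.0)
        t = make_table({"A": x, "B": x[::-1]}, ["g0"] * 4 + ["g1"] * 4)
        pair = spearman_pair(t)
        assert pair.rho_group0.loc["A", "B"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_formula_oracle(self, seed):
        """No-ties n=8: rho equals 1 - 6 sum(d^2) / (n(n^2-1))."""
        rng = np.random.default_rng(seed)
        x = rng.permutation(8).astype(float)
        y = rng.permutation(8).astype(float)
        d = stats.rankdata(x) - stats.rankdata(y)
        oracle = 1.0 - 6.0 * (d**2).sum() / (8 * 63)
        rho, _ = spearman_exact(x, y)
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_exact_p_by_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 2, 3, 5, 4])
        rho, p = spearman_exact(x, y)
        # oracle: enumerate all 120 permutations directly
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            1
            for perm in itertools.permutations(range(5))
            if abs(np.corrcoef(rx[list(perm)], ry)[0, 1]) >= obs - 1e-12
        )
        assert p == pytest.approx(count / 120)

    def test_constant_variable_masked(self):
        t = make_table(
            {"A": np.arange(1.0, 9.0), "B": [2.0] * 8}, ["g0"] * 4 + ["g1"] * 4
        )
        pair = spearman_pair(t)
        assert np.isnan(pair.rho_group0.loc["A", "B"])

    def test_rank_invariance_of_matrices(self, paper_cohort):
        """Strictly monotone per-variable transforms leave rho unchanged."""
        t = paper_cohort
        pair1 = spearman_pair(t, variables=t.metabolites[:6])
        from lipidcohort.core import CohortTable

        conc = t.concentrations.copy()
        for c in t.metabolites[:6]:
            conc[c] = np.exp(conc[c] / conc[c].max() * 3)
        t2 = CohortTable(conc, t.group, t.clinical, t.panel, t.group_order)
        pair2 = spearman_pair(t2, variables=t.metabolites[:6])
        pd.testing.assert_frame_equal(pair1.rho_group0, pair2.rho_group0)


class TestCorrelationDistance:
    def test_extremes(self):
        rho = pd.DataFrame([[1.0, -1.0, 0.0],
                            [-1.0, 1.0, 0.5],
                            [0.0, 0.5, 1.0]],
                           index=list("abc"), columns=list("abc"))
        d = correlation_distance(rho)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0
        assert d.loc["b", "c"] == 0.5

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, (6, 6))
        rho = pd.DataFrame((m + m.T) / 2)
        np.fill_diagonal(rho.values, 1.0)
        d = correlation_distance(rho).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all()


class TestMDS:
    def test_equilateral_configuration(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, stress = mds_embed(D, dims=2, method="classical")
        pd_ = _pairwise(coords)
        off = pd_[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0], atol=1e-6)
        assert stress < 1e-8

    def test_classical_recovers_planar_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (12, 2))
        D = _pairwise(pts)
        coords, stress = mds_embed(D, dims=2, method="classical")
        assert np.abs(_pairwise(coords) - D).max() < 1e-8
        assert stress < 1e-8

    def test_full_dimension_embedding_near_zero_stress(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (6, 5))
        D = _pairwise(pts)
        _, stress = mds_embed(D, dims=5, method="classical")
        assert stress < 1e-8

    def test_smacof_seeded_and_reasonable(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, (10, 2))
        D = _pairwise(pts)
        c1, s1 = mds_embed(D, dims=2, method="stress-majorization", seed=0)
        c2, s2 = mds_embed(D, dims=2, method="stress-majorization", seed=0)
        assert np.allclose(c1, c2)
        assert s1 < 0.05

    def test_dims_must_be_below_n(self):
        with pytest.raises(ValidationError):
            mds_embed(np.zeros((3, 3)), dims=3)

    def test_rigid_align_preserves_distances(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 2, (9, 2))
        out = rigid_align(coords, origin_index=0, quadrant_indices=[3, 4, 5])
        assert np.abs(_pairwise(out) - _pairwise(coords)).max() < 1e-10
        assert np.allclose(out[0], 0.0)
        cx, cy = out[[3, 4, 5]].mean(axis=0)
        assert cx > 0 and cy < 0  # lower-right quadrant


class TestHotellingEllipse:
    def test_isotropic_cloud_gives_circle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 1, (4000, 2))
        _, shape, _ = hotelling_ellipse(pts)
        evals = np.linalg.eigvalsh(shape)
        assert evals[1] / evals[0] < 1.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            hotelling_ellipse(np.zeros((3, 2)) + np.arange(6).reshape(3, 2))

    def test_coverage_calibrated(self):
        """95% prediction ellipse covers ~95% of a large bivariate
        normal sample."""
        rng = np.random.default_rng(6)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        pts = rng.multivariate_normal([1, -2], cov, size=5000)
        center, shape, radius = hotelling_ellipse(pts, alpha=0.05)
        z = pts - center
        m = np.einsum("ij,jk,ik->i", z, np.linalg.inv(shape), z)
        cover = float((m <= radius**2).mean())
        assert 0.93 <= cover <= 0.97


class TestBuildPCN:
    def test_default_thresholds_per_group(self, paper_cohort):
        g0, g1 = paper_cohort.group_order
        net0 = build_pcn(paper_cohort, g0, variables=paper_cohort.metabolites[:8])
        net1 = build_pcn(paper_cohort, g1, variables=paper_cohort.metabolites[:8])
        assert net0.p_threshold == 0.05
        assert net1.p_threshold == 0.01

    def test_edges_respect_threshold_and_nesting(self, paper_cohort):
        g1 = paper_cohort.group_order[1]
        strict = build_pcn(paper_cohort, g1, p_threshold=0.01,
                           variables=paper_cohort.metabolites[:10])
        loose = build_pcn(paper_cohort, g1, p_threshold=0.05,
                          variables=paper_cohort.metabolites[:10])
        assert all(e[3] < 0.01 for e in strict.edges)
        strict_pairs = {(e[0], e[1]) for e in strict.edges}
        loose_pairs = {(e[0], e[1]) for e in loose.edges}
        assert strict_pairs <= loose_pairs

    def test_perfectly_correlated_pair_always_connected(self):
        x = np.arange(1.0, 13.0)
        rng = np.random.default_rng(7)
        t = make_table(
            {"A": x, "B": x**2, "C": np.exp(rng.normal(0, 1, 12))},
            ["g0"] * 6 + ["g1"] * 6,
        )
        net = build_pcn(t, "g0", p_threshold=1e-6)
        assert ("A", "B") in {(e[0], e[1]) for e in net.edges}
        names = net.variables
        d = np.linalg.norm(
            net.coordinates[names.index("A")] - net.coordinates[names.index("B")]
        )
        assert d < 0.15

    def test_planted_correlation_blocks_embed_close(self):
        """Two rank-coupled variable blocks end up nearer within than
        between blocks in the embedding."""
        rng = np.random.default_rng(8)
        n = 40
        z1, z2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        cols = {}
        for i in range(4):
            cols[f"u{i}"] = np.exp(z1 + 0.3 * rng.normal(0, 1, n))
            cols[f"v{i}"] = np.exp(z2 + 0.3 * rng.normal(0, 1, n))
        t = make_table(cols, ["g0"] * 20 + ["g1"] * 20)
        net = build_pcn(t, "g0", p_threshold=0.05)
        names = net.variables
        co = net.coordinates
        u = [names.index(f"u{i}") for i in range(4)]
        v = [names.index(f"v{i}") for i in range(4)]
        within = np.mean(
            [np.linalg.norm(co[a] - co[b]) for a in u for b in u if a < b]
            + [np.linalg.norm(co[a] - co[b]) for a in v for b in v if a < b]
        )
        between = np.mean([np.linalg.norm(co[a] - co[b]) for a in u for b in v])
        assert within < between

    def test_glucose_at_origin(self, paper_cohort):
        net = build_pcn(
            paper_cohort,
            paper_cohort.group_order[1],
            variables=paper_cohort.metabolites[:10] + ["Glucose"],
        )
        g = net.variables.index("Glucose")
        assert np.allclose(net.coordinates[g], 0.0, atol=1e-12)


class TestHeatmap:
    def test_triangles_hold_the_right_groups(self, paper_cohort):
        vars6 = paper_cohort.metabolites[:6]
        pair = spearman_pair(paper_cohort, variables=vars6)
        hm = heatmap_matrix(pair, p_threshold=1.1)  # keep everything
        r0 = pair.rho_group0.to_numpy()
        r1 = pair.rho_group1.to_numpy()
        m = hm.to_numpy()
        iu = np.triu_indices(6, 1)
        il = np.tril_indices(6, -1)
        assert np.allclose(m[iu], r0[iu])
        assert np.allclose(m[il], r1[il])
        assert np.allclose(np.diag(m), 0)


class TestPathwayGraph:
    def test_node_size_ordering_matches_effect_magnitude(self, paper_cohort):
        from lipidcohort.indices import summarize_indices
        from lipidcohort.univariate import summarize_cohort

        univ = summarize_cohort(paper_cohort)
        idx = summarize_indices(paper_cohort)
        g = build_pathway_graph(univ, idx, paper_cohort).graph
        by_name = {r.metabolite: abs(r.delta_gm_pct) for r in univ}
        sizes = {n: d["size"] for n, d in g.nodes(data=True) if n in by_name}
        ordered = sorted(sizes, key=sizes.get)
        assert ordered == sorted(sizes, key=lambda n: by_name[n])

    def test_scd_edges_marked_increased(self, paper_cohort):
        from lipidcohort.indices import summarize_indices
        from lipidcohort.univariate import summarize_cohort

        univ = summarize_cohort(paper_cohort)
        idx = summarize_indices(paper_cohort)
        g = build_pathway_graph(univ, idx, paper_cohort).graph
        assert g.edges[("18:0", "18:1n9")]["direction"] == "increased"
        # SPCS axis falls in the diseased group
        assert g.edges[("22:4n6", "22:5n6")]["direction"] == "decreased"

    def test_edge_without_ratio_result_flagged(self, paper_cohort):
        from lipidcohort.univariate import summarize_cohort

        univ = summarize_cohort(paper_cohort)
        g = build_pathway_graph(univ, [], paper_cohort).graph
        assert all(d["missing_ratio"] for _, _, d in g.edges(data=True))
        assert all(d["width"] == 0.0 for _, _, d in g.edges(data=True))
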