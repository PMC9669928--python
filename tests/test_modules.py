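"""Module detection: clustering, tree cut, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from sclerolink import ExpressionMatrix
from sclerolink.errors import DegenerateModuleError, InvalidMatrixError
from sclerolink.modules import (
    GREY,
    ModuleAssignment,
    cluster_tom,
    dynamic_tree_cut,
    eigengene_adjacency,
    module_eigengene,
)
from sclerolink.network import TOMatrix


def tom_from(omega):
    omega = np.asarray(omega, dtype=float)
    return TOMatrix(omega=omega, analyte_ids=[f"A{i}" for i in range(omega.shape[0])])


def block_tom(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    omega = np.full((n, n), between)
    pos = 0
    for s in sizes:
        omega[pos : pos + s, pos : pos + s] = within
        pos += s
    np.fill_diagonal(omega, 1.0)
    return tom_from(omega)


def naive_average_linkage(d: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration oracle returning the cophenetic matrix."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros_like(d)
    while len(clusters) > 1:
        best, pair = np.inf, None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if h < best - 1e-15:
                    best, pair = h, (a, b)
        a, b = pair
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best
        clusters[a] = clusters[a] + clusters.pop(b)
    return coph


class TestClusterTom:
    def test_perfect_blocks_merge_internally_first(self):
        dend = cluster_tom(block_tom([4, 4]))
        heights = dend.heights
        # 6 within-block merges at height 0, final cross-block merge at 1
        assert np.allclose(heights[:6], 0.0)
        assert heights[-1] == pytest.approx(1.0)

    def test_three_items_closest_pair_first(self):
        omega = 1.0 - np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dend = cluster_tom(tom_from(omega))
        first = dend.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.1)

    def test_cophenetic_matches_naive_agglomeration_oracle(self, rng):
        omega = np.corrcoef(rng.normal(size=(10, 8))) ** 2
        np.fill_diagonal(omega, 1.0)
        dend = cluster_tom(tom_from(omega))
        d = 1.0 - omega
        np.fill_diagonal(d, 0.0)
        coph = squareform(cophenet(dend.merges))
        np.testing.assert_allclose(coph, naive_average_linkage(d), atol=1e-10)

    def test_asymmetric_input_rejected(self):
        omega = np.eye(3)
        omega[0, 1] = 0.5
        with pytest.raises(InvalidMatrixError):
            cluster_tom(tom_from(omega))


class TestDynamicTreeCut:
    def test_two_clean_blocks_no_grey(self):
        assign = dynamic_tree_cut(cluster_tom(block_tom([50, 50])), min_size=30)
        sizes = assign.sizes()
        assert sorted(sizes.values()) == [50, 50]
        assert (assign.labels == 0).sum() == 0

    def test_uniform_noise_never_yields_small_modules(self, rng):
        # weak random overlaps: modules of >= 30 cannot form below the cut
        omega = np.abs(np.corrcoef(rng.normal(size=(40, 12)))) ** 7
        np.fill_diagonal(omega, 1.0)
        assign = dynamic_tree_cut(cluster_tom(tom_from(omega)), min_size=30)
        assert len(assign.module_ids) <= 1
        for size in assign.sizes().values():
            assert size >= 30

    def test_min_size_exceeding_leaves_gives_all_grey(self, caplog):
        with caplog.at_level("WARNING"):
            assign = dynamic_tree_cut(cluster_tom(block_tom([10])), min_size=30)
        assert set(assign.labels) == {0}

    def test_modules_ordered_by_size_with_stable_colors(self):
        assign = dynamic_tree_cut(cluster_tom(block_tom([30, 45, 60])), min_size=30)
        sizes = assign.sizes()
        assert [sizes[m] for m in sorted(sizes)] == [60, 45, 30]
        colors = [assign.colors[m] for m in sorted(sizes)]
        assert len(set(colors)) == 3 and GREY not in colors

    def test_quantile_mode(self):
        dend = cluster_tom(block_tom([40, 40], within=0.9, between=0.1))
        assign = dynamic_tree_cut(dend, min_size=30, cut_quantile=0.5)
        assert len(assign.module_ids) == 2

    def test_permuting_analytes_preserves_partition(self, rng, small_study):
        from sklearn.metrics import adjusted_rand_score

        from sclerolink.network import NetworkConfig, adjacency, topological_overlap

        expr = small_study.prot_blister
        perm = rng.permutation(len(expr.analytes))
        expr_p = expr.subset_analytes([expr.analytes[i] for i in perm])

        def modules_of(e):
            tom = topological_overlap(adjacency(e, NetworkConfig()))
            return dynamic_tree_cut(cluster_tom(tom), min_size=30)

        a1, a2 = modules_of(expr), modules_of(expr_p)
        joint = a1.labels.to_frame("x").join(a2.labels.rename("y"))
        assert adjusted_rand_score(joint["x"], joint["y"]) == pytest.approx(1.0)


class TestModuleEigengene:
    def make_expr(self, values):
        return ExpressionMatrix(
            pd.DataFrame(values, index=[f"A{i}" for i in range(len(values))],
                         columns=[f"S{j}" for j in range(np.asarray(values).shape[1])])
        )

    def assign_all(self, n, min_size=2):
        labels = pd.Series(1, index=[f"A{i}" for i in range(n)])
        return ModuleAssignment(labels=labels, colors={0: GREY, 1: "turquoise"}, min_size=min_size)

    def test_identical_analytes_give_common_profile(self, rng):
        profile = rng.normal(size=9)
        expr = self.make_expr([profile, profile, profile])
        mes = module_eigengene(expr, self.assign_all(3))
        zp = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(mes.me.loc["turquoise"], zp, atol=1e-10)

    def test_matches_full_svd_oracle(self, rng):
        values = rng.normal(size=(7, 12))
        expr = self.make_expr(values)
        mes = module_eigengene(expr, self.assign_all(7))
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
        # oracle: eigenvector of the sample-space covariance
        evals, evecs = np.linalg.eigh(z.T @ z)
        pc = evecs[:, -1]
        pc = pc / pc.std(ddof=1)
        got = mes.me.loc["turquoise"].to_numpy()
        assert min(np.abs(got - pc).max(), np.abs(got + pc).max()) < 1e-8

    def test_negation_symmetry(self, rng):
        values = rng.normal(size=(6, 10))
        flipped = values.copy()
        flipped[:3] *= -1
        m1 = module_eigengene(self.make_expr(values), self.assign_all(6))
        m2 = module_eigengene(self.make_expr(flipped), self.assign_all(6))
        c = np.corrcoef(m1.me.loc["turquoise"], m2.me.loc["turquoise"])[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_rule(self, rng):
        values = rng.normal(size=(5, 11))
        mes = module_eigengene(self.make_expr(values), self.assign_all(5))
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
        c = np.corrcoef(mes.me.loc["turquoise"], z.mean(axis=0))[0, 1]
        assert c > 0

    def test_single_analyte_module_rejected(self, rng):
        expr = self.make_expr(rng.normal(size=(1, 8)))
        labels = pd.Series([1], index=["A0"])
        with pytest.raises(DegenerateModuleError):
            module_eigengene(expr, ModuleAssignment(labels=labels, colors={1: "blue"}))


class TestEigengeneAdjacency:
    def test_duplicated_and_orthogonal_modules(self, rng, small_result):
        mes = small_result.skin.eigengenes
        adj = eigengene_adjacency(mes)
        assert np.allclose(np.diag(adj.to_numpy()), 1.0)
        # elementwise oracle
        from sclerolink.stats import spearman
        for i, a in enumerate(mes.modules):
            for j, b in enumerate(mes.modules):
                if i < j:
                    ref = spearman(mes.me.loc[a], mes.me.loc[b]).rho
                    assert adj.loc[a, b] == pytest.approx(ref, abs=1e-12)

    def test_duplicate_module_correlation_one(self, rng):
        from sclerolink.modules import EigengeneSet
        e = rng.normal(size=12)
        me = pd.DataFrame([e, e], index=["blue", "red"], columns=[f"S{i}" for i in range(12)])
        adj = eigengene_adjacency(EigengeneSet(me=me))
        assert adj.loc["blue", "red"] == pytest.approx(1.0)
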