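import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from cytoborder import (DistanceMatrix, distance_matrix, make_laminar_model,
                        mds_embed, mean_area_feature, render_ribbon, upgma_tree)
from cytoborder.borders import profile_features
from cytoborder.similarity import _stress1


def dm(labels, values):
    return DistanceMatrix(tuple(labels), np.asarray(values, dtype=float))


class TestMeanAreaFeature:
    def sections(self, noise, seed=0):
        m = make_laminar_model([0.25, 0.5, 0.25], [0.6, 0.3, 0.5], noise)
        return [render_ribbon([m], [60], seed=seed + k).profiles for k in range(3)]

    def test_identical_profiles_mean_equals_single(self):
        secs = self.sections(noise=0.0)
        mean = mean_area_feature(secs, n_per_section=45, seed=1)
        single = profile_features(secs[0][:1])[0]
        assert np.allclose(mean, single)

    def test_seed_stability_on_homogeneous_profiles(self):
        secs = self.sections(noise=0.02)
        m1 = mean_area_feature(secs, seed=1)
        m2 = mean_area_feature(secs, seed=2)
        # different subsamples of one distribution agree within sampling noise
        feats = profile_features(np.vstack(secs))
        sem = feats.std(axis=0, ddof=1) / np.sqrt(135)
        assert np.all(np.abs(m1 - m2) < 5 * sem + 1e-12)

    def test_insufficient_profiles_rejected(self):
        secs = self.sections(noise=0.0)
        secs[1] = secs[1][:44]
        with pytest.raises(ValueError, match="44"):
            mean_area_feature(secs, n_per_section=45)


class TestDistanceMatrix:
    def test_identical_vectors_zero(self):
        v = np.arange(10.0)
        d = distance_matrix({"a": v, "b": v.copy()})
        assert d.values[0, 1] == 0.0

    def test_three_four_five(self):
        a = np.zeros(10)
        b = np.zeros(10); b[0], b[1] = 3.0, 4.0
        d = distance_matrix({"a": a, "b": b})
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop(self, rng):
        table = {f"x{i}": rng.normal(size=10) for i in range(6)}
        d = distance_matrix(table)
        for i, ki in enumerate(table):
            for j, kj in enumerate(table):
                brute = np.sqrt(np.sum((table[ki] - table[kj]) ** 2))
                assert d.values[i, j] == pytest.approx(brute, abs=1e-12)

    def test_label_permutation_consistency(self, rng):
        table = {f"x{i}": rng.normal(size=10) for i in range(5)}
        d1 = distance_matrix(table)
        order = list(table)[::-1]
        d2 = distance_matrix({k: table[k] for k in order})
        perm = [list(d1.labels).index(k) for k in d2.labels]
        assert np.allclose(d2.values, d1.values[np.ix_(perm, perm)])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix({"a": np.zeros(10), "b": np.full(10, np.nan)})


class TestMDS:
    def test_recovers_exactly_embeddable_configuration(self, rng):
        pts = rng.normal(size=(5, 2)) * 3
        d = dm([f"p{i}" for i in range(5)], squareform(pdist(pts)))
        emb = mds_embed(d, dims=2, seed=0)
        assert emb.stress < 1e-6
        assert np.allclose(squareform(pdist(emb.coords)), d.values, atol=1e-6)

    def test_stress_rotation_invariant(self, rng):
        pts = rng.normal(size=(6, 2))
        d = dm([f"p{i}" for i in range(6)], squareform(pdist(pts)))
        emb = mds_embed(d, dims=2, seed=0)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert _stress1(emb.coords @ rot, d.values) == pytest.approx(emb.stress, abs=1e-12)
        assert _stress1(emb.coords * [1, -1], d.values) == pytest.approx(emb.stress, abs=1e-12)

    def test_simplex_matches_direct_optimizer(self):
        # four points, all pairwise distances 1: not embeddable in 2D
        d = dm(list("abcd"), np.ones((4, 4)) - np.eye(4))
        emb = mds_embed(d, dims=2, n_restarts=8, seed=0)

        def objective(flat):
            return _stress1(flat.reshape(4, 2), d.values)

        rng = np.random.default_rng(3)
        best = min(minimize(objective, rng.normal(size=8), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000}).fun
                   for _ in range(5))
        assert emb.stress == pytest.approx(best, abs=1e-3)

    def test_dims_validation(self):
        d = dm(list("ab"), [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            mds_embed(d, dims=2)

    def test_centred_output(self, rng):
        pts = rng.normal(size=(7, 3))
        d = dm([f"p{i}" for i in range(7)], squareform(pdist(pts)))
        emb = mds_embed(d, dims=2, seed=1)
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-9)


def brute_force_upgma(labels, values):
    """Exhaustive greedy UPGMA used as the enumeration oracle."""
    clusters = {i: [i] for i in range(len(labels))}
    d = {frozenset((i, j)): values[i, j]
         for i, j in itertools.combinations(range(len(labels)), 2)}
    heights = {}
    merges = []
    nxt = len(labels)
    while len(clusters) > 1:
        (i, j), dist = min(d.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        i, j = sorted((min(kv for kv in (i, j)),) + tuple({x for x in (i, j)} - {min(i, j)}))
        merges.append((sorted(clusters[i] + clusters[j]), dist / 2))
        ni, nj = len(clusters[i]), len(clusters[j])
        for k in clusters:
            if k in (i, j):
                continue
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            d[frozenset((nxt, k))] = (ni * dik + nj * djk) / (ni + nj)
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        d = {key: v for key, v in d.items() if not (key & {i, j})}
        nxt += 1
    return merges


class TestUPGMA:
    def test_two_taxa(self):
        tree = upgma_tree(dm(["a", "b"], [[0, 4], [4, 0]]))
        assert len(tree.merges) == 1
        assert tree.merges[0][2] == pytest.approx(2.0)
        assert tree.to_newick() == "(a:2,b:2);"

    def test_three_taxa_hand_computed(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6: (A,B) joins at height 1, C at height 3
        tree = upgma_tree(dm(list("ABC"), [[0, 2, 6], [2, 0, 6], [6, 6, 0]]))
        heights = [m[2] for m in tree.merges]
        assert heights == pytest.approx([1.0, 3.0])
        assert tree.to_newick() == "((A:1,B:1):2,C:3);"

    def test_matches_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(42)
        for n in (3, 4, 5, 6):
            for _ in range(10):
                vals = squareform(rng.random(n * (n - 1) // 2) + 0.1)
                labels = [f"t{i}" for i in range(n)]
                tree = upgma_tree(dm(labels, vals))
                oracle = brute_force_upgma(labels, vals)
                mine = [(sorted(self.members(tree, k)), m[2])
                        for k, m in enumerate(tree.merges)]
                for (mem_a, h_a), (mem_b, h_b) in zip(mine, oracle):
                    assert mem_a == mem_b
                    assert h_a == pytest.approx(h_b, abs=1e-12)

    @staticmethod
    def members(tree, merge_idx):
        n = tree.n_leaves
        groups = {i: [i] for i in range(n)}
        for k, (a, b, _, _) in enumerate(tree.merges[: merge_idx + 1]):
            groups[n + k] = groups.pop(a) + groups.pop(b)
        return groups[n + merge_idx]

    def test_cophenetic_exact_on_ultrametric_input(self):
        # build an ultrametric matrix from a known tree, then recover it
        linkage = hierarchy.linkage(np.array([1.0, 4.0, 4.0, 8.0, 8.0, 8.0,
                                              8.0, 8.0, 8.0, 8.0]), "average")
        ultra = squareform(hierarchy.cophenet(linkage))
        tree = upgma_tree(dm(list("vwxyz"), ultra))
        assert np.allclose(tree.cophenetic_matrix(), ultra, atol=1e-12)

    def test_agrees_with_scipy_average_linkage(self, rng):
        vals = squareform(rng.random(15) + 0.1)
        tree = upgma_tree(dm([f"t{i}" for i in range(6)], vals))
        link = hierarchy.linkage(squareform(vals, checks=False), "average")
        assert np.allclose(sorted(m[2] * 2 for m in tree.merges),
                           sorted(link[:, 2]), atol=1e-12)

    def test_ultrametric_heights_non_decreasing(self, rng):
        vals = squareform(rng.random(28) + 0.1)
        tree = upgma_tree(dm([f"t{i}" for i in range(8)], vals))
        heights = [m[2] for m in tree.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))


class TestTwoFamilySplit:
    def area_features(self, seed):
        """Seven synthetic areas from two laminar families (dorsal/ventral-like)."""
        rng = np.random.default_rng(seed)
        flat = np.array([0.50, 0.42, 0.38, 0.46, 0.44])       # weak layering
        peaked = np.array([0.62, 0.30, 0.55, 0.28, 0.50])     # strong layering
        table = {}
        for i, name in enumerate(["d1", "d2", "d3"]):
            dens = np.clip(flat + rng.normal(0, 0.01, 5), 0, 1)
            m = make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2], dens, 0.02, name)
            profs = [render_ribbon([m], [60], seed=seed * 100 + i * 3 + k).profiles
                     for k in range(3)]
            table[name] = mean_area_feature(profs, seed=seed + i)
        for i, name in enumerate(["v1", "v2", "v3", "r1"]):
            dens = np.clip(peaked + rng.normal(0, 0.01, 5), 0, 1)
            m = make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2], dens, 0.02, name)
            profs = [render_ribbon([m], [60], seed=seed * 100 + 20 + i * 3 + k).profiles
                     for k in range(3)]
            table[name] = mean_area_feature(profs, seed=seed + 10 + i)
        return table

    def test_dorsal_ventral_families_split_into_two_clusters(self):
        for seed in range(10):
            table = self.area_features(seed)
            d = distance_matrix(table)
            tree = upgma_tree(d)
            clusters = tree.cut(2)
            assert sorted(map(sorted, clusters)) == [["d1", "d2", "d3"],
                                                     ["r1", "v1", "v2", "v3"]]
            emb = mds_embed(d, seed=seed)
            coords = dict(zip(emb.labels, emb.coords))
            within, between = [], []
            for a, b in itertools.combinations(table, 2):
                dist = np.linalg.norm(coords[a] - coords[b])
                (within if a[0] == b[0] else between).append(dist)
            assert np.mean(between) > np.mean(within)
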