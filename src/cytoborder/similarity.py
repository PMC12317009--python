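"""Inter-areal cytoarchitectonic similarity.

Each area is summarised by the average of feature vectors sampled from its
laminar profiles (the mapping protocol uses 45 profiles from each of three
sections per hemisphere and area).  Pairwise Euclidean distances between
these mean vectors feed a two-dimensional metric MDS (SMACOF, stress-1)
for visualisation and a UPGMA dendrogram for grouping areas into clusters
such as the dorsal/ventral premotor division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .borders import profile_features

logger = logging.getLogger(__name__)


def mean_area_feature(section_profiles: list[np.ndarray], n_per_section: int = 45,
                      seed: int | None = None,
                      depth_grid: np.ndarray | None = None) -> np.ndarray:
    """Average feature vector of profiles sampled from several sections.

    From each section's profile matrix, ``n_per_section`` profiles are drawn
    without replacement (seed-deterministic); the ten-element feature
    vectors of all sampled profiles are averaged elementwise.
    """
    if not section_profiles:
        raise ValueError("need at least one section of profiles")
    rng = np.random.default_rng(seed)
    feats = []
    for k, profs in enumerate(section_profiles):
        profs = np.asarray(profs, dtype=float)
        if profs.shape[0] < n_per_section:
            raise ValueError(
                f"section {k} supplies {profs.shape[0]} profiles; need {n_per_section}")
        pick = rng.choice(profs.shape[0], size=n_per_section, replace=False)
        feats.append(profile_features(profs[pick], depth_grid))
    return np.concatenate(feats).mean(axis=0)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match the number of labels")
        if not np.allclose(v, v.T, atol=1e-12) or np.any(np.diag(v) != 0) or v.min() < 0:
            raise ValueError("matrix must be symmetric, non-negative, zero-diagonal")
        self.values = 0.5 * (v + v.T)

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def distance_matrix(table: dict[str, np.ndarray], standardize: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distances between per-area feature vectors.

    ``standardize`` z-scores each feature across areas before computing
    distances (off by default; the ten moments have very different scales,
    so this flag matters for which features dominate).
    """
    if len(table) < 2:
        raise ValueError("need at least two areas")
    labels = tuple(table.keys())
    X = np.stack([np.asarray(table[lab], dtype=float) for lab in labels])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return DistanceMatrix(labels=labels, values=squareform(pdist(X)))


# ---------------------------------------------------------------------------
# metric MDS (SMACOF) with stress-1
# ---------------------------------------------------------------------------

@dataclass
class MDSEmbedding:
    labels: tuple[str, ...]
    coords: np.ndarray          # (n, dims), centred at the origin
    stress: float               # normalised stress-1


def _stress1(coords: np.ndarray, d: np.ndarray) -> float:
    dhat = pdist(coords)
    dcond = squareform(d, checks=False)
    return float(np.sqrt(np.sum((dhat - dcond) ** 2) / np.sum(dcond**2)))


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centring solution; exact for embeddable distances."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def mds_embed(dmat: DistanceMatrix, dims: int = 2, n_restarts: int = 8,
              seed: int | None = None, max_iter: int = 500,
              tol: float = 1e-12) -> MDSEmbedding:
    """Least-squares metric MDS minimising normalised stress-1.

    SMACOF majorisation iterations; the first start is the classical
    (Torgerson) solution and the remaining ``n_restarts - 1`` starts are
    random. The best configuration over all starts is returned, centred at
    the origin.
    """
    d = dmat.values
    n = d.shape[0]
    if dims >= n:
        raise ValueError("dims must be smaller than the number of labels")
    rng = np.random.default_rng(seed)
    scale = d.max() if d.max() > 0 else 1.0
    best_coords, best_stress = None, np.inf
    for r in range(max(n_restarts, 1)):
        if r == 0:
            x = _classical_mds(d, dims)
        else:
            x = rng.normal(0.0, scale / 2.0, (n, dims))
        stress = _stress1(x, d)
        for _ in range(max_iter):
            full = squareform(pdist(x))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(full > 0, d / full, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x_new = (b @ x) / n                      # Guttman transform
            new_stress = _stress1(x_new, d)
            if abs(stress - new_stress) < tol * max(stress, 1e-30):
                x, stress = x_new, new_stress
                break
            x, stress = x_new, new_stress
        if stress < best_stress:
            best_stress, best_coords = stress, x
    best_coords = best_coords - best_coords.mean(axis=0)
    return MDSEmbedding(labels=dmat.labels, coords=best_coords, stress=best_stress)


# ---------------------------------------------------------------------------
# UPGMA clustering with Newick export
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge history; ultrametric node heights (= merge distance / 2).

    ``merges`` lists (left child, right child, height, size) where children
    index leaves 0..n-1 and internal nodes n, n+1, ... in merge order, as in
    a linkage matrix.
    """
    labels: tuple[str, ...]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> dict[int, float]:
        h = {i: 0.0 for i in range(self.n_leaves)}
        for k, (_, _, height, _) in enumerate(self.merges):
            h[self.n_leaves + k] = height
        return h

    def to_newick(self) -> str:
        h = self.heights()
        children = {self.n_leaves + k: (a, b) for k, (a, b, _, _) in enumerate(self.merges)}

        def min_leaf(node: int) -> int:
            if node < self.n_leaves:
                return node
            return min(min_leaf(c) for c in children[node])

        def render(node: int) -> str:
            if node < self.n_leaves:
                return self.labels[node]
            a, b = sorted(children[node], key=min_leaf)
            return (f"({render(a)}:{h[node] - h[a]:.10g},"
                    f"{render(b)}:{h[node] - h[b]:.10g})")

        root = self.n_leaves + len(self.merges) - 1
        return render(root) + ";"

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise cophenetic distances (2x the height of the joining node)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        out = np.zeros((n, n))
        for k, (a, b, height, _) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    out[i, j] = out[j, i] = 2.0 * height
            members[n + k] = members.pop(a) + members.pop(b)
        return out

    def cut(self, n_clusters: int) -> list[set[str]]:
        """Leaf label sets after undoing the last ``n_clusters - 1`` merges."""
        n = self.n_leaves
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.merges[: n - n_clusters]):
            members[n + k] = members.pop(a) | members.pop(b)
        return [{self.labels[i] for i in grp} for grp in members.values()]


def upgma_tree(dmat: DistanceMatrix) -> Dendrogram:
    """Agglomerative UPGMA (arithmetic-mean linkage) dendrogram.

    At each step the closest pair of clusters merges at height = distance/2;
    the distance of the merged cluster to any other is the size-weighted
    mean of its parts' distances.  Ties between closest pairs are broken by
    the lexicographically smallest pair of cluster ids and logged.
    """
    n = len(dmat.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    d = {(i, j): dmat.values[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = min(d[key] for key in
                   ((min(a, b), max(a, b)) for ai, a in enumerate(active)
                    for b in active[ai + 1:]))
        pairs = sorted((min(a, b), max(a, b)) for ai, a in enumerate(active)
                       for b in active[ai + 1:]
                       if d[(min(a, b), max(a, b))] == best)
        i, j = pairs[0]
        if len(pairs) > 1:
            logger.info("UPGMA tie at distance %g; merging %s", best, (i, j))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(k, next_id), max(k, next_id))] = (ni * dik + nj * djk) / (ni + nj)
        merges.append((i, j, best / 2.0, ni + nj))
        sizes[next_id] = ni + nj
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Dendrogram(labels=dmat.labels, merges=merges)
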