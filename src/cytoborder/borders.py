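"""Observer-independent detection of cytoarchitectonic borders.

The laminar GLI profile of a cortical area is summarised by a ten-element
feature vector of central moments.  Differences between neighbouring blocks
of profiles are measured with the Mahalanobis distance computed with a
sliding window along the cortical ribbon; the significance of distance
maxima is assessed with a two-sample Hotelling T-squared test and a
Bonferroni correction over sliding positions.  Maxima that are significant
across several block sizes mark borders between areas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

N_FEATURES = 10


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean weight, centroid, sd, skewness, kurtosis) of position x weighted by w.

    Skewness is standardised by sd**3 and kurtosis by sd**4.  A degenerate
    weight distribution (zero spread) reports skewness and kurtosis as 0;
    an all-zero weight vector reports the centre of the grid as centroid and
    zero spread.
    """
    mean_w = float(np.mean(w))
    total = float(np.sum(w))
    if total <= 0.0:
        # no mass at all: centroid pinned at the grid centre, spread zero
        warnings.warn("zero-mass weight vector; moments degenerate to centre/zero",
                      RuntimeWarning, stacklevel=3)
        return mean_w, float(0.5 * (x[0] + x[-1])), 0.0, 0.0, 0.0
    mu = float(np.sum(x * w) / total)
    var = float(np.sum(w * (x - mu) ** 2) / total)
    sd = float(np.sqrt(var))
    if sd == 0.0:
        warnings.warn("zero spread in weighted moments; skew/kurtosis set to 0",
                      RuntimeWarning, stacklevel=3)
        return mean_w, mu, 0.0, 0.0, 0.0
    skew = float(np.sum(w * (x - mu) ** 3) / total / sd**3)
    kurt = float(np.sum(w * (x - mu) ** 4) / total / sd**4)
    return mean_w, mu, sd, skew, kurt


def feature_vector(profile: np.ndarray, depth_grid: np.ndarray | None = None) -> np.ndarray:
    """Ten-element shape descriptor of one laminar GLI profile.

    Elements 0-4 are the mean density, depth centroid (mean x), standard
    deviation, skewness and kurtosis of the profile treated as a weight
    distribution over normalised depth; elements 5-9 are the same five
    statistics of the absolute first difference of the profile (evaluated on
    the midpoints of the depth grid).

    Parameters
    ----------
    profile:
        GLI values along one traverse, ordered from the outer (layer I/II)
        to the inner (layer VI / white matter) contour.
    depth_grid:
        Normalised depths of the samples; defaults to bin centres on [0, 1].
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("profile must be one-dimensional with at least 4 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("profile contains non-finite values")
    if depth_grid is None:
        depth_grid = (np.arange(y.size) + 0.5) / y.size
    x = np.asarray(depth_grid, dtype=float)
    if x.shape != y.shape:
        raise ValueError("depth_grid must match profile length")
    if np.sum(y) <= 0.0:
        raise ValueError("all-zero profile: moment weights undefined")
    dy = np.abs(np.diff(y))
    xm = 0.5 * (x[:-1] + x[1:])
    return np.array(_weighted_moments(x, y) + _weighted_moments(xm, dy))


def profile_features(profiles: np.ndarray, depth_grid: np.ndarray | None = None) -> np.ndarray:
    """Feature vectors for every row of an (n_traverses, depth_bins) matrix."""
    profiles = np.asarray(profiles, dtype=float)
    return np.stack([feature_vector(p, depth_grid) for p in profiles])


# ---------------------------------------------------------------------------
# Mahalanobis distance functions and the Hotelling T-squared test
# ---------------------------------------------------------------------------

@dataclass
class DistanceFunction:
    """Mahalanobis distance vs. profile position for one block size.

    ``positions[i]`` is the traverse index splitting the two compared blocks:
    the left block covers traverses [k-b, k) and the right block [k, k+b).
    ``pvalues`` are Hotelling T-squared p values Bonferroni-multiplied by the
    number of sliding positions and capped at 1.
    """
    block_size: int
    positions: np.ndarray
    md: np.ndarray
    pvalues: np.ndarray
    pvalues_raw: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def hotelling_p(md2: np.ndarray, n1: int, n2: int, dim: int = N_FEATURES) -> np.ndarray:
    """p value of the two-sample Hotelling T-squared test given squared MD.

    T2 = (n1*n2/(n1+n2)) * MD^2 is referred to an F distribution with
    (dim, n1+n2-dim-1) degrees of freedom via the standard scaling.
    """
    md2 = np.asarray(md2, dtype=float)
    n = n1 + n2
    if n - dim - 1 <= 0:
        raise ValueError("blocks too small for a Hotelling test in this dimension")
    t2 = (n1 * n2 / n) * md2
    f = (n - dim - 1) / ((n - 2) * dim) * t2
    return stats.f.sf(f, dim, n - dim - 1)


def _sliding_sums(arr: np.ndarray, width: int) -> np.ndarray:
    """Sums of ``arr`` over sliding windows of ``width`` rows (axis 0)."""
    c = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
    return c[width:] - c[:-width]


def md_function(profiles: np.ndarray, block_size: int, *,
                depth_grid: np.ndarray | None = None,
                features: np.ndarray | None = None,
                shrinkage: float = 0.0) -> DistanceFunction:
    """Sliding-window Mahalanobis distance between adjacent profile blocks.

    At each admissible position k, the mean feature vectors of the blocks
    [k-b, k) and [k, k+b) are compared with the Mahalanobis distance using
    the pooled within-block sample covariance of the per-profile feature
    vectors.  Significance comes from the Hotelling T-squared test with a
    Bonferroni correction over the sliding positions.

    ``shrinkage`` in [0, 1) blends the pooled covariance towards a scaled
    identity (lambda * mean-variance * I) for near-singular cases.
    """
    if features is None:
        features = profile_features(profiles, depth_grid)
    feats = np.asarray(features, dtype=float)
    n, p = feats.shape
    b = int(block_size)
    if 2 * b > n:
        raise ValueError(f"block size {b} too large for {n} traverses")
    if 2 * b - 2 <= p and shrinkage <= 0.0:
        raise ValueError(
            f"block size {b} gives a singular pooled covariance for {p} features; "
            "enable shrinkage or use a larger block")

    # standardising each feature over the ribbon leaves the Mahalanobis
    # distance unchanged (affine invariance) but canonicalises the floating
    # point computation, so equivalent inputs give near-identical output
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    zfeats = (feats - mu) / sd

    # sliding sums of features and their outer products give every block's
    # mean and scatter matrix in O(n p^2)
    sums = _sliding_sums(zfeats, b)                                  # (n-b+1, p)
    outer = zfeats[:, :, None] * zfeats[:, None, :]
    osums = _sliding_sums(outer, b)                                  # (n-b+1, p, p)
    means = sums / b
    scatter = osums - b * means[:, :, None] * means[:, None, :]

    # position k corresponds to left block starting at k-b: left window index
    # k-b, right window index k, for k in [b, n-b]
    left = np.arange(0, n - 2 * b + 1)
    right = left + b
    d = means[right] - means[left]
    pooled = (scatter[left] + scatter[right]) / (2 * b - 2)
    if shrinkage > 0.0:
        tr = np.maximum(np.trace(pooled, axis1=1, axis2=2) / p, 1e-12)
        eye = np.eye(p)
        pooled = (1.0 - shrinkage) * pooled + shrinkage * tr[:, None, None] * eye

    # blocks with bitwise-identical member features are at distance exactly
    # zero regardless of covariance conditioning (noise-free ribbons); the
    # check is exact, immune to cumulative-sum roundoff in the block means
    pair_eq = np.all(feats[:-b] == feats[b:], axis=1).astype(int)
    eq_csum = np.concatenate([[0], np.cumsum(pair_eq)])
    zero_d = (eq_csum[b:] - eq_csum[:-b])[left] == b
    zero_d |= np.all(d == 0.0, axis=1)
    md2 = np.zeros(len(d))
    active = ~zero_d
    if active.any():
        try:
            sol = np.linalg.solve(pooled[active], d[active, :, None])[..., 0]
            md2[active] = np.maximum(np.einsum("ij,ij->i", d[active], sol), 0.0)
        except np.linalg.LinAlgError:
            for i in np.nonzero(active)[0]:
                try:
                    sol_i = np.linalg.solve(pooled[i], d[i])
                except np.linalg.LinAlgError as exc:
                    raise np.linalg.LinAlgError(
                        "singular pooled covariance at position "
                        f"{i + b}; configure shrinkage > 0") from exc
                md2[i] = max(float(d[i] @ sol_i), 0.0)
    md = np.sqrt(md2)

    praw = hotelling_p(md2, b, b, p)
    pcorr = np.minimum(praw * len(praw), 1.0)
    positions = np.arange(b, n - b + 1)
    return DistanceFunction(block_size=b, positions=positions, md=md,
                            pvalues=pcorr, pvalues_raw=praw)


# ---------------------------------------------------------------------------
# consensus border detection across block sizes
# ---------------------------------------------------------------------------

@dataclass
class BorderSet:
    """Accepted borders with the block sizes supporting each of them."""
    borders: list[int] = field(default_factory=list)
    support: dict[int, tuple[int, ...]] = field(default_factory=dict)
    alpha: float = 0.001

    def __len__(self) -> int:
        return len(self.borders)


def significant_maxima(df: DistanceFunction, alpha: float) -> list[int]:
    """Traverse positions of significant local maxima of an MD function.

    A maximum is a run of equal values strictly greater than both of its
    neighbours; plateaus are collapsed to their midpoint (lower index on
    even-length plateaus).  Positions at the ends of the admissible range
    cannot be confirmed as maxima and are excluded.
    """
    md, pv = df.md, df.pvalues
    out: list[int] = []
    i, m = 0, len(md)
    while i < m:
        j = i
        while j + 1 < m and md[j + 1] == md[i]:
            j += 1
        if i > 0 and j < m - 1 and md[i] > md[i - 1] and md[j] > md[j + 1]:
            mid = (i + j) // 2
            if pv[mid] < alpha:
                out.append(int(df.positions[mid]))
        i = j + 1
    return out


def detect_borders(profiles: np.ndarray, *,
                   depth_grid: np.ndarray | None = None,
                   block_range: tuple[int, int] = (12, 24),
                   alpha: float = 0.001,
                   min_support: int | None = None,
                   merge_window: int = 3,
                   shrinkage: float = 0.0) -> BorderSet:
    """Consensus border positions over a range of block sizes.

    For every block size in ``block_range`` (inclusive), significant local
    maxima of the Bonferroni-corrected MD function are candidate borders.
    Candidates from different block sizes lying within ``merge_window``
    traverses of each other are merged at their median position; merged
    candidates supported by at least ``min_support`` block sizes (default:
    half the number of block sizes, rounded up) are accepted.
    """
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    lo, hi = block_range
    if lo < 2 or hi < lo:
        raise ValueError("invalid block range")
    sizes = [b for b in range(lo, hi + 1) if 2 * b <= n]
    if not sizes:
        raise ValueError(f"no admissible block size in {block_range} for {n} traverses")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if min_support is None:
        min_support = (len(sizes) + 1) // 2

    feats = profile_features(profiles, depth_grid)
    candidates: list[tuple[int, int]] = []          # (position, block size)
    for b in sizes:
        df = md_function(profiles, b, features=feats, shrinkage=shrinkage)
        for pos in significant_maxima(df, alpha):
            candidates.append((pos, b))
    candidates.sort()

    borders: list[int] = []
    support: dict[int, tuple[int, ...]] = {}
    cluster: list[tuple[int, int]] = []

    def flush(cluster: list[tuple[int, int]]) -> None:
        sizes_here = sorted({b for _, b in cluster})
        if len(sizes_here) < min_support:
            return
        pos = int(np.median([k for k, _ in cluster]))
        borders.append(pos)
        support[pos] = tuple(sizes_here)
        logger.info("border at traverse %d supported by block sizes %s", pos, sizes_here)

    for cand in candidates:
        if cluster and cand[0] - cluster[-1][0] > merge_window:
            flush(cluster)
            cluster = []
        cluster.append(cand)
    if cluster:
        flush(cluster)

    return BorderSet(borders=sorted(borders), support=support, alpha=alpha)


def plot_md_functions(dfs: list[DistanceFunction], path: str | None = None):
    """Stacked MD-vs-position panels, one per block size (largest on top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(dfs), 1, sharex=True,
                             figsize=(6, 1.2 * len(dfs) + 1), squeeze=False)
    for ax, df in zip(axes[:, 0], sorted(dfs, key=lambda d: -d.block_size)):
        ax.plot(df.positions, df.md, lw=0.8)
        sig = df.pvalues < 0.001
        ax.plot(df.positions[sig], df.md[sig], "r.", ms=4)
        ax.set_ylabel(f"b={df.block_size}", fontsize=7)
    axes[-1, 0].set_xlabel("profile position")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
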