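"""Probabilistic areal maps in a common voxel space.

Individual subjects' area labels, already co-registered to one reference
grid, are superimposed into per-area probability maps (voxel value = the
fraction of subjects in which the area occupies the voxel).  A maximum
probability map (MPM) assigns each voxel to its most probable area with a
neighbourhood-mean tie-break and a threshold at borders where no competing
area is mapped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

logger = logging.getLogger(__name__)

_AFFINE_ATOL = 1e-6


@dataclass
class LabelVolume:
    """3D integer label grid with a voxel-to-world (RAS mm) affine."""
    grid: np.ndarray
    affine: np.ndarray
    vocabulary: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be integer-valued")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or np.linalg.det(self.affine[:3, :3]) == 0:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.vocabulary:
            present = set(np.unique(self.grid)) - {0}
            unknown = present - set(self.vocabulary)
            if unknown:
                raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")


@dataclass
class ProbabilityMap:
    """Per-voxel frequency with which one area was mapped across subjects."""
    grid: np.ndarray
    affine: np.ndarray
    area: str
    n_subjects: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("probability grid must be 3D")
        if self.grid.min() < -1e-12 or self.grid.max() > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class MPMVolume:
    """Winner-take-all parcellation; 0 marks unassigned voxels."""
    grid: np.ndarray
    affine: np.ndarray
    vocabulary: dict[int, str]
    threshold: float
    n_ties: int = 0
    n_unresolved_ties: int = 0


def _check_aligned(affines: list[np.ndarray], shapes: list[tuple]) -> None:
    if len(set(shapes)) > 1:
        raise ValueError("volumes do not share a common shape")
    a0 = affines[0]
    for a in affines[1:]:
        if not np.allclose(a, a0, atol=_AFFINE_ATOL):
            raise ValueError("affine mismatch beyond tolerance; resample inputs first")


def build_pmap(volumes: list[LabelVolume], area: str) -> ProbabilityMap:
    """Superimpose subject label volumes into one area's probability map."""
    if not volumes:
        raise ValueError("need at least one subject volume")
    _check_aligned([v.affine for v in volumes], [v.grid.shape for v in volumes])
    labels = []
    for v in volumes:
        match = [lab for lab, name in v.vocabulary.items() if name == area]
        if len(match) != 1:
            raise ValueError(f"area {area!r} not uniquely defined in vocabulary")
        labels.append(match[0])
    counts = np.zeros(volumes[0].grid.shape, dtype=float)
    for v, lab in zip(volumes, labels):
        counts += v.grid == lab
    return ProbabilityMap(grid=counts / len(volumes), affine=volumes[0].affine.copy(),
                          area=area, n_subjects=len(volumes))


def centre_of_gravity(pmap: ProbabilityMap) -> np.ndarray:
    """Probability-weighted mean world coordinate of the non-zero voxels (mm)."""
    idx = np.argwhere(pmap.grid > 0)
    if idx.size == 0:
        raise ValueError("all-zero probability map has no centre of gravity")
    w = pmap.grid[tuple(idx.T)]
    homog = np.c_[idx, np.ones(len(idx))]
    world = homog @ pmap.affine.T
    return np.average(world[:, :3], axis=0, weights=w)


_NEIGHBOURHOODS = {
    6: [d for d in product((-1, 0, 1), repeat=3) if sum(abs(x) for x in d) == 1],
    18: [d for d in product((-1, 0, 1), repeat=3) if 1 <= sum(abs(x) for x in d) <= 2],
    26: [d for d in product((-1, 0, 1), repeat=3) if any(d)],
}


def _neighbourhood_mean(grid: np.ndarray, voxel: tuple[int, int, int],
                        offsets: list[tuple[int, int, int]]) -> float:
    vals = []
    for d in offsets:
        v = tuple(np.add(voxel, d))
        if all(0 <= v[i] < grid.shape[i] for i in range(3)):
            vals.append(grid[v])
    return float(np.mean(vals)) if vals else 0.0


def build_mpm(pmaps: list[ProbabilityMap], *, unmapped_threshold: float = 0.4,
              neighbourhood: int = 26) -> MPMVolume:
    """Maximum probability map over a family of aligned area probability maps.

    Each voxel goes to the area with the highest probability.  Voxels where
    several areas tie are assigned to the tied area with the highest mean
    probability over the voxel's neighbourhood (6/18/26-connectivity,
    centre excluded); a tie surviving that rule falls to the lowest area id
    and is counted.  Voxels whose winning probability is below
    ``unmapped_threshold`` while no other area is mapped there (all
    competitors at zero) are left unassigned — the thresholding applied at
    borders with not-yet-mapped neighbouring cortex.
    """
    if not pmaps:
        raise ValueError("empty probability map family")
    if not 0.0 <= unmapped_threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    offsets = _NEIGHBOURHOODS[neighbourhood]
    _check_aligned([p.affine for p in pmaps], [p.grid.shape for p in pmaps])
    stack = np.stack([p.grid for p in pmaps])                  # (A, X, Y, Z)
    n_areas = len(pmaps)

    winner = np.argmax(stack, axis=0)
    pmax = np.take_along_axis(stack, winner[None], axis=0)[0]
    out = (winner + 1).astype(np.int16)
    out[pmax <= 0.0] = 0

    # runner-up probability decides whether a mapped competitor exists
    if n_areas > 1:
        second = np.partition(stack, n_areas - 2, axis=0)[n_areas - 2]
    else:
        second = np.zeros_like(pmax)
    out[(pmax < unmapped_threshold) & (second <= 0.0)] = 0

    n_ties = 0
    n_unresolved = 0
    tie_count = np.sum(stack == pmax[None], axis=0)
    for voxel in map(tuple, np.argwhere((tie_count > 1) & (out > 0))):
        tied = [a for a in range(n_areas) if stack[(a,) + voxel] == pmax[voxel]]
        n_ties += 1
        means = [_neighbourhood_mean(stack[a], voxel, offsets) for a in tied]
        best = max(means)
        winners = [a for a, m in zip(tied, means) if m == best]
        if len(winners) > 1:
            n_unresolved += 1
            logger.info("unresolved tie at voxel %s; lowest area id wins", voxel)
        out[voxel] = winners[0] + 1
    if n_ties:
        logger.info("resolved %d ties (%d by lowest-id fallback)", n_ties, n_unresolved)

    vocab = {i + 1: p.area for i, p in enumerate(pmaps)}
    return MPMVolume(grid=out, affine=pmaps[0].affine.copy(), vocabulary=vocab,
                     threshold=unmapped_threshold, n_ties=n_ties,
                     n_unresolved_ties=n_unresolved)


def correlate_maps(map_a: ProbabilityMap, map_b: ProbabilityMap,
                   domain_mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two probability maps over a voxel domain.

    The default domain is the union of both maps' non-zero voxels; pass an
    explicit boolean mask (e.g. the whole grid) to change it.
    """
    _check_aligned([map_a.affine, map_b.affine], [map_a.grid.shape, map_b.grid.shape])
    if domain_mask is None:
        domain_mask = (map_a.grid > 0) | (map_b.grid > 0)
    domain_mask = np.asarray(domain_mask, dtype=bool)
    if not domain_mask.any():
        raise ValueError("empty correlation domain")
    a = map_a.grid[domain_mask]
    b = map_b.grid[domain_mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance over the correlation domain")
    return float(np.corrcoef(a, b)[0, 1])


def assign_coordinate(xyz_mm, pmaps: list[ProbabilityMap],
                      threshold: float = 0.2) -> list[tuple[str, float]]:
    """Areas whose probability map reaches ``threshold`` at a world coordinate.

    Returns (area, probability) pairs in descending probability order.  A
    coordinate outside the grid yields an empty list with a warning — the
    case of a point that cannot be localised within any map.
    """
    if not pmaps:
        raise ValueError("empty probability map family")
    _check_aligned([p.affine for p in pmaps], [p.grid.shape for p in pmaps])
    inv = np.linalg.inv(pmaps[0].affine)
    voxel = inv @ np.append(np.asarray(xyz_mm, dtype=float), 1.0)
    ijk = np.round(voxel[:3]).astype(int)
    shape = pmaps[0].grid.shape
    if np.any(ijk < 0) or np.any(ijk >= shape):
        warnings.warn(f"coordinate {tuple(xyz_mm)} lies outside the map grid",
                      RuntimeWarning, stacklevel=2)
        return []
    hits = [(p.area, float(p.grid[tuple(ijk)])) for p in pmaps
            if p.grid[tuple(ijk)] >= threshold]
    return sorted(hits, key=lambda t: (-t[1], t[0]))
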