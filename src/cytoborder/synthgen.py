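"""Synthetic laminar ribbons, cell-body images and multi-subject label volumes.

Real cytoarchitectonic mapping starts from cell-body stained histological
sections; here every downstream stage is exercised against generated data
with known ground truth instead: laminar GLI profiles built from explicit
layer models, binarised "cell" images whose local foreground fraction
follows those models across a flat or curved cortical ribbon, and families
of co-registered subject label volumes with controlled spatial jitter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .atlas import LabelVolume

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# laminar models and 1D ribbons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LaminarModel:
    """Piecewise-constant laminar density pattern of one cortical area.

    ``layer_fractions`` are relative layer widths over normalised depth
    (summing to 1), ``layer_densities`` the mean GLI (cell packing density
    fraction) of each layer, ``noise_sd`` the standard deviation of the
    additive Gaussian noise applied to generated GLI values.
    """
    layer_fractions: tuple[float, ...]
    layer_densities: tuple[float, ...]
    noise_sd: float = 0.0
    name: str = "area"

    def __post_init__(self) -> None:
        f = np.asarray(self.layer_fractions, dtype=float)
        d = np.asarray(self.layer_densities, dtype=float)
        if f.size == 0 or f.size != d.size:
            raise ValueError("layer_fractions and layer_densities must have equal, non-zero length")
        if np.any(f <= 0):
            raise ValueError("layer fractions must be positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"layer fractions must sum to 1 (got {f.sum()!r})")
        if np.any((d < 0) | (d > 1)):
            raise ValueError("layer densities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def density_at(self, depth: np.ndarray) -> np.ndarray:
        """Mean GLI at normalised depth(s) in [0, 1] (piecewise constant)."""
        depth = np.asarray(depth, dtype=float)
        bounds = np.cumsum(self.layer_fractions)[:-1]
        idx = np.searchsorted(bounds, depth, side="right")
        return np.asarray(self.layer_densities, dtype=float)[idx]


def make_laminar_model(layer_fractions, layer_densities, noise_sd=0.0,
                       name="area") -> LaminarModel:
    """Validated laminar model (see :class:`LaminarModel`)."""
    return LaminarModel(tuple(layer_fractions), tuple(layer_densities),
                        float(noise_sd), str(name))


@dataclass
class SyntheticRibbon:
    """Profiles along a ribbon with ground-truth borders and area labels."""
    profiles: np.ndarray                 # (n_traverses, depth_bins)
    depth_grid: np.ndarray               # bin centres in [0, 1]
    true_borders: tuple[int, ...]        # traverse index of the first profile of each new area
    area_labels: tuple[str, ...]         # per traverse

    def __post_init__(self) -> None:
        tb = np.asarray(self.true_borders)
        if tb.size and (np.any(np.diff(tb) <= 0) or tb.min() <= 0
                        or tb.max() >= self.profiles.shape[0]):
            raise ValueError("true_borders must be strictly increasing within (0, n_traverses)")


def render_ribbon(models: list[LaminarModel], segment_lengths: list[int],
                  depth_bins: int = 100, seed: int | None = None,
                  smoothing_bins: int = 0) -> SyntheticRibbon:
    """Sample GLI profiles for a sequence of areas along a ribbon.

    Each traverse's profile is its area's layer-density step function
    sampled at ``depth_bins`` bin centres, optionally smoothed with a
    moving average of ``smoothing_bins`` (mimicking gradual laminar
    transitions), plus i.i.d. Gaussian noise clipped to [0, 1].
    """
    if not models:
        raise ValueError("need at least one laminar model")
    if len(models) != len(segment_lengths):
        raise ValueError("models and segment_lengths must have equal length")
    if any(s < 1 for s in segment_lengths):
        raise ValueError("segment lengths must be >= 1")
    if depth_bins < 10:
        raise ValueError("depth_bins must be >= 10")
    rng = np.random.default_rng(seed)
    grid = (np.arange(depth_bins) + 0.5) / depth_bins
    rows, labels = [], []
    for model, length in zip(models, segment_lengths):
        clean = model.density_at(grid)
        if smoothing_bins > 1:
            clean = uniform_filter1d(clean, smoothing_bins, mode="nearest")
        block = np.tile(clean, (length, 1))
        if model.noise_sd > 0:
            block = block + rng.normal(0.0, model.noise_sd, block.shape)
        rows.append(np.clip(block, 0.0, 1.0))
        labels.extend([model.name] * length)
    borders = tuple(int(x) for x in np.cumsum(segment_lengths)[:-1])
    return SyntheticRibbon(profiles=np.vstack(rows), depth_grid=grid,
                           true_borders=borders, area_labels=tuple(labels))


# ---------------------------------------------------------------------------
# 2D binary cell-body images with contours
# ---------------------------------------------------------------------------

@dataclass
class GLIRender:
    """Binary cell image of a ribbon plus its bounding contours.

    Contours are (N, 2) float arrays of (row, col) pixel coordinates,
    ordered along the ribbon; ``border_arcpos`` gives the arc-length pixel
    position (along the outer contour) of each ground-truth area border.
    """
    image: np.ndarray
    outer_contour: np.ndarray
    inner_contour: np.ndarray
    border_arcpos: tuple[float, ...]


def render_gli_image(models: list[LaminarModel], segment_lengths_px: list[int],
                     thickness_px: int = 160, curvature: float = 0.0,
                     seed: int | None = None, margin: int = 8) -> GLIRender:
    """Binary image whose local foreground fraction follows the laminar models.

    ``curvature`` is the reciprocal of the outer-contour radius in 1/pixels
    (0 gives a flat ribbon); ``segment_lengths_px`` are arc lengths along
    the outer contour per area.  Each pixel between the two contours is
    foreground with probability equal to its area's layer density at the
    pixel's normalised depth.
    """
    if thickness_px < 64:
        raise ValueError("thickness_px must be >= 64 (>= 4 GLI windows across depth)")
    if not models or len(models) != len(segment_lengths_px):
        raise ValueError("models and segment_lengths_px must have equal, non-zero length")
    rng = np.random.default_rng(seed)
    total_arc = int(sum(segment_lengths_px))
    bounds = np.cumsum(segment_lengths_px)[:-1].astype(float)

    if curvature == 0.0:
        shape = (thickness_px + 2 * margin, total_arc + 2 * margin)
        rows = np.arange(shape[0])[:, None] - margin
        cols = np.arange(shape[1])[None, :] - margin
        depth = np.broadcast_to((rows + 0.5) / thickness_px, shape)
        arcpos = np.broadcast_to(cols + 0.5, shape).astype(float)
        ribbon = (rows >= 0) & (rows < thickness_px) & (cols >= 0) & (cols < total_arc)
        # tissue boundaries run between pixel rows: centre coordinates -0.5
        t = np.arange(total_arc + 1, dtype=float) - 0.5
        outer = np.c_[np.full_like(t, margin - 0.5), margin + t]
        inner = np.c_[np.full_like(t, margin + thickness_px - 0.5), margin + t]
    else:
        # arc of outer radius 1/|curvature| opening upward, symmetric about
        # the vertical through the circle centre
        r_out = 1.0 / abs(curvature)
        r_in = r_out - thickness_px
        if r_in <= 1.0:
            raise ValueError("curvature too strong: inner contour self-intersects")
        theta = total_arc / r_out
        if theta > np.pi:
            raise ValueError("arc span too large for the given curvature")
        half = theta / 2.0
        row_c = margin + r_out                       # circle centre (row)
        col_c = margin + r_out * np.sin(half)        # circle centre (col)
        h = int(np.ceil(row_c - r_in * np.cos(min(half, np.pi / 2)))) + margin + 1
        w = int(np.ceil(2 * col_c)) + 1
        shape = (h, w)
        rr = row_c - (np.arange(h)[:, None] + 0.5)   # up is positive
        cc = (np.arange(w)[None, :] + 0.5) - col_c
        rad = np.hypot(rr, cc)
        alpha = np.arctan2(cc, rr)                   # 0 at arc midpoint
        ribbon = (rad <= r_out) & (rad >= r_in) & (np.abs(alpha) <= half)
        depth = (r_out - rad) / thickness_px
        arcpos = (alpha + half) * r_out
        # contour coordinates in pixel-centre convention (centre of pixel i
        # sits at coordinate i): shift the geometric frame by half a pixel
        arc_ang = np.linspace(-half, half, 4 * total_arc)
        outer = np.c_[row_c - r_out * np.cos(arc_ang) - 0.5,
                      col_c + r_out * np.sin(arc_ang) - 0.5]
        inner = np.c_[row_c - r_in * np.cos(arc_ang) - 0.5,
                      col_c + r_in * np.sin(arc_ang) - 0.5]

    seg = np.searchsorted(bounds, arcpos, side="right")
    seg = np.clip(seg, 0, len(models) - 1)
    dens = np.zeros(shape, dtype=float)
    d_clipped = np.clip(depth, 0.0, 1.0)
    for i, model in enumerate(models):
        sel = ribbon & (seg == i)
        dens[sel] = model.density_at(d_clipped[sel])
    image = np.zeros(shape, dtype=bool)
    image[ribbon] = rng.random(int(ribbon.sum())) < dens[ribbon]
    return GLIRender(image=image, outer_contour=outer, inner_contour=inner,
                     border_arcpos=tuple(float(b) for b in bounds))


# ---------------------------------------------------------------------------
# multi-subject label volumes
# ---------------------------------------------------------------------------

@dataclass
class SubjectLabelSet:
    """Per-subject label volumes derived from one canonical area layout."""
    volumes: list[LabelVolume]
    canonical: LabelVolume
    jitter_mm: float


def ellipsoid_mask(shape: tuple[int, int, int], center, radii) -> np.ndarray:
    """Boolean ellipsoid in voxel coordinates; building block for area layouts."""
    grids = np.indices(shape, dtype=float)
    c = np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    r = np.asarray(radii, dtype=float).reshape(3, 1, 1, 1)
    return np.sum(((grids - c) / r) ** 2, axis=0) <= 1.0


def make_subject_labelsets(shape: tuple[int, int, int], affine: np.ndarray,
                           area_specs: list[tuple[str, int, np.ndarray]],
                           n_subjects: int, jitter_mm: float = 0.0,
                           seed: int | None = None) -> SubjectLabelSet:
    """Displaced copies of a canonical area layout, one per synthetic subject.

    ``area_specs`` is a list of (name, label, boolean mask) triples defining
    disjoint areas on the canonical grid.  Each subject's volume is the
    canonical layout shifted rigidly by a random integer-voxel translation
    drawn from a Gaussian of scale ``jitter_mm`` per axis; labels shifted
    outside the grid are clipped with a warning.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be non-negative")
    affine = np.asarray(affine, dtype=float)
    canonical = np.zeros(shape, dtype=np.int16)
    occupancy = np.zeros(shape, dtype=bool)
    vocab: dict[int, str] = {}
    for name, label, mask in area_specs:
        mask = np.asarray(mask, dtype=bool)
        if label <= 0:
            raise ValueError("area labels must be positive (0 is background)")
        if mask.shape != tuple(shape):
            raise ValueError(f"mask shape mismatch for area {name!r}")
        if np.any(occupancy & mask):
            raise ValueError(f"area {name!r} overlaps another area in the canonical layout")
        occupancy |= mask
        canonical[mask] = label
        vocab[label] = name

    voxel_size = np.abs(np.diag(affine)[:3])
    rng = np.random.default_rng(seed)
    volumes = []
    for s in range(n_subjects):
        if jitter_mm > 0:
            shift = np.round(rng.normal(0.0, jitter_mm, 3) / voxel_size).astype(int)
        else:
            shift = np.zeros(3, dtype=int)
        grid = _shift_labels(canonical, shift)
        if jitter_mm > 0 and np.count_nonzero(grid) < np.count_nonzero(canonical):
            warnings.warn(f"subject {s}: jitter moved labels outside the grid; clipped",
                          RuntimeWarning, stacklevel=2)
        volumes.append(LabelVolume(grid=grid, affine=affine.copy(), vocabulary=dict(vocab)))
    canon = LabelVolume(grid=canonical, affine=affine.copy(), vocabulary=dict(vocab))
    return SubjectLabelSet(volumes=volumes, canonical=canon, jitter_mm=float(jitter_mm))


def _shift_labels(grid: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Integer-voxel translation with zero fill (labels leaving the grid are lost)."""
    out = np.zeros_like(grid)
    src, dst = [], []
    for axis in range(3):
        n, d = grid.shape[axis], int(shift[axis])
        if abs(d) >= n:
            return out
        src.append(slice(max(0, -d), min(n, n - d)))
        dst.append(slice(max(0, d), min(n, n + d)))
    out[tuple(dst)] = grid[tuple(src)]
    return out
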