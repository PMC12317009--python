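"""Grey Level Index images and laminar profile extraction.

The GLI of a binarised cell-body image is the foreground (cell) fraction in
small square windows — a proxy for cell packing density.  Laminar profiles
are the GLI sampled along traverses running from the outer contour (layer
I/II border) to the inner contour (layer VI / white matter border).  On
curved cortex the traverses are streamlines of the gradient of a harmonic
depth field (Laplace equation with the outer contour held at 0 and the
inner at 1), which degenerate to straight vertical lines on a flat ribbon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt
from scipy.sparse.linalg import spsolve
from skimage.draw import polygon

logger = logging.getLogger(__name__)


@dataclass
class GLIImage:
    """Windowed cell packing density grid.

    ``values[i, j]`` is the foreground fraction of the source-image window
    of side ``window_px`` whose top-left corner is (i*stride, j*stride).
    """
    values: np.ndarray
    window_px: int
    resolution_um_per_px: float = 1.02
    stride: int | None = None

    def __post_init__(self) -> None:
        if self.stride is None:
            self.stride = self.window_px
        v = np.asarray(self.values, dtype=float)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("GLI values must lie in [0, 1]")
        self.values = v


@dataclass
class ContourPair:
    """Outer (layer I/II) and inner (layer VI/WM) contour polylines.

    Both are (N, 2) arrays of (row, col) pixel coordinates, 0-based,
    ordered consistently along the ribbon.
    """
    outer: np.ndarray
    inner: np.ndarray

    def __post_init__(self) -> None:
        for name in ("outer", "inner"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
                raise ValueError(f"{name} contour must be an (N>=2, 2) array")
            setattr(self, name, a)

    def swapped(self) -> "ContourPair":
        return ContourPair(outer=self.inner.copy(), inner=self.outer.copy())


@dataclass
class ProfileSet:
    """Depth-normalised laminar profiles ordered along the ribbon."""
    profiles: np.ndarray                       # (n_traverses, depth_bins)
    depth_grid: np.ndarray                     # bin centres in [0, 1]
    traverse_arclength_mm: np.ndarray          # position along the outer contour
    excluded: tuple[int, ...] = ()             # seed indices of discarded traverses

    @property
    def n_traverses(self) -> int:
        return self.profiles.shape[0]


def compute_gli(binary_image: np.ndarray, window_px: int = 16,
                stride: int | None = None,
                resolution_um_per_px: float = 1.02) -> GLIImage:
    """GLI image: foreground fraction per window of a binarised cell image.

    Windows are non-overlapping by default (``stride`` = ``window_px``);
    trailing partial windows are dropped.
    """
    img = np.asarray(binary_image)
    if img.dtype != bool:
        vals = np.unique(img)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("input image is not binary; binarize (cells = foreground) first")
        img = img.astype(bool)
    if window_px < 2:
        raise ValueError("window_px must be >= 2")
    if stride is None:
        stride = window_px
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = img.shape
    ni = (h - window_px) // stride + 1
    nj = (w - window_px) // stride + 1
    if ni < 1 or nj < 1:
        raise ValueError("image smaller than one GLI window")
    # integral image gives every window sum in O(1)
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(img, axis=0), axis=1)
    r0 = np.arange(ni) * stride
    c0 = np.arange(nj) * stride
    r1, c1 = r0 + window_px, c0 + window_px
    sums = (ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)]
            - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)])
    return GLIImage(values=sums / float(window_px**2), window_px=window_px,
                    stride=stride, resolution_um_per_px=resolution_um_per_px)


# ---------------------------------------------------------------------------
# harmonic depth field
# ---------------------------------------------------------------------------

def ribbon_mask_from_contours(contours: ContourPair, shape: tuple[int, int]) -> np.ndarray:
    """Boolean ribbon mask bounded by the two contours (closed polygon fill)."""
    ring = np.vstack([contours.outer, contours.inner[::-1]])
    rr, cc = polygon(ring[:, 0], ring[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    for pts in (contours.outer, contours.inner):
        ij = _rasterize(pts, shape)
        mask[ij[:, 0], ij[:, 1]] = True
    return mask


def _rasterize(polyline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixel coordinates visited by a polyline (dense resampling + rounding)."""
    seglen = np.hypot(*np.diff(polyline, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(int(np.ceil(s[-1] * 4)), 2)
    t = np.linspace(0.0, s[-1], n)
    pts = np.c_[np.interp(t, s, polyline[:, 0]), np.interp(t, s, polyline[:, 1])]
    ij = np.round(pts).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
    return np.unique(ij, axis=0)


def solve_depth_field(ribbon_mask: np.ndarray, contours: ContourPair) -> np.ndarray:
    """Harmonic depth field: 0 on the outer contour, 1 on the inner.

    Solves the Laplace equation on the ribbon with the contour polylines as
    sub-pixel Dirichlet boundaries (Shortley-Weller finite differences:
    grid links crossing a contour get fractional arm lengths, so accuracy
    does not degrade to the pixel rasterisation of the boundary).  Mask
    edges that meet no contour — the cut ends of the ribbon — behave as
    no-flux (Neumann) boundaries.  Returns NaN outside the mask.
    """
    from shapely import LineString, STRtree

    mask = np.asarray(ribbon_mask, dtype=bool)
    shape = mask.shape
    dist_out = distance_transform_edt(~_pixel_set(contours.outer, shape))
    dist_in = distance_transform_edt(~_pixel_set(contours.inner, shape))
    if (dist_out[mask].min() if mask.any() else np.inf) > 2.0 \
            or (dist_in[mask].min() if mask.any() else np.inf) > 2.0:
        raise ValueError("contours must lie on the ribbon mask boundary")
    # unknowns: pixels between the contours (ring polygon interior) plus any
    # mask pixel clear of both polylines — the latter keeps pixels on the
    # ring's closing edges (cut ends, or the slit of a closed contour pair)
    # in the solve; the remaining pixels form the Dirichlet band
    ring = np.vstack([contours.outer, contours.inner[::-1]])
    import matplotlib.path as mpath
    poly = mpath.Path(ring)
    rr, cc = np.nonzero(mask)
    inside = np.zeros(shape, dtype=bool)
    inside[rr, cc] = poly.contains_points(np.c_[rr, cc])
    unknown = mask & (inside | ((dist_out > 0.75) & (dist_in > 0.75)))
    nf = int(unknown.sum())
    if nf == 0:
        raise ValueError("no interior pixels between the contours")
    idx = -np.ones(shape, dtype=np.int64)
    ur, uc = np.nonzero(unknown)
    idx[ur, uc] = np.arange(nf)

    # segments per contour for fast link-crossing queries
    def _segments(poly_pts: np.ndarray) -> STRtree:
        segs = [LineString(poly_pts[i:i + 2]) for i in range(len(poly_pts) - 1)]
        return STRtree(segs), segs

    trees = {0.0: _segments(contours.outer), 1.0: _segments(contours.inner)}

    def crossing(p: tuple[float, float], q: tuple[float, float]):
        """(theta, dirichlet value) of the nearest contour crossing on p->q."""
        link = LineString([p, q])
        best = None
        for value, (tree, segs) in trees.items():
            for si in tree.query(link):
                inter = segs[si].intersection(link)
                if inter.is_empty:
                    continue
                pts = [inter] if inter.geom_type == "Point" else list(getattr(inter, "geoms", []))
                for pt in pts:
                    if pt.geom_type != "Point":
                        continue
                    theta = float(np.hypot(pt.x - p[0], pt.y - p[1]))
                    if best is None or theta < best[0]:
                        best = (theta, value)
        return best

    THETA_MIN = 0.02
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    rhs = np.zeros(nf)
    offsets = ((1, 0), (-1, 0), (0, 1), (0, -1))

    # interior pixels (all four neighbours unknown) assemble vectorised
    nb_unknown = np.zeros((4, nf), dtype=bool)
    for a, (dr, dc) in enumerate(offsets):
        nr, nc = ur + dr, uc + dc
        ok = (0 <= nr) & (nr < shape[0]) & (0 <= nc) & (nc < shape[1])
        nb_unknown[a, ok] = unknown[nr[ok], nc[ok]]
    interior = nb_unknown.all(axis=0)
    ci = idx[ur, uc]
    for a, (dr, dc) in enumerate(offsets):
        sel = np.nonzero(interior)[0]
        rows.extend(ci[sel]); cols.extend(idx[ur[sel] + dr, uc[sel] + dc])
        data.extend([-1.0] * len(sel))
    rows.extend(ci[interior]); cols.extend(ci[interior])
    data.extend([4.0] * int(interior.sum()))

    # boundary pixels: fractional arms towards contour crossings
    for k in np.nonzero(~interior)[0]:
        r, c = int(ur[k]), int(uc[k])
        arms: list[tuple[float, int | None, float]] = []   # (theta, nb index, value)
        for a, (dr, dc) in enumerate(offsets):
            nr, nc = r + dr, c + dc
            if 0 <= nr < shape[0] and 0 <= nc < shape[1] and unknown[nr, nc]:
                arms.append((1.0, int(idx[nr, nc]), 0.0))
                continue
            # probe past the neighbour: a contour passing a hair beyond its
            # centre must still register as a Dirichlet arm, not a cut edge
            hit = crossing((float(r), float(c)), (float(r + 2 * dr), float(c + 2 * dc)))
            if hit is None:
                arms.append((np.nan, None, 0.0))           # Neumann (cut edge)
            else:
                arms.append((float(np.clip(hit[0], THETA_MIN, 1.95)), None, hit[1]))
        diag = 0.0
        for a in (0, 2):                                   # axis pairs (+,-)
            t_p, nb_p, v_p = arms[a]
            t_m, nb_m, v_m = arms[a + 1]
            for (t, nb, v), t_o in (((t_p, nb_p, v_p), t_m), ((t_m, nb_m, v_m), t_p)):
                if np.isnan(t):
                    continue
                t_other = 1.0 if np.isnan(t_o) else t_o
                coef = 2.0 / (t * (t + t_other))
                diag += coef
                if nb is not None:
                    rows.append(int(ci[k])); cols.append(nb); data.append(-coef)
                else:
                    rhs[ci[k]] += coef * v
        if diag == 0.0:
            raise ValueError("isolated ribbon pixel: Laplace system is singular")
        rows.append(int(ci[k])); cols.append(int(ci[k])); data.append(diag)

    A = sparse.csr_matrix((data, (rows, cols)), shape=(nf, nf))
    try:
        u = spsolve(A, rhs)
    except Exception as exc:  # pragma: no cover - degenerate geometry
        raise RuntimeError(f"depth-field solve failed: {exc}") from exc
    residual = np.abs(A @ u - rhs).max() / max(np.abs(rhs).max(), 1.0)
    if not np.isfinite(u).all() or residual > 1e-8:
        raise RuntimeError(f"depth-field solve did not converge (residual {residual:.2e})")

    out = np.full(shape, np.nan)
    out[ur, uc] = np.clip(u, 0.0, 1.0)
    # the Dirichlet band keeps the value of its contour
    rest = mask & ~unknown
    if rest.any():
        out[rest & (dist_out <= dist_in)] = 0.0
        out[rest & (dist_in < dist_out)] = 1.0
    return out


def _pixel_set(polyline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    ij = _rasterize(polyline, shape)
    grid[ij[:, 0], ij[:, 1]] = True
    return grid


# ---------------------------------------------------------------------------
# profile extraction along gradient streamlines
# ---------------------------------------------------------------------------

def _arclength_seeds(polyline: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n points at equidistant arc length (half-step inset at both ends)."""
    seglen = np.hypot(*np.diff(polyline, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    targets = (np.arange(n) + 0.5) / n * total
    pts = np.c_[np.interp(targets, s, polyline[:, 0]),
                np.interp(targets, s, polyline[:, 1])]
    return pts, targets


def extract_profiles(gli_image: GLIImage, contours: ContourPair,
                     n_traverses: int, depth_bins: int = 100,
                     shape: tuple[int, int] | None = None) -> ProfileSet:
    """GLI profiles along depth-field streamlines across the ribbon.

    Traverses are seeded at ``n_traverses`` equidistant arc-length positions
    on the outer contour and follow the gradient of the harmonic depth
    field; each profile samples the GLI image (bilinear interpolation) at
    ``depth_bins`` equidistant normalised depths (bin centres).  Traverses
    that exit the ribbon before reaching the inner contour are excluded and
    reported.

    ``shape`` is the source-image pixel extent; by default it is inferred
    from the contour bounding box.
    """
    if n_traverses < 2:
        raise ValueError("need at least 2 traverses")
    if shape is None:
        allpts = np.vstack([contours.outer, contours.inner])
        shape = (int(np.ceil(allpts[:, 0].max())) + 2,
                 int(np.ceil(allpts[:, 1].max())) + 2)
    mask = ribbon_mask_from_contours(contours, shape)
    phi = solve_depth_field(mask, contours)

    # fill the field outside the mask with nearest in-mask values so that
    # gradients and interpolation stay finite near the boundary
    filled = phi.copy()
    if np.isnan(filled).any():
        _, (ir, ic) = distance_transform_edt(np.isnan(filled), return_indices=True)
        filled = filled[ir, ic]
    gr, gc = np.gradient(filled)
    grid_r = np.arange(shape[0], dtype=float)
    grid_c = np.arange(shape[1], dtype=float)
    interp_phi = RegularGridInterpolator((grid_r, grid_c), filled,
                                         bounds_error=False, fill_value=None)
    interp_gr = RegularGridInterpolator((grid_r, grid_c), gr,
                                        bounds_error=False, fill_value=None)
    interp_gc = RegularGridInterpolator((grid_r, grid_c), gc,
                                        bounds_error=False, fill_value=None)
    interp_mask = RegularGridInterpolator((grid_r, grid_c), mask.astype(float),
                                          bounds_error=False, fill_value=0.0)

    seeds, arcs = _arclength_seeds(contours.outer, n_traverses)
    depth_targets = (np.arange(depth_bins) + 0.5) / depth_bins

    # integrate dx/dt = grad(phi)/|grad(phi)|^2 so that t tracks depth
    pos = seeds.copy()
    active = np.ones(n_traverses, dtype=bool)
    n_steps = 6 * depth_bins
    dt = 1.2 / n_steps
    path_pos = np.full((n_steps + 1, n_traverses, 2), np.nan)
    path_phi = np.full((n_steps + 1, n_traverses), np.nan)
    path_pos[0] = pos
    path_phi[0] = interp_phi(pos)

    def velocity(p: np.ndarray) -> np.ndarray:
        g = np.c_[interp_gr(p), interp_gc(p)]
        norm2 = np.maximum(np.sum(g * g, axis=1, keepdims=True), 1e-12)
        return g / norm2

    for step in range(1, n_steps + 1):
        if not active.any():
            break
        p = pos[active]
        k1 = velocity(p)
        k2 = velocity(p + 0.5 * dt * k1)
        newp = p + dt * k2
        newp[:, 0] = np.clip(newp[:, 0], 0, shape[0] - 1)
        newp[:, 1] = np.clip(newp[:, 1], 0, shape[1] - 1)
        pos[active] = newp
        ph = interp_phi(newp)
        inside = interp_mask(newp) > 0.25
        path_pos[step, active] = newp
        path_phi[step, active] = ph
        done = ph >= depth_targets[-1]
        escaped = ~inside & ~done
        idx_active = np.nonzero(active)[0]
        active[idx_active[done | escaped]] = False

    profiles = np.full((n_traverses, depth_bins), np.nan)
    excluded: list[int] = []
    # map source-pixel coordinates to GLI-grid coordinates (window centres);
    # windows straddling the ribbon edge are renormalised by their in-ribbon
    # coverage so the sampled value is a density of tissue, not of window area
    w, st = gli_image.window_px, gli_image.stride
    offset = (w - 1) / 2.0
    gvals = gli_image.values.copy()
    # tissue = pixels whose centres lie between the contours; the rasterised
    # mask overshoots by the half-out contour band and would deflate coverage
    import matplotlib.path as mpath
    ring = mpath.Path(np.vstack([contours.outer, contours.inner[::-1]]))
    pix = np.stack(np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                               indexing="ij"), axis=-1).reshape(-1, 2)
    tissue = ring.contains_points(pix).reshape(shape)
    coverage = compute_gli(tissue, window_px=w, stride=st).values
    gshape = np.minimum(gvals.shape, coverage.shape)
    gvals = gvals[: gshape[0], : gshape[1]]
    coverage = coverage[: gshape[0], : gshape[1]]
    covered = coverage > 0.05
    gvals[covered] = np.minimum(gvals[covered] / coverage[covered], 1.0)
    if (~covered).any():
        # windows with (almost) no tissue inherit the nearest covered value
        _, (jr, jc) = distance_transform_edt(~covered, return_indices=True)
        gvals = gvals[jr, jc]
    interp_gli = RegularGridInterpolator(
        (np.arange(gvals.shape[0]) * st + offset,
         np.arange(gvals.shape[1]) * st + offset),
        gvals, bounds_error=False, fill_value=None)

    for i in range(n_traverses):
        ph = path_phi[:, i]
        valid = np.isfinite(ph)
        ph, pp = ph[valid], path_pos[valid, i]
        if ph.size < 2 or ph.max() < depth_targets[-1]:
            excluded.append(i)
            continue
        order = np.argsort(ph, kind="stable")
        ph, pp = ph[order], pp[order]
        keep = np.concatenate([[True], np.diff(ph) > 0])
        ph, pp = ph[keep], pp[keep]
        sr = np.interp(depth_targets, ph, pp[:, 0])
        sc = np.interp(depth_targets, ph, pp[:, 1])
        profiles[i] = np.clip(interp_gli(np.c_[sr, sc]), 0.0, 1.0)

    if excluded:
        logger.warning("%d of %d traverses exited the ribbon and were excluded",
                       len(excluded), n_traverses)
    keepers = np.setdiff1d(np.arange(n_traverses), excluded)
    mm = gli_image.resolution_um_per_px / 1000.0
    return ProfileSet(profiles=profiles[keepers], depth_grid=depth_targets,
                      traverse_arclength_mm=arcs[keepers] * mm,
                      excluded=tuple(excluded))
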