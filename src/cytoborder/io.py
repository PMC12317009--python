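"""File formats: NIfTI label volumes and probability maps, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import LabelVolume, MPMVolume, ProbabilityMap
from .gli import ContourPair, ProfileSet


def read_label_volume(path, vocabulary: dict[int, str] | None = None) -> LabelVolume:
    """Load a 3D integer label volume from a NIfTI(.gz) file.

    If a vocabulary is given, any voxel carrying a label outside it is
    rejected with an error naming the offending voxel.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    data = np.asanyarray(img.dataobj)
    rounded = np.round(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError(f"{path}: label volume contains non-integer values")
    grid = rounded.astype(np.int16)
    if vocabulary is not None:
        bad = ~np.isin(grid, [0, *vocabulary])
        if bad.any():
            voxel = tuple(int(v) for v in np.argwhere(bad)[0])
            raise ValueError(
                f"{path}: label {int(grid[voxel])} at voxel {voxel} is outside the vocabulary")
    return LabelVolume(grid=grid, affine=img.affine, vocabulary=vocabulary or {})


def write_label_volume(volume: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.grid.astype(np.int16), volume.affine), str(path))


def read_pmap(path, area: str | None = None, n_subjects: int = 0) -> ProbabilityMap:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    return ProbabilityMap(grid=np.asanyarray(img.dataobj).astype(float),
                          affine=img.affine, area=area or Path(path).stem,
                          n_subjects=n_subjects)


def write_pmap(pmap: ProbabilityMap, path) -> None:
    nib.save(nib.Nifti1Image(pmap.grid.astype(np.float32), pmap.affine), str(path))


def write_mpm(mpm: MPMVolume, path) -> None:
    nib.save(nib.Nifti1Image(mpm.grid.astype(np.int16), mpm.affine), str(path))


def write_contours(contours: ContourPair, outer_path, inner_path) -> None:
    for arr, p in ((contours.outer, outer_path), (contours.inner, inner_path)):
        pd.DataFrame(arr, columns=["row", "col"]).to_csv(p, index=False)


def read_contours(outer_path, inner_path) -> ContourPair:
    outer = pd.read_csv(outer_path)[["row", "col"]].to_numpy(dtype=float)
    inner = pd.read_csv(inner_path)[["row", "col"]].to_numpy(dtype=float)
    return ContourPair(outer=outer, inner=inner)


def write_profile_set(ps: ProfileSet, csv_path, meta_path=None) -> None:
    """One CSV row per traverse; sidecar JSON carries grid and exclusions."""
    pd.DataFrame(ps.profiles).to_csv(csv_path, index=False,
                                     header=[f"d{j}" for j in range(ps.profiles.shape[1])])
    if meta_path is not None:
        meta = {"depth_grid": ps.depth_grid.tolist(),
                "traverse_arclength_mm": ps.traverse_arclength_mm.tolist(),
                "excluded": list(ps.excluded)}
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_profile_set(csv_path, meta_path=None) -> ProfileSet:
    profiles = pd.read_csv(csv_path).to_numpy(dtype=float)
    if meta_path is not None and Path(meta_path).exists():
        meta = json.loads(Path(meta_path).read_text())
        return ProfileSet(profiles=profiles,
                          depth_grid=np.asarray(meta["depth_grid"]),
                          traverse_arclength_mm=np.asarray(meta["traverse_arclength_mm"]),
                          excluded=tuple(meta["excluded"]))
    nbins = profiles.shape[1]
    return ProfileSet(profiles=profiles,
                      depth_grid=(np.arange(nbins) + 0.5) / nbins,
                      traverse_arclength_mm=np.arange(profiles.shape[0], dtype=float))
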