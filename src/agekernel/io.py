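"""File I/O: NIfTI volumes/series, TSV tables and curves.

Conventions
-----------
* Masked voxels are enumerated in Fortran order (x fastest), matching the
  NIfTI on-disk layout; this order defines ActivationMatrix columns.
* Age-indexed series are written as 4-D NIfTI with age on the 4th axis.
* Curves are TSV with a header row of baseline ages.
* Volumes are written uncompressed (.nii) so byte-identical reruns hash
  identically.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .change import ChangeMapSeries, GrayMatterMask
from .kernel import ActivationMatrix, AgeWeightedSeries

__all__ = [
    "write_mask",
    "read_mask",
    "write_volume",
    "read_activation_volumes",
    "write_series_nifti",
    "write_curve_tsv",
    "read_curve_tsv",
    "write_cohort_tsv",
    "read_cohort_tsv",
]


def write_mask(mask: GrayMatterMask, path) -> Path:
    img = nib.Nifti1Image(mask.included.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return Path(path)


def read_mask(path) -> GrayMatterMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    zooms = img.header.get_zooms()[:3]
    return GrayMatterMask(grid_shape=data.shape, voxel_size_mm=zooms, included=data)


def write_volume(values: np.ndarray, mask: GrayMatterMask, path) -> Path:
    """Write one masked-voxel vector as a 3-D volume (zeros off-mask)."""
    img = nib.Nifti1Image(mask.embed(values).astype(np.float64), mask.affine)
    nib.save(img, str(path))
    return Path(path)


def read_activation_volumes(paths, mask: GrayMatterMask, participant_ids=None) -> ActivationMatrix:
    """Stack per-participant volumes into an ActivationMatrix.

    ``paths`` must already be in cohort-table order (row order is the
    caller's contract, never the filesystem's); every volume must share
    the mask's grid shape.
    """
    paths = [Path(p) for p in paths]
    lin = None
    rows = []
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.shape != mask.grid_shape:
            raise ValueError(
                f"volume {p.name} has shape {data.shape}, expected {mask.grid_shape}"
            )
        if lin is None:
            lin = mask.linear_indices
        rows.append(data.ravel(order="F")[lin])
    if participant_ids is None:
        participant_ids = np.array([p.stem for p in paths])
    return ActivationMatrix(
        values=np.vstack(rows) if rows else np.zeros((0, mask.n_voxels)),
        participant_ids=np.asarray(participant_ids),
        voxel_index=mask.linear_indices,
    )


def write_series_nifti(series, mask: GrayMatterMask, path) -> Path:
    """Write an age-indexed map series as 4-D NIfTI (age on axis 3)."""
    maps = series.maps if isinstance(series, ChangeMapSeries) else series.values
    vols = np.stack([mask.embed(row) for row in np.atleast_2d(maps)], axis=-1)
    img = nib.Nifti1Image(vols.astype(np.float64), mask.affine)
    nib.save(img, str(path))
    return Path(path)


def write_curve_tsv(curves, ages, path, index_name: str = "roi") -> Path:
    """Write one or many curves as TSV with a header row of ages."""
    arr = np.atleast_2d(np.asarray(curves, dtype=float))
    df = pd.DataFrame(arr, columns=[str(int(a)) for a in np.asarray(ages)])
    df.index.name = index_name
    df.to_csv(path, sep="\t")
    return Path(path)


def read_curve_tsv(path) -> tuple:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ages = np.array([int(c) for c in df.columns])
    return ages, df.to_numpy(dtype=float)


def write_cohort_tsv(cohort, path) -> Path:
    cohort.table.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
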