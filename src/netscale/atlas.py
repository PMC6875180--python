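"""Label-volume container and NIfTI I/O.

A :class:`LabelAtlas` is a 3D integer grid assigning every voxel to a parent
brain region (0 = background), together with the physical voxel spacing in
millimetres.  It is the parent scheme that the parcellation module subdivides
into finer node sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabelAtlas", "load_label_volume", "save_label_volume"]


@dataclass
class LabelAtlas:
    """3D integer label volume with voxel spacing.

    Parameters
    ----------
    labels
        Integer array of shape ``(nx, ny, nz)``; 0 marks background, every
        positive value is a region id.
    spacing
        Per-axis voxel size in mm.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    region_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if min(self.labels.shape) < 1:
            raise ValueError("every grid dimension must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        ids = np.unique(self.labels)
        self.region_ids = ids[ids > 0]
        if self.region_ids.size == 0:
            raise ValueError("atlas contains no foreground region")

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.labels))

    def region_voxels(self, region_id: int) -> np.ndarray:
        """Voxel indices of one region, ordered by linear (C-order) index."""
        coords = np.argwhere(self.labels == region_id)
        if coords.size == 0:
            raise KeyError(f"region {region_id} has no voxels")
        return coords

    def voxel_mm(self, coords: np.ndarray) -> np.ndarray:
        """Physical centre coordinates (mm) of voxel index triples."""
        return np.asarray(coords, dtype=float) * np.asarray(self.spacing)


def save_label_volume(atlas: LabelAtlas, path: str) -> None:
    """Write a label volume as NIfTI-1 with a diagonal mm affine."""
    affine = np.diag(list(atlas.spacing) + [1.0])
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), affine)
    nib.save(img, path)


def load_label_volume(path: str) -> LabelAtlas:
    """Read an integer label volume from NIfTI; spacing from the header zooms."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    labels = np.rint(data).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelAtlas(labels=labels, spacing=spacing)
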