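"""Lesion volumes within functionally defined networks.

Probabilistic activation maps are thresholded (inclusive, default 5%) into
binary network masks; lesion masks are intersected with them voxelwise and
overlap volumes are reported in cm^3.  Inputs must share grid shape, voxel
dimensions and affine -- no silent resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "OverlapResult", "threshold_map", "lesion_overlap"]

_GRID_ATOL = 1e-4  # mm tolerance on voxel dims / affine agreement


@dataclass
class VolumeGrid:
    """A 3-D scalar volume on a regular grid.

    kind: ``"probability"`` (values in [0, 1]) or ``"binary"`` ({0, 1}).
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray = field(default=None)
    kind: str = "probability"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3-D array")
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_dims, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.kind == "probability":
            if self.data.min() < 0 or self.data.max() > 1:
                raise ValueError("probability grid must lie in [0, 1]")
        elif self.kind == "binary":
            if not np.isin(self.data, (0, 1)).all():
                raise ValueError("binary grid must contain only 0 and 1")
        else:
            raise ValueError(f"unknown grid kind {self.kind!r}")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_dims)) / 1000.0

    @property
    def volume_cm3(self) -> float:
        """Total volume of nonzero voxels (binary grids)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_cm3

    @classmethod
    def from_nifti(cls, path_or_img, kind: str = "probability") -> "VolumeGrid":
        img = path_or_img if isinstance(path_or_img, nib.spatialimages.SpatialImage) \
            else nib.load(str(path_or_img))
        data = np.asarray(img.get_fdata())
        dims = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, voxel_dims=dims, affine=np.asarray(img.affine),
                   kind=kind)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)


@dataclass(frozen=True)
class OverlapResult:
    n_overlap_voxels: int
    overlap_volume: float
    network_volume: float
    lesion_volume: float
    proportion_network_damaged: float
    proportion_lesion_in_network: float


def threshold_map(prob_map: VolumeGrid, threshold: float = 0.05) -> VolumeGrid:
    """Binarise a probabilistic map, retaining voxels with value >= threshold."""
    if prob_map.kind != "probability":
        raise ValueError("threshold_map expects a probability grid")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    binary = (prob_map.data >= threshold).astype(np.uint8)
    return VolumeGrid(data=binary, voxel_dims=prob_map.voxel_dims,
                      affine=prob_map.affine.copy(), kind="binary")


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(
            f"grid shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.voxel_dims, b.voxel_dims, atol=_GRID_ATOL):
        raise ValueError(
            f"voxel_dims mismatch: {a.voxel_dims} vs {b.voxel_dims}")
    if not np.allclose(a.affine, b.affine, atol=_GRID_ATOL):
        raise ValueError("affine mismatch between grids")


def lesion_overlap(lesion: VolumeGrid, network: VolumeGrid) -> OverlapResult:
    """Voxelwise intersection of a binary lesion mask with a binary network mask."""
    if lesion.kind != "binary" or network.kind != "binary":
        raise ValueError("lesion_overlap expects binary grids")
    _check_same_grid(lesion, network)
    overlap = np.logical_and(lesion.data > 0, network.data > 0)
    n_overlap = int(np.count_nonzero(overlap))
    vox = lesion.voxel_volume_cm3
    net_vol = network.volume_cm3
    les_vol = lesion.volume_cm3
    return OverlapResult(
        n_overlap_voxels=n_overlap,
        overlap_volume=n_overlap * vox,
        network_volume=net_vol,
        lesion_volume=les_vol,
        proportion_network_damaged=(n_overlap * vox / net_vol) if net_vol else 0.0,
        proportion_lesion_in_network=(n_overlap * vox / les_vol) if les_vol else 0.0,
    )
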