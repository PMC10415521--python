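"""Volumes, dynamic series and mask resampling.

Every processing stage consumes and produces :class:`VolumeGrid` objects — a
3D scalar array bundled with a voxel-to-world affine — so that geometric
questions (laterality, resampling between the T2w and DCE grids) are always
answered in world coordinates, never from array-index conventions.

World coordinates follow the RAS+ convention used by NIfTI: +x points to the
subject's right, +y anterior, +z superior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """A file could not be interpreted as the expected volume type."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with geometry metadata.

    Parameters
    ----------
    values : (nx, ny, nz) ndarray
        Scalar voxel values; must be finite.
    affine : (4, 4) ndarray
        Voxel-index to world-millimetre map (homogeneous).
    axis_convention : str
        Label of the world frame; ``"RAS+"`` throughout this package.
    """

    values: np.ndarray
    affine: np.ndarray
    axis_convention: str = "RAS+"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(
                f"VolumeGrid requires a 3D array, got shape {self.values.shape}"
            )
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("volume values must be finite")
        if np.any(self.voxel_size_mm <= 0):
            raise FormatError("voxel spacings derived from the affine must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis spacing (mm) — column norms of the linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.affine.copy(), self.axis_convention)


@dataclass
class DceSeries:
    """An ordered dynamic contrast-enhanced series on one geometry.

    ``data`` is 4D with time last; frame 0 is the pre-contrast (FTP) frame.
    """

    data: np.ndarray
    affine: np.ndarray
    times_s: np.ndarray
    pre_contrast_index: int = 0
    axis_convention: str = "RAS+"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"DceSeries requires a 4D array, got {self.data.shape}")
        if self.times_s.shape != (self.data.shape[3],):
            raise FormatError("times_s length must equal the number of frames")
        if np.any(np.diff(self.times_s) <= 0):
            raise FormatError("times_s must be strictly increasing")
        if self.pre_contrast_index != 0:
            raise FormatError("pre-contrast frame must be frame 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_post(self) -> int:
        return self.n_frames - 1

    def frame(self, t: int) -> VolumeGrid:
        return VolumeGrid(self.data[..., t], self.affine.copy(), self.axis_convention)


# ---------------------------------------------------------------------------
# I/O


def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI volume.

    Raises
    ------
    FormatError
        If the file holds a non-spatial 4th dimension (use
        :func:`read_series` for dynamic data).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] == 1:
            data = data[..., 0]
        else:
            raise FormatError(
                f"{path}: 4th dimension of size {data.shape[3]} is non-spatial; "
                "use read_series for dynamic data"
            )
    elif data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    return VolumeGrid(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(volume: VolumeGrid, path) -> str:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return str(path)


def write_mask_volume(values: np.ndarray, affine: np.ndarray, path) -> str:
    """Write a boolean mask as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.uint8), np.asarray(affine, float))
    nib.save(img, str(path))
    return str(path)


def read_series(path, times_path=None) -> DceSeries:
    """Read a 4D NIfTI series; frame times from a JSON sidecar if given.

    The sidecar must hold ``{"times_s": [...]}``.  Without one, frames are
    placed at unit spacing.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4D data, got shape {data.shape}")
    if times_path is not None:
        with open(times_path) as fh:
            times = np.asarray(json.load(fh)["times_s"], dtype=float)
    else:
        times = np.arange(data.shape[3], dtype=float)
    return DceSeries(np.asarray(data, dtype=np.float64), np.asarray(img.affine), times)


def write_series(series: DceSeries, path, times_path=None) -> str:
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float64), series.affine)
    nib.save(img, str(path))
    if times_path is not None:
        with open(times_path, "w") as fh:
            json.dump({"times_s": series.times_s.tolist()}, fh)
    return str(path)


# ---------------------------------------------------------------------------
# Resampling


def resample_mask_values(
    mask_values: np.ndarray,
    source_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbour transfer of a boolean mask onto a target grid.

    Each target voxel centre is mapped to world coordinates and back into the
    source voxel frame; the nearest source voxel supplies the value.  Target
    voxels that land outside the source field of view are False.
    """
    src_inv = np.linalg.inv(np.asarray(source_affine, dtype=float))
    tgt = np.asarray(target_affine, dtype=float)
    # voxel(target) -> world -> voxel(source), as one homogeneous map
    m = src_inv @ tgt
    ii, jj, kk = np.meshgrid(
        np.arange(target_shape[0]),
        np.arange(target_shape[1]),
        np.arange(target_shape[2]),
        indexing="ij",
    )
    coords = np.stack([ii, jj, kk], axis=0).reshape(3, -1).astype(float)
    src_coords = m[:3, :3] @ coords + m[:3, 3:4]
    out = ndimage.map_coordinates(
        np.asarray(mask_values, dtype=np.uint8),
        src_coords,
        order=0,
        mode="constant",
        cval=0,
    )
    out = out.reshape(target_shape).astype(bool)
    if np.any(mask_values) and not np.any(out):
        warnings.warn(
            "resampled mask is empty: source and target fields of view "
            "do not overlap",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def write_map_volume(values: np.ndarray, affine: np.ndarray, path) -> str:
    """Write a float map that may contain NaN background (e.g. a BPE map
    defined only over the parenchyma)."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64),
                          np.asarray(affine, float))
    nib.save(img, str(path))
    return str(path)
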