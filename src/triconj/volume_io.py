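"""Volume/table I/O, acquisition-grid geometry and world<->lattice conversion.

All pipeline volumes live on a single :class:`AcquisitionGrid`.  Lattice
coordinates are 0-based voxel indices; world coordinates are MNI millimetres
obtained through the grid affine.  Event and motion tables are plain
tab-separated files so that every artifact in a dataset is text.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionGrid",
    "Volume",
    "Mask",
    "VolumeIOError",
    "read_volume",
    "read_run",
    "write_volume",
    "write_run",
    "read_events",
    "write_events",
    "read_motion",
    "write_motion",
    "gray_matter_mask",
    "EVENT_COLUMNS",
    "MOTION_COLUMNS",
]

EVENT_COLUMNS = ("onset_s", "duration_s", "condition", "outcome")
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class VolumeIOError(IOError):
    """Raised for unreadable or malformed volume files."""


@dataclasses.dataclass(frozen=True)
class AcquisitionGrid:
    """Lattice dimensions, voxel sizes (mm), TR (s) and world affine.

    Parameters
    ----------
    dims
        Number of voxels along each axis; all >= 1.
    voxel_size
        Voxel edge lengths in mm; all > 0.
    tr
        Repetition time in seconds.
    affine
        4x4 voxel-index -> world-mm transform; must be invertible.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {dims}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be > 0, got {vs}")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or not np.all(np.isfinite(aff)):
            raise ValueError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "tr", float(self.tr))
        aff = aff.copy()
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def centered(
        cls,
        dims: Sequence[int],
        voxel_size: Sequence[float],
        tr: float,
    ) -> "AcquisitionGrid":
        """Grid whose world origin sits at the lattice centre (RAS axes)."""
        dims = tuple(int(d) for d in dims)
        vs = tuple(float(v) for v in voxel_size)
        affine = np.eye(4)
        for ax in range(3):
            affine[ax, ax] = vs[ax]
            affine[ax, 3] = -vs[ax] * (dims[ax] - 1) / 2.0
        return cls(dims=dims, voxel_size=vs, tr=tr, affine=affine)

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        """Map continuous lattice coordinates to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz_mm: Sequence[float]) -> np.ndarray:
        """Map world mm to continuous lattice coordinates."""
        xyz = np.asarray(xyz_mm, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """World mm coordinate of every voxel centre, shape dims + (3,)."""
        idx = np.indices(self.dims, dtype=float)
        ijk = np.stack(idx, axis=-1)
        return self.voxel_to_world(ijk)

    def same_geometry(self, other: "AcquisitionGrid", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclasses.dataclass
class Volume:
    """Scalar lattice with its grid."""

    values: np.ndarray
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"value shape {self.values.shape} != grid dims {self.grid.dims}"
            )


@dataclasses.dataclass
class Mask:
    """Boolean lattice with its grid."""

    membership: np.ndarray
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.membership.shape} != grid dims {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


def _grid_from_img(img: nib.Nifti1Image) -> AcquisitionGrid:
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    affine = np.asarray(img.affine, dtype=float)
    if not np.all(np.isfinite(affine)):
        raise VolumeIOError("non-finite affine in NIfTI header")
    return AcquisitionGrid(
        dims=tuple(int(d) for d in img.shape[:3]),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=tr,
        affine=affine,
    )


def read_volume(path: str | Path):
    """Read a NIfTI-1 file.

    Returns a single :class:`Volume` for 3-D images and an ordered list of
    Volumes (one per frame) for 4-D images.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    grid = _grid_from_img(img)
    if data.ndim == 3:
        return Volume(values=data, grid=grid)
    if data.ndim == 4:
        return [Volume(values=data[..., t], grid=grid) for t in range(data.shape[3])]
    raise VolumeIOError(f"unsupported image dimensionality {data.ndim} in {path}")


def read_run(path: str | Path) -> tuple[np.ndarray, AcquisitionGrid]:
    """Read a 4-D run as a (x, y, z, t) array plus its grid."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:
        raise VolumeIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise VolumeIOError(f"expected a 4-D run, got {data.ndim}-D in {path}")
    return data, _grid_from_img(img)


def _make_img(data: np.ndarray, grid: AcquisitionGrid) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(grid.affine))
    zooms = grid.voxel_size + ((grid.tr,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    if data.ndim == 4:
        img.header.set_xyzt_units("mm", "sec")
    return img


def write_volume(path: str | Path, volume: Volume) -> None:
    _make_img(volume.values, volume.grid).to_filename(str(path))


def write_run(path: str | Path, data: np.ndarray, grid: AcquisitionGrid) -> None:
    data = np.asarray(data)
    if data.ndim != 4:
        raise ValueError("write_run expects (x, y, z, t) data")
    _make_img(data, grid).to_filename(str(path))


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated event table (onset_s, duration_s, condition, outcome)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event table {path} missing columns {sorted(missing)}")
    return table


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    events.loc[:, list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_motion(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(MOTION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"motion table {path} missing columns {sorted(missing)}")
    return table


def write_motion(path: str | Path, motion: pd.DataFrame) -> None:
    motion.loc[:, list(MOTION_COLUMNS)].to_csv(path, sep="\t", index=False)


def gray_matter_mask(prob: Volume, threshold: float = 0.8) -> Mask:
    """Threshold a tissue-probability volume; membership where prob >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    values = prob.values
    if values.min() < 0 or values.max() > 1:
        raise ValueError("probability volume has values outside [0, 1]")
    return Mask(membership=values >= threshold, grid=prob.grid)
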