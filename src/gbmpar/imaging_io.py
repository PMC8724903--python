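"""Volume containers, NIfTI I/O, grid resampling and mask algebra.

Every map and mask in the pipeline is carried as a :class:`VolumeImage` or
:class:`BinaryMask` on a voxel grid with physical spacing and an axis
orientation (RAS-style axis codes).  All mask algebra happens in grid space
after resampling to a single reference grid; geometry mismatches are hard
errors, never silently resampled away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "DynamicSeries",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_series",
    "write_series",
    "resample_to_reference",
    "mirror_mask",
    "mask_ops",
]

#: spacing agreement tolerance (mm) for "same geometry"
SPACING_TOL_MM = 1e-6


class GeometryError(ValueError):
    """Raised when two volumes that must share a grid do not."""


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeImage:
    """A 3D scalar map (SUV, CBV, rCBV, ...) on a physical voxel grid.

    Parameters
    ----------
    voxels
        3D array of map values.
    spacing
        Voxel size (dx, dy, dz) in mm, all > 0.
    orientation
        Axis-code triple (e.g. ``('R', 'A', 'S')``) identifying, in
        particular, which array axis runs left-right.
    units
        Free-form unit tag, e.g. ``"SUV g/mL"`` or ``"rCBV ratio"``.
    affine
        Voxel-to-world transform; defaults to a diagonal built from spacing.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: tuple[str, str, str] = ("R", "A", "S")
    units: str = "a.u."
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.orientation = tuple(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def lr_axis(self) -> int:
        """Array axis running left-right, from the orientation codes."""
        for ax, code in enumerate(self.orientation):
            if code in ("L", "R"):
                return ax
        raise ValueError(
            f"no left-right axis in orientation {self.orientation}"
        )

    def same_geometry(self, other: "VolumeImage | BinaryMask") -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= SPACING_TOL_MM
            for a, b in zip(self.spacing, other.spacing)
        )

    def check_geometry(self, other: "VolumeImage | BinaryMask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )

    def with_voxels(self, voxels: np.ndarray, units: str | None = None) -> "VolumeImage":
        return replace(
            self, voxels=voxels, units=self.units if units is None else units
        )


@dataclass
class BinaryMask:
    """A boolean ROI sharing the geometry contract of :class:`VolumeImage`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: tuple[str, str, str] = ("R", "A", "S")
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.orientation = tuple(self.orientation)

    shape = VolumeImage.shape
    voxel_volume_mm3 = VolumeImage.voxel_volume_mm3
    lr_axis = VolumeImage.lr_axis
    same_geometry = VolumeImage.same_geometry
    check_geometry = VolumeImage.check_geometry

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def with_voxels(self, voxels: np.ndarray) -> "BinaryMask":
        return replace(self, voxels=np.asarray(voxels).astype(bool))

    @classmethod
    def like(cls, ref: "VolumeImage | BinaryMask", voxels: np.ndarray) -> "BinaryMask":
        return cls(
            voxels=voxels,
            spacing=ref.spacing,
            orientation=ref.orientation,
            affine=ref.affine,
        )


@dataclass
class DynamicSeries:
    """A 4D DSC-MRI acquisition: T frames of a 3D grid plus timing metadata.

    ``injection_delay_s`` is the pre-bolus baseline duration; at least one
    full frame must fall before it so a baseline S0 can be estimated.
    """

    frames: np.ndarray  # (T, x, y, z)
    tr_s: float
    te_ms: float
    injection_delay_s: float
    spacing: tuple[float, float, float] = (2.19, 2.19, 7.0)
    orientation: tuple[str, str, str] = ("R", "A", "S")
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError(f"expected 4D series, got {self.frames.ndim}D")
        if self.frames.shape[0] < 2:
            raise ValueError("series needs at least 2 time points")
        if self.tr_s <= 0 or self.te_ms <= 0:
            raise ValueError("tr_s and te_ms must be positive")
        if self.injection_delay_s < 0:
            raise ValueError("injection_delay_s must be >= 0")
        if self.injection_delay_s < self.tr_s:
            raise ValueError(
                "need at least one fully pre-bolus frame "
                "(injection_delay_s >= tr_s)"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.orientation = tuple(self.orientation)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        """Acquisition time of each frame (s), frame k at k*TR."""
        return np.arange(self.n_frames) * self.tr_s

    def spatial_reference(self) -> VolumeImage:
        return VolumeImage(
            voxels=self.frames[0],
            spacing=self.spacing,
            orientation=self.orientation,
            affine=self.affine,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return img


def _header_geometry(img) -> tuple[tuple, tuple, np.ndarray]:
    zooms = img.header.get_zooms()[:3]
    if not all(np.isfinite(zooms)) or any(z <= 0 for z in zooms):
        raise ValueError(f"non-finite or non-positive spacing {zooms}")
    orientation = nib.aff2axcodes(img.affine)
    return tuple(float(z) for z in zooms), orientation, np.asarray(img.affine)


def read_volume(path: str | Path, units: str = "a.u.") -> VolumeImage:
    """Read a 3D NIfTI volume; spacing and orientation from the header."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D payload")
    spacing, orientation, affine = _header_geometry(img)
    return VolumeImage(
        voxels=np.asarray(data, dtype=float),
        spacing=spacing,
        orientation=orientation,
        units=units,
        affine=affine,
    )


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.voxels, dtype=np.float32), vol.affine
    )
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a uint8 0/1 NIfTI mask."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D payload")
    spacing, orientation, affine = _header_geometry(img)
    return BinaryMask(
        voxels=data > 0, spacing=spacing, orientation=orientation,
        affine=affine,
    )


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_series(path: str | Path, sidecar: str | Path | None = None) -> DynamicSeries:
    """Read a 4D NIfTI DSC series.

    TR is taken from the header time step; TE and injection delay come from a
    sidecar JSON (keys ``"EchoTimeMs"``, ``"InjectionDelayS"``); by default
    the sidecar is the NIfTI path with a ``.json`` suffix.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D series, got {data.ndim}D payload")
    spacing, orientation, affine = _header_geometry(img)
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
    if sidecar is None:
        sidecar = Path(path).with_suffix("").with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text())
    return DynamicSeries(
        frames=np.moveaxis(np.asarray(data, dtype=float), 3, 0),
        tr_s=tr_s,
        te_ms=float(meta["EchoTimeMs"]),
        injection_delay_s=float(meta["InjectionDelayS"]),
        spacing=spacing,
        orientation=orientation,
        affine=affine,
    )


def write_series(series: DynamicSeries, path: str | Path,
                 sidecar: str | Path | None = None) -> None:
    data = np.moveaxis(series.frames, 0, 3).astype(np.float32)
    img = nib.Nifti1Image(data, series.affine)
    img.header.set_zooms(series.spacing + (series.tr_s,))
    nib.save(img, str(path))
    if sidecar is None:
        sidecar = Path(path).with_suffix("").with_suffix(".json")
    Path(sidecar).write_text(json.dumps({
        "EchoTimeMs": series.te_ms,
        "InjectionDelayS": series.injection_delay_s,
    }))


# ---------------------------------------------------------------------------
# Resampling, mirroring, mask algebra


def resample_to_reference(moving, reference, mode: str = "trilinear"):
    """Resample ``moving`` onto the grid of ``reference``.

    Inputs are assumed co-registered (identity world transform); only the
    grids differ.  Reference voxel centers are mapped to moving voxel indices
    through both affines.  ``mode="nearest"`` is mandatory for masks; values
    outside the moving extent are 0.
    """
    is_mask = isinstance(moving, BinaryMask)
    if is_mask and mode == "trilinear":
        raise ValueError("trilinear interpolation requested for a boolean mask")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")

    if moving.same_geometry(reference):
        return moving.with_voxels(moving.voxels.copy())

    ref_shape = reference.shape
    idx = np.indices(ref_shape).reshape(3, -1)
    ones = np.ones((1, idx.shape[1]))
    world = reference.affine @ np.vstack([idx, ones])
    mov_idx = np.linalg.inv(moving.affine) @ world
    coords = mov_idx[:3]

    order = 0 if mode == "nearest" else 1
    src = moving.voxels.astype(float)
    out = ndimage.map_coordinates(
        src, coords, order=order, mode="constant", cval=0.0
    ).reshape(ref_shape)

    if is_mask:
        return BinaryMask(
            voxels=out > 0.5, spacing=reference.spacing,
            orientation=reference.orientation, affine=reference.affine,
        )
    return VolumeImage(
        voxels=out, spacing=reference.spacing,
        orientation=reference.orientation, units=moving.units,
        affine=reference.affine,
    )


def mirror_mask(mask: BinaryMask) -> BinaryMask:
    """Reflect a mask about the mid-sagittal plane.

    Voxel ``i`` along the left-right axis maps to ``N-1-i``; this realizes
    the "normal-appearing contralateral side" as a mirror of the grid.
    """
    ax = mask.lr_axis()
    return mask.with_voxels(np.flip(mask.voxels, axis=ax))


def mirror_volume(vol: VolumeImage) -> VolumeImage:
    ax = vol.lr_axis()
    return vol.with_voxels(np.flip(vol.voxels, axis=ax))


def mask_ops(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Voxelwise Boolean combination of two masks on the same grid.

    ``NOT`` is set difference (a AND NOT b), the Boolean operation behind the
    peripheral-volume definitions.
    """
    a.check_geometry(b)
    op = op.upper()
    if op == "AND":
        out = a.voxels & b.voxels
    elif op == "OR":
        out = a.voxels | b.voxels
    elif op == "NOT":
        out = a.voxels & ~b.voxels
    elif op == "XOR":
        out = a.voxels ^ b.voxels
    else:
        raise ValueError(f"unknown op {op!r}")
    return a.with_voxels(out)
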