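"""Core voxel-grid containers shared by every pipeline stage.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` (single channel) or ``(c, z, y, x)``
  (multi-channel); physical spacing is given as ``(dz, dy, dx)`` in µm.
* The centre of voxel ``(i, j, k)`` sits at the physical coordinate
  ``(i*dz, j*dy, k*dx)`` µm, so the sampled physical domain of an axis with
  ``n`` voxels is ``[0, (n-1)*spacing]``.

The default acquisition geometry mirrors a typical high-NA confocal
z-stack: ~60 optical sections at 0.2 µm z-spacing with 0.299 µm pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import DomainError

__all__ = [
    "AcquisitionGeometry",
    "ChannelStack",
    "SurfaceMask",
    "SpotSet",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
]

DEFAULT_SPACING_UM = (0.2, 0.299, 0.299)
DEFAULT_SHAPE = (60, 256, 256)

#: 6-connectivity structuring element used for surface extraction.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel lattice of a z-stack: shape in voxels plus physical spacing.

    Parameters
    ----------
    shape_voxels:
        ``(nz, ny, nx)``; every entry must be at least 8.
    spacing_um:
        ``(dz, dy, dx)`` in µm; strictly positive.
    """

    shape_voxels: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if len(self.shape_voxels) != 3 or len(self.spacing_um) != 3:
            raise DomainError("geometry must be three-dimensional")
        if any(int(n) < 8 for n in self.shape_voxels):
            raise DomainError(f"stack shape {self.shape_voxels} has an axis < 8 voxels")
        if any(s <= 0 for s in self.spacing_um):
            raise DomainError(f"voxel spacing {self.spacing_um} must be positive")
        object.__setattr__(self, "shape_voxels", tuple(int(n) for n in self.shape_voxels))
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent spanned by voxel centres, per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape_voxels, self.spacing_um))

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape_voxels))


@dataclass
class ChannelStack:
    """One or more fluorescence channels on a common voxel lattice.

    ``data`` is ``(z, y, x)`` for a single channel or ``(c, z, y, x)`` for a
    multi-channel stack.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise DomainError(f"stack data must be 3D or 4D, got ndim={self.data.ndim}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise DomainError(f"voxel spacing {self.spacing_um} must be positive")

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return tuple(self.data.shape[-3:])

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing_um))

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def channel(self, i: int) -> "ChannelStack":
        """Return channel ``i`` as a single-channel view."""
        if self.data.ndim == 3:
            if i != 0:
                raise DomainError(f"single-channel stack has no channel {i}")
            return self
        return ChannelStack(self.data[i], self.spacing_um)


@dataclass
class SurfaceMask:
    """Binary voxel mask of a segmented object plus its 6-connectivity surface.

    The *surface* is the set of mask voxels with at least one face-neighbour
    outside the mask; voxels on the array border count as surface (the stack
    edge truncates the object).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    smoothing_detail_um: float = 0.145

    _surface: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise DomainError("mask must be a 3D voxel grid")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return self.n_voxels * dz * dy * dx

    @property
    def surface_mask(self) -> np.ndarray:
        """Boolean grid of surface voxels (6-connectivity boundary)."""
        if self._surface is None:
            interior = ndimage.binary_erosion(self.voxels, structure=_STRUCT_6, border_value=0)
            self._surface = self.voxels & ~interior
        return self._surface

    @property
    def surface_voxels(self) -> np.ndarray:
        """``(n, 3)`` integer indices of surface voxels, lexicographic order."""
        return np.argwhere(self.surface_mask)

    def centroid_um(self) -> np.ndarray:
        if self.is_empty:
            raise DomainError("cannot take the centroid of an empty mask")
        idx = np.argwhere(self.voxels)
        return idx.mean(axis=0) * np.asarray(self.spacing_um)


@dataclass
class SpotSet:
    """Point objects (detected or simulated) with physical coordinates.

    ``centers_um`` is ``(n, 3)`` in ``(z, y, x)`` µm; ``diameter_um`` is the
    common detection/render diameter; ``quality`` is an optional per-spot
    detection score.
    """

    centers_um: np.ndarray
    diameter_um: float = 0.723
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.centers_um = np.atleast_2d(np.asarray(self.centers_um, dtype=float))
        if self.centers_um.size == 0:
            self.centers_um = self.centers_um.reshape(0, 3)
        if self.centers_um.shape[1] != 3:
            raise DomainError("spot centers must be (n, 3) in (z, y, x) µm")
        if self.diameter_um <= 0:
            raise DomainError("spot diameter must be positive")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape[0] != len(self):
                raise DomainError("quality must have one entry per spot")

    def __len__(self) -> int:
        return self.centers_um.shape[0]

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    def to_csv(self, path) -> None:
        q = self.quality if self.quality is not None else np.full(len(self), np.nan)
        df = pd.DataFrame(
            {
                "z_um": self.centers_um[:, 0],
                "y_um": self.centers_um[:, 1],
                "x_um": self.centers_um[:, 2],
                "diameter_um": np.full(len(self), self.diameter_um),
                "quality": q,
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "SpotSet":
        df = pd.read_csv(path)
        cols = {"z_um", "y_um", "x_um"}
        if not cols.issubset(df.columns):
            raise DomainError(f"spot CSV {path} lacks columns {sorted(cols)}")
        centers = df[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        if "diameter_um" in df.columns and len(df):
            diameter = float(df["diameter_um"].iloc[0])
        elif "radius_um" in df.columns and len(df):
            diameter = 2.0 * float(df["radius_um"].iloc[0])
        else:
            diameter = 0.723
        quality = df["quality"].to_numpy(dtype=float) if "quality" in df.columns else None
        return cls(centers, diameter_um=diameter, quality=quality)


# ---------------------------------------------------------------------------
# TIFF round-trips (ImageJ-style metadata: z-spacing + x/y resolution)
# ---------------------------------------------------------------------------


def write_stack(path, stack: ChannelStack) -> None:
    """Write a stack as ImageJ-flavoured TIFF with voxel size metadata."""
    dz, dy, dx = stack.spacing_um
    arr = np.asarray(stack.data, dtype=np.float32)
    if arr.ndim == 4:  # (c, z, y, x) -> ImageJ hyperstack axis order (z, c, y, x)
        arr = np.moveaxis(arr, 0, 1)
        axes = "ZCYX"
    else:
        axes = "ZYX"
    tifffile.imwrite(
        str(path),
        arr,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": axes},
    )


def _read_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float]:
    dz = dy = dx = 1.0
    meta = tif.imagej_metadata or {}
    if "spacing" in meta:
        dz = float(meta["spacing"])
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None:
        num, den = xres.value
        if num:
            dx = den / num
    if yres is not None:
        num, den = yres.value
        if num:
            dy = den / num
    return (dz, dy, dx)


def read_stack(path) -> ChannelStack:
    """Read a TIFF written by :func:`write_stack` (or any ZYX/ZCYX TIFF)."""
    path = Path(path)
    if not path.exists():
        raise DomainError(f"stack file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        spacing = _read_spacing(tif)
    if "C" in axes and arr.ndim == 4:
        arr = np.moveaxis(arr, axes.index("C"), 0)  # -> (c, z, y, x)
    return ChannelStack(np.asarray(arr, dtype=np.float32), spacing)


def write_mask(path, mask: SurfaceMask) -> None:
    """Write a binary mask as uint8 TIFF with voxel size metadata."""
    dz, dy, dx = mask.spacing_um
    tifffile.imwrite(
        str(path),
        mask.voxels.astype(np.uint8),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def read_mask(path) -> SurfaceMask:
    path = Path(path)
    if not path.exists():
        raise DomainError(f"mask file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.series[0].asarray()
        spacing = _read_spacing(tif)
    return SurfaceMask(arr > 0, spacing)
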