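"""Marker arborization volume fractions in standardized ROIs.

Two marker channels (e.g. interneuron vs principal-neuron stains) are
binarized in fixed-size ROIs and the voxel volume of each is expressed as a
percentage of the two-marker total (marker₁% + marker₂% = 100).  The
default ROI is 185 µm × 185 µm × 5 µm (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ChannelStack, SurfaceMask
from .errors import DomainError
from .stats import unpaired_t

__all__ = [
    "DEFAULT_ROI_UM",
    "VolumeFractionResult",
    "crop_roi",
    "channel_volume_fraction",
    "volume_fraction_cohort",
]

#: Default ROI size in µm, (x, y, z) order.
DEFAULT_ROI_UM = (185.0, 185.0, 5.0)


@dataclass
class VolumeFractionResult:
    """Two-marker volume split within one ROI, normalized to 100%."""

    vol_marker1_um3: float
    vol_marker2_um3: float
    pct_marker1: float
    pct_marker2: float
    ratio: float
    roi_id: str | None = None
    roi_size_um: tuple[float, float, float] = DEFAULT_ROI_UM


def crop_roi(
    stack: ChannelStack,
    roi_size_um: Sequence[float] = DEFAULT_ROI_UM,
    origin_um: Sequence[float] = (0.0, 0.0, 0.0),
) -> ChannelStack:
    """Crop a fixed-size ROI with preserved spacing metadata.

    ``roi_size_um`` and ``origin_um`` are in (x, y, z) µm.  The voxel count
    per axis is ``round(size/spacing)`` (so a 1 µm slab at 0.2 µm z-spacing
    is exactly 5 voxels); ROIs extending beyond the stack raise
    :class:`DomainError`.
    """
    size_xyz = np.asarray(roi_size_um, dtype=float)
    origin_xyz = np.asarray(origin_um, dtype=float)
    if np.any(size_xyz <= 0):
        raise DomainError(f"ROI size {tuple(size_xyz)} µm must be positive on every axis")
    size_zyx = size_xyz[::-1]
    origin_zyx = origin_xyz[::-1]
    spacing = np.asarray(stack.spacing_um)
    n_vox = np.rint(size_zyx / spacing).astype(int)
    if np.any(n_vox < 1):
        raise DomainError(f"ROI {tuple(size_xyz)} µm resolves below one voxel on an axis")
    start = np.rint(origin_zyx / spacing).astype(int)
    stop = start + n_vox
    shape = np.asarray(stack.shape)
    if np.any(start < 0) or np.any(stop > shape):
        raise DomainError(
            f"ROI voxel range {tuple(start)}..{tuple(stop)} exceeds stack shape {tuple(shape)}"
        )
    sl = tuple(slice(a, b) for a, b in zip(start, stop))
    data = stack.data[(...,) + sl] if stack.data.ndim == 4 else stack.data[sl]
    return ChannelStack(data.copy(), stack.spacing_um)


def channel_volume_fraction(
    mask1: SurfaceMask,
    mask2: SurfaceMask,
    roi_id: str | None = None,
    roi_size_um: tuple[float, float, float] = DEFAULT_ROI_UM,
) -> VolumeFractionResult:
    """Percent volume of each marker, normalized so the two sum to 100.

    ``ratio`` is larger/smaller (``inf`` when one marker is absent).
    """
    if mask1.voxels.shape != mask2.voxels.shape or mask1.spacing_um != mask2.spacing_um:
        raise DomainError("marker masks live on different ROI grids")
    v1, v2 = mask1.volume_um3, mask2.volume_um3
    total = v1 + v2
    if total == 0:
        raise DomainError("both marker masks are empty; volume fractions undefined")
    p1 = 100.0 * v1 / total
    p2 = 100.0 - p1
    lo, hi = min(p1, p2), max(p1, p2)
    ratio = np.inf if lo == 0 else hi / lo
    return VolumeFractionResult(v1, v2, p1, p2, ratio, roi_id=roi_id, roi_size_um=roi_size_um)


def volume_fraction_cohort(results: Sequence[VolumeFractionResult]) -> dict:
    """Cohort summary plus an unpaired two-tailed t-test between markers.

    The test compares the per-ROI percent volumes of marker 1 against those
    of marker 2 across ROIs.
    """
    if len(results) < 2:
        raise DomainError("cohort summary requires at least 2 ROIs")
    p1 = np.array([r.pct_marker1 for r in results])
    p2 = np.array([r.pct_marker2 for r in results])
    ratios = np.array([r.ratio for r in results])
    t, p = unpaired_t(p1, p2)
    n = len(results)
    return {
        "n_rois": n,
        "mean_pct_marker1": float(p1.mean()),
        "sem_pct_marker1": float(p1.std(ddof=1) / np.sqrt(n)),
        "mean_pct_marker2": float(p2.mean()),
        "sem_pct_marker2": float(p2.std(ddof=1) / np.sqrt(n)),
        "mean_ratio": float(ratios[np.isfinite(ratios)].mean()),
        "t": t,
        "p": p,
    }


def cohort_frame(results: Sequence[VolumeFractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in results],
            "pct_marker1": [r.pct_marker1 for r in results],
            "pct_marker2": [r.pct_marker2 for r in results],
            "ratio": [r.ratio for r in results],
        }
    )
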