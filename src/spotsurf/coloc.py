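"""Voxel-volume overlap colocalization and double-positive soma counting.

The overlap statistic is the directional volume fraction between two
binarized channels: ``frac_a_in_b = 100·|A∩B|/|A|`` (what fraction of
channel A's voxel volume also carries channel B) and vice versa.  ROI-level
results are pooled volume-weighted (``100·Σ|∩| / Σ|A|``), not as a mean of
per-ROI ratios, so large ROIs contribute proportionally to their volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import SurfaceMask
from .errors import DomainError

__all__ = [
    "OverlapResult",
    "overlap_fractions",
    "aggregate_overlap",
    "count_double_positive",
    "recombination_rate",
    "proportion_pct",
]


@dataclass
class OverlapResult:
    """Directional voxel-volume overlap between two binarized channels."""

    vol_a_um3: float
    vol_b_um3: float
    vol_intersection_um3: float
    roi_id: Optional[str] = None
    group: Optional[str] = None

    @property
    def frac_a_in_b(self) -> float:
        """Percentage of channel A volume that overlaps channel B."""
        return 100.0 * self.vol_intersection_um3 / self.vol_a_um3 if self.vol_a_um3 > 0 else 0.0

    @property
    def frac_b_in_a(self) -> float:
        """Percentage of channel B volume that overlaps channel A."""
        return 100.0 * self.vol_intersection_um3 / self.vol_b_um3 if self.vol_b_um3 > 0 else 0.0


def overlap_fractions(mask_a: SurfaceMask, mask_b: SurfaceMask,
                      roi_id: Optional[str] = None,
                      group: Optional[str] = None) -> OverlapResult:
    """Voxelwise intersection volumes and both directional fractions."""
    if mask_a.voxels.shape != mask_b.voxels.shape or mask_a.spacing_um != mask_b.spacing_um:
        raise DomainError(
            f"masks live on different grids: {mask_a.voxels.shape}@{mask_a.spacing_um} "
            f"vs {mask_b.voxels.shape}@{mask_b.spacing_um}"
        )
    vv = float(np.prod(mask_a.spacing_um))
    inter = int(np.count_nonzero(mask_a.voxels & mask_b.voxels))
    return OverlapResult(
        vol_a_um3=mask_a.n_voxels * vv,
        vol_b_um3=mask_b.n_voxels * vv,
        vol_intersection_um3=inter * vv,
        roi_id=roi_id,
        group=group,
    )


def aggregate_overlap(results: Sequence[OverlapResult], by_group: bool = False) -> pd.DataFrame:
    """Volume-weighted pooled overlap fractions, overall and per group.

    Pooled fraction = ``100·Σ∩ / ΣA`` over the contributing ROIs; the
    per-ROI mean ± SEM is reported alongside for reference.
    """
    if not results:
        raise DomainError("no overlap results to aggregate")

    def _row(label, rs):
        va = sum(r.vol_a_um3 for r in rs)
        vb = sum(r.vol_b_um3 for r in rs)
        vi = sum(r.vol_intersection_um3 for r in rs)
        fa = np.array([r.frac_a_in_b for r in rs])
        fb = np.array([r.frac_b_in_a for r in rs])
        n = len(rs)
        return {
            "group": label,
            "n_rois": n,
            "pooled_frac_a_in_b_pct": 100.0 * vi / va if va > 0 else 0.0,
            "pooled_frac_b_in_a_pct": 100.0 * vi / vb if vb > 0 else 0.0,
            "mean_frac_a_in_b_pct": fa.mean(),
            "sem_frac_a_in_b_pct": fa.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "mean_frac_b_in_a_pct": fb.mean(),
            "sem_frac_b_in_a_pct": fb.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        }

    rows = [_row("all", list(results))]
    if by_group:
        groups = sorted({r.group for r in results if r.group is not None})
        for g in groups:
            rows.append(_row(g, [r for r in results if r.group == g]))
    return pd.DataFrame(rows)


@dataclass
class DoublePositiveCount:
    n_double: int
    n_a_only: int
    pct_double: float
    pct_a_only: float


def count_double_positive(
    somata: Sequence[Union[SurfaceMask, np.ndarray]],
    mask_b: SurfaceMask,
    min_overlap_frac: float = 0.5,
) -> DoublePositiveCount:
    """Count somata that are also positive for a second marker.

    Each entry of ``somata`` is either a :class:`SurfaceMask` (double
    positive when at least ``min_overlap_frac`` of its own volume overlaps
    ``mask_b``) or a centroid in (z, y, x) µm (double positive when the
    containing voxel of ``mask_b`` is set).
    """
    if not somata:
        raise DomainError("no somata supplied")
    if not 0.0 <= min_overlap_frac <= 1.0:
        raise DomainError("min_overlap_frac must lie in [0, 1]")
    spacing = np.asarray(mask_b.spacing_um)
    n_double = 0
    for s in somata:
        if isinstance(s, SurfaceMask):
            if s.voxels.shape != mask_b.voxels.shape:
                raise DomainError("soma mask grid differs from marker mask grid")
            own = s.n_voxels
            if own == 0:
                continue
            inter = int(np.count_nonzero(s.voxels & mask_b.voxels))
            if inter >= min_overlap_frac * own:
                n_double += 1
        else:
            c = np.asarray(s, dtype=float)
            vox = np.rint(c / spacing).astype(int)
            if np.any(vox < 0) or np.any(vox >= np.asarray(mask_b.voxels.shape)):
                raise DomainError(f"soma centroid {tuple(c)} µm outside the mask grid")
            if mask_b.voxels[tuple(vox)]:
                n_double += 1
    n = len(somata)
    n_only = n - n_double
    return DoublePositiveCount(
        n_double=n_double,
        n_a_only=n_only,
        pct_double=100.0 * n_double / n,
        pct_a_only=100.0 * n_only / n,
    )


def recombination_rate(n_observed_reporter: int, n_pv: int,
                       expected_pv_frac: float = 0.83) -> float:
    """Reporter recombination rate as a percentage of the expected population.

    ``100 · n_observed / (expected_pv_frac · n_pv)``: the observed number of
    reporter-positive neurons relative to the number expected if every
    co-expressing interneuron (a fraction ``expected_pv_frac`` of the PV
    count) had recombined.
    """
    if n_pv <= 0:
        raise DomainError("n_pv must be positive")
    if not 0.0 < expected_pv_frac <= 1.0:
        raise DomainError("expected_pv_frac must lie in (0, 1]")
    if n_observed_reporter < 0:
        raise DomainError("counts must be non-negative")
    return 100.0 * n_observed_reporter / (expected_pv_frac * n_pv)


def proportion_pct(count: int, total: int) -> float:
    """Simple count percentage ``100·k/n`` with validation."""
    if total <= 0:
        raise DomainError("total must be positive")
    if not 0 <= count <= total:
        raise DomainError("count must lie in [0, total]")
    return 100.0 * count / total
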