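"""Synthetic two/three-channel z-stacks with known ground truth.

Every downstream stage of the pipeline (background subtraction, spot and
surface detection, distance-binned enrichment, colocalization, volumetry)
can be exercised against known truth generated here:

* a neuron (soma sphere + branched tubes) occupying one channel,
* punctate axonal signal in a second channel whose placement density is
  enriched within a chemoattraction radius ``R`` of the neuron surface,
* channel pairs with prescribed voxel-overlap fractions,
* Poisson shot noise, Gaussian read noise and a smooth background.

The fiber channel is modelled as PSF-rendered point spots (not curvilinear
fibers) because the enrichment statistic itself reduces fibers to spots at a
fixed detection diameter; ground truth must live in the representation the
statistic consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from . import coloc as _coloc
from .chemo import DistanceField, distance_to_surface
from .core import AcquisitionGeometry, ChannelStack, SpotSet, SurfaceMask
from .errors import DomainError

__all__ = [
    "NeuronModel",
    "ChemoattractionKernel",
    "NoiseModel",
    "generate_neuron_mask",
    "rasterize_neuron",
    "sample_spots",
    "render_stack",
    "generate_coloc_pair",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian point-spread profile.
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class NeuronModel:
    """Generating geometry of a synthetic neuron: soma sphere + tube branches.

    ``branches`` is a list of ``(polyline_um, tube_radius_um)`` where the
    polyline is an ``(n, 3)`` array of control points in (z, y, x) µm.
    """

    soma_center_um: np.ndarray
    soma_radius_um: float
    branches: list[tuple[np.ndarray, float]] = field(default_factory=list)
    intensity: float = 100.0

    def __post_init__(self) -> None:
        self.soma_center_um = np.asarray(self.soma_center_um, dtype=float)
        if self.soma_radius_um <= 0:
            raise DomainError("soma radius must be positive")
        if self.intensity <= 0:
            raise DomainError("neuron intensity must be positive")


@dataclass(frozen=True)
class ChemoattractionKernel:
    """Distance-dependent placement-density multiplier for axonal spots.

    ``m(d) = 1 + A·1[d ≤ R]`` (flat) or ``1 + A·max(0, 1 − d/R)``
    (linear_ramp); ``m ≡ 1`` when ``A = 0`` or ``R = 0`` (pure CSR).
    """

    radius_um: float = 7.0
    amplitude: float = 1.0
    profile: str = "flat"

    def __post_init__(self) -> None:
        if self.radius_um < 0 or self.amplitude < 0:
            raise DomainError("kernel radius and amplitude must be non-negative")
        if self.profile not in ("flat", "linear_ramp"):
            raise DomainError(f"unknown kernel profile {self.profile!r}")

    def multiplier(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.amplitude == 0.0 or self.radius_um == 0.0:
            return np.ones_like(d)
        if self.profile == "flat":
            return 1.0 + self.amplitude * (d <= self.radius_um)
        return 1.0 + self.amplitude * np.maximum(0.0, 1.0 - d / self.radius_um)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: smooth background, Poisson shot, Gaussian read.

    ``photon_scale`` converts intensity to expected photon counts for the
    Poisson stage (``math.inf`` disables shot noise); ``read_sigma`` is the
    Gaussian read-noise standard deviation in intensity units.
    """

    background_level: float = 0.0
    background_smoothness_um: float = 5.0
    photon_scale: float = math.inf
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level < 0 or self.read_sigma < 0:
            raise DomainError("noise levels must be non-negative")
        if self.background_smoothness_um <= 0:
            raise DomainError("background smoothness must be positive")
        if not self.photon_scale > 0:
            raise DomainError("photon_scale must be positive (math.inf for noiseless)")


def _stamp_sphere(grid: np.ndarray, center_um: np.ndarray, radius_um: float,
                  spacing: np.ndarray) -> None:
    """Mark voxels whose centre lies within radius of a physical point."""
    lo = np.maximum(np.floor((center_um - radius_um) / spacing), 0).astype(int)
    hi = np.minimum(np.ceil((center_um + radius_um) / spacing) + 1,
                    np.asarray(grid.shape)).astype(int)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(*[np.arange(lo[a], hi[a]) * spacing[a] - center_um[a]
                               for a in range(3)], indexing="ij")
    ball = zz * zz + yy * yy + xx * xx <= radius_um * radius_um
    grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball


def rasterize_neuron(geom: AcquisitionGeometry, model: NeuronModel) -> np.ndarray:
    """Boolean voxel grid of the neuron (soma plus tubes) on the lattice."""
    spacing = np.asarray(geom.spacing_um)
    grid = np.zeros(geom.shape_voxels, dtype=bool)
    _stamp_sphere(grid, model.soma_center_um, model.soma_radius_um, spacing)
    for polyline, radius in model.branches:
        pts = np.asarray(polyline, dtype=float)
        # resample densely so consecutive stamps overlap (step < tube diameter)
        seg = np.diff(pts, axis=0)
        for i, s in enumerate(seg):
            length = float(np.linalg.norm(s))
            n = max(2, int(np.ceil(length / (0.8 * radius))) + 1)
            for t in np.linspace(0.0, 1.0, n):
                _stamp_sphere(grid, pts[i] + t * s, radius, spacing)
    return grid


def generate_neuron_mask(
    geom: AcquisitionGeometry,
    n_branches: int = 5,
    branch_length_um: float = 15.0,
    seed: int = 0,
    *,
    soma_radius_um: float = 4.0,
    tube_radius_um: float = 0.4,
    soma_center_um: Optional[Sequence[float]] = None,
    intensity: float = 100.0,
) -> tuple[SurfaceMask, NeuronModel]:
    """Generate a connected soma + arbor mask with its generating model.

    Branches grow outward from the soma surface as smoothly meandering
    polylines; points are clamped to stay one tube radius inside the stack,
    so a long branch bends along the border instead of leaving the volume.
    A soma that does not fit inside the stack raises :class:`DomainError`.
    """
    if n_branches < 0:
        raise DomainError("n_branches must be non-negative")
    if tube_radius_um < min(geom.spacing_um):
        raise DomainError(
            f"tube radius {tube_radius_um} µm below one voxel on the finest axis "
            f"({min(geom.spacing_um)} µm)"
        )
    extent = np.asarray(geom.extent_um)
    center = (extent / 2.0 if soma_center_um is None
              else np.asarray(soma_center_um, dtype=float))
    if np.any(center - soma_radius_um < 0) or np.any(center + soma_radius_um > extent):
        raise DomainError(
            f"soma (center {tuple(center)} µm, radius {soma_radius_um} µm) exceeds "
            f"the stack extent {tuple(extent)} µm"
        )
    rng = np.random.default_rng(seed)
    margin = tube_radius_um + float(max(geom.spacing_um))
    branches: list[tuple[np.ndarray, float]] = []
    step = 1.0
    for _ in range(n_branches):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts = [center + soma_radius_um * 0.95 * direction]
        n_steps = max(1, int(round(branch_length_um / step)))
        for _ in range(n_steps):
            direction = direction + 0.25 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            nxt = np.clip(pts[-1] + step * direction, margin, extent - margin)
            pts.append(nxt)
        branches.append((np.asarray(pts), tube_radius_um))
    model = NeuronModel(center, soma_radius_um, branches, intensity)
    mask = SurfaceMask(rasterize_neuron(geom, model), geom.spacing_um)
    return mask, model


def sample_spots(
    mask: SurfaceMask,
    n_spots: int,
    kernel: ChemoattractionKernel,
    seed: int = 0,
    *,
    diameter_um: float = 0.723,
    field: Optional[DistanceField] = None,
) -> SpotSet:
    """Draw spot centres outside the mask with distance-dependent density.

    Rejection sampling over the stack volume: a uniform candidate at surface
    distance ``d`` is accepted with probability ``m(d)/m(0)``.  With
    amplitude 0 this reduces to complete spatial randomness outside the
    neuron.  ``field`` may be passed to reuse a precomputed distance field.
    """
    if n_spots < 1:
        raise DomainError("n_spots must be at least 1")
    if mask.is_empty:
        raise DomainError("cannot place spots around an empty mask")
    if mask.voxels.all():
        raise DomainError("mask fills the stack; no volume left for spots")
    if field is None:
        field = distance_to_surface(mask)
    spacing = np.asarray(mask.spacing_um)
    hi = np.asarray(field.extent_um)
    m0 = float(kernel.multiplier(np.zeros(1))[0])
    p_out = 1.0 - mask.voxels.mean()
    rng = np.random.default_rng(seed)
    out = np.empty((n_spots, 3))
    got = 0
    while got < n_spots:
        m = int(np.ceil((n_spots - got) * m0 / max(p_out, 1e-3) * 1.3)) + 64
        cand = rng.uniform(0.0, 1.0, size=(m, 3)) * hi
        vox = np.rint(cand / spacing).astype(np.intp)
        outside = ~mask.voxels[vox[:, 0], vox[:, 1], vox[:, 2]]
        u = rng.uniform(0.0, 1.0, size=m)
        cand = cand[outside]
        u = u[outside]
        d = map_coordinates(field.values, (cand / spacing).T, order=1, mode="nearest")
        accept = u < kernel.multiplier(d) / m0
        cand = cand[accept]
        take = min(n_spots - got, cand.shape[0])
        out[got : got + take] = cand[:take]
        got += take
    return SpotSet(out, diameter_um=diameter_um)


def _add_gaussian_spots(channel: np.ndarray, spots: SpotSet, peak: float,
                        spacing: np.ndarray) -> None:
    sigma_um = spots.diameter_um * _FWHM_TO_SIGMA
    sigma_vox = sigma_um / spacing
    half = np.ceil(4.0 * sigma_vox).astype(int)
    shape = np.asarray(channel.shape)
    for c in spots.centers_um:
        cv = c / spacing
        lo = np.maximum(np.floor(cv).astype(int) - half, 0)
        hi = np.minimum(np.floor(cv).astype(int) + half + 2, shape)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[a], hi[a]) - cv[a] for a in range(3)]
        g = [np.exp(-0.5 * (v / sigma_vox[a]) ** 2) for a, v in enumerate(ax)]
        channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            peak * g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        )


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = img
    if math.isfinite(noise.photon_scale):
        out = rng.poisson(np.maximum(out, 0.0) * noise.photon_scale) / noise.photon_scale
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return np.maximum(out, 0.0)


def _smooth_background(shape, level: float, smoothness_um: float,
                       spacing: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if level <= 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=smoothness_um / spacing)
    sd = sm.std()
    if sd > 0:
        sm = sm / sd
    return np.maximum(level * (1.0 + 0.3 * sm), 0.0)


def render_stack(
    geom: AcquisitionGeometry,
    neuron: NeuronModel,
    spots: SpotSet,
    noise: NoiseModel,
    *,
    spot_peak: float = 100.0,
) -> ChannelStack:
    """Render a two-channel stack: channel 0 = neuron, channel 1 = spots.

    Spots are rendered as 3D Gaussians whose FWHM equals the spot diameter
    (the point-spread reduction of a thin fiber).  The smooth background is
    added to both channels, then Poisson shot noise and Gaussian read noise
    are applied; identical seeds give identical stacks.
    """
    extent = np.asarray(geom.extent_um)
    if len(spots) and (np.any(spots.centers_um < -1e-9) or
                       np.any(spots.centers_um > extent + 1e-9)):
        raise DomainError("spot centres lie outside the stack extent")
    spacing = np.asarray(geom.spacing_um)
    ch_neuron = rasterize_neuron(geom, neuron).astype(np.float64) * neuron.intensity
    ch_spots = np.zeros(geom.shape_voxels, dtype=np.float64)
    if len(spots):
        _add_gaussian_spots(ch_spots, spots, spot_peak, spacing)
    rng = np.random.default_rng(noise.seed)
    bg = _smooth_background(geom.shape_voxels, noise.background_level,
                            noise.background_smoothness_um, spacing, rng)
    data = np.stack([
        _apply_noise(ch_neuron + bg, noise, rng),
        _apply_noise(ch_spots + bg, noise, rng),
    ])
    return ChannelStack(data, geom.spacing_um)


def generate_coloc_pair(
    geom: AcquisitionGeometry,
    target_frac_a_in_b: float,
    target_frac_b_in_a: float,
    seed: int = 0,
    *,
    intensity: float = 100.0,
    noise: Optional[NoiseModel] = None,
    budget_frac: float = 0.15,
) -> tuple[ChannelStack, "_coloc.OverlapResult"]:
    """Two binary-rendered channels with prescribed voxel-overlap fractions.

    Fractions are in [0, 1]; ``frac_a_in_b = |A∩B|/|A|``.  Exactly one of
    the two fractions being zero is infeasible (a shared intersection cannot
    be empty for one channel only).  Channel masks are raster-contiguous
    voxel blocks achieving the requested fractions to within rounding; the
    returned :class:`OverlapResult` is the exact ground truth of the
    rendered masks.
    """
    fa, fb = float(target_frac_a_in_b), float(target_frac_b_in_a)
    for f in (fa, fb):
        if not 0.0 <= f <= 1.0:
            raise DomainError("overlap fractions must lie in [0, 1]")
    if (fa == 0.0) != (fb == 0.0):
        raise DomainError(
            "infeasible fraction pair: the intersection is empty for one channel "
            "only (f_ab·|A| = f_ba·|B| has no positive solution)"
        )
    n_total = geom.n_voxels
    flat_a = np.zeros(n_total, dtype=bool)
    flat_b = np.zeros(n_total, dtype=bool)
    if fa == 0.0:  # disjoint pair
        n_each = int(round(0.1 * n_total))
        gap = 2 * geom.shape_voxels[1] * geom.shape_voxels[2]
        if 2 * n_each + gap > n_total:
            raise DomainError("stack too small for two disjoint volumes")
        flat_a[:n_each] = True
        flat_b[n_each + gap : 2 * n_each + gap] = True
    else:
        n_inter = int(round(budget_frac * n_total * min(fa, fb)))
        n_inter = max(n_inter, 1)
        n_a = int(round(n_inter / fa))
        n_b = int(round(n_inter / fb))
        if n_a + n_b - n_inter > n_total:
            raise DomainError("requested volumes exceed the stack; lower budget_frac")
        flat_a[:n_a] = True
        flat_b[n_a - n_inter : n_a - n_inter + n_b] = True
    mask_a = SurfaceMask(flat_a.reshape(geom.shape_voxels), geom.spacing_um)
    mask_b = SurfaceMask(flat_b.reshape(geom.shape_voxels), geom.spacing_um)
    truth = _coloc.overlap_fractions(mask_a, mask_b)
    data = np.stack([
        mask_a.voxels.astype(np.float64) * intensity,
        mask_b.voxels.astype(np.float64) * intensity,
    ])
    if noise is not None:
        rng = np.random.default_rng(seed if noise.seed == 0 else noise.seed)
        spacing = np.asarray(geom.spacing_um)
        bg = _smooth_background(geom.shape_voxels, noise.background_level,
                                noise.background_smoothness_um, spacing, rng)
        data = np.stack([_apply_noise(c + bg, noise, rng) for c in data])
    return ChannelStack(data, geom.spacing_um), truth
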