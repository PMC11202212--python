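"""Cohort-scale wiring of the synthetic generator and the enrichment statistic.

A chemoattraction experiment on synthetic data has three stages:

1. realize a cohort of synthetic neurons (mask, distance field, CSR null
   ensemble) — the expensive, kernel-independent part;
2. sample an observed spot set per neuron under a chemoattraction kernel;
3. build per-neuron enrichment profiles and the cohort summary.

Separating stage 1 lets several spot laws (different kernels, or the CSR
control) be analyzed on the same neurons without recomputing distance
fields or null ensembles, which is also how paired comparisons are made.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chemo import (
    FINE_BINS_UM,
    ChemoattractionSummary,
    DistanceField,
    DistanceProfile,
    distance_to_surface,
    enrichment_profile,
    simulate_null,
    summarize_cohort,
)
from .core import AcquisitionGeometry, SurfaceMask
from .synth import ChemoattractionKernel, NeuronModel, generate_neuron_mask, sample_spots

__all__ = ["NeuronRealization", "build_cohort", "cohort_profiles", "run_chemoattraction_experiment"]


@dataclass
class NeuronRealization:
    """One synthetic neuron with its distance field and null ensemble."""

    mask: SurfaceMask
    model: NeuronModel
    field: DistanceField
    null_counts: np.ndarray
    bin_edges_um: np.ndarray
    n_spots: int
    seed: int


def build_cohort(
    geom: AcquisitionGeometry,
    n_neurons: int,
    n_spots: int,
    n_sims: int = 1000,
    bin_edges: np.ndarray = FINE_BINS_UM,
    seed: int = 0,
    n_branches: int = 5,
    branch_length_um: float = 15.0,
    **neuron_kwargs,
) -> list[NeuronRealization]:
    """Realize ``n_neurons`` synthetic neurons with per-neuron CSR nulls."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_neurons)
    cohort = []
    for i in range(n_neurons):
        mask, model = generate_neuron_mask(
            geom, n_branches=n_branches, branch_length_um=branch_length_um,
            seed=int(seeds[2 * i]), **neuron_kwargs,
        )
        fld = distance_to_surface(mask)
        null = simulate_null(
            n_spots, fld, exclusion=mask, n_sims=n_sims,
            bin_edges=bin_edges, seed=int(seeds[2 * i + 1]),
        )
        cohort.append(NeuronRealization(mask, model, fld, null, np.asarray(bin_edges, float),
                                        n_spots, int(seeds[2 * i])))
    return cohort


def cohort_profiles(
    cohort: Sequence[NeuronRealization],
    kernel: ChemoattractionKernel,
    seed: int = 0,
) -> list[DistanceProfile]:
    """Sample observed spots under ``kernel`` and profile every neuron."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(cohort))
    profiles = []
    for i, nr in enumerate(cohort):
        spots = sample_spots(nr.mask, nr.n_spots, kernel, seed=int(seeds[i]), field=nr.field)
        profiles.append(
            enrichment_profile(spots, nr.field, nr.null_counts, nr.bin_edges_um,
                               neuron_id=f"neuron_{i:03d}")
        )
    return profiles


def run_chemoattraction_experiment(
    geom: AcquisitionGeometry,
    n_neurons: int,
    n_spots: int,
    kernel: ChemoattractionKernel,
    n_sims: int = 1000,
    bin_edges: np.ndarray = FINE_BINS_UM,
    alpha: float = 0.05,
    seed: int = 0,
    cohort: Optional[Sequence[NeuronRealization]] = None,
) -> tuple[list[DistanceProfile], ChemoattractionSummary]:
    """End-to-end synthetic chemoattraction experiment.

    Pass a prebuilt ``cohort`` to reuse neurons/nulls across kernels.
    """
    if cohort is None:
        cohort = build_cohort(geom, n_neurons, n_spots, n_sims=n_sims,
                              bin_edges=bin_edges, seed=seed)
    profiles = cohort_profiles(cohort, kernel, seed=seed + 1)
    summary = summarize_cohort(profiles, alpha=alpha)
    return profiles, summary
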