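"""Shared fixtures.

The session-scoped cohort mirrors the study conditions of the synthetic
chemoattraction experiment (40 neurons on full-size stacks, 300 spots per
neuron, 1000-replicate nulls).  Distance fields and null ensembles depend
only on the neuron geometry, so the same cohort serves every spot-placement
law (wide kernel, narrow kernel, CSR control).
"""

from __future__ import annotations

import numpy as np
import pytest

import spotsurf as ss
from spotsurf.pipeline import build_cohort, cohort_profiles

FULL_GEOM = ss.AcquisitionGeometry()
SMALL_GEOM = ss.AcquisitionGeometry((24, 32, 32), (1.0, 1.0, 1.0))

COHORT_SEED = 101
SPOT_SEED = 202


@pytest.fixture(scope="session")
def study_cohort():
    """40 synthetic neurons with per-neuron 1000-simulation CSR nulls."""
    return build_cohort(
        FULL_GEOM, n_neurons=40, n_spots=300, n_sims=1000,
        bin_edges=ss.FINE_BINS_UM, seed=COHORT_SEED,
    )


@pytest.fixture(scope="session")
def cohort_summaries(study_cohort):
    """Profiles + cohort summaries for the wide, narrow and CSR spot laws."""
    laws = {
        "R7": ss.ChemoattractionKernel(7.0, 1.0, "flat"),
        "R1": ss.ChemoattractionKernel(1.0, 1.0, "flat"),
        "CSR": ss.ChemoattractionKernel(0.0, 0.0, "flat"),
    }
    out = {}
    for name, kernel in laws.items():
        profiles = cohort_profiles(study_cohort, kernel, seed=SPOT_SEED)
        out[name] = (profiles, ss.summarize_cohort(profiles))
    return out


@pytest.fixture(scope="session")
def small_soma():
    """Isotropic 1 µm grid with a branch-free soma — cheap analytic geometry."""
    mask, model = ss.generate_neuron_mask(
        SMALL_GEOM, n_branches=0, seed=1, soma_radius_um=4.0, tube_radius_um=1.0,
    )
    return mask, model


@pytest.fixture(scope="session")
def small_field(small_soma):
    mask, _ = small_soma
    return ss.distance_to_surface(mask)
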