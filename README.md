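# spotsurf

**Spot-to-surface chemoattraction, colocalization and volumetry for 3D
fluorescence z-stacks.**

`spotsurf` quantifies whether punctate axonal signal accumulates near the
surface of a target neuron in confocal z-stacks — the spatial signature of
chemoattraction.  The motivating biology is the striatal GDNF system:
GDNF-secreting interneurons make up only ~0.6% of striatal neurons, yet
their arborizations appear to chemoattract incoming RET⁺ dopamine axons far
more strongly than the abundant medium spiny neurons (MSNs).  Because raw
imaging data for such studies is rarely shared, the package pairs every
analysis stage with a synthetic-stack generator that produces the same kind
of data with *known* ground truth, so the whole pipeline can be validated
end to end by parameter recovery.

## The statistic

For one neuron in one image:

1. segment the neuron surface and reduce the axonal channel to point
   **spots** at a fixed detection diameter (default 0.723 µm, after
   background subtraction with a 46.2 µm Gaussian filter);
2. compute each spot's anisotropic Euclidean distance *d* to the nearest
   surface voxel and bin the distances (per-µm bins from 0–15 µm, or 5 µm
   display bins to 30 µm);
3. place the same number of spots uniformly at random in the same imaged
   volume outside the neuron (complete spatial randomness, CSR), 1000
   times, and bin each replicate — the Monte Carlo null;
4. report the **normalized percentage** per bin,
   `100 × observed / mean(null)`; under CSR this is 100%.

Across a cohort of neurons, a two-way ANOVA (dataset × distance bin) tests
the overall interaction and Šidák-adjusted per-bin contrasts
(`p_adj = 1 − (1 − p)^m`, m = number of bins) locate the enriched bins.
The **chemoattraction radius** is the upper edge of the maximal contiguous
run of significantly enriched bins starting at the surface.

Complementary analyses: directional voxel-volume overlap between two
binarized channels (`100·|A∩B|/|A|` and `100·|A∩B|/|B|`, pooled
volume-weighted across ROIs), double-positive soma counting, two-marker
volume fractions in standard ROIs (185 × 185 × 5 µm), and the closed-form
striatal geometry arithmetic (effective interaction volumes, neurons per
dopamine arbor, arbor overlap counts).

## Worked example

Recover a known 5 µm chemoattraction radius from synthetic neurons
(`examples/chemoattraction_radius.py`):

```bash
$ python examples/chemoattraction_radius.py
 bin_lo_um  bin_hi_um  mean_pct  sem_pct  p_unadjusted  p_adjusted  significant
         0          1       203     12.5      4.94e-06    7.42e-05         True
         1          2       176     7.68      8.51e-07    1.28e-05         True
         2          3       172      6.2      1.71e-07    2.57e-06         True
         3          4       181     8.71      1.53e-06     2.3e-05         True
         4          5       172     7.73      1.58e-06    2.37e-05         True
         5          6      86.6     4.04        0.0068      0.0972        False
         ...

estimated chemoattraction radius: 5 µm (generator used 5 µm)
interaction p (observed vs null × distance): 4.2e-82
```

Spots are about twice as dense as random placement within 5 µm of the
neurons (~170–200%), depleted below 100% beyond (the fixed spot budget has
to come from somewhere), and the contiguous-significance rule returns the
generating radius exactly.  The other examples cover noisy
rendering + spot detection (`simulate_and_detect.py`, prints precision
0.952 / recall 0.895 at SNR ≈ 5), overlap colocalization
(`colocalization_overlap.py`, recovers a 55.2% / 97.9% directional overlap
pair), and volumetry plus the geometry table
(`volumetry_and_geometry.py`).

A thin CLI wraps the same functions for shell use:

```bash
spotsurf simulate --config cfg.yaml --out sim/       # stacks + ground truth
spotsurf chemoattract --inputs sim/ --out results/   # profiles + radius
spotsurf coloc --manifest rois.csv --out results/
spotsurf volumetry --manifest rois.csv --out results/
spotsurf geometry                                    # derived-constants table
```

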