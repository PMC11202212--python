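"""Distance field, Monte Carlo null, enrichment profiles, cohort inference."""

import numpy as np
import pytest

import spotsurf as ss
from spotsurf.chemo import _bin_counts
from spotsurf.pipeline import build_cohort, cohort_profiles


def brute_force_distance(mask: ss.SurfaceMask) -> np.ndarray:
    """Oracle: per-voxel minimum physical distance over all surface voxels."""
    spacing = np.asarray(mask.spacing_um)
    surf = mask.surface_voxels * spacing
    shape = mask.voxels.shape
    coords = np.indices(shape).reshape(3, -1).T * spacing
    out = np.empty(coords.shape[0])
    chunk = 4096
    for i in range(0, coords.shape[0], chunk):
        diff = coords[i : i + chunk, None, :] - surf[None, :, :]
        out[i : i + chunk] = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    out = out.reshape(shape)
    out[mask.voxels] = 0.0
    return out


class TestDistanceField:
    def test_single_voxel_axis_distances(self):
        vox = np.zeros((9, 9, 9), bool)
        vox[4, 4, 4] = True
        fld = ss.distance_to_surface(ss.SurfaceMask(vox, (1.0, 1.0, 1.0)))
        assert fld.values[4, 4, 7] == pytest.approx(3.0)

    def test_anisotropic_z_step(self):
        vox = np.zeros((9, 9, 9), bool)
        vox[4, 4, 4] = True
        fld = ss.distance_to_surface(ss.SurfaceMask(vox, (0.2, 0.299, 0.299)))
        assert fld.values[5, 4, 4] == pytest.approx(0.2)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            vox = np.random.default_rng(seed).random((24, 24, 24)) > 0.97
            vox[12, 12, 12] = True  # never empty
            mask = ss.SurfaceMask(vox, (0.2, 0.299, 0.299))
            fld = ss.distance_to_surface(mask)
            assert np.abs(fld.values - brute_force_distance(mask)).max() < 1e-6

    def test_zero_inside_mask(self, small_soma):
        mask, _ = small_soma
        fld = ss.distance_to_surface(mask)
        assert np.all(fld.values[mask.voxels] == 0.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ss.DomainError):
            ss.distance_to_surface(ss.SurfaceMask(np.zeros((8, 8, 8), bool), (1, 1, 1)))


class TestSpotDistances:
    def test_on_surface_voxel_center_is_zero(self, small_soma, small_field):
        mask, _ = small_soma
        sv = mask.surface_voxels[0] * np.asarray(mask.spacing_um)
        d = ss.spot_distances(ss.SpotSet(sv[None, :]), small_field)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_interpolation(self):
        vox = np.zeros((9, 9, 9), bool)
        vox[4, 4, 0] = True
        fld = ss.distance_to_surface(ss.SurfaceMask(vox, (1.0, 1.0, 1.0)))
        # midway along x between voxels at distances 4 and 5
        d = ss.spot_distances(ss.SpotSet(np.array([[4.0, 4.0, 4.5]])), fld)
        assert d[0] == pytest.approx(4.5, abs=1e-6)

    def test_close_to_nearest_neighbour_lookup(self, small_soma, small_field):
        mask, _ = small_soma
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1, (1000, 3)) * np.asarray(small_field.extent_um)
        d = ss.spot_distances(ss.SpotSet(pts), small_field)
        vox = np.rint(pts / np.asarray(mask.spacing_um)).astype(int)
        nn = small_field.values[vox[:, 0], vox[:, 1], vox[:, 2]]
        diag = np.linalg.norm(mask.spacing_um)
        assert np.abs(d - nn).max() <= diag

    def test_out_of_bounds_names_spot(self, small_field):
        with pytest.raises(ss.DomainError, match="spot 1"):
            ss.spot_distances(ss.SpotSet(np.array([[1.0, 1.0, 1.0], [99.0, 0.0, 0.0]])),
                              small_field)


class TestSimulateNull:
    def test_plane_surface_slab_volumes(self):
        # mask: slab z ≤ 4 in a 40×16×16 box at 1 µm; d(z) = z − 4 beyond it
        vox = np.zeros((41, 16, 16), bool)
        vox[:5] = True
        mask = ss.SurfaceMask(vox, (1.0, 1.0, 1.0))
        fld = ss.distance_to_surface(mask)
        edges = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        n_spots, n_sims = 200, 400
        counts = ss.simulate_null(n_spots, fld, mask, n_sims=n_sims, bin_edges=edges,
                                  seed=9)
        # accepted z range: (4.5, 40); expected mass of bin [lo, hi) is the
        # covered z length / total accepted length
        total = 40.0 - 4.5
        mean = counts.mean(axis=0)
        sem_scale = counts.std(axis=0, ddof=1) / np.sqrt(n_sims)
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            zlo, zhi = max(4.0 + lo, 4.5), min(4.0 + hi, 40.0)
            expect = n_spots * max(zhi - zlo, 0.0) / total
            assert abs(mean[b] - expect) <= max(2.0 * sem_scale[b], 0.35)

    def test_counts_conserved_single_replicate(self, small_soma, small_field):
        mask, _ = small_soma
        edges = np.array([0.0, 100.0])  # one bin covering everything
        counts = ss.simulate_null(10, small_field, mask, n_sims=1, bin_edges=edges, seed=1)
        assert counts.sum() == 10

    def test_seed_determinism(self, small_soma, small_field):
        mask, _ = small_soma
        a = ss.simulate_null(50, small_field, mask, n_sims=20, bin_edges=ss.FINE_BINS_UM, seed=4)
        b = ss.simulate_null(50, small_field, mask, n_sims=20, bin_edges=ss.FINE_BINS_UM, seed=4)
        assert np.array_equal(a, b)

    def test_full_exclusion_raises(self, small_field):
        full = ss.SurfaceMask(np.ones(small_field.shape, bool), small_field.spacing_um)
        with pytest.raises(ss.DomainError):
            ss.simulate_null(10, small_field, full, n_sims=2, bin_edges=ss.FINE_BINS_UM)


class TestEnrichmentProfile:
    def test_csr_self_consistency(self, small_soma, small_field):
        # observed CSR draws, averaged over replicates, stay within
        # 3 null SD / √replicates of 100% in every defined bin
        mask, _ = small_soma
        null = ss.simulate_null(300, small_field, mask, n_sims=500,
                                bin_edges=ss.COARSE_BINS_UM, seed=7)
        reps = 8
        pcts = []
        for r in range(reps):
            spots = ss.sample_spots(mask, 300, ss.ChemoattractionKernel(0, 0),
                                    seed=800 + r, field=small_field)
            prof = ss.enrichment_profile(spots, small_field, null, ss.COARSE_BINS_UM)
            pcts.append(prof.normalized_pct)
            sd_pct = 100.0 * prof.null_sd / prof.null_mean
            ok = prof.null_mean > 0
        mean_pct = np.vstack(pcts).mean(axis=0)
        assert np.all(np.abs(mean_pct[ok] - 100.0) <= 3.0 * sd_pct[ok] / np.sqrt(reps))

    def test_all_spots_first_bin_arithmetic(self):
        edges = np.arange(0.0, 7.0)
        null = np.tile(np.full(6, 5), (10, 1))  # uniform null, 5 per bin
        prof = ss.DistanceProfile(edges, np.array([30, 0, 0, 0, 0, 0]), null)
        assert prof.normalized_pct[0] == pytest.approx(600.0)
        assert np.all(prof.normalized_pct[1:] == 0.0)

    def test_bin_mismatch_raises(self, small_soma, small_field):
        mask, _ = small_soma
        null = ss.simulate_null(10, small_field, mask, n_sims=2,
                                bin_edges=ss.COARSE_BINS_UM, seed=1)
        spots = ss.sample_spots(mask, 10, ss.ChemoattractionKernel(0, 0), seed=2)
        with pytest.raises(ss.DomainError):
            ss.enrichment_profile(spots, small_field, null, ss.FINE_BINS_UM)

    def test_half_open_binning_drops_beyond_last_edge(self):
        counts = _bin_counts(np.array([0.0, 0.999, 1.0, 14.9, 15.0, 20.0]),
                             ss.FINE_BINS_UM)
        assert counts[0] == 2 and counts[14] == 1 and counts.sum() == 4


class TestCohortInference:
    @pytest.fixture(scope="class")
    def mini_cohort(self):
        geom = ss.AcquisitionGeometry((30, 96, 96), (0.4, 0.4, 0.4))
        return build_cohort(geom, n_neurons=16, n_spots=2000, n_sims=300,
                            bin_edges=ss.FINE_BINS_UM, seed=31,
                            n_branches=2, branch_length_um=8.0, soma_radius_um=3.0)

    def test_csr_cohort_radius_zero(self, mini_cohort):
        profiles = cohort_profiles(mini_cohort, ss.ChemoattractionKernel(0, 0), seed=41)
        summary = ss.summarize_cohort(profiles)
        assert summary.radius_um == 0.0

    def test_radius_recovery_small_scale(self, mini_cohort):
        profiles = cohort_profiles(mini_cohort, ss.ChemoattractionKernel(3.0, 2.0, "flat"),
                                   seed=42)
        summary = ss.summarize_cohort(profiles)
        assert 2.0 <= summary.radius_um <= 4.0
        assert summary.anova["p_interaction"] < 0.01

    def test_identical_cohorts_compare_null(self, mini_cohort):
        profiles = cohort_profiles(mini_cohort, ss.ChemoattractionKernel(3.0, 1.0), seed=43)
        s = ss.summarize_cohort(profiles)
        cmp = ss.compare_cohorts(s, s)
        assert np.all(cmp.table["p_adj_two_sided"] > 0.05)
        assert cmp.radius_ratio == pytest.approx(1.0)

    def test_amplitude_doubling_raises_first_bin(self, mini_cohort):
        pa = cohort_profiles(mini_cohort, ss.ChemoattractionKernel(3.0, 1.5), seed=44)
        pb = cohort_profiles(mini_cohort, ss.ChemoattractionKernel(3.0, 3.0), seed=45)
        sa, sb = ss.summarize_cohort(pa), ss.summarize_cohort(pb)
        cmp = ss.compare_cohorts(sa, sb)
        assert cmp.table["p_adj_b_greater"].iloc[0] < 0.05

    def test_fewer_than_two_profiles_raises(self, mini_cohort):
        profiles = cohort_profiles(mini_cohort[:1], ss.ChemoattractionKernel(0, 0), seed=46)
        with pytest.raises(ss.DomainError):
            ss.summarize_cohort(profiles)

    def test_border_translation_keeps_csr_calibrated(self):
        # same-domain null ⇒ pushing the neuron toward the stack border must
        # not bias the CSR-normalized percentages
        geom = ss.AcquisitionGeometry((30, 96, 96), (0.4, 0.4, 0.4))
        extent = np.asarray(geom.extent_um)
        edges = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        means = []
        for center in (extent / 2, np.array([extent[0] / 2, 4.0, 4.0])):
            mask, _ = ss.generate_neuron_mask(geom, n_branches=0, seed=3,
                                              soma_radius_um=3.0,
                                              soma_center_um=center)
            fld = ss.distance_to_surface(mask)
            null = ss.simulate_null(1500, fld, mask, n_sims=400, bin_edges=edges, seed=5)
            pcts = []
            for s in range(80):
                spots = ss.sample_spots(mask, 1500, ss.ChemoattractionKernel(0, 0),
                                        seed=100 + s, field=fld)
                prof = ss.enrichment_profile(spots, fld, null, edges)
                pcts.append(prof.normalized_pct)
            means.append(np.nanmean(np.vstack(pcts), axis=0))
        rel = np.abs(means[0] - means[1])
        assert np.all(rel < 5.0)
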