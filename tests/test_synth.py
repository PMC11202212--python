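"""Synthetic generator: known geometry, placement law and noise behaviour."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.ndimage import map_coordinates

import spotsurf as ss
from tests.conftest import SMALL_GEOM

ISO = ss.AcquisitionGeometry((24, 32, 32), (1.0, 1.0, 1.0))


def _uniform_distance_sample(mask, field, n, seed):
    """Independent CSR oracle: uniform points outside the mask, interpolated d."""
    rng = np.random.default_rng(seed)
    spacing = np.asarray(field.spacing_um)
    hi = np.asarray(field.extent_um)
    pts = rng.uniform(0, 1, (int(n * 1.6), 3)) * hi
    vox = np.rint(pts / spacing).astype(int)
    keep = ~mask.voxels[vox[:, 0], vox[:, 1], vox[:, 2]]
    pts = pts[keep][:n]
    return map_coordinates(field.values, (pts / spacing).T, order=1)


class TestGenerateNeuronMask:
    def test_soma_volume_matches_sphere(self, small_soma):
        mask, _ = small_soma
        expected = 4.0 / 3.0 * np.pi * 4.0**3
        assert abs(mask.volume_um3 - expected) / expected < 0.15

    def test_determinism(self):
        a, _ = ss.generate_neuron_mask(ISO, n_branches=3, seed=7, tube_radius_um=1.0)
        b, _ = ss.generate_neuron_mask(ISO, n_branches=3, seed=7, tube_radius_um=1.0)
        assert np.array_equal(a.voxels, b.voxels)

    def test_branched_mask_is_connected(self):
        mask, _ = ss.generate_neuron_mask(ss.AcquisitionGeometry(), n_branches=5, seed=3)
        _, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_soma_exceeding_bounds_raises(self):
        with pytest.raises(ss.DomainError):
            ss.generate_neuron_mask(ISO, n_branches=0, seed=0, soma_radius_um=40.0)

    def test_tube_radius_below_voxel_raises(self):
        with pytest.raises(ss.DomainError):
            ss.generate_neuron_mask(ss.AcquisitionGeometry(), n_branches=1, seed=0,
                                    tube_radius_um=0.05)


class TestSampleSpots:
    def test_csr_density_uniform_across_distance_slabs(self, small_soma, small_field):
        # equal-volume slabs defined by the median free-space distance
        mask, _ = small_soma
        spots = ss.sample_spots(mask, 50_000, ss.ChemoattractionKernel(0, 0), seed=11,
                                field=small_field)
        d = ss.spot_distances(spots, small_field)
        ref = _uniform_distance_sample(mask, small_field, 200_000, seed=99)
        med = np.median(ref)
        frac_low = (d <= med).mean()
        assert abs(frac_low / (1 - frac_low) - 1.0) < 0.05

    def test_flat_kernel_density_ratio_two(self, small_soma, small_field):
        mask, _ = small_soma
        R = 5.0
        spots = ss.sample_spots(mask, 50_000, ss.ChemoattractionKernel(R, 1.0, "flat"),
                                seed=12, field=small_field)
        d = ss.spot_distances(spots, small_field)
        ref = _uniform_distance_sample(mask, small_field, 300_000, seed=98)
        vin, vout = (ref <= R).mean(), (ref > R).mean()
        fin, fout = (d <= R).mean(), (d > R).mean()
        ratio = (fin / vin) / (fout / vout)
        assert abs(ratio - 2.0) < 0.1

    def test_single_spot_outside_mask(self, small_soma):
        mask, _ = small_soma
        spots = ss.sample_spots(mask, 1, ss.ChemoattractionKernel(0, 0), seed=5)
        assert len(spots) == 1
        vox = np.rint(spots.centers_um[0] / np.asarray(mask.spacing_um)).astype(int)
        assert not mask.voxels[tuple(vox)]

    def test_csr_distance_law_matches_volume_weighted_null(self, small_soma, small_field):
        # KS distance between sampled distances and the CSR law itself
        mask, _ = small_soma
        spots = ss.sample_spots(mask, 100_000, ss.ChemoattractionKernel(0, 0), seed=13,
                                field=small_field)
        d = np.sort(ss.spot_distances(spots, small_field))
        ref = np.sort(_uniform_distance_sample(mask, small_field, 400_000, seed=97))
        grid = np.linspace(0, ref.max(), 512)
        cdf_d = np.searchsorted(d, grid) / len(d)
        cdf_r = np.searchsorted(ref, grid) / len(ref)
        assert np.abs(cdf_d - cdf_r).max() < 0.01

    def test_kernel_monotonicity_in_amplitude(self, small_soma, small_field):
        mask, _ = small_soma
        R = 5.0
        fracs = []
        for A in (0.0, 0.5, 1.0, 2.0):
            spots = ss.sample_spots(mask, 20_000, ss.ChemoattractionKernel(R, A, "flat"),
                                    seed=21, field=small_field)
            d = ss.spot_distances(spots, small_field)
            fracs.append((d <= R).mean())
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_full_mask_raises(self):
        full = ss.SurfaceMask(np.ones((8, 8, 8), bool), (1, 1, 1))
        with pytest.raises(ss.DomainError):
            ss.sample_spots(full, 10, ss.ChemoattractionKernel(0, 0), seed=0)

    def test_determinism(self, small_soma):
        mask, _ = small_soma
        k = ss.ChemoattractionKernel(3.0, 1.0, "linear_ramp")
        a = ss.sample_spots(mask, 500, k, seed=3)
        b = ss.sample_spots(mask, 500, k, seed=3)
        assert np.array_equal(a.centers_um, b.centers_um)


class TestRenderStack:
    def test_zero_spots_zero_noise_channel_empty(self, small_soma):
        _, model = small_soma
        stack = ss.render_stack(ISO, model, ss.SpotSet(np.empty((0, 3))), ss.NoiseModel())
        assert np.all(stack.channel(1).data == 0)

    def test_single_spot_argmax_at_center(self, small_soma):
        _, model = small_soma
        spots = ss.SpotSet(np.array([[5.0, 25.0, 7.0]]))
        stack = ss.render_stack(ISO, model, spots, ss.NoiseModel())
        peak = np.unravel_index(np.argmax(stack.channel(1).data), stack.shape)
        assert np.all(np.abs(np.asarray(peak) - np.array([5, 25, 7])) <= 1)

    def test_high_photon_limit_approaches_noiseless(self, small_soma):
        _, model = small_soma
        spots = ss.SpotSet(np.array([[12.0, 16.0, 16.0], [5.0, 8.0, 20.0]]))
        clean = ss.render_stack(ISO, model, spots, ss.NoiseModel()).channel(1).data
        noisy = ss.render_stack(
            ISO, model, spots, ss.NoiseModel(photon_scale=1e6, seed=4)
        ).channel(1).data
        sig = clean > 1.0
        rel = np.abs(noisy[sig] - clean[sig]) / clean[sig]
        assert np.median(rel) < 0.01

    def test_render_determinism(self, small_soma):
        _, model = small_soma
        spots = ss.SpotSet(np.array([[5.0, 5.0, 5.0]]))
        nm = ss.NoiseModel(background_level=1.0, photon_scale=20.0, read_sigma=0.5, seed=9)
        a = ss.render_stack(ISO, model, spots, nm).data
        b = ss.render_stack(ISO, model, spots, nm).data
        assert np.array_equal(a, b)

    def test_intensities_nonnegative_under_noise(self, small_soma):
        _, model = small_soma
        nm = ss.NoiseModel(background_level=0.5, photon_scale=5.0, read_sigma=2.0, seed=2)
        stack = ss.render_stack(ISO, model, ss.SpotSet(np.empty((0, 3))), nm)
        assert np.all(stack.data >= 0)


class TestGenerateColocPair:
    @pytest.mark.parametrize(
        "fa,fb",
        [(1.0, 1.0), (0.0, 0.0), (0.552, 0.979), (0.5, 0.5)],
    )
    def test_requested_fractions_achieved(self, fa, fb):
        geom = ss.AcquisitionGeometry((16, 64, 64), (1.0, 1.0, 1.0))
        stack, truth = ss.generate_coloc_pair(geom, fa, fb, seed=1)
        assert abs(truth.frac_a_in_b - 100 * fa) < 0.5
        assert abs(truth.frac_b_in_a - 100 * fb) < 0.5
        a = stack.channel(0).data > 0
        b = stack.channel(1).data > 0
        if fa == 1.0:
            assert np.array_equal(a, b)
        if fa == 0.0:
            assert not (a & b).any()

    def test_infeasible_pair_raises(self):
        geom = ss.AcquisitionGeometry((16, 32, 32), (1.0, 1.0, 1.0))
        with pytest.raises(ss.DomainError):
            ss.generate_coloc_pair(geom, 0.0, 0.5, seed=0)

    def test_ground_truth_consistency_identity(self):
        geom = ss.AcquisitionGeometry((16, 64, 64), (1.0, 1.0, 1.0))
        _, truth = ss.generate_coloc_pair(geom, 0.3, 0.8, seed=2)
        lhs = truth.frac_a_in_b * truth.vol_a_um3
        rhs = truth.frac_b_in_a * truth.vol_b_um3
        assert lhs == pytest.approx(rhs, rel=1e-12)
        assert lhs == pytest.approx(100 * truth.vol_intersection_um3, rel=1e-12)
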