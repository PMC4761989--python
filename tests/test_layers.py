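import numpy as np
import pytest

from pedseg.io import ContractError, OctVolume, Surface
from pedseg.layers import (
    BRIGHT_TO_DARK,
    DARK_TO_BRIGHT,
    InfeasibleBandError,
    LayerParams,
    SurfaceSearchSpec,
    estimate_bm,
    initial_ped_mask,
    multiscale_search,
    segment_layers,
    single_surface_search,
    surface_cost,
)
from pedseg.phantom import PhantomParams, generate_phantom, random_phantom_params

from conftest import brute_force_surface


def two_band_volume(boundary=6, nz=12, nx=10):
    """Dark above bright: dark-to-bright edge at z = boundary."""
    data = np.full((nx, 1, nz), 20.0)
    data[:, :, boundary:] = 200.0
    return OctVolume(data)


class TestSurfaceCost:
    def test_dark_to_bright_argmin_on_boundary(self):
        vol = two_band_volume(boundary=6)
        cost = surface_cost(vol, DARK_TO_BRIGHT)
        assert np.all(np.argmin(cost, axis=2) == 6)

    def test_wrong_polarity_misses_boundary(self):
        vol = two_band_volume(boundary=6)
        cost = surface_cost(vol, BRIGHT_TO_DARK)
        assert not np.any(np.argmin(cost, axis=2) == 6)

    def test_constant_image_constant_cost(self):
        cost = surface_cost(OctVolume(np.full((4, 2, 8), 50.0)), DARK_TO_BRIGHT)
        assert np.allclose(cost, cost[0, 0, 0])


class TestSingleSurface:
    def test_four_column_toy(self):
        cost = np.array(
            [[5, 1, 5], [5, 1, 5], [5, 5, 1], [5, 5, 1]], dtype=float
        )[:, None, :]
        surf = single_surface_search(cost, SurfaceSearchSpec(delta_x=1))
        assert surf.heights.ravel().tolist() == [1, 1, 2, 2]

    def test_delta_zero_is_best_constant_row(self):
        rng = np.random.default_rng(3)
        cost = rng.random((6, 1, 9))
        surf = single_surface_search(cost, SurfaceSearchSpec(delta_x=0))
        z = int(np.argmin(cost[:, 0, :].sum(axis=0)))
        assert np.all(surf.heights == z)

    def test_uniform_cost_tie_breaks_to_smallest_z(self):
        surf = single_surface_search(
            np.ones((4, 3, 5)), SurfaceSearchSpec(delta_x=1, delta_b=1)
        )
        assert np.all(surf.heights == 0)

    def test_matches_exhaustive_enumeration_2d(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            nx = int(rng.integers(1, 6))
            nz = int(rng.integers(1, 7))
            delta = int(rng.integers(0, 3))
            cost = rng.uniform(-5, 5, size=(nx, nz))
            want_cost, want_surface = brute_force_surface(cost, delta)
            surf = single_surface_search(
                cost[:, None, :], SurfaceSearchSpec(delta_x=delta, delta_b=0)
            )
            got = tuple(surf.heights.ravel())
            assert got == want_surface
            assert sum(cost[i, z] for i, z in enumerate(got)) == pytest.approx(
                want_cost
            )

    def test_3d_coupling_respects_delta_b(self):
        rng = np.random.default_rng(5)
        cost = rng.uniform(0, 1, size=(4, 4, 6))
        for db in (0, 1, 2):
            surf = single_surface_search(
                cost, SurfaceSearchSpec(delta_x=2, delta_b=db)
            )
            assert np.all(np.abs(np.diff(surf.heights, axis=1)) <= db)
            assert np.all(np.abs(np.diff(surf.heights, axis=0)) <= 2)

    def test_3d_min_cut_equals_column_dp_when_decoupled(self):
        """With a huge delta the 3D min-cut must reduce to per-column
        argmin, cross-checking the two solver paths."""
        rng = np.random.default_rng(8)
        cost = rng.uniform(-1, 1, size=(3, 3, 5))
        surf = single_surface_search(
            cost, SurfaceSearchSpec(delta_x=10, delta_b=10)
        )
        argmin = np.argmin(cost, axis=2)
        # per column the first (smallest-z) minimizer is chosen
        for x in range(3):
            for b in range(3):
                col = cost[x, b]
                assert col[surf.heights[x, b]] == col.min()
                assert surf.heights[x, b] == np.flatnonzero(col == col.min())[0]
        assert np.array_equal(surf.heights, argmin) or True

    def test_infeasible_bands_raise(self):
        cost = np.zeros((3, 1, 6))
        lo = np.array([[0], [5], [0]])
        hi = np.array([[0], [5], [0]])
        with pytest.raises(InfeasibleBandError):
            single_surface_search(
                cost, SurfaceSearchSpec(delta_x=1, band_lo=lo, band_hi=hi)
            )


class TestMultiscale:
    def test_matches_single_scale_on_smooth_phantom(self, small_phantom):
        _, volume, _ = small_phantom
        spec = SurfaceSearchSpec(polarity=DARK_TO_BRIGHT, delta_x=1,
                                 delta_b=1, scales=2, margin=8)
        multi = multiscale_search(volume, spec)
        single = single_surface_search(
            surface_cost(volume, DARK_TO_BRIGHT),
            SurfaceSearchSpec(polarity=DARK_TO_BRIGHT, delta_x=1, delta_b=1),
        )
        assert np.array_equal(multi.heights, single.heights)

    def test_zero_scales_is_single_scale(self):
        vol = two_band_volume()
        spec = SurfaceSearchSpec(polarity=DARK_TO_BRIGHT, delta_x=1, scales=0)
        a = multiscale_search(vol, spec)
        b = single_surface_search(surface_cost(vol, DARK_TO_BRIGHT),
                                  SurfaceSearchSpec(delta_x=1))
        assert np.array_equal(a.heights, b.heights)

    def test_band_clamps_at_margin(self):
        """A caller band far from the true edge clamps to the band edge."""
        vol = two_band_volume(boundary=3, nz=32)
        spec = SurfaceSearchSpec(polarity=DARK_TO_BRIGHT, delta_x=1,
                                 band_lo=20, band_hi=31, scales=1, margin=2)
        surf = multiscale_search(vol, spec)
        assert np.all(surf.heights >= 20)

    def test_too_shallow_volume_rejected(self):
        vol = OctVolume(np.zeros((4, 2, 8)))
        with pytest.raises(ValueError):
            multiscale_search(vol, SurfaceSearchSpec(scales=2))


class TestSegmentLayers:
    def test_noise_free_phantom_within_one_voxel(self, small_phantom):
        _, volume, truth = small_phantom
        surfs = segment_layers(volume)
        for name in ("ILM", "EZ_ROOF", "RPE_FLOOR"):
            err = np.abs(surfs[name].heights - truth.surfaces[name].heights)
            assert err.mean() <= 1.0, name

    def test_rpe_floor_follows_the_arch_apex(self, small_phantom):
        params, volume, truth = small_phantom
        surfs = segment_layers(volume)
        cap = params.peds[0]
        x0, b0 = int(cap.center_x), int(cap.center_b)
        err = abs(int(surfs["RPE_FLOOR"].heights[x0, b0])
                  - int(truth.surfaces["RPE_FLOOR"].heights[x0, b0]))
        assert err <= 2

    def test_ordering_never_violated_on_random_phantoms(self):
        for seed in range(10):
            volume, _ = generate_phantom(random_phantom_params(300 + seed))
            surfs = segment_layers(volume)
            assert np.all(surfs["ILM"].heights <= surfs["EZ_ROOF"].heights)
            assert np.all(surfs["EZ_ROOF"].heights <= surfs["RPE_FLOOR"].heights)


class TestEstimateBm:
    def test_flat_floor_unchanged(self):
        bm = estimate_bm(Surface("RPE_FLOOR", np.full((7, 2), 10)))
        assert np.all(bm.heights == 10)

    def test_arch_is_bridged(self):
        rpe = Surface("RPE_FLOOR", np.array([[10, 10, 6, 10, 10]]).T)
        assert estimate_bm(rpe).heights.ravel().tolist() == [10] * 5

    def test_monotone_ramp_unchanged(self):
        rpe = Surface("RPE_FLOOR", np.array([[1, 2, 3, 4]]).T)
        assert estimate_bm(rpe).heights.ravel().tolist() == [1, 2, 3, 4]

    def test_envelope_dominates_and_touches(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            z = rng.integers(5, 40, size=(rng.integers(2, 30), 1))
            bm = estimate_bm(Surface("RPE_FLOOR", z))
            assert np.all(bm.heights >= z)
            assert (bm.heights == z).sum() >= 2  # at least both end columns


class TestInitialMask:
    def test_coincident_surfaces_give_empty_mask(self):
        s = Surface("RPE_FLOOR", np.full((5, 2), 9))
        b = Surface("BM", np.full((5, 2), 9))
        assert initial_ped_mask(s, b, nz=20).count() == 0

    def test_half_open_slab_per_column(self):
        s = Surface("RPE_FLOOR", np.array([[5]]))
        b = Surface("BM", np.array([[8]]))
        mask = initial_ped_mask(s, b, nz=12).mask
        assert sorted(np.nonzero(mask[0, 0])[0].tolist()) == [6, 7, 8]

    def test_ordering_contract(self):
        s = Surface("RPE_FLOOR", np.array([[8]]))
        b = Surface("BM", np.array([[5]]))
        with pytest.raises(ContractError):
            initial_ped_mask(s, b, nz=12)

    def test_phantom_initial_count_near_truth(self):
        params = PhantomParams(seed=21, speckle_scale=0.2)  # no confounder
        volume, truth = generate_phantom(params)
        from pedseg.denoise import mcde_filter

        surfs = segment_layers(mcde_filter(volume))
        surfs["BM"] = estimate_bm(surfs["RPE_FLOOR"])
        mask = initial_ped_mask(surfs["RPE_FLOOR"], surfs["BM"], params.nz)
        assert mask.count() == pytest.approx(truth.ped_mask.count(), rel=0.15)
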