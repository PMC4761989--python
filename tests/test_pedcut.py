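import itertools

import numpy as np
import pytest

from pedseg.io import ContractError, OctVolume, RegionMask, Surface
from pedseg.pedcut import (
    EnergyWeights,
    SeedError,
    SeedSet,
    ball,
    brightness_transform,
    build_shape_prior,
    energy_of,
    energy_terms,
    estimate_weights,
    graph_cut,
    make_seeds,
    postprocess,
    se_radius,
)


def blob_mask(shape, rng, n_blobs=2):
    from scipy import ndimage

    m = np.zeros(shape, bool)
    for _ in range(n_blobs):
        c = [rng.integers(2, s - 2) for s in shape]
        m[tuple(c)] = True
    return ndimage.binary_dilation(m, iterations=int(rng.integers(1, 3)))


class TestSeRadius:
    def test_zero_volume(self):
        assert se_radius(0, 0.143) == 0

    def test_foreground_coefficient(self):
        assert se_radius(1000, 0.143) == 1

    def test_background_coefficient(self):
        assert se_radius(1000, 1.143) == 11

    def test_monotone_in_volume(self):
        r = [se_radius(v, 0.7) for v in range(0, 5000, 50)]
        assert all(b >= a for a, b in zip(r, r[1:]))

    def test_invalid_coefficient(self):
        with pytest.raises(ContractError):
            se_radius(10, 0.0)


class TestMakeSeeds:
    def test_cube_erosion_exact_count(self):
        m = np.zeros((20, 20, 20), bool)
        m[4:15, 4:15, 4:15] = True  # 11^3 = 1331, r_fg = round(.143*11) = 2
        seeds = make_seeds(RegionMask(m))
        assert seeds.foreground.sum() == 343  # inner 7^3 cube
        assert np.all(m[seeds.foreground])

    def test_containment_chain_and_disjointness(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            m = blob_mask((16, 10, 16), rng)
            if not m.any():
                continue
            seeds = make_seeds(RegionMask(m))
            assert np.all(m[seeds.foreground])            # fg inside region
            assert not np.any(m & seeds.background)       # bg outside region
            assert not np.any(seeds.foreground & seeds.background)

    def test_small_region_falls_back_to_innermost_voxel(self):
        m = np.zeros((10, 10, 10), bool)
        m[4:6, 4:6, 4:6] = True  # V=8, r_fg=round(.286)=0 -> erosion=identity
        m2 = np.zeros((30, 30, 30), bool)
        m2[5:9, 5:9, 5:25] = True  # elongated: erosion by r_fg may empty it
        for mask in (m, m2):
            seeds = make_seeds(RegionMask(mask))
            assert seeds.foreground.sum() >= 1
            assert np.all(mask[seeds.foreground])

    def test_empty_mask_empty_seeds(self):
        seeds = make_seeds(RegionMask(np.zeros((8, 8, 8), bool)))
        assert not seeds.foreground.any() and not seeds.background.any()


class TestBrightnessTransform:
    def surfaces(self, nx, nB):
        levels = {"ILM": 10, "EZ_ROOF": 25, "RPE_FLOOR": 35, "BM": 40}
        return {n: Surface(n, np.full((nx, nB), z)) for n, z in levels.items()}

    def volume(self, rpe_level=170.0):
        data = np.full((12, 2, 60), 10.0)
        data[:, :, 10:26] = 90.0
        data[:, :, 26:36] = rpe_level
        return OctVolume(data)

    def test_dimmed_rpe_band_restored_to_target(self):
        surfs = self.surfaces(12, 2)
        out = brightness_transform(self.volume(85.0), surfs, target_rpe=200.0)
        band = out.data[:, :, 26:36]
        assert abs(np.median(band) - 200.0) <= 1.0

    def test_monotone_within_each_column(self):
        rng = np.random.default_rng(5)
        data = np.clip(rng.normal(80, 40, (12, 2, 60)), 0, 255)
        out = brightness_transform(OctVolume(data), self.surfaces(12, 2))
        for x in range(12):
            for b in range(2):
                order = np.argsort(data[x, b], kind="stable")
                assert np.all(np.diff(out.data[x, b][order]) >= -1e-6)

    def test_degenerate_slab_keeps_identity(self):
        surfs = self.surfaces(12, 2)
        surfs["EZ_ROOF"] = Surface("EZ_ROOF", np.full((12, 2), 35))  # empty slab
        vol = self.volume()
        out = brightness_transform(vol, surfs)
        assert np.array_equal(out.data, vol.data.astype(np.float32))


def tiny_cut_problem(rng, shape=(3, 4, 1)):
    """Random small volume with a random region, valid seeds and weights."""
    data = rng.uniform(0, 255, size=shape)
    region = np.zeros(shape, bool)
    region[tuple(rng.integers(0, s) for s in shape)] = True
    fg = region.copy()
    bg = np.zeros(shape, bool)
    free = ~region
    bg_idx = rng.choice(np.flatnonzero(free), size=2, replace=False)
    bg.reshape(-1)[bg_idx] = True
    seeds = SeedSet(fg, bg)
    prior = build_shape_prior(RegionMask(region))
    lr, ls = rng.dirichlet([1, 1, 1])[:2]
    weights = EnergyWeights(lr, ls, 1 - lr - ls)
    tables = energy_terms(data, seeds, prior, weights)
    return data, seeds, prior, weights, tables


def exhaustive_min_energy(tables, seeds):
    shape = tables.unary.shape[:3]
    n = int(np.prod(shape))
    best = np.inf
    fg = seeds.foreground.ravel()
    bg = seeds.background.ravel()
    for bits in itertools.product([False, True], repeat=n):
        lab = np.asarray(bits)
        if np.any(lab[bg]) or not np.all(lab[fg]):
            continue
        best = min(best, energy_of(tables, lab.reshape(shape)))
    return best


class TestEnergyAndCut:
    def test_shape_prior_anchors(self):
        region = np.zeros((5, 5, 5), bool)
        region[2, 2, 2] = True
        prior = build_shape_prior(RegionMask(region))
        assert prior.d[2, 2, 2] == 0
        s_obj = np.minimum(prior.d / prior.r_map, 1.0)
        assert s_obj[2, 2, 2] == 0                       # inside: S(obj)=0
        far = prior.d >= prior.r_map
        assert np.all(s_obj[far] == 1.0)                 # saturation at d>=r

    def test_equal_intensity_pair_has_maximal_boundary_weight(self):
        rng = np.random.default_rng(0)
        data, seeds, prior, weights, tables = tiny_cut_problem(rng)
        data2 = data.copy()
        data2[0, 0, 0] = data2[1, 0, 0]  # equal neighbors along x
        t2 = energy_terms(data2, seeds, prior, weights)
        assert t2.pair[0][0, 0, 0] == pytest.approx(weights.lambda_b)

    def test_empty_seed_histogram_raises(self):
        region = np.zeros((4, 4, 4), bool)
        region[1, 1, 1] = True
        prior = build_shape_prior(RegionMask(region))
        seeds = SeedSet(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool))
        with pytest.raises(SeedError):
            energy_terms(np.zeros((4, 4, 4)), seeds, prior, EnergyWeights())

    def test_pure_region_term_is_per_voxel_argmin(self):
        rng = np.random.default_rng(7)
        data, seeds, prior, _, _ = tiny_cut_problem(rng, shape=(4, 4, 2))
        weights = EnergyWeights(1.0, 0.0, 0.0)
        tables = energy_terms(data, seeds, prior, weights)
        cut = graph_cut(data, seeds, prior, weights, tables=tables)
        free = ~(seeds.foreground | seeds.background)
        expect = tables.unary[..., 1] < tables.unary[..., 0]
        assert np.array_equal(cut.mask[free], expect[free])

    def test_pure_shape_term_thresholds_distance_at_half_radius(self):
        rng = np.random.default_rng(11)
        data, seeds, prior, _, _ = tiny_cut_problem(rng, shape=(4, 3, 2))
        weights = EnergyWeights(0.0, 1.0, 0.0)
        cut = graph_cut(data, seeds, prior, weights)
        free = ~(seeds.foreground | seeds.background)
        expect = (prior.d / prior.r_map) < 0.5
        assert np.array_equal(cut.mask[free], expect[free])
        assert np.all(cut.mask[seeds.foreground])
        assert not np.any(cut.mask[seeds.background])

    def test_cut_energy_equals_exhaustive_minimum(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            data, seeds, prior, weights, tables = tiny_cut_problem(rng)
            cut = graph_cut(data, seeds, prior, weights, tables=tables)
            got = energy_of(tables, cut.mask)
            want = exhaustive_min_energy(tables, seeds)
            assert got == pytest.approx(want, abs=1e-9)

    def test_cut_beats_random_seed_consistent_labelings(self):
        rng = np.random.default_rng(2)
        data, seeds, prior, weights, tables = tiny_cut_problem(rng, (4, 4, 3))
        cut = graph_cut(data, seeds, prior, weights, tables=tables)
        e0 = energy_of(tables, cut.mask)
        free = ~(seeds.foreground | seeds.background)
        for _ in range(200):
            lab = seeds.foreground | (free & (rng.random(free.shape) < 0.5))
            assert e0 <= energy_of(tables, lab) + 1e-9


class TestEstimateWeights:
    def cases(self):
        rng = np.random.default_rng(4)
        cases = []
        for _ in range(2):
            shape = (16, 8, 16)
            truth = np.zeros(shape, bool)
            truth[6:10, 3:5, 6:10] = True
            data = np.where(truth, 40.0, 160.0) + rng.normal(0, 5, shape)
            seeds = make_seeds(RegionMask(truth))
            prior = build_shape_prior(RegionMask(truth))
            cases.append((data, seeds, prior, truth))
        return cases

    def test_simplex_constraint_exact(self):
        w = estimate_weights(self.cases(), n_iter=2)
        assert w.lambda_r + w.lambda_s + w.lambda_b == pytest.approx(1.0, abs=1e-12)
        assert min(w.lambda_r, w.lambda_s, w.lambda_b) >= 0

    def test_objective_never_decreases_from_init(self):
        cases = self.cases()
        init = EnergyWeights(0.4, 0.2, 0.4)

        def dsc_at(w):
            vals = []
            for data, seeds, prior, truth in cases:
                auto = graph_cut(data, seeds, prior, w).mask
                vals.append(2 * (auto & truth).sum() / (auto.sum() + truth.sum()))
            return np.mean(vals)

        tuned = estimate_weights(cases, init, n_iter=3)
        assert dsc_at(tuned) >= dsc_at(init) - 1e-12

    def test_empty_truths_rejected(self):
        with pytest.raises(ContractError):
            estimate_weights([])


class TestPostprocess:
    def test_solid_ball_region_unchanged(self):
        m = np.zeros((20, 20, 20), bool)
        m[4:15, 4:15, 4:15] = ball(5)[:11, :11, :11] | m[4:15, 4:15, 4:15]
        m = np.zeros((20, 20, 20), bool)
        m[10 - 5: 10 + 6, 10 - 5: 10 + 6, 10 - 5: 10 + 6] = ball(5)
        out = postprocess(RegionMask(m))
        assert np.array_equal(out.mask, m)

    def test_diagonal_spur_removed_and_hole_filled(self):
        m = np.zeros((16, 16, 16), bool)
        m[4:11, 4:11, 4:11] = True
        m[7, 7, 7] = False       # 1-voxel interior hole
        m[11, 11, 11] = True     # diagonally attached 1-voxel spur
        out = postprocess(RegionMask(m))
        assert not out.mask[11, 11, 11]
        assert out.mask[7, 7, 7]

    def test_thin_isolated_sheet_removed_compact_body_kept(self):
        m = np.zeros((20, 20, 20), bool)
        m[2:10, 2:10, 2:10] = True     # compact body survives
        m[13:18, 1:18, 14] = True      # 1-voxel-thick sheet: erodes away
        out = postprocess(RegionMask(m))
        assert not out.mask[13:18, 1:18, 14].any()
        assert np.array_equal(out.mask[2:10, 2:10, 2:10],
                              m[2:10, 2:10, 2:10])

    def test_empty_mask(self):
        out = postprocess(RegionMask(np.zeros((6, 6, 6), bool)))
        assert out.count() == 0

    def test_idempotent_on_random_blobby_masks(self):
        rng = np.random.default_rng(9)
        for _ in range(8):
            m = blob_mask((18, 12, 18), rng, n_blobs=3)
            once = postprocess(RegionMask(m))
            twice = postprocess(once)
            assert np.array_equal(once.mask, twice.mask)

    def test_region_count_never_increases(self):
        from scipy import ndimage

        rng = np.random.default_rng(13)
        for _ in range(8):
            m = blob_mask((18, 12, 18), rng, n_blobs=4)
            out = postprocess(RegionMask(m))
            _, n0 = ndimage.label(m, structure=np.ones((3, 3, 3)))
            _, n1 = ndimage.label(out.mask, structure=np.ones((3, 3, 3)))
            assert n1 <= n0
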