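import numpy as np
import pytest

from airseg import (
    Block,
    LandmarkSet,
    Mask,
    SegParams,
    Volume,
    apply_blocks,
    binarize_air,
    load_blocks,
    max_disconnecting_threshold,
    measure_volume,
    region_grow,
    save_blocks,
    segment_nasal_airway,
    smooth_volume,
)
from airseg.phantom import Channel, Ellipsoid, PhantomSpec, generate_phantom
from airseg.segmentation import SegmentationError
from conftest import make_shell_volume
from oracles import (
    bfs_flood_fill,
    exhaustive_disconnecting_threshold,
    slab_contains,
)


class TestSmoothVolume:
    def test_zero_parameters_identity(self, random_volume):
        out = smooth_volume(random_volume, 0, 0.0)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_constant_volume_unchanged(self):
        vol = Volume(np.full((9, 9, 9), 7.0), spacing=(0.5, 0.5, 0.5))
        out = smooth_volume(vol, 2, 1.0)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-9)

    def test_median_removes_impulse(self):
        # a single impulse is a minority in every 3x3x3 window -> all zeros
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        out = smooth_volume(Volume(data), 1, 0.0)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_invalid_parameters(self, random_volume):
        with pytest.raises(ValueError):
            smooth_volume(random_volume, -1, 0.0)
        with pytest.raises(ValueError):
            smooth_volume(random_volume, 0, -0.5)


class TestBinarizeAir:
    def test_all_air(self):
        vol = Volume(np.full((4, 4, 4), -1000, dtype=np.int32))
        assert binarize_air(vol, -400).data.all()

    def test_all_bone(self):
        vol = Volume(np.full((4, 4, 4), 800, dtype=np.int32))
        assert not binarize_air(vol, -400).data.any()

    def test_count_nondecreasing_in_threshold(self, random_volume):
        counts = [
            binarize_air(random_volume, t).voxel_count
            for t in np.linspace(-1200, 900, 10)
        ]
        assert counts == sorted(counts)

    def test_closed_on_threshold(self):
        vol = Volume(np.array([[[-400, -399]]], dtype=np.int32))
        mask = binarize_air(vol, -400)
        assert mask.data[0, 0, 0] and not mask.data[0, 0, 1]


class TestApplyBlocks:
    def test_empty_blockset_identity(self, two_chamber_mask):
        out = apply_blocks(two_chamber_mask, ())
        np.testing.assert_array_equal(out.data, two_chamber_mask.data)

    def test_block_disconnects_channel(self, two_chamber_mask):
        block = Block(center=(7.5, 3.5, 3.5), normal=(1.0, 0.0, 0.0),
                      radius=3.0, thickness=2.0)
        before = two_chamber_mask
        after = apply_blocks(before, (block,))
        seed = (3, 3, 3)
        assert bfs_flood_fill(before.data, seed, 6)[11, 3, 3]
        filled = bfs_flood_fill(after.data, seed, 6)
        assert not filled[11, 3, 3]

    def test_matches_scalar_slab_oracle(self, rng):
        import warnings

        mask = Mask(np.ones((10, 9, 8), dtype=bool), spacing=(0.7, 1.1, 0.9),
                    origin=(-2.0, 1.0, 0.0))
        for _ in range(5):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            block = Block(
                center=tuple(rng.uniform(-1, 6, size=3)),
                normal=tuple(n),
                radius=float(rng.uniform(0.5, 4.0)),
                thickness=float(rng.uniform(1.5, 4.0)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # a draw may miss the grid
                out = apply_blocks(mask, (block,))
            for i in range(10):
                for j in range(9):
                    for k in range(8):
                        centre = mask.index_to_world((i, j, k))
                        assert out.data[i, j, k] == (not slab_contains(block, centre))

    def test_block_outside_grid_warns_no_effect(self, two_chamber_mask):
        block = Block(center=(100.0, 100.0, 100.0), normal=(0.0, 0.0, 1.0),
                      radius=1.0, thickness=2.0)
        with pytest.warns(UserWarning, match="outside"):
            out = apply_blocks(two_chamber_mask, (block,))
        np.testing.assert_array_equal(out.data, two_chamber_mask.data)

    def test_block_validation(self):
        with pytest.raises(ValueError, match="unit"):
            Block(center=(0, 0, 0), normal=(1.0, 1.0, 0.0), radius=1.0, thickness=1.0)
        with pytest.raises(ValueError, match="radius"):
            Block(center=(0, 0, 0), normal=(0, 0, 1.0), radius=0.0, thickness=1.0)

    def test_json_round_trip(self, tmp_path):
        blocks = (
            Block(center=(1.0, 2.0, 3.0), normal=(0.0, 1.0, 0.0), radius=2.5, thickness=1.2),
        )
        save_blocks(blocks, tmp_path / "blocks.json")
        assert load_blocks(tmp_path / "blocks.json") == blocks


class TestRegionGrow:
    @staticmethod
    def two_cubes_mask():
        data = np.zeros((10, 10, 10), dtype=bool)
        data[1:4, 1:4, 1:4] = True
        data[6:9, 6:9, 6:9] = True
        return Mask(data, spacing=(1.0, 1.0, 1.0))

    def test_two_disjoint_cubes(self):
        mask = self.two_cubes_mask()
        out = region_grow(mask, seed=(2.5, 2.5, 2.5), connectivity=6)
        assert out.voxel_count == 27
        np.testing.assert_array_equal(
            out.data, bfs_flood_fill(mask.data, (2, 2, 2), 6)
        )

    def test_singleton(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        out = region_grow(Mask(data), seed=(2.5, 2.5, 2.5), connectivity=26)
        assert out.voxel_count == 1

    def test_corner_touching_cubes_connectivity(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[1:4, 1:4, 1:4] = True
        data[4:7, 4:7, 4:7] = True  # touch only at the (3,3,3)/(4,4,4) corner
        mask = Mask(data)
        assert region_grow(mask, (2.0, 2.0, 2.0), 6).voxel_count == 27
        assert region_grow(mask, (2.0, 2.0, 2.0), 26).voxel_count == 54
        for conn in (6, 26):
            np.testing.assert_array_equal(
                region_grow(mask, (2.0, 2.0, 2.0), conn).data,
                bfs_flood_fill(data, (1, 1, 1), conn),
            )

    def test_18_connectivity_edge_touch(self):
        # cubes sharing only an edge: connected at 18/26 but not 6
        data = np.zeros((8, 8, 4), dtype=bool)
        data[1:4, 1:4, 1:3] = True
        data[4:7, 4:7, 1:3] = True
        mask = Mask(data)
        assert region_grow(mask, (2.0, 2.0, 1.5), 6).voxel_count == 18
        assert region_grow(mask, (2.0, 2.0, 1.5), 18).voxel_count == 36

    def test_bad_seed_reports_position(self):
        mask = self.two_cubes_mask()
        with pytest.raises(SegmentationError, match="non-air"):
            region_grow(mask, seed=(5.0, 5.0, 5.0), connectivity=6)

    def test_output_subset_and_connected(self, rng):
        data = rng.random((12, 12, 12)) > 0.6
        data[5, 5, 5] = True
        mask = Mask(data)
        out = region_grow(mask, (5.5, 5.5, 5.5), 6)
        assert np.all(mask.data[out.data])
        np.testing.assert_array_equal(out.data, bfs_flood_fill(data, (5, 5, 5), 6))


class TestMeasureVolume:
    def test_paper_conversion(self):
        _, mm3 = measure_volume(4518.4, spacing=(0.4, 0.4, 0.4))
        assert round(mm3, 1) == 289.2
        _, one = measure_volume(15.625, spacing=(0.4, 0.4, 0.4))
        assert one == pytest.approx(1.0)

    def test_empty_mask(self):
        count, mm3 = measure_volume(Mask(np.zeros((3, 3, 3), dtype=bool)))
        assert (count, mm3) == (0, 0.0)

    def test_exact_product(self, rng):
        mask = Mask(rng.random((7, 6, 5)) > 0.5, spacing=(0.4, 0.25, 0.8))
        count, mm3 = measure_volume(mask)
        assert mm3 == count * 0.4 * 0.25 * 0.8


class TestMaxDisconnectingThreshold:
    def test_shell_phantom_largest_below_wall(self, shell_volume):
        inner, outer = (6.5, 6.5, 6.5), (0.5, 0.5, 0.5)
        t = max_disconnecting_threshold(shell_volume, inner, outer, 6)
        values = np.unique(shell_volume.data)
        assert t == values[values < 300].max()

    def test_matches_exhaustive_scan(self, rng):
        for trial in range(5):
            vol = make_shell_volume(wall_level=int(rng.integers(100, 500)))
            noisy = Volume(
                vol.data + rng.integers(-40, 40, size=vol.shape),
                spacing=vol.spacing,
            )
            inner_idx, outer_idx = (6, 6, 6), (0, 0, 0)
            expected = exhaustive_disconnecting_threshold(noisy, inner_idx, outer_idx, 6)
            got = max_disconnecting_threshold(noisy, (6.5, 6.5, 6.5), (0.5, 0.5, 0.5), 6)
            assert got == expected

    def test_pinholed_shell_rejected(self):
        vol = make_shell_volume(pinhole=(6, 6, 9))
        with pytest.raises(SegmentationError, match="no separating threshold"):
            max_disconnecting_threshold(vol, (6.5, 6.5, 6.5), (0.5, 0.5, 0.5), 6)

    def test_monotone_in_wall_intensity(self, rng):
        for _ in range(3):
            wall = int(rng.integers(100, 400))
            lo = make_shell_volume(wall_level=wall)
            hi = make_shell_volume(wall_level=wall + 100)
            t_lo = max_disconnecting_threshold(lo, (6.5, 6.5, 6.5), (0.5, 0.5, 0.5), 6)
            t_hi = max_disconnecting_threshold(hi, (6.5, 6.5, 6.5), (0.5, 0.5, 0.5), 6)
            assert t_hi >= t_lo


def single_cavity_spec(**kwargs):
    cavity = Ellipsoid(center=(15.0, 15.0, 15.0), semi_axes=(6.0, 7.0, 8.0))
    defaults = dict(
        cavities={"main": cavity},
        wall_mm=2.0,
        spacing=(0.5, 0.5, 0.5),
        extent_mm=(30.0, 30.0, 32.0),
        skull_wall_mm=0.0,
        noise_sd=0.0,
        blur_sigma_mm=0.0,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestSegmentNasalAirway:
    def test_ellipsoid_cavity_recovered(self):
        volume, truth = generate_phantom(single_cavity_spec())
        params = SegParams(threshold=-400.0, seed=truth.seeds["main"],
                          median_radius=0, gaussian_sigma=0.0)
        result = segment_nasal_airway(volume, truth.landmarks, (), params)
        analytic = truth.cavity_volumes["main"]
        assert result.volume_mm3 == pytest.approx(analytic, rel=0.02)
        assert result.volume_mm3 == result.voxel_count * 0.5**3

    def test_threshold_monotonicity(self):
        volume, truth = generate_phantom(
            single_cavity_spec(noise_sd=25.0, blur_sigma_mm=0.5, rng_seed=3)
        )
        vols = []
        for t in (-700.0, -500.0, -300.0, -100.0):
            params = SegParams(threshold=t, seed=truth.seeds["main"],
                              median_radius=0, gaussian_sigma=0.0)
            vols.append(segment_nasal_airway(volume, truth.landmarks, (), params).volume_mm3)
        assert vols == sorted(vols)

    @staticmethod
    def chamber_spec():
        cavity = Ellipsoid(center=(12.0, 15.0, 15.0), semi_axes=(5.0, 5.0, 6.0))
        sinus = Ellipsoid(center=(22.0, 15.0, 15.0), semi_axes=(3.0, 3.0, 3.0))
        channel = Channel(p0=(16.0, 15.0, 15.0), p1=(20.0, 15.0, 15.0), radius=1.0,
                          links=("main", "sinus"))
        return PhantomSpec(
            cavities={"main": cavity},
            sinus_chambers={"sinus": sinus},
            channels=(channel,),
            wall_mm=2.0,
            spacing=(0.5, 0.5, 0.5),
            extent_mm=(32.0, 30.0, 30.0),
            skull_wall_mm=0.0,
        )

    def test_blocked_channel_excludes_side_chamber(self):
        volume, truth = generate_phantom(self.chamber_spec())
        channel = truth.adjacency[0][2]
        block = Block(center=channel.midpoint(), normal=channel.axis(),
                      radius=3.0, thickness=2.0)
        params = SegParams(threshold=-400.0, seed=truth.seeds["main"],
                          median_radius=0, gaussian_sigma=0.0)
        without = segment_nasal_airway(volume, truth.landmarks, (), params)
        with_block = segment_nasal_airway(volume, truth.landmarks, (block,), params)
        main_analytic = truth.cavity_volumes["main"]
        sinus_analytic = 4.0 / 3.0 * np.pi * 27.0
        assert without.volume_mm3 > with_block.volume_mm3
        assert with_block.volume_mm3 == pytest.approx(main_analytic, rel=0.05)
        assert without.volume_mm3 == pytest.approx(
            main_analytic + sinus_analytic, rel=0.10
        )

    def test_blocks_never_increase_volume(self):
        volume, truth = generate_phantom(self.chamber_spec())
        channel = truth.adjacency[0][2]
        params = SegParams(threshold=-400.0, seed=truth.seeds["main"],
                          median_radius=0, gaussian_sigma=0.0)
        base = segment_nasal_airway(volume, truth.landmarks, (), params)
        block = Block(center=channel.midpoint(), normal=channel.axis(),
                      radius=2.0, thickness=1.5)
        blocked = segment_nasal_airway(volume, truth.landmarks, (block,), params)
        assert blocked.volume_mm3 <= base.volume_mm3
        assert np.all(base.mask.data[blocked.mask.data])

    def test_seed_inside_blocked_voxel_rejected(self):
        volume, truth = generate_phantom(single_cavity_spec())
        seed = truth.seeds["main"]
        block = Block(center=seed, normal=(0.0, 0.0, 1.0), radius=2.0, thickness=2.0)
        params = SegParams(threshold=-400.0, seed=seed,
                          median_radius=0, gaussian_sigma=0.0)
        with pytest.raises(SegmentationError, match="blocked"):
            segment_nasal_airway(volume, truth.landmarks, (block,), params)

    def test_result_single_component_with_seed(self):
        volume, truth = generate_phantom(single_cavity_spec())
        params = SegParams(threshold=-400.0, seed=truth.seeds["main"],
                          median_radius=0, gaussian_sigma=0.0)
        result = segment_nasal_airway(volume, truth.landmarks, (), params)
        seed_idx = result.mask.world_to_index(truth.seeds["main"])
        np.testing.assert_array_equal(
            result.mask.data, bfs_flood_fill(result.mask.data, seed_idx, 6)
        )


class TestPropertyInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @given(
        data=hnp.arrays(
            dtype=np.int16,
            shape=hnp.array_shapes(min_dims=3, max_dims=3, min_side=2, max_side=8),
            elements=st.integers(-1100, 900),
        ),
        thresholds=st.lists(st.integers(-1100, 900), min_size=2, max_size=5),
    )
    @settings(max_examples=40, deadline=None)
    def test_air_count_monotone_in_threshold(self, data, thresholds):
        vol = Volume(data)
        counts = [binarize_air(vol, t).voxel_count for t in sorted(thresholds)]
        assert counts == sorted(counts)

    @given(
        data=hnp.arrays(
            dtype=bool,
            shape=hnp.array_shapes(min_dims=3, max_dims=3, min_side=3, max_side=10),
        ),
        conn=st.sampled_from([6, 18, 26]),
    )
    @settings(max_examples=40, deadline=None)
    def test_region_grow_subset_and_idempotent(self, data, conn):
        true_idx = np.argwhere(data)
        if len(true_idx) == 0:
            return
        mask = Mask(data)
        seed_idx = tuple(true_idx[0])
        seed = tuple(i + 0.5 for i in seed_idx)
        grown = region_grow(mask, seed, conn)
        assert np.all(mask.data[grown.data])
        again = region_grow(grown, seed, conn)
        np.testing.assert_array_equal(again.data, grown.data)
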