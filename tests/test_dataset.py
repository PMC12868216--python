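import numpy as np
import pytest
from scipy import stats as sps

from osteoseg.dataset import (
    AugmentationPolicy,
    ConfigurationError,
    PatchSpec,
    SplitPlan,
    augment_geometric,
    augment_intensity,
    build_folds,
    draw_intensity_params,
    patches_per_epoch,
    sample_patch_origins,
    serialize_split,
    split_scans,
)

IDS20 = [f"scan{i:02d}" for i in range(20)]


class TestSplitScans:
    def test_16_scans_at_0_8125(self):
        plan = split_scans([f"s{i}" for i in range(16)], 0.8125, seed=42)
        assert len(plan.train_ids) == 13
        assert len(plan.val_ids) == 3

    def test_two_scans_half(self):
        plan = split_scans(["a", "b"], 0.5, seed=0)
        assert len(plan.train_ids) == 1 and len(plan.val_ids) == 1

    def test_20_scans_at_0_8_brute_force(self):
        # oracle: enumerate candidate counts, pick the closest feasible one
        n, frac = 20, 0.8
        best = min(range(1, n), key=lambda c: abs(c / n - frac))
        plan = split_scans(IDS20, frac, seed=7)
        assert len(plan.train_ids) == best == 16

    def test_no_leakage_and_coverage(self):
        plan = split_scans(IDS20, 0.7, seed=3)
        assert not set(plan.train_ids) & set(plan.val_ids)
        assert set(plan.train_ids) | set(plan.val_ids) == set(IDS20)

    def test_seed_determinism(self):
        a = split_scans(IDS20, 0.6, seed=5)
        b = split_scans(IDS20, 0.6, seed=5)
        assert a == b

    def test_too_few_scans(self):
        with pytest.raises(ConfigurationError):
            split_scans(["only"], 0.5, seed=0)

    def test_split_plan_rejects_overlap(self):
        with pytest.raises(ConfigurationError):
            SplitPlan(train_ids=("a", "b"), val_ids=("b",),
                      requested_fraction=0.5, seed=0)

    def test_serialize_round_trip_fields(self):
        plan = split_scans(IDS20[:4], 0.5, seed=9)
        text = serialize_split(plan)
        assert "seed\t9" in text
        for sid in plan.train_ids:
            assert f"train\t{sid}" in text


class TestBuildFolds:
    def test_20_scans_5_folds(self):
        plan = build_folds(IDS20, 5)
        assert plan.fold_size == 4
        assert plan.test_ids(0) == tuple(IDS20[:4])

    def test_9_scans_3_folds(self):
        ids = [f"x{i}" for i in range(9)]
        plan = build_folds(ids, 3)
        assert [plan.test_ids(i) for i in range(3)] == [
            tuple(ids[0:3]), tuple(ids[3:6]), tuple(ids[6:9])]

    def test_pool_is_disjoint_complement(self):
        plan = build_folds(IDS20, 5)
        for i in range(5):
            test, pool = set(plan.test_ids(i)), set(plan.pool_ids(i))
            assert not test & pool
            assert test | pool == set(IDS20)

    def test_every_scan_in_exactly_one_fold(self):
        plan = build_folds(IDS20, 5)
        seen = [sid for i in range(5) for sid in plan.test_ids(i)]
        assert sorted(seen) == sorted(IDS20)

    def test_non_divisible_errors(self):
        with pytest.raises(ConfigurationError):
            build_folds(IDS20[:7], 3)


class TestSamplePatchOrigins:
    def test_patch_equals_tile_forces_origin(self, rng):
        spec = PatchSpec(patch_px=256, patches_per_tile=4, max_overlap=0.0)
        with pytest.warns(UserWarning):
            origins = sample_patch_origins((256, 256), spec, rng)
        assert origins == [(0, 0)] * 4

    def test_zero_overlap_achieved_on_large_tile(self, rng):
        spec = PatchSpec(patch_px=256, patches_per_tile=4, max_overlap=0.0)
        origins = sample_patch_origins((1024, 1024), spec, rng)
        assert len(origins) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                dy = max(0, 256 - abs(origins[i][0] - origins[j][0]))
                dx = max(0, 256 - abs(origins[i][1] - origins[j][1]))
                assert dy * dx == 0  # rectangle intersection is empty

    def test_same_seed_same_origins(self):
        spec = PatchSpec(patch_px=64, patches_per_tile=4, max_overlap=0.5)
        a = sample_patch_origins((256, 256), spec, np.random.default_rng(5))
        b = sample_patch_origins((256, 256), spec, np.random.default_rng(5))
        assert a == b

    def test_origins_stay_in_bounds(self, rng):
        spec = PatchSpec(patch_px=50, patches_per_tile=8, max_overlap=1.0)
        for y, x in sample_patch_origins((70, 90), spec, rng):
            assert 0 <= y <= 20 and 0 <= x <= 40


class TestAugmentGeometric:
    def test_branch_frequencies_100k(self):
        policy = AugmentationPolicy()
        rng = np.random.default_rng(2024)
        patch = np.zeros((4, 4), dtype=np.float32)
        counts = {"hflip": 0, "vflip": 0, "rot": 0, "none": 0}
        n = 100_000
        for _ in range(n):
            _, _, branch = augment_geometric(patch, patch, policy, rng)
            counts[branch] += 1
        assert abs(counts["rot"] / n - 0.5) < 0.005
        expected = [0.166, 0.166, 0.5, 0.168]
        observed = [counts[k] for k in ("hflip", "vflip", "rot", "none")]
        chi = sps.chisquare(observed, [p * n for p in expected])
        assert chi.pvalue > 0.01

    def test_hflip_twice_is_identity(self, rng):
        policy = AugmentationPolicy(p_hflip=1.0, p_vflip=0.0, p_rot90s=0.0, p_none=0.0)
        patch = np.arange(16, dtype=np.float32).reshape(4, 4)
        once, m1, _ = augment_geometric(patch, patch, policy, rng)
        twice, m2, _ = augment_geometric(once, m1, policy, rng)
        np.testing.assert_array_equal(twice, patch)

    def test_same_seed_same_output(self):
        policy = AugmentationPolicy()
        patch = np.arange(16, dtype=np.float32).reshape(4, 4)
        a = augment_geometric(patch, patch, policy, np.random.default_rng(3))
        b = augment_geometric(patch, patch, policy, np.random.default_rng(3))
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_scan_and_mask_stay_aligned(self, rng):
        # coordinate-encoding image: any de-synchronized transform breaks equality
        coords = np.arange(64, dtype=np.float32).reshape(8, 8)
        policy = AugmentationPolicy()
        for _ in range(200):
            s, m, _ = augment_geometric(coords, coords.copy(), policy, rng)
            np.testing.assert_array_equal(s, m)

    def test_requires_square(self, rng):
        with pytest.raises(ValueError, match="square"):
            augment_geometric(np.zeros((2, 4)), np.zeros((2, 4)),
                              AugmentationPolicy(), rng)

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            AugmentationPolicy(p_none=0.5)


class TestAugmentIntensity:
    def test_identity_params(self):
        patch = np.random.default_rng(0).uniform(0, 1, (4, 4)).astype(np.float32)
        out = augment_intensity(patch, AugmentationPolicy(), "minmax",
                                params=(1.0, 0.0))
        np.testing.assert_allclose(out, patch)

    def test_clip_upper_bound_minmax(self):
        patch = np.ones((4, 4), dtype=np.float32)
        out = augment_intensity(patch, AugmentationPolicy(), "minmax",
                                params=(1.0, 0.15))
        np.testing.assert_allclose(out, 1.0)

    def test_draw_ranges_100k(self):
        policy = AugmentationPolicy()
        rng = np.random.default_rng(77)
        scales, shifts = [], []
        for _ in range(100_000):
            s, d = draw_intensity_params(policy, rng)
            scales.append(s)
            shifts.append(d)
        assert min(scales) >= 0.75 and max(scales) <= 1.25
        assert min(shifts) >= -0.15 and max(shifts) <= 0.15
        # each transform fires ~40% of the time
        assert abs(np.mean([s != 1.0 for s in scales]) - 0.4) < 0.01
        assert abs(np.mean([d != 0.0 for d in shifts]) - 0.4) < 0.01


class TestPatchesPerEpoch:
    def test_single_scan(self):
        assert patches_per_epoch(["a"], {"a": 10}, 4) == (40, 0, 40)

    def test_conservation_under_any_split(self):
        tiles = {f"s{i}": 10 + i for i in range(6)}
        total = 4 * sum(tiles.values())
        for seed in range(5):
            plan = split_scans(list(tiles), 0.5, seed=seed)
            n_train, n_val, n_total = patches_per_epoch(plan, tiles, 4)
            assert n_train + n_val == n_total == total

    def test_unknown_scan_id(self):
        with pytest.raises(KeyError):
            patches_per_epoch(["missing"], {"a": 1}, 4)
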