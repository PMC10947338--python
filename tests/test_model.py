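"""Loss, patch machinery, tiling, ensemble averaging and D95 renormalization."""

import numpy as np
import pytest
from scipy import stats

from dosepred3d import (
    LossConfig,
    PatchSpec,
    StructureMask,
    VolumeGrid,
    combined_loss,
    dose_percentile,
    normalize_to_reference_d95,
    predict_volume,
    tile_patches,
)
from dosepred3d.model import LRState, lr_schedule_step, sample_training_patch


class TestCombinedLoss:
    def _ptv(self, shape=(8, 8, 8)):
        m = np.zeros(shape, dtype=np.uint8)
        m[2:6, 2:6, 2:6] = 1
        return StructureMask("ptv", m)

    def test_zero_on_identical_fields(self):
        rng = np.random.default_rng(0)
        x = VolumeGrid(rng.uniform(0, 50, (8, 8, 8)).astype(np.float32))
        assert combined_loss(x, x, self._ptv()) == 0.0

    def test_uniform_offset_analytic(self):
        """+2 Gy everywhere: MSE = 4; each D_V% error = 2; loss = 4 + 0.25*6."""
        rng = np.random.default_rng(1)
        ref = rng.uniform(10, 40, (8, 8, 8)).astype(np.float64)
        pred = ref + 2.0
        loss = combined_loss(pred, ref, self._ptv(), LossConfig(dvh_weight=0.25))
        assert loss == pytest.approx(5.5, abs=1e-9)

    def test_pure_mse_when_weight_zero(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(10, 40, (8, 8, 8)).astype(np.float64)
        loss = combined_loss(ref + 0.5, ref, self._ptv(), LossConfig(dvh_weight=0.0))
        assert loss == pytest.approx(0.25, abs=1e-9)

    def test_non_negative_on_random_fields(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.uniform(0, 50, (6, 6, 6))
            b = rng.uniform(0, 50, (6, 6, 6))
            assert combined_loss(a, b, self._ptv((6, 6, 6))) >= 0.0

    def test_no_ptv_in_patch_falls_back_to_mse(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 40, (6, 6, 6))
        empty = np.zeros((6, 6, 6), dtype=np.uint8)
        loss = combined_loss(ref + 1.0, ref, empty)
        assert loss == pytest.approx(1.0, abs=1e-9)


class TestSampleTrainingPatch:
    def test_exact_fit_forces_origin(self):
        rng = np.random.default_rng(0)
        stack = np.zeros((16, 16, 16, 16), dtype=np.float32)
        dose = np.arange(16**3, dtype=np.float32).reshape(16, 16, 16)
        ptv = np.zeros((16, 16, 16), dtype=np.uint8)
        _, pd, _ = sample_training_patch(stack, dose, ptv, 16, rng)
        assert np.array_equal(pd, dose)

    def test_seeded_reproducibility(self):
        stack = np.zeros((2, 32, 32, 32), dtype=np.float32)
        dose = np.random.default_rng(0).random((32, 32, 32)).astype(np.float32)
        ptv = np.zeros((32, 32, 32), dtype=np.uint8)
        a = [sample_training_patch(stack, dose, ptv, 16, np.random.default_rng(5))[1] for _ in range(3)]
        b = [sample_training_patch(stack, dose, ptv, 16, np.random.default_rng(5))[1] for _ in range(3)]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_offsets_uniform(self):
        """Empirical offset marginals over {0..8} pass a chi-square test."""
        rng = np.random.default_rng(123)
        stack = np.zeros((1, 24, 24, 24), dtype=np.float32)
        dose = np.zeros((24, 24, 24), dtype=np.float32)
        marker = np.arange(24**3, dtype=np.float32).reshape(24, 24, 24)
        counts = np.zeros(9)
        for _ in range(5000):
            _, pd, _ = sample_training_patch(stack, marker, dose.astype(np.uint8), 16, rng)
            counts[int(pd[0, 0, 0]) // (24 * 24)] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=8)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            sample_training_patch(
                np.zeros((1, 8, 8, 8), np.float32), np.zeros((8, 8, 8), np.float32),
                np.zeros((8, 8, 8), np.uint8), 16, np.random.default_rng(0),
            )


class TestLRSchedule:
    def test_patience_window(self):
        state = LRState(lr=0.001, best_val_loss=1.0)
        for _ in range(54):
            state = lr_schedule_step(state, 2.0, patience=55)
        assert state.lr == 0.001
        state = lr_schedule_step(state, 2.0, patience=55)
        assert state.lr == pytest.approx(0.0005)

    def test_improvement_resets_counter(self):
        state = LRState(lr=0.001, best_val_loss=1.0)
        for _ in range(30):
            state = lr_schedule_step(state, 2.0, patience=55)
        assert state.stagnation == 30
        state = lr_schedule_step(state, 0.5, patience=55)
        assert state.stagnation == 0 and state.lr == 0.001 and state.best_val_loss == 0.5


class TestTilePatches:
    @pytest.mark.parametrize(
        "shape,size,stride,n_expected",
        [((64, 64, 64), 64, 16, 1), ((96, 96, 96), 64, 16, 27), ((70, 70, 70), 64, 16, 8)],
    )
    def test_enumerated_counts(self, shape, size, stride, n_expected):
        offs = tile_patches(shape, PatchSpec(size=size, stride=stride))
        assert len(offs) == n_expected
        assert len(set(offs)) == len(offs)

    def test_clamped_final_offset(self):
        offs = tile_patches((70, 70, 70), PatchSpec(size=64, stride=16))
        per_axis = sorted({o[0] for o in offs})
        assert per_axis == [0, 6]

    def test_full_coverage_random_shapes(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            shape = tuple(int(rng.integers(64, 129)) for _ in range(3))
            spec = PatchSpec(size=64, stride=int(rng.integers(1, 65)))
            cover = np.zeros(shape, dtype=np.int32)
            for off in tile_patches(shape, spec):
                sl = tuple(slice(o, o + spec.size) for o in off)
                cover[sl] += 1
            assert cover.min() >= 1

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            tile_patches((32, 32, 32), PatchSpec(size=64, stride=16))


class TestPredictVolume:
    def _stack(self, shape=(40, 40, 40)):
        rng = np.random.default_rng(0)
        return rng.integers(0, 8, size=(16,) + shape).astype(np.float32)

    def test_mean_of_constant_models(self):
        stack = self._stack()
        models = [lambda p, c=c: np.full(p.shape[1:], c, np.float32) for c in (1.0, 2.0, 6.0)]
        out = predict_volume(models, stack, PatchSpec(size=16, stride=8))
        assert np.allclose(out.values, 3.0, atol=1e-6)

    def test_single_exact_fit_patch_is_identity(self):
        stack = self._stack((16, 16, 16))
        model = lambda p: p[0] * 2.0 + 1.0
        out = predict_volume([model], stack, PatchSpec(size=16, stride=16))
        assert np.array_equal(out.values, stack[0] * 2.0 + 1.0)

    def test_voxelwise_model_matches_full_volume_oracle(self):
        """A receptive-field-1 model gives identical output patched or whole."""
        stack = self._stack((40, 40, 40))
        model = lambda p: 3.0 * p[0] + p[1]
        out = predict_volume([model], stack, PatchSpec(size=16, stride=8))
        oracle = 3.0 * stack[0] + stack[1]
        assert np.array_equal(out.values, oracle.astype(np.float32))

    def test_permutation_invariant_in_model_order(self):
        stack = self._stack((24, 24, 24))
        models = [lambda p, c=c: p[0] + c for c in (0.0, 1.0, 5.0)]
        a = predict_volume(models, stack, PatchSpec(size=16, stride=8))
        b = predict_volume(models[::-1], stack, PatchSpec(size=16, stride=8))
        assert np.array_equal(a.values, b.values)

    def test_requires_models(self):
        with pytest.raises(ValueError):
            predict_volume([], self._stack((16, 16, 16)), PatchSpec(size=16, stride=16))


class TestD95Renormalization:
    def _setup(self):
        rng = np.random.default_rng(13)
        ref = VolumeGrid(rng.uniform(20, 50, (10, 10, 10)).astype(np.float32))
        ptv = np.zeros((10, 10, 10), dtype=np.uint8)
        ptv[3:7, 3:7, 3:7] = 1
        return ref, StructureMask("ptv", ptv)

    def test_scaling_cancels(self):
        ref, ptv = self._setup()
        pred = ref.with_values(ref.values * 0.9)
        out = normalize_to_reference_d95(pred, ref, ptv)
        assert np.allclose(out.values, ref.values, rtol=1e-6)

    def test_explicit_ratio(self):
        ref, ptv = self._setup()
        pred = ref.with_values(np.asarray(ref.values) * (40.0 / dose_percentile(ref, ptv, 95)))
        out = normalize_to_reference_d95(pred, ref, ptv)
        factor = dose_percentile(ref, ptv, 95) / 40.0
        assert np.allclose(out.values, pred.values * factor, rtol=1e-6)

    def test_identity_when_equal(self):
        ref, ptv = self._setup()
        out = normalize_to_reference_d95(ref, ref, ptv)
        assert np.allclose(out.values, ref.values, rtol=1e-7)

    def test_post_condition_d95_matches(self):
        ref, ptv = self._setup()
        rng = np.random.default_rng(14)
        pred = ref.with_values(rng.uniform(10, 60, ref.shape).astype(np.float32))
        out = normalize_to_reference_d95(pred, ref, ptv)
        assert dose_percentile(out, ptv, 95) == pytest.approx(
            dose_percentile(ref, ptv, 95), rel=1e-6
        )

    def test_d95_percentage_delta_vanishes_after_renormalization(self):
        """Renormalization zeroes the relative D95% delta between plans."""
        from dosepred3d import plan_dose_deltas

        ref, ptv = self._setup()
        rng = np.random.default_rng(15)
        pred = ref.with_values(rng.uniform(10, 60, ref.shape).astype(np.float32))
        out = normalize_to_reference_d95(pred, ref, ptv)
        body = StructureMask("body", np.ones(ref.shape, dtype=np.uint8))
        cmp = plan_dose_deltas(out, ref, {"ptv": ptv, "body": body}, prescription_Gy=45.0)
        assert abs(cmp.ptv_delta_pct[95.0]) < 1e-4  # percent scale, 1e-6 relative

    def test_zero_d95_rejected(self):
        ref, ptv = self._setup()
        zero = ref.with_values(np.zeros(ref.shape, dtype=np.float32))
        with pytest.raises(ValueError):
            normalize_to_reference_d95(zero, ref, ptv)
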