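"""DVH, percentile, conformity/homogeneity, deltas and isodose operations.

Every statistic here has an independent brute-force oracle based on explicit
sorting or counting of masked voxel doses.
"""

import math

import numpy as np
import pytest

from dosepred3d import (
    StructureMask,
    VolumeGrid,
    compute_dvh,
    conformity_index,
    dose_percentile,
    homogeneity_index,
    isodose_volume,
    plan_dose_deltas,
    reference_isodose_level,
    volume_at_dose,
)
from dosepred3d.metrics import falloff_structure


# --- independent oracles ----------------------------------------------------

def oracle_dvh_fraction(doses, edge):
    return sum(1 for d in doses if d >= edge) / len(doses)


def oracle_percentile(doses, v_percent):
    """D_V% by descending sort: minimum of the hottest ceil(V*N/100) voxels."""
    s = sorted(doses, reverse=True)
    k = math.ceil(v_percent * len(s) / 100.0)
    return s[k - 1]


def _field_1_to_100():
    vals = np.arange(1.0, 101.0)
    dose = VolumeGrid(np.pad(vals, (0, 25)).reshape(5, 5, 5).astype(np.float32))
    mask = np.zeros(125)
    mask[:100] = 1
    return dose, StructureMask("roi", mask.reshape(5, 5, 5).astype(np.uint8))


class TestDosePercentile:
    def test_uniform_field(self):
        dose = VolumeGrid(np.full((4, 4, 4), 45.0, dtype=np.float32))
        mask = StructureMask("roi", np.ones((4, 4, 4), dtype=np.uint8))
        for v in (1, 5, 50, 95, 100):
            assert dose_percentile(dose, mask, v) == 45.0

    def test_ladder_field(self):
        dose, mask = _field_1_to_100()
        assert dose_percentile(dose, mask, 95) == 6.0
        assert dose_percentile(dose, mask, 1) == 100.0
        assert dose_percentile(dose, mask, 98) == 3.0

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            vals = rng.uniform(0, 60, (8, 8, 8)).astype(np.float32)
            mask_vals = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
            mask_vals[0, 0, 0] = 1
            dose, mask = VolumeGrid(vals), StructureMask("m", mask_vals)
            v = float(rng.uniform(0.5, 100.0))
            expected = oracle_percentile(vals[mask_vals == 1].tolist(), v)
            assert dose_percentile(dose, mask, v) == pytest.approx(expected, abs=0)

    def test_monotone_in_volume(self):
        rng = np.random.default_rng(7)
        dose = VolumeGrid(rng.uniform(0, 50, (8, 8, 8)).astype(np.float32))
        mask = StructureMask("m", np.ones((8, 8, 8), dtype=np.uint8))
        values = [dose_percentile(dose, mask, v) for v in np.linspace(1, 100, 40)]
        assert np.all(np.diff(values) <= 1e-12)

    def test_empty_mask_rejected(self):
        dose = VolumeGrid(np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError):
            dose_percentile(dose, StructureMask("m", np.zeros((4, 4, 4), dtype=np.uint8)), 95)


class TestDVH:
    def test_uniform_structure_is_step(self):
        dose = VolumeGrid(np.full((4, 4, 4), 45.0, dtype=np.float32))
        mask = StructureMask("roi", np.ones((4, 4, 4), dtype=np.uint8))
        curve = compute_dvh(dose, mask, bin_width_Gy=1.0)
        below = curve.dose_edges_Gy <= 45.0
        assert np.all(curve.cumulative_volume[below] == 1.0)
        assert np.all(curve.cumulative_volume[~below] == 0.0)

    def test_counting_oracle(self):
        dose, mask = _field_1_to_100()
        curve = compute_dvh(dose, mask, bin_width_Gy=0.5)
        idx = int(np.argmin(np.abs(curve.dose_edges_Gy - 40.5)))
        assert curve.cumulative_volume[idx] == pytest.approx(0.60)

    def test_monotone_and_covers_dmax(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 55, (8, 8, 8)).astype(np.float32)
        dose = VolumeGrid(vals)
        mask = StructureMask("m", np.ones((8, 8, 8), dtype=np.uint8))
        curve = compute_dvh(dose, mask)
        assert np.all(np.diff(curve.cumulative_volume) <= 1e-12)
        assert curve.dose_edges_Gy[-1] >= vals.max()
        assert curve.cumulative_volume[0] == 1.0


class TestConformity:
    def test_reference_isodose_level(self):
        assert reference_isodose_level(45.0) == pytest.approx(42.75)

    def test_perfectly_conformal(self):
        vals = np.zeros((6, 6, 6), dtype=np.float32)
        ptv = np.zeros((6, 6, 6), dtype=np.uint8)
        ptv[2:4, 2:4, 2:4] = 1
        vals[ptv == 1] = 45.0
        assert conformity_index(VolumeGrid(vals), StructureMask("ptv", ptv), 42.75) == 1.0

    def test_voxel_counting(self):
        vals = np.zeros((8, 8, 8), dtype=np.float32)
        ptv = np.zeros((8, 8, 8), dtype=np.uint8)
        ptv.ravel()[:100] = 1
        vals.ravel()[:125] = 45.0  # 100 PTV voxels + 25 spill voxels covered
        ci = conformity_index(VolumeGrid(vals), StructureMask("ptv", ptv), 42.75)
        assert ci == pytest.approx(0.8)

    def test_empty_isodose_raises(self):
        vals = np.full((4, 4, 4), 10.0, dtype=np.float32)
        ptv = np.ones((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            conformity_index(VolumeGrid(vals), StructureMask("ptv", ptv), 42.75)


class TestHomogeneity:
    def test_uniform_dose(self):
        dose = VolumeGrid(np.full((4, 4, 4), 45.0, dtype=np.float32))
        assert homogeneity_index(dose, StructureMask("ptv", np.ones((4, 4, 4), dtype=np.uint8))) == 1.0

    def test_ladder_oracle(self):
        dose, mask = _field_1_to_100()
        # D5% = 96 (ceil convention), D95% = 6
        assert homogeneity_index(dose, mask) == pytest.approx(96.0 / 6.0)

    def test_at_least_one(self):
        rng = np.random.default_rng(11)
        dose = VolumeGrid(rng.uniform(1, 50, (6, 6, 6)).astype(np.float32))
        mask = StructureMask("ptv", np.ones((6, 6, 6), dtype=np.uint8))
        assert homogeneity_index(dose, mask) >= 1.0


class TestVolumeAtDose:
    def test_counting_and_monotonicity(self):
        dose, mask = _field_1_to_100()
        assert volume_at_dose(dose, mask, 40.5) == pytest.approx(0.60)
        fracs = [volume_at_dose(dose, mask, x) for x in np.linspace(0, 101, 30)]
        assert np.all(np.diff(fracs) <= 1e-12)
        assert 0.0 <= min(fracs) and max(fracs) <= 1.0


class TestPlanDeltas:
    def _structures(self, shape=(6, 6, 6)):
        ptv = np.zeros(shape, dtype=np.uint8)
        ptv[2:4, 2:4, 2:4] = 1
        bladder = np.zeros(shape, dtype=np.uint8)
        bladder[0:2, 0:2, 0:2] = 1
        body = np.ones(shape, dtype=np.uint8)
        return {
            "ptv": StructureMask("ptv", ptv),
            "bladder": StructureMask("bladder", bladder),
            "body": StructureMask("body", body),
        }

    def test_identity(self):
        rng = np.random.default_rng(3)
        ref = VolumeGrid(rng.uniform(10, 50, (6, 6, 6)).astype(np.float32))
        cmp = plan_dose_deltas(ref, ref, self._structures(), prescription_Gy=30.0)
        assert all(v == 0.0 for v in cmp.ptv_delta_pct.values())
        assert cmp.oar_delta_mean_Gy["bladder"] == 0.0
        assert cmp.voxel_mean_diff_Gy == 0.0

    def test_relative_percentage_arithmetic(self):
        structures = self._structures()
        ref_vals = np.full((6, 6, 6), 45.0, dtype=np.float32)
        pred_vals = np.full((6, 6, 6), 44.5, dtype=np.float32)
        cmp = plan_dose_deltas(
            VolumeGrid(pred_vals), VolumeGrid(ref_vals), structures, prescription_Gy=45.0
        )
        assert cmp.ptv_delta_pct[1.0] == pytest.approx((44.5 - 45.0) / 45.0 * 100.0)
        assert cmp.ptv_delta_pct[1.0] == pytest.approx(-1.111, abs=1e-3)

    def test_oar_mean_delta_in_gray(self):
        structures = self._structures()
        rng = np.random.default_rng(4)
        base = rng.uniform(30, 50, (6, 6, 6)).astype(np.float32)
        pred = base.copy()
        pred[structures["bladder"].boolean()] -= 2.0
        cmp = plan_dose_deltas(VolumeGrid(pred), VolumeGrid(base), structures, prescription_Gy=40.0)
        assert cmp.oar_delta_mean_Gy["bladder"] == pytest.approx(-2.0, abs=1e-5)

    def test_antisymmetry_of_gray_deltas(self):
        structures = self._structures()
        rng = np.random.default_rng(6)
        a = VolumeGrid(rng.uniform(20, 50, (6, 6, 6)).astype(np.float32))
        b = VolumeGrid(rng.uniform(20, 50, (6, 6, 6)).astype(np.float32))
        ab = plan_dose_deltas(a, b, structures, prescription_Gy=40.0)
        ba = plan_dose_deltas(b, a, structures, prescription_Gy=40.0)
        assert ab.oar_delta_mean_Gy["bladder"] == pytest.approx(-ba.oar_delta_mean_Gy["bladder"], abs=1e-6)
        assert ab.oar_delta_max_Gy["bladder"] == pytest.approx(-ba.oar_delta_max_Gy["bladder"], abs=1e-6)
        assert ab.voxel_mean_diff_Gy == pytest.approx(-ba.voxel_mean_diff_Gy, abs=1e-6)


class TestIsodose:
    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        dose = VolumeGrid(rng.uniform(0, 50, (8, 8, 8)).astype(np.float32))
        lo = isodose_volume(dose, 20.0).boolean()
        hi = isodose_volume(dose, 40.0).boolean()
        assert np.all(hi <= lo)

    def test_level_above_max_is_empty(self):
        dose = VolumeGrid(np.full((4, 4, 4), 10.0, dtype=np.float32))
        assert isodose_volume(dose, 99.0).voxel_count == 0

    def test_falloff_structures_nest(self):
        rng = np.random.default_rng(9)
        dose = VolumeGrid(rng.uniform(0, 50, (8, 8, 8)).astype(np.float32))
        body = StructureMask("body", np.ones((8, 8, 8), dtype=np.uint8))
        s40 = falloff_structure(dose, body, 40.0).boolean()
        s20 = falloff_structure(dose, body, 20.0).boolean()
        # body minus the larger (lower-level) isodose is the smaller structure
        assert np.all(s20 <= s40)
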