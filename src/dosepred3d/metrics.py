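"""Plan-quality analytics: DVHs, dose metrics, equivalence testing, objectives.

Conventions
-----------
* ``D_V%`` is the minimum dose received by the hottest ``V`` percent of a
  structure's volume, computed by exact voxel sorting: with ``N`` masked
  voxels it is the ``ceil(V * N / 100)``-th largest masked dose.
* Conformity index ``CI = TV_RI / V_RI``: the fraction of the reference
  isodose volume occupied by the PTV, evaluated by default at 95% of the
  prescription (42.75 Gy for a 45 Gy plan).
* Homogeneity index ``HI = D5% / D95%`` of the PTV (1 = perfectly
  homogeneous).
* Equivalence of predicted and reference mean doses uses the paired two
  one-sided t-test (TOST) with a 1 Gy bound by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.weightstats import ttost_paired

from .grids import GeometryError, StructureMask, VolumeGrid

__all__ = [
    "DVHCurve",
    "DoseMetrics",
    "EquivalenceResult",
    "PlanComparison",
    "ReplanObjective",
    "FlagThresholds",
    "reference_isodose_level",
    "dose_percentile",
    "volume_at_dose",
    "compute_dvh",
    "conformity_index",
    "homogeneity_index",
    "structure_dose_metrics",
    "plan_dose_deltas",
    "tost_equivalence",
    "isodose_volume",
    "flag_and_extract_objectives",
]

DEFAULT_ISODOSE_FRACTION = 0.95


def reference_isodose_level(prescription_Gy: float, fraction: float = DEFAULT_ISODOSE_FRACTION) -> float:
    """Reference isodose for conformity: ``fraction`` of the prescription."""
    if prescription_Gy <= 0 or fraction <= 0:
        raise ValueError("prescription and fraction must be positive")
    return prescription_Gy * fraction


def _masked_doses(dose: VolumeGrid, mask: StructureMask) -> np.ndarray:
    dose.require_same_geometry(mask)
    vals = np.asarray(dose.values, dtype=np.float64)[mask.boolean()]
    if vals.size == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    return vals


def dose_percentile(dose: VolumeGrid, mask: StructureMask, volume_percent: float) -> float:
    """``D_V%``: minimum dose among the hottest ``ceil(V*N/100)`` masked voxels."""
    if not (0 < volume_percent <= 100):
        raise ValueError("volume percentage must lie in (0, 100]")
    vals = _masked_doses(dose, mask)
    k = math.ceil(volume_percent * vals.size / 100.0)
    return float(np.partition(vals, vals.size - k)[vals.size - k])


def volume_at_dose(dose: VolumeGrid, mask: StructureMask, level_Gy: float) -> float:
    """``V_x``: fraction of the structure's volume receiving at least ``x`` Gy."""
    vals = _masked_doses(dose, mask)
    return float(np.mean(vals >= level_Gy))


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    dose_edges_Gy: np.ndarray
    cumulative_volume: np.ndarray  # fraction of volume receiving >= edge

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative_volume) > 1e-12):
            raise ValueError("cumulative DVH must be monotone non-increasing")

    def volume_at(self, level_Gy: float) -> float:
        """Interpolated fractional volume at a dose level."""
        return float(np.interp(level_Gy, self.dose_edges_Gy, self.cumulative_volume))


def compute_dvh(dose: VolumeGrid, mask: StructureMask, bin_width_Gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH on a uniform dose grid reaching at least Dmax."""
    if bin_width_Gy <= 0:
        raise ValueError("bin width must be positive")
    vals = _masked_doses(dose, mask)
    dmax = float(vals.max())
    n_edges = int(math.ceil(dmax / bin_width_Gy + 1e-9)) + 1
    edges = np.arange(n_edges + 1) * bin_width_Gy
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(mask.name, edges, frac)


def conformity_index(dose: VolumeGrid, ptv: StructureMask, reference_isodose_Gy: float) -> float:
    """``CI = TV_RI / V_RI`` by voxel counting at the reference isodose."""
    if reference_isodose_Gy <= 0:
        raise ValueError("isodose level must be positive")
    dose.require_same_geometry(ptv)
    covered = np.asarray(dose.values) >= reference_isodose_Gy
    v_ri = int(covered.sum())
    if v_ri == 0:
        raise ValueError(
            f"no voxel reaches the {reference_isodose_Gy} Gy reference isodose; CI is undefined"
        )
    tv_ri = int((covered & ptv.boolean()).sum())
    return tv_ri / v_ri


def homogeneity_index(dose: VolumeGrid, ptv: StructureMask) -> float:
    """``HI = D5% / D95%`` of the PTV."""
    d95 = dose_percentile(dose, ptv, 95.0)
    if d95 <= 0:
        raise ValueError("D95% must be positive for the homogeneity index")
    return dose_percentile(dose, ptv, 5.0) / d95


@dataclass(frozen=True)
class DoseMetrics:
    """Scalar dose metrics of one structure under one dose distribution."""

    structure: str
    Dmean_Gy: float
    Dmax_Gy: float
    D1_Gy: float
    D5_Gy: float
    D95_Gy: float
    D98_Gy: float
    V_Gy: dict[float, float] = field(default_factory=dict)  # level -> fraction
    CI: float | None = None
    HI: float | None = None


def structure_dose_metrics(
    dose: VolumeGrid,
    mask: StructureMask,
    v_levels_Gy: tuple[float, ...] = (40.0,),
    is_target: bool = False,
    prescription_Gy: float | None = None,
) -> DoseMetrics:
    """All scalar metrics for one structure; CI/HI only for the target."""
    vals = _masked_doses(dose, mask)
    ci = hi = None
    if is_target:
        if prescription_Gy is None:
            raise ValueError("prescription required for target CI")
        ci = conformity_index(dose, mask, reference_isodose_level(prescription_Gy))
        hi = homogeneity_index(dose, mask)
    return DoseMetrics(
        structure=mask.name,
        Dmean_Gy=float(vals.mean()),
        Dmax_Gy=float(vals.max()),
        D1_Gy=dose_percentile(dose, mask, 1.0),
        D5_Gy=dose_percentile(dose, mask, 5.0),
        D95_Gy=dose_percentile(dose, mask, 95.0),
        D98_Gy=dose_percentile(dose, mask, 98.0),
        V_Gy={lvl: volume_at_dose(dose, mask, lvl) for lvl in v_levels_Gy},
        CI=ci,
        HI=hi,
    )


# ---------------------------------------------------------------------------
# predicted-vs-reference comparison
# ---------------------------------------------------------------------------

@dataclass
class PlanComparison:
    """Per-structure predicted-vs-reference deltas for one plan.

    PTV percentile deltas are relative percentages
    (``(pred - ref) / ref * 100``); OAR mean/max deltas are absolute Gy.
    """

    plan_id: str
    ptv_delta_pct: dict[float, float]  # V% -> percentage delta
    oar_delta_mean_Gy: dict[str, float]
    oar_delta_max_Gy: dict[str, float]
    voxel_mean_diff_Gy: float
    pred_metrics: dict[str, DoseMetrics] = field(default_factory=dict)
    ref_metrics: dict[str, DoseMetrics] = field(default_factory=dict)
    flag: bool | None = None
    objectives: list["ReplanObjective"] = field(default_factory=list)


def plan_dose_deltas(
    pred: VolumeGrid,
    reference: VolumeGrid,
    structures: dict[str, StructureMask],
    ptv_name: str = "ptv",
    body_name: str = "body",
    ptv_percentiles: tuple[float, ...] = (1.0, 95.0, 98.0),
    plan_id: str = "plan",
    prescription_Gy: float | None = None,
) -> PlanComparison:
    """Predicted-vs-reference deltas: PTV percentage deltas, OAR Gy deltas,
    and the mean voxel-wise dose difference inside the body."""
    pred.require_same_geometry(reference)
    if ptv_name not in structures:
        raise ValueError("PTV mask is required")
    ptv = structures[ptv_name]

    ptv_delta: dict[float, float] = {}
    for v in ptv_percentiles:
        d_pred = dose_percentile(pred, ptv, v)
        d_ref = dose_percentile(reference, ptv, v)
        ptv_delta[v] = (d_pred - d_ref) / d_ref * 100.0

    pred_metrics: dict[str, DoseMetrics] = {}
    ref_metrics: dict[str, DoseMetrics] = {}
    d_mean: dict[str, float] = {}
    d_max: dict[str, float] = {}
    for name, mask in structures.items():
        is_target = name == ptv_name
        pm = structure_dose_metrics(pred, mask, is_target=is_target, prescription_Gy=prescription_Gy if is_target else None)
        rm = structure_dose_metrics(reference, mask, is_target=is_target, prescription_Gy=prescription_Gy if is_target else None)
        pred_metrics[name] = pm
        ref_metrics[name] = rm
        if name not in (ptv_name, body_name):
            d_mean[name] = pm.Dmean_Gy - rm.Dmean_Gy
            d_max[name] = pm.Dmax_Gy - rm.Dmax_Gy

    if body_name in structures:
        region = structures[body_name].boolean()
    else:
        region = np.ones(pred.shape, dtype=bool)
    diff = np.asarray(pred.values, dtype=np.float64) - np.asarray(reference.values, dtype=np.float64)
    voxel_mean = float(diff[region].mean())

    return PlanComparison(
        plan_id=plan_id,
        ptv_delta_pct=ptv_delta,
        oar_delta_mean_Gy=d_mean,
        oar_delta_max_Gy=d_max,
        voxel_mean_diff_Gy=voxel_mean,
        pred_metrics=pred_metrics,
        ref_metrics=ref_metrics,
    )


# ---------------------------------------------------------------------------
# equivalence testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalenceResult:
    """Paired TOST outcome for predicted vs reference mean doses."""

    mean_diff_Gy: float
    se_Gy: float
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    bound_Gy: float
    alpha: float
    equivalent: bool

    @property
    def p_value(self) -> float:
        """Overall TOST p-value: the larger of the two one-sided p-values."""
        return max(self.p_lower, self.p_upper)


def tost_equivalence(
    paired_pred,
    paired_ref,
    bound_Gy: float = 1.0,
    alpha: float = 0.05,
) -> EquivalenceResult:
    """Paired two one-sided t-test: are the mean doses equivalent within the bound?

    Tests mean(pred - ref) > -bound and < +bound, each one-sided at ``alpha``;
    equivalence is declared when both reject.  A zero-variance difference
    vector (undefined t statistic) is judged by |mean| < bound directly.
    """
    pred = np.asarray(paired_pred, dtype=np.float64)
    ref = np.asarray(paired_ref, dtype=np.float64)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("paired vectors must be 1D and equal length")
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if bound_Gy <= 0:
        raise ValueError("equivalence bound must be positive")

    d = pred - ref
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)

    if se == 0.0:
        inside = abs(mean) < bound_Gy
        p = 0.0 if inside else 1.0
        sign = math.inf if inside else 0.0
        return EquivalenceResult(mean, se, sign, -sign, p, p, bound_Gy, alpha, inside)

    _, (t_lower, p_lower, _), (t_upper, p_upper, _) = ttost_paired(
        pred, ref, -bound_Gy, bound_Gy
    )
    equivalent = max(p_lower, p_upper) < alpha
    return EquivalenceResult(
        mean, se, float(t_lower), float(t_upper), float(p_lower), float(p_upper),
        bound_Gy, alpha, equivalent,
    )


# ---------------------------------------------------------------------------
# replanning-objective extraction
# ---------------------------------------------------------------------------

def isodose_volume(dose: VolumeGrid, level_Gy: float) -> StructureMask:
    """Mask of voxels at or above a dose level (may be empty)."""
    if level_Gy <= 0:
        raise ValueError("isodose level must be positive")
    return StructureMask(
        f"isodose_{level_Gy:g}Gy",
        (np.asarray(dose.values) >= level_Gy).astype(np.uint8),
        dose.spacing_mm,
        dose.origin_mm,
    )


@dataclass(frozen=True)
class ReplanObjective:
    """One optimization objective extracted from a predicted dose."""

    kind: str  # "max_dose" | "max_dvh" | "dose_falloff_structure"
    structure: str
    dose_Gy: float
    volume_fraction: float | None = None  # only for max_dvh

    def __post_init__(self) -> None:
        if self.kind not in ("max_dose", "max_dvh", "dose_falloff_structure"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose_Gy <= 0:
            raise ValueError("objective dose level must be positive")


@dataclass(frozen=True)
class FlagThresholds:
    """Sparing thresholds (Gy) that flag a plan as improvable.

    A plan is flagged when the prediction spares some OAR by at least
    ``theta_mean`` in mean dose or ``theta_max`` in max dose.  ``push``
    scales extracted objective levels slightly below the predicted values.
    """

    theta_mean_Gy: float = 2.0
    theta_max_Gy: float = 3.0
    push: float = 1.0
    falloff_levels_Gy: tuple[float, ...] = (40.0, 20.0)
    max_dvh_volume_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.push <= 1):
            raise ValueError("push factor must lie in (0, 1]")


def flag_and_extract_objectives(
    comparison: PlanComparison,
    pred_dose: VolumeGrid,
    body: StructureMask,
    thresholds: FlagThresholds = FlagThresholds(),
) -> tuple[bool, list[ReplanObjective]]:
    """Flag a plan whose prediction indicates achievable OAR sparing, and
    extract the replanning objectives that would push the plan toward it.

    For every flagged OAR a max-dose and a max-DVH point objective are set at
    the predicted values (scaled by the push factor).  Dose-falloff planning
    structures are derived by subtracting the predicted isodose volumes from
    the body contour, each with a max-dose objective at its level.
    """
    flagged_oars = sorted(
        set(
            [n for n, v in comparison.oar_delta_mean_Gy.items() if v <= -thresholds.theta_mean_Gy]
            + [n for n, v in comparison.oar_delta_max_Gy.items() if v <= -thresholds.theta_max_Gy]
        )
    )
    flag = bool(flagged_oars)
    objectives: list[ReplanObjective] = []
    for name in flagged_oars:
        pm = comparison.pred_metrics[name]
        objectives.append(ReplanObjective("max_dose", name, pm.Dmax_Gy * thresholds.push))
        objectives.append(
            ReplanObjective(
                "max_dvh",
                name,
                pm.D5_Gy * thresholds.push,
                volume_fraction=thresholds.max_dvh_volume_fraction,
            )
        )
    if flag:
        for level in thresholds.falloff_levels_Gy:
            iso = isodose_volume(pred_dose, level)
            descriptor = f"body_minus_isodose_{level:g}Gy"
            objectives.append(ReplanObjective("dose_falloff_structure", descriptor, level))
    return flag, objectives


def falloff_structure(pred_dose: VolumeGrid, body: StructureMask, level_Gy: float) -> StructureMask:
    """Planning structure: body minus the predicted isodose volume at a level."""
    body.require_same_geometry(pred_dose)
    iso = isodose_volume(pred_dose, level_Gy)
    vals = (body.boolean() & ~iso.boolean()).astype(np.uint8)
    return StructureMask(f"body_minus_isodose_{level_Gy:g}Gy", vals, body.spacing_mm, body.origin_mm)
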