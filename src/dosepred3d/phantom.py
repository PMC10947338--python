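"""Synthetic female-pelvis phantom cohorts with analytic VMAT-like dose.

Each phantom is an ellipsoidal anatomy on a regular grid (default 3 mm
isotropic): a body, a central PTV prescribed to 45 Gy in 25 fractions, and
the thirteen normal-tissue structures the model expects (bladder, bowel bag,
rectum, femoral heads, kidneys, liver, spinal cord, L4, L5, pelvic bone,
sacrum).  Per-plan anatomical variation comes from seeded Gaussian jitter of
organ centers and radii, so a cohort has learnable but non-trivial structure.

The reference dose is an analytic stand-in for a clinical VMAT dose:
homogeneous inside the PTV with a small seeded hotspot (bounded by the
hotspot fraction ``h``), and outside the PTV an exponential falloff

    D(x) = Rx * exp(-d(x) / tau) * s(x)

where ``d`` is the Euclidean distance (mm) to the PTV surface, ``tau`` the
falloff length, and ``s(x)`` in (0, 1] a direction-dependent sparing factor
taken from the nearest configured organ at risk (1 where no organ applies).
Dose is zero outside the body.  The closed form makes point values and DVH
statistics exactly checkable.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import StructureMask, VolumeGrid
from .pipeline import (
    CHANNEL_ORDER,
    PlanSample,
    STRUCTURE_NAMES,
    assemble_inputs,
    normalize_ct,
)

__all__ = [
    "OrganSpec",
    "PhantomConfig",
    "PhantomGeometryError",
    "CohortSplit",
    "scaled_config",
    "split_sizes",
    "falloff_dose",
    "analytic_dose",
    "generate_phantom",
    "split_cohort",
    "make_cohort",
    "cohort_content_hash",
]

SOFT_TISSUE_HU = 40.0
AIR_HU = -1000.0


class PhantomGeometryError(ValueError):
    """Raised when the configured anatomy cannot be realized on the grid."""


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ: center offset from body center and radii, in mm.

    ``inner_radii_mm`` carves out a concentric cavity (used for the pelvic
    bone ring).  ``sparing`` < 1 marks an organ at risk the dose model spares
    in its direction; ``hu`` paints the CT.
    """

    name: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    hu: float = SOFT_TISSUE_HU
    sparing: float = 1.0
    inner_radii_mm: tuple[float, float, float] | None = None


def _default_organs() -> tuple[OrganSpec, ...]:
    # Axis convention: 0 = left/right, 1 = anterior(-)/posterior(+), 2 = inferior(-)/superior(+).
    return (
        OrganSpec("bladder", (0.0, -42.0, -18.0), (18.0, 14.0, 13.0), hu=10.0, sparing=0.85),
        OrganSpec("bowel_bag", (0.0, -16.0, 40.0), (44.0, 28.0, 30.0), hu=-40.0, sparing=0.90),
        OrganSpec("rectum", (0.0, 40.0, -14.0), (9.0, 8.0, 22.0), hu=20.0, sparing=0.75),
        OrganSpec("femoral_head_l", (-54.0, -6.0, -24.0), (13.0, 13.0, 13.0), hu=600.0, sparing=0.70),
        OrganSpec("femoral_head_r", (54.0, -6.0, -24.0), (13.0, 13.0, 13.0), hu=600.0, sparing=0.70),
        OrganSpec("kidney_l", (-36.0, 12.0, 62.0), (10.0, 8.0, 14.0), hu=35.0, sparing=0.60),
        OrganSpec("kidney_r", (36.0, 12.0, 62.0), (10.0, 8.0, 14.0), hu=35.0, sparing=0.60),
        OrganSpec("liver", (44.0, -4.0, 66.0), (28.0, 20.0, 18.0), hu=55.0, sparing=0.80),
        OrganSpec("spinal_cord", (0.0, 46.0, 42.0), (4.0, 4.0, 48.0), hu=35.0, sparing=0.50),
        OrganSpec("l4", (0.0, 32.0, 76.0), (14.0, 11.0, 11.0), hu=700.0),
        OrganSpec("l5", (0.0, 34.0, 52.0), (14.0, 11.0, 11.0), hu=700.0),
        OrganSpec(
            "pelvic_bone",
            (0.0, 4.0, -16.0),
            (62.0, 48.0, 30.0),
            hu=700.0,
            inner_radii_mm=(50.0, 38.0, 24.0),
        ),
        OrganSpec("sacrum", (0.0, 44.0, 12.0), (20.0, 13.0, 24.0), hu=700.0),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, dose-model and jitter parameters for one phantom cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    prescription_Gy: float = 45.0
    n_fractions: int = 25
    body_radii_mm: tuple[float, float, float] = (88.0, 80.0, 92.0)
    ptv_center_mm: tuple[float, float, float] = (0.0, 4.0, 0.0)
    ptv_radii_mm: tuple[float, float, float] = (22.0, 20.0, 26.0)
    organs: tuple[OrganSpec, ...] = field(default_factory=_default_organs)
    # dose model
    falloff_tau_mm: float = 15.0
    hotspot_fraction: float = 0.05
    sparing_influence_mm: float = 25.0
    # per-plan jitter
    center_jitter_mm: float = 3.0
    radius_jitter_frac: float = 0.05
    ct_noise_hu: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in np.atleast_1d(self.spacing_mm)):
            raise ValueError("spacing must be positive")
        if not (0.0 <= self.hotspot_fraction <= 0.10):
            raise ValueError("hotspot fraction must be in [0, 0.10]")
        if self.falloff_tau_mm <= 0:
            raise ValueError("falloff length must be positive")
        if not all(p < b for p, b in zip(self.ptv_radii_mm, self.body_radii_mm)):
            raise PhantomGeometryError("PTV radii must be smaller than body radii")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _coordinate_grids(config: PhantomConfig) -> list[np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(config.grid_shape, config.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center_mm, radii_mm) -> np.ndarray:
    q = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center_mm, radii_mm))
    return q <= 1.0


def _jitter_organ(
    spec: OrganSpec, rng: np.random.Generator, config: PhantomConfig
) -> OrganSpec:
    dc = rng.normal(0.0, config.center_jitter_mm, 3)
    dr = np.clip(rng.normal(1.0, config.radius_jitter_frac, 3), 0.85, 1.15)
    new = replace(
        spec,
        center_mm=tuple(np.asarray(spec.center_mm) + dc),
        radii_mm=tuple(np.asarray(spec.radii_mm) * dr),
    )
    if spec.inner_radii_mm is not None:
        new = replace(new, inner_radii_mm=tuple(np.asarray(spec.inner_radii_mm) * dr))
    return new


# ---------------------------------------------------------------------------
# dose model
# ---------------------------------------------------------------------------

def falloff_dose(distance_mm, sparing, config: PhantomConfig) -> np.ndarray:
    """Closed-form out-of-field dose: ``Rx * exp(-d / tau) * s``."""
    d = np.asarray(distance_mm, dtype=float)
    return config.prescription_Gy * np.exp(-d / config.falloff_tau_mm) * np.asarray(sparing)


def analytic_dose(
    ptv_mask: StructureMask,
    organ_masks: list[StructureMask],
    config: PhantomConfig,
    body_mask: StructureMask | None = None,
    plan_seed: int = 0,
) -> VolumeGrid:
    """Analytic VMAT-like dose for one phantom.

    Inside the PTV: ``Rx * (1 + h * g(x))`` with ``g`` a seeded Gaussian bump
    in (0, 1], so dose lies in [Rx, (1+h) Rx].  Outside: exponential falloff
    with the sparing factor of the nearest spared organ applied within its
    influence radius.  Zero outside the body.
    """
    ptv = ptv_mask.boolean()
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    rx = config.prescription_Gy
    spacing = ptv_mask.spacing_mm

    d_out = ndimage.distance_transform_edt(~ptv, sampling=spacing)
    sparing = np.ones(ptv.shape)
    spared = [(m, s) for m, s in organ_masks_with_sparing(organ_masks, config) if s < 1.0]
    if spared:
        dists = np.stack(
            [ndimage.distance_transform_edt(~m.boolean(), sampling=spacing) for m, _ in spared]
        )
        nearest = np.argmin(dists, axis=0)
        min_d = np.take_along_axis(dists, nearest[None], axis=0)[0]
        factors = np.asarray([s for _, s in spared])
        within = min_d <= config.sparing_influence_mm
        sparing[within] = factors[nearest[within]]

    dose = rx * np.exp(-d_out / config.falloff_tau_mm) * sparing

    # seeded in-target hotspot, bounded by the hotspot fraction
    rng = np.random.default_rng(plan_seed)
    idx = np.argwhere(ptv)
    center = idx[rng.integers(len(idx))] * np.asarray(spacing)
    coords = np.meshgrid(*[np.arange(n) * s for n, s in zip(ptv.shape, spacing)], indexing="ij")
    r2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
    sigma = 0.4 * float(np.mean(config.ptv_radii_mm))
    bump = np.exp(-r2 / (2.0 * sigma**2))
    dose[ptv] = rx * (1.0 + config.hotspot_fraction * bump[ptv])

    if body_mask is not None:
        dose[~body_mask.boolean()] = 0.0
    return VolumeGrid(
        np.maximum(dose, 0.0).astype(np.float32), ptv_mask.spacing_mm, ptv_mask.origin_mm
    )


def organ_masks_with_sparing(
    organ_masks: list[StructureMask], config: PhantomConfig
) -> list[tuple[StructureMask, float]]:
    by_name = {o.name: o.sparing for o in config.organs}
    return [(m, by_name.get(m.name, 1.0)) for m in organ_masks]


# ---------------------------------------------------------------------------
# phantom synthesis
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig, plan_seed: int, plan_id: str | None = None) -> PlanSample:
    """Generate one seeded phantom plan (16 input channels + reference dose)."""
    if any(n < 32 for n in config.grid_shape):
        raise ValueError("grid must be at least 32 voxels per axis")
    half_extent = config.extent_mm / 2.0
    if np.any(np.asarray(config.body_radii_mm) > half_extent + 1e-9):
        raise PhantomGeometryError("body ellipsoid does not fit inside the grid extent")

    rng = np.random.default_rng(plan_seed)
    coords = _coordinate_grids(config)
    center = half_extent

    body_r = np.asarray(config.body_radii_mm) * np.clip(
        rng.normal(1.0, config.radius_jitter_frac / 2.0, 3), 0.92, 1.08
    )
    body_r = np.minimum(body_r, half_extent)
    body = _ellipsoid(coords, center, body_r)

    ptv_spec = OrganSpec("ptv", config.ptv_center_mm, config.ptv_radii_mm)
    ptv_spec = _jitter_organ(ptv_spec, rng, config)
    if not all(p < b for p, b in zip(ptv_spec.radii_mm, body_r)):
        raise PhantomGeometryError("jittered PTV radii exceed body radii")
    ptv = _ellipsoid(coords, center + np.asarray(ptv_spec.center_mm), ptv_spec.radii_mm) & body
    if not ptv.any():
        raise PhantomGeometryError("PTV is empty on this grid")

    spacing = tuple(float(s) for s in np.broadcast_to(config.spacing_mm, (3,)))
    masks: dict[str, StructureMask] = {
        "body": StructureMask("body", body.astype(np.uint8), spacing)
    }
    ct_hu = np.full(config.grid_shape, AIR_HU)
    ct_hu[body] = SOFT_TISSUE_HU

    for spec in config.organs:
        jit = _jitter_organ(spec, rng, config)
        c = center + np.asarray(jit.center_mm)
        if np.any(np.abs(np.asarray(jit.center_mm)) >= body_r):
            raise PhantomGeometryError(f"organ {spec.name!r} center lies outside the body")
        m = _ellipsoid(coords, c, jit.radii_mm)
        if jit.inner_radii_mm is not None:
            m &= ~_ellipsoid(coords, c, jit.inner_radii_mm)
        m &= body  # anatomy nesting: every organ is a subset of the body
        if not m.any():
            raise PhantomGeometryError(f"organ {spec.name!r} fell outside the body")
        masks[spec.name] = StructureMask(spec.name, m.astype(np.uint8), spacing)
        ct_hu[m] = spec.hu

    ct_hu += rng.normal(0.0, config.ct_noise_hu, config.grid_shape)
    ct_hu[~body] = AIR_HU
    ct = normalize_ct(VolumeGrid(ct_hu, spacing))

    ptv_mask = StructureMask("ptv", ptv.astype(np.uint8), spacing)
    organ_masks = [masks[n] for n in STRUCTURE_NAMES if n not in ("body",) and n in masks]
    dose = analytic_dose(ptv_mask, organ_masks, config, body_mask=masks["body"], plan_seed=plan_seed)

    return assemble_inputs(
        ct=ct,
        ptv=ptv_mask,
        masks=masks,
        prescription_Gy=config.prescription_Gy,
        dose=dose,
        plan_id=plan_id or f"phantom_{plan_seed}",
    )


def scaled_config(
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    spacing_mm: float | tuple[float, float, float] = 3.0,
    **overrides,
) -> PhantomConfig:
    """A :class:`PhantomConfig` with the anatomy scaled to fit a smaller grid.

    All mm geometry (body, PTV, organ centers and radii) is shrunk by one
    isotropic factor so the default layout fits the requested extent; dose
    model parameters (falloff length, hotspot fraction, sparing) are physical
    properties and are left unchanged.
    """
    base = PhantomConfig(**{k: v for k, v in overrides.items() if k in PhantomConfig.__dataclass_fields__})
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    half_extent = (np.asarray(grid_shape) - 1) * spacing / 2.0
    factor = min(1.0, float(np.min(0.98 * half_extent / np.asarray(base.body_radii_mm))))

    def _s(v):
        return tuple(float(x) * factor for x in v)

    organs = tuple(
        replace(
            o,
            center_mm=_s(o.center_mm),
            radii_mm=_s(o.radii_mm),
            inner_radii_mm=_s(o.inner_radii_mm) if o.inner_radii_mm is not None else None,
        )
        for o in base.organs
    )
    return replace(
        base,
        grid_shape=tuple(int(n) for n in grid_shape),
        spacing_mm=tuple(float(s) for s in spacing),
        body_radii_mm=_s(base.body_radii_mm),
        ptv_center_mm=_s(base.ptv_center_mm),
        ptv_radii_mm=_s(base.ptv_radii_mm),
        organs=organs,
        center_jitter_mm=base.center_jitter_mm * factor,
    )


# ---------------------------------------------------------------------------
# cohort assembly and 3:1:1 split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSplit:
    """Disjoint train/validation/test plan identifiers (3:1:1)."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.validation_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split partitions must be disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.validation_ids), len(self.test_ids))


def split_sizes(n_plans: int, ratios=(3, 1, 1)) -> tuple[int, ...]:
    """Largest-remainder allocation of ``n_plans`` across the 3:1:1 quotas."""
    total = sum(ratios)
    quotas = [n_plans * r / total for r in ratios]
    sizes = [math.floor(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for i in sorted(range(len(ratios)), key=lambda i: (-remainders[i], i))[: n_plans - sum(sizes)]:
        sizes[i] += 1
    return tuple(sizes)


def split_cohort(plan_ids: list[str], seed: int) -> CohortSplit:
    """Random 3:1:1 split with largest-remainder partition sizes."""
    n = len(plan_ids)
    if n < 5:
        raise ValueError("need at least 5 plans so each partition is non-empty")
    n_train, n_val, n_test = split_sizes(n)
    rng = np.random.default_rng(seed)
    order = [plan_ids[i] for i in rng.permutation(n)]
    return CohortSplit(
        train_ids=tuple(order[:n_train]),
        validation_ids=tuple(order[n_train : n_train + n_val]),
        test_ids=tuple(order[n_train + n_val :]),
    )


def _plan_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    config: PhantomConfig, n_plans: int, seed: int
) -> tuple[list[PlanSample], CohortSplit]:
    """Generate ``n_plans`` seeded phantoms and their random 3:1:1 split."""
    if n_plans < 5:
        raise ValueError("need at least 5 plans so each partition is non-empty")
    samples = [
        generate_phantom(config, _plan_seed(seed, i), plan_id=f"plan_{i:03d}")
        for i in range(n_plans)
    ]
    split = split_cohort([s.plan_id for s in samples], seed=seed)
    return samples, split


def cohort_content_hash(samples: list[PlanSample]) -> str:
    """Deterministic content hash of a cohort (for reproducibility checks)."""
    h = hashlib.sha256()
    for s in samples:
        h.update(s.plan_id.encode())
        h.update(np.asarray(s.input_stack(), dtype=np.float32).tobytes())
        h.update(np.asarray(s.reference_dose.values, dtype=np.float32).tobytes())
    return h.hexdigest()
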