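"""Preprocessing: raw volumes and masks to the 16-channel model input stack.

The model consumes one fixed-order stack of 16 channels per plan:

======  ======================  =========================================
index   channel                 contents
======  ======================  =========================================
0       ct                      CT normalized to [0, 1]
1       target                  prescription dose (Gy) on PTV voxels, 0 off
2..15   structure masks         body, bladder, bowel_bag, rectum,
                                femoral_head_l, femoral_head_r, kidney_l,
                                kidney_r, liver, spinal_cord, l4, l5,
                                pelvic_bone, sacrum (binary)
======  ======================  =========================================

CT normalization clips Hounsfield units to [-1000, 1000] and rescales to
[0, 1].  The target channel carries the physical prescription in Gy.  All
channels must share one grid geometry (resample first if they do not).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import GeometryError, StructureMask, VolumeGrid, read_nifti_mask, read_nifti_volume

logger = logging.getLogger(__name__)

#: Structure vocabulary (channel 2 onward), in channel order.
STRUCTURE_NAMES: tuple[str, ...] = (
    "body",
    "bladder",
    "bowel_bag",
    "rectum",
    "femoral_head_l",
    "femoral_head_r",
    "kidney_l",
    "kidney_r",
    "liver",
    "spinal_cord",
    "l4",
    "l5",
    "pelvic_bone",
    "sacrum",
)

#: Full 16-channel order.
CHANNEL_ORDER: tuple[str, ...] = ("ct", "target") + STRUCTURE_NAMES

HU_WINDOW = (-1000.0, 1000.0)


class StructureNameError(ValueError):
    """Raised for a structure name outside the fixed vocabulary."""


@dataclass
class PlanSample:
    """One plan: the 16-channel input stack plus the reference dose grid."""

    plan_id: str
    prescription_Gy: float
    channels: list[VolumeGrid]
    reference_dose: VolumeGrid
    ptv_mask: StructureMask
    body_mask: StructureMask

    def __post_init__(self) -> None:
        if len(self.channels) != len(CHANNEL_ORDER):
            raise ValueError(
                f"expected {len(CHANNEL_ORDER)} channels, got {len(self.channels)}"
            )
        ref = self.channels[0]
        for ch in self.channels[1:]:
            ref.require_same_geometry(ch)
        ref.require_same_geometry(self.reference_dose)
        ref.require_same_geometry(self.ptv_mask)
        ref.require_same_geometry(self.body_mask)
        ct = self.channels[0].values
        if ct.min() < -1e-6 or ct.max() > 1 + 1e-6:
            raise ValueError("CT channel must be normalized to [0, 1]")
        tgt = np.unique(self.channels[1].values)
        if not np.all(np.isin(tgt, (0.0, self.prescription_Gy))):
            raise ValueError("target channel must be {0, prescription} valued")
        if self.ptv_mask.voxel_count == 0:
            raise ValueError("PTV mask is empty")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    def input_stack(self, dtype=np.float32) -> np.ndarray:
        """Stack the 16 channels into a (16, Z, Y, X) array."""
        return np.stack([np.asarray(c.values, dtype=dtype) for c in self.channels])

    # --- disk round trip --------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / self.plan_id
        out.mkdir(parents=True, exist_ok=True)
        for name, ch in zip(CHANNEL_ORDER, self.channels):
            ch.save(out / f"{name}.nii.gz")
        self.reference_dose.save(out / "dose.nii.gz")
        self.ptv_mask.save(out / "ptv.nii.gz")
        manifest = {
            "plan_id": self.plan_id,
            "prescription_Gy": self.prescription_Gy,
            "channel_order": list(CHANNEL_ORDER),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out

    @classmethod
    def load(cls, plan_dir: str | Path) -> "PlanSample":
        plan_dir = Path(plan_dir)
        manifest = json.loads((plan_dir / "manifest.json").read_text())
        channels = [read_nifti_volume(plan_dir / f"{n}.nii.gz") for n in manifest["channel_order"]]
        dose = read_nifti_volume(plan_dir / "dose.nii.gz")
        ptv = read_nifti_mask(plan_dir / "ptv.nii.gz", "ptv")
        body_idx = CHANNEL_ORDER.index("body")
        body = StructureMask(
            "body",
            (channels[body_idx].values > 0.5).astype(np.uint8),
            channels[body_idx].spacing_mm,
            channels[body_idx].origin_mm,
        )
        return cls(
            plan_id=manifest["plan_id"],
            prescription_Gy=float(manifest["prescription_Gy"]),
            channels=channels,
            reference_dose=dose,
            ptv_mask=ptv,
            body_mask=body,
        )

    def structure_mask(self, name: str) -> StructureMask:
        """Recover a named structure mask from its input channel."""
        if name not in STRUCTURE_NAMES:
            raise StructureNameError(f"unknown structure {name!r}")
        ch = self.channels[CHANNEL_ORDER.index(name)]
        return StructureMask(name, (ch.values > 0.5).astype(np.uint8), ch.spacing_mm, ch.origin_mm)


def normalize_ct(ct: VolumeGrid) -> VolumeGrid:
    """Clip HU to [-1000, 1000] and rescale linearly to [0, 1]."""
    vals = np.asarray(ct.values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("CT contains non-finite values")
    lo, hi = HU_WINDOW
    out = (np.clip(vals, lo, hi) - lo) / (hi - lo)
    return ct.with_values(out.astype(np.float32))


def build_target_channel(ptv: StructureMask, prescription_Gy: float) -> VolumeGrid:
    """Target array: prescription dose on PTV voxels, zero elsewhere."""
    if prescription_Gy <= 0:
        raise ValueError("prescription must be positive")
    if ptv.voxel_count == 0:
        raise ValueError("PTV mask is empty")
    vals = ptv.values.astype(np.float32) * np.float32(prescription_Gy)
    return VolumeGrid(vals, ptv.spacing_mm, ptv.origin_mm)


def resample_volume(
    vol: VolumeGrid | StructureMask,
    target_spacing_mm,
    mode: str = "continuous",
):
    """Resample to a new spacing, preserving physical extent within one voxel.

    ``continuous`` uses trilinear interpolation; ``label`` uses nearest
    neighbour and preserves binarity.  Voxel centres follow the node-centered
    convention ``origin + index * spacing``; the origin is unchanged.
    """
    if mode not in ("continuous", "label"):
        raise ValueError(f"mode must be 'continuous' or 'label', got {mode!r}")
    new_spacing = np.broadcast_to(np.asarray(target_spacing_mm, dtype=float), (3,))
    if np.any(new_spacing <= 0):
        raise ValueError("target spacing must be positive")
    old_spacing = np.asarray(vol.spacing_mm)
    shape = np.asarray(vol.shape)
    extent = (shape - 1) * old_spacing
    new_shape = np.maximum(np.floor(extent / new_spacing + 1e-9).astype(int) + 1, 1)
    axes = [np.arange(n) * s / o for n, s, o in zip(new_shape, new_spacing, old_spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 1 if mode == "continuous" else 0
    vals = np.asarray(vol.values, dtype=np.float32)
    out = ndimage.map_coordinates(vals, coords, order=order, mode="nearest")
    spacing = tuple(float(s) for s in new_spacing)
    if isinstance(vol, StructureMask):
        return StructureMask(vol.name, np.rint(out).astype(np.uint8), spacing, vol.origin_mm)
    return VolumeGrid(out, spacing, vol.origin_mm)


def assemble_inputs(
    ct: VolumeGrid,
    ptv: StructureMask,
    masks: dict[str, StructureMask],
    prescription_Gy: float,
    dose: VolumeGrid,
    plan_id: str = "plan",
) -> PlanSample:
    """Build a :class:`PlanSample` from normalized CT, PTV, structures and dose.

    All inputs must already share one geometry.  A structure missing from
    ``masks`` is supplied as an all-zero mask and logged as a warning; a name
    outside the fixed vocabulary is an error.
    """
    for name in masks:
        if name not in STRUCTURE_NAMES:
            raise StructureNameError(f"unknown structure {name!r}")
    for m in masks.values():
        ct.require_same_geometry(m)
    ct.require_same_geometry(ptv)
    ct.require_same_geometry(dose)

    target = build_target_channel(ptv, prescription_Gy)
    channels: list[VolumeGrid] = [ct, target]
    for name in STRUCTURE_NAMES:
        if name in masks:
            channels.append(masks[name].as_grid())
        else:
            logger.warning("plan %s: structure %r missing, using zero mask", plan_id, name)
            zero = StructureMask(name, np.zeros(ct.shape, dtype=np.uint8), ct.spacing_mm, ct.origin_mm)
            channels.append(zero.as_grid())

    body = masks.get("body")
    if body is None:
        body = StructureMask("body", np.zeros(ct.shape, dtype=np.uint8), ct.spacing_mm, ct.origin_mm)
    return PlanSample(
        plan_id=plan_id,
        prescription_Gy=float(prescription_Gy),
        channels=channels,
        reference_dose=dose,
        ptv_mask=ptv,
        body_mask=body,
    )
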