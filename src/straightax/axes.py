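"""Anatomical coordinate fields, cardinal planes and limb axes.

In straight space the anatomical axes are Cartesian: the world z
coordinate is the A-P position, y the (signed) D-V position and x the
(signed) L-R position.  Pulling those coordinates back through the
fitted transform defines the anatomical axes at every voxel of the
original curved model, which is the whole point of straightening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdt import CdtTransform, _interp_field
from .distance import constrained_distance_map
from .fields import AxisFields
from .volumes import Volume

__all__ = [
    "AxisFields",
    "PlaneSpec",
    "PlaneExtraction",
    "straight_axis_fields",
    "curved_axis_fields",
    "normalized_ap",
    "axis_colourmap",
    "extract_cardinal_plane",
    "limb_pd_field",
    "symmetry_check",
]

_PLANE_AXES = {"transverse": 2, "sagittal": 0, "coronal": 1}  # fixed world axis


@dataclass(frozen=True)
class PlaneSpec:
    """A cardinal plane of straight space.

    transverse: x-y plane at z = level; sagittal: y-z at x = level;
    coronal: z-x at y = level.
    """

    kind: str
    level: float

    def __post_init__(self) -> None:
        if self.kind not in _PLANE_AXES:
            raise ValueError(
                f"unknown plane kind {self.kind!r}; valid: {sorted(_PLANE_AXES)}"
            )

    @property
    def fixed_axis(self) -> int:
        return _PLANE_AXES[self.kind]


@dataclass
class PlaneExtraction:
    """A straight-space plane resampled through the inverse transform."""

    spec: PlaneSpec
    image: np.ndarray        # 2D, NaN where off-mask
    points: np.ndarray       # (h, w, 3) curved-space sample positions
    in_mask: np.ndarray      # (h, w) bool

    @property
    def empty(self) -> bool:
        return not self.in_mask.any()

    def points_dataframe(self) -> pd.DataFrame:
        h, w = self.in_mask.shape
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        sel = self.in_mask
        return pd.DataFrame(
            {
                "row": ii[sel],
                "col": jj[sel],
                "x": self.points[sel][:, 0],
                "y": self.points[sel][:, 1],
                "z": self.points[sel][:, 2],
                "value": self.image[sel],
            }
        )


def straight_axis_fields(straight_mask: Volume) -> AxisFields:
    """Axis fields on the straight model: literally the world coordinates."""
    m = straight_mask.data.astype(bool)
    if not m.any():
        raise ValueError("straight mask is empty")
    idx = np.indices(straight_mask.shape, dtype=float)
    world = [
        straight_mask.origin[a] + idx[a] * straight_mask.spacing[a] for a in range(3)
    ]
    nan = np.where(m, 1.0, np.nan)
    return AxisFields(
        ap=straight_mask.with_data(world[2] * nan),
        dv=straight_mask.with_data(world[1] * nan),
        lr=straight_mask.with_data(world[0] * nan),
        mask=straight_mask,
    )


def curved_axis_fields(t: CdtTransform) -> AxisFields:
    """Anatomical coordinates on the curved model: each in-mask voxel's
    forward-mapped straight-space (z, y, x)."""
    mask = t.source_mask
    m = mask.data.astype(bool)
    idx = np.indices(mask.shape, dtype=float)
    world = np.stack(
        [mask.origin[a] + idx[a] * mask.spacing[a] for a in range(3)], axis=-1
    )
    mapped = world + t.forward_field
    nan = np.where(m, 1.0, np.nan)
    return AxisFields(
        ap=mask.with_data(mapped[..., 2] * nan),
        dv=mask.with_data(mapped[..., 1] * nan),
        lr=mask.with_data(mapped[..., 0] * nan),
        mask=mask,
    )


def normalized_ap(fields: AxisFields) -> Volume:
    """A-P coordinate rescaled to [0, 1] over the mask, for cross-specimen
    comparison (the raw field is in world units and is the default)."""
    m = fields.mask.data.astype(bool)
    ap = fields.ap.data
    lo, hi = np.nanmin(ap[m]), np.nanmax(ap[m])
    if hi == lo:
        return fields.ap.with_data(np.where(m, 0.5, np.nan))
    return fields.ap.with_data((ap - lo) / (hi - lo))


def axis_colourmap(f: Volume, mask: Volume, reverse: bool = False) -> np.ndarray:
    """Linear red-to-blue ramp over the in-mask value range.

    Returns an RGB uint8 array of shape ``mask.shape + (3,)``; out-of-mask
    voxels are black (0, 0, 0).  ``reverse`` flips the ramp direction
    (e.g. to show V-D instead of D-V).
    """
    m = mask.data.astype(bool)
    vals = f.data[m]
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if hi == lo:
        warnings.warn("constant coordinate field; colourmap is all mid-ramp", stacklevel=2)
        tt = np.full(mask.shape, 0.5)
    else:
        tt = np.clip((f.data - lo) / (hi - lo), 0.0, 1.0)
    if reverse:
        tt = 1.0 - tt
    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.where(m, np.round((1.0 - tt) * 255), 0)
    rgb[..., 2] = np.where(m, np.round(tt * 255), 0)
    return rgb


def extract_cardinal_plane(
    t: CdtTransform, spec: PlaneSpec, v: Volume
) -> PlaneExtraction:
    """Resample a curved-space volume on a straight-space cardinal plane.

    The plane is rasterised on the straight grid's spacing, every sample
    inside the straight mask is inverse-mapped into curved space, and
    ``v`` is read there with trilinear interpolation.
    """
    tgt = t.target_mask
    ax = spec.fixed_axis
    free = [a for a in range(3) if a != ax]
    m = tgt.data.astype(bool)

    n0, n1 = tgt.shape[free[0]], tgt.shape[free[1]]
    c0 = tgt.origin[free[0]] + np.arange(n0) * tgt.spacing[free[0]]
    c1 = tgt.origin[free[1]] + np.arange(n1) * tgt.spacing[free[1]]
    A, B = np.meshgrid(c0, c1, indexing="ij")
    pts = np.empty((n0, n1, 3))
    pts[..., free[0]] = A
    pts[..., free[1]] = B
    pts[..., ax] = spec.level

    idx = tgt.world_to_nearest_index(pts.reshape(-1, 3))
    inside = m[tuple(idx.T)].reshape(n0, n1)
    # the level must actually cut the mask
    lev_idx = int(round((spec.level - tgt.origin[ax]) / tgt.spacing[ax]))
    if lev_idx < 0 or lev_idx >= tgt.shape[ax] or not inside.any():
        warnings.warn(
            f"{spec.kind} plane at level {spec.level} misses the straight mask",
            stacklevel=2,
        )
        return PlaneExtraction(spec, np.full((n0, n1), np.nan), pts, np.zeros((n0, n1), bool))

    flat = pts.reshape(-1, 3)
    mapped = flat + _interp_field(t.inverse_field, tgt, flat)
    from scipy import ndimage

    coords = v.world_to_index(mapped).T
    vals = ndimage.map_coordinates(
        v.data.astype(float), coords, order=1, mode="constant", cval=np.nan
    ).reshape(n0, n1)
    image = np.where(inside, vals, np.nan)
    return PlaneExtraction(spec, image, mapped.reshape(n0, n1, 3), inside)


def limb_pd_field(limb_mask: Volume, base_point: np.ndarray) -> Volume:
    """Proximo-distal coordinate inside an appendage: constrained distance
    from the attachment (proximal = 0, distal = far)."""
    return constrained_distance_map(limb_mask, np.atleast_2d(base_point))


def symmetry_check(
    fields: AxisFields,
    paired_points: list[tuple[np.ndarray, np.ndarray]],
    tolerance: float = 1.0,
) -> pd.DataFrame:
    """Check that left/right paired points mirror correctly.

    For each (left, right) pair reports |ap_L - ap_R|, |dv_L - dv_R| and
    |lr_L + lr_R| (the L-R field should be antisymmetric under the
    mirror), flagging pairs exceeding ``tolerance`` (world units).
    """
    rows = []
    for i, (pl, pr) in enumerate(paired_points):
        ap_l, ap_r = fields.sample_nearest("ap", pl)[0], fields.sample_nearest("ap", pr)[0]
        dv_l, dv_r = fields.sample_nearest("dv", pl)[0], fields.sample_nearest("dv", pr)[0]
        lr_l, lr_r = fields.sample_nearest("lr", pl)[0], fields.sample_nearest("lr", pr)[0]
        d_ap = abs(ap_l - ap_r)
        d_dv = abs(dv_l - dv_r)
        d_lr = abs(lr_l + lr_r)
        rows.append(
            {
                "pair": i,
                "d_ap": d_ap,
                "d_dv": d_dv,
                "d_lr_mirror": d_lr,
                "ok": bool(max(d_ap, d_dv, d_lr) <= tolerance),
            }
        )
    return pd.DataFrame(rows)
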