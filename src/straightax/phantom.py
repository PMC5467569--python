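"""Synthetic curved-embryo phantoms with analytically known anatomy.

The phantom is a tube of varying radius swept along a planar circular
arc (the "body"), with cylindrical limb buds, a midline marker
expression ("Shh-like": the midline tube plus the posterior cap of each
limb bud, mimicking notochord/floor-plate expression and the zone of
polarizing activity), planted spherical expression domains, anatomical
region labels, and landmark pairs into the matching straight tube.

Because the midline is a circular arc, arc length, local frames and
nearest-point projection are closed-form, so every voxel's true
anatomical coordinates (A-P arc length, signed D-V, signed L-R) are
known exactly — the phantom is the ground-truth oracle against which
the straightening transform is judged.

Geometry: curved and straight models share one world frame.  The
straight midline is the segment x=y=0, z in [0, L]; the curved midline
is an arc of the same length L in the x=0 plane, bending toward -y so
that the dorsal surface faces -y (ventral positive, per the package
sign convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .fields import AxisFields
from .volumes import LandmarkSet, RegionMap, Volume

__all__ = [
    "PhantomConfig",
    "LimbSpec",
    "DomainSpec",
    "LimbInfo",
    "PhantomBundle",
    "make_phantom",
    "make_landmarks",
    "default_config",
]


@dataclass(frozen=True)
class LimbSpec:
    """A limb bud: capsule of given radius from the body surface outward."""

    name: str
    s: float               # attachment station along the midline, in [0, 1]
    side: str              # "left" or "right"
    length: float          # world units from base to tip
    radius: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"limb {self.name!r}: side must be 'left' or 'right'")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"limb {self.name!r}: s must be in [0, 1]")
        if self.length <= 0 or self.radius <= 0:
            raise ValueError(f"limb {self.name!r}: length and radius must be positive")


@dataclass(frozen=True)
class DomainSpec:
    """A planted spherical expression domain.

    Body placement: anatomical centre ``(s, d, l)`` — arc-length station,
    signed dorso-ventral offset (ventral positive) and signed left-right
    offset.  Limb placement: ``(limb, p, offset)`` — limb index, axial
    fraction of the limb length, and posterior offset along the body
    tangent at the attachment.  Several specs sharing a name merge into
    one domain.
    """

    name: str
    radius: float
    s: float | None = None
    d: float = 0.0
    l: float = 0.0
    limb: int | None = None
    p: float | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        if (self.s is None) == (self.limb is None):
            raise ValueError(f"domain {self.name!r}: give exactly one of s (body) or limb")
        if self.radius <= 0:
            raise ValueError(f"domain {self.name!r}: radius must be positive")
        if self.s is not None and not (0.0 <= self.s <= 1.0):
            raise ValueError(f"domain {self.name!r}: s must be in [0, 1]")


def _default_radius_profile(s):
    """Body radius tapering from head (10) to tail (6), world units."""
    return 10.0 - 4.0 * np.asarray(s)


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    curl_angle: float = math.pi
    body_radius_profile: Callable[[np.ndarray], np.ndarray] = _default_radius_profile
    midline_length: float | None = None   # default: 72% of the grid z extent
    limb_specs: tuple[LimbSpec, ...] = ()
    domain_specs: tuple[DomainSpec, ...] = ()
    n_landmarks: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.curl_angle <= 1.5 * math.pi):
            raise ValueError(f"curl_angle must be in [0, 3pi/2], got {self.curl_angle}")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape too small")


class ArcGeometry:
    """Closed-form planar-arc midline: points, frames, projection."""

    def __init__(self, curl: float, length: float):
        self.curl = float(curl)
        self.L = float(length)
        self.straightish = self.curl < 1e-9
        self.R = np.inf if self.straightish else self.L / self.curl

    # local frames -------------------------------------------------------
    def _alpha(self, s):
        return (np.asarray(s, dtype=float) - 0.5) * self.curl

    def midline(self, s) -> np.ndarray:
        """World points m(s) of the curved midline, shape (..., 3)."""
        s = np.asarray(s, dtype=float)
        if self.straightish:
            return np.stack([np.zeros_like(s), np.zeros_like(s), s * self.L], axis=-1)
        a = self._alpha(s)
        return np.stack(
            [np.zeros_like(s), -self.R * (1.0 - np.cos(a)), self.L / 2 + self.R * np.sin(a)],
            axis=-1,
        )

    def straight_midline(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.stack([np.zeros_like(s), np.zeros_like(s), s * self.L], axis=-1)

    def tangent(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.straightish:
            t = np.zeros(s.shape + (3,))
            t[..., 2] = 1.0
            return t
        a = self._alpha(s)
        return np.stack([np.zeros_like(a), -np.sin(a), np.cos(a)], axis=-1)

    def ventral(self, s) -> np.ndarray:
        """Unit ventral normal (away from the arc centre; +y at mid-arc)."""
        s = np.asarray(s, dtype=float)
        if self.straightish:
            v = np.zeros(s.shape + (3,))
            v[..., 1] = 1.0
            return v
        a = self._alpha(s)
        return np.stack([np.zeros_like(a), np.cos(a), np.sin(a)], axis=-1)

    def dorsal(self, s) -> np.ndarray:
        return -self.ventral(s)

    def left(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = np.zeros(s.shape + (3,))
        out[..., 0] = -1.0
        return out

    # projection ---------------------------------------------------------
    def project(self, pts: np.ndarray):
        """Project world points onto the midline segment.

        Returns ``(s, dv, lr, dist)``: clamped arc-length fraction, signed
        dorso-ventral offset (ventral positive), signed left-right offset
        (right positive) and Euclidean distance to the nearest midline
        point (used for the tube mask).
        """
        pts = np.asarray(pts, dtype=float)
        x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
        lr = x
        if self.straightish:
            s = np.clip(z / self.L, 0.0, 1.0)
            dv = y
            dist = np.sqrt(x**2 + y**2 + (z - s * self.L) ** 2)
            return s, dv, lr, dist
        uy = y + self.R
        uz = z - self.L / 2
        beta = np.arctan2(uz, uy)
        half = self.curl / 2
        bc = np.clip(beta, -half, half)
        s = bc / self.curl + 0.5
        cos_a, sin_a = np.cos(bc), np.sin(bc)
        # ventral = radial direction, tangent = increasing-s direction
        dv = uy * cos_a + uz * sin_a - self.R
        tangential = -uy * sin_a + uz * cos_a
        clamped = np.abs(beta) > half
        tang = np.where(clamped, tangential, 0.0)
        dist = np.sqrt(x**2 + dv**2 + tang**2)
        return s, dv, lr, dist


@dataclass
class LimbInfo:
    """Resolved geometry of one limb bud of a built phantom."""

    spec: LimbSpec
    curved_base: np.ndarray
    curved_tip: np.ndarray
    straight_base: np.ndarray
    straight_tip: np.ndarray
    direction: np.ndarray       # unit axis, identical in both spaces
    mask: Volume                # limb capsule, curved space
    truth_pd: Volume            # Euclidean distance to the base inside the capsule


@dataclass
class PhantomBundle:
    """A built phantom: curved specimen, straight target, ground truth."""

    config: PhantomConfig
    geometry: ArcGeometry
    curved_volume: Volume
    curved_mask: Volume
    straight_mask: Volume
    midline_points: np.ndarray
    truth_axis_fields: AxisFields
    regions: RegionMap
    expression: dict[str, Volume]
    midline_expression: Volume
    limbs: list[LimbInfo]
    landmarks: LandmarkSet


def _world_grid(cfg: PhantomConfig, L: float):
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing
    origin = (
        -(nx - 1) * sx / 2.0,
        -(ny - 1) * sy / 2.0,
        -((nz - 1) * sz - L) / 2.0,
    )
    xs = origin[0] + np.arange(nx) * sx
    ys = origin[1] + np.arange(ny) * sy
    zs = origin[2] + np.arange(nz) * sz
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return origin, np.stack([X, Y, Z], axis=-1)


def _capsule_mask(P: np.ndarray, base: np.ndarray, direction: np.ndarray,
                  length: float, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean capsule mask and axial coordinate along the limb."""
    rel = P - base
    axial = rel @ direction
    ax_cl = np.clip(axial, 0.0, length)
    closest = base + ax_cl[..., None] * direction
    rad = np.linalg.norm(P - closest, axis=-1)
    return rad <= radius, axial


def make_phantom(cfg: PhantomConfig) -> PhantomBundle:
    """Build a phantom bundle; deterministic given ``cfg`` (incl. seed)."""
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.spacing
    L = cfg.midline_length if cfg.midline_length is not None else 0.72 * (nz - 1) * sz
    geom = ArcGeometry(cfg.curl_angle, L)
    origin, P = _world_grid(cfg, L)
    spacing = cfg.spacing
    min_sp = min(spacing)

    # --- body tube, curved and straight ---------------------------------
    s, dv, lr, dist = geom.project(P)
    radius = np.asarray(cfg.body_radius_profile(s), dtype=float)
    if np.any(radius <= 0):
        raise ValueError("body_radius_profile must be strictly positive on [0, 1]")
    body = dist <= radius

    sg = ArcGeometry(0.0, L)
    s2, dv2, lr2, dist2 = sg.project(P)
    straight = dist2 <= np.asarray(cfg.body_radius_profile(s2), dtype=float)

    # grid-fit check: the tube must not touch the world window boundary
    def _touches(mask3):
        return (
            mask3[0].any() or mask3[-1].any()
            or mask3[:, 0].any() or mask3[:, -1].any()
            or mask3[:, :, 0].any() or mask3[:, :, -1].any()
        )

    if _touches(body) or _touches(straight):
        raise ValueError(
            "grid too small: the phantom tube reaches the volume boundary; "
            "enlarge grid_shape or shorten midline_length"
        )

    # --- limbs -----------------------------------------------------------
    limb_masks = []
    limb_infos: list[LimbInfo] = []
    for li, spec in enumerate(cfg.limb_specs):
        sign = -1.0 if spec.side == "left" else 1.0
        direction = np.array([sign, 0.0, 0.0])
        r_at = float(np.asarray(cfg.body_radius_profile(spec.s)))
        curved_base = geom.midline(spec.s) + direction * r_at
        straight_base = geom.straight_midline(spec.s) + direction * r_at
        cm, _ = _capsule_mask(P, curved_base, direction, spec.length, spec.radius)
        if not cm.any() or _touches(cm):
            raise ValueError(f"limb {spec.name!r} lies outside the usable grid")
        pd = np.linalg.norm(P - curved_base, axis=-1)
        limb_masks.append((cm, straight_base, direction, spec))
        limb_infos.append(
            LimbInfo(
                spec=spec,
                curved_base=curved_base,
                curved_tip=curved_base + direction * spec.length,
                straight_base=straight_base,
                straight_tip=straight_base + direction * spec.length,
                direction=direction,
                mask=Volume(cm.astype(np.uint8), spacing, origin),
                truth_pd=Volume(np.where(cm, pd, np.inf), spacing, origin),
            )
        )

    mask = body.copy()
    straight_full = straight.copy()
    for cm, sb, direction, spec in limb_masks:
        mask |= cm
        sm, _ = _capsule_mask(P, sb, direction, spec.length, spec.radius)
        straight_full |= sm

    curved_mask = Volume(mask.astype(np.uint8), spacing, origin)
    straight_mask = Volume(straight_full.astype(np.uint8), spacing, origin)

    # --- ground-truth anatomical coordinate fields ----------------------
    nanmask = np.where(mask, 1.0, np.nan)
    truth = AxisFields(
        ap=Volume((s * L) * nanmask, spacing, origin),
        dv=Volume(dv * nanmask, spacing, origin),
        lr=Volume(lr * nanmask, spacing, origin),
        mask=curved_mask,
    )

    # --- intensity image (radially shaded tube + mild deterministic noise)
    rng = np.random.default_rng(cfg.seed)
    with np.errstate(invalid="ignore"):
        shade = np.clip(1.0 - dist / np.maximum(radius, 1e-9), 0.0, 1.0)
    intensity = np.where(mask, 40.0 + 160.0 * shade, 0.0)
    intensity += np.where(mask, rng.normal(0.0, 2.0, size=mask.shape), 0.0)
    curved_volume = Volume(intensity.astype(np.float32), spacing, origin)

    # --- midline ("Shh-like") expression --------------------------------
    midline_only = mask & (dist <= 1.0 * min_sp + 1e-9)
    shh = midline_only.copy()
    for info, (cm, _, direction, spec) in zip(limb_infos, limb_masks):
        axial = (P - info.curved_base) @ info.direction
        posterior = (P - info.curved_base) @ geom.tangent(spec.s)
        zpa = cm & (axial >= 0.55 * spec.length) & (posterior > 0.2 * spec.radius)
        shh |= zpa
    midline_expression = Volume(
        np.where(midline_only, 200.0, 0.0).astype(np.float32), spacing, origin
    )

    # --- anatomical regions ----------------------------------------------
    labels = np.zeros(mask.shape, dtype=np.int32)
    names: dict[int, str] = {}
    bins = [(1, "craniofacial", 0.0, 0.2), (2, "midbrain", 0.2, 0.4),
            (3, "hindbrain", 0.4, 0.6), (4, "trunk", 0.6, 1.0001)]
    for lab, nm, lo, hi in bins:
        labels[body & (s >= lo) & (s < hi)] = lab
        names[lab] = nm
    for li, (cm, _, _, spec) in enumerate(limb_masks):
        lab = 10 + li
        labels[cm & (labels == 0) & mask] = lab
        names[lab] = spec.name
    regions = RegionMap(Volume(labels, spacing, origin), names)

    # --- planted expression domains --------------------------------------
    expression: dict[str, Volume] = {}
    domain_masks: dict[str, np.ndarray] = {}
    for dspec in cfg.domain_specs:
        if dspec.s is not None:
            centre = (
                geom.midline(dspec.s)
                + geom.ventral(dspec.s) * dspec.d
                + np.array([dspec.l, 0.0, 0.0])
            )
        else:
            if dspec.limb >= len(limb_infos):
                raise ValueError(f"domain {dspec.name!r} references unknown limb {dspec.limb}")
            info = limb_infos[dspec.limb]
            centre = (
                info.curved_base
                + info.direction * (dspec.p * info.spec.length)
                + geom.tangent(info.spec.s) * dspec.offset
            )
        sphere = np.linalg.norm(P - centre, axis=-1) <= dspec.radius
        dm = sphere & mask
        if not dm.any():
            raise ValueError(f"domain {dspec.name!r} does not intersect the phantom mask")
        domain_masks[dspec.name] = domain_masks.get(dspec.name, np.zeros_like(mask)) | dm
    for nm, dm in domain_masks.items():
        expression[nm] = Volume(np.where(dm, 200.0, 0.0).astype(np.float32), spacing, origin)
    expression["Shh"] = Volume(np.where(shh, 200.0, 0.0).astype(np.float32), spacing, origin)

    midline_points = geom.midline(np.linspace(0.0, 1.0, 129))

    bundle = PhantomBundle(
        config=cfg,
        geometry=geom,
        curved_volume=curved_volume,
        curved_mask=curved_mask,
        straight_mask=straight_mask,
        midline_points=midline_points,
        truth_axis_fields=truth,
        regions=regions,
        expression=expression,
        midline_expression=midline_expression,
        limbs=limb_infos,
        landmarks=LandmarkSet(),
    )
    bundle.landmarks = make_landmarks(bundle, cfg.n_landmarks, cfg.seed)
    return bundle


def make_landmarks(bundle: PhantomBundle, n: int, seed: int) -> LandmarkSet:
    """Sample ``n`` landmark pairs at matched arc-length stations.

    Station rule: a midline pair plus dorsal and ventral surface pairs
    at every station, a tip pair for each limb, and (when there are no
    limb tips to break planarity) a left/right surface pair at the
    middle station.  The dorsal/ventral pairs at every station are what
    anchor the anterior-posterior shear of the bending deformation
    (straight-space z depends on the dorso-ventral offset through the
    local turning angle); without them, extracted transverse planes
    tilt in the ring gaps.  Stations are evenly spaced with a small
    seeded jitter, so different seeds move the stations but keep the
    rule set.
    """
    if n < 8:
        raise ValueError(f"need at least 8 landmarks for a stable 3D fit, got {n}")
    geom = bundle.geometry
    cfg = bundle.config
    rng = np.random.default_rng(seed)
    n_limbs = len(bundle.limbs)

    n_tips = n_limbs if (n_limbs and n >= 12 + n_limbs) else 0
    # without limb tips every station point lies in the x=0 plane; a
    # left/right pair keeps the affine term identifiable
    n_lr = 0 if n_tips else 2
    K = max(4, (n - n_tips - n_lr) // 3)
    # Chebyshev-style spacing: stations cluster toward the ends, where the
    # local turning angle (hence the A-P shear to be anchored) is largest
    base = 0.5 - 0.5 * np.cos(np.pi * (np.arange(K) + 0.5) / K)
    base = 0.03 + 0.94 * (base - base.min()) / (base.max() - base.min())
    gap = float(np.min(np.diff(base))) if K > 1 else 0.5
    stations = np.clip(base + rng.uniform(-0.25, 0.25, size=K) * gap, 0.02, 0.98)
    stations.sort()

    margin = 1.2 * min(cfg.spacing)
    names: list[str] = []
    src: list[np.ndarray] = []
    tgt: list[np.ndarray] = []

    def add(name, sp, tp):
        names.append(name)
        src.append(np.asarray(sp, float))
        tgt.append(np.asarray(tp, float))

    budget = n - n_tips - n_lr
    for i, s in enumerate(stations):
        m_c = geom.midline(s)
        m_s = geom.straight_midline(s)
        off = float(np.asarray(cfg.body_radius_profile(s))) - margin
        entries = [
            (f"mid-{i:02d}", m_c, m_s),
            (f"srf-{i:02d}-dor", m_c + off * geom.dorsal(s), m_s + off * np.array([0.0, -1.0, 0.0])),
            (f"srf-{i:02d}-ven", m_c + off * geom.ventral(s), m_s + off * np.array([0.0, 1.0, 0.0])),
        ]
        for name, sp, tp in entries:
            if len(names) < budget:
                add(name, sp, tp)
    if n_lr:
        s = stations[K // 2]
        off = float(np.asarray(cfg.body_radius_profile(s))) - margin
        m_c, m_s = geom.midline(s), geom.straight_midline(s)
        add(f"srf-{K // 2:02d}-lef", m_c + off * geom.left(s), m_s + off * np.array([-1.0, 0.0, 0.0]))
        add(f"srf-{K // 2:02d}-rig", m_c - off * geom.left(s), m_s + off * np.array([1.0, 0.0, 0.0]))
    if n_tips:
        for li, info in enumerate(bundle.limbs):
            add(f"limb-{li}-tip", info.curved_tip, info.straight_tip)

    # snap both sides to voxel centres of their grids so the fitted
    # interpolation conditions hold exactly at the stored coordinates
    grid = bundle.curved_mask
    src_a = grid.index_to_world(np.rint(grid.world_to_index(np.array(src[:n]))))
    tgt_a = grid.index_to_world(np.rint(grid.world_to_index(np.array(tgt[:n]))))
    return LandmarkSet(names[:n], src_a, tgt_a)


def default_config(seed: int = 0, **overrides) -> PhantomConfig:
    """The study phantom: half-circle curl, four limb buds, planted
    Shh/Fgf-style expression domains spanning every axis vocabulary."""
    limbs = (
        LimbSpec("left forelimb bud", 0.55, "left", 9.0, 3.5),
        LimbSpec("right forelimb bud", 0.55, "right", 9.0, 3.5),
        LimbSpec("left hindlimb bud", 0.82, "left", 7.0, 3.0),
        LimbSpec("right hindlimb bud", 0.82, "right", 7.0, 3.0),
    )
    domains = (
        # craniofacial A-P sequence (anterior to posterior)
        DomainSpec("Fgf8", 2.5, s=0.08),
        DomainSpec("Fgf9", 2.5, s=0.14),
        DomainSpec("Fgf20", 2.5, s=0.19),
        # midbrain: Fgf10 dorsal to the midline Shh
        DomainSpec("Fgf10", 2.2, s=0.30, d=-4.5),
        # hindbrain: Fgf10 bilateral about the midline
        DomainSpec("Fgf10", 2.2, s=0.50, l=-5.0),
        DomainSpec("Fgf10", 2.2, s=0.50, l=+5.0),
        # hindbrain: one strictly left, one strictly right domain
        DomainSpec("Fgf17", 2.2, s=0.55, l=-5.0),
        DomainSpec("Fgf18", 2.2, s=0.55, l=+5.0),
        # trunk A-P pair
        DomainSpec("Fgf5", 2.5, s=0.68),
        DomainSpec("Fgf6", 2.5, s=0.90),
        # forelimb buds: Fgf10 proximal, Fgf8 distal
        DomainSpec("Fgf10", 2.0, limb=0, p=0.35),
        DomainSpec("Fgf8", 2.0, limb=0, p=0.85),
        DomainSpec("Fgf10", 2.0, limb=1, p=0.35),
        DomainSpec("Fgf8", 2.0, limb=1, p=0.85),
    )
    kwargs = dict(limb_specs=limbs, domain_specs=domains, seed=seed)
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)
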