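"""Invertible landmark-driven deformation between curved and straight space.

The transform interpolates landmark displacements with multiquadric
radial basis functions whose "radius" is the *constrained* distance
inside the specimen mask (the 26-connected geodesic of
:mod:`straightax.distance`), plus an affine term:

    u(p) = sum_i w_i * phi(d_c(p, s_i)) + A(p),   phi(r) = sqrt(r^2 + delta^2)

with interpolation conditions ``u(s_i) = t_i - s_i`` and the standard
moment side-conditions ``P^T w = 0`` (P the affine design at the
landmarks).  Measuring kernel distances along in-mask paths is what
allows the very large, fold-free bending deformations needed to
straighten a curled specimen: points that are close in space but far
along the body (e.g. head and tail of a curled embryo) are far in the
kernel metric, so they deform independently.

The inverse direction is fitted the same way with landmark roles
swapped, then refined per-voxel by Newton iteration against the forward
field, giving a numerically verified round-trip bound.

Exposed in a statsmodels-like shape: :class:`CdtModel` is built from
data and ``fit()`` returns a :class:`CdtTransform` results object that
carries the displacement fields, fit diagnostics and a ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import linalg, ndimage

from .distance import (
    MaskGraph,
    distance_maps_from_points,
    geodesic_path,
    mask_graph,
    snap_to_mask,
)
from .volumes import LandmarkSet, Volume, read_landmarks, write_landmarks, read_volume, write_volume

__all__ = [
    "CdtParams",
    "CdtModel",
    "CdtTransform",
    "fit_cdt",
    "transform_points",
    "apply_transform",
    "subdivide_landmarks",
]

_SERIAL_VERSION = 1


@dataclass(frozen=True)
class CdtParams:
    """Tunables of the constrained-distance deformation model.

    ``delta`` is the multiquadric shape parameter in world units
    (default: mean nearest-neighbour landmark separation in the
    constrained metric).  ``regularization`` adds a ridge to the
    interpolation solve (0 = exact interpolation).
    ``inversion_tolerance`` is the target round-trip error in world
    units (default 0.5 * min spacing).
    """

    delta: float | None = None
    include_affine: bool = True
    regularization: float = 0.0
    connectivity: int = 26
    inversion_tolerance: float | None = None
    max_newton_iters: int = 20

    def __post_init__(self) -> None:
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is supported")


class _RbfField:
    """A fitted RBF+affine displacement interpolant in one direction."""

    def __init__(self, points, displacements, dist_matrix, delta, lam, include_affine):
        k = points.shape[0]
        phi = np.sqrt(dist_matrix**2 + delta**2)
        if include_affine:
            P = np.column_stack([np.ones(k), points])
            M = np.zeros((k + 4, k + 4))
            M[:k, :k] = phi + lam * np.eye(k)
            M[:k, k:] = P
            M[k:, :k] = P.T
            rhs = np.vstack([displacements, np.zeros((4, 3))])
        else:
            M = phi + lam * np.eye(k)
            rhs = displacements
        try:
            sol = linalg.solve(M, rhs)
        except linalg.LinAlgError:
            ridge = 1e-8 * np.trace(phi) / k
            warnings.warn(
                f"singular RBF system; retrying with ridge {ridge:.3e}", stacklevel=3
            )
            M[:k, :k] += ridge * np.eye(k)
            sol = linalg.solve(M, rhs)
        self.weights = sol[:k]
        self.affine = sol[k:] if include_affine else np.zeros((4, 3))
        self.delta = delta
        self.points = points

    def evaluate(self, dists: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Displacements given kernel distances (k, m) and positions (m, 3)."""
        phi = np.sqrt(dists**2 + self.delta**2)
        u = phi.T @ self.weights
        u += np.column_stack([np.ones(positions.shape[0]), positions]) @ self.affine
        return u

    def residual_at_points(self, dist_matrix, displacements) -> float:
        u = self.evaluate(dist_matrix, self.points)
        return float(np.linalg.norm(u - displacements, axis=1).max())


def _dense_field(
    rbf: _RbfField,
    g: MaskGraph,
    dmaps: np.ndarray,
    band_voxels: float = 2.5,
) -> np.ndarray:
    """Displacement field on the full grid of ``g.volume``.

    In-mask voxels get the exact interpolant.  Voxels within
    ``band_voxels`` of the mask get the interpolant evaluated with
    distances continued as d(nearest in-mask voxel) + Euclidean
    remainder, so trilinear interpolation stays accurate across the
    mask boundary.  Remaining voxels copy their nearest computed value.
    """
    vol = g.volume
    shape = vol.shape
    m = vol.data.astype(bool)
    spacing = np.asarray(vol.spacing)

    disp = np.zeros(shape + (3,), dtype=np.float64)
    node_pos = g.node_world()
    disp[tuple(g.node_index.T)] = rbf.evaluate(dmaps, node_pos)

    dist_vox, nearest = ndimage.distance_transform_edt(~m, return_indices=True)
    band = (~m) & (dist_vox <= band_voxels)
    if band.any():
        bidx = np.argwhere(band)
        nn = nearest[:, band].T                       # (b, 3) nearest in-mask voxel
        nn_nodes = g.voxel_to_node[tuple(nn.T)]
        bpos = vol.index_to_world(bidx)
        npos = vol.index_to_world(nn)
        remainder = np.linalg.norm((bpos - npos), axis=1)
        d_ext = dmaps[:, nn_nodes] + remainder[None, :]
        disp[band] = rbf.evaluate(d_ext, bpos)
    far = (~m) & (~band)
    if far.any():
        # copy from nearest computed voxel (mask or band)
        computed = m | band
        _, near2 = ndimage.distance_transform_edt(~computed, return_indices=True)
        src = tuple(near2[:, far])
        disp[far] = disp[src]
    return disp


def _interp_field(field: np.ndarray, vol: Volume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (..., 3) grid field at world points."""
    idx = vol.world_to_index(points).T  # (3, m)
    out = np.empty((points.shape[0], 3))
    for a in range(3):
        out[:, a] = ndimage.map_coordinates(field[..., a], idx, order=1, mode="nearest")
    return out


@dataclass
class CdtTransform:
    """Fitted invertible curved<->straight mapping with diagnostics.

    The forward field maps curved (source) space to straight (target)
    space; the inverse field is Newton-refined against the forward one
    so that the sampled round-trip error is bounded.
    """

    source_mask: Volume
    target_mask: Volume
    landmarks: LandmarkSet
    params: CdtParams
    delta: float
    forward_field: np.ndarray          # (nx, ny, nz, 3) on the source grid
    inverse_field: np.ndarray          # (nx, ny, nz, 3) on the target grid
    fit_residual: float
    roundtrip_mean: float
    roundtrip_p99: float
    roundtrip_max: float
    newton_iters: int
    direction: str = "curved->straight"

    # -- evaluation -------------------------------------------------------
    def transform_points(self, points: np.ndarray, inverse: bool = False) -> np.ndarray:
        """Map world points forward (curved->straight) or inverse.

        Points up to 2 voxels outside the relevant mask are evaluated on
        the boundary-extended displacement field; farther points are
        rejected (they are outside the transform's domain of validity).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        mask = self.target_mask if inverse else self.source_mask
        fld = self.inverse_field if inverse else self.forward_field
        m = mask.data.astype(bool)
        idx = mask.world_to_nearest_index(pts)
        inside = m[tuple(idx.T)]
        if not inside.all():
            # validates the 2-voxel tolerance; raises listing offenders
            snap_to_mask(mask, pts[~inside], what="query point")
        return pts + _interp_field(fld, mask, pts)

    def apply(self, v: Volume, inverse: bool = False, interpolation: str = "linear") -> Volume:
        """Resample a volume across the transform (pull-back).

        ``inverse=False`` maps a curved-space volume onto the straight
        grid (each straight in-mask voxel reads the volume at its
        inverse-mapped position); ``inverse=True`` does the opposite.
        Use ``interpolation="nearest"`` for masks and label maps.
        """
        if interpolation not in ("nearest", "linear"):
            raise ValueError("interpolation must be 'nearest' or 'linear'")
        order = 0 if interpolation == "nearest" else 1
        src_mask = self.target_mask if inverse else self.source_mask
        dst_mask = self.source_mask if inverse else self.target_mask
        fld = self.forward_field if inverse else self.inverse_field
        if not v.same_grid(src_mask):
            raise ValueError(
                "volume grid does not match the "
                + ("target (straight)" if inverse else "source (curved)")
                + " mask grid"
            )
        dm = dst_mask.data.astype(bool)
        didx = np.argwhere(dm)
        dpos = dst_mask.index_to_world(didx)
        mapped = dpos + fld[dm]
        coords = v.world_to_index(mapped).T
        vals = ndimage.map_coordinates(
            v.data.astype(np.float64), coords, order=order, mode="constant", cval=0.0
        )
        out = np.zeros(v.shape, dtype=np.float64)
        out[dm] = vals
        if order == 0:
            out = out.astype(v.data.dtype)
        return Volume(out, dst_mask.spacing, dst_mask.origin)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        sp = min(self.source_mask.spacing)
        lines = [
            "Constrained-distance transform (curved -> straight)",
            "=" * 51,
            f"landmarks:            {len(self.landmarks)}",
            f"multiquadric delta:   {self.delta:.4g} world units",
            f"regularization:       {self.params.regularization:.4g}",
            f"fit residual (max):   {self.fit_residual:.3e} world units",
            f"round-trip mean:      {self.roundtrip_mean:.4f} ({self.roundtrip_mean / sp:.3f} voxels)",
            f"round-trip p99:       {self.roundtrip_p99:.4f}",
            f"round-trip max:       {self.roundtrip_max:.4f}",
            f"newton iterations:    {self.newton_iters}",
        ]
        return "\n".join(lines)

    def report(self) -> dict:
        return {
            "n_landmarks": len(self.landmarks),
            "delta": self.delta,
            "regularization": self.params.regularization,
            "fit_residual": self.fit_residual,
            "roundtrip_mean": self.roundtrip_mean,
            "roundtrip_p99": self.roundtrip_p99,
            "roundtrip_max": self.roundtrip_max,
            "newton_iters": self.newton_iters,
        }

    # -- serialization ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for tag, fld, grid in (
            ("forward", self.forward_field, self.source_mask),
            ("inverse", self.inverse_field, self.target_mask),
        ):
            for a, ax in enumerate("xyz"):
                write_volume(grid.with_data(fld[..., a]), d / f"{tag}_{ax}.nrrd")
        write_volume(self.source_mask, d / "source_mask.nrrd")
        write_volume(self.target_mask, d / "target_mask.nrrd")
        write_landmarks(self.landmarks, d / "landmarks.tsv")
        meta = {
            "version": _SERIAL_VERSION,
            "direction": self.direction,
            "delta": self.delta,
            "params": {
                "delta": self.params.delta,
                "include_affine": self.params.include_affine,
                "regularization": self.params.regularization,
                "connectivity": self.params.connectivity,
                "inversion_tolerance": self.params.inversion_tolerance,
                "max_newton_iters": self.params.max_newton_iters,
            },
            "fit_residual": self.fit_residual,
            "roundtrip_mean": self.roundtrip_mean,
            "roundtrip_p99": self.roundtrip_p99,
            "roundtrip_max": self.roundtrip_max,
            "newton_iters": self.newton_iters,
        }
        (d / "params.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "CdtTransform":
        d = Path(directory)
        meta = json.loads((d / "params.json").read_text())
        if meta.get("version") != _SERIAL_VERSION:
            raise ValueError(f"unsupported transform version {meta.get('version')}")
        src = read_volume(d / "source_mask.nrrd")
        tgt = read_volume(d / "target_mask.nrrd")
        fwd = np.stack(
            [read_volume(d / f"forward_{ax}.nrrd").data for ax in "xyz"], axis=-1
        )
        inv = np.stack(
            [read_volume(d / f"inverse_{ax}.nrrd").data for ax in "xyz"], axis=-1
        )
        p = meta["params"]
        return cls(
            source_mask=src,
            target_mask=tgt,
            landmarks=read_landmarks(d / "landmarks.tsv"),
            params=CdtParams(**p),
            delta=meta["delta"],
            forward_field=fwd,
            inverse_field=inv,
            fit_residual=meta["fit_residual"],
            roundtrip_mean=meta["roundtrip_mean"],
            roundtrip_p99=meta["roundtrip_p99"],
            roundtrip_max=meta["roundtrip_max"],
            newton_iters=meta["newton_iters"],
            direction=meta["direction"],
        )


class CdtModel:
    """Deformation model built from landmark pairs and the two masks.

    ``fit()`` solves the forward interpolation system, evaluates the
    dense displacement field, fits and Newton-refines the inverse, and
    returns a :class:`CdtTransform`.
    """

    def __init__(
        self,
        landmarks: LandmarkSet,
        source_mask: Volume,
        target_mask: Volume,
        params: CdtParams | None = None,
    ):
        if len(landmarks) < 4:
            raise ValueError("need at least 4 landmarks for a 3D fit")
        source_mask.require_binary("source mask")
        target_mask.require_binary("target mask")
        self.landmarks = landmarks
        self.source_mask = source_mask
        self.target_mask = target_mask
        self.params = params or CdtParams()
        if self.params.include_affine:
            centred = landmarks.source_points - landmarks.source_points.mean(axis=0)
            if np.linalg.matrix_rank(centred, tol=1e-8) < 3:
                raise ValueError(
                    "source landmarks are coplanar; the affine term is unidentifiable "
                    "(add non-coplanar landmarks or set include_affine=False)"
                )

    # -- internals --------------------------------------------------------
    def _forward(self, g: MaskGraph):
        src_idx = snap_to_mask(self.source_mask, self.landmarks.source_points, what="source landmark")
        if np.unique(src_idx, axis=0).shape[0] != src_idx.shape[0]:
            raise ValueError("two source landmarks snap to the same voxel; thin them out")
        src_pts = self.source_mask.index_to_world(src_idx)
        dmaps = distance_maps_from_points(g, src_pts, "source landmark")
        nodes = g.voxel_to_node[tuple(src_idx.T)]
        D = dmaps[:, nodes]
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        delta = self.params.delta
        if delta is None:
            # near-polyharmonic regime: small relative to the landmark
            # separation, which keeps the (geodesic-metric) kernel matrix
            # away from sign-change singularities
            offdiag = D + np.diag(np.full(len(D), np.inf))
            delta = 0.1 * float(offdiag.min(axis=1).mean())
        disp = self.landmarks.target_points - src_pts
        rbf = _RbfField(src_pts, disp, D, delta, self.params.regularization,
                        self.params.include_affine)
        residual = rbf.residual_at_points(D, disp)
        # oscillation diagnostic: weights far larger than the displacement
        # scale mean the interpolant rings between landmarks
        disp_scale = max(float(np.linalg.norm(disp, axis=1).max()), 1e-12)
        wmax = float(np.abs(rbf.weights).max())
        if wmax > 0.5 * disp_scale:
            warnings.warn(
                f"RBF weights are large (max {wmax:.3g} vs displacement scale "
                f"{disp_scale:.3g}); the interpolant may oscillate — consider a "
                "different delta or a small regularization",
                stacklevel=3,
            )
        return rbf, dmaps, D, src_pts, delta, residual

    def _inverse_init(self, delta: float):
        g_t = mask_graph(self.target_mask)
        # unbounded snap: these voxels only seed the reverse-RBF initial
        # guess, which the Newton refinement replaces
        tgt_idx = snap_to_mask(
            self.target_mask, self.landmarks.target_points,
            max_voxels=np.inf, what="target landmark",
        )
        tgt_pts = self.target_mask.index_to_world(tgt_idx)
        uniq, keep = np.unique(tgt_idx, axis=0, return_index=True)
        keep = np.sort(keep)
        tgt_pts = tgt_pts[keep]
        src_pts = self.landmarks.source_points[keep]
        dmaps = distance_maps_from_points(g_t, tgt_pts, "target landmark")
        nodes = g_t.voxel_to_node[tuple(tgt_idx[keep].T)]
        D = dmaps[:, nodes]
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        rbf = _RbfField(tgt_pts, src_pts - tgt_pts, D, delta,
                        self.params.regularization, self.params.include_affine)
        return rbf, g_t, dmaps

    def _refine_inverse(self, fwd_field, inv_field, eps, max_iters):
        """Newton-refine the inverse displacement at straight-space voxels.

        Solves x + u_fwd(x) = y for each target voxel centre y within the
        mask or its 2.5-voxel boundary band, starting from the reverse
        RBF estimate.  Falls back to damped fixed-point steps where the
        local Jacobian is near-singular.
        """
        tgt = self.target_mask
        src = self.source_mask
        m = tgt.data.astype(bool)
        dist_vox = ndimage.distance_transform_edt(~m)
        active = m | (dist_vox <= 2.5)
        yidx = np.argwhere(active)
        y = tgt.index_to_world(yidx)
        x = y + inv_field[active]

        sp = np.asarray(src.spacing)
        grads = np.empty(src.shape + (3, 3))
        for a in range(3):
            for b in range(3):
                grads[..., a, b] = np.gradient(fwd_field[..., a], sp[b], axis=b)

        iters_used = 0
        for it in range(max_iters):
            F = x + _interp_field(fwd_field, src, x)
            r = y - F
            err = np.linalg.norm(r, axis=1)
            iters_used = it
            if err.max() <= 0.25 * eps:
                break
            J = np.eye(3)[None] + _interp_tensor(grads, src, x)
            det = np.linalg.det(J)
            ok = np.abs(det) > 1e-6
            dx = np.empty_like(r)
            if ok.any():
                dx[ok] = np.linalg.solve(J[ok], r[ok][..., None])[..., 0]
            if (~ok).any():
                dx[~ok] = 0.5 * r[~ok]
            # trust-region cap keeps boundary voxels from overshooting
            step = np.linalg.norm(dx, axis=1, keepdims=True)
            cap = 4.0 * float(sp.max())
            dx = np.where(step > cap, dx * (cap / np.maximum(step, 1e-12)), dx)
            x = x + dx
        refined = np.array(inv_field)
        refined[active] = x - y
        far = ~active
        if far.any():
            _, near2 = ndimage.distance_transform_edt(~active, return_indices=True)
            refined[far] = refined[tuple(near2[:, far])]
        return refined, iters_used + 1

    # -- fitting -----------------------------------------------------------
    def fit(self) -> CdtTransform:
        g = mask_graph(self.source_mask)
        rbf_f, dmaps_f, _, src_pts, delta, residual = self._forward(g)
        fwd = _dense_field(rbf_f, g, dmaps_f)

        rbf_i, g_t, dmaps_i = self._inverse_init(delta)
        inv0 = _dense_field(rbf_i, g_t, dmaps_i)

        eps = self.params.inversion_tolerance
        if eps is None:
            eps = 0.5 * min(self.source_mask.spacing)
        inv, iters = self._refine_inverse(fwd, inv0, eps, self.params.max_newton_iters)

        # sampled round-trip verification: curved voxel -> straight -> curved
        nodes = g.node_index
        stride = max(1, nodes.shape[0] // 1000)
        sample = self.source_mask.index_to_world(nodes[::stride])
        yy = sample + _interp_field(fwd, self.source_mask, sample)
        back = yy + _interp_field(inv, self.target_mask, yy)
        err = np.linalg.norm(back - sample, axis=1)
        r_mean = float(err.mean())
        r_p99 = float(np.quantile(err, 0.99))
        r_max = float(err.max())
        if np.mean(err > 10 * eps) > 0.10:
            worst = sample[int(np.argmax(err))]
            raise RuntimeError(
                f"inverse refinement failed: >1% of sampled points exceed 10*eps_inv; "
                f"worst at world {tuple(np.round(worst, 2))} (error {r_max:.3g})"
            )
        if r_p99 > eps:
            worst = sample[int(np.argmax(err))]
            warnings.warn(
                f"round-trip p99 {r_p99:.3g} exceeds eps_inv {eps:.3g}; "
                f"worst voxel at world {tuple(np.round(worst, 2))}",
                stacklevel=2,
            )

        return CdtTransform(
            source_mask=self.source_mask,
            target_mask=self.target_mask,
            landmarks=self.landmarks,
            params=self.params,
            delta=delta,
            forward_field=fwd,
            inverse_field=inv,
            fit_residual=residual,
            roundtrip_mean=r_mean,
            roundtrip_p99=r_p99,
            roundtrip_max=r_max,
            newton_iters=iters,
        )


def _interp_tensor(grads: np.ndarray, vol: Volume, points: np.ndarray) -> np.ndarray:
    idx = vol.world_to_index(points).T
    out = np.empty((points.shape[0], 3, 3))
    for a in range(3):
        for b in range(3):
            out[:, a, b] = ndimage.map_coordinates(
                grads[..., a, b], idx, order=1, mode="nearest"
            )
    return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_cdt(
    ls: LandmarkSet,
    source_mask: Volume,
    target_mask: Volume,
    params: CdtParams | None = None,
) -> CdtTransform:
    """Fit the constrained-distance transform (see :class:`CdtModel`)."""
    return CdtModel(ls, source_mask, target_mask, params).fit()


def transform_points(t: CdtTransform, points: np.ndarray, inverse: bool = False) -> np.ndarray:
    return t.transform_points(points, inverse=inverse)


def apply_transform(
    t: CdtTransform, v: Volume, inverse: bool = False, interpolation: str = "linear"
) -> Volume:
    return t.apply(v, inverse=inverse, interpolation=interpolation)


def subdivide_landmarks(
    ls: LandmarkSet, source_mask: Volume, target_mask: Volume
) -> LandmarkSet:
    """Insert constrained-geodesic midpoints between consecutive landmarks
    sharing a name prefix (text before the last ``-``).

    This is the "distance subdivision" refinement step: each inserted
    pair sits at half the geodesic arc length between its parents in the
    source and target masks respectively, densifying correspondence
    without new manual annotation.
    """
    g_s = mask_graph(source_mask)
    g_t = mask_graph(target_mask)

    def prefix(name: str) -> str:
        return name.rsplit("-", 1)[0]

    def midpoint(g: MaskGraph, a, b, pairname) -> np.ndarray:
        pts, cum = geodesic_path(g, a, b, what=pairname)
        half = cum[-1] / 2.0
        j = int(np.searchsorted(cum, half))
        if j == 0:
            return pts[0]
        seg = cum[j] - cum[j - 1]
        f = 0.0 if seg == 0 else (half - cum[j - 1]) / seg
        return pts[j - 1] + f * (pts[j] - pts[j - 1])

    names = list(ls.names)
    src = [p for p in ls.source_points]
    tgt = [p for p in ls.target_points]
    min_sep = 1.0 * min(source_mask.spacing)
    out_names: list[str] = []
    out_src: list[np.ndarray] = []
    out_tgt: list[np.ndarray] = []
    for i in range(len(names)):
        out_names.append(names[i])
        out_src.append(src[i])
        out_tgt.append(tgt[i])
        if i + 1 < len(names) and prefix(names[i]) == prefix(names[i + 1]):
            pairname = f"{names[i]}--{names[i + 1]}"
            ms = midpoint(g_s, src[i], src[i + 1], pairname)
            mt = midpoint(g_t, tgt[i], tgt[i + 1], pairname)
            # skip midpoints colliding with an existing landmark (e.g. the
            # dorsal->ventral surface path passes through the midline point)
            d_exist = np.linalg.norm(np.asarray(src) - ms, axis=1).min()
            d_new = (
                np.linalg.norm(np.asarray(out_src) - ms, axis=1).min()
                if out_src
                else np.inf
            )
            if min(d_exist, d_new) <= min_sep:
                continue
            used = set(names) | set(out_names)
            c = i
            while f"{names[i]}+sub{c:02d}" in used:
                c += 100
            out_names.append(f"{names[i]}+sub{c:02d}")
            out_src.append(ms)
            out_tgt.append(mt)
    return LandmarkSet(out_names, np.array(out_src), np.array(out_tgt))
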