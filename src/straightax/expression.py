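"""Thresholded expression domains and axial occupancy profiles.

An expression domain is the binary region where a mapped gene-expression
volume exceeds an intensity threshold (chosen to reflect signal level
and exclude artefacts).  Its axial profile bins every embryo voxel by an
anatomical coordinate and reports, per bin, the fraction of embryo
volume the domain occupies — expression per unit volume along the axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import AxisFields
from .volumes import Volume

__all__ = [
    "ExpressionDomain",
    "AxialProfile",
    "threshold_expression",
    "axial_profile",
    "profile_peak",
]


@dataclass
class ExpressionDomain:
    """A named binary expression region within the embryo mask."""

    name: str
    mask: Volume
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask.require_binary(f"expression domain {self.name!r}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.data.sum())

    def restricted_to(self, region_mask: Volume) -> "ExpressionDomain":
        region_mask.require_binary("region mask")
        return ExpressionDomain(
            self.name,
            self.mask.with_data((self.mask.data.astype(bool) & region_mask.data.astype(bool)).astype(np.uint8)),
            self.threshold_used,
        )


@dataclass
class AxialProfile:
    """Per-bin occupancy of a domain along one anatomical axis.

    ``occupancy[b] = expressing[b] / total[b]`` where ``total`` counts
    embryo-mask voxels in the bin (``denominator="bin"``, the default
    per-unit-volume reading) or, with ``denominator="domain"``, the
    domain's own voxel count.
    """

    axis: str
    bin_edges: np.ndarray     # ascending, len n_bins + 1
    expressing: np.ndarray    # per-bin expressing voxel counts
    total: np.ndarray         # per-bin embryo voxel counts
    denominator: str = "bin"

    @property
    def n_bins(self) -> int:
        return len(self.expressing)

    @property
    def occupancy(self) -> np.ndarray:
        if self.denominator == "domain":
            tot = self.expressing.sum()
            return self.expressing / tot if tot > 0 else np.zeros(self.n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            occ = np.where(self.total > 0, self.expressing / np.maximum(self.total, 1), 0.0)
        return occ

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "expressing": self.expressing,
                "total": self.total,
                "occupancy": self.occupancy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def threshold_expression(
    v: Volume,
    t: float,
    embryo_mask: Volume,
    name: str = "domain",
) -> ExpressionDomain:
    """Binary domain where intensity >= t, inside the embryo mask."""
    embryo_mask.require_binary("embryo mask")
    if not v.same_grid(embryo_mask):
        raise ValueError("expression volume and embryo mask are on different grids")
    dom = (v.data >= t) & embryo_mask.data.astype(bool)
    if not dom.any():
        warnings.warn(f"threshold {t} yields an empty domain {name!r}", stacklevel=2)
    return ExpressionDomain(name, v.with_data(dom.astype(np.uint8)), float(t))


def axial_profile(
    d: ExpressionDomain,
    fields: AxisFields,
    axis: str,
    embryo_mask: Volume,
    n_bins: int,
    denominator: str = "bin",
    pd_field: Volume | None = None,
) -> AxialProfile:
    """Bin the embryo along an axis and count expressing voxels per bin.

    ``axis`` is one of ``ap``, ``dv``, ``lr``, ``ml`` or ``pd`` (the
    latter requires ``pd_field``).  Bins partition the in-mask coordinate
    range into ``n_bins`` half-open intervals (last bin closed).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if denominator not in ("bin", "domain"):
        raise ValueError("denominator must be 'bin' or 'domain'")
    embryo_mask.require_binary("embryo mask")
    if axis == "pd":
        if pd_field is None:
            raise ValueError("axis 'pd' requires pd_field")
        coord = pd_field
    else:
        coord = fields.get(axis)  # raises with the valid-name list
    m = embryo_mask.data.astype(bool)
    vals = coord.data[m]
    if not np.isfinite(vals).all():
        raise ValueError("axis field is not finite on the embryo mask")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    # half-open bins [e_i, e_{i+1}), final bin closed
    which = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_bins - 1)
    dom = d.mask.data.astype(bool)[m]
    total = np.bincount(which, minlength=n_bins)
    expressing = np.bincount(which[dom], minlength=n_bins)
    return AxialProfile(axis, edges, expressing, total, denominator)


def profile_peak(p: AxialProfile) -> tuple[int, float] | None:
    """Bin index and coordinate midpoint of the occupancy peak.

    Ties break toward the smallest coordinate (most anterior for the
    A-P axis); an all-zero profile returns None.
    """
    occ = p.occupancy
    if not occ.any():
        return None
    b = int(np.argmax(occ))  # argmax returns the first (smallest-coordinate) maximum
    return b, float(p.bin_midpoints[b])
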