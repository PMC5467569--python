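"""Paired qualitative spatial relations between expression domains.

Given two domains restricted to a named anatomical region, directional
relations are asserted per axis when the median coordinates separate by
more than a margin:

* A-P: smaller A-P coordinate is anterior (``anterior_to``/``posterior_to``);
* D-V: dorsal is the negative D-V side (``dorsal_to``/``ventral_to``);
* M-L: closer to the midline is medial (``medial_to``/``lateral_to``);
* L-R: left is the negative L-R side, as seen looking from dorsal to
  ventral (``left_of``/``right_of``);
* P-D (appendages only): smaller proximo-distal coordinate is proximal
  (``proximal_to``/``distal_to``).

Left/right is special: a domain that is bilateral (enough mass on each
side of the midline) is decomposed into connected components, and
component pairs are compared — so a midline domain can correctly be
both ``left_of`` and ``right_of`` a bilateral partner, while also being
``medial_to`` it.  Every assertion is emitted together with its dual.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .expression import ExpressionDomain, axial_profile, profile_peak
from .fields import AxisFields
from .volumes import RegionMap, Volume

__all__ = [
    "RelationParams",
    "Assertion",
    "RelationReport",
    "relate_pair",
    "rank_along_axis",
    "RELATION_DUALS",
]

RELATION_DUALS = {
    "anterior_to": "posterior_to",
    "posterior_to": "anterior_to",
    "dorsal_to": "ventral_to",
    "ventral_to": "dorsal_to",
    "left_of": "right_of",
    "right_of": "left_of",
    "medial_to": "lateral_to",
    "lateral_to": "medial_to",
    "proximal_to": "distal_to",
    "distal_to": "proximal_to",
}


@dataclass(frozen=True)
class RelationParams:
    """Margin (axis units) required to assert a directional relation,
    and the minimum per-side mass fraction for a domain to count as
    bilateral."""

    margin: float = 2.0
    bilateral_min_fraction: float = 0.2
    component_connectivity: int = 26

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if not (0.0 < self.bilateral_min_fraction <= 0.5):
            raise ValueError("bilateral_min_fraction must be in (0, 0.5]")
        if self.component_connectivity != 26:
            raise ValueError("only 26-connectivity is supported")


@dataclass(frozen=True)
class Assertion:
    subject: str
    relation: str
    object: str
    region: str
    median_subject: float
    median_object: float
    margin: float

    def dual(self) -> "Assertion":
        return Assertion(
            self.object,
            RELATION_DUALS[self.relation],
            self.subject,
            self.region,
            self.median_object,
            self.median_subject,
            self.margin,
        )

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.subject, self.relation, self.object, self.region)


@dataclass
class RelationReport:
    assertions: list[Assertion] = dc_field(default_factory=list)

    def add_with_dual(self, a: Assertion) -> None:
        if a.as_tuple() not in {x.as_tuple() for x in self.assertions}:
            self.assertions.append(a)
        d = a.dual()
        if d.as_tuple() not in {x.as_tuple() for x in self.assertions}:
            self.assertions.append(d)

    def holds(self, subject: str, relation: str, object: str, region: str | None = None) -> bool:
        for a in self.assertions:
            if (a.subject, a.relation, a.object) == (subject, relation, object):
                if region is None or a.region == region:
                    return True
        return False

    def extend(self, other: "RelationReport") -> None:
        for a in other.assertions:
            if a.as_tuple() not in {x.as_tuple() for x in self.assertions}:
                self.assertions.append(a)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": a.subject,
                    "relation": a.relation,
                    "object": a.object,
                    "region": a.region,
                    "medianA": a.median_subject,
                    "medianB": a.median_object,
                    "margin": a.margin,
                }
                for a in self.assertions
            ],
            columns=["subject", "relation", "object", "region", "medianA", "medianB", "margin"],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        self.to_dataframe().to_json(path, orient="records", indent=1)


def _axis_values(domain_mask: np.ndarray, coord: Volume) -> np.ndarray:
    return coord.data[domain_mask]


def _components(mask: np.ndarray) -> list[np.ndarray]:
    lab = cc_label(mask, connectivity=3)  # 3 = 26-connectivity in 3D
    return [(lab == i) for i in range(1, lab.max() + 1)]


def _is_bilateral(mask: np.ndarray, lr: Volume, min_fraction: float) -> bool:
    vals = lr.data[mask]
    n = vals.size
    if n == 0:
        return False
    return (vals < 0).sum() >= min_fraction * n and (vals > 0).sum() >= min_fraction * n


def relate_pair(
    a: ExpressionDomain,
    b: ExpressionDomain,
    regions: RegionMap,
    region_name: str,
    fields: AxisFields,
    params: RelationParams | None = None,
    pd_field: Volume | None = None,
) -> RelationReport:
    """Directional relations between two domains within one region.

    ``pd_field`` (a proximo-distal coordinate volume, e.g. from
    :func:`straightax.axes.limb_pd_field`) enables the proximal/distal
    vocabulary for appendage regions.
    """
    params = params or RelationParams()
    region_mask = regions.mask_of(region_name)
    ra = a.restricted_to(region_mask)
    rb = b.restricted_to(region_mask)
    ma = ra.mask.data.astype(bool)
    mb = rb.mask.data.astype(bool)
    for dom, m in ((a, ma), (b, mb)):
        if not m.any():
            raise ValueError(
                f"domain {dom.name!r} does not intersect region {region_name!r}"
            )

    report = RelationReport()
    margin = params.margin

    def med(m, coord):
        return float(np.median(coord.data[m]))

    # axes where smaller coordinate wins the first-named relation
    axis_rules = [
        (fields.ap, "anterior_to", "posterior_to"),
        (fields.dv, "dorsal_to", "ventral_to"),
        (fields.ml, "medial_to", "lateral_to"),
    ]
    if pd_field is not None:
        axis_rules.append((pd_field, "proximal_to", "distal_to"))
    for coord, small_rel, large_rel in axis_rules:
        qa, qb = med(ma, coord), med(mb, coord)
        if qa < qb - margin:
            report.add_with_dual(Assertion(a.name, small_rel, b.name, region_name, qa, qb, margin))
        elif qa > qb + margin:
            report.add_with_dual(Assertion(a.name, large_rel, b.name, region_name, qa, qb, margin))

    # left/right: component decomposition when either domain is bilateral
    lr = fields.lr
    bilat = _is_bilateral(ma, lr, params.bilateral_min_fraction) or _is_bilateral(
        mb, lr, params.bilateral_min_fraction
    )
    comps_a = _components(ma) if bilat else [ma]
    comps_b = _components(mb) if bilat else [mb]
    for ca in comps_a:
        for cb in comps_b:
            qa, qb = med(ca, lr), med(cb, lr)
            if qa < qb - margin:
                report.add_with_dual(
                    Assertion(a.name, "left_of", b.name, region_name, qa, qb, margin)
                )
            elif qa > qb + margin:
                report.add_with_dual(
                    Assertion(a.name, "right_of", b.name, region_name, qa, qb, margin)
                )
    return report


def rank_along_axis(
    domains: list[ExpressionDomain],
    fields: AxisFields,
    axis: str,
    embryo_mask: Volume,
    region_mask: Volume | None = None,
    n_bins: int = 20,
    pd_field: Volume | None = None,
) -> pd.DataFrame:
    """Order domains by median axis coordinate (ties by name).

    Returns a DataFrame with one row per nonempty domain, sorted, with
    the occupancy-profile peak position attached.
    """
    if axis == "pd" and pd_field is None:
        raise ValueError("axis 'pd' requires pd_field")
    coord = pd_field if axis == "pd" else fields.get(axis)
    emask = embryo_mask
    if region_mask is not None:
        region_mask.require_binary("region mask")
        emask = embryo_mask.with_data(
            (embryo_mask.data.astype(bool) & region_mask.data.astype(bool)).astype(np.uint8)
        )
    rows = []
    for d in domains:
        rd = d.restricted_to(emask) if region_mask is not None else d
        m = rd.mask.data.astype(bool) & emask.data.astype(bool)
        if not m.any():
            continue
        prof = axial_profile(rd, fields, axis, emask, n_bins, pd_field=pd_field)
        peak = profile_peak(prof)
        rows.append(
            {
                "name": d.name,
                "median": float(np.median(coord.data[m])),
                "voxels": int(m.sum()),
                "peak_bin": peak[0] if peak else -1,
                "peak_coordinate": peak[1] if peak else np.nan,
            }
        )
    if not rows:
        raise ValueError("all domains are empty in the requested region")
    df = pd.DataFrame(rows).sort_values(["median", "name"], kind="stable").reset_index(drop=True)
    return df
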