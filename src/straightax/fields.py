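"""The AxisFields container: anatomical coordinates as scalar volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import Volume

__all__ = ["AxisFields"]

_AXIS_NAMES = ("ap", "dv", "lr", "ml")


@dataclass
class AxisFields:
    """Anterior-posterior, dorsal-ventral, left-right and medio-lateral
    coordinate fields, finite exactly on the embryo mask (NaN elsewhere).

    ``ap`` is the straight-space world z coordinate (anterior small),
    ``dv`` the signed world y (ventral positive), ``lr`` the signed
    world x (right positive, as seen looking from dorsal to ventral),
    and ``ml = |lr|``.
    """

    ap: Volume
    dv: Volume
    lr: Volume
    mask: Volume

    def __post_init__(self) -> None:
        for name in ("ap", "dv", "lr"):
            v: Volume = getattr(self, name)
            if not v.same_grid(self.mask):
                raise ValueError(f"{name} field is not on the mask grid")
        m = self.mask.data.astype(bool)
        for name in ("ap", "dv", "lr"):
            v = getattr(self, name)
            if not np.isfinite(v.data[m]).all():
                raise ValueError(f"{name} field is not finite everywhere on the mask")

    @property
    def ml(self) -> Volume:
        return self.lr.with_data(np.abs(self.lr.data))

    def get(self, axis: str) -> Volume:
        if axis not in _AXIS_NAMES:
            raise ValueError(f"unknown axis {axis!r}; valid axes: {list(_AXIS_NAMES)}")
        return self.ml if axis == "ml" else getattr(self, axis)

    def sample_nearest(self, axis: str, points: np.ndarray) -> np.ndarray:
        """Axis values at world points, read from the nearest grid voxel."""
        f = self.get(axis)
        idx = f.world_to_nearest_index(np.atleast_2d(points))
        return f.data[tuple(idx.T)]

    @staticmethod
    def axis_names() -> tuple[str, ...]:
        return _AXIS_NAMES
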