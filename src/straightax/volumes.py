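"""Volumes, landmark sets and region label maps, plus their file formats.

Geometric conventions used throughout the package:

* a :class:`Volume` stores its data as a 3D array indexed ``(i, j, k)``
  mapping to world axes ``(x, y, z)``; 0-based indices;
  ``world = origin + index * spacing`` componentwise;
* all public APIs exchange *world* coordinates (float xyz triples);
* in straight (anatomical) space ``+z`` runs anterior to posterior,
  ``+y`` dorsal to ventral, and ``+x`` left to right as seen looking
  from the dorsal side toward the ventral side.

Supported on-disk formats: NRRD (via SimpleITK), NIfTI-1 (via nibabel),
single multi-page TIFF or a directory of numbered TIFF slices (via
tifffile).  TIFF carries no reliable spacing: an optional JSON sidecar
``<name>.json`` with ``spacing``/``origin`` keys is honoured, otherwise
spacing defaults to 1 with a warning.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Volume",
    "LandmarkSet",
    "RegionMap",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
]

_VALID_AXIS_ORDER = "xyz"


@dataclass
class Volume:
    """A 3D scalar grid (intensity, binary mask, label map or coordinate field).

    Parameters
    ----------
    data
        3D array, index ``(i, j, k)`` along world ``(x, y, z)``.
    spacing
        Per-axis voxel size in world units; strictly positive.
    origin
        World coordinate of voxel index ``(0, 0, 0)``.
    axis_order
        Fixed declaration of the index-to-world mapping; only ``"xyz"``
        is supported and the field exists to make the convention explicit.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = _VALID_AXIS_ORDER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be xyz triples")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.axis_order != _VALID_AXIS_ORDER:
            raise ValueError("only axis_order='xyz' is supported")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates of (possibly fractional) voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points, shape (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_to_nearest_index(self, pts: np.ndarray) -> np.ndarray:
        """Nearest integer voxel indices, clipped into the grid."""
        idx = np.rint(self.world_to_index(pts)).astype(np.int64)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def same_grid(self, other: "Volume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid carrying ``data``."""
        return Volume(data, self.spacing, self.origin)

    # -- predicates -------------------------------------------------------
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def require_binary(self, what: str = "volume") -> None:
        if not self.is_binary():
            raise ValueError(f"{what} must be binary (values in {{0, 1}})")


@dataclass
class LandmarkSet:
    """Ordered pairs of equivalent world-space points on a source (curved)
    and a target (straight) volume."""

    names: list[str] = field(default_factory=list)
    source_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    target_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.source_points = np.atleast_2d(np.asarray(self.source_points, dtype=float))
        self.target_points = np.atleast_2d(np.asarray(self.target_points, dtype=float))
        if len(self.names) == 0:
            self.source_points = self.source_points.reshape(0, 3)
            self.target_points = self.target_points.reshape(0, 3)
        n = len(self.names)
        if self.source_points.shape != (n, 3) or self.target_points.shape != (n, 3):
            raise ValueError("source/target point arrays must have shape (n_names, 3)")
        if len(set(self.names)) != n:
            dupes = sorted({m for m in self.names if self.names.count(m) > 1})
            raise ValueError(f"duplicate landmark names: {dupes}")
        if n > 1:
            # duplicated source points make the interpolation system singular
            uniq = np.unique(np.round(self.source_points, 9), axis=0)
            if uniq.shape[0] != n:
                raise ValueError("duplicated source points in landmark set")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        for name, s, t in zip(self.names, self.source_points, self.target_points):
            yield name, s, t

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return (
            self.names == other.names
            and np.allclose(self.source_points, other.source_points)
            and np.allclose(self.target_points, other.target_points)
        )

    def swapped(self) -> "LandmarkSet":
        """Landmark roles exchanged (target becomes source)."""
        return LandmarkSet(list(self.names), self.target_points.copy(), self.source_points.copy())


@dataclass
class RegionMap:
    """Integer label volume plus a label -> region-name table."""

    labels: Volume
    names: dict[int, str]

    def __post_init__(self) -> None:
        lab = self.labels.data
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.rint(lab)):
                raise ValueError("label volume must hold integers")
            self.labels = self.labels.with_data(lab.astype(np.int32))
        if self.labels.data.min() < 0:
            raise ValueError("label volume must be non-negative")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels.data).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def label_of(self, region_name: str) -> int:
        for lab, nm in self.names.items():
            if nm == region_name:
                return lab
        raise KeyError(f"unknown region {region_name!r}; known: {sorted(self.names.values())}")

    def mask_of(self, region_name: str) -> Volume:
        lab = self.label_of(region_name)
        return self.labels.with_data((self.labels.data == lab).astype(np.uint8))


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

_NIFTI_EXT = (".nii", ".nii.gz")
_NRRD_EXT = (".nrrd", ".nhdr")
_TIFF_EXT = (".tif", ".tiff")


def _format_of(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    name = path.name.lower()
    if name.endswith(_NIFTI_EXT):
        return "nifti"
    if name.endswith(_NRRD_EXT):
        return "nrrd"
    if name.endswith(_TIFF_EXT):
        return "tiff"
    if path.is_dir():
        return "tiff_stack"
    raise ValueError(
        f"cannot infer volume format of {path}; supported: NRRD (.nrrd/.nhdr), "
        "NIfTI (.nii/.nii.gz), TIFF (.tif/.tiff or a directory of numbered slices)"
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.is_file() else path / "spacing.json"


def _tiff_metadata(path: Path) -> tuple[tuple, tuple]:
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        return tuple(meta.get("spacing", (1.0, 1.0, 1.0))), tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    warnings.warn(
        f"no JSON sidecar with voxel spacing next to {path}; assuming spacing (1, 1, 1)",
        stacklevel=3,
    )
    return (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)


def read_volume(path: str | Path, format_hint: str | None = None) -> Volume:
    """Read a 3D volume with its spacing/origin metadata.

    ``format_hint`` may be ``"nrrd"``, ``"nifti"``, ``"tiff"`` or
    ``"tiff_stack"``; otherwise the extension decides.  Array values are
    returned unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    fmt = _format_of(path, format_hint)

    if fmt == "nrrd":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - corrupt file path
            raise IOError(f"unreadable NRRD file {path}: {exc}") from exc
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0)), img.GetSpacing(), img.GetOrigin())

    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        return Volume(np.ascontiguousarray(data), zooms, origin)

    if fmt in ("tiff", "tiff_stack"):
        import tifffile

        if path.is_dir():
            slices = sorted(
                (p for p in path.iterdir() if p.suffix.lower() in _TIFF_EXT),
                key=lambda p: [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)],
            )
            if not slices:
                raise IOError(f"no TIFF slices found in directory {path}")
            arr = np.stack([tifffile.imread(str(p)) for p in slices], axis=0)
        else:
            arr = tifffile.imread(str(path))
        if arr.ndim != 3:
            raise IOError(f"TIFF at {path} is not a 3D stack (shape {arr.shape})")
        spacing, origin = _tiff_metadata(path)
        # stored as (z, y, x) pages
        return Volume(np.ascontiguousarray(arr.transpose(2, 1, 0)), spacing, origin)

    raise ValueError(f"unsupported format hint {fmt!r}")


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume; format chosen by extension (see :func:`read_volume`)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    fmt = _format_of(path, None) if path.suffix else None
    if fmt is None:
        raise ValueError("write_volume needs an extension: .nrrd, .nhdr, .nii[.gz], .tif")

    if fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
        img.SetSpacing(v.spacing)
        img.SetOrigin(v.origin)
        sitk.WriteImage(img, str(path), useCompression=False)
        return
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        data = v.data
        if data.dtype == np.bool_:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(
            str(path),
            np.ascontiguousarray(v.data.transpose(2, 1, 0)),
            photometric="minisblack",
        )
        _sidecar_path(path).write_text(
            json.dumps({"spacing": list(v.spacing), "origin": list(v.origin)})
        )
        return
    raise ValueError(
        f"unsupported extension on {path}; supported: .nrrd/.nhdr, .nii/.nii.gz, .tif/.tiff"
    )


# ---------------------------------------------------------------------------
# landmark I/O  (TSV: name  sx sy sz  tx ty tz, world coordinates)
# ---------------------------------------------------------------------------

_LM_COLUMNS = ["name", "sx", "sy", "sz", "tx", "ty", "tz"]


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read paired landmarks from a TSV with header ``name sx sy sz tx ty tz``."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise IOError(f"landmark file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    if list(df.columns) != _LM_COLUMNS:
        raise ValueError(f"landmark TSV must have columns {_LM_COLUMNS}, got {list(df.columns)}")
    for col in _LM_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna()) if len(df) else []
        if len(df) and vals.isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at data row {row + 1} of {path}"
            )
        df[col] = vals
    names = df["name"].tolist()
    return LandmarkSet(
        names,
        df[["sx", "sy", "sz"]].to_numpy(float).reshape(len(names), 3),
        df[["tx", "ty", "tz"]].to_numpy(float).reshape(len(names), 3),
    )


def write_landmarks(ls: LandmarkSet, path: str | Path) -> None:
    """Write a LandmarkSet as the TSV dialect read by :func:`read_landmarks`."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "name": ls.names,
            "sx": ls.source_points[:, 0],
            "sy": ls.source_points[:, 1],
            "sz": ls.source_points[:, 2],
            "tx": ls.target_points[:, 0],
            "ty": ls.target_points[:, 1],
            "tz": ls.target_points[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# region-name table I/O (JSON)
# ---------------------------------------------------------------------------

def read_region_names(path: str | Path) -> dict[int, str]:
    return {int(k): str(v) for k, v in json.loads(Path(path).read_text()).items()}


def write_region_names(names: dict[int, str], path: str | Path) -> None:
    Path(path).write_text(json.dumps({str(k): v for k, v in sorted(names.items())}, indent=1))
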