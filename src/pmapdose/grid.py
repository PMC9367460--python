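"""Voxel-lattice primitives shared by every pipeline stage.

All volumetric objects live on a :class:`GridGeometry`: a regular lattice with
array axis order ``(z, y, x)``, voxel-centred world coordinates in millimetres
and 0-based indices.  Doses are stored in Gy (physical or biologically
effective), structures as boolean masks.  Every downstream metric assumes the
dose grid and all masks share one lattice; :func:`validate_same_lattice`
enforces that contract explicitly rather than letting shape broadcasting hide
a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "GeometryError",
    "GridGeometry",
    "DoseGrid",
    "BinaryMask",
    "StructureSet",
    "union_masks",
    "intersect_masks",
    "mask_volume_cc",
    "validate_same_lattice",
]

#: Tolerance (mm) within which two lattices count as identical.
LATTICE_TOL_MM = 1e-6


class GeometryError(ValueError):
    """Raised when voxel lattices disagree or a geometry is malformed."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular voxel lattice: shape ``(nz, ny, nx)``, spacing and origin in mm.

    ``origin`` is the world coordinate of the *centre* of voxel ``(0, 0, 0)``;
    spacing and origin use the same ``(z, y, x)`` axis order as the arrays.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise GeometryError("shape, spacing and origin must be triples")
        if any(n < 1 for n in shape):
            raise GeometryError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise GeometryError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)`` in (z,y,x) mm."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz, yy, xx], axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional (z,y,x) indices of world points, shape ``(..., 3)``."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def describe_mismatch(self, other: "GridGeometry", tol: float = LATTICE_TOL_MM) -> str | None:
        """First differing field versus ``other``, or None if equal within ``tol``."""
        if self.shape != other.shape:
            return f"shape differs: {self.shape} vs {other.shape}"
        for name in ("spacing", "origin"):
            a = np.asarray(getattr(self, name))
            b = np.asarray(getattr(other, name))
            if np.any(np.abs(a - b) > tol):
                return f"{name} differs: {tuple(a)} vs {tuple(b)}"
        return None

    def approx_equal(self, other: "GridGeometry", tol: float = LATTICE_TOL_MM) -> bool:
        return self.describe_mismatch(other, tol) is None


def _check_geometry_match(a, b, context: str) -> None:
    msg = a.geometry.describe_mismatch(b.geometry)
    if msg is not None:
        raise GeometryError(f"{context}: lattices differ ({msg})")


@dataclass
class DoseGrid:
    """3-D dose distribution on a lattice, in Gy.

    ``dose_kind`` distinguishes physical dose from biologically effective dose
    (BED); conversions must go through :func:`pmapdose.dosimetry.to_bed` so the
    kind can never silently flip.
    """

    geometry: GridGeometry
    values: np.ndarray
    dose_kind: str = "physical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"dose array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.dose_kind not in ("physical", "BED"):
            raise ValueError(f"dose_kind must be 'physical' or 'BED', got {self.dose_kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")


@dataclass
class BinaryMask:
    """Boolean volume of interest (VOI) on a lattice."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"mask shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_cc(self) -> float:
        """Mask volume in cubic centimetres (1 cc = 1000 mm^3)."""
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0

    def centroid_index(self) -> np.ndarray:
        """Mean (z, y, x) index of the true voxels; NaNs when empty."""
        if self.voxel_count == 0:
            return np.full(3, np.nan)
        return np.mean(np.argwhere(self.values), axis=0)


def union_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise OR of two masks on the same lattice."""
    _check_geometry_match(a, b, "union_masks")
    return BinaryMask(a.geometry, a.values | b.values)


def intersect_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise AND of two masks on the same lattice."""
    _check_geometry_match(a, b, "intersect_masks")
    return BinaryMask(a.geometry, a.values & b.values)


def mask_volume_cc(m: BinaryMask) -> float:
    """Volume of a mask in cc (voxel count times voxel volume)."""
    return m.volume_cc


def validate_same_lattice(objects: Iterable[DoseGrid | BinaryMask]) -> None:
    """Raise :class:`GeometryError` unless all objects share one lattice.

    The error message names the first differing field (shape, spacing or
    origin) so a caller can tell a resampling problem from a cropping one.
    """
    objs = list(objects)
    if not objs:
        raise ValueError("validate_same_lattice requires at least one object")
    ref = objs[0].geometry
    for i, obj in enumerate(objs[1:], start=1):
        msg = ref.describe_mismatch(obj.geometry)
        if msg is not None:
            raise GeometryError(f"object {i} not on the reference lattice: {msg}")


#: Structure names every full plan evaluation needs.
REQUIRED_STRUCTURES = ("PTV", "LungH", "LungC", "Heart", "SpinalCord", "Pmap")


@dataclass
class StructureSet:
    """Named binary masks sharing one lattice.

    Holds the planning target volume (PTV), homolateral and contralateral
    lungs (LungH / LungC), heart, spinal cord and the pneumonitis-associated
    Pmap sub-region.  ``2Lungs`` may be stored explicitly; otherwise it is
    derived as LungH | LungC on access.
    """

    geometry: GridGeometry
    masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            msg = self.geometry.describe_mismatch(mask.geometry)
            if msg is not None:
                raise GeometryError(f"structure {name!r} not on the set lattice: {msg}")
        ptv = self.masks.get("PTV")
        if ptv is not None and ptv.voxel_count == 0:
            raise ValueError("PTV mask must be non-empty")

    def __getitem__(self, name: str) -> BinaryMask:
        if name == "2Lungs" and "2Lungs" not in self.masks:
            return union_masks(self.masks["LungH"], self.masks["LungC"])
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} missing; available: {sorted(self.masks)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        if name == "2Lungs":
            return "2Lungs" in self.masks or ("LungH" in self.masks and "LungC" in self.masks)
        return name in self.masks

    def names(self) -> list[str]:
        return sorted(self.masks)

    def require(self, names: Iterable[str] = REQUIRED_STRUCTURES) -> None:
        missing = [n for n in names if n not in self]
        if missing:
            raise KeyError(f"missing required structures: {missing}")
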