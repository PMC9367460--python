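"""Transfer of the phantom-defined Pmap sub-region into a patient lattice.

The pneumonitis-associated sub-region is delineated once on a reference
thoracic phantom; per patient it must be carried into the planning lattice by
the inverse of the phantom-to-patient registration.  The registration itself
(elastic, segmentation-based, run in external software) is out of scope: this
module consumes a precomputed :class:`SpatialTransform` — identity and affine
as fully testable stand-ins, dense displacement fields for external elastic
registrations — and quantifies registration quality with the DICE overlap of
the hybrid lungs+heart VOI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import BinaryMask, GeometryError, GridGeometry
from .indices import dice

__all__ = ["SpatialTransform", "map_pmap_to_patient", "registration_qa"]


@dataclass
class SpatialTransform:
    """Phantom-to-patient spatial mapping in world coordinates (mm).

    kind 'identity': no-op.  kind 'affine': homogeneous 4x4 matrix acting on
    (z, y, x, 1) world vectors.  kind 'displacement_field': per-voxel
    displacement vectors (mm, (3, nz, ny, nx)) defined on the phantom lattice,
    mapping each phantom voxel centre to its patient-space position.
    """

    kind: str
    matrix: np.ndarray | None = None
    displacement: np.ndarray | None = None
    field_geometry: GridGeometry | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "affine", "displacement_field"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "affine":
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.shape != (4, 4):
                raise ValueError("affine transform needs a 4x4 matrix")
            if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
                raise ValueError("affine matrix is singular")
        if self.kind == "displacement_field":
            self.displacement = np.asarray(self.displacement, dtype=float)
            if self.field_geometry is None:
                raise ValueError("displacement_field requires field_geometry")
            if self.displacement.shape != (3, *self.field_geometry.shape):
                raise ValueError(
                    "displacement must have shape (3, nz, ny, nx) on the phantom lattice"
                )

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(kind="identity")

    @classmethod
    def from_affine(cls, matrix: np.ndarray) -> "SpatialTransform":
        return cls(kind="affine", matrix=matrix)

    @classmethod
    def translation(cls, offset_mm) -> "SpatialTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(offset_mm, dtype=float)
        return cls.from_affine(m)

    @classmethod
    def from_displacement(cls, field: np.ndarray, geometry: GridGeometry) -> "SpatialTransform":
        return cls(kind="displacement_field", displacement=field, field_geometry=geometry)

    def inverse(self) -> "SpatialTransform":
        if self.kind == "identity":
            return SpatialTransform.identity()
        if self.kind == "affine":
            return SpatialTransform.from_affine(np.linalg.inv(self.matrix))
        raise ValueError("a dense displacement field has no closed-form inverse")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points (z, y, x mm) phantom -> patient."""
        pts = np.asarray(points, dtype=float)
        if self.kind == "identity":
            return pts.copy()
        if self.kind == "affine":
            flat = pts.reshape(-1, 3)
            out = flat @ self.matrix[:3, :3].T + self.matrix[:3, 3]
            return out.reshape(pts.shape)
        raise ValueError("displacement fields map voxels, not arbitrary points")


def map_pmap_to_patient(
    pmap_phantom: BinaryMask, t: SpatialTransform, target: GridGeometry
) -> BinaryMask:
    """Resample a phantom-space mask onto a patient lattice through ``t``.

    Identity/affine transforms use inverse-lookup nearest-neighbour sampling:
    each target voxel centre is pulled back to phantom space and takes the
    nearest phantom voxel's label, so no holes can appear.  Displacement
    fields (no closed-form inverse) are applied forward: each true phantom
    voxel is pushed to its patient position and the nearest target voxel set.

    If the region lands entirely outside the target grid an empty mask is
    returned with a warning rather than an error — downstream code treats it
    as a failed registration.
    """
    src_geo = pmap_phantom.geometry
    out = np.zeros(target.shape, dtype=bool)

    if t.kind in ("identity", "affine"):
        inv = t.inverse()
        centers = target.voxel_centers().reshape(-1, 3)
        phantom_pts = inv.apply_points(centers)
        idx = np.rint(src_geo.world_to_index(phantom_pts)).astype(int)
        valid = np.all((idx >= 0) & (idx < np.asarray(src_geo.shape)), axis=1)
        flat = out.reshape(-1)
        vi = idx[valid]
        flat[valid] = pmap_phantom.values[vi[:, 0], vi[:, 1], vi[:, 2]]
    else:  # displacement field, forward splat
        if not src_geo.approx_equal(t.field_geometry):
            raise GeometryError("displacement field not on the phantom mask lattice")
        src_idx = np.argwhere(pmap_phantom.values)
        if src_idx.size:
            world = (
                np.asarray(src_geo.origin)
                + src_idx * np.asarray(src_geo.spacing)
                + t.displacement[:, pmap_phantom.values].T
            )
            idx = np.rint(target.world_to_index(world)).astype(int)
            valid = np.all((idx >= 0) & (idx < np.asarray(target.shape)), axis=1)
            vi = idx[valid]
            out[vi[:, 0], vi[:, 1], vi[:, 2]] = True

    result = BinaryMask(target, out)
    if pmap_phantom.voxel_count > 0 and result.voxel_count == 0:
        warnings.warn(
            "mapped region lies entirely outside the target grid; returning empty mask",
            stacklevel=2,
        )
    return result


def registration_qa(phantom_voi: BinaryMask, mapped_patient_voi: BinaryMask) -> float:
    """Registration-quality DICE between the phantom hybrid VOI (lungs ∪ heart)
    and the patient's hybrid VOI warped into phantom space."""
    return dice(phantom_voi, mapped_patient_voi)
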