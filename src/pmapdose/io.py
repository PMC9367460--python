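"""Readers/writers and run configuration.

Volumes travel as NIfTI (via nibabel): arrays are stored in the package's
(z, y, x) axis order transposed to NIfTI's (x, y, z) on disk, with spacing
and origin carried in the affine and the dose kind ('physical'/'BED') in the
header description field.  Masks round-trip bit-exactly (uint8 on disk);
doses as float64.  Patient tables are comma-separated UTF-8 CSV with '.'
decimals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import ConstraintSet, DEFAULT_CONSTRAINTS, OARConstraint
from .dosimetry import FractionationScheme
from .grid import BinaryMask, DoseGrid, GridGeometry
from .risk import DMEAN_THRESHOLD_GY, PROB_THRESHOLD, ClinicalFeatures

__all__ = [
    "read_volume",
    "write_volume",
    "read_patient_table",
    "RunConfig",
]

_MASK_TAG = "pmapdose:mask"
_DOSE_TAG = "pmapdose:dose"


def _affine_from_geometry(geo: GridGeometry) -> np.ndarray:
    # disk order (x, y, z) -> package order reversed
    sp = geo.spacing[::-1]
    og = geo.origin[::-1]
    aff = np.diag([sp[0], sp[1], sp[2], 1.0])
    aff[:3, 3] = og
    return aff


def _geometry_from_img(img) -> GridGeometry:
    aff = img.affine
    if aff is None:
        raise ValueError("volume has no affine: spacing/origin metadata missing")
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-9):
        raise ValueError("only axis-aligned volumes are supported")
    spacing_xyz = np.diag(rot)
    if np.any(spacing_xyz <= 0):
        raise ValueError(f"non-positive spacing in affine: {tuple(spacing_xyz)}")
    origin_xyz = aff[:3, 3]
    shape_xyz = img.shape
    return GridGeometry(
        shape=tuple(int(n) for n in shape_xyz[::-1]),
        spacing=tuple(float(s) for s in spacing_xyz[::-1]),
        origin=tuple(float(o) for o in origin_xyz[::-1]),
    )


def write_volume(obj: DoseGrid | BinaryMask, path: str | Path) -> None:
    """Write a dose grid or mask as NIfTI (.nii or .nii.gz)."""
    path = Path(path)
    aff = _affine_from_geometry(obj.geometry)
    if isinstance(obj, BinaryMask):
        data = obj.values.astype(np.uint8).transpose(2, 1, 0)
        descrip = _MASK_TAG
    elif isinstance(obj, DoseGrid):
        data = obj.values.astype(np.float64).transpose(2, 1, 0)
        descrip = f"{_DOSE_TAG}:{obj.dose_kind}"
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, aff)
    img.header["descrip"] = descrip.encode()
    nib.save(img, str(path))


def read_volume(path: str | Path) -> DoseGrid | BinaryMask:
    """Read a NIfTI volume back as a DoseGrid or BinaryMask.

    The object kind comes from the header tag written by :func:`write_volume`;
    foreign volumes fall back on the dtype (integer -> mask, float ->
    physical dose).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    geo = _geometry_from_img(img)
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    if descrip == _MASK_TAG:
        return BinaryMask(geo, data.astype(bool))
    if descrip.startswith(_DOSE_TAG):
        kind = descrip.split(":")[-1]
        return DoseGrid(geo, data.astype(np.float64), dose_kind=kind)
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        return BinaryMask(geo, data.astype(bool))
    return DoseGrid(geo, data.astype(np.float64), dose_kind="physical")


MANDATORY_PATIENT_COLUMNS = ("id", "smoking_status", "copd", "mevs", "ajcc_stage")


def read_patient_table(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a clinical-feature CSV; returns (clean table, row-level issues).

    Mandatory columns: id, smoking_status, copd, mevs, ajcc_stage; any other
    columns (e.g. precomputed dose metrics) pass through untouched.  Rows
    with unparseable numeric values are excluded from the returned table and
    reported in the issues list rather than aborting the run.
    """
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    missing = [c for c in MANDATORY_PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing mandatory columns: {missing}")
    issues: list[str] = []
    numeric = ["smoking_status", "copd", "mevs"] + [
        c
        for c in df.columns
        if c not in MANDATORY_PATIENT_COLUMNS and df[c].dtype == object
    ]
    keep = np.ones(len(df), dtype=bool)
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        for i in np.nonzero(bad.to_numpy())[0]:
            issues.append(f"row {i} (id={df['id'].iloc[i]}): non-numeric {col}={df[col].iloc[i]!r}")
        keep &= ~bad.to_numpy()
        df[col] = coerced
    clean = df.loc[keep].reset_index(drop=True)
    for _, row in clean.iterrows():  # validates ranges, raises on nonsense
        ClinicalFeatures(
            smoking_status=int(row["smoking_status"]),
            copd=int(row["copd"]),
            mevs=float(row["mevs"]),
            ajcc_stage=str(row["ajcc_stage"]),
        )
    return clean, issues


@dataclass
class RunConfig:
    """Serializable run configuration: thresholds, constraints, seed, paths.

    All thresholds sit here so a study can tighten or relax them in one
    place; the defaults are the pipeline's standard operating point (30.3 Gy
    BED Pmap threshold, 8% probability cutoff, 20% relative-reduction rule,
    1 point coverage tolerance).
    """

    prescription_dose: float = 66.0
    n_fractions: int = 33
    dmean_threshold: float = DMEAN_THRESHOLD_GY
    prob_threshold: float = PROB_THRESHOLD
    reduction_fraction: float = 0.20
    ptv95_floor: float = 95.0
    ptv95_drop_tolerance: float = 1.0
    oar_constraints: list[tuple[str, float, str]] = field(
        default_factory=lambda: [
            (c.metric, c.bound, c.direction) for c in DEFAULT_CONSTRAINTS.oar_constraints
        ]
    )
    model_backend: str = "logistic_surrogate"
    model_path: str | None = None
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("dmean_threshold", "reduction_fraction", "ptv95_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.prob_threshold < 1):
            raise ValueError("prob_threshold must be in (0, 1)")

    @property
    def fractionation(self) -> FractionationScheme:
        return FractionationScheme(self.prescription_dose, self.n_fractions)

    @property
    def constraint_set(self) -> ConstraintSet:
        return ConstraintSet(
            oar_constraints=tuple(OARConstraint(m, b, d) for m, b, d in self.oar_constraints),
            ptv95_floor=self.ptv95_floor,
            ptv95_drop_tolerance=self.ptv95_drop_tolerance,
            dmean_threshold=self.dmean_threshold,
            reduction_fraction=self.reduction_fraction,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload["oar_constraints"] = [tuple(c) for c in payload.get("oar_constraints", [])]
        return cls(**payload)
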