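"""Overlap and plan-quality indices: DICE, conformity (IC), heterogeneity (HIV)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import BinaryMask, DoseGrid, validate_same_lattice
from .dosimetry import (
    DEFAULT_BIN_WIDTH_GY,
    EmptyStructureError,
    FractionationScheme,
    cumulative_dvh,
    d_at_volume,
)

__all__ = ["PlanQualityIndices", "dice", "conformity_index", "heterogeneity_index"]


@dataclass(frozen=True)
class PlanQualityIndices:
    """IC = PIV/PTV, HIV = D95%/D5% (always <= 1), and the PTV-Pmap DICE."""

    ic: float
    hiv: float
    dice_ptv_pmap: float


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """DICE overlap 2|A∩B| / (|A|+|B|) between two masks on one lattice.

    Two empty masks return 0.0 by convention (with a warning) so that
    downstream ROC analyses never see a NaN.
    """
    validate_same_lattice([a, b])
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        warnings.warn("dice of two empty masks defined as 0.0", stacklevel=2)
        return 0.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def conformity_index(d: DoseGrid, ptv: BinaryMask, fx: FractionationScheme) -> float:
    """Conformity index IC = PIV / PTV volume.

    PIV (prescription isodose volume) is the volume of the whole grid
    receiving at least the prescription dose (inclusive threshold); it is not
    restricted to a body contour.  IC = 1 means the prescription isodose
    exactly fills the PTV volume; values > 1 indicate spill.
    """
    validate_same_lattice([d, ptv])
    if ptv.voxel_count == 0:
        raise EmptyStructureError("conformity_index: empty PTV")
    piv_voxels = int(np.count_nonzero(d.values >= fx.prescription_dose))
    return piv_voxels / ptv.voxel_count


def heterogeneity_index(
    d: DoseGrid, ptv: BinaryMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> float:
    """Heterogeneity index HIV = D95% / D5% over the PTV.

    Lies in (0, 1] by cumulative-DVH monotonicity: 1 for a perfectly uniform
    PTV dose, smaller as the cold tail deepens.  Undefined (raises) when
    D5% = 0, i.e. the PTV is essentially unirradiated.
    """
    curve = cumulative_dvh(d, ptv, bin_width=bin_width)
    d95 = d_at_volume(curve, 95.0)
    d5 = d_at_volume(curve, 5.0)
    # guard on the true in-mask maximum: sub-bin interpolation can report a
    # spuriously positive D5 on an unirradiated PTV
    if d5 <= 0 or float(d.values[ptv.values].max()) <= 0:
        raise ValueError("heterogeneity_index undefined: D5% is zero")
    return d95 / d5
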