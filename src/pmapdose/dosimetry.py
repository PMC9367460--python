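"""BED conversion and the dose-volume-histogram metric panel.

The panel mirrors routine lung-plan review: per-lung Vx/Dmean/Dmax, combined
lung and heart metrics, spinal-cord maximum, PTV coverage (PTV95), the
conformity and heterogeneity indices, and the mean biologically effective
dose over the Pmap sub-region (the quantity the 30.3 Gy toxicity threshold
applies to).

Conventions: Vx uses an inclusive threshold (dose >= x counts as covered) and
is an exact voxel count, never read off a binned curve; a voxel is in or out
of a structure, with no partial-volume weighting.  Dq% is interpolated on a
cumulative DVH with 0.1 Gy bins by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask, DoseGrid, StructureSet, validate_same_lattice

__all__ = [
    "FractionationScheme",
    "DVHCurve",
    "PlanMetrics",
    "to_bed",
    "cumulative_dvh",
    "v_at_dose",
    "d_at_volume",
    "dose_stats",
    "ptv_coverage",
    "compute_plan_metrics",
    "EmptyStructureError",
]

#: alpha/beta ratio (Gy) for normal tissue and for tumour in the
#: linear-quadratic model.
ALPHA_BETA_NORMAL = 3.0
ALPHA_BETA_TUMOUR = 10.0

DEFAULT_BIN_WIDTH_GY = 0.1


class EmptyStructureError(ValueError):
    """A DVH quantity was requested on an empty structure."""


@dataclass(frozen=True)
class FractionationScheme:
    """Total prescription dose (Gy) delivered in ``n_fractions`` equal fractions."""

    prescription_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0 Gy")
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be >= 1")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        d = self.dose_per_fraction
        if not (0 < d <= 20):
            raise ValueError(f"dose per fraction {d:.2f} Gy outside (0, 20]")

    @property
    def dose_per_fraction(self) -> float:
        return self.prescription_dose / self.n_fractions


def to_bed(d: DoseGrid, fx: FractionationScheme, alpha_beta: float) -> DoseGrid:
    """Convert a physical dose grid to biologically effective dose (BED).

    Uses the linear-quadratic model with the voxel's own per-fraction dose::

        BED(v) = D(v) * (1 + (D(v) / n) / (alpha/beta))

    where ``n`` is the number of fractions.  BED(v) >= D(v) always, with
    equality in the limit alpha/beta -> infinity.
    """
    if d.dose_kind != "physical":
        raise ValueError(f"to_bed expects physical dose, got {d.dose_kind!r}")
    if alpha_beta <= 0:
        raise ValueError("alpha_beta must be > 0 Gy")
    per_fraction = d.values / fx.n_fractions
    bed = d.values * (1.0 + per_fraction / alpha_beta)
    return DoseGrid(d.geometry, bed, dose_kind="BED")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``cum_volume_fraction[k]`` is the fraction of structure voxels receiving
    at least ``dose_edges[k]`` Gy; it starts at 1 and is non-increasing.
    """

    dose_edges: np.ndarray
    cum_volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.cum_volume_fraction = np.asarray(self.cum_volume_fraction, dtype=float)
        if self.dose_edges.shape != self.cum_volume_fraction.shape:
            raise ValueError("dose_edges and cum_volume_fraction lengths differ")
        if self.dose_edges.size < 2:
            raise ValueError("a DVH curve needs at least two edges")
        if self.dose_edges[0] != 0:
            raise ValueError("dose_edges must start at 0 Gy")
        if np.any(np.diff(self.dose_edges) <= 0):
            raise ValueError("dose_edges must be strictly increasing")
        if np.any(np.diff(self.cum_volume_fraction) > 1e-12):
            raise ValueError("cum_volume_fraction must be non-increasing")
        if np.any((self.cum_volume_fraction < 0) | (self.cum_volume_fraction > 1)):
            raise ValueError("cum_volume_fraction must lie in [0, 1]")


def _in_mask_doses(d: DoseGrid, voi: BinaryMask, op_name: str) -> np.ndarray:
    validate_same_lattice([d, voi])
    if voi.voxel_count == 0:
        raise EmptyStructureError(f"{op_name}: empty structure")
    return d.values[voi.values]


def cumulative_dvh(
    d: DoseGrid, voi: BinaryMask, bin_width: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Cumulative DVH of ``voi`` with edges 0, w, 2w, ... past the maximum dose."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0 Gy")
    doses = np.sort(_in_mask_doses(d, voi, "cumulative_dvh"))
    n_bins = int(np.ceil(doses[-1] / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    # fraction with dose >= edge, inclusive: count via left-side binary search
    frac = 1.0 - np.searchsorted(doses, edges, side="left") / doses.size
    return DVHCurve(edges, frac)


def v_at_dose(d: DoseGrid, voi: BinaryMask, x: float) -> float:
    """Vx: percent of the structure receiving at least ``x`` Gy (exact count)."""
    doses = _in_mask_doses(d, voi, "v_at_dose")
    return 100.0 * float(np.count_nonzero(doses >= x)) / doses.size


def d_at_volume(curve: DVHCurve, q: float) -> float:
    """Dq%: dose (Gy) received by at least ``q`` percent of the structure.

    The largest dose whose cumulative volume fraction is still >= q/100,
    linearly interpolated between the bracketing DVH edges; accurate to one
    bin width.  Monotone non-increasing in q.
    """
    if not (0 < q <= 100):
        raise ValueError("q must be in (0, 100]")
    p = q / 100.0
    e = curve.dose_edges
    f = curve.cum_volume_fraction
    above = np.nonzero(f >= p)[0]
    if above.size == 0:
        return float(e[0])
    j = int(above[-1])
    if j == e.size - 1 or f[j] == f[j + 1]:
        return float(e[j])
    # interpolate down from (e[j], f[j]) to (e[j+1], f[j+1]) where f drops below p
    t = (p - f[j]) / (f[j + 1] - f[j])
    return float(e[j] + t * (e[j + 1] - e[j]))


def dose_stats(d: DoseGrid, voi: BinaryMask) -> tuple[float, float]:
    """(Dmean, Dmax) in Gy over the structure voxels."""
    doses = _in_mask_doses(d, voi, "dose_stats")
    return float(np.mean(doses)), float(np.max(doses))


def ptv_coverage(d: DoseGrid, ptv: BinaryMask, fx: FractionationScheme) -> float:
    """PTV95: percent of the PTV receiving >= 95% of the prescription dose."""
    if d.dose_kind != "physical":
        raise ValueError("ptv_coverage is defined on physical dose")
    return v_at_dose(d, ptv, 0.95 * fx.prescription_dose)


# The Table-1-style panel: Vx thresholds (Gy) plus Dmean/Dmax per structure.
_PANEL_VX = {
    "LungH": (5, 10, 13, 20, 30),
    "LungC": (5, 10, 13, 20, 30),
    "2Lungs": (13, 20, 30),
    "Heart": (30, 40),
}
_PANEL_DMEAN = ("LungH", "LungC", "2Lungs", "Heart")
_PANEL_DMAX = ("LungH", "LungC", "SpinalCord")


@dataclass
class PlanMetrics:
    """Flat metric panel for one plan of one patient.

    Keys follow ``<VOI>_<metric>`` (e.g. ``LungH_V20``, ``SpinalCord_Dmax``),
    plus ``PTV95``, ``IC``, ``HIV`` and ``Pmap_Dmean_BED``.  Vx values are
    percentages on the 0-100 scale; doses are Gy.
    """

    values: dict[str, float] = field(default_factory=dict)

    @property
    def ptv95(self) -> float:
        return self.values["PTV95"]

    @property
    def dmean_pmap_bed(self) -> float:
        return self.values["Pmap_Dmean_BED"]

    @property
    def ic(self) -> float:
        return self.values["IC"]

    @property
    def hiv(self) -> float:
        return self.values["HIV"]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def compute_plan_metrics(
    d: DoseGrid,
    ss: StructureSet,
    fx: FractionationScheme,
    *,
    alpha_beta_normal: float = ALPHA_BETA_NORMAL,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
    all_bed: bool = False,
) -> PlanMetrics:
    """Evaluate the full plan panel on one physical dose grid.

    The Pmap mean dose is computed on the BED grid (normal-tissue alpha/beta,
    3 Gy by default) because the 30.3 Gy decision threshold is a BED value;
    every other organ-at-risk metric is reported on physical dose unless
    ``all_bed`` is set, in which case the whole organ panel switches to BED
    (PTV95, IC and HIV stay physical — they are prescription-relative).
    """
    from .indices import conformity_index, heterogeneity_index  # cycle guard

    if d.dose_kind != "physical":
        raise ValueError("compute_plan_metrics expects a physical dose grid")
    ss.require()
    validate_same_lattice([d] + [ss[name] for name in ("PTV", "Pmap")])

    bed = to_bed(d, fx, alpha_beta_normal)
    oar_grid = bed if all_bed else d

    out: dict[str, float] = {}
    out["PTV95"] = ptv_coverage(d, ss["PTV"], fx)
    for voi, thresholds in _PANEL_VX.items():
        for x in thresholds:
            out[f"{voi}_V{x}"] = v_at_dose(oar_grid, ss[voi], x)
    for voi in _PANEL_DMEAN:
        out[f"{voi}_Dmean"] = dose_stats(oar_grid, ss[voi])[0]
    for voi in _PANEL_DMAX:
        out[f"{voi}_Dmax"] = dose_stats(oar_grid, ss[voi])[1]
    out["Pmap_Dmean_BED"] = dose_stats(bed, ss["Pmap"])[0]
    out["IC"] = conformity_index(d, ss["PTV"], fx)
    try:
        out["HIV"] = heterogeneity_index(d, ss["PTV"], bin_width=bin_width)
    except ValueError:
        # an essentially unirradiated PTV has no defined D95/D5 ratio
        warnings.warn("HIV undefined (D5% = 0); reporting NaN", stacklevel=2)
        out["HIV"] = float("nan")
    return PlanMetrics(out)
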