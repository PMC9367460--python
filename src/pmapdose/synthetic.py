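"""Synthetic thoracic phantom, paired dose maps and patient cohorts.

Nothing in the real study's inputs is public: planning CTs, dose grids and
clinical tables are all private.  This module therefore generates, from a
single master seed, everything the pipeline consumes:

* a geometric thoracic phantom — lung ellipsoids, heart ellipsoid, spinal
  cord cylinder, a spherical PTV inside the homolateral (right) lung and the
  Pmap sub-region as a box in the posterior right lung;
* paired "initial" and "optimized" dose maps.  The inverse VMAT optimisation
  itself is out of scope; the painter emulates its *outcome* by direct dose
  sculpting: a prescription-level PTV dose with a blurred penumbra, a
  posterior dose bath raising the Pmap mean dose, and, for the optimised
  plan, a smooth attenuation field centred on Pmap that spares the
  sub-region while leaving PTV voxel doses untouched;
* synthetic patient cohorts: per-patient anatomy jitter, dose painting, the
  full metric panel, clinical covariates and an APT outcome drawn from an
  explicit logistic model, so every cohort branch (1, 2, 3, excluded) is
  exercised and model-recovery experiments have a known ground truth.

Everything is deterministic under the master seed, with hierarchical
per-patient seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cohort import ConstraintSet, DEFAULT_CONSTRAINTS, PatientRecord, label_record
from .dosimetry import FractionationScheme, compute_plan_metrics
from .grid import BinaryMask, DoseGrid, GridGeometry, StructureSet
from .indices import dice
from .risk import (
    FEATURE_ORDER,
    ClinicalFeatures,
    RiskFeatureVector,
    RiskModel,
    predict_prob_apt,
)

__all__ = [
    "PhantomSpec",
    "PlanPainterSpec",
    "CohortGeneratorSpec",
    "DEFAULT_OUTCOME_MODEL",
    "generate_phantom",
    "paint_plan_pair",
    "generate_cohort",
    "sample_feature_table",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric thoracic phantom on a 64x64x64, 4 mm isotropic lattice.

    Coordinates are voxel indices (z, y, x); y grows toward posterior and x
    toward the patient's left, so the homolateral lung (LungH, containing the
    PTV and Pmap) is the low-x, right lung.  Ellipsoid/sphere parameters are
    (center, radii) in voxels.
    """

    geometry: GridGeometry = GridGeometry((64, 64, 64), (4.0, 4.0, 4.0))
    lungh_center: tuple[float, float, float] = (32, 32, 20)
    lungh_radii: tuple[float, float, float] = (24, 14, 10)
    lungc_center: tuple[float, float, float] = (32, 32, 44)
    lungc_radii: tuple[float, float, float] = (24, 14, 10)
    heart_center: tuple[float, float, float] = (28, 26, 36)
    heart_radii: tuple[float, float, float] = (9, 8, 9)
    cord_yx: tuple[float, float] = (52, 32)
    cord_radius: float = 2.0
    ptv_center: tuple[float, float, float] = (32, 30, 20)
    ptv_radius: float = 5.0
    pmap_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (26, 38),
        (38, 45),
        (14, 26),
    )
    seed: int = 0


def _ellipsoid(geometry: GridGeometry, center, radii) -> np.ndarray:
    if any(r <= 0 for r in radii):
        raise ValueError(f"ellipsoid radii must be positive, got {radii}")
    idx = np.indices(geometry.shape, dtype=float)
    r2 = sum(((idx[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> StructureSet:
    """Build the phantom structure set; deterministic for a given spec.

    Validates the anatomical invariants: PTV inside LungH, Pmap inside the
    posterior half of LungH, spinal cord disjoint from both lungs, all
    structures within the grid.
    """
    geo = spec.geometry
    if spec.ptv_radius <= 0:
        raise ValueError("ptv_radius must be > 0")
    heart = _ellipsoid(geo, spec.heart_center, spec.heart_radii)
    lungh = _ellipsoid(geo, spec.lungh_center, spec.lungh_radii) & ~heart
    lungc = _ellipsoid(geo, spec.lungc_center, spec.lungc_radii) & ~heart

    zz, yy, xx = np.indices(geo.shape, dtype=float)
    cord = ((yy - spec.cord_yx[0]) ** 2 + (xx - spec.cord_yx[1]) ** 2) <= spec.cord_radius**2
    cord &= ~(lungh | lungc)

    ptv = _ellipsoid(geo, spec.ptv_center, (spec.ptv_radius,) * 3)
    (z0, z1), (y0, y1), (x0, x1) = spec.pmap_bounds
    pmap_box = np.zeros(geo.shape, dtype=bool)
    pmap_box[z0:z1, y0:y1, x0:x1] = True
    pmap = pmap_box & lungh  # keep the sub-region inside lung tissue

    if not np.all(lungh[ptv]):
        raise ValueError("phantom invariant violated: PTV not inside LungH")
    if pmap.sum() == 0:
        raise ValueError("phantom invariant violated: Pmap empty")
    if np.any(np.argwhere(pmap)[:, 1] < spec.lungh_center[1]):
        raise ValueError("phantom invariant violated: Pmap not in posterior half")
    if np.any(cord & (lungh | lungc)):
        raise ValueError("phantom invariant violated: cord intersects lungs")

    masks = {
        "PTV": ptv,
        "LungH": lungh,
        "LungC": lungc,
        "Heart": heart,
        "SpinalCord": cord,
        "Pmap": pmap,
    }
    return StructureSet(geo, {k: BinaryMask(geo, v) for k, v in masks.items()})


@dataclass(frozen=True)
class PlanPainterSpec:
    """Dose-painting parameters emulating a VMAT plan pair.

    posterior_spill scales a broad Gaussian dose bath (relative to the
    prescription) centred on the Pmap sub-region — it controls the initial
    Pmap mean dose.  pmap_reduction_target is the fractional reduction of the
    Pmap physical mean dose the emulated optimisation aims for; voxel doses
    inside the PTV are preserved exactly, so the achieved reduction falls
    short of the target where PTV and Pmap overlap (that shortfall is the
    mechanism making high PTV-Pmap DICE plans fail adjudication).
    """

    fx: FractionationScheme = FractionationScheme(66.0, 33)
    normalization: float = 1.02  # plan renormalization: interior dose / prescription
    penumbra_sigma: float = 3.0  # mm
    posterior_spill: float = 0.52
    spill_sigma: float = 40.0  # mm
    pmap_reduction_target: float = 0.30
    attenuation_sigma: float = 25.0  # mm falloff of the sparing field
    noise_sd: float = 0.5  # Gy
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pmap_reduction_target < 1):
            raise ValueError("pmap_reduction_target must be in [0, 1)")
        if self.posterior_spill < 0 or self.noise_sd < 0:
            raise ValueError("posterior_spill and noise_sd must be >= 0")


def paint_plan_pair(
    ss: StructureSet, spec: PlanPainterSpec = PlanPainterSpec()
) -> tuple[DoseGrid, DoseGrid]:
    """Paint a (initial, optimized) physical dose pair on the phantom lattice.

    Initial plan: prescription dose inside a dilated, Gaussian-blurred PTV,
    plus the posterior spill bath, plus seeded voxel noise.  Optimised plan:
    the same deterministic dose multiplied by a smooth attenuation field that
    equals ``1 - pmap_reduction_target`` over the (dilated) Pmap region and
    relaxes to 1 over ``attenuation_sigma``; PTV voxels are reset to their
    initial deterministic values, then independent noise of the same
    amplitude is added.  Both grids are clipped at 0 Gy.
    """
    geo = ss.geometry
    spacing = np.asarray(geo.spacing)
    rng = np.random.default_rng(spec.seed)
    rx = spec.fx.prescription_dose

    ptv = ss["PTV"].values
    pmap = ss["Pmap"].values
    sigma_vox = spec.penumbra_sigma / spacing
    target = ndimage.binary_dilation(ptv, iterations=2)
    base = spec.normalization * rx * ndimage.gaussian_filter(target.astype(float), sigma=sigma_vox)

    centers = geo.voxel_centers()
    pmap_centroid_world = np.asarray(geo.origin) + spacing * ss["Pmap"].centroid_index()
    r2 = np.sum((centers - pmap_centroid_world) ** 2, axis=-1)
    bath = np.exp(-r2 / (2.0 * spec.spill_sigma**2))
    # voxelwise max, not sum: the bath fills in around the target without
    # stacking a hot spot on top of the prescription dose
    deterministic = np.maximum(base, spec.posterior_spill * rx * bath)

    spared = deterministic.copy()
    if spec.pmap_reduction_target > 0:
        pmap_dilated = ndimage.binary_dilation(pmap, iterations=1)
        dist_mm = ndimage.distance_transform_edt(~pmap_dilated, sampling=geo.spacing)
        profile = np.exp(-(dist_mm**2) / (2.0 * spec.attenuation_sigma**2))
        spared = deterministic * (1.0 - spec.pmap_reduction_target * profile)
        spared[ptv] = deterministic[ptv]  # PTV coverage is never traded away

    noise_i = rng.normal(0.0, spec.noise_sd, geo.shape) if spec.noise_sd else 0.0
    noise_o = rng.normal(0.0, spec.noise_sd, geo.shape) if spec.noise_sd else 0.0
    initial = np.clip(deterministic + noise_i, 0.0, None)
    optimized = np.clip(spared + noise_o, 0.0, None)
    return DoseGrid(geo, initial), DoseGrid(geo, optimized)


#: Generative APT outcome model used by default for synthetic cohorts.  The
#: Pmap mean BED dose dominates; binary comorbidity indicators carry sizeable
#: weights so that low-dose patients can still be at high predicted risk.
DEFAULT_OUTCOME_MODEL = RiskModel(
    kind="logistic_surrogate",
    intercept=-12.5,
    weights={
        "dmean_pmap_bed": 0.35,
        "dmean_2lungs": 0.08,
        "v30_2lungs": 0.03,
        "smoking_status": 2.0,
        "mevs": -0.06,
        "copd": 3.0,
        "v10_lungh": 0.01,
        "ajcc_stage": 0.5,
        "v5_lungh": 0.005,
        "dmean_lungh": 0.02,
        "v40_heart": 0.03,
    },
)

#: Marginal distributions of the clinical covariates (typical locally
#: advanced lung-cancer population: mostly smokers, a third with COPD,
#: moderately impaired expiratory function, stage III disease).
CLINICAL_DISTRIBUTIONS = {
    "smoking_p": 0.7,
    "copd_p": 0.35,
    "mevs_mean": 70.0,
    "mevs_sd": 15.0,
    "stage_labels": ("IIIA", "IIIB", "IIIC"),
    "stage_probs": (0.5, 0.4, 0.1),
}

#: Clinical overrides for the low-dose stratum: patients whose plans kept the
#: posterior lung cold tend to be the frailer ones (confounding by
#: indication), which is what lets a patient sit below the 30.3 Gy Pmap
#: threshold yet above the 8% predicted-risk cutoff.
LOW_STRATUM_CLINICAL = {
    "smoking_p": 0.95,
    "copd_p": 0.8,
    "mevs_mean": 48.0,
}


@dataclass(frozen=True)
class CohortGeneratorSpec:
    """Cohort size, covariate distributions and the generative outcome model.

    ``spill_high``/``spill_low`` are the two modes of the posterior-spill
    mixture; the high mode produces initial Pmap mean BED doses around 40 Gy
    (clearly above the 30.3 Gy threshold), the low mode around 15 Gy, so a
    default cohort populates Cohorts 1-3 and the excluded branch.
    """

    n: int = 100
    seed: int = 0
    outcome_model: RiskModel = field(default_factory=lambda: DEFAULT_OUTCOME_MODEL)
    clinical: dict = field(default_factory=lambda: dict(CLINICAL_DISTRIBUTIONS))
    high_fraction: float = 0.55
    spill_high: tuple[float, float] = (0.52, 0.045)
    spill_low: tuple[float, float] = (0.22, 0.04)
    reduction_target: tuple[float, float] = (0.35, 0.05)
    ptv_jitter: tuple[int, int, int] = (3, 6, 2)  # max |dz|, dy posterior reach, |dx|

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if not (0 <= self.high_fraction <= 1):
            raise ValueError("high_fraction must be a probability")


def _sample_features(rng: np.random.Generator, clinical: dict) -> ClinicalFeatures:
    mevs = float(np.clip(rng.normal(clinical["mevs_mean"], clinical["mevs_sd"]), 20, 130))
    return ClinicalFeatures(
        smoking_status=int(rng.random() < clinical["smoking_p"]),
        copd=int(rng.random() < clinical["copd_p"]),
        mevs=mevs,
        ajcc_stage=str(rng.choice(clinical["stage_labels"], p=clinical["stage_probs"])),
    )


def _feature_vector(features: ClinicalFeatures, metrics) -> RiskFeatureVector:
    return RiskFeatureVector(
        dmean_pmap_bed=metrics["Pmap_Dmean_BED"],
        dmean_2lungs=metrics["2Lungs_Dmean"],
        v30_2lungs=metrics["2Lungs_V30"],
        smoking_status=features.smoking_status,
        mevs=features.mevs,
        copd=features.copd,
        v10_lungh=metrics["LungH_V10"],
        ajcc_stage=features.ajcc_stage,
        v5_lungh=metrics["LungH_V5"],
        dmean_lungh=metrics["LungH_Dmean"],
        v40_heart=metrics["Heart_V40"],
    )


def _jittered_phantom(
    rng: np.random.Generator, base: PhantomSpec, jitter: tuple[int, int, int]
) -> StructureSet:
    """Per-patient anatomy: shift and rescale the PTV, shrinking the shift on
    the rare draws that would push it out of the lung."""
    dz = int(rng.integers(-jitter[0], jitter[0] + 1))
    dy = int(rng.integers(-2, jitter[1] + 1))  # biased toward posterior reach
    dx = int(rng.integers(-jitter[2], jitter[2] + 1))
    radius = float(rng.choice((4.0, 5.0, 6.0)))
    cz, cy, cx = base.ptv_center
    for shrink in (1.0, 0.5, 0.0):
        spec = replace(
            base,
            ptv_center=(cz + dz * shrink, cy + dy * shrink, cx + dx * shrink),
            ptv_radius=radius if shrink else base.ptv_radius,
        )
        try:
            return generate_phantom(spec)
        except ValueError:
            continue
    return generate_phantom(base)


def generate_cohort(
    spec: CohortGeneratorSpec = CohortGeneratorSpec(),
    phantom_spec: PhantomSpec = PhantomSpec(),
    painter_spec: PlanPainterSpec = PlanPainterSpec(),
    constraints: ConstraintSet = DEFAULT_CONSTRAINTS,
) -> list[PatientRecord]:
    """Generate, paint, measure and label ``spec.n`` synthetic patients.

    Per patient (hierarchically seeded from the master seed): clinical
    covariates; a jittered phantom; a plan pair with its own spill and
    reduction-target draws; the full metric panel on both plans; predicted
    APT probabilities from the generative model; an observed APT outcome
    drawn from the initial-plan probability; then success adjudication and
    cohort assignment.
    """
    master = np.random.SeedSequence(spec.seed)
    records: list[PatientRecord] = []
    for i, child in enumerate(master.spawn(spec.n)):
        rng = np.random.default_rng(child)
        is_high = rng.random() < spec.high_fraction
        clinical = dict(spec.clinical)
        if not is_high:
            clinical.update(LOW_STRATUM_CLINICAL)
        features = _sample_features(rng, clinical)
        ss = _jittered_phantom(rng, phantom_spec, spec.ptv_jitter)

        mode = spec.spill_high if is_high else spec.spill_low
        spill = float(np.clip(rng.normal(*mode), 0.05, 1.0))
        target = float(np.clip(rng.normal(*spec.reduction_target), 0.10, 0.60))
        painter = replace(
            painter_spec,
            posterior_spill=spill,
            pmap_reduction_target=target,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        d_ini, d_opt = paint_plan_pair(ss, painter)
        m_ini = compute_plan_metrics(d_ini, ss, painter.fx)
        m_opt = compute_plan_metrics(d_opt, ss, painter.fx)

        prob_ini = predict_prob_apt(_feature_vector(features, m_ini), spec.outcome_model)
        prob_opt = predict_prob_apt(_feature_vector(features, m_opt), spec.outcome_model)
        record = PatientRecord(
            id=f"SYN{i:04d}",
            features=features,
            metrics_initial=m_ini,
            metrics_optimized=m_opt,
            prob_initial=prob_ini,
            prob_optimized=prob_opt,
            dice_ptv_pmap=dice(ss["PTV"], ss["Pmap"]),
            apt_observed=int(rng.random() < prob_ini),
        )
        records.append(label_record(record, constraints))
    return records


#: Parametric marginals for the fast, image-free feature sampler.
TABLE_MARGINALS = {
    "dmean_2lungs": (15.0, 2.5),
    "v30_2lungs": (15.0, 4.0),
    "v10_lungh": (56.0, 8.0),
    "v5_lungh": (65.0, 8.0),
    "dmean_lungh": (21.0, 3.0),
    "v40_heart": (4.0, 2.0),
}


def sample_feature_table(
    n: int,
    seed: int,
    outcome_model: RiskModel = DEFAULT_OUTCOME_MODEL,
    high_fraction: float = 0.55,
):
    """Sample an 11-feature table plus APT outcomes without dose painting.

    Dosimetric features come from parametric marginals matched to what the
    painter produces (Pmap mean BED dose as a two-component normal mixture
    straddling the 30.3 Gy threshold); outcomes are Bernoulli draws from
    ``outcome_model``.  This is the fast path for model-recovery experiments
    at cohort sizes where painting every patient would be wasteful.
    """
    import pandas as pd

    from .risk import predict_prob_table

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    clinical = CLINICAL_DISTRIBUTIONS
    high = rng.random(n) < high_fraction
    dmean_pmap = np.where(high, rng.normal(40.0, 4.4, n), rng.normal(14.6, 3.5, n))
    cols = {"dmean_pmap_bed": np.clip(dmean_pmap, 1.0, None)}
    for name, (mu, sd) in TABLE_MARGINALS.items():
        cols[name] = np.clip(rng.normal(mu, sd, n), 0.0, None)
    cols["smoking_status"] = (rng.random(n) < clinical["smoking_p"]).astype(int)
    cols["copd"] = (rng.random(n) < clinical["copd_p"]).astype(int)
    cols["mevs"] = np.clip(rng.normal(clinical["mevs_mean"], clinical["mevs_sd"], n), 20, 130)
    cols["ajcc_stage"] = rng.choice(
        clinical["stage_labels"], size=n, p=clinical["stage_probs"]
    )
    df = pd.DataFrame(cols)[list(FEATURE_ORDER)]
    probs = predict_prob_table(df, outcome_model)
    df["apt"] = (rng.random(n) < probs).astype(int)
    return df
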