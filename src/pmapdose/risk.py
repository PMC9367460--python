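"""Acute-pulmonary-toxicity (APT) risk model interface and classifiers.

The published APT model combines the mean BED dose to the Pmap sub-region
with ten further clinical and dosimetric features; its internals (an ensemble
with reported feature importances) were never released.  This module
therefore exposes a pluggable interface with three backends:

* ``threshold_only`` — the bare decision rules (DMeanPmap >= 30.3 Gy BED,
  predicted probability >= 8%), usable without any fitted model;
* ``logistic_surrogate`` — a maximum-likelihood logistic model over the same
  11 features, used for synthetic studies and testing (it makes no claim to
  reproduce the original model's probabilities);
* ``external`` — weights loaded from JSON for a model fitted elsewhere.

Both decision thresholds are inclusive (>=).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_ORDER",
    "DEFAULT_STAGE_ENCODING",
    "ClinicalFeatures",
    "RiskFeatureVector",
    "RiskModel",
    "classify_by_dmean",
    "classify_by_prob",
    "predict_prob_apt",
    "fit_surrogate",
]

#: The 11 model features, in fixed order (most important first).
FEATURE_ORDER = (
    "dmean_pmap_bed",
    "dmean_2lungs",
    "v30_2lungs",
    "smoking_status",
    "mevs",
    "copd",
    "v10_lungh",
    "ajcc_stage",
    "v5_lungh",
    "dmean_lungh",
    "v40_heart",
)

#: Ordinal encoding for AJCC stage; override via RiskModel.stage_encoding.
DEFAULT_STAGE_ENCODING = {"I": 0, "II": 1, "IIIA": 2, "IIIB": 3, "IIIC": 4, "IV": 5}

DMEAN_THRESHOLD_GY = 30.3
PROB_THRESHOLD = 0.08


@dataclass(frozen=True)
class ClinicalFeatures:
    """Patient-level clinical covariates.

    smoking_status / copd are 0-1 indicators; mevs is the mean expiratory
    volume per second as percent of the theoretical value; ajcc_stage is a
    category key of the stage encoding.
    """

    smoking_status: int
    copd: int
    mevs: float
    ajcc_stage: str

    def __post_init__(self) -> None:
        if self.smoking_status not in (0, 1) or self.copd not in (0, 1):
            raise ValueError("smoking_status and copd must be 0/1")
        if not (0 < self.mevs <= 200):
            raise ValueError(f"mevs must be in (0, 200], got {self.mevs}")


@dataclass(frozen=True)
class RiskFeatureVector:
    """The 11-feature input of the APT model (doses Gy, Vx percent)."""

    dmean_pmap_bed: float
    dmean_2lungs: float
    v30_2lungs: float
    smoking_status: int
    mevs: float
    copd: int
    v10_lungh: float
    ajcc_stage: str
    v5_lungh: float
    dmean_lungh: float
    v40_heart: float

    def encoded(self, stage_encoding: dict[str, int] | None = None) -> np.ndarray:
        """Numeric vector in FEATURE_ORDER with the stage ordinally encoded."""
        enc = stage_encoding or DEFAULT_STAGE_ENCODING
        out = []
        for name in FEATURE_ORDER:
            v = getattr(self, name)
            if name == "ajcc_stage":
                if isinstance(v, str):
                    if v not in enc:
                        raise ValueError(f"unknown AJCC stage {v!r}")
                    v = enc[v]
            out.append(float(v))
        return np.asarray(out)


@dataclass
class RiskModel:
    """Pluggable APT probability model plus the two decision thresholds."""

    kind: str = "threshold_only"
    weights: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    prob_threshold: float = PROB_THRESHOLD
    dmean_threshold: float = DMEAN_THRESHOLD_GY
    stage_encoding: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_STAGE_ENCODING))
    importance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("threshold_only", "logistic_surrogate", "external"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not (0 < self.prob_threshold < 1):
            raise ValueError("prob_threshold must be in (0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "feature_order": list(FEATURE_ORDER),
            "weights": self.weights,
            "intercept": self.intercept,
            "prob_threshold": self.prob_threshold,
            "dmean_threshold": self.dmean_threshold,
            "stage_encoding": self.stage_encoding,
            "importance": self.importance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        payload.pop("feature_order", None)
        return cls(**payload)


def classify_by_dmean(dmean_pmap_bed: float, threshold: float = DMEAN_THRESHOLD_GY) -> str:
    """'high' iff the Pmap mean BED dose is >= the threshold (inclusive)."""
    if not np.isfinite(dmean_pmap_bed):
        raise ValueError("dmean_pmap_bed must be finite")
    return "high" if dmean_pmap_bed >= threshold else "low"


def classify_by_prob(p: float, threshold: float = PROB_THRESHOLD) -> str:
    """'high' iff the predicted APT probability is >= the threshold (inclusive)."""
    if not (0 <= p <= 1):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return "high" if p >= threshold else "low"


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def predict_prob_apt(f: RiskFeatureVector, m: RiskModel) -> float:
    """APT probability for one feature vector under a weighted model.

    ``threshold_only`` models carry no probability surface and raise; use
    :func:`classify_by_dmean` with them instead.
    """
    if m.kind == "threshold_only":
        raise ValueError("threshold_only models do not produce probabilities")
    missing = [n for n in FEATURE_ORDER if n not in m.weights]
    if missing:
        raise ValueError(f"model is missing weights for features: {missing}")
    x = f.encoded(m.stage_encoding)
    w = np.asarray([m.weights[n] for n in FEATURE_ORDER])
    return float(_logistic(m.intercept + float(w @ x)))


def predict_prob_table(df: pd.DataFrame, m: RiskModel) -> np.ndarray:
    """Vectorised probabilities for a DataFrame with the 11 feature columns."""
    x = _encode_frame(df, m.stage_encoding)
    w = np.asarray([m.weights[n] for n in FEATURE_ORDER])
    return np.asarray(_logistic(m.intercept + x @ w))


def _encode_frame(df: pd.DataFrame, stage_encoding: dict[str, int]) -> np.ndarray:
    missing = [n for n in FEATURE_ORDER if n not in df.columns]
    if missing:
        raise ValueError(f"table is missing feature columns: {missing}")
    cols = []
    for name in FEATURE_ORDER:
        col = df[name]
        if name == "ajcc_stage" and col.dtype == object:
            unknown = set(col) - set(stage_encoding)
            if unknown:
                raise ValueError(f"unknown AJCC stages {sorted(unknown)}")
            col = col.map(stage_encoding)
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_surrogate(
    cohort: pd.DataFrame,
    outcome_col: str = "apt",
    stage_encoding: dict[str, int] | None = None,
) -> RiskModel:
    """Fit the logistic surrogate by maximum likelihood on a feature table.

    ``cohort`` must hold the 11 feature columns plus a binary outcome column.
    Requires at least 50 records with both outcome classes present.  The
    fitted model also reports per-feature standardised |weight| shares as an
    importance analogue (weight times in-sample feature SD, normalised to
    sum to 1).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    enc = stage_encoding or DEFAULT_STAGE_ENCODING
    y = cohort[outcome_col].to_numpy(dtype=float)
    if len(y) < 50:
        raise ValueError(f"need >= 50 records to fit the surrogate, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit is degenerate")
    x = _encode_frame(cohort, enc)
    design = sm.add_constant(x, has_constant="add")
    try:
        result = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(f"degenerate design or separation in logistic fit: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge (separation or collinearity?)")
    params = np.asarray(result.params)
    weights = {name: float(w) for name, w in zip(FEATURE_ORDER, params[1:])}
    sds = x.std(axis=0, ddof=1)
    raw = np.abs(params[1:]) * sds
    shares = raw / raw.sum() if raw.sum() > 0 else raw
    importance = {name: float(s) for name, s in zip(FEATURE_ORDER, shares)}
    return RiskModel(
        kind="logistic_surrogate",
        weights=weights,
        intercept=float(params[0]),
        stage_encoding=dict(enc),
        importance=importance,
    )
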