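"""Predictiveness-score construction and patient classification.

The top-ranked modulator gene V is turned into a linear predictiveness
score  PS = slope * V + intercept  by ordinary least squares of the OS
hazard-ratio difference on the per-cancer median expression of V, with
leave-one-out cross-validation as an out-of-sample diagnostic.  Patients
are then scored from their own expression of V and bifurcated into
Predictiveness-High (PH, score >= reference median) and
Predictiveness-Low (PL).  With a negative fitted slope — the empirically
relevant orientation — PH corresponds to *low* modulator expression.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .stats import ValidationError

__all__ = ["ScoreModel", "fit_ps_model", "score_and_split"]

REFERENCES = ("TREATED_ARM", "ITT")


@dataclass(frozen=True)
class ScoreModel:
    """Linear predictiveness-score model for one gene."""

    gene: str
    slope: float
    intercept: float
    loocv_rmse: float
    n_points: int

    def predict(self, expression) -> np.ndarray:
        return self.slope * np.asarray(expression, dtype=float) + self.intercept

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ScoreModel":
        return cls(**json.loads(s))


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)


def fit_ps_model(medians: pd.Series, hrd: pd.Series,
                 gene: str = "") -> ScoreModel:
    """OLS fit of per-cancer HRD on per-cancer gene medians, with LOOCV.

    ``loocv_rmse`` is the root mean square of the leave-one-out prediction
    errors, each obtained by refitting the line without that cancer.
    """
    shared = sorted(set(medians.index) & set(hrd.index))
    x = medians.loc[shared].to_numpy(dtype=float)
    y = hrd.loc[shared].to_numpy(dtype=float)
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 cancers with both values, "
                              f"found {len(shared)}")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in the predictor medians")
    slope, intercept = _ols_line(x, y)
    errs = []
    for i in range(len(x)):
        mask = np.arange(len(x)) != i
        if np.ptp(x[mask]) == 0:
            raise ValidationError("leave-one-out subset has constant predictor")
        s_i, b_i = _ols_line(x[mask], y[mask])
        errs.append(y[i] - (s_i * x[i] + b_i))
    rmse = float(np.sqrt(np.mean(np.square(errs))))
    return ScoreModel(gene=gene or str(medians.name or ""), slope=slope,
                      intercept=intercept, loocv_rmse=rmse, n_points=len(x))


def score_and_split(clinical: pd.DataFrame, expression: pd.DataFrame,
                    model: ScoreModel,
                    reference: str = "TREATED_ARM") -> pd.DataFrame:
    """Score patients and split them into PH/PL at the reference median.

    The cutoff is the median score of the reference population: the
    ICI-treated arm (``TREATED_ARM``, single-arm analyses) or all patients
    (``ITT``, arm-comparison analyses).  Patients with score >= cutoff are
    PH.  Returns patient_id, ps, group, cutoff_used, reference_population.
    """
    if reference not in REFERENCES:
        raise ValidationError(f"reference must be one of {REFERENCES}")
    if model.gene not in expression.index:
        raise ValidationError(f"model gene '{model.gene}' absent from panel")
    patients = clinical["patient_id"].tolist()
    expr = expression.loc[model.gene, patients].to_numpy(dtype=float)
    if np.ptp(expr) == 0:
        raise ValidationError(
            "all patients share one expression value: median split impossible")
    ps = model.predict(expr)
    if reference == "TREATED_ARM":
        mask = (clinical["arm"] == "ICI").to_numpy()
        if not mask.any():
            raise ValidationError("no ICI-arm patients for TREATED_ARM reference")
    else:
        mask = np.ones(len(clinical), dtype=bool)
    cutoff = float(np.median(ps[mask]))
    out = pd.DataFrame({
        "patient_id": patients,
        "ps": ps,
        "group": np.where(ps >= cutoff, "PH", "PL"),
        "cutoff_used": cutoff,
        "reference_population": reference,
    })
    return out
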