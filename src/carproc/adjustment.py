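"""Age-and-gender adjustment and the percentile rank transformation.

A proxy is *adjusted* by taking the residual of an ordinary-least-squares
regression of the (optionally log-transformed) proxy on continuous age and a
male indicator, fitted on a reference cohort.  Adjusted values are therefore
uncorrelated with age and gender on the fitting cohort.  The *adjusted
percentile rank transform* (aPRT) re-expresses adjusted values as midrank
percentiles 100 * (rank - 0.5) / n, mapping any variable onto (0, 100) with
mean 50 in the absence of ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from carproc.proxies import LOG_PROXIES, PROXY_NAMES

#: Variables adjusted by default: the 16 proxies plus BMI (needed for BMI_aPRT).
DEFAULT_ADJUST_VARS: tuple[str, ...] = (*PROXY_NAMES, "bmi")


def assign_bmi_group(bmi) -> np.ndarray | str:
    """Classify BMI (kg/m^2) into 'NW' (< 25), 'OW' (25 <= BMI < 30) or
    'OB' (>= 30).  Accepts a scalar or an array; intervals closed on the left.
    """
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("BMI values must be finite and positive")
    labels = np.where(arr < 25.0, "NW", np.where(arr < 30.0, "OW", "OB"))
    if np.isscalar(bmi) or arr.ndim == 0:
        return str(labels)
    return labels


@dataclass
class ProxyAdjustment:
    """OLS sub-model for a single variable: value ~ intercept + age + male."""

    intercept: float
    age_coef: float
    gender_coef: float
    residual_scale: float
    log_transform: bool = False


@dataclass
class AdjustmentModel:
    """Per-variable age/gender adjustment models fitted on a reference cohort."""

    models: dict[str, ProxyAdjustment]
    reference: str = ""
    age_se: dict[str, float] = field(default_factory=dict)

    def variables(self) -> list[str]:
        return list(self.models)

    def to_json(self, path) -> None:
        payload = {
            "reference": self.reference,
            "models": {
                name: {
                    "intercept": m.intercept,
                    "age_coef": m.age_coef,
                    "gender_coef": m.gender_coef,
                    "residual_scale": m.residual_scale,
                    "log_transform": m.log_transform,
                }
                for name, m in self.models.items()
            },
            "age_se": self.age_se,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "AdjustmentModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        models = {name: ProxyAdjustment(**m) for name, m in payload["models"].items()}
        return cls(models=models, reference=payload.get("reference", ""),
                   age_se=payload.get("age_se", {}))


def fit_adjustment(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_ADJUST_VARS,
    log_transform: bool = True,
    reference: str = "",
) -> AdjustmentModel:
    """Fit one OLS age+gender model per variable on ``cohort``.

    ``log_transform=True`` log-transforms the right-skewed power proxies
    (RR TP, RR LFa, RR HFa, SAP LFa) before fitting; the flag is stored in the
    model so scoring applies the same pre-transform.
    """
    if len(cohort) < 30:
        raise ValueError("adjustment requires at least 30 subjects")
    male = (cohort["gender"].to_numpy() == "M").astype(float)
    if male.min() == male.max():
        raise ValueError("cohort must contain both genders")
    age = cohort["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("cohort has constant age")

    X = np.column_stack([np.ones_like(age), age, male])
    xtx_inv = np.linalg.inv(X.T @ X)
    models: dict[str, ProxyAdjustment] = {}
    age_se: dict[str, float] = {}
    for name in variables:
        use_log = log_transform and name in LOG_PROXIES
        y = cohort[name].to_numpy(dtype=float)
        if use_log:
            if np.any(y <= 0):
                raise ValueError(f"{name!r} must be positive for log transform")
            y = np.log(y)
        if np.ptp(y) == 0:
            raise ValueError(f"variable {name!r} is constant")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - 3, 1)
        sigma2 = float(resid @ resid) / dof
        models[name] = ProxyAdjustment(
            intercept=float(beta[0]),
            age_coef=float(beta[1]),
            gender_coef=float(beta[2]),
            residual_scale=float(np.sqrt(sigma2)),
            log_transform=use_log,
        )
        age_se[name] = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return AdjustmentModel(models=models, reference=reference, age_se=age_se)


def adjust(
    cohort: pd.DataFrame,
    model: AdjustmentModel,
    variables: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Residualize each variable against age and gender using ``model``.

    Returns a DataFrame of adjusted values (same row order as ``cohort``).
    """
    if variables is None:
        variables = tuple(v for v in model.variables() if v in cohort.columns)
    missing = [v for v in variables if v not in model.models]
    if missing:
        raise KeyError(f"variable(s) not in adjustment model: {', '.join(missing)}")
    age = cohort["age"].to_numpy(dtype=float)
    male = (cohort["gender"].to_numpy() == "M").astype(float)
    out = {}
    for name in variables:
        m = model.models[name]
        y = cohort[name].to_numpy(dtype=float)
        if m.log_transform:
            if np.any(y <= 0):
                raise ValueError(f"{name!r} must be positive for log transform")
            y = np.log(y)
        out[name] = y - (m.intercept + m.age_coef * age + m.gender_coef * male)
    return pd.DataFrame(out, index=cohort.index)


def percentile_rank(values) -> np.ndarray:
    """Midrank percentile transform: p_i = 100 * (r_i - 0.5) / n.

    Ties share their midrank percentile; output lies strictly inside (0, 100)
    and has mean 50 when there are no ties.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("percentile_rank expects a 1-D array")
    if arr.size < 2:
        raise ValueError("percentile_rank requires at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("percentile_rank requires finite input")
    ranks = rankdata(arr, method="average")
    return 100.0 * (ranks - 0.5) / arr.size


def aprt(cohort: pd.DataFrame, variable: str, model: AdjustmentModel) -> np.ndarray:
    """Adjusted percentile rank transform of one variable of ``cohort``."""
    adjusted = adjust(cohort, model, variables=(variable,))
    return percentile_rank(adjusted[variable].to_numpy())
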