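"""Maximum-likelihood factor analysis of the adjusted proxies and the
construction of the percentile-ranked indicators.

The extraction maximizes the Gaussian likelihood on the correlation matrix by
profiling out the loadings (eigen-decomposition given uniquenesses, the
classic ``factanal``-style algorithm), followed by varimax rotation with
Kaiser normalization.  Retention keeps factors reproducing at least 10% of
total variance and 15% of total communality; factors are interpreted against
the reference sign pattern of the four autonomic domains and re-expressed as
midrank percentiles.  ``compute_ansi`` builds the composite autonomic index
from the adjusted percentiles of RR Mean, RR TP and ΔRR LFnu.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import svd
from scipy.optimize import linear_sum_assignment, minimize

from carproc.adjustment import AdjustmentModel, aprt, percentile_rank
from carproc.proxies import (
    DOMAIN_LABELS,
    DOMAIN_TO_INDICATOR,
    PROXY_NAMES,
    REFERENCE_SIGN_PATTERN,
)

MIN_UNIQUENESS = 0.005


class HeywoodWarning(UserWarning):
    """A uniqueness hit its lower bound (quasi-Heywood case)."""


class AmbiguousMatchError(ValueError):
    """Two factors match a domain label equally well."""


@dataclass
class FactorModel:
    """Rotated ML factor solution on standardized adjusted proxies.

    ``loadings`` holds correlations between variables and factors (rows follow
    ``variable_names``).  ``pct_total_variance[k]`` is the percentage of total
    variance (p = number of variables) reproduced by factor k;
    ``pct_total_communality[k]`` is its share of the total communality.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    variable_names: tuple[str, ...]
    pct_total_variance: np.ndarray
    pct_total_communality: np.ndarray
    q_retained: int
    correlation: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray
    n_obs: int
    converged: bool
    n_iter: int
    rotation: str = "varimax"
    score_method: str = "regression"
    heywood: tuple[str, ...] = ()
    log_likelihood_criterion: float = float("nan")

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"factor{k + 1}" for k in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=list(self.variable_names), columns=cols)

    def to_json(self, path) -> None:
        payload = {
            "variable_names": list(self.variable_names),
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "pct_total_variance": self.pct_total_variance.tolist(),
            "pct_total_communality": self.pct_total_communality.tolist(),
            "q_retained": self.q_retained,
            "correlation": self.correlation.tolist(),
            "train_mean": self.train_mean.tolist(),
            "train_sd": self.train_sd.tolist(),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "rotation": self.rotation,
            "score_method": self.score_method,
            "heywood": list(self.heywood),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "FactorModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["variable_names"] = tuple(payload["variable_names"])
        payload["heywood"] = tuple(payload["heywood"])
        for key in ("loadings", "uniquenesses", "pct_total_variance",
                    "pct_total_communality", "correlation", "train_mean", "train_sd"):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _ml_objective(psi: np.ndarray, corr: np.ndarray, q: int) -> float:
    scale = 1.0 / np.sqrt(psi)
    star = corr * np.outer(scale, scale)
    eigvals = np.linalg.eigvalsh(star)[::-1]
    tail = eigvals[q:]
    tail = np.clip(tail, 1e-12, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _ml_loadings(psi: np.ndarray, corr: np.ndarray, q: int) -> np.ndarray:
    scale = 1.0 / np.sqrt(psi)
    star = corr * np.outer(scale, scale)
    eigvals, eigvecs = np.linalg.eigh(star)
    order = np.argsort(eigvals)[::-1][:q]
    lam = np.clip(eigvals[order] - 1.0, 0.0, None)
    return np.sqrt(psi)[:, None] * eigvecs[:, order] * np.sqrt(lam)[None, :]


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-6,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray, int]:
    """Orthogonal varimax rotation (Kaiser-normalized by default).

    Returns the rotated loadings, the rotation matrix and the sweep count.
    """
    p, q = loadings.shape
    if q < 2:
        return loadings.copy(), np.eye(q), 0
    h = np.sqrt(np.sum(loadings**2, axis=1))
    h = np.where(h > 0, h, 1.0)
    A = loadings / h[:, None] if kaiser else loadings.copy()
    T = np.eye(q)
    d = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        B = A @ T
        u, s, vt = svd(A.T @ (B**3 - B @ np.diag(np.sum(B**2, axis=0)) / p))
        T = u @ vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    rotated = (A @ T) * h[:, None] if kaiser else A @ T
    return rotated, T, it


def _reference_sign_vector(variable_names: tuple[str, ...]) -> np.ndarray:
    """Union of the (disjoint) domain sign patterns as one signed vector."""
    ref = np.zeros(len(variable_names))
    idx = {v: i for i, v in enumerate(variable_names)}
    for pattern in REFERENCE_SIGN_PATTERN.values():
        for proxy, sign in pattern.items():
            if proxy in idx:
                ref[idx[proxy]] = sign
    return ref


def fit_efa(
    adjusted: pd.DataFrame,
    max_factors: int = 4,
    rotation: str = "varimax",
    score_method: str = "regression",
) -> FactorModel:
    """Fit an ML factor model with ``max_factors`` factors to the adjusted
    proxy matrix, varimax-rotate, order factors by explained variance, and
    align factor signs with the reference domain pattern.

    The optimization profiles the loadings out of the likelihood and minimizes
    over uniquenesses with L-BFGS-B from the standard starting value, so the
    fit is deterministic for a given input.
    """
    X = adjusted.to_numpy(dtype=float)
    names = tuple(adjusted.columns)
    n, p = X.shape
    if n < 5 * p:
        raise ValueError(f"need at least {5 * p} rows to fit {p} variables, got {n}")
    if not 1 <= max_factors < p:
        raise ValueError("max_factors must be in [1, n_variables)")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = names[int(np.argmin(sd))]
        raise ValueError(f"variable {bad!r} has zero variance")
    Z = (X - mean) / sd
    corr = np.corrcoef(Z, rowvar=False)
    if np.linalg.eigvalsh(corr).min() <= 1e-10:
        raise ValueError("correlation matrix is not positive definite")

    q = max_factors
    # factanal-style start: psi_j = (1 - q/(2p)) / (R^{-1})_jj
    start = (1.0 - 0.5 * q / p) / np.diag(np.linalg.inv(corr))
    start = np.clip(start, MIN_UNIQUENESS, 1.0)
    res = minimize(
        _ml_objective,
        start,
        args=(corr, q),
        method="L-BFGS-B",
        bounds=[(MIN_UNIQUENESS, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    psi = np.clip(res.x, MIN_UNIQUENESS, 1.0)
    if not res.success:
        raise RuntimeError(
            f"ML factor extraction did not converge after {res.nit} iterations: {res.message}"
        )
    heywood = tuple(names[j] for j in np.flatnonzero(psi <= MIN_UNIQUENESS * (1 + 1e-9)))
    if heywood:
        warnings.warn(
            f"uniqueness at lower bound (Heywood case) for: {', '.join(heywood)}",
            HeywoodWarning,
        )

    raw = _ml_loadings(psi, corr, q)
    if rotation == "varimax":
        rotated, _, _ = varimax(raw)
    elif rotation == "none":
        rotated = raw
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    # Order by explained variance, then align signs with the reference pattern.
    ss = np.sum(rotated**2, axis=0)
    order = np.argsort(ss)[::-1]
    rotated = rotated[:, order]
    ref = _reference_sign_vector(names)
    for k in range(q):
        if ref @ rotated[:, k] < 0:
            rotated[:, k] *= -1.0

    ss = np.sum(rotated**2, axis=0)
    communality = np.sum(rotated**2, axis=1)
    total_comm = float(communality.sum())
    pct_var = 100.0 * ss / p
    pct_comm = 100.0 * ss / total_comm

    return FactorModel(
        loadings=rotated,
        uniquenesses=psi,
        variable_names=names,
        pct_total_variance=pct_var,
        pct_total_communality=pct_comm,
        q_retained=q,
        correlation=corr,
        train_mean=mean,
        train_sd=sd,
        n_obs=n,
        converged=bool(res.success),
        n_iter=int(res.nit),
        rotation=rotation,
        score_method=score_method,
        heywood=heywood,
        log_likelihood_criterion=float(res.fun),
    )


def retain_factors(
    model: FactorModel,
    min_pct_variance: float = 10.0,
    min_pct_communality: float = 15.0,
) -> FactorModel:
    """Keep exactly the factors reproducing at least ``min_pct_variance`` % of
    total variance AND ``min_pct_communality`` % of total communality."""
    keep = np.flatnonzero(
        (model.pct_total_variance >= min_pct_variance)
        & (model.pct_total_communality >= min_pct_communality)
    )
    if keep.size == 0:
        raise ValueError("no factor satisfies both retention thresholds")
    return replace(
        model,
        loadings=model.loadings[:, keep],
        pct_total_variance=model.pct_total_variance[keep],
        pct_total_communality=model.pct_total_communality[keep],
        q_retained=int(keep.size),
    )


def fit_retained_efa(adjusted: pd.DataFrame, max_factors: int = 4,
                     **kwargs) -> FactorModel:
    """Fit, apply retention, and refit with the retained factor count until the
    solution is stable (every fitted factor passes both thresholds)."""
    q = max_factors
    for _ in range(max_factors):
        model = fit_efa(adjusted, max_factors=q, **kwargs)
        retained = retain_factors(model)
        if retained.q_retained == q:
            return retained
        q = retained.q_retained
    return retained


def label_factors(
    model: FactorModel, threshold: float = 0.5
) -> dict[int, tuple[str, dict[str, float]]]:
    """Interpret retained factors against the reference domain sign pattern.

    Each factor's cluster of loadings with absolute value >= ``threshold`` is
    matched to the four domain patterns by optimal assignment on the signed
    agreement score.  Returns ``{factor_index: (label, contributing loadings)}``
    with label 'unassigned' for factors matching no pattern.  Raises
    :class:`AmbiguousMatchError` when two factors tie for the same label.
    """
    q = model.loadings.shape[1]
    idx = {v: i for i, v in enumerate(model.variable_names)}
    agreement = np.zeros((q, len(DOMAIN_LABELS)))
    for k in range(q):
        col = model.loadings[:, k]
        for d, domain in enumerate(DOMAIN_LABELS):
            score = 0
            for proxy, sign in REFERENCE_SIGN_PATTERN[domain].items():
                if proxy not in idx:
                    continue
                lam = col[idx[proxy]]
                if abs(lam) >= threshold:
                    score += 1 if np.sign(lam) == sign else -1
            agreement[k, d] = score

    rows, cols = linear_sum_assignment(-agreement)
    labels: dict[int, tuple[str, dict[str, float]]] = {}
    for k, d in zip(rows, cols):
        score = agreement[k, d]
        if score <= 0:
            labels[k] = ("unassigned", {})
            continue
        ties = [kk for kk in range(q) if kk != k and agreement[kk, d] == score]
        if ties:
            raise AmbiguousMatchError(
                f"factors {k} and {ties[0]} match domain {DOMAIN_LABELS[d]!r} equally well"
            )
        contributing = {
            v: float(model.loadings[idx[v], k])
            for v in model.variable_names
            if abs(model.loadings[idx[v], k]) >= threshold
        }
        labels[k] = (DOMAIN_LABELS[d], contributing)
    for k in range(q):
        labels.setdefault(k, ("unassigned", {}))
    return dict(sorted(labels.items()))


def factor_scores(model: FactorModel, adjusted: pd.DataFrame) -> np.ndarray:
    """Per-subject factor scores (n x q).

    'regression' (Thomson) scores Z R^{-1} L by default; 'bartlett' scores
    Z P^{-1} L (L' P^{-1} L)^{-1} as an option (P = diag uniquenesses).
    """
    if tuple(adjusted.columns) != model.variable_names:
        raise ValueError("adjusted matrix columns do not match the fitted model")
    Z = (adjusted.to_numpy(dtype=float) - model.train_mean) / model.train_sd
    L = model.loadings
    if np.any(np.sum(L**2, axis=0) <= 0):
        raise ValueError("cannot score a zero-variance factor")
    if model.score_method == "regression":
        return Z @ np.linalg.solve(model.correlation, L)
    if model.score_method == "bartlett":
        pinv = 1.0 / model.uniquenesses
        A = L * pinv[:, None]
        return Z @ A @ np.linalg.inv(L.T @ A)
    raise ValueError(f"unknown score method {model.score_method!r}")


def indicators_from_scores(
    scores: np.ndarray,
    labels: dict[int, tuple[str, dict[str, float]]],
) -> pd.DataFrame:
    """Percentile-rank each labelled factor's scores into its domain indicator
    column (OSC_ind, AMP_ind, PRESS_ind, PUL_ind).  Unassigned factors are
    excluded with a warning."""
    out = {}
    for k, (domain, _) in labels.items():
        if domain == "unassigned":
            warnings.warn(f"factor {k} unassigned; excluded from indicators")
            continue
        out[DOMAIN_TO_INDICATOR[domain]] = percentile_rank(scores[:, k])
    return pd.DataFrame(out)


ANSI_COMPONENTS: tuple[str, ...] = ("RR Mean", "RR TP", "ΔRR LFnu")


def compute_ansi(
    cohort: pd.DataFrame,
    model: AdjustmentModel,
    delta_higher_is_better: bool = True,
) -> np.ndarray:
    """Composite autonomic index on (0, 100), higher = better.

    Each component (RR Mean, RR TP, ΔRR LFnu) is adjusted for age and gender
    and percentile-ranked; the three percentiles (oriented so higher is
    better) are averaged with equal weights and the average is re-expressed as
    a percentile rank.
    """
    missing = [c for c in ANSI_COMPONENTS if c not in cohort.columns]
    if missing:
        raise KeyError(f"missing ANSI component(s): {', '.join(missing)}")
    parts = []
    for name in ANSI_COMPONENTS:
        pct = aprt(cohort, name, model)
        if name == "ΔRR LFnu" and not delta_higher_is_better:
            pct = 100.0 - pct
        parts.append(pct)
    return percentile_rank(np.mean(parts, axis=0))


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))
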