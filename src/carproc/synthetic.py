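"""Seeded synthetic-cohort generator with planted latent structure.

Each subject draws a BMI group, demographics (age, gender, BMI truncated to the
group interval), four i.i.d. standard-normal latent domain scores, and
independent proxy noise.  Proxy ``j`` is assembled on a latent (pre-link) scale

    z_j = mu_j + shift_{j,g} + age_coef_j * (age - ref_age)
          + gender_coef_j * 1[male] + sum_k Lambda_{jk} F_k + eps_j

and mapped into its legal range by a fixed monotone link:

* ``softplus`` (strict positivity; identity to double precision at
  physiological magnitudes): HR, RR Mean, alpha index, SAP, DAP, SAP Mean;
* ``exp`` (log-normal-like spectral powers; ``mu`` is on the log scale):
  RR TP, RR LFa, RR HFa, RR LF/HF, SAP LFa;
* ``100 * expit`` (normalized units in (0, 100)): RR LFnu, RR HFnu;
* affine-logistic into the LF/HF frequency band: RR LFHz, RR HFHz;
* identity: ΔRR LFnu (a difference, may be negative).

Monotone links preserve the planted group trends and rank-based statistics.
All randomness derives from a single seed via named child streams, so a fixed
seed yields a bit-identical cohort.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from carproc.proxies import (
    HF_BAND,
    LF_BAND,
    N_PROXIES,
    PROXY_NAMES,
    REFERENCE_SIGN_PATTERN,
    TREND_DIRECTION,
)
from carproc.reference import BMI_GROUPS, REFERENCE_DEMOGRAPHICS, group_proportions

AGE_RANGE = (17.0, 80.0)

BMI_BOUNDS: dict[str, tuple[float, float]] = {
    "NW": (13.0, 25.0),
    "OW": (25.0, 30.0),
    "OB": (30.0, 75.0),
}

LINKS: dict[str, str] = {
    "HR": "softplus",
    "RR Mean": "softplus",
    "RR TP": "exp",
    "RR LFa": "exp",
    "RR HFa": "exp",
    "RR LFnu": "logit100",
    "RR HFnu": "logit100",
    "RR LF/HF": "exp",
    "RR LFHz": "band_lf",
    "RR HFHz": "band_hf",
    "ΔRR LFnu": "identity",
    "α index": "softplus",
    "SAP": "softplus",
    "DAP": "softplus",
    "SAP Mean": "softplus",
    "SAP LFa": "exp",
}

COHORT_COLUMNS: tuple[str, ...] = ("id", "age", "gender", "bmi", *PROXY_NAMES)


def apply_link(link: str, z: np.ndarray) -> np.ndarray:
    """Map latent values to the observed proxy scale by a monotone link."""
    if link == "identity":
        return z
    if link == "softplus":
        return np.logaddexp(0.0, z)
    if link == "exp":
        return np.exp(z)
    if link == "logit100":
        return 100.0 * expit(z)
    if link == "band_lf":
        lo, hi = LF_BAND
        return lo + (hi - lo) * expit(z)
    if link == "band_hf":
        lo, hi = HF_BAND
        return lo + (hi - lo) * expit(z)
    raise ValueError(f"unknown link {link!r}")


# Latent-scale defaults, one row per proxy (order of PROXY_NAMES):
# mu, loadings on (osc, amp, press, pulse), age coef, gender (M) coef,
# noise sd, group shifts (NW, OW, OB).
_DEFAULTS: dict[str, tuple[float, tuple[float, float, float, float], float, float, float, tuple[float, float, float]]] = {
    "HR": (72.0, (0, 0, 0, 7.0), -0.05, -2.0, 2.9, (-1.5, 0.0, 1.5)),
    "RR Mean": (850.0, (0, 0, 0, -80.0), -1.0, 20.0, 31.0, (20.0, 0.0, -20.0)),
    "RR TP": (7.60, (0, 0.55, 0, 0), -0.020, 0.10, 0.41, (0.15, 0.0, -0.15)),
    "RR LFa": (6.40, (0, 0.55, 0, 0), -0.020, 0.15, 0.41, (0.12, 0.0, -0.12)),
    "RR HFa": (6.20, (0, 0.55, 0, 0), -0.025, 0.0, 0.41, (0.12, 0.0, -0.12)),
    "RR LFnu": (0.10, (0.60, 0, 0, 0), 0.004, 0.08, 0.145, (-0.08, 0.0, 0.08)),
    "RR HFnu": (-0.35, (-0.60, 0, 0, 0), -0.004, -0.08, 0.145, (0.08, 0.0, -0.08)),
    "RR LF/HF": (0.47, (0.50, 0, 0, 0), 0.004, 0.10, 0.30, (-0.07, 0.0, 0.07)),
    "RR LFHz": (-0.30, (0, 0, 0, 0), 0.0, 0.0, 1.0, (0.28, 0.0, -0.28)),
    "RR HFHz": (-0.50, (0, 0, 0, 0), 0.0, 0.0, 1.0, (-0.28, 0.0, 0.28)),
    "ΔRR LFnu": (12.0, (-9.0, 0, 0, 0), -0.10, 1.0, 8.4, (2.0, 0.0, -2.0)),
    "α index": (16.0, (0, 3.5, 0, 0), -0.15, 0.5, 2.6, (1.2, 0.0, -1.2)),
    "SAP": (120.0, (0, 0, 8.0, 0), 0.20, 3.0, 5.0, (-3.0, 0.0, 3.0)),
    "DAP": (76.0, (0, 0, 5.0, 0), 0.15, 2.0, 4.0, (-2.0, 0.0, 2.0)),
    "SAP Mean": (118.0, (0, 0, 7.5, 0), 0.20, 2.5, 5.5, (-3.0, 0.0, 3.0)),
    "SAP LFa": (1.80, (0, 0, 0, 0), 0.005, 0.10, 0.50, (0.0, 0.20, 0.0)),
}

# Group-shift overrides for the "paper-like" scenario: a strong pressure-domain
# shift, moderate pulse / baroreflex / composite-index shifts, and null
# oscillatory/amplitude-domain shifts (only the small RR TP and ΔRR LFnu shifts
# that feed the composite index remain; ΔRR LFnu barely moves the oscillatory
# score, whose regression weights are dominated by the normalized powers).
_PAPER_LIKE_SHIFTS: dict[str, tuple[float, float, float]] = {
    "HR": (-1.2, 0.0, 1.2),
    "RR Mean": (18.0, 0.0, -18.0),
    "RR TP": (0.06, 0.0, -0.06),
    "RR LFa": (0.0, 0.0, 0.0),
    "RR HFa": (0.0, 0.0, 0.0),
    "RR LFnu": (0.0, 0.0, 0.0),
    "RR HFnu": (0.0, 0.0, 0.0),
    "RR LF/HF": (0.0, 0.0, 0.0),
    "RR LFHz": (0.0, 0.0, 0.0),
    "RR HFHz": (0.0, 0.0, 0.0),
    "ΔRR LFnu": (2.4, 0.0, -2.4),
    "α index": (0.9, 0.0, -0.9),
    "SAP": (-4.5, 0.0, 4.5),
    "DAP": (-3.0, 0.0, 3.0),
    "SAP Mean": (-4.2, 0.0, 4.2),
    "SAP LFa": (0.0, 0.0, 0.0),
}

# In the same scenario the alpha index keeps only a modest share of the
# amplitude factor (its group shift must reach alpha_aPRT without dragging the
# amplitude indicator along).
_PAPER_LIKE_ALPHA_LOADING = 1.8


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator.

    Matrix rows follow :data:`carproc.proxies.PROXY_NAMES`; group columns
    follow ``('NW', 'OW', 'OB')``.  ``proxy_mu``, ``loading_matrix``,
    ``group_shifts``, ``age_coefs``, ``gender_coefs`` and ``noise_sd`` are all
    expressed on the latent (pre-link) scale.
    """

    n_total: int = 756
    group_props: np.ndarray = field(default_factory=lambda: np.array(group_proportions()))
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            g: (REFERENCE_DEMOGRAPHICS[g].age_mean, REFERENCE_DEMOGRAPHICS[g].age_sd)
            for g in BMI_GROUPS
        }
    )
    male_prob: dict[str, float] = field(
        default_factory=lambda: {
            g: REFERENCE_DEMOGRAPHICS[g].n_male / REFERENCE_DEMOGRAPHICS[g].count
            for g in BMI_GROUPS
        }
    )
    bmi_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            g: (REFERENCE_DEMOGRAPHICS[g].bmi_mean, REFERENCE_DEMOGRAPHICS[g].bmi_sd)
            for g in BMI_GROUPS
        }
    )
    proxy_mu: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULTS[p][0] for p in PROXY_NAMES])
    )
    loading_matrix: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULTS[p][1] for p in PROXY_NAMES], dtype=float)
    )
    group_shifts: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULTS[p][5] for p in PROXY_NAMES], dtype=float)
    )
    age_coefs: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULTS[p][2] for p in PROXY_NAMES])
    )
    gender_coefs: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULTS[p][3] for p in PROXY_NAMES])
    )
    noise_sd: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULTS[p][4] for p in PROXY_NAMES])
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_props = np.asarray(self.group_props, dtype=float)
        self.proxy_mu = np.asarray(self.proxy_mu, dtype=float)
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        self.group_shifts = np.asarray(self.group_shifts, dtype=float)
        self.age_coefs = np.asarray(self.age_coefs, dtype=float)
        self.gender_coefs = np.asarray(self.gender_coefs, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.group_props.shape != (3,):
            raise ValueError("group_props must be a 3-vector")
        if np.any(self.group_props < 0):
            raise ValueError("group_props must be non-negative")
        if abs(float(self.group_props.sum()) - 1.0) > 1e-12:
            raise ValueError("group_props must sum to 1 within 1e-12")
        if self.loading_matrix.shape != (N_PROXIES, 4):
            raise ValueError("loading_matrix must be 16x4")
        if self.group_shifts.shape != (N_PROXIES, 3):
            raise ValueError("group_shifts must be 16x3")
        for name, vec in (
            ("proxy_mu", self.proxy_mu),
            ("age_coefs", self.age_coefs),
            ("gender_coefs", self.gender_coefs),
            ("noise_sd", self.noise_sd),
        ):
            if vec.shape != (N_PROXIES,):
                raise ValueError(f"{name} must be a 16-vector")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")

    @property
    def reference_age(self) -> float:
        """Expected cohort mean age (group-proportion-weighted)."""
        means = np.array([self.age_params[g][0] for g in BMI_GROUPS])
        return float(self.group_props @ means)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_total": int(self.n_total),
            "group_props": self.group_props.tolist(),
            "age_params": {g: list(v) for g, v in self.age_params.items()},
            "male_prob": dict(self.male_prob),
            "bmi_params": {g: list(v) for g, v in self.bmi_params.items()},
            "proxy_mu": self.proxy_mu.tolist(),
            "loading_matrix": self.loading_matrix.tolist(),
            "group_shifts": self.group_shifts.tolist(),
            "age_coefs": self.age_coefs.tolist(),
            "gender_coefs": self.gender_coefs.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("age_params", "bmi_params"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    factor_scores: np.ndarray
    group_labels: np.ndarray
    age_coefs: np.ndarray
    gender_coefs: np.ndarray
    group_shifts: np.ndarray
    reference_age: float


def default_config(seed: int = 0, n_total: int = 756) -> GeneratorConfig:
    """Default generator: reference demographics, four planted domains, and
    monotone NW -> OW -> OB trends on all 15 trending proxies."""
    return GeneratorConfig(n_total=n_total, seed=seed)


def paper_like_config(seed: int = 0, n_total: int = 756) -> GeneratorConfig:
    """Scenario with a strong pressure shift, moderate pulse/baroreflex/
    composite-index shifts, and null oscillatory/amplitude shifts."""
    cfg = default_config(seed=seed, n_total=n_total)
    shifts = np.array([_PAPER_LIKE_SHIFTS[p] for p in PROXY_NAMES], dtype=float)
    loadings = cfg.loading_matrix.copy()
    loadings[PROXY_NAMES.index("α index"), 1] = _PAPER_LIKE_ALPHA_LOADING
    return replace(cfg, group_shifts=shifts, loading_matrix=loadings)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Draw a cohort from ``config``.

    Returns the cohort table (columns ``id, age, gender, bmi`` plus the 16
    proxies) and the planted ground truth.  Identical configs (including seed)
    produce bit-identical outputs.
    """
    config.validate()
    n = config.n_total
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_group, rng_demo, rng_bmi, rng_factor, rng_noise = (
        np.random.default_rng(s) for s in streams
    )

    group_idx = rng_group.choice(3, size=n, p=config.group_props)
    labels = np.array(BMI_GROUPS)[group_idx]

    age = np.empty(n)
    male = np.empty(n, dtype=bool)
    bmi = np.empty(n)
    for gi, g in enumerate(BMI_GROUPS):
        mask = group_idx == gi
        m = int(mask.sum())
        if m == 0:
            continue
        a_mean, a_sd = config.age_params[g]
        age[mask] = _truncated_normal(rng_demo, a_mean, a_sd, *AGE_RANGE, size=m)
        male[mask] = rng_demo.random(m) < config.male_prob[g]
        b_mean, b_sd = config.bmi_params[g]
        bmi[mask] = _truncated_normal(rng_bmi, b_mean, b_sd, *BMI_BOUNDS[g], size=m)

    factors = rng_factor.standard_normal((n, 4))
    eps = rng_noise.standard_normal((n, N_PROXIES)) * config.noise_sd

    ref_age = config.reference_age
    z = (
        config.proxy_mu
        + config.group_shifts.T[group_idx]
        + np.outer(age - ref_age, config.age_coefs)
        + np.outer(male.astype(float), config.gender_coefs)
        + factors @ config.loading_matrix.T
        + eps
    )

    data = {
        "id": [f"S{i + 1:05d}" for i in range(n)],
        "age": age,
        "gender": np.where(male, "M", "F"),
        "bmi": bmi,
    }
    for j, name in enumerate(PROXY_NAMES):
        data[name] = apply_link(LINKS[name], z[:, j])
    cohort = pd.DataFrame(data, columns=list(COHORT_COLUMNS))

    truth = PlantedTruth(
        factor_scores=factors,
        group_labels=labels,
        age_coefs=config.age_coefs.copy(),
        gender_coefs=config.gender_coefs.copy(),
        group_shifts=config.group_shifts.copy(),
        reference_age=ref_age,
    )
    return cohort, truth


class CohortFormatError(ValueError):
    """Malformed cohort CSV (missing column, bad cell, bad gender code)."""


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (UTF-8, full float precision)."""
    cohort.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortFormatError` naming the offending column for missing
    headers and the offending row and column for non-numeric or invalid cells.
    """
    if isinstance(path, io.TextIOBase):
        raw = pd.read_csv(path, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"missing column(s): {', '.join(missing)}")

    out = pd.DataFrame({"id": raw["id"].astype(str)})
    bad_gender = ~raw["gender"].isin(["M", "F"])
    if bad_gender.any():
        row = int(np.flatnonzero(bad_gender.to_numpy())[0])
        raise CohortFormatError(
            f"invalid gender value {raw['gender'].iloc[row]!r} in row {row} "
            "(expected 'M' or 'F')"
        )
    out["age"] = _numeric_column(raw, "age")
    out["gender"] = raw["gender"]
    out["bmi"] = _numeric_column(raw, "bmi")
    for name in PROXY_NAMES:
        out[name] = _numeric_column(raw, name)
    return out[list(COHORT_COLUMNS)]


def _numeric_column(raw: pd.DataFrame, column: str) -> np.ndarray:
    converted = pd.to_numeric(raw[column], errors="coerce")
    bad = converted.isna() & raw[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortFormatError(
            f"non-numeric value {raw[column].iloc[row]!r} in row {row}, column {column!r}"
        )
    return converted.to_numpy(dtype=float)


def check_sign_pattern(config: GeneratorConfig) -> bool:
    """True iff the loading matrix signs match the reference domain pattern."""
    from carproc.proxies import DOMAIN_LABELS

    idx = {p: i for i, p in enumerate(PROXY_NAMES)}
    for k, domain in enumerate(DOMAIN_LABELS):
        for proxy, sign in REFERENCE_SIGN_PATTERN[domain].items():
            if np.sign(config.loading_matrix[idx[proxy], k]) != sign:
                return False
    return True


def check_trend_pattern(config: GeneratorConfig) -> bool:
    """True iff latent group shifts are monotone NW < OW < OB in the trend
    direction for every trending proxy (links are monotone, so latent
    monotonicity implies observed-mean monotonicity up to sampling noise)."""
    idx = {p: i for i, p in enumerate(PROXY_NAMES)}
    for proxy, direction in TREND_DIRECTION.items():
        nw, ow, ob = config.group_shifts[idx[proxy]]
        if direction > 0 and not (nw < ow < ob):
            return False
        if direction < 0 and not (nw > ow > ob):
            return False
    return True
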