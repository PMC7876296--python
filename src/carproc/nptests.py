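"""Non-parametric battery for BMI-group effects on an indicator.

Per indicator the battery runs nine tests: one Kruskal-Wallis omnibus test,
three pairwise bootstrap median tests (NW-OW, NW-OB, OW-OB), three pairwise
kernel-density equality (Bowman-Azzalini-type) tests at the Bonferroni level
0.05/3, one Jonckheere-Terpstra and one Hettmansperger-Norton test against an
ordered monotone alternative.  Supporting utilities: Pearson correlation
screen with significance codes, per-proxy ANOVA/KW screen, bootstrap median
confidence intervals, and notched-box-plot intervals.

All resampling procedures accept a seed and are bit-reproducible; the
permutation tests switch to exhaustive enumeration on request (or, for JT,
automatically at small total sample size).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from carproc.reference import BMI_GROUPS

GROUP_PAIRS: tuple[tuple[str, str], ...] = (("NW", "OW"), ("NW", "OB"), ("OW", "OB"))

_Z975 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# result containers


@dataclass
class TestResult:
    __test__ = False  # not a pytest class despite the name

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    direction: str | None = None
    groups_compared: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.significant != (self.p_value <= self.alpha):
            raise ValueError("significance flag inconsistent with p-value and alpha")


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float = 0.95
    replicates: int = 5000
    statistic: str = "median"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass
class NotchInterval:
    """Notched-box-plot interval: median +/- 1.58 * IQR / sqrt(n)."""

    median: float
    q1: float
    q3: float
    n: int
    iqr: float = field(init=False)
    lower: float = field(init=False)
    upper: float = field(init=False)

    def __post_init__(self) -> None:
        self.iqr = self.q3 - self.q1
        half = 1.58 * self.iqr / math.sqrt(self.n)
        self.lower = self.median - half
        self.upper = self.median + half


@dataclass
class DensityComparison:
    grid: np.ndarray
    density_g1: np.ndarray
    density_g2: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    bandwidth: float
    statistic: float
    p_value: float
    groups_compared: str = ""


@dataclass
class TestBattery:
    """Exactly nine test results for one indicator."""

    __test__ = False  # not a pytest class despite the name

    indicator: str
    results: list[TestResult]

    def __post_init__(self) -> None:
        if len(self.results) != 9:
            raise ValueError(f"battery must hold 9 results, got {len(self.results)}")

    @property
    def kw(self) -> TestResult:
        return self.results[0]

    @property
    def median_tests(self) -> list[TestResult]:
        return self.results[1:4]

    @property
    def ba_tests(self) -> list[TestResult]:
        return self.results[4:7]

    @property
    def jt(self) -> TestResult:
        return self.results[7]

    @property
    def hn(self) -> TestResult:
        return self.results[8]

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicator,
                "test": [r.test_name for r in self.results],
                "pair": [r.groups_compared for r in self.results],
                "statistic": [r.statistic for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "alpha": [r.alpha for r in self.results],
                "significant": [r.significant for r in self.results],
                "direction": [r.direction for r in self.results],
            }
        )


# ---------------------------------------------------------------------------
# screens


def _star_code(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlation_screen(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided tests of zero correlation.

    Returns (r, p, significance-code) matrices.  Codes: '***' P <= 0.001,
    '**' P <= 0.01, '*' P <= 0.05.
    """
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("correlation screen needs at least 3 complete rows")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = data.columns[int(np.argmin(sds))]
        raise ValueError(f"column {bad!r} is constant")
    cols = list(data.columns)
    m = len(cols)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            res = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    codes = np.vectorize(_star_code)(p)
    np.fill_diagonal(codes, "")
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        pd.DataFrame(codes, index=cols, columns=cols),
    )


def proxy_group_screen(
    cohort: pd.DataFrame,
    proxies: tuple[str, ...] | None = None,
    group_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-way ANOVA F and (tie-corrected) Kruskal-Wallis H per proxy across
    the three BMI groups."""
    from carproc.adjustment import assign_bmi_group
    from carproc.proxies import PROXY_NAMES

    if proxies is None:
        proxies = tuple(p for p in PROXY_NAMES if p in cohort.columns)
    if group_labels is None:
        group_labels = assign_bmi_group(cohort["bmi"].to_numpy())
    rows = []
    for name in proxies:
        groups = [
            cohort.loc[np.asarray(group_labels) == g, name].to_numpy(dtype=float)
            for g in BMI_GROUPS
        ]
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"each BMI group needs >= 2 observations for {name!r}")
        f_stat, p_anova = stats.f_oneway(*groups)
        kw = kruskal_wallis(groups)
        rows.append(
            {
                "proxy": name,
                "anova_F": float(f_stat),
                "anova_p": float(p_anova),
                "kw_H": kw.statistic,
                "kw_p": kw.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("proxy")


# ---------------------------------------------------------------------------
# bootstrap median inference


def _bootstrap_medians(values: np.ndarray, replicates: int,
                       rng: np.random.Generator) -> np.ndarray:
    n = values.size
    idx = rng.integers(0, n, size=(replicates, n))
    return np.median(values[idx], axis=1)


def bootstrap_median_ci(
    values,
    replicates: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap confidence interval for the median."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 8:
        raise ValueError("bootstrap median CI requires n >= 8")
    rng = np.random.default_rng(seed)
    meds = _bootstrap_medians(arr, replicates, rng)
    lo, hi = np.quantile(meds, [(1 - level) / 2, (1 + level) / 2])
    return BootstrapCI(lower=float(lo), upper=float(hi), level=level, replicates=replicates)


def bootstrap_median_test(
    g1,
    g2,
    replicates: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    groups_compared: str = "",
) -> TestResult:
    """Bootstrap test of equality of two medians.

    The percentile bootstrap distribution of median(g1) - median(g2) is
    computed; the test is significant when the ``level`` CI excludes zero.
    The p-value is the smallest level alpha on a fine grid at which the
    (1 - alpha) percentile CI excludes zero.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 8 or b.size < 8:
        raise ValueError("bootstrap median test requires n >= 8 per group")
    rng = np.random.default_rng(seed)
    diffs = _bootstrap_medians(a, replicates, rng) - _bootstrap_medians(b, replicates, rng)
    observed = float(np.median(a) - np.median(b))

    alphas = np.linspace(0.0005, 0.9995, 1999)
    lo = np.quantile(diffs, alphas / 2)
    hi = np.quantile(diffs, 1 - alphas / 2)
    excluded = (lo > 0) | (hi < 0)
    p_value = float(alphas[excluded][0]) if excluded.any() else 1.0
    alpha = round(1 - level, 10)
    return TestResult(
        test_name="median",
        statistic=observed,
        p_value=p_value,
        alpha=alpha,
        significant=p_value <= alpha,
        groups_compared=groups_compared,
    )


# ---------------------------------------------------------------------------
# kernel density comparison (Bowman-Azzalini style)


def _normal_optimal_bandwidth(pooled: np.ndarray) -> float:
    sd = pooled.std(ddof=1)
    iqr = np.subtract(*np.quantile(pooled, [0.75, 0.25]))
    robust = min(sd, iqr / 1.349) if iqr > 0 else sd
    if robust <= 0:
        raise ValueError("degenerate bandwidth: pooled sample has zero spread")
    return float(robust * (4.0 / (3.0 * pooled.size)) ** 0.2)


def _kernel_matrix(values: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    u = (values[:, None] - grid[None, :]) / h
    return np.exp(-0.5 * u**2) / (h * math.sqrt(2 * math.pi))


def ba_density_test(
    g1,
    g2,
    nboot: int = 500,
    seed: int | None = None,
    grid_size: int = 100,
    alpha: float = 0.05 / 3,
    exact: bool = False,
    groups_compared: str = "",
) -> DensityComparison:
    """Kernel-density equality test of two samples.

    Gaussian kernel estimates with a common normal-optimal bandwidth on the
    pooled sample; statistic = integrated squared difference of the two
    estimates; p-value by permutation of group labels (``nboot`` random
    permutations, or exhaustive enumeration when ``exact``).  The reference
    band is centered on the pooled density with half-width z_0.975 times the
    pointwise standard error of the difference of the estimates under H0.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 4 or b.size < 4:
        raise ValueError("density comparison requires n >= 4 per group")
    pooled = np.concatenate([a, b])
    h = _normal_optimal_bandwidth(pooled)
    grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, grid_size)
    K = _kernel_matrix(pooled, grid, h)
    n1, n2 = a.size, b.size
    N = n1 + n2

    # trapezoid quadrature weights on the uniform grid
    w = np.full(grid_size, grid[1] - grid[0])
    w[0] *= 0.5
    w[-1] *= 0.5

    def ise_batch(masks: np.ndarray) -> np.ndarray:
        """Integrated squared density difference for each row-mask of group 1."""
        f1 = (masks @ K) / n1
        f2 = ((1.0 - masks) @ K) / n2
        return ((f1 - f2) ** 2) @ w

    obs_mask = np.zeros((1, N))
    obs_mask[0, :n1] = 1.0
    observed = float(ise_batch(obs_mask)[0])

    if exact:
        combos = list(itertools.combinations(range(N), n1))
        masks = np.zeros((len(combos), N))
        for i, combo in enumerate(combos):
            masks[i, list(combo)] = 1.0
        p_value = float(np.mean(ise_batch(masks) >= observed - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((nboot, N))
        for i in range(nboot):
            masks[i, rng.permutation(N)[:n1]] = 1.0
        count = int(np.sum(ise_batch(masks) >= observed - 1e-12))
        p_value = (1 + count) / (1 + nboot)

    f1 = K[:n1].mean(axis=0)
    f2 = K[n1:].mean(axis=0)
    f_pooled = K.mean(axis=0)
    rk = 1.0 / (2.0 * math.sqrt(math.pi))  # roughness of the Gaussian kernel
    se = np.sqrt(np.clip(f_pooled, 0, None) * rk / h * (1.0 / n1 + 1.0 / n2))
    band_half = _Z975 * se
    return DensityComparison(
        grid=grid,
        density_g1=f1,
        density_g2=f2,
        band_lower=np.clip(f_pooled - band_half, 0.0, None),
        band_upper=f_pooled + band_half,
        bandwidth=h,
        statistic=observed,
        p_value=float(p_value),
        groups_compared=groups_compared,
    )


def ba_test_result(comparison: DensityComparison, alpha: float = 0.05 / 3) -> TestResult:
    """Wrap a :class:`DensityComparison` as a :class:`TestResult`."""
    return TestResult(
        test_name="BA",
        statistic=comparison.statistic,
        p_value=comparison.p_value,
        alpha=alpha,
        significant=comparison.p_value <= alpha,
        groups_compared=comparison.groups_compared,
    )


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(groups, alpha: float = 0.05) -> TestResult:
    """Tie-corrected Kruskal-Wallis test; H = 0, p = 1 when all observations
    are identical (H is undefined in that degenerate case)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("KW", 0.0, 1.0, alpha, False)
    stat, p = stats.kruskal(*arrays)
    return TestResult("KW", float(stat), float(p), alpha, p <= alpha)


def _jt_statistic(values: np.ndarray, sizes: np.ndarray) -> float:
    """J = sum over ordered group pairs of #{x < y} + 0.5 #{x = y}."""
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    j = 0.0
    for i in range(len(sizes)):
        gi = values[bounds[i]:bounds[i + 1]]
        for jdx in range(i + 1, len(sizes)):
            gj = values[bounds[jdx]:bounds[jdx + 1]]
            less = np.sum(gi[:, None] < gj[None, :])
            ties = np.sum(gi[:, None] == gj[None, :])
            j += less + 0.5 * ties
    return float(j)


def _distinct_assignments(n_total: int, sizes) -> "itertools.chain":
    """Yield index tuples per group for all distinct partitions of
    range(n_total) into groups of the given sizes."""

    def rec(remaining: tuple[int, ...], sizes_left):
        if not sizes_left:
            yield ()
            return
        m = sizes_left[0]
        for combo in itertools.combinations(remaining, m):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield (combo, *tail)

    return rec(tuple(range(n_total)), tuple(sizes))


def jonckheere_terpstra(
    groups,
    alternative: str = "increasing",
    exact: bool | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Jonckheere-Terpstra test against an ordered monotone alternative.

    One-sided p-value in the requested direction; exact permutation null when
    the total sample size is <= 12 (or ``exact=True``), otherwise a
    tie-corrected normal approximation.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if alternative == "decreasing":
        arrays = arrays[::-1]
    sizes = np.array([a.size for a in arrays])
    values = np.concatenate(arrays)
    N = int(sizes.sum())
    if N < 4:
        raise ValueError("total sample size must be >= 4")
    observed = _jt_statistic(values, sizes)

    if exact is None:
        exact = N <= 12
    if exact:
        count = 0
        total = 0
        for assignment in _distinct_assignments(N, sizes):
            perm = np.concatenate([values[list(ix)] for ix in assignment])
            total += 1
            if _jt_statistic(perm, sizes) >= observed - 1e-12:
                count += 1
        p_value = count / total
    else:
        mean = (N**2 - np.sum(sizes**2)) / 4.0
        _, tie_counts = np.unique(values, return_counts=True)
        t = tie_counts.astype(float)
        n = sizes.astype(float)
        term1 = (
            N * (N - 1) * (2 * N + 5)
            - np.sum(n * (n - 1) * (2 * n + 5))
            - np.sum(t * (t - 1) * (2 * t + 5))
        ) / 72.0
        term2 = (
            np.sum(n * (n - 1) * (n - 2))
            * np.sum(t * (t - 1) * (t - 2))
            / (36.0 * N * (N - 1) * (N - 2))
        )
        term3 = np.sum(n * (n - 1)) * np.sum(t * (t - 1)) / (8.0 * N * (N - 1))
        var = term1 + term2 + term3
        if var <= 0:
            p_value = 1.0
        else:
            z = (observed - mean) / math.sqrt(var)
            p_value = float(stats.norm.sf(z))
    return TestResult(
        test_name="JT",
        statistic=observed,
        p_value=float(p_value),
        alpha=alpha,
        significant=p_value <= alpha,
        direction=alternative,
    )


def _tie_blocks(sorted_values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block structure of a sorted array: for each element, the index of its
    tie block, plus each block's start and end (exclusive) positions."""
    n = sorted_values.size
    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    new_block[1:] = sorted_values[1:] != sorted_values[:-1]
    block_id = np.cumsum(new_block) - 1
    starts = np.flatnonzero(new_block)
    ends = np.append(starts[1:], n)
    return block_id, starts, ends


def pseudoranks(values: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Pseudoranks psi(x) = N * (1/k) * sum_i F_i(x) + 1/2 with F_i the
    mid-ECDF of group i.  Reduces to ordinary midranks for equal group sizes."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    N = values.size
    order = np.argsort(values, kind="mergesort")
    sorted_vals = values[order]
    block_id, starts, ends = _tie_blocks(sorted_vals)
    n_blocks = starts.size
    mean_f = np.zeros(n_blocks)
    for i in range(k):
        member = (labels[order] == i).astype(float)
        n_i = member.sum()
        csum = np.concatenate([[0.0], np.cumsum(member)])
        less = csum[starts]
        eq = csum[ends] - csum[starts]
        mean_f += (less + 0.5 * eq) / n_i
    psi_block = N * mean_f / k + 0.5
    psi = np.empty(N)
    psi[order] = psi_block[block_id]
    return psi


def hettmansperger_norton(
    groups,
    trend_scores=(1.0, 2.0, 3.0),
    alternative: str = "increasing",
    method: str = "permutation",
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
    alpha: float = 0.05,
) -> TestResult:
    """Hettmansperger-Norton pseudorank test for an ordered alternative.

    Statistic: standardized sum_i c_i * (mean pseudorank of group i) with
    centered contrasts c_i = w_i - mean(w) ('decreasing' negates them).
    P-value by label permutation (pseudoranks recomputed per permutation),
    exhaustive when ``exact``; ``method='asymptotic'`` uses the permutation
    normal approximation with the observed pseudoranks as fixed scores.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    k = len(arrays)
    sizes = np.array([a.size for a in arrays])
    N = int(sizes.sum())
    values = np.concatenate(arrays)
    labels = np.repeat(np.arange(k), sizes)
    w = np.asarray(trend_scores, dtype=float)
    if w.size != k:
        raise ValueError("trend_scores length must equal the number of groups")
    c = w - w.mean()
    if alternative == "decreasing":
        c = -c

    def statistic(lbl: np.ndarray) -> float:
        psi = pseudoranks(values, lbl, k)
        means = np.array([psi[lbl == i].mean() for i in range(k)])
        return float(c @ means)

    t_raw = statistic(labels)
    psi_obs = pseudoranks(values, labels, k)
    sigma2 = psi_obs.var()  # population variance of the observed scores
    scale = math.sqrt(sigma2 * N / (N - 1) * np.sum(c**2 / sizes))
    t_std = t_raw / scale if scale > 0 else 0.0

    if method == "asymptotic":
        p_value = float(stats.norm.sf(t_std)) if scale > 0 else 1.0
    elif method == "permutation":
        if exact:
            count = 0
            total = 0
            for assignment in _distinct_assignments(N, sizes):
                lbl = np.empty(N, dtype=int)
                for i, ix in enumerate(assignment):
                    lbl[list(ix)] = i
                total += 1
                if statistic(lbl) >= t_raw - 1e-12:
                    count += 1
            p_value = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                lbl = rng.permutation(labels)
                if statistic(lbl) >= t_raw - 1e-12:
                    count += 1
            p_value = (1 + count) / (1 + n_perm)
    else:
        raise ValueError("method must be 'permutation' or 'asymptotic'")
    return TestResult(
        test_name="HN",
        statistic=t_std,
        p_value=float(p_value),
        alpha=alpha,
        significant=p_value <= alpha,
        direction=alternative,
    )


# ---------------------------------------------------------------------------
# notches and the battery


def notch_interval(values) -> NotchInterval:
    """Notched-box-plot median interval with linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValueError("notch interval requires n >= 5")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return NotchInterval(median=float(med), q1=float(q1), q3=float(q3), n=arr.size)


@dataclass
class BatteryConfig:
    """Replicate counts, significance levels and trend direction policy."""

    alpha: float = 0.05
    ba_alpha: float = 0.05 / 3
    median_replicates: int = 5000
    median_level: float = 0.95
    ba_permutations: int = 500
    hn_permutations: int = 10000
    hn_method: str = "permutation"
    direction: str = "auto"  # 'auto', 'increasing' or 'decreasing'
    seed: int = 0


def trend_direction(values: np.ndarray, group_labels: np.ndarray) -> str:
    """'increasing' or 'decreasing' from the sign of the Spearman correlation
    between the NW/OW/OB ordinal and the values."""
    mapping = {g: i for i, g in enumerate(BMI_GROUPS)}
    ordinal = np.array([mapping[g] for g in np.asarray(group_labels)])
    rho = stats.spearmanr(ordinal, values).statistic
    return "increasing" if rho >= 0 else "decreasing"


def run_battery(
    values,
    group_labels,
    config: BatteryConfig | None = None,
    indicator: str = "",
) -> TestBattery:
    """Run the nine-test battery on one indicator column.

    Order of results: KW, median NW-OW, NW-OB, OW-OB, BA NW-OW, NW-OB, OW-OB,
    JT, HN.
    """
    if config is None:
        config = BatteryConfig()
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = {g: values[group_labels == g] for g in BMI_GROUPS}
    if any(arr.size == 0 for arr in groups.values()):
        raise ValueError("all three BMI groups must be present")

    direction = config.direction
    if direction == "auto":
        direction = trend_direction(values, group_labels)

    seeds = np.random.SeedSequence(config.seed).spawn(7)
    results: list[TestResult] = [
        kruskal_wallis([groups[g] for g in BMI_GROUPS], alpha=config.alpha)
    ]
    for (ga, gb), ss in zip(GROUP_PAIRS, seeds[:3]):
        res = bootstrap_median_test(
            groups[ga],
            groups[gb],
            replicates=config.median_replicates,
            level=config.median_level,
            seed=ss,
            groups_compared=f"{ga}-{gb}",
        )
        results.append(res)
    for (ga, gb), ss in zip(GROUP_PAIRS, seeds[3:6]):
        comp = ba_density_test(
            groups[ga],
            groups[gb],
            nboot=config.ba_permutations,
            seed=ss,
            alpha=config.ba_alpha,
            groups_compared=f"{ga}-{gb}",
        )
        results.append(ba_test_result(comp, alpha=config.ba_alpha))
    results.append(
        jonckheere_terpstra(
            [groups[g] for g in BMI_GROUPS], alternative=direction, alpha=config.alpha
        )
    )
    results.append(
        hettmansperger_norton(
            [groups[g] for g in BMI_GROUPS],
            alternative=direction,
            method=config.hn_method,
            n_perm=config.hn_permutations,
            seed=seeds[6],
            alpha=config.alpha,
        )
    )
    return TestBattery(indicator=indicator, results=results)
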