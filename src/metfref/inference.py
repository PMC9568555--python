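"""Group comparisons and crossed random-effects variance decomposition.

Between-group differences are assessed frequency-wise with Welch
t-tests (robust to unequal variances) under Holm's sequentially
rejective multiplicity adjustment.  The variance decomposition fits a
linear mixed model with a cubic fixed-effect polynomial in standardized
log10 frequency and crossed random intercepts for specimen, measurement
method and research group:

    y = Xβ + u_tb + u_method + u_group + ε,   u_r ~ N(0, σ²_r I).

The REML criterion is profiled over the residual variance and the
fixed effects, leaving an optimization over the variance ratios
γ_r = σ²_r/σ²_ε only; each evaluation reduces to a Cholesky factor of
the q×q system (q = total number of random levels) via the Woodbury
identity, which keeps crossed designs with hundreds of specimens fast.
Explained variance is split into marginal R² (fixed effects only) and
conditional R² (fixed plus random) after Nakagawa & Schielzeth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

from .core_model import FrequencyGrid, METFTable, get_logger
from .synthetic_data import standardize_log_frequency

__all__ = [
    "PairwiseComparison",
    "VarianceDecomposition",
    "Moments",
    "welch_t",
    "holm_adjust",
    "pairwise_by_frequency",
    "moments",
    "fit_lmm",
    "r2_nakagawa",
]

_log = get_logger("inference")


# ---------------------------------------------------------------------------
# Welch t-tests and Holm adjustment
# ---------------------------------------------------------------------------


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    mean_diff: float


def welch_t(sample_a, sample_b) -> WelchResult:
    """Two-sided Welch t-test (unequal variances) for two samples.

    Returns the t statistic, Welch–Satterthwaite degrees of freedom,
    two-sided p-value and the mean difference a − b.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need n >= 2 per sample, got {len(a)}, {len(b)}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / len(a), vb / len(b)
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (len(a) - 1)
                               + se2b ** 2 / (len(b) - 1))
    return WelchResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue),
                       mean_diff=float(a.mean() - b.mean()))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class PairwiseComparison:
    frequency_hz: float
    level_a: str
    level_b: str
    n_a: int
    n_b: int
    mean_diff_db: float
    t: float
    df: float
    p: float
    p_adj: float = np.nan
    significant: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.p_adj):
            if self.p_adj < self.p - 1e-12 or self.p_adj > 1 + 1e-12:
                raise ValueError("adjusted p must satisfy p <= p_adj <= 1")


def pairwise_by_frequency(table: METFTable, factor: str = "group",
                          alpha: float = 0.05,
                          holm_family: str = "frequency",
                          ) -> list[PairwiseComparison]:
    """All pairwise Welch comparisons of factor levels at each frequency.

    The Holm family is the set of pairwise tests within one frequency
    by default ("frequency"); ``holm_family="global"`` pools every test
    into a single family.  Levels with fewer than 2 observations at a
    frequency are skipped with a warning.
    """
    if factor not in ("group", "method"):
        raise ValueError(f"factor must be 'group' or 'method', got {factor!r}")
    raw: list[PairwiseComparison] = []
    families: list[list[int]] = []
    for f, sub in table.df.groupby("frequency_hz", sort=True):
        samples = {lev: g["metf_db"].to_numpy()
                   for lev, g in sub.groupby(factor, sort=True)}
        usable = {lev: v for lev, v in samples.items() if len(v) >= 2}
        skipped = sorted(set(samples) - set(usable))
        if skipped:
            _log.warning("%g Hz: skipping %s level(s) %s with n < 2",
                         f, factor, skipped)
        if len(usable) < 2:
            if len(usable) < len(samples) or len(samples) == 1:
                _log.warning("%g Hz: fewer than 2 usable levels, no tests", f)
            continue
        family: list[int] = []
        for lev_a, lev_b in itertools.combinations(sorted(usable), 2):
            res = welch_t(usable[lev_a], usable[lev_b])
            family.append(len(raw))
            raw.append(PairwiseComparison(
                frequency_hz=float(f), level_a=lev_a, level_b=lev_b,
                n_a=len(usable[lev_a]), n_b=len(usable[lev_b]),
                mean_diff_db=res.mean_diff, t=res.t, df=res.df, p=res.p))
        families.append(family)
    if holm_family == "global":
        families = [[i for fam in families for i in fam]]
    elif holm_family != "frequency":
        raise ValueError(f"unknown holm_family {holm_family!r}")
    out: list[PairwiseComparison | None] = [None] * len(raw)
    for fam in families:
        adj = holm_adjust([raw[i].p for i in fam])
        for i, p_adj in zip(fam, adj):
            c = raw[i]
            out[i] = PairwiseComparison(
                frequency_hz=c.frequency_hz, level_a=c.level_a,
                level_b=c.level_b, n_a=c.n_a, n_b=c.n_b,
                mean_diff_db=c.mean_diff_db, t=c.t, df=c.df, p=c.p,
                p_adj=float(p_adj), significant=bool(p_adj < alpha))
    return [c for c in out if c is not None]


def comparisons_frame(comparisons: Sequence[PairwiseComparison]
                      ) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


# ---------------------------------------------------------------------------
# Distribution moments
# ---------------------------------------------------------------------------


class Moments(NamedTuple):
    """Sample shape statistics; kurtosis in both conventions."""

    skewness: float          # adjusted Fisher-Pearson (bias-corrected)
    kurtosis_excess: float   # bias-corrected, normal -> 0
    kurtosis_raw: float      # normal -> 3
    convention: str = "adjusted Fisher-Pearson; excess = raw - 3"


def moments(values) -> Moments:
    """Adjusted Fisher–Pearson skewness and sample excess kurtosis."""
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError(f"need n >= 4 for moments, got {len(v)}")
    skew = float(stats.skew(v, bias=False))
    kurt_ex = float(stats.kurtosis(v, bias=False))
    return Moments(skewness=skew, kurtosis_excess=kurt_ex,
                   kurtosis_raw=kurt_ex + 3.0)


# ---------------------------------------------------------------------------
# Crossed random-intercepts REML
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceDecomposition:
    """Fixed coefficients, variance components and R² summaries.

    Variances are in dB².  ``sigma2_fixed`` is the population variance
    of the fixed-effect predictions over the observed design.  Factors
    estimated at the boundary (variance → 0) are listed in
    ``boundary_factors``; factors dropped for having a single level are
    in ``dropped_factors`` with variance reported 0.
    """

    beta: tuple[float, ...]
    sigma2_tb: float
    sigma2_method: float
    sigma2_group: float
    sigma2_resid: float
    sigma2_fixed: float
    r2_marginal: float
    r2_conditional: float
    loglik: float
    converged: bool
    n_obs: int
    poly_order: int
    criterion: str = "REML"
    covariate: str = "standardized log10 frequency"
    boundary_factors: tuple[str, ...] = ()
    dropped_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sigma2_tb", "sigma2_method", "sigma2_group",
                     "sigma2_resid", "sigma2_fixed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.r2_marginal <= self.r2_conditional <= 1 + 1e-12:
            raise ValueError("need 0 <= R2_marginal <= R2_conditional <= 1")

    def sd(self, factor: str) -> float:
        return float(np.sqrt(getattr(self, f"sigma2_{factor}")))

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["beta"] = list(self.beta)
        d["boundary_factors"] = list(self.boundary_factors)
        d["dropped_factors"] = list(self.dropped_factors)
        return d


class _RemlProblem:
    """Precomputed cross-products for the profiled REML criterion.

    All per-evaluation work is O(q²) plus one q×q Cholesky; nothing
    touches the n×q indicator matrix explicitly.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 factor_codes: list[np.ndarray],
                 factor_sizes: list[int]):
        self.n, self.p = X.shape
        self.sizes = factor_sizes
        self.q = int(sum(factor_sizes))
        offs = np.concatenate([[0], np.cumsum(factor_sizes)])
        self.offsets = offs
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtX = np.zeros((self.q, self.p))
        self.Zty = np.zeros(self.q)
        self.ZtZ = np.zeros((self.q, self.q))
        for r, codes_r in enumerate(factor_codes):
            np.add.at(self.ZtX[offs[r]:offs[r + 1]], codes_r, X)
            np.add.at(self.Zty[offs[r]:offs[r + 1]], codes_r, y)
            for s, codes_s in enumerate(factor_codes):
                block = np.zeros((factor_sizes[r], factor_sizes[s]))
                np.add.at(block, (codes_r, codes_s), 1.0)
                self.ZtZ[offs[r]:offs[r + 1], offs[s]:offs[s + 1]] = block

    def _expand(self, gammas: np.ndarray) -> np.ndarray:
        return np.repeat(gammas, self.sizes)

    def profile(self, gammas: np.ndarray):
        """Profiled REML pieces at variance ratios γ ≥ 0.

        Returns ``(criterion, beta, sigma2_resid)`` where criterion is
        −2·(restricted log-likelihood) up to an additive constant.
        """
        d = np.sqrt(self._expand(gammas))
        M = np.eye(self.q) + (d[:, None] * self.ZtZ) * d[None, :]
        cF = linalg.cho_factor(M, lower=True)
        logdet_w = 2.0 * float(np.sum(np.log(np.diag(cF[0]))))
        A = d[:, None] * self.ZtX          # q x p
        b = d * self.Zty                   # q
        MiA = linalg.cho_solve(cF, A)
        Mib = linalg.cho_solve(cF, b)
        XWX = self.XtX - A.T @ MiA
        XWy = self.Xty - A.T @ Mib
        yWy = self.yty - b @ Mib
        cX = linalg.cho_factor(XWX, lower=True)
        beta = linalg.cho_solve(cX, XWy)
        rss = max(yWy - XWy @ beta, 1e-12)
        sigma2 = rss / (self.n - self.p)
        logdet_xwx = 2.0 * float(np.sum(np.log(np.diag(cX[0]))))
        crit = (self.n - self.p) * np.log(rss) + logdet_w + logdet_xwx
        return float(crit), beta, float(sigma2)


def fit_lmm(table: METFTable, poly_order: int = 3,
            grid: FrequencyGrid | None = None,
            max_iter: int = 200, tol: float = 1e-8,
            ) -> VarianceDecomposition:
    """REML variance decomposition of an METF table.

    Fixed effects: polynomial of ``poly_order`` in standardized log10
    frequency.  Random effects: crossed intercepts for specimen
    (``tb``), measurement ``method`` and research ``group``; factors
    with a single observed level are dropped with a warning and their
    variance reported as 0.  The optimization (Nelder–Mead over
    log-variance-ratios, started from equal ratios) is deterministic
    given the data; non-convergence is flagged, never silent.
    """
    df = table.df
    if not len(df):
        raise ValueError("cannot fit an empty table")
    freqs = np.sort(df["frequency_hz"].unique())
    if grid is None:
        grid = FrequencyGrid(tuple(freqs))
    z = standardize_log_frequency(df["frequency_hz"].to_numpy(), grid)
    X = np.vander(z, poly_order + 1, increasing=True)
    y = df["metf_db"].to_numpy()

    all_factors = ("tb", "method", "group")
    col_of = {"tb": "tb_id", "method": "method", "group": "group"}
    codes_list, sizes, active, dropped = [], [], [], []
    for name in all_factors:
        codes, levels = pd.factorize(df[col_of[name]], sort=True)
        if len(levels) < 2:
            dropped.append(name)
            _log.warning("random factor %r has a single level; dropped "
                         "(variance reported 0)", name)
            continue
        codes_list.append(codes)
        sizes.append(len(levels))
        active.append(name)
    if not active:
        raise ValueError("no random factor has >= 2 levels")

    prob = _RemlProblem(y, X, codes_list, sizes)
    lo, hi = -16.0, 8.0

    def objective(theta: np.ndarray) -> float:
        return prob.profile(np.exp(np.clip(theta, lo, hi)))[0]

    x0 = np.zeros(len(active))
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"maxiter": max_iter * len(active) * 20,
                                     "xatol": 1e-6, "fatol": tol,
                                     "adaptive": True})
    theta = np.clip(res.x, lo, hi)
    gammas = np.exp(theta)
    crit, beta, sigma2_resid = prob.profile(gammas)

    sigma2 = {name: 0.0 for name in all_factors}
    boundary = []
    for name, g in zip(active, gammas):
        var = g * sigma2_resid
        if g <= np.exp(lo) * 1.01 or var < 1e-10:
            var = 0.0
            boundary.append(name)
        sigma2[name] = float(var)

    fixed_pred = X @ beta
    sigma2_fixed = float(fixed_pred.var(ddof=0))
    total = sigma2_fixed + sum(sigma2.values()) + sigma2_resid
    r2_m = sigma2_fixed / total
    r2_c = (sigma2_fixed + sum(sigma2.values())) / total

    return VarianceDecomposition(
        beta=tuple(float(b) for b in beta),
        sigma2_tb=sigma2["tb"], sigma2_method=sigma2["method"],
        sigma2_group=sigma2["group"], sigma2_resid=sigma2_resid,
        sigma2_fixed=sigma2_fixed, r2_marginal=r2_m, r2_conditional=r2_c,
        loglik=-0.5 * crit, converged=bool(res.success),
        n_obs=prob.n, poly_order=poly_order,
        boundary_factors=tuple(boundary), dropped_factors=tuple(dropped))


def r2_nakagawa(decomp: VarianceDecomposition) -> tuple[float, float]:
    """Marginal and conditional R² from the variance components.

    R²_marginal = σ²_f / (σ²_f + Σσ²_random + σ²_ε); the conditional
    variant adds the random components to the numerator.
    """
    s_rand = (decomp.sigma2_tb + decomp.sigma2_method + decomp.sigma2_group)
    denom = decomp.sigma2_fixed + s_rand + decomp.sigma2_resid
    if denom <= 0:
        raise ValueError("total variance is zero; R² undefined")
    return (decomp.sigma2_fixed / denom,
            (decomp.sigma2_fixed + s_rand) / denom)
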