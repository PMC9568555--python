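"""Synthetic METF populations with the variance structure of real data.

Real multicenter METF data decomposes into a shared cubic-in-log-
frequency mean curve, crossed random intercepts for specimen (temporal
bone), measurement method, and research group, and per-point residual
noise that is mildly left-skewed at low frequencies.  The generator
reproduces exactly that structure:

    y(tb, f) = Σ_q β_q·z(f)^q + u_group + u_method + u_tb + ε(tb, f)

with z the standardized log10 frequency, u's drawn once per level
(crossed, not nested) and ε i.i.d. per point, optionally passed through
a variance-preserving skew-normal transform.  Default standard
deviations follow the published variance decomposition: 4.2 dB
(specimen), 3.4 dB (method), 1.4 dB (group); the residual default of
3.0 dB is derived so the implied total SD ≈ 5.2 dB matches the
published 95% tolerance half-width near 1 kHz (≈10.4 dB) divided by the
large-sample two-sided tolerance factor ≈ 2.0.

Each entity class (groups, methods, specimens, residuals) draws from
its own RNG stream derived from the master seed, so enlarging the
population never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    AUDIOLOGICAL_GRID,
    FrequencyGrid,
    METFTable,
    METF_COLUMNS,
    ReferenceTable,
    get_logger,
    packaged_reference,
)

__all__ = [
    "PopulationSpec",
    "GroundTruth",
    "standardize_log_frequency",
    "fit_mean_curve",
    "default_mean_curve",
    "sample_population",
    "make_outlier_fixtures",
]

_log = get_logger("synthetic")

#: Published random-intercept standard deviations, dB.
SIGMA_TB_DEFAULT = 4.2
SIGMA_METHOD_DEFAULT = 3.4
SIGMA_GROUP_DEFAULT = 1.4
#: Derived residual SD, dB (see module docstring).
SIGMA_RESID_DEFAULT = 3.0

_GROUP_LABELS = ("Dresden", "Hannover", "Shanghai", "Zurich", "Colorado")
_METHOD_LABELS = ("A", "B", "C", "D")


def standardize_log_frequency(frequencies_hz, grid: FrequencyGrid):
    """Map frequencies to standardized log10 scale over a grid.

    z = (log10 f − mean)/SD with mean/SD taken over the grid (population
    SD).  Keeps the cubic design well-conditioned.
    """
    logg = np.log10(grid.as_array())
    mu, sd = logg.mean(), logg.std()
    return (np.log10(np.asarray(frequencies_hz, dtype=float)) - mu) / sd


def fit_mean_curve(reference: ReferenceTable,
                   grid: FrequencyGrid | None = None):
    """Least-squares cubic (in standardized log10 f) through reference means.

    Returns ``(coeffs, residuals)`` where ``coeffs`` are β_0..β_3 in
    ascending power order and ``residuals`` are the per-frequency
    fit residuals in dB.
    """
    freqs = np.asarray(reference.frequencies_hz)
    if len(freqs) < 4:
        raise ValueError(
            f"need >= 4 frequencies to fit a cubic, got {len(freqs)}")
    if grid is None:
        grid = FrequencyGrid(tuple(freqs))
    z = standardize_log_frequency(freqs, grid)
    means = np.array([reference.stats[f].mean_db for f in freqs])
    coeffs = np.polynomial.polynomial.polyfit(z, means, deg=3)
    residuals = means - np.polynomial.polynomial.polyval(z, coeffs)
    return coeffs, residuals


def default_mean_curve() -> np.ndarray:
    """Cubic coefficients fitted to the packaged displacement means."""
    coeffs, _ = fit_mean_curve(packaged_reference("displacement"),
                               grid=AUDIOLOGICAL_GRID)
    return coeffs


@dataclass(frozen=True)
class PopulationSpec:
    """Design and variance parameters of a synthetic METF population.

    The population is a full cross of ``n_groups`` research groups and
    ``n_methods`` measurement methods with ``n_tb_per_cell`` specimens
    in each cell.  Groups/methods reuse the real lab labels while they
    last ("Dresden", …, method "A"–"D") and switch to synthetic labels
    ("G06", "M05", …) beyond them.  ``skew_shape`` is the skew-normal
    shape applied to residuals (0 = Gaussian; negative = left skew).
    """

    n_groups: int = 4
    n_methods: int = 1
    n_tb_per_cell: int = 30
    sigma_tb: float = SIGMA_TB_DEFAULT
    sigma_method: float = SIGMA_METHOD_DEFAULT
    sigma_group: float = SIGMA_GROUP_DEFAULT
    sigma_resid: float = SIGMA_RESID_DEFAULT
    mean_curve: tuple[float, float, float, float] | None = None
    skew_shape: float = 0.0
    grid: FrequencyGrid = AUDIOLOGICAL_GRID
    unit: str = "displacement"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_tb", "sigma_method", "sigma_group",
                     "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_groups, self.n_methods, self.n_tb_per_cell) < 1:
            raise ValueError("design counts must be >= 1")
        if len(self.grid) == 0:
            raise ValueError("grid must be nonempty")
        if self.mean_curve is not None:
            mc = tuple(float(c) for c in self.mean_curve)
            if len(mc) != 4:
                raise ValueError("mean_curve must have 4 coefficients")
            object.__setattr__(self, "mean_curve", mc)

    def resolved_mean_curve(self) -> np.ndarray:
        if self.mean_curve is not None:
            return np.asarray(self.mean_curve, dtype=float)
        return default_mean_curve()

    def group_labels(self) -> list[str]:
        return [_GROUP_LABELS[i] if i < len(_GROUP_LABELS) else f"G{i + 1:02d}"
                for i in range(self.n_groups)]

    def method_labels(self) -> list[str]:
        return [_METHOD_LABELS[i] if i < len(_METHOD_LABELS)
                else f"M{i + 1:02d}" for i in range(self.n_methods)]


@dataclass(frozen=True)
class GroundTruth:
    """Realized random effects and noise-free values of a sample.

    ``intercepts`` has one row per specimen (tb_id, group, method,
    u_tb, u_method, u_group); ``noise_free`` one row per data point
    (tb_id, frequency_hz, truth_db) where truth_db is the mean curve
    plus the specimen's intercept sum.
    """

    intercepts: pd.DataFrame
    noise_free: pd.DataFrame
    mean_curve: tuple[float, float, float, float]


def _standardized_skew_normal(rng: np.random.Generator, shape: float,
                              size: int) -> np.ndarray:
    """Skew-normal draws standardized to mean 0, variance 1."""
    if shape == 0.0:
        return rng.standard_normal(size)
    delta = shape / np.sqrt(1.0 + shape ** 2)
    mean = delta * np.sqrt(2.0 / np.pi)
    sd = np.sqrt(1.0 - 2.0 * delta ** 2 / np.pi)
    draws = stats.skewnorm.rvs(shape, size=size, random_state=rng)
    return (draws - mean) / sd


def sample_population(spec: PopulationSpec) -> tuple[METFTable, GroundTruth]:
    """Draw a synthetic METF population; fully seed-deterministic.

    Returns the long-format table together with its ground truth
    (realized intercepts and noise-free values), enabling parameter-
    recovery tests downstream.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_group, rng_method, rng_tb, rng_resid = (
        np.random.default_rng(c) for c in ss.spawn(4))

    groups = spec.group_labels()
    methods = spec.method_labels()
    u_group = dict(zip(groups,
                       spec.sigma_group * rng_group.standard_normal(
                           spec.n_groups)))
    u_method = dict(zip(methods,
                        spec.sigma_method * rng_method.standard_normal(
                            spec.n_methods)))

    z = standardize_log_frequency(spec.grid.as_array(), spec.grid)
    coeffs = spec.resolved_mean_curve()
    mean_db = np.polynomial.polynomial.polyval(z, coeffs)
    n_f = len(spec.grid)

    rows = []
    icpt_rows = []
    truth_rows = []
    tb_counter = 0
    for g in groups:
        for m in methods:
            n_cell = spec.n_tb_per_cell
            u_tbs = spec.sigma_tb * rng_tb.standard_normal(n_cell)
            for j in range(n_cell):
                tb_counter += 1
                tb_id = f"TB{tb_counter:05d}"
                base = mean_db + u_group[g] + u_method[m] + u_tbs[j]
                eps = spec.sigma_resid * _standardized_skew_normal(
                    rng_resid, spec.skew_shape, n_f)
                vals = base + eps
                for f, t_db, v in zip(spec.grid, base, vals):
                    rows.append((tb_id, g, m, f, v, spec.unit,
                                 np.nan, False))
                    truth_rows.append((tb_id, f, t_db))
                icpt_rows.append((tb_id, g, m, u_tbs[j],
                                  u_method[m], u_group[g]))

    table = METFTable(pd.DataFrame(rows, columns=METF_COLUMNS))
    truth = GroundTruth(
        intercepts=pd.DataFrame(
            icpt_rows, columns=["tb_id", "group", "method",
                                "u_tb", "u_method", "u_group"]),
        noise_free=pd.DataFrame(
            truth_rows, columns=["tb_id", "frequency_hz", "truth_db"]),
        mean_curve=tuple(coeffs),
    )
    _log.info("sampled population: %d specimens x %d frequencies",
              tb_counter, n_f)
    return table, truth


# ---------------------------------------------------------------------------
# Adversarial fixtures for the outlier stage
# ---------------------------------------------------------------------------

#: Verdict labels used in outlier-fixture manifests.
FIXTURE_VERDICTS = ("discard", "truncate_high", "truncate_low", "keep")


def make_outlier_fixtures(base: METFTable, seed: int = 0,
                          k: float = 1.75) -> tuple[METFTable,
                                                    dict[str, str]]:
    """Inject known-outlier curves into a table; returns the manifest.

    The base is first screened at the same ``k`` so that chance
    extremes of the base population do not masquerade as fixtures;
    three seeded-chosen curves of the screened base are then displaced
    far outside any plausible fence: +30 dB at 2 kHz only (a core-band
    outlier, expected verdict ``discard``), −30 dB at 6 kHz only
    (expected ``truncate_high``), and −30 dB at 125 Hz only (expected
    ``truncate_low``).  All other curves are untouched and expected
    ``keep``.  The manifest maps tb_id to the expected verdict.
    """
    from .outlier_detection import screen_table
    rng = np.random.default_rng(seed)
    injections = ((2000.0, +30.0, "discard"),
                  (6000.0, -30.0, "truncate_high"),
                  (125.0, -30.0, "truncate_low"))
    for _ in range(20):
        # screen the base to a fixed point: removing extremes tightens
        # the fences, which can expose new borderline points
        for _ in range(20):
            screened, rep = screen_table(base, k=k)
            if all(v.verdict == "keep" for v in rep.verdicts.values()):
                break
            base = screened
        tb_ids = base.tb_ids
        if len(tb_ids) < 4:
            raise ValueError("need >= 4 curves to build outlier fixtures")
        df = base.df.copy()
        manifest = {tb: "keep" for tb in tb_ids}
        taken: set[str] = set()
        for f, delta, verdict in injections:
            has_f = set(df.loc[df["frequency_hz"] == f, "tb_id"]) - taken
            if not has_f:
                raise ValueError(f"no remaining curve has a point at {f} Hz")
            tb = str(rng.choice(sorted(has_f)))
            sel = (df["tb_id"] == tb) & (df["frequency_hz"] == f)
            df.loc[sel, "metf_db"] += delta
            manifest[tb] = verdict
            taken.add(tb)
        fixture = METFTable(df)
        # the injections themselves shift the fences slightly; verify
        # the manifest is self-consistent and drop any base curve the
        # shifted fences now flag, then rebuild
        _, rep = screen_table(fixture, k=k)
        offenders = [t for t, v in manifest.items()
                     if rep.verdicts[t].verdict != v]
        if not offenders:
            return fixture, manifest
        keep_ids = [t for t in tb_ids if t not in offenders or t in taken]
        base = METFTable(base.df[base.df["tb_id"].isin(keep_ids)])
    raise RuntimeError("outlier fixtures did not stabilise in 20 rounds")
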