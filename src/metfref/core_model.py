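"""Core domain types and I/O for METF reference-range analysis.

The middle ear transfer function (METF) relates sound pressure at the
tympanic membrane to the motion of the stapes footplate, the chain's
output into the inner ear.  Magnitudes are analysed on the dB scale in
one of two unit conventions:

* ``displacement`` — dB re 1 µm/Pa (stapes footplate displacement), and
* ``velocity``     — dB re 1 µm/s/Pa (stapes footplate velocity),

which are related per frequency by the exact affine map
``velocity_db = displacement_db + 20·log10(2·pi·f)``.

This module holds the frequency grid and curve/table containers, the CSV
interchange format, the packaged multicenter reference table, the LDV
angle correction, and pipeline configuration/logging.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUDIOLOGICAL_GRID",
    "GROUPS",
    "METHODS",
    "UNITS",
    "FrequencyGrid",
    "METFCurve",
    "METFTable",
    "FrequencyStats",
    "ReferenceTable",
    "PipelineConfig",
    "SchemaError",
    "IntegrityError",
    "read_metf_csv",
    "write_metf_csv",
    "read_reference_csv",
    "write_reference_csv",
    "packaged_reference",
    "convert_unit",
    "unit_offset_db",
    "apply_angle_correction",
    "angle_correction_db",
    "get_logger",
    "configure_logging",
]

# ---------------------------------------------------------------------------
# Configuration & logging
# ---------------------------------------------------------------------------

_LOGGER_NAME = "metfref"


def get_logger(child: str | None = None) -> logging.Logger:
    name = _LOGGER_NAME if child is None else f"{_LOGGER_NAME}.{child}"
    return logging.getLogger(name)


def configure_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = logging.WARNING
    if verbosity == 1:
        level = logging.INFO
    elif verbosity >= 2:
        level = logging.DEBUG
    logger = logging.getLogger(_LOGGER_NAME)
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the analysis pipeline.

    ``outlier_k`` multiplies the interquartile range when setting Tukey
    fences (1.75 accommodates the left skew of METF magnitudes).  The
    ``core_band_hz`` is the frequency band whose integrity decides
    whole-curve exclusion versus edge truncation.  ``interp_axis``
    selects the interpolation abscissa ("hz" for linear-in-Hz, "log_hz"
    for linear in log10 frequency).  ``holm_family`` scopes the Holm
    adjustment ("frequency" = pairwise tests within one frequency,
    "global" = all tests pooled).  ``quantile_method`` is handed to
    numpy's quantile routine; exclusion counts are sensitive to it.
    """

    outlier_k: float = 1.75
    core_band_hz: tuple[float, float] = (500.0, 4000.0)
    alpha: float = 0.05
    ti_proportions: tuple[float, ...] = (0.90, 0.95, 0.99)
    quality_profile: str = "dresden"
    interp_axis: str = "hz"
    holm_family: str = "frequency"
    quantile_method: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outlier_k <= 0:
            raise ValueError(f"outlier_k must be > 0, got {self.outlier_k}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for p in self.ti_proportions:
            if not 0 < p < 1:
                raise ValueError(f"TI proportion must be in (0, 1), got {p}")
        lo, hi = self.core_band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid core band {self.core_band_hz}")
        if self.interp_axis not in ("hz", "log_hz"):
            raise ValueError(f"unknown interp_axis {self.interp_axis!r}")
        if self.holm_family not in ("frequency", "global"):
            raise ValueError(f"unknown holm_family {self.holm_family!r}")


# ---------------------------------------------------------------------------
# Frequency grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive measurement frequencies in Hz."""

    frequencies_hz: tuple[float, ...]

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_hz)
        if len(freqs) == 0:
            raise ValueError("frequency grid must be nonempty")
        if any(f <= 0 for f in freqs):
            raise ValueError("all grid frequencies must be positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("grid frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", freqs)

    def __iter__(self):
        return iter(self.frequencies_hz)

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    def __contains__(self, f: float) -> bool:
        return float(f) in self.frequencies_hz

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies_hz, dtype=float)


#: The canonical audiological reporting grid in Hz.
AUDIOLOGICAL_GRID = FrequencyGrid((125.0, 250.0, 500.0, 1000.0,
                                   2000.0, 3000.0, 4000.0, 6000.0))

GROUPS = ("Colorado", "Dresden", "Hannover", "Shanghai", "Zurich", "synthetic")
METHODS = ("A", "B", "C", "D")
UNITS = ("displacement", "velocity")

#: dB reference strings per unit, for display only.
UNIT_LABELS = {
    "displacement": "dB re 1 um/Pa",
    "velocity": "dB re 1 um/s/Pa",
}


# ---------------------------------------------------------------------------
# Curves and tables
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


class IntegrityError(ValueError):
    """Table content violates a structural invariant (e.g. duplicates)."""


@dataclass(frozen=True)
class METFCurve:
    """One specimen's METF magnitude record with provenance.

    ``points`` maps frequency in Hz to magnitude in dB; frequencies may
    be any subset of a grid (missing points are simply absent).
    ``angle_deg`` is the LDV incidence angle to the footplate normal,
    when recorded; ``angle_corrected`` states whether the cos(θ)
    underestimation has already been compensated.
    """

    tb_id: str
    group: str
    method: str
    unit: str
    points: Mapping[float, float]
    angle_deg: float | None = None
    angle_corrected: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown research group {self.group!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown measurement method {self.method!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        pts = {float(f): float(m) for f, m in self.points.items()}
        if any(f <= 0 for f in pts):
            raise ValueError("curve frequencies must be positive")
        if any(not math.isfinite(m) for m in pts.values()):
            raise ValueError(f"non-finite magnitude in curve {self.tb_id!r}")
        if self.angle_deg is not None and not 0 <= self.angle_deg < 90:
            raise ValueError(f"angle must be in [0, 90), got {self.angle_deg}")
        object.__setattr__(self, "points", dict(sorted(pts.items())))

    @property
    def frequencies_hz(self) -> tuple[float, ...]:
        return tuple(self.points.keys())

    def magnitude_at(self, f: float) -> float:
        return self.points[float(f)]


#: Frozen column order of the METF CSV interchange format.
METF_COLUMNS = ["tb_id", "group", "method", "frequency_hz", "metf_db",
                "unit", "angle_deg", "angle_corrected"]


class METFTable:
    """Long-format collection of METF curves (one row per data point).

    Thin wrapper over a pandas DataFrame with the frozen METF column
    schema; the unit must be uniform and (tb_id, frequency) pairs unique.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in METF_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = df[METF_COLUMNS].copy()
        df["tb_id"] = df["tb_id"].astype(str)
        df["frequency_hz"] = df["frequency_hz"].astype(float)
        df["metf_db"] = df["metf_db"].astype(float)
        df["angle_corrected"] = df["angle_corrected"].astype(bool)
        if len(df):
            units = df["unit"].unique()
            if len(units) > 1:
                raise IntegrityError(f"mixed units in table: {sorted(units)}")
            if not np.isfinite(df["metf_db"]).all():
                bad = df.loc[~np.isfinite(df["metf_db"]), "tb_id"].tolist()
                raise IntegrityError(f"non-finite magnitudes for {bad}")
            dup = df.duplicated(subset=["tb_id", "frequency_hz"])
            if dup.any():
                pairs = df.loc[dup, ["tb_id", "frequency_hz"]]
                raise IntegrityError(
                    "duplicate (tb_id, frequency) pairs: "
                    f"{pairs.to_records(index=False).tolist()}"
                )
        self.df = df.sort_values(["tb_id", "frequency_hz"],
                                 kind="stable").reset_index(drop=True)

    # -- container basics ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, METFTable):
            return NotImplemented
        a, b = self.df, other.df
        if len(a) != len(b):
            return False
        return a.equals(b)

    @property
    def unit(self) -> str | None:
        return self.df["unit"].iloc[0] if len(self.df) else None

    @property
    def tb_ids(self) -> list[str]:
        return self.df["tb_id"].unique().tolist()

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.sort(self.df["frequency_hz"].unique())

    def n_curves(self) -> int:
        return self.df["tb_id"].nunique()

    # -- conversions --------------------------------------------------------

    @classmethod
    def from_curves(cls, curves: Iterable[METFCurve]) -> "METFTable":
        rows = []
        for c in curves:
            for f, m in c.points.items():
                rows.append((c.tb_id, c.group, c.method, f, m, c.unit,
                             np.nan if c.angle_deg is None else c.angle_deg,
                             c.angle_corrected))
        df = pd.DataFrame(rows, columns=METF_COLUMNS)
        if not rows:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                METF_COLUMNS,
                [str, str, str, float, float, str, float, bool])})
        return cls(df)

    def curves(self) -> list[METFCurve]:
        out = []
        for tb_id, sub in self.df.groupby("tb_id", sort=True):
            first = sub.iloc[0]
            angle = first["angle_deg"]
            out.append(METFCurve(
                tb_id=str(tb_id),
                group=first["group"],
                method=first["method"],
                unit=first["unit"],
                points=dict(zip(sub["frequency_hz"], sub["metf_db"])),
                angle_deg=None if pd.isna(angle) else float(angle),
                angle_corrected=bool(first["angle_corrected"]),
            ))
        return out

    def subset(self, mask) -> "METFTable":
        return METFTable(self.df.loc[mask])


def read_metf_csv(path: str | Path) -> METFTable:
    """Read the long-format METF CSV; rejects malformed rows by address.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`IntegrityError` on duplicate (tb_id, frequency) pairs or rows
    whose numeric fields do not parse (the error lists offending line
    numbers, 1-based including the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")

    def parse_floats(col: str, allow_empty: bool) -> np.ndarray:
        # Python's float() round-trips %.17g exactly; pandas' fast
        # parser can be off by one ulp.
        out = np.empty(len(df))
        for j, s in enumerate(df[col]):
            s = s.strip()
            if s == "" and allow_empty:
                out[j] = np.nan
                continue
            try:
                out[j] = float(s)
            except ValueError:
                out[j] = np.inf  # marked unparseable below
                bad_cells.add((j, col))
        return out

    bad_cells: set[tuple[int, str]] = set()
    bad_rows: list[str] = []
    freq = parse_floats("frequency_hz", allow_empty=False)
    mag = parse_floats("metf_db", allow_empty=False)
    angle = parse_floats("angle_deg", allow_empty=True)
    corrected = df["angle_corrected"].str.strip().str.lower()
    for i in range(len(df)):
        problems = [c for c in ("frequency_hz", "metf_db", "angle_deg")
                    if (i, c) in bad_cells]
        if "metf_db" not in problems and not np.isfinite(mag[i]):
            problems.append("metf_db")
        if corrected.iloc[i] not in ("true", "false", "0", "1"):
            problems.append("angle_corrected")
        if problems:
            bad_rows.append(f"row {i + 2}: unparseable {problems}")
    if bad_rows:
        raise IntegrityError(f"{path.name}: " + "; ".join(bad_rows))

    out = df.copy()
    out["frequency_hz"] = freq
    out["metf_db"] = mag
    out["angle_deg"] = angle
    out["angle_corrected"] = corrected.isin(("true", "1"))
    return METFTable(out)


def write_metf_csv(table: METFTable, path: str | Path) -> None:
    """Write the table as RFC-4180-style CSV at full float precision."""
    df = table.df.copy()
    df["angle_corrected"] = np.where(df["angle_corrected"], "true", "false")
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyStats:
    """Per-frequency reference statistics: mean, CI of mean, TIs."""

    n: int
    mean_db: float
    ci95: tuple[float, float]
    ti: Mapping[float, tuple[float, float]]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.mean_db <= hi:
            raise ValueError("mean must lie inside its confidence interval")
        for p, (tlo, thi) in self.ti.items():
            if not 0 < p < 1:
                raise ValueError(f"TI proportion {p} outside (0, 1)")
            if not (tlo <= lo and hi <= thi):
                raise ValueError(
                    f"TI({p}) must contain the CI of the mean "
                    f"({tlo}, {thi}) vs ({lo}, {hi})"
                )
        object.__setattr__(self, "ti", dict(sorted(self.ti.items())))


@dataclass(frozen=True)
class ReferenceTable:
    """Per-frequency reference range for a stated unit.

    ``stats`` maps frequency in Hz to :class:`FrequencyStats`.  ``alpha``
    is the TI confidence complement (TIs are (p, 1−alpha) two-sided).
    ``n_curves``/``n_points`` are provenance metadata about the sample
    the table was built from.
    """

    unit: str
    stats: Mapping[float, FrequencyStats]
    alpha: float = 0.05
    n_curves: int | None = None
    n_points: int | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        stats = {float(f): s for f, s in self.stats.items()}
        for f, s in stats.items():
            widths = [hi - lo for (lo, hi) in s.ti.values()]
            if any(b < a - 1e-12 for a, b in zip(widths, widths[1:])):
                raise ValueError(
                    f"TI widths must be non-decreasing in p at {f} Hz")
        object.__setattr__(self, "stats", dict(sorted(stats.items())))

    @property
    def frequencies_hz(self) -> tuple[float, ...]:
        return tuple(self.stats.keys())

    def ti_bounds(self, f: float, p: float = 0.95) -> tuple[float, float]:
        """TI bounds at frequency ``f``, falling back to p=0.95 if the
        requested proportion is not tabulated."""
        s = self.stats[float(f)]
        if p in s.ti:
            return s.ti[p]
        if 0.95 in s.ti:
            get_logger("core").warning(
                "TI proportion %.2f not tabulated at %g Hz; using 0.95", p, f)
            return s.ti[0.95]
        raise KeyError(f"no TI at p={p} or 0.95 for {f} Hz")


REFERENCE_COLUMNS = ["unit", "frequency_hz", "n", "mean_db",
                     "ci95_lo", "ci95_hi", "ti90_lo", "ti90_hi",
                     "ti95_lo", "ti95_hi", "ti99_lo", "ti99_hi"]


def write_reference_csv(tables: Sequence[ReferenceTable],
                        path: str | Path) -> None:
    rows = []
    for t in tables:
        for f, s in t.stats.items():
            row: dict[str, object] = {
                "unit": t.unit, "frequency_hz": f, "n": s.n,
                "mean_db": s.mean_db,
                "ci95_lo": s.ci95[0], "ci95_hi": s.ci95[1],
            }
            for p, key in ((0.90, "ti90"), (0.95, "ti95"), (0.99, "ti99")):
                lo, hi = s.ti.get(p, (np.nan, np.nan))
                row[f"{key}_lo"], row[f"{key}_hi"] = lo, hi
            rows.append(row)
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_reference_csv(path: str | Path) -> list[ReferenceTable]:
    df = pd.read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing reference column(s): {missing}")
    tables = []
    for unit, sub in df.groupby("unit", sort=True):
        stats = {}
        for _, r in sub.iterrows():
            ti = {}
            for p, key in ((0.90, "ti90"), (0.95, "ti95"), (0.99, "ti99")):
                lo, hi = r[f"{key}_lo"], r[f"{key}_hi"]
                if np.isfinite(lo) and np.isfinite(hi):
                    ti[p] = (float(lo), float(hi))
            stats[float(r["frequency_hz"])] = FrequencyStats(
                n=int(r["n"]), mean_db=float(r["mean_db"]),
                ci95=(float(r["ci95_lo"]), float(r["ci95_hi"])), ti=ti)
        tables.append(ReferenceTable(unit=str(unit), stats=stats))
    return tables


# ---------------------------------------------------------------------------
# Packaged multicenter reference (printed values)
# ---------------------------------------------------------------------------

# Mean, 95% CI of the mean, and two-sided (0.95, 0.95) TI per audiological
# frequency, for the pooled single-point-LDV footplate data (method "A")
# from the four contributing laboratories.  The underlying multicenter
# dataset is described both as 366 curves / 2321 points and as 362
# measurements; 366/2321 is recorded here and the discrepancy left as
# stated.  90% and 99% TI bounds are not tabulated for these constants,
# so only the 95% proportion is populated.
_TABLE_DISPLACEMENT = {
    # f_hz: (mean, ci_lo, ci_hi, ti95_lo, ti95_hi)   [dB re 1 um/Pa]
    125.0:  (-31.6, -32.2, -30.9, -43.2, -19.9),
    250.0:  (-34.2, -34.8, -33.6, -46.1, -22.3),
    500.0:  (-33.2, -33.8, -32.5, -45.8, -20.5),
    1000.0: (-34.4, -34.9, -33.8, -44.7, -24.0),
    2000.0: (-45.7, -46.3, -45.0, -58.0, -33.3),
    3000.0: (-53.2, -54.0, -52.5, -68.1, -38.4),
    4000.0: (-57.8, -58.7, -56.9, -76.0, -39.6),
    6000.0: (-67.0, -68.0, -66.1, -85.5, -48.7),
}
_TABLE_VELOCITY = {
    # f_hz: (mean, ci_lo, ci_hi, ti95_lo, ti95_hi)   [dB re 1 um/s/Pa]
    125.0:  (26.3, 25.6, 27.0, 14.7, 38.0),
    250.0:  (29.7, 29.1, 30.3, 17.8, 41.6),
    500.0:  (36.8, 36.1, 37.4, 24.1, 49.4),
    1000.0: (41.6, 41.1, 42.1, 31.3, 52.0),
    2000.0: (36.3, 35.7, 36.9, 24.0, 48.7),
    3000.0: (32.3, 31.5, 33.0, 17.4, 47.1),
    4000.0: (30.2, 29.3, 31.1, 12.0, 48.4),
    6000.0: (24.4, 23.5, 25.4, 6.0, 42.9),
}

REFERENCE_N_CURVES = 366
REFERENCE_N_POINTS = 2321


def packaged_reference(unit: str) -> ReferenceTable:
    """Packaged multicenter reference constants for the requested unit.

    Returns the printed per-frequency mean, 95% CI of the mean, and
    two-sided 95%/95% tolerance interval; only the 95% TI proportion is
    populated (see module notes).  ``n`` per frequency is not published
    per frequency and is recorded as the overall curve count.
    """
    if unit == "displacement":
        src = _TABLE_DISPLACEMENT
    elif unit == "velocity":
        src = _TABLE_VELOCITY
    else:
        raise ValueError(f"unknown unit {unit!r}; expected one of {UNITS}")
    stats = {
        f: FrequencyStats(
            n=REFERENCE_N_CURVES, mean_db=mean, ci95=(clo, chi),
            ti={0.95: (tlo, thi)})
        for f, (mean, clo, chi, tlo, thi) in src.items()
    }
    return ReferenceTable(unit=unit, stats=stats, alpha=0.05,
                          n_curves=REFERENCE_N_CURVES,
                          n_points=REFERENCE_N_POINTS)


# ---------------------------------------------------------------------------
# Unit conversion and angle correction
# ---------------------------------------------------------------------------


def unit_offset_db(frequency_hz: float) -> float:
    """dB offset from displacement to velocity at one frequency.

    Differentiating a sinusoidal displacement multiplies its amplitude
    by the angular frequency, hence +20·log10(2·pi·f) on the dB scale.
    """
    f = float(frequency_hz)
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return 20.0 * math.log10(2.0 * math.pi * f)


def convert_unit(curve: METFCurve, target_unit: str) -> METFCurve:
    """Convert a curve between displacement and velocity dB conventions."""
    if target_unit not in UNITS:
        raise ValueError(f"unknown unit {target_unit!r}")
    if curve.unit == target_unit:
        raise ValueError(f"curve is already in unit {target_unit!r}")
    sign = +1.0 if target_unit == "velocity" else -1.0
    points = {f: m + sign * unit_offset_db(f) for f, m in curve.points.items()}
    return replace(curve, unit=target_unit, points=points)


def angle_correction_db(theta_deg: float) -> float:
    """Magnitude correction in dB for LDV incidence angle θ.

    A beam at angle θ to the footplate normal measures the motion
    projection ``d·cos(θ)``; adding ``−20·log10(cos θ)`` dB restores the
    actual magnitude.  Zero at θ=0 and strictly increasing on [0°, 90°).
    """
    if not 0 <= theta_deg < 90:
        raise ValueError(f"angle must be in [0, 90) degrees, got {theta_deg}")
    return -20.0 * math.log10(math.cos(math.radians(theta_deg)))


def apply_angle_correction(curve: METFCurve,
                           theta_deg: float | None = None) -> METFCurve:
    """Apply the cos(θ) angle correction to every point of a curve.

    Uses the curve's recorded angle when ``theta_deg`` is omitted.
    Raises if the curve is already corrected (the correction must not be
    applied twice).
    """
    if curve.angle_corrected:
        raise ValueError(f"curve {curve.tb_id!r} is already angle-corrected")
    if theta_deg is None:
        theta_deg = curve.angle_deg
    if theta_deg is None:
        raise ValueError(f"no angle recorded for curve {curve.tb_id!r}")
    delta = angle_correction_db(theta_deg)
    points = {f: m + delta for f, m in curve.points.items()}
    return replace(curve, points=points, angle_deg=float(theta_deg),
                   angle_corrected=True)
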