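"""From gated transfer estimates to analysis-ready METF tables.

Acquisition grids differ between labs (64–1024 FFT bins, stepped single
sines), so every measurement is linearly interpolated onto the common
audiological grid.  Points that fail the lab quality gate cannot be
used as interpolation support; a curve is usable at all only when the
core 1000–4000 Hz band can be interpolated entirely from valid points.
The pipeline order is fixed: quality gate → interpolation → outlier
detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_model import (
    AUDIOLOGICAL_GRID,
    FrequencyGrid,
    METFCurve,
    METFTable,
    get_logger,
)

__all__ = [
    "RawCurve",
    "interpolate_to_grid",
    "enforce_core_validity",
    "assemble_table",
]

_log = get_logger("preprocessing")


@dataclass(frozen=True)
class RawCurve:
    """A quality-gated magnitude spectrum on an arbitrary grid."""

    tb_id: str
    frequencies_hz: np.ndarray
    magnitude_db: np.ndarray
    valid: np.ndarray
    group: str = "synthetic"
    method: str = "A"
    unit: str = "displacement"
    angle_deg: float | None = None
    angle_corrected: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        m = np.asarray(self.magnitude_db, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if not (f.shape == m.shape == v.shape) or f.ndim != 1:
            raise ValueError("frequencies, magnitudes and mask must align")
        if (np.diff(f) <= 0).any():
            order = np.argsort(f)
            f, m, v = f[order], m[order], v[order]
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "magnitude_db", m)
        object.__setattr__(self, "valid", v)


def interpolate_to_grid(raw: RawCurve,
                        grid: FrequencyGrid = AUDIOLOGICAL_GRID,
                        axis: str = "hz") -> METFCurve:
    """Linear interpolation of a raw curve onto the reporting grid.

    Only valid source points participate.  A target frequency takes an
    exact valid match verbatim, is linearly interpolated when valid
    points bracket it, and is left missing otherwise — never
    extrapolated.  ``axis`` selects the interpolation abscissa: "hz"
    (default) interpolates dB magnitude linearly against frequency in
    Hz, "log_hz" against log10 frequency.
    """
    if axis not in ("hz", "log_hz"):
        raise ValueError(f"unknown interpolation axis {axis!r}")
    f = raw.frequencies_hz[raw.valid]
    m = raw.magnitude_db[raw.valid]
    if len(f) == 0:
        raise ValueError(f"curve {raw.tb_id!r} has no valid points")
    x = np.log10(f) if axis == "log_hz" else f
    points: dict[float, float] = {}
    for target in grid:
        exact = np.nonzero(np.isclose(f, target, rtol=1e-9, atol=0.0))[0]
        if len(exact):
            points[target] = float(m[exact[0]])
            continue
        if f.min() < target < f.max():
            xt = np.log10(target) if axis == "log_hz" else target
            points[target] = float(np.interp(xt, x, m))
        # else: no valid bracket; leave missing
    if not points:
        raise ValueError(
            f"curve {raw.tb_id!r}: no grid frequency is covered by "
            "valid points")
    return METFCurve(tb_id=raw.tb_id, group=raw.group, method=raw.method,
                     unit=raw.unit, points=points, angle_deg=raw.angle_deg,
                     angle_corrected=raw.angle_corrected)


def enforce_core_validity(raw: RawCurve,
                          grid: FrequencyGrid = AUDIOLOGICAL_GRID,
                          core_band_hz: tuple[float, float] = (1000.0, 4000.0),
                          ) -> bool:
    """Whole-curve usability: the core band must interpolate from valid
    points.

    Returns True (keep) iff every grid target inside ``core_band_hz``
    is supported by valid measurements: an exact source match must
    itself be valid, otherwise the *nearest* source points bracketing
    the target — the points linear interpolation would use — must both
    exist and be valid.  Invalid points affecting only the spectrum
    edges do not reject the curve (those frequencies are handled later
    by truncation).
    """
    f, v = raw.frequencies_hz, raw.valid
    lo, hi = core_band_hz
    for target in grid:
        if not lo <= target <= hi:
            continue
        exact = np.nonzero(np.isclose(f, target, rtol=1e-9, atol=0.0))[0]
        if len(exact):
            if v[exact].any():
                continue
        else:
            below = np.nonzero(f < target)[0]
            above = np.nonzero(f > target)[0]
            if (len(below) and len(above)
                    and v[below[-1]] and v[above[0]]):
                continue
        _log.info("curve %s rejected: %g Hz not supported by valid "
                  "points", raw.tb_id, target)
        return False
    return True


def assemble_table(curves: Iterable[METFCurve]) -> METFTable:
    """Collect curves into the long-format analysis table.

    Row order is deterministic (tb_id, then frequency); mixed units are
    rejected.
    """
    curves = list(curves)
    units = {c.unit for c in curves}
    if len(units) > 1:
        raise ValueError(f"mixed units: {sorted(units)}")
    return METFTable.from_curves(curves)


def preprocess_raw_curves(raws: Sequence[RawCurve],
                          grid: FrequencyGrid = AUDIOLOGICAL_GRID,
                          core_band_hz: tuple[float, float] = (1000.0, 4000.0),
                          axis: str = "hz") -> METFTable:
    """Gate → interpolate → assemble, in the mandated order."""
    kept: list[METFCurve] = []
    for raw in raws:
        if not enforce_core_validity(raw, grid, core_band_hz):
            continue
        kept.append(interpolate_to_grid(raw, grid, axis=axis))
    _log.info("preprocessing: kept %d of %d curves", len(kept), len(raws))
    return assemble_table(kept)
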