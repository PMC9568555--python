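"""Applying a reference range to new METF measurements.

A new study's curves are checked frequency-by-frequency against the
reference tolerance interval.  Violations confined to the spectrum
edges (below 500 Hz or above 4 kHz) permit truncation; any violation in
the 500–4000 Hz core band flags the curve for the researcher's judgment
— flagged curves are reported, never auto-excluded, because an
out-of-range METF may reflect an undetected pathology, a measurement
error, or a genuinely unusual but healthy ear.  The study mean is
compared against the reference mean (deviations beyond 6 dB warrant
discussion), and the leverage of a single measurement at the edge of
the range is quantified as a function of the study size n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    METFCurve,
    METFTable,
    ReferenceTable,
    get_logger,
)
from .reference_builder import tolerance_factor

__all__ = [
    "ValidationVerdict",
    "ImpactResult",
    "validate_curve",
    "compare_study_mean",
    "impact_of_extreme",
    "guideline_report",
]

_log = get_logger("validation")

CORE_BAND_HZ = (500.0, 4000.0)
STUDY_MEAN_RULE_DB = 6.0

SMALL_N_CAVEAT = (
    "for small studies it is unlikely that the study mean falls inside "
    "the reference CI of the mean even when the population matches; "
    "judge agreement by the 6 dB deviation rule instead")
NARROW_BAND_CAVEAT = (
    "single-frequency violations may reflect narrow-band resonances or "
    "antiresonances of an otherwise normal middle ear; avoid drawing "
    "conclusions from data immediately around such a peak/notch")


@dataclass(frozen=True)
class Violation:
    frequency_hz: float
    direction: str        # "above" | "below"
    exceedance_db: float  # distance beyond the violated TI bound, > 0


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of checking one curve against the reference range."""

    tb_id: str
    status: str   # valid | valid_after_truncation | flagged
    violations: tuple[Violation, ...] = ()
    truncated_hz: tuple[float, ...] = ()
    notes: tuple[str, ...] = ()
    ti_p: float = 0.95

    def __post_init__(self) -> None:
        if self.status not in ("valid", "valid_after_truncation", "flagged"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "valid" and self.violations:
            raise ValueError("a valid curve cannot have violations")
        if self.status == "valid_after_truncation":
            lo, hi = CORE_BAND_HZ
            if any(lo <= v.frequency_hz <= hi for v in self.violations):
                raise ValueError(
                    "truncation only permitted for edge violations")

    def to_dict(self) -> dict:
        return {
            "tb_id": self.tb_id, "status": self.status, "ti_p": self.ti_p,
            "violations": [v.__dict__ for v in self.violations],
            "truncated_hz": list(self.truncated_hz),
            "notes": list(self.notes),
        }


def validate_curve(curve: METFCurve, reference: ReferenceTable,
                   ti_p: float = 0.95) -> ValidationVerdict:
    """Check a curve against the reference TI, frequency by frequency.

    Frequencies the curve shares with the reference are tested for
    containment in the (ti_p, 1−α) TI; if that proportion is not
    tabulated the 95% TI is used.  Violations only below 500 Hz or
    above 4 kHz give ``valid_after_truncation`` with the offending
    band(s) listed for removal; any core-band violation gives
    ``flagged`` — the decision on a flagged curve stays with the
    researcher.
    """
    if curve.unit != reference.unit:
        raise ValueError(
            f"unit mismatch: curve {curve.unit!r} vs "
            f"reference {reference.unit!r}")
    shared = [f for f in curve.frequencies_hz if f in reference.stats]
    if not shared:
        raise ValueError(
            f"curve {curve.tb_id!r} shares no frequencies with reference")
    if curve.angle_deg is not None and not curve.angle_corrected:
        _log.warning("curve %s has a recorded angle but no correction "
                     "applied; validate the corrected curve if possible",
                     curve.tb_id)
    violations: list[Violation] = []
    for f in shared:
        lo, hi = reference.ti_bounds(f, ti_p)
        v = curve.magnitude_at(f)
        if v < lo:
            violations.append(Violation(f, "below", lo - v))
        elif v > hi:
            violations.append(Violation(f, "above", v - hi))
    notes: list[str] = []
    band_lo, band_hi = CORE_BAND_HZ
    if not violations:
        return ValidationVerdict(curve.tb_id, "valid", ti_p=ti_p)
    if len(violations) == 1:
        notes.append(NARROW_BAND_CAVEAT)
    core = [v for v in violations if band_lo <= v.frequency_hz <= band_hi]
    if core:
        return ValidationVerdict(curve.tb_id, "flagged",
                                 violations=tuple(violations),
                                 notes=tuple(notes), ti_p=ti_p)
    truncated = tuple(sorted(v.frequency_hz for v in violations))
    return ValidationVerdict(curve.tb_id, "valid_after_truncation",
                             violations=tuple(violations),
                             truncated_hz=truncated,
                             notes=tuple(notes), ti_p=ti_p)


def truncate_per_verdict(curve: METFCurve,
                         verdict: ValidationVerdict) -> METFCurve:
    """Remove the bands a ``valid_after_truncation`` verdict names."""
    from dataclasses import replace
    if verdict.status != "valid_after_truncation":
        return curve
    points = {f: m for f, m in curve.points.items()
              if f not in verdict.truncated_hz}
    return replace(curve, points=points)


def compare_study_mean(study: METFTable, reference: ReferenceTable
                       ) -> pd.DataFrame:
    """Per-frequency study mean versus the reference mean.

    Returns a frame with the study mean, deviation from the reference
    mean, an ``advisory`` flag where |deviation| > 6 dB (the rule-of-
    thumb bound on a plausible lab effect), and whether the study mean
    falls inside the reference CI of the mean — reported with the
    caveat that the latter is unlikely for small n.
    """
    if not len(study.df):
        raise ValueError("study table is empty")
    if study.unit != reference.unit:
        raise ValueError(
            f"unit mismatch: study {study.unit!r} vs "
            f"reference {reference.unit!r}")
    rows = []
    for f, sub in study.df.groupby("frequency_hz", sort=True):
        if float(f) not in reference.stats:
            continue
        s = reference.stats[float(f)]
        mean = float(sub["metf_db"].mean())
        dev = mean - s.mean_db
        rows.append({
            "frequency_hz": float(f), "n": len(sub), "study_mean_db": mean,
            "reference_mean_db": s.mean_db, "deviation_db": dev,
            "advisory": bool(abs(dev) > STUDY_MEAN_RULE_DB),
            "within_reference_ci": bool(s.ci95[0] <= mean <= s.ci95[1]),
        })
    out = pd.DataFrame(rows)
    out.attrs["caveat"] = SMALL_N_CAVEAT
    return out


@dataclass(frozen=True)
class ImpactResult:
    """Leverage of one extreme measurement on a study of size n."""

    n: int
    p: float
    k2: float
    sigma_db: float
    mean_shift_db: float
    sd_change_db: float
    model: str   # deterministic_surrogate | monte_carlo

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def impact_of_extreme(n: int, p: float = 0.95, sigma_db: float = 5.2,
                      k2: float | None = None, reference_n: int = 366,
                      alpha: float = 0.05, model: str =
                      "deterministic_surrogate",
                      n_replicates: int = 10_000, seed: int = 0,
                      ) -> ImpactResult:
    """Effect of a single at-the-edge measurement on mean and SD.

    Surrogate model: a study of n−1 typical observations (mean μ,
    sample SD σ) plus one observation at μ + k₂σ, the edge of the
    (p, 1−α) reference TI.  Then

        mean shift = k₂σ/n,
        new SD     = sqrt( σ²(n−2)/(n−1) + (k₂σ)²/n ),

    the first term being the n−1 typical deviations re-centred, the
    second the edge observation's leverage.  ``model="monte_carlo"``
    draws the n−1 observations from N(μ, σ²) instead and averages the
    realized shifts over ``n_replicates`` seeded replicates.  k₂
    defaults to the reference sample size's factor
    (``tolerance_factor(reference_n, p, alpha)``).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if k2 is None:
        k2 = tolerance_factor(reference_n, p, alpha)
    edge = k2 * sigma_db
    if model == "deterministic_surrogate":
        mean_shift = edge / n
        new_sd = np.sqrt(sigma_db ** 2 * (n - 2) / (n - 1)
                         + edge ** 2 / n) if n > 2 else \
            np.sqrt(edge ** 2 / n)
        return ImpactResult(n=n, p=p, k2=float(k2), sigma_db=sigma_db,
                            mean_shift_db=float(mean_shift),
                            sd_change_db=float(new_sd - sigma_db),
                            model=model)
    if model == "monte_carlo":
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((n_replicates, n - 1)) * sigma_db
        with_edge = np.concatenate(
            [base, np.full((n_replicates, 1), edge)], axis=1)
        mean_shift = float(np.mean(with_edge.mean(axis=1)))
        sd_change = float(np.mean(with_edge.std(axis=1, ddof=1)) - sigma_db)
        return ImpactResult(n=n, p=p, k2=float(k2), sigma_db=sigma_db,
                            mean_shift_db=mean_shift,
                            sd_change_db=sd_change, model=model)
    raise ValueError(f"unknown impact model {model!r}")


def guideline_report(study: METFTable, reference: ReferenceTable,
                     ti_p: float = 0.95) -> dict:
    """Full usage-guideline report for a study against a reference.

    Aggregates per-curve verdicts, the study-mean comparison, a
    sample-size advisory (n < 5: strong warning; 5 ≤ n < 10: soft
    warning; statistical analyses should use at least 5 and preferably
    10 valid measurements), and the extreme-measurement impact at the
    study's n.
    """
    curves = study.curves()
    verdicts = [validate_curve(c, reference, ti_p) for c in curves]
    n = len(curves)
    if n < 5:
        size_advisory = ("strong_warning", "fewer than 5 measurements: "
                         "statistical conclusions are unreliable")
    elif n < 10:
        size_advisory = ("soft_warning", "fewer than 10 measurements: "
                         "results are sensitive to single specimens")
    else:
        size_advisory = ("ok", "sample size adequate")
    # pooled per-frequency SD of the study as the impact sigma, falling
    # back to a typical reference-population value for tiny studies
    sds = study.df.groupby("frequency_hz")["metf_db"].std(ddof=1).dropna()
    sigma = float(sds.mean()) if len(sds) and n >= 3 else 5.2
    impact = impact_of_extreme(max(n, 2), p=ti_p, sigma_db=sigma)
    status_counts = pd.Series([v.status for v in verdicts]
                              ).value_counts().to_dict()
    report = {
        "n_curves": n,
        "ti_p": ti_p,
        "verdicts": [v.to_dict() for v in verdicts],
        "status_counts": status_counts,
        "study_mean": compare_study_mean(study, reference
                                         ).to_dict(orient="records"),
        "study_mean_caveat": SMALL_N_CAVEAT,
        "sample_size_advisory": {"level": size_advisory[0],
                                 "message": size_advisory[1]},
        "impact_of_extreme": impact.to_dict(),
        "all_clear": (size_advisory[0] == "ok"
                      and all(v.status == "valid" for v in verdicts)),
    }
    if any(len(v.violations) == 1 for v in verdicts):
        report["narrow_band_caveat"] = NARROW_BAND_CAVEAT
    return report
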