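"""Per-frequency Tukey-fence outlier screening with discard/truncate rules.

Outliers are flagged per frequency against fences Q1 − k·IQR and
Q3 + k·IQR (k = 1.75 by default, accommodating the left skew of METF
magnitudes).  A curve with any outlier inside the core speech band
(500–4000 Hz) is discarded entirely — a single outlier there may be
part of a wider peak whose neighbours escaped flagging — while curves
with outliers only at the spectrum edges are truncated at the most
medial flagged frequency.  Screening runs twice: once within each
(group, method) cell for between-group comparisons, and once on the
pooled single-point-LDV (method "A") data from which the reference
range is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import METFTable, get_logger

__all__ = [
    "FenceSet",
    "CurveVerdict",
    "ExclusionReport",
    "compute_fences",
    "flag_outliers",
    "apply_exclusion_rules",
    "two_pass_screen",
]

_log = get_logger("outliers")

CORE_BAND_HZ = (500.0, 4000.0)


@dataclass(frozen=True)
class FenceSet:
    """Per-frequency quartiles and Tukey fences.

    ``table`` columns: frequency_hz, q1, q3, iqr, lower, upper;
    ``k`` the IQR multiple; ``quantile_method`` the order-statistic
    interpolation convention used (numpy naming).
    """

    table: pd.DataFrame
    k: float
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        t = self.table
        if (t["iqr"] < 0).any():
            raise ValueError("IQR must be nonnegative")
        bad = ~((t["lower"] <= t["q1"]) & (t["q1"] <= t["q3"])
                & (t["q3"] <= t["upper"]))
        if bad.any():
            raise ValueError("fence ordering violated")

    def bounds(self, frequency_hz: float) -> tuple[float, float]:
        row = self.table[self.table["frequency_hz"] == frequency_hz]
        if not len(row):
            raise KeyError(f"no fences for {frequency_hz} Hz")
        return float(row["lower"].iloc[0]), float(row["upper"].iloc[0])


@dataclass(frozen=True)
class CurveVerdict:
    verdict: str                      # keep|truncate_low|truncate_high|truncate_both|discard
    offending_hz: tuple[float, ...]   # flagged frequencies
    removed_hz: tuple[float, ...]     # points actually dropped


@dataclass(frozen=True)
class ExclusionReport:
    """Screening outcome: per-curve verdicts and per-group counts.

    ``interpretation`` documents the truncation semantics: a flagged
    edge frequency is removed together with everything outward of it;
    unflagged more-medial points survive.
    """

    verdicts: Mapping[str, CurveVerdict]
    fences: FenceSet
    core_band_hz: tuple[float, float] = CORE_BAND_HZ
    interpretation: str = (
        "truncate at the most medial flagged frequency: the flagged point "
        "and all points outward of it are removed; unflagged points medial "
        "of it are kept")

    def n_discarded(self) -> int:
        return sum(v.verdict == "discard" for v in self.verdicts.values())

    def counts_by_group(self, table: METFTable) -> pd.DataFrame:
        meta = table.df.groupby("tb_id")[["group", "method"]].first()
        rows = []
        for (g, m), sub in meta.groupby(["group", "method"]):
            ids = sub.index
            n_excl = sum(self.verdicts[i].verdict == "discard"
                         for i in ids if i in self.verdicts)
            rows.append({"group": g, "method": m, "n_curves": len(ids),
                         "n_discarded": n_excl})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "k": self.fences.k,
            "quantile_method": self.fences.quantile_method,
            "core_band_hz": list(self.core_band_hz),
            "interpretation": self.interpretation,
            "fences": self.fences.table.to_dict(orient="records"),
            "verdicts": {
                tb: {"verdict": v.verdict,
                     "offending_hz": list(v.offending_hz),
                     "removed_hz": list(v.removed_hz)}
                for tb, v in self.verdicts.items()},
        }


def compute_fences(table: METFTable, k: float = 1.75,
                   quantile_method: str = "linear") -> FenceSet:
    """Quartiles and Tukey fences per frequency.

    Quartiles use linear interpolation of order statistics by default
    (the common spreadsheet/statistical convention); exclusion counts
    are sensitive to this, so the convention is configurable and
    recorded in the result.  Requires ≥ 4 values per frequency.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    rows = []
    for f, sub in table.df.groupby("frequency_hz", sort=True):
        vals = sub["metf_db"].to_numpy()
        if len(vals) < 4:
            raise ValueError(
                f"{f} Hz: need >= 4 values for quartiles, got {len(vals)}")
        q1, q3 = np.quantile(vals, [0.25, 0.75], method=quantile_method)
        iqr = q3 - q1
        rows.append({"frequency_hz": f, "q1": q1, "q3": q3, "iqr": iqr,
                     "lower": q1 - k * iqr, "upper": q3 + k * iqr})
    return FenceSet(table=pd.DataFrame(rows), k=k,
                    quantile_method=quantile_method)


def flag_outliers(table: METFTable, fences: FenceSet) -> pd.Series:
    """Boolean per-point outlier flags, aligned with ``table.df``.

    A point is an outlier iff it lies strictly outside its frequency's
    fences; values exactly on a fence are kept.
    """
    fl = fences.table.set_index("frequency_hz")
    missing = set(table.df["frequency_hz"].unique()) - set(fl.index)
    if missing:
        raise KeyError(f"fences missing for frequencies {sorted(missing)}")
    lower = fl["lower"].reindex(table.df["frequency_hz"]).to_numpy()
    upper = fl["upper"].reindex(table.df["frequency_hz"]).to_numpy()
    vals = table.df["metf_db"].to_numpy()
    return pd.Series((vals < lower) | (vals > upper), index=table.df.index)


def _verdict_for(freqs_flagged: np.ndarray,
                 core_band_hz: tuple[float, float]) -> str:
    lo, hi = core_band_hz
    if len(freqs_flagged) == 0:
        return "keep"
    if ((freqs_flagged >= lo) & (freqs_flagged <= hi)).any():
        return "discard"
    low = (freqs_flagged < lo).any()
    high = (freqs_flagged > hi).any()
    if low and high:
        return "truncate_both"
    return "truncate_low" if low else "truncate_high"


def apply_exclusion_rules(table: METFTable, flags: pd.Series,
                          core_band_hz: tuple[float, float] = CORE_BAND_HZ,
                          fences: FenceSet | None = None,
                          ) -> tuple[METFTable, ExclusionReport]:
    """Discard/truncate curves according to where their outliers sit.

    Any flagged point inside the core band discards the whole curve;
    flags confined to the low (f < core lower) or high (f > core upper)
    edge truncate the curve at the most medial flagged frequency —
    removing that point and everything outward of it — on the affected
    side(s).
    """
    if not flags.index.equals(table.df.index):
        raise ValueError("flags must be aligned to the table index")
    df = table.df
    verdicts: dict[str, CurveVerdict] = {}
    keep_mask = pd.Series(True, index=df.index)
    for tb_id, sub in df.groupby("tb_id", sort=True):
        fl = flags[sub.index]
        freqs_flagged = np.sort(sub.loc[fl[fl].index, "frequency_hz"]
                                .unique())
        verdict = _verdict_for(freqs_flagged, core_band_hz)
        removed: list[float] = []
        if verdict == "discard":
            keep_mask[sub.index] = False
            removed = sorted(sub["frequency_hz"].unique())
        elif verdict != "keep":
            lo, hi = core_band_hz
            if verdict in ("truncate_low", "truncate_both"):
                cut = freqs_flagged[freqs_flagged < lo].max()
                sel = sub["frequency_hz"] <= cut
                keep_mask[sub.index[sel]] = False
                removed += sorted(sub.loc[sel, "frequency_hz"].unique())
            if verdict in ("truncate_high", "truncate_both"):
                cut = freqs_flagged[freqs_flagged > hi].min()
                sel = sub["frequency_hz"] >= cut
                keep_mask[sub.index[sel]] = False
                removed += sorted(sub.loc[sel, "frequency_hz"].unique())
        verdicts[str(tb_id)] = CurveVerdict(
            verdict=verdict, offending_hz=tuple(freqs_flagged),
            removed_hz=tuple(removed))
    if fences is None:
        fences = compute_fences(table)
    report = ExclusionReport(verdicts=verdicts, fences=fences,
                             core_band_hz=core_band_hz)
    _log.info("exclusion: %d of %d curves discarded",
              report.n_discarded(), table.n_curves())
    return table.subset(keep_mask), report


def screen_table(table: METFTable, k: float = 1.75,
                 core_band_hz: tuple[float, float] = CORE_BAND_HZ,
                 quantile_method: str = "linear",
                 ) -> tuple[METFTable, ExclusionReport]:
    """Fences → flags → exclusion in one step."""
    fences = compute_fences(table, k=k, quantile_method=quantile_method)
    flags = flag_outliers(table, fences)
    return apply_exclusion_rules(table, flags, core_band_hz, fences=fences)


def two_pass_screen(table: METFTable, k: float = 1.75,
                    core_band_hz: tuple[float, float] = CORE_BAND_HZ,
                    quantile_method: str = "linear",
                    pooled_method: str = "A",
                    chain_passes: bool = False,
                    ) -> tuple[dict[tuple[str, str], METFTable], METFTable,
                               dict[tuple[str, str], ExclusionReport],
                               ExclusionReport]:
    """Branched two-pass screening.

    Pass 1 screens each (group, method) cell separately, producing the
    per-cell clean tables used for between-group comparisons.  Pass 2
    pools the ``pooled_method`` data and screens it again with fences
    recomputed from the pooled sample, producing the table the reference
    range is built from.  By default the branches are independent (pass
    2 pools the *raw* method data, mirroring the parallel branches of
    the study design); ``chain_passes=True`` pools the pass-1 survivors
    instead.

    Returns ``(per_cell_tables, pooled_clean, per_cell_reports,
    pooled_report)``.
    """
    per_cell: dict[tuple[str, str], METFTable] = {}
    reports: dict[tuple[str, str], ExclusionReport] = {}
    for (g, m), sub in table.df.groupby(["group", "method"], sort=True):
        cell = METFTable(sub)
        clean, rep = screen_table(cell, k=k, core_band_hz=core_band_hz,
                                  quantile_method=quantile_method)
        per_cell[(g, m)] = clean
        reports[(g, m)] = rep

    if chain_passes:
        parts = [t.df for (g, m), t in per_cell.items()
                 if m == pooled_method and len(t.df)]
        pooled_df = (pd.concat(parts, ignore_index=True) if parts
                     else table.df.iloc[0:0])
    else:
        pooled_df = table.df[table.df["method"] == pooled_method]
    pooled = METFTable(pooled_df)
    if pooled.n_curves() == 0:
        raise ValueError(f"no curves with method {pooled_method!r} to pool")
    pooled_clean, pooled_report = screen_table(
        pooled, k=k, core_band_hz=core_band_hz,
        quantile_method=quantile_method)
    return per_cell, pooled_clean, reports, pooled_report
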