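r"""Outcome variables per tooth rotation and Table-style group summaries.

Definitions, all in degrees unless noted:

* accuracy  = achieved / prescribed * 100 (percent; prescribed > 0)
* performance = achieved - prescribed (signed; negative = under-correction)
* FOPE bin of \|performance\|: <=1, (1,2], (2,4], >4
* direction: under (< -1), right ([-1, 1]), over (> 1)
* records with prescribed below the clinical cutoff (default 2) are excluded

The headline "mean performance" statistic of a group is the absolute value
of the mean signed difference, \|mean(achieved - prescribed)\|; the stricter
mean of absolute differences is emitted alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedStatisticError
from .rotation_measure import AngleMeasurement

FOPE_BINS = ("<=1", "(1,2]", "(2,4]", ">4")
DIRECTIONS = ("under", "right", "over")

DEFAULT_CUTOFF_DEG = 2.0


def classify_direction(performance: float) -> str:
    """under if < -1; right if within [-1, 1]; over if > 1."""
    if not math.isfinite(performance):
        raise InvalidInputError("performance must be finite")
    if performance < -1.0:
        return "under"
    if performance > 1.0:
        return "over"
    return "right"


def fope_bin(abs_performance: float) -> str:
    """Half-open FOPE ranges applied to the unrounded absolute performance."""
    if not math.isfinite(abs_performance) or abs_performance < 0:
        raise InvalidInputError("absolute performance must be finite and >= 0")
    if abs_performance <= 1.0:
        return "<=1"
    if abs_performance <= 2.0:
        return "(1,2]"
    if abs_performance <= 4.0:
        return "(2,4]"
    return ">4"


@dataclass
class RotationRecord:
    case_id: str
    arch: str
    fdi: int
    tooth_type: str
    prescribed: float  # deg, >= 0 after re-signing
    achieved: float  # deg, signed relative to the prescribed direction
    accuracy: float | None  # percent; None when undefined (prescribed == 0)
    performance: float
    abs_performance: float
    fope_bin: str
    direction: str
    excluded: bool
    exclusion_reason: str = ""


def build_records(
    measurements: list[AngleMeasurement], cutoff_deg: float = DEFAULT_CUTOFF_DEG
) -> list[RotationRecord]:
    """Derive all outcome fields; mark sub-cutoff prescriptions excluded."""
    records = []
    for m in measurements:
        if m.prescribed < 0:
            raise InvalidInputError(
                f"tooth {m.tooth}: prescribed must be >= 0 after re-signing"
            )
        excluded = m.prescribed < cutoff_deg
        if m.prescribed == 0 and not excluded:
            raise UndefinedStatisticError(
                f"tooth {m.tooth}: accuracy undefined at zero prescription; "
                "raise the cutoff or drop the record"
            )
        perf = m.achieved - m.prescribed
        records.append(
            RotationRecord(
                case_id=m.case_id,
                arch=m.arch,
                fdi=m.tooth,
                tooth_type=m.tooth_type,
                prescribed=m.prescribed,
                achieved=m.achieved,
                accuracy=(m.achieved / m.prescribed * 100.0) if m.prescribed > 0 else None,
                performance=perf,
                abs_performance=abs(perf),
                fope_bin=fope_bin(abs(perf)),
                direction=classify_direction(perf),
                excluded=excluded,
                exclusion_reason=(
                    f"prescribed {m.prescribed:.3f} deg below {cutoff_deg} deg cutoff"
                    if excluded
                    else ""
                ),
            )
        )
    return records


def _mean_sd_ci(values: np.ndarray) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else float("nan")
    if n > 1 and sd > 0:
        half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    elif n > 1:
        half = 0.0
    else:
        half = float("nan")
    return {"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half}


@dataclass
class GroupSummary:
    """Table-style descriptive block for one tooth-type/arch group."""

    key: tuple  # (arch, tooth_type) or (arch, "total")
    n: int
    prescription: dict
    achieved: dict
    accuracy: dict
    mean_performance: float  # |mean(achieved - prescribed)|
    performance_sd: float
    performance_ci: tuple  # CI of the mean signed difference, presented |.| sorted
    mean_abs_performance: float  # mean(|achieved - prescribed|), supplementary
    fope_counts: dict = field(default_factory=dict)
    fope_percents: dict = field(default_factory=dict)
    direction_counts: dict = field(default_factory=dict)
    direction_percents: dict = field(default_factory=dict)


def _summarize_group(key: tuple, group: list[RotationRecord]) -> GroupSummary:
    n = len(group)
    prescribed = np.array([r.prescribed for r in group])
    achieved = np.array([r.achieved for r in group])
    accuracy = np.array([r.accuracy for r in group], dtype=float)
    perf = achieved - prescribed
    perf_stats = _mean_sd_ci(perf)
    ci = tuple(sorted((abs(perf_stats["ci_low"]), abs(perf_stats["ci_high"]))))
    fope_counts = {b: sum(r.fope_bin == b for r in group) for b in FOPE_BINS}
    dir_counts = {d: sum(r.direction == d for r in group) for d in DIRECTIONS}
    return GroupSummary(
        key=key,
        n=n,
        prescription=_mean_sd_ci(prescribed),
        achieved=_mean_sd_ci(achieved),
        accuracy=_mean_sd_ci(accuracy),
        mean_performance=abs(perf_stats["mean"]),
        performance_sd=perf_stats["sd"],
        performance_ci=ci,
        mean_abs_performance=float(np.mean(np.abs(perf))),
        fope_counts=fope_counts,
        fope_percents={b: c / n * 100.0 for b, c in fope_counts.items()},
        direction_counts=dir_counts,
        direction_percents={d: c / n * 100.0 for d, c in dir_counts.items()},
    )


def group_summary(
    records: list[RotationRecord], grouping: str = "tooth_type"
) -> list[GroupSummary]:
    """Summaries per (arch, tooth type) plus per-arch totals.

    ``grouping`` may be "tooth_type" (default) or "arch" (totals only).
    Excluded records are dropped; groups with fewer than 2 records are
    omitted (SD/CI undefined).
    """
    kept = [r for r in records if not r.excluded]
    keys: list[tuple] = []
    for r in kept:
        k = (r.arch, r.tooth_type) if grouping == "tooth_type" else (r.arch, "total")
        if k not in keys:
            keys.append(k)
    if grouping == "tooth_type":
        for arch in dict.fromkeys(r.arch for r in kept):
            keys.append((arch, "total"))
    out = []
    for key in keys:
        arch, ttype = key
        group = [
            r for r in kept if r.arch == arch and (ttype == "total" or r.tooth_type == ttype)
        ]
        if len(group) < 2:
            continue
        out.append(_summarize_group(key, group))
    return out


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------


def records_to_frame(records: list[RotationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def records_from_frame(df: pd.DataFrame) -> list[RotationRecord]:
    recs = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        d["accuracy"] = None if pd.isna(d["accuracy"]) else float(d["accuracy"])
        d["exclusion_reason"] = (
            "" if pd.isna(d.get("exclusion_reason")) else str(d["exclusion_reason"])
        )
        recs.append(RotationRecord(**d))
    return recs


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"arch": s.key[0], "group": s.key[1], "n": s.n}
        for name, block in (
            ("prescribed", s.prescription),
            ("achieved", s.achieved),
            ("accuracy", s.accuracy),
        ):
            for stat, val in block.items():
                row[f"{name}_{stat}"] = val
        row["mean_performance"] = s.mean_performance
        row["performance_sd"] = s.performance_sd
        row["performance_ci_low"], row["performance_ci_high"] = s.performance_ci
        row["mean_abs_performance"] = s.mean_abs_performance
        for b in FOPE_BINS:
            row[f"fope_{b}_n"] = s.fope_counts[b]
            row[f"fope_{b}_pct"] = s.fope_percents[b]
        for d in DIRECTIONS:
            row[f"{d}_n"] = s.direction_counts[d]
            row[f"{d}_pct"] = s.direction_percents[d]
        rows.append(row)
    return pd.DataFrame(rows)
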