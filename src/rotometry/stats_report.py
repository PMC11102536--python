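"""Statistical layer: method error, normality-gated paired comparisons,
accuracy-on-prescription regression, power analysis, and report emission."""

from __future__ import annotations

import hashlib
import json
import math
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InvalidInputError, StageError, UndefinedStatisticError
from .outcome_metrics import (
    DIRECTIONS,
    FOPE_BINS,
    RotationRecord,
    group_summary,
)


@dataclass
class ReliabilityResult:
    icc: float
    dahlberg_deg: float
    paired_t_p: float


@dataclass
class ComparisonResult:
    group: tuple
    test_used: str  # "paired_t" | "wilcoxon"
    statistic: float
    p_value: float
    normality_p: float
    degenerate: bool = False
    # Both branches are always computed so the gate is auditable.
    paired_t_p: float = float("nan")
    wilcoxon_p: float = float("nan")


@dataclass
class RegressionResult:
    group: tuple
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    intercept: float
    n: int


def dahlberg_error(first, second) -> float:
    """Technical error of duplicate determinations: sqrt(sum(d^2) / (2 n))."""
    a = np.asarray(first, dtype=np.float64)
    b = np.asarray(second, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidInputError("dahlberg_error needs two equal-length series, n >= 2")
    d = a - b
    return float(np.sqrt(np.sum(d**2) / (2.0 * len(d))))


def icc_agreement(ratings) -> float:
    """Two-way absolute-agreement single-measure intraclass correlation (ICC(2,1)).

    ``ratings``: (n items, 2 occasions/raters), no missing values.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 5:
        raise InvalidInputError("icc_agreement needs an (n >= 5, 2) array")
    if not np.isfinite(x).all():
        raise InvalidInputError("icc_agreement does not accept missing values")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def method_error(first, second) -> ReliabilityResult:
    """ICC + Dahlberg + paired-t bias check between duplicate series."""
    a = np.asarray(first, dtype=np.float64)
    b = np.asarray(second, dtype=np.float64)
    if np.allclose(a, b):
        t_p = 1.0
    else:
        t_p = float(sps.ttest_rel(a, b).pvalue)
    return ReliabilityResult(
        icc=icc_agreement(np.column_stack([a, b])),
        dahlberg_deg=dahlberg_error(a, b),
        paired_t_p=t_p,
    )


def paired_compare(
    prescribed, achieved, alpha: float = 0.05, group: tuple = ("", "")
) -> ComparisonResult:
    """Compare paired series; Shapiro-Wilk on the differences gates the test.

    Normal-looking differences (p >= alpha) get the paired t test, otherwise
    the two-sided Wilcoxon signed-rank test (zero differences dropped; normal
    approximation with tie correction beyond n = 25).
    """
    a = np.asarray(prescribed, dtype=np.float64)
    b = np.asarray(achieved, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 6:
        raise InvalidInputError("paired_compare needs equal-length series, n >= 6")
    d = a - b
    if np.allclose(d, 0.0):
        return ComparisonResult(
            group, "paired_t", 0.0, 1.0, float("nan"), degenerate=True,
            paired_t_p=1.0, wilcoxon_p=1.0,
        )
    sw_p = float(sps.shapiro(d).pvalue)
    t_res = sps.ttest_rel(a, b)
    nz = d[d != 0.0]
    if len(nz) == 0:
        w_stat, w_p = float("nan"), 1.0
    else:
        method = "approx" if len(nz) > 25 else "exact"
        try:
            w = sps.wilcoxon(nz, method=method, correction=False)
        except ValueError:  # exact method refuses ties; fall back
            w = sps.wilcoxon(nz, method="approx", correction=False)
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    if sw_p >= alpha:
        used, stat, p = "paired_t", float(t_res.statistic), float(t_res.pvalue)
    else:
        used, stat, p = "wilcoxon", w_stat, w_p
    return ComparisonResult(
        group, used, stat, p, sw_p,
        paired_t_p=float(t_res.pvalue), wilcoxon_p=w_p,
    )


def accuracy_regression(
    records: list[RotationRecord], group: tuple = ("", "")
) -> RegressionResult:
    """OLS of accuracy (%) on prescription (deg) for one group of records."""
    kept = [r for r in records if not r.excluded and r.accuracy is not None]
    if len(kept) < 10:
        raise InvalidInputError("accuracy_regression needs at least 10 records")
    x = np.array([r.prescribed for r in kept])
    y = np.array([r.accuracy for r in kept])
    if np.allclose(x, x[0]):
        raise UndefinedStatisticError("zero variance in prescription: degenerate design")
    if np.allclose(y, y[0]):  # perfectly flat response: slope exactly 0
        return RegressionResult(group, 0.0, 0.0, 0.0, 1.0, float(y[0]), len(kept))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        group=group,
        beta=float(model.params[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_value=float(model.pvalues[1]),
        intercept=float(model.params[0]),
        n=len(kept),
    )


def paired_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided one-sample/paired t at effect size ``d``."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * math.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    )


def paired_t_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 100000
) -> int:
    """Smallest n reaching the requested power for a two-sided paired t test."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidInputError("alpha and power must lie in (0, 1)")
    if d <= 0:
        raise InvalidInputError("effect size must be positive (power unreachable at 0)")
    for n in range(2, n_max + 1):
        if paired_t_power(n, d, alpha) >= power:
            return n
    raise InvalidInputError(f"requested power not reached by n = {n_max}")


# ---------------------------------------------------------------------------
# Report emission (Tables 1-4 analogues)
# ---------------------------------------------------------------------------


def _fmt(x, nd=2):
    return round(float(x), nd)


def build_report(
    records: list[RotationRecord],
    out_dir,
    alpha: float = 0.05,
    seed: int | None = None,
    config_digest: str = "",
) -> dict:
    """Write the four summary CSVs plus run metadata; returns written paths."""
    if not records:
        raise StageError("report", "no rotation records supplied")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = group_summary(records, grouping="tooth_type")
    kept = [r for r in records if not r.excluded]

    def group_records(key):
        arch, ttype = key
        return [
            r for r in kept if r.arch == arch and (ttype == "total" or r.tooth_type == ttype)
        ]

    # Table 1 analogue: prescription / achieved / mean performance + paired test.
    rows1, rows2, rows3, rows4 = [], [], [], []
    for s in summaries:
        grp = group_records(s.key)
        prescribed = np.array([r.prescribed for r in grp])
        achieved = np.array([r.achieved for r in grp])
        try:
            cmp_res = paired_compare(prescribed, achieved, alpha=alpha, group=s.key)
        except InvalidInputError:  # group too small for the paired test
            cmp_res = ComparisonResult(
                s.key, "none", float("nan"), float("nan"), float("nan")
            )
        rows1.append(
            {
                "arch": s.key[0],
                "group": s.key[1],
                "n": s.n,
                "prescribed_mean": _fmt(s.prescription["mean"]),
                "prescribed_sd": _fmt(s.prescription["sd"]),
                "prescribed_ci_low": _fmt(s.prescription["ci_low"]),
                "prescribed_ci_high": _fmt(s.prescription["ci_high"]),
                "achieved_mean": _fmt(s.achieved["mean"]),
                "achieved_sd": _fmt(s.achieved["sd"]),
                "achieved_ci_low": _fmt(s.achieved["ci_low"]),
                "achieved_ci_high": _fmt(s.achieved["ci_high"]),
                "mean_performance": _fmt(s.mean_performance),
                "performance_sd": _fmt(s.performance_sd),
                "performance_ci_low": _fmt(s.performance_ci[0]),
                "performance_ci_high": _fmt(s.performance_ci[1]),
                "mean_abs_performance": _fmt(s.mean_abs_performance),
                "test_used": cmp_res.test_used,
                "p_value": _fmt(cmp_res.p_value, 4)
                if math.isfinite(cmp_res.p_value)
                else float("nan"),
                "normality_p": _fmt(cmp_res.normality_p, 4)
                if math.isfinite(cmp_res.normality_p)
                else float("nan"),
            }
        )
        rows2.append(
            {
                "arch": s.key[0],
                "group": s.key[1],
                "n": s.n,
                "accuracy_mean": _fmt(s.accuracy["mean"]),
                "accuracy_sd": _fmt(s.accuracy["sd"]),
                "accuracy_ci_low": _fmt(s.accuracy["ci_low"]),
                "accuracy_ci_high": _fmt(s.accuracy["ci_high"]),
            }
        )
        row3 = {"arch": s.key[0], "group": s.key[1], "n": s.n}
        for dname in DIRECTIONS:
            row3[f"{dname}_n"] = s.direction_counts[dname]
            row3[f"{dname}_pct"] = _fmt(s.direction_percents[dname])
        for b in FOPE_BINS:
            row3[f"fope_{b}_n"] = s.fope_counts[b]
            row3[f"fope_{b}_pct"] = _fmt(s.fope_percents[b])
        rows3.append(row3)
        if s.key[1] != "total":
            try:
                reg = accuracy_regression(grp, group=s.key)
                rows4.append(
                    {
                        "arch": s.key[0],
                        "group": s.key[1],
                        "n": reg.n,
                        "beta": _fmt(reg.beta, 3),
                        "ci_low": _fmt(reg.ci_low, 3),
                        "ci_high": _fmt(reg.ci_high, 3),
                        "p_value": _fmt(reg.p_value, 4),
                    }
                )
            except (InvalidInputError, UndefinedStatisticError):
                pass

    paths = {}
    for name, rows in (
        ("table1_prescription_vs_achieved.csv", rows1),
        ("table2_accuracy.csv", rows2),
        ("table3_fope_direction.csv", rows3),
        ("table4_regression.csv", rows4),
    ):
        p = out_dir / name
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[name] = str(p)

    meta = {
        "n_records": len(records),
        "n_excluded": sum(r.excluded for r in records),
        "alpha": alpha,
        "seed": seed,
        "config_digest": config_digest,
        "python": sys.version.split()[0],
        "notes": [
            "no multiple-testing correction across per-tooth comparisons",
            "regression pools teeth across cases and ignores within-case clustering",
        ],
    }
    meta_path = out_dir / "report_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["report_metadata.json"] = str(meta_path)
    return paths


def digest_of(obj) -> str:
    """Stable short digest of a JSON-serializable config blob."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
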