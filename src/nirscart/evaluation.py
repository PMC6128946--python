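"""Model evaluation: RMSE / NRMSE / RPIQ, rank statistics, group
comparisons, per-location aggregation of arthroscopic predictions, and the
tabular report builders.

NRMSE is RMSE expressed as a percentage of the reference-parameter range
(max - min of the measured values over the pooled in vitro reference set).
RPIQ is the interquartile range of the measured data divided by RMSE; models
with RPIQ >= 2 are flagged reliable. Group statistics are nonparametric:
Mann-Whitney U between repair and control locations and two-tailed Spearman
rank correlation between measured and predicted values, with a Shapiro-Wilk
normality gate available as an informational check.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RPIQ_RELIABLE_THRESHOLD = 2.0

REPORT_COLUMNS = (
    "parameter",
    "variant",
    "region_um",
    "n_variables",
    "set",
    "rho",
    "p",
    "nrmse_pct",
    "rpiq",
    "reliable_flag",
)


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("inputs must be equal-length and nonempty")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def nrmse(y_true, y_pred, reference_range: float) -> float:
    """RMSE as a percentage of the reference parameter range."""
    if reference_range <= 0:
        raise ValueError("reference_range must be positive")
    return 100.0 * rmse(y_true, y_pred) / reference_range


def iqr(values) -> float:
    """Interquartile range with linear-interpolation (type-7) quantiles."""
    values = np.asarray(values, dtype=float)
    q25, q75 = np.percentile(values, [25.0, 75.0])
    return float(q75 - q25)


def rpiq(y_true_measured, rmse_value: float) -> float:
    """Ratio of performance to interquartile range: IQR(measured) / RMSE.

    A zero RMSE yields +inf (flagged in the log); models are deemed reliable
    at RPIQ >= 2.
    """
    y_true_measured = np.asarray(y_true_measured, dtype=float)
    if y_true_measured.size < 4:
        raise ValueError("need at least 4 measured values for the IQR")
    if rmse_value < 0:
        raise ValueError("rmse must be non-negative")
    if rmse_value == 0:
        logger.warning("zero RMSE: RPIQ undefined, reporting +inf")
        return math.inf
    return iqr(y_true_measured) / rmse_value


def is_reliable(rpiq_value: float) -> bool:
    return rpiq_value >= RPIQ_RELIABLE_THRESHOLD


def aggregate_location_prediction(predictions) -> float:
    """Final per-location prediction: the mean of the non-negative
    per-spectrum predictions; NaN (with a flag in the log) if every
    prediction is negative."""
    predictions = np.asarray(predictions, dtype=float)
    if predictions.size == 0:
        raise ValueError("no predictions to aggregate")
    keep = predictions >= 0
    if not np.any(keep):
        logger.warning("all %d predictions negative; location prediction missing",
                       predictions.size)
        return math.nan
    return float(predictions[keep].mean())


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

_EXACT_SPEARMAN_N = 8


def spearman(x, y) -> tuple[float, float]:
    """Two-tailed Spearman rank correlation with average ranks for ties.

    The p-value is exact (full permutation enumeration) for n <= 8 and uses
    the t-distribution approximation otherwise. Constant inputs yield
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= _EXACT_SPEARMAN_N:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx_c @ rx_c) * np.sum(ry_c**2, axis=1))
        rho_perm = (ry_c @ rx_c) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U (U of the first sample).

    Exact null enumeration when both groups have n <= 8 and the pooled data
    are tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk_gate(values) -> str:
    """Informational normality gate: 'nonparametric' iff Shapiro-Wilk
    rejects at p < 0.05, else 'parametric'. The analysis pipeline uses the
    nonparametric path regardless; the gate documents why."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    _, p = stats.shapiro(values)
    return "nonparametric" if p < 0.05 else "parametric"


# ---------------------------------------------------------------------------
# Report builders
# ---------------------------------------------------------------------------


def evaluate_set(
    y_true, y_pred, reference_range: float, measured_for_iqr=None
) -> dict:
    """Spearman rho/p, NRMSE %, RPIQ and the reliability flag for one
    evaluation set. NaN predictions (all-negative arthroscopic aggregates)
    are dropped pairwise."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ok = np.isfinite(y_pred) & np.isfinite(y_true)
    y_true, y_pred = y_true[ok], y_pred[ok]
    rho, p = spearman(y_true, y_pred)
    err = rmse(y_true, y_pred)
    measured = y_true if measured_for_iqr is None else np.asarray(measured_for_iqr)
    q = rpiq(measured, err) if err > 0 else math.inf
    return {
        "rho": rho,
        "p": p,
        "nrmse_pct": nrmse(y_true, y_pred, reference_range),
        "rpiq": q,
        "reliable_flag": is_reliable(q),
    }


def build_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-(parameter, variant, set) evaluation table with the
    canonical column order; rows missing an evaluated set are omitted by the
    caller with a log message."""
    if not rows:
        return pd.DataFrame(columns=list(REPORT_COLUMNS))
    report = pd.DataFrame(rows)
    missing = set(REPORT_COLUMNS) - set(report.columns)
    if missing:
        raise ValueError(f"report rows missing columns: {sorted(missing)}")
    return report[list(REPORT_COLUMNS)].reset_index(drop=True)


def write_report_csv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False, float_format="%.6g")


def read_report_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def group_summary(
    references: pd.DataFrame, parameters: list[str]
) -> pd.DataFrame:
    """Boxplot-style summary per (parameter, distance class, group):
    median, quartiles, outlier values (beyond 1.5 IQR whiskers) and n."""
    rows = []
    for param in parameters:
        for (dclass, group), sub in references.groupby(
            ["distance_class", "group"], sort=True
        ):
            vals = sub[param].to_numpy(dtype=float)
            q25, med, q75 = np.percentile(vals, [25.0, 50.0, 75.0])
            whisker = 1.5 * (q75 - q25)
            outliers = vals[(vals < q25 - whisker) | (vals > q75 + whisker)]
            rows.append(
                {
                    "parameter": param,
                    "distance_class": int(dclass),
                    "group": group,
                    "median": float(med),
                    "q25": float(q25),
                    "q75": float(q75),
                    "n": int(vals.size),
                    "outliers": ";".join(f"{v:.6g}" for v in sorted(outliers)),
                }
            )
    return pd.DataFrame(rows)


def group_comparison(
    references: pd.DataFrame, parameters: list[str]
) -> pd.DataFrame:
    """Mann-Whitney U repair vs. control per parameter (pooled over
    locations), with the normality gate result."""
    rows = []
    rep = references[references["group"] == "repair"]
    ctl = references[references["group"] == "control"]
    for param in parameters:
        a = rep[param].to_numpy(dtype=float)
        b = ctl[param].to_numpy(dtype=float)
        u, p = mann_whitney_u(a, b)
        rows.append(
            {
                "parameter": param,
                "U": u,
                "p": p,
                "significant": p < 0.05,
                "gate": shapiro_wilk_gate(np.concatenate([a, b])),
            }
        )
    return pd.DataFrame(rows)
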