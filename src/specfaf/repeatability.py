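"""Test-retest repeatability statistics for paired imaging measurements.

Implements the agreement battery for a two-session, single-rater design:

* ICC(A,1) — intraclass correlation, two-way random effects, absolute
  agreement, single measurement — from the subjects x sessions ANOVA
  decomposition:

      ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

  with MS_R, MS_C, MS_E the row (subject), column (session) and residual
  mean squares, n subjects, k = 2 sessions;
* 95% coefficient of repeatability CR = 1.96 x SD of the signed
  between-session differences (sample SD, n-1 denominator) — the value
  below which the difference between two measurements lies in 95% of
  cases. This is the direct operational definition; it coincides with
  1.96 sqrt(2) x within-subject SD when the mean difference is zero;
* within-subject coefficient of variation, root-mean-square method:
  CV% = 100 sqrt( mean_i( s_i^2 / m_i^2 ) ), where for k = 2 the
  within-subject variance is s_i^2 = d_i^2 / 2 and m_i is the subject's
  session mean;
* mean absolute intraobserver variability = mean_i |d_i|, in the units of
  the measured metric;
* Bland-Altman summary: per-subject (mean, difference) points, mean
  difference and 95% limits of agreement mean_diff +/- 1.96 SD(diff).

Degenerate inputs (zero variance where a ratio is taken) raise typed
errors rather than returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.96  # two-sided 95% normal quantile, as conventionally rounded


class DegenerateDataError(ValueError):
    """The statistic is undefined on this input (zero variance or scale)."""


@dataclass
class PairedMeasurements:
    """One metric in one sector, measured in two sessions on n subjects."""

    subject_ids: list[str]
    session1: np.ndarray
    session2: np.ndarray
    metric_name: str = ""
    sector: str = ""

    def __post_init__(self) -> None:
        self.session1 = np.asarray(self.session1, dtype=float)
        self.session2 = np.asarray(self.session2, dtype=float)
        n = len(self.subject_ids)
        if self.session1.shape != (n,) or self.session2.shape != (n,):
            raise ValueError("session vectors must align with subject_ids")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if not (np.isfinite(self.session1).all() and np.isfinite(self.session2).all()):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def differences(self) -> np.ndarray:
        return self.session1 - self.session2


@dataclass
class RepeatabilityReport:
    """The per-sector agreement summary (one table row)."""

    metric_name: str
    sector: str
    n: int
    icc: float
    cr: float
    cv_pct: float
    mean_abs_variability: float
    mean_diff: float
    loa_low: float
    loa_high: float


def icc_two_way_random_absolute(pm: PairedMeasurements) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single score."""
    x = np.stack([pm.session1, pm.session2], axis=1)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise DegenerateDataError(
            "ICC undefined: total variance of the measurements is zero"
        )
    return float((ms_r - ms_e) / denom)


def icc_confidence_interval(
    pm: PairedMeasurements, confidence: float = 0.95
) -> tuple[float, float]:
    """F-distribution confidence interval for ICC(A,1) (McGraw & Wong)."""
    from scipy import stats

    x = np.stack([pm.session1, pm.session2], axis=1)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_r = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
    if ms_e == 0:
        raise DegenerateDataError("CI undefined: zero residual variance")
    alpha = 1 - confidence
    r = icc_two_way_random_absolute(pm)
    a = (k * r) / (n * (1 - r)) if r != 1 else np.inf
    b = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r != 1 else np.inf
    v_num = (a * ms_c + b * ms_e) ** 2
    v_den = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_star = ms_r / ms_e
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (f_star - f_l) / (f_l * (k * ms_c / ms_e + k * n - k - n) + n * f_star)
    upper = n * (f_u * f_star - 1) / (k * ms_c / ms_e + k * n - k - n + n * f_u * f_star)
    return float(lower), float(upper)


def coefficient_of_repeatability(pm: PairedMeasurements) -> float:
    """95% coefficient of repeatability: 1.96 x sample SD of differences."""
    d = pm.differences
    return float(Z95 * d.std(ddof=1))


def coefficient_of_variation(pm: PairedMeasurements) -> float:
    """Within-subject CV (%) by the root-mean-square method."""
    m = (pm.session1 + pm.session2) / 2.0
    if np.any(m <= 0):
        raise DegenerateDataError(
            "CV undefined: some subject means are <= 0 (nonpositive scale)"
        )
    s2 = pm.differences**2 / 2.0
    return float(100.0 * np.sqrt(np.mean(s2 / m**2)))


def mean_absolute_variability(pm: PairedMeasurements) -> float:
    """Mean absolute intraobserver variability, mean_i |session1 - session2|."""
    return float(np.abs(pm.differences).mean())


def bland_altman_summary(pm: PairedMeasurements) -> dict:
    """Bland-Altman agreement summary with plot-ready points.

    Returns mean_diff, loa_low/loa_high (mean_diff -/+ 1.96 SD of the
    differences) and the per-subject (mean, diff) points.
    """
    d = pm.differences
    m = (pm.session1 + pm.session2) / 2.0
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    points = pd.DataFrame(
        {"subject_id": pm.subject_ids, "mean": m, "diff": d}
    )
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - Z95 * sd,
        "loa_high": mean_diff + Z95 * sd,
        "points": points,
    }


def repeatability_report(pm: PairedMeasurements) -> RepeatabilityReport:
    """All agreement statistics for one metric x sector."""
    ba = bland_altman_summary(pm)
    return RepeatabilityReport(
        metric_name=pm.metric_name,
        sector=pm.sector,
        n=pm.n,
        icc=icc_two_way_random_absolute(pm),
        cr=coefficient_of_repeatability(pm),
        cv_pct=coefficient_of_variation(pm),
        mean_abs_variability=mean_absolute_variability(pm),
        mean_diff=ba["mean_diff"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
    )


def paired_from_metrics(
    metrics: pd.DataFrame, metric: str, sector: str
) -> PairedMeasurements:
    """Assemble a PairedMeasurements from the tidy sector-metrics table."""
    sub = metrics[metrics["sector"] == sector]
    wide = sub.pivot(index="eye_id", columns="session_id", values=metric)
    if wide.isna().any().any() or set(wide.columns) != {"1", "2"}:
        raise ValueError(
            f"metrics table is not a complete two-session design for "
            f"{metric}/{sector}"
        )
    wide = wide.sort_index()
    return PairedMeasurements(
        subject_ids=list(wide.index),
        session1=wide["1"].to_numpy(),
        session2=wide["2"].to_numpy(),
        metric_name=metric,
        sector=sector,
    )


def repeatability_table(
    metrics: pd.DataFrame,
    metric: str = "area_fraction_pct",
    sectors: tuple[str, ...] = ("macula", "fovea", "parafovea", "perifovea"),
) -> pd.DataFrame:
    """Agreement table: one statistic per row, one sector per column."""
    reports = {
        s: repeatability_report(paired_from_metrics(metrics, metric, s))
        for s in sectors
    }
    rows = {
        "mean_abs_variability": [reports[s].mean_abs_variability for s in sectors],
        "cr": [reports[s].cr for s in sectors],
        "cv_pct": [reports[s].cv_pct for s in sectors],
        "icc": [reports[s].icc for s in sectors],
        "mean_diff": [reports[s].mean_diff for s in sectors],
        "loa_low": [reports[s].loa_low for s in sectors],
        "loa_high": [reports[s].loa_high for s in sectors],
    }
    return pd.DataFrame(rows, index=list(sectors)).T
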