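"""Cohort-level descriptive and comparative statistics.

Session-1 measurements feed the group analyses: medians with
interquartile ranges per region, a Friedman two-way nonparametric ANOVA
across the related macular regions, pairwise Wilcoxon signed-rank
follow-up (raw and Bonferroni-adjusted p), and a Mann-Whitney U
comparison between age subgroups (dichotomized at 25 years by default).

Conventions, pinned because the numbers depend on them:

* quartiles by linear interpolation between order statistics;
* Friedman with within-subject mid-ranks and the standard tie correction;
  a table where every subject ranks all regions identically gives Q = 0,
  p = 1;
* Wilcoxon signed-rank drops zero differences; if every difference is
  zero the test is vacuous and p = 1 is reported;
* Mann-Whitney U is the count of (a, b) pairs with a > b (plus half the
  ties); exact p when the sample product is small and tie-free, otherwise
  the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

RING_SECTORS = ("fovea", "parafovea", "perifovea")

#: largest n_A * n_B for which the exact Mann-Whitney null is enumerated
_EXACT_LIMIT = 400


@dataclass
class RegionMatrix:
    """n_subjects x m_regions matrix of one metric (complete block design)."""

    values: np.ndarray
    region_labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if m != len(self.region_labels) or n != len(self.subject_ids):
            raise ValueError("matrix dimensions do not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("incomplete block design: missing cells")

    @classmethod
    def from_metrics(
        cls,
        metrics: pd.DataFrame,
        metric: str = "area_fraction_pct",
        regions: tuple[str, ...] = RING_SECTORS,
        session_id: str = "1",
    ) -> "RegionMatrix":
        sub = metrics[metrics["session_id"] == session_id]
        wide = sub.pivot(index="eye_id", columns="sector", values=metric)
        wide = wide[list(regions)].sort_index()
        if wide.isna().any().any():
            raise ValueError("incomplete block design: missing cells")
        return cls(
            values=wide.to_numpy(),
            region_labels=list(regions),
            subject_ids=list(wide.index),
        )


def median_iqr(values: np.ndarray | list[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with quartiles by linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("median/IQR undefined on an empty vector")
    med, q1, q3 = np.percentile(values, [50, 25, 75])
    return float(med), float(q1), float(q3)


def friedman_test(rm: RegionMatrix) -> tuple[float, float]:
    """Friedman chi-square test across related regions.

    Within-subject mid-ranks with the standard tie correction
    (Conover form); Q has m-1 degrees of freedom under the null.
    """
    x = rm.values
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 subjects and 2 regions")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    ss_effect = ((col_sums - n * (m + 1) / 2.0) ** 2).sum()
    denom = (ranks**2).sum() - n * m * (m + 1) ** 2 / 4.0
    if denom == 0:  # every subject ties all regions
        return 0.0, 1.0
    q = (m - 1) * ss_effect / denom
    p = float(stats.chi2.sf(q, m - 1))
    return float(q), p


def _wilcoxon_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def pairwise_region_tests(rm: RegionMatrix) -> pd.DataFrame:
    """Wilcoxon signed-rank test for every region pair.

    Returns region_a, region_b, statistic, p_raw and p_bonferroni
    (raw p x number of pairs, capped at 1).
    """
    pairs = list(combinations(range(len(rm.region_labels)), 2))
    rows = []
    for i, j in pairs:
        stat, p = _wilcoxon_pair(rm.values[:, i], rm.values[:, j])
        rows.append(
            {
                "region_a": rm.region_labels[i],
                "region_b": rm.region_labels[j],
                "statistic": stat,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def mann_whitney_u(
    group_a: np.ndarray | list[float], group_b: np.ndarray | list[float]
) -> tuple[float, float]:
    """Mann-Whitney U (two-sided) between two independent groups.

    U counts pairs where group A exceeds group B (ties count 1/2). The
    exact null distribution is used when n_A x n_B <= 400 and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def age_group_tests(
    metrics: pd.DataFrame,
    manifest: pd.DataFrame,
    metric: str = "area_fraction_pct",
    age_cutoff: float = 25.0,
    sectors: tuple[str, ...] = ("macula",) + RING_SECTORS,
    session_id: str = "1",
) -> pd.DataFrame:
    """Mann-Whitney comparison (age <= cutoff vs > cutoff) per sector."""
    ages = (
        manifest[["eye_id", "age"]]
        .drop_duplicates("eye_id")
        .set_index("eye_id")["age"]
    )
    sub = metrics[metrics["session_id"] == session_id]
    rows = []
    for sector in sectors:
        vals = sub[sub["sector"] == sector].set_index("eye_id")[metric]
        young = vals[ages.reindex(vals.index) <= age_cutoff].to_numpy()
        old = vals[ages.reindex(vals.index) > age_cutoff].to_numpy()
        u, p = mann_whitney_u(young, old)
        rows.append(
            {
                "sector": sector,
                "n_young": young.size,
                "n_old": old.size,
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def cohort_report(
    metrics: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    metric: str = "area_fraction_pct",
    age_cutoff: float = 25.0,
) -> dict:
    """Full session-1 group analysis of one metric.

    Returns a JSON-serializable dict: per-sector median/IQR, the Friedman
    test across the three rings, the pairwise Wilcoxon table, and (when a
    manifest with ages is given) the age-group Mann-Whitney tests.
    """
    sub = metrics[metrics["session_id"] == "1"]
    descriptives = {}
    for sector in ("macula",) + RING_SECTORS:
        med, q1, q3 = median_iqr(
            sub[sub["sector"] == sector][metric].to_numpy()
        )
        descriptives[sector] = {"median": med, "q1": q1, "q3": q3}
    rm = RegionMatrix.from_metrics(metrics, metric=metric)
    q, p = friedman_test(rm)
    pairwise = pairwise_region_tests(rm)
    report = {
        "metric": metric,
        "n_subjects": len(rm.subject_ids),
        "descriptives": descriptives,
        "friedman": {"statistic": q, "p": p},
        "pairwise": pairwise.to_dict(orient="records"),
    }
    if manifest is not None and "age" in manifest.columns:
        ages = age_group_tests(
            metrics, manifest, metric=metric, age_cutoff=age_cutoff
        )
        report["age_groups"] = ages.to_dict(orient="records")
    return report
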