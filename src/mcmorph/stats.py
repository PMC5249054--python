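"""Group summaries and hypothesis tests over the per-sample cohort table.

The cohort comparisons are nonparametric: Kruskal-Wallis rank tests for the
continuous morphometric statistics across the three histologic groups, and
Pearson chi-square tests (no continuity correction) on the 2x3
presence/absence tables of the morphology flags, with a Bonferroni
correction over the flag family.  A Kolmogorov-Smirnov normality check is
provided descriptively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .categorization import FLAG_NAMES, GROUPS, CohortRecord, presence_table

logger = logging.getLogger(__name__)

#: Fields of SampleMorphometry that group_summary/kruskal_wallis accept.
SUMMARY_FIELDS = ("n_objects", "mean_V", "mean_SMI", "sd_SMI")


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    p_adjusted: float | None = None


def _group_values(
    records: list[CohortRecord], field: str, include_excluded: bool
) -> dict[str, np.ndarray]:
    if field not in SUMMARY_FIELDS:
        raise ValueError(f"field must be one of {SUMMARY_FIELDS}, got {field!r}")
    values: dict[str, list[float]] = {g: [] for g in GROUPS}
    for r in records:
        if r.morphometry is None:
            raise ValueError(f"sample {r.sample_id} carries no morphometry")
        if r.morphometry.excluded and not include_excluded:
            continue
        values[r.group].append(float(getattr(r.morphometry, field)))
    empty = [g for g in GROUPS if not values[g]]
    if empty:
        raise ValueError(f"no samples in group(s) {empty}")
    return {g: np.asarray(v) for g, v in values.items()}


def group_summary(
    records: list[CohortRecord], field: str, include_excluded: bool = False
) -> dict[str, GroupSummary]:
    """Arithmetic mean and SD (n-1) of one statistic per histologic group."""
    grouped = _group_values(records, field, include_excluded)
    return {
        g: GroupSummary(
            group=g,
            n=len(v),
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        )
        for g, v in grouped.items()
    }


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test with midrank tie correction; df = k - 1.

    When every value is identical the statistic is degenerate; by convention
    the result is H = 0, p = 1 (logged).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        logger.info("kruskal_wallis: all values identical; returning p = 1")
        return TestResult(statistic=0.0, df=len(groups) - 1, p_value=1.0)
    h, p = sps.kruskal(*groups)
    return TestResult(statistic=float(h), df=len(groups) - 1, p_value=float(p))


def pearson_chi_square(table: np.ndarray | pd.DataFrame) -> TestResult:
    """Pearson X^2 on a 2xk contingency table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError(
            "zero row or column margin: expected counts are undefined"
        )
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(statistic=float(chi2), df=int(dof), p_value=float(p))


def bonferroni(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values ``min(1, m * p)``; m defaults to len."""
    ps = [float(p) for p in p_values]
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else int(m)
    return [min(1.0, m * p) for p in ps]


def ks_normality(values: np.ndarray) -> TestResult:
    """One-sample KS test against a normal with the sample's mean and SD.

    Descriptive only: the p-value is the asymptotic one and is optimistic
    because the null parameters are estimated from the same data (no
    Lilliefors correction).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: normality test undefined")
    d, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(statistic=float(d), df=None, p_value=float(p))


def morphology_tests(
    records: list[CohortRecord], m: int | None = 4
) -> pd.DataFrame:
    """Chi-square battery over all four morphology flags, Bonferroni-adjusted.

    Returns a tidy frame with one row per flag: statistic, df, p, p_adjusted.
    """
    results = {flag: pearson_chi_square(presence_table(records, flag)) for flag in FLAG_NAMES}
    adjusted = bonferroni([results[f].p_value for f in FLAG_NAMES], m=m)
    return pd.DataFrame(
        {
            "test": [f"chi_square_{f}" for f in FLAG_NAMES],
            "flag": list(FLAG_NAMES),
            "statistic": [results[f].statistic for f in FLAG_NAMES],
            "df": [results[f].df for f in FLAG_NAMES],
            "p": [results[f].p_value for f in FLAG_NAMES],
            "p_adjusted": adjusted,
        }
    )


def kruskal_wallis_battery(
    records: list[CohortRecord], include_excluded: bool = False
) -> pd.DataFrame:
    """Kruskal-Wallis tests of every summary field across groups A/B/C."""
    rows = []
    for fld in SUMMARY_FIELDS:
        grouped = _group_values(records, fld, include_excluded)
        res = kruskal_wallis([grouped[g] for g in GROUPS])
        rows.append(
            {
                "test": f"kruskal_wallis_{fld}",
                "field": fld,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
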