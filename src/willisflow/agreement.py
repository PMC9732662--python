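"""Agreement statistics between measured and simulated velocities.

The validation protocol treats each (investigation, site) observation as a
subject rated by two methods - TCD and the simulation - and reports:

* the intraclass correlation coefficient of the two-way random-effects
  model, consistency definition, single rater: ``ICC(C,1) = (MS_S - MS_E) /
  (MS_S + (k-1) MS_E)`` with ``k = 2`` raters, with the exact F-based 95%
  confidence interval;
* Bland-Altman limits of agreement on base-10 logarithms, reported as
  multiplicative factors ``10^(mean +/- 1.96 sd)`` - "in 95% of cases the
  simulation differs from TCD by (1 - lower) below to (upper - 1) above";
* the Wilcoxon signed-rank test of the paired differences;
* per-subgroup ICCs with a confidence-interval overlap flag (no overlap is
  the criterion for a genuine subgroup difference).

The ICC is computed from the explicit two-way ANOVA decomposition, not from
a Pearson-correlation shortcut (the two coincide only for balanced,
bias-free tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

REQUIRED_COLUMNS = ("investigation_id", "site", "v_tcd", "v_sim")


def validate_paired_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the paired-velocity table invariants; returns the table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"paired table missing columns: {missing}")
    if (table[["v_tcd", "v_sim"]] <= 0).any().any():
        raise ValueError("velocities must be > 0 (log transform requires it)")
    if table.duplicated(["investigation_id", "site"]).any():
        raise ValueError("duplicated (investigation, site) pairs")
    return table


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int

    def overlaps(self, other: "ICCResult") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


@dataclass(frozen=True)
class LogLoA:
    """Multiplicative limits of agreement from base-10 log differences."""

    mean_log_diff: float
    sd_log_diff: float
    lower_factor: float
    upper_factor: float
    n: int

    def describe(self) -> str:
        return (
            f"{(1 - self.lower_factor) * 100:.0f}% below to "
            f"{(self.upper_factor - 1) * 100:.0f}% above"
        )


def icc_consistency(table: pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1) with its exact F-based confidence interval.

    Subjects are the (investigation, site) rows; raters are {TCD,
    simulation}.  A constant offset between the raters does not lower the
    consistency ICC.  Degenerate tables (no between-subject variance)
    return 0 with a warning.
    """
    validate_paired_table(table)
    x = table[["v_tcd", "v_sim"]].to_numpy(dtype=float)
    n, k = x.shape
    if n < 5:
        raise ValueError("ICC requires at least 5 subject pairs")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0 or (ms_rows + (k - 1) * ms_err) == 0:
        warnings.warn("degenerate table: no between-subject variance", stacklevel=2)
        return ICCResult(0.0, 0.0, 0.0, n)
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    if ms_err == 0:
        return ICCResult(1.0, 1.0, 1.0, n)
    # Exact interval: F = MS_S/MS_E with (n-1, (n-1)(k-1)) dof.
    f_obs = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_low = f_obs / scipy.stats.f.ppf(1 - alpha / 2, df1, df2)
    f_high = f_obs * scipy.stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_high - 1) / (f_high + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), n)


def log_bland_altman(table: pd.DataFrame) -> LogLoA:
    """Limits of agreement of ``log10(v_sim) - log10(v_tcd)``.

    The antilogged limits are multiplicative: simulated velocities fall
    between ``lower_factor`` and ``upper_factor`` times the TCD value in 95%
    of cases under normality of the log differences.
    """
    validate_paired_table(table)
    d = np.log10(table["v_sim"].to_numpy(float)) - np.log10(
        table["v_tcd"].to_numpy(float)
    )
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return LogLoA(
        mean_log_diff=mean,
        sd_log_diff=sd,
        lower_factor=float(10 ** (mean - 1.96 * sd)),
        upper_factor=float(10 ** (mean + 1.96 * sd)),
        n=int(d.size),
    )


def paired_difference_test(table: pd.DataFrame) -> tuple[float, float]:
    """Wilcoxon signed-rank test on ``v_sim - v_tcd``.

    Exact null distribution for n <= 25 without ties; normal approximation
    with tie correction otherwise.  Returns (statistic, two-sided p).
    """
    validate_paired_table(table)
    d = table["v_sim"].to_numpy(float) - table["v_tcd"].to_numpy(float)
    if d.size < 6:
        raise ValueError("paired test requires n >= 6")
    if np.all(d == 0):
        return 0.0, 1.0
    nonzero = d[d != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    stat, p = scipy.stats.wilcoxon(d, method=method, correction=(method == "approx"))
    return float(stat), float(p)


@dataclass(frozen=True)
class SubgroupAgreement:
    label: str
    per_level: dict
    ci_overlap: bool | None
    excluded_levels: tuple[str, ...]


def subgroup_agreement(
    table: pd.DataFrame, label: str, min_n: int = 5
) -> SubgroupAgreement:
    """ICC per level of a subgroup label, plus the CI-overlap flag.

    Non-overlapping 95% intervals mark a subgroup difference as genuine
    rather than random.  Levels below the minimum subject count are
    excluded with a warning; the overlap flag is only defined when exactly
    two levels survive.
    """
    validate_paired_table(table)
    if label not in table.columns:
        raise KeyError(f"subgroup label {label!r} not in table")
    per_level: dict = {}
    excluded = []
    for level, sub in table.groupby(label, sort=True):
        if len(sub) < min_n:
            warnings.warn(
                f"subgroup {label}={level!r} has n={len(sub)} < {min_n}; excluded",
                stacklevel=2,
            )
            excluded.append(str(level))
            continue
        per_level[level] = icc_consistency(sub)
    overlap: bool | None = None
    if len(per_level) == 2:
        a, b = per_level.values()
        overlap = a.overlaps(b)
    return SubgroupAgreement(label, per_level, overlap, tuple(excluded))
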