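"""Cohort statistics layer: site-stratified uptake summaries, the
metastasis-versus-healthy paired comparison, SUVmax-SUVpeak and ki67
correlations, and marker positivity rates.

Summaries pool lesions (not patients) across scans, matching how the
uptake tables are reported.  Tests back every statistic with a small-n
closed-form oracle; no bit-compatibility with any commercial statistics
package is claimed.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatisticsError(ValueError):
    """Raised for invalid statistical inputs."""


SIGNIFICANCE_LEVEL = 0.05

_SUMMARY_COLUMNS = ("suv_max", "suv_peak", "reference_suv", "tln_ratio")


def format_p(p: float) -> str:
    """p to three decimals; values below 0.0005 render as '0.000'."""
    return f"{p:.3f}"


def format_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.2f} ± {sd:.2f}"


def site_summary(table: pd.DataFrame, site: str) -> dict:
    """Sample mean and SD (n-1 denominator) per uptake column at one site.

    Returns ``{column: (mean, sd)}`` for every summary column present with
    at least one non-missing value; requires >= 2 lesions at the site.
    """
    rows = table[table["site"] == site]
    if len(rows) < 2:
        raise StatisticsError(f"need >= 2 lesions at site {site!r}, got {len(rows)}")
    out = {}
    for col in _SUMMARY_COLUMNS:
        if col not in rows.columns:
            continue
        vals = rows[col].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        out[col] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return out


def paired_t_test(lesion_values: Sequence[float],
                  reference_values: Sequence[float]) -> Tuple[float, float]:
    """Paired-samples t-test on per-lesion (lesion, reference) pairs.

    Returns (t, two-sided p).  Identical pairs everywhere give t = 0, p = 1
    (no evidence of a difference); a nonzero constant difference has zero
    variance and is rejected as degenerate.
    """
    x = np.asarray(lesion_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape:
        raise StatisticsError("paired samples must have equal length")
    if len(x) < 3:
        raise StatisticsError("need at least 3 pairs")
    diffs = x - y
    if np.std(diffs, ddof=1) == 0:
        if np.all(diffs == 0):
            return 0.0, 1.0
        raise StatisticsError("zero variance of nonzero differences: t undefined")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatisticsError("samples must have equal length")
    if len(x) < 3:
        raise StatisticsError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticsError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def positivity_rates(table: pd.DataFrame, markers: Sequence[str]) -> dict:
    """Percent of patients flagged positive per marker, to one decimal."""
    if len(table) < 1:
        raise StatisticsError("at least one patient is required")
    out = {}
    for marker in markers:
        if marker not in table.columns:
            raise StatisticsError(f"unknown marker {marker!r}")
        flags = table[marker].astype(bool)
        out[marker] = round(float(100.0 * flags.sum() / len(flags)), 1)
    return out


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def uptake_summary_table(lesion_table: pd.DataFrame,
                         sites: Sequence[str] = ("liver", "lymph_node", "bone"),
                         ) -> pd.DataFrame:
    """Tumoral versus healthy-tissue uptake per metastatic site
    (mean ± SD of lesion SUVmax, reference SUVmax and TL/N ratio)."""
    rows = []
    for site in sites:
        summ = site_summary(lesion_table, site)
        row = {"site": site}
        for col, name in (("suv_max", "suv_max_metastases"),
                          ("reference_suv", "suv_max_healthy"),
                          ("tln_ratio", "tln_ratio")):
            if col in summ:
                row[name] = format_mean_sd(*summ[col])
                row[name + "_mean"] = summ[col][0]
                row[name + "_sd"] = summ[col][1]
        rows.append(row)
    return pd.DataFrame(rows)


def suv_correlation_table(lesion_table: pd.DataFrame,
                          sites: Sequence[str] = ("liver", "lymph_node", "bone"),
                          ) -> pd.DataFrame:
    """Per-site SUVmax/SUVpeak summaries with their Pearson correlation."""
    rows = []
    for site in sites:
        sub = lesion_table[lesion_table["site"] == site]
        summ = site_summary(lesion_table, site)
        r, p = pearson_correlation(sub["suv_max"], sub["suv_peak"])
        rows.append({
            "site": site,
            "suv_max": format_mean_sd(*summ["suv_max"]),
            "suv_peak": format_mean_sd(*summ["suv_peak"]),
            "r": round(r, 3),
            "p": format_p(p),
            "significant": p < SIGNIFICANCE_LEVEL,
        })
    return pd.DataFrame(rows)


def ki67_correlation_table(lesion_table: pd.DataFrame,
                           patient_table: pd.DataFrame,
                           sites: Sequence[str] = ("liver", "lymph_node", "bone"),
                           ) -> pd.DataFrame:
    """Correlation of ki67 with SUVmax and SUVpeak per site and overall."""
    merged = lesion_table.merge(patient_table[["patient_id", "ki67_pct"]],
                                on="patient_id")
    rows = []
    for label, sub in ([(s, merged[merged["site"] == s]) for s in sites]
                       + [("all_lesions", merged)]):
        if len(sub) < 3:
            continue
        r_max, p_max = pearson_correlation(sub["ki67_pct"], sub["suv_max"])
        r_peak, p_peak = pearson_correlation(sub["ki67_pct"], sub["suv_peak"])
        rows.append({
            "site": label,
            "r_suv_max": round(r_max, 3), "p_suv_max": format_p(p_max),
            "r_suv_peak": round(r_peak, 3), "p_suv_peak": format_p(p_peak),
        })
    return pd.DataFrame(rows)
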