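"""Differentially variable position (DVP) detection.

Implements the two-stage gating procedure known in the methylation
literature as iEVORA: per probe, Bartlett's test compares group variances
and is corrected genome-wide with Benjamini-Hochberg; probes passing a
stringent variability threshold (q < 0.001) are then gated and ranked by a
standard t-test on the means (p < 0.05).  The t-gate regularizes the
variance test, which is exquisitely sensitive to single outliers: genuine
hypervariable subpopulations drag the group mean with them, while a lone
outlier does not.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import bh_adjust

__all__ = ["bartlett_test", "ievora", "summarize_dvp_directionality"]

_VAR_FLOOR = 1e-12


def _bartlett_two_group(
    var_x: np.ndarray, n_x: int, var_y: np.ndarray, n_y: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized classical Bartlett statistic for two groups, chi2(1) p."""
    vx = np.maximum(var_x, _VAR_FLOOR)
    vy = np.maximum(var_y, _VAR_FLOOR)
    n = n_x + n_y
    pooled = ((n_x - 1) * vx + (n_y - 1) * vy) / (n - 2)
    num = (n - 2) * np.log(pooled) - (n_x - 1) * np.log(vx) - (n_y - 1) * np.log(vy)
    corr = 1.0 + (1.0 / (n_x - 1) + 1.0 / (n_y - 1) - 1.0 / (n - 2)) / 3.0
    b = num / corr
    return b, stats.chi2.sf(b, 1)


def bartlett_test(x, y) -> Tuple[float, float]:
    """Two-group Bartlett test of variance homogeneity.

    Returns ``(B, p)`` with p from chi-square(1).  Zero sample variances are
    floored at 1e-12 so degenerate probes produce a finite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx <= _VAR_FLOOR and vy <= _VAR_FLOOR:
        return 0.0, 1.0
    b, p = _bartlett_two_group(
        np.atleast_1d(vx), len(x), np.atleast_1d(vy), len(y)
    )
    return float(b[0]), float(p[0])


def ievora(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    q_thresh: float = 1e-3,
    p_thresh: float = 0.05,
    annotation: Optional[pd.DataFrame] = None,
    scale: str = "beta",
) -> pd.DataFrame:
    """Bartlett + t-test gated DVP table.

    Per probe: Bartlett p over case vs control, BH-corrected across all
    probes; probes with q < ``q_thresh`` are retained and tested for a mean
    difference (Welch t); survivors (p < ``p_thresh``) are ranked ascending
    by the t-test p-value (ties broken by Bartlett p, then probe ID).  The
    hypervariable group is the one with larger sample variance; the trend
    records whether cases are hypo- or hypermethylated relative to controls.
    """
    if scale not in ("beta", "M"):
        raise ValueError("scale must be 'beta' or 'M'")
    values = beta
    if scale == "M":
        from .preprocess import beta_to_m

        values = beta_to_m(beta)

    status = sample_sheet.loc[values.columns, "status"]
    case = values.loc[:, (status == "case").values].values
    control = values.loc[:, (status == "control").values].values
    if case.shape[1] < 3 or control.shape[1] < 3:
        raise ValueError("need at least 3 samples per group")

    var_case = case.var(axis=1, ddof=1)
    var_control = control.var(axis=1, ddof=1)
    b_stat, p_bt = _bartlett_two_group(
        var_case, case.shape[1], var_control, control.shape[1]
    )
    q_bt = bh_adjust(p_bt)

    keep = q_bt < q_thresh
    t_stat = np.full(len(values), np.nan)
    p_tt = np.full(len(values), np.nan)
    if keep.any():
        res = stats.ttest_ind(case[keep], control[keep], axis=1, equal_var=False)
        t_stat[keep] = res.statistic
        p_tt[keep] = res.pvalue
    final = keep & (p_tt < p_thresh)

    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    table = pd.DataFrame(
        {
            "bartlett_stat": b_stat[final],
            "p_bartlett": p_bt[final],
            "q_bartlett": q_bt[final],
            "t_stat": t_stat[final],
            "p_ttest": p_tt[final],
            "mean_case": mean_case[final],
            "mean_control": mean_control[final],
            "var_case": var_case[final],
            "var_control": var_control[final],
        },
        index=values.index[final],
    )
    table["hypervariable_group"] = np.where(
        table["var_case"] > table["var_control"], "case", "control"
    )
    table["trend"] = np.where(
        table["mean_case"] < table["mean_control"], "hypo_in_case", "hyper_in_case"
    )
    order = np.lexsort(
        (table.index.values, table["p_bartlett"].values, table["p_ttest"].values)
    )
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    if annotation is not None:
        join_cols = [
            c
            for c in ("CHR", "UCSC_RefGene_Name", "UCSC_RefGene_Group")
            if c in annotation.columns
        ]
        table = table.join(annotation[join_cols], how="left")
    table.attrs["q_thresh"] = q_thresh
    table.attrs["p_thresh"] = p_thresh
    table.attrs["n_tested"] = len(values)
    return table


def summarize_dvp_directionality(dvp_table: pd.DataFrame) -> Dict[str, int]:
    """Partition counts of a DVP table by hypervariable group and trend.

    ``n_hyper_case_hypo_trend`` counts case-hypervariable probes whose cases
    trend hypomethylated; ``n_hyper_control_hypo_trend`` counts
    control-hypervariable probes whose controls trend hypomethylated (i.e.
    cases trend hypermethylated).
    """
    if len(dvp_table) == 0:
        return {
            "n_total": 0,
            "n_hyper_case": 0,
            "n_hyper_control": 0,
            "n_hyper_case_hypo_trend": 0,
            "n_hyper_control_hypo_trend": 0,
        }
    hyper_case = dvp_table["hypervariable_group"] == "case"
    hypo_case = dvp_table["trend"] == "hypo_in_case"
    return {
        "n_total": int(len(dvp_table)),
        "n_hyper_case": int(hyper_case.sum()),
        "n_hyper_control": int((~hyper_case).sum()),
        "n_hyper_case_hypo_trend": int((hyper_case & hypo_case).sum()),
        "n_hyper_control_hypo_trend": int((~hyper_case & ~hypo_case).sum()),
    }
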