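"""Cohort descriptives and simple categorical tests for study reports."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cells import welch_t_test

__all__ = ["contingency_test", "cohort_summary"]


def contingency_test(table) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns ``(chi2, df, p)``.  No continuity correction is applied.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal; test undefined")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cohort_summary(
    sample_sheet: pd.DataFrame,
    composition: Optional[pd.DataFrame] = None,
) -> Dict:
    """Table-1-style descriptives of a discordant twin cohort.

    Per group: n, % female, mean (SD) age, smoking distribution with a
    chi-square p for independence from disease status, and (when a
    composition estimate is supplied) mean cell fractions with Welch p.
    Degenerate statistics (single pair, empty smoking category) are reported
    as notes rather than raising.
    """
    summary: Dict = {"groups": {}, "notes": []}
    for status in ("case", "control"):
        grp = sample_sheet[sample_sheet["status"] == status]
        entry = {
            "n": int(len(grp)),
            "pct_female": float((grp["sex"] == "F").mean() * 100)
            if "sex" in grp
            else None,
            "age_mean": float(grp["age"].mean()) if "age" in grp else None,
            "age_sd": float(grp["age"].std(ddof=1)) if "age" in grp else None,
        }
        summary["groups"][status] = entry

    if "smoking" in sample_sheet.columns:
        counts = pd.crosstab(sample_sheet["status"], sample_sheet["smoking"])
        summary["smoking_counts"] = counts.to_dict()
        try:
            chi2, df, p = contingency_test(counts.values)
            summary["smoking_p"] = p
        except ValueError as exc:
            summary["smoking_p"] = None
            summary["notes"].append(f"smoking test degenerate: {exc}")

    if composition is not None:
        cells = {}
        status = sample_sheet.loc[composition.index, "status"]
        for cell in composition.columns:
            case_vals = composition.loc[(status == "case").values, cell].values
            ctrl_vals = composition.loc[(status == "control").values, cell].values
            entry = {
                "mean_case": float(np.mean(case_vals)),
                "mean_control": float(np.mean(ctrl_vals)),
            }
            try:
                _, _, p = welch_t_test(case_vals, ctrl_vals)
                entry["p_value"] = p
            except ValueError as exc:
                entry["p_value"] = None
                summary["notes"].append(f"cell '{cell}' test degenerate: {exc}")
            cells[cell] = entry
        summary["cell_composition"] = cells
    return summary
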