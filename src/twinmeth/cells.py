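"""Reference-based cell-composition estimation and group comparison.

Houseman-style deconvolution: each sample's methylome over a discriminating
probe subset is regressed on purified-cell reference profiles under a
nonnegativity constraint, and the weights are renormalized to sum to one.
Group differences in the estimated fractions are tested with Welch's
two-sample t-test.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "select_discriminating_probes",
    "estimate_cell_fractions",
    "welch_t_test",
    "compare_composition",
]


def select_discriminating_probes(
    reference: pd.DataFrame, n_per_type: int = 100
) -> List[str]:
    """Top discriminating probes per cell type, one-vs-rest.

    Probes are ranked for each type by |mean(type) - mean(others)| divided by
    the pooled between-type SD; the union of the per-type top lists is
    returned (deduplicated, stable order by probe ID within ties).
    """
    if reference.shape[1] < 2:
        raise ValueError("reference must contain at least 2 cell types")
    r = reference.values
    row_sd = r.std(axis=1, ddof=0)
    if np.allclose(row_sd, 0.0):
        warnings.warn("reference columns are identical; probe selection is degenerate")
    denom = row_sd + 1e-12
    selected: List[str] = []
    seen = set()
    for j in range(r.shape[1]):
        others = np.delete(r, j, axis=1).mean(axis=1)
        score = np.abs(r[:, j] - others) / denom
        order = np.lexsort((reference.index.values, -score))
        take = min(n_per_type, len(order))
        if take < n_per_type:
            warnings.warn("fewer candidate probes than requested; returning all")
        for idx in order[:take]:
            pid = reference.index[idx]
            if pid not in seen:
                seen.add(pid)
                selected.append(pid)
    return selected


def estimate_cell_fractions(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
    probe_subset: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Estimate per-sample cell-type fractions by constrained projection.

    Solves ``min || beta_s - R w ||^2`` subject to ``w >= 0`` per sample
    (nonnegative least squares), then renormalizes to ``sum(w) = 1``.
    Returns a samples x cell-types DataFrame.
    """
    if probe_subset is None:
        probe_subset = select_discriminating_probes(reference)
    probes = [p for p in probe_subset]
    if len(probes) == 0:
        raise ValueError("empty probe subset")
    missing = [p for p in probes if p not in beta.index or p not in reference.index]
    if missing:
        raise ValueError(f"{len(missing)} subset probes missing from inputs")
    r = reference.loc[probes].values
    if np.linalg.matrix_rank(r) < r.shape[1]:
        raise ValueError("reference is rank deficient on the probe subset")
    y = beta.loc[probes].values
    weights = np.empty((beta.shape[1], reference.shape[1]))
    for s in range(beta.shape[1]):
        w, _ = optimize.nnls(r, y[:, s])
        total = w.sum()
        if total <= 0:
            raise ValueError(f"deconvolution failed for sample {beta.columns[s]}")
        weights[s] = w / total
    return pd.DataFrame(weights, index=beta.columns, columns=reference.columns)


def welch_t_test(x, y) -> Tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    Two degenerate zero-variance groups with equal means return ``(0, df, 1)``
    by convention; zero variance with unequal means is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    if vx == 0.0 and vy == 0.0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(nx + ny - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def compare_composition(
    composition: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cell-type case/control comparison of estimated fractions.

    Returns one row per cell type with group means, Welch p-value, and a
    ``confounder`` flag (p < alpha) indicating that composition should be
    carried as a model covariate.
    """
    status = sample_sheet.loc[composition.index, "status"]
    case = composition.loc[(status == "case").values]
    control = composition.loc[(status == "control").values]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    for cell in composition.columns:
        t, df, p = welch_t_test(case[cell].values, control[cell].values)
        rows.append(
            {
                "cell_type": cell,
                "mean_case": case[cell].mean(),
                "mean_control": control[cell].mean(),
                "t": t,
                "df": df,
                "p_value": p,
                "confounder": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
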