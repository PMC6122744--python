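"""Differentially methylated position (DMP) testing for discordant pairs.

The model is a per-probe linear model of methylation on disease status with
a sibling-pair random intercept.  In the fully balanced discordant design
(every pair contributes exactly one case and one control) the REML mixed
model is algebraically equivalent, for the disease effect and every
within-pair-varying covariate, to ordinary least squares on within-pair
differences: the pair random effect cancels in the contrast, and the REML
residual variance equals the within-pair residual mean square.  The
implementation therefore fits the difference regression, which is exact,
fast (one closed-form solve shared by all probes) and free of convergence
failures.  Covariates that are constant within pairs (age, sex, cohort) are
absorbed by the pair effect; they are detected and dropped with a log note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PowerSpec",
    "bh_adjust",
    "summarize_group_means",
    "fit_dmp_model",
    "ewas_power",
    "sd_for_power",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pair_columns(
    beta: pd.DataFrame, sample_sheet: pd.DataFrame
) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    sheet = sample_sheet.loc[beta.columns]
    case_ids, control_ids = [], []
    for pair, grp in sheet.groupby("pair_id", sort=True):
        statuses = set(grp["status"])
        if len(grp) != 2 or statuses != {"case", "control"}:
            raise ValueError(
                f"pair '{pair}' is not a discordant case/control pair"
            )
        case_ids.append(grp.index[(grp["status"] == "case").values][0])
        control_ids.append(grp.index[(grp["status"] == "control").values][0])
    return sheet, np.asarray(case_ids), np.asarray(control_ids)


def summarize_group_means(
    beta: pd.DataFrame, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-probe group means and their difference (case - control)."""
    status = sample_sheet.loc[beta.columns, "status"]
    case_cols = beta.columns[(status == "case").values]
    control_cols = beta.columns[(status == "control").values]
    if len(case_cols) == 0 or len(control_cols) == 0:
        raise ValueError("both groups must be nonempty")
    mean_case = beta[case_cols].mean(axis=1)
    mean_control = beta[control_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_beta_control": mean_control,
            "mean_beta_case": mean_case,
            "diff": mean_case - mean_control,
        }
    )


def _covariate_deltas(
    sheet: pd.DataFrame,
    case_ids: np.ndarray,
    control_ids: np.ndarray,
    covariates: Sequence[str],
) -> Tuple[np.ndarray, list]:
    """Within-pair differences of the covariates, dummy-coding categoricals."""
    blocks, names = [], []
    for cov in covariates:
        series = sheet[cov]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series, prefix=cov, drop_first=True).astype(float)
        else:
            dummies = series.astype(float).to_frame(cov)
        delta = dummies.loc[case_ids].values - dummies.loc[control_ids].values
        for j, name in enumerate(dummies.columns):
            col = delta[:, j]
            if np.max(np.abs(col)) < 1e-12:
                logger.info(
                    "covariate '%s' is constant within pairs; absorbed by the "
                    "pair effect and dropped",
                    name,
                )
                continue
            blocks.append(col)
            names.append(name)
    if blocks:
        return np.column_stack(blocks), names
    return np.empty((len(case_ids), 0)), names


def fit_dmp_model(
    beta: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    covariates: Sequence[str] = (),
    annotation: Optional[pd.DataFrame] = None,
    scale: str = "beta",
) -> pd.DataFrame:
    """Per-probe disease-effect test with a sibling-pair random intercept.

    Fits, per probe, methylation ~ status + covariates + (1 | pair) via the
    exact within-pair reduction (see module docstring), returning a table
    with group means, effect estimate, two-sided p and BH q, sorted by p.
    ``scale='M'`` tests logit-transformed values instead of betas.
    """
    if scale not in ("beta", "M"):
        raise ValueError("scale must be 'beta' or 'M'")
    values = beta
    if scale == "M":
        from .preprocess import beta_to_m

        values = beta_to_m(beta)

    sheet, case_ids, control_ids = _pair_columns(values, sample_sheet)
    d = values[case_ids].values - values[control_ids].values  # probes x pairs
    x, cov_names = _covariate_deltas(sheet, case_ids, control_ids, covariates)
    n_pairs = d.shape[1]
    z = np.column_stack([np.ones(n_pairs), x])
    # drop covariate columns that are collinear with the intercept or each
    # other (e.g. an array-position delta that is identical in every pair)
    keep = [0]
    for j in range(1, z.shape[1]):
        trial = z[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
        else:
            logger.info(
                "covariate '%s' is collinear in the within-pair design; dropped",
                cov_names[j - 1],
            )
    cov_names = [cov_names[j - 1] for j in keep[1:]]
    z = z[:, keep]
    df = n_pairs - z.shape[1]
    if df < 1:
        raise ValueError("not enough pairs for the requested covariates")

    ztz_inv = np.linalg.inv(z.T @ z)
    coefs = d @ z @ ztz_inv  # probes x (1 + k)
    resid = d - coefs @ z.T
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.maximum(sigma2 * ztz_inv[0, 0], 1e-300))
    effect = coefs[:, 0]
    t = effect / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    table = summarize_group_means(beta, sample_sheet)
    table["effect"] = effect
    table["se"] = se
    table["t"] = t
    table["p_value"] = p
    table["q_value"] = bh_adjust(p)
    if annotation is not None:
        join_cols = [
            c
            for c in ("CHR", "UCSC_RefGene_Name", "UCSC_RefGene_Group")
            if c in annotation.columns
        ]
        table = table.join(annotation[join_cols], how="left")
    table.attrs["covariates"] = cov_names
    table.attrs["scale"] = scale
    table.attrs["df"] = int(df)
    order = np.lexsort((table.index.values, table["p_value"].values))
    return table.iloc[order]


@dataclass
class PowerSpec:
    """Inputs of the paired-design power calculation.

    ``sd_diff`` is the standard deviation of within-pair methylation
    differences on the beta scale; it must be supplied explicitly because
    per-probe variances span orders of magnitude on real arrays.
    """

    n_pairs: int
    delta_beta: float
    sd_diff: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.sd_diff <= 0:
            raise ValueError("sd_diff must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def ewas_power(
    n_pairs: int,
    delta_beta: float,
    sd_diff: float,
    alpha: float = 0.05,
) -> float:
    """Two-sided paired t-test power via the noncentral t distribution."""
    spec = PowerSpec(n_pairs, delta_beta, sd_diff, alpha)
    spec.validate()
    df = n_pairs - 1
    ncp = delta_beta / (sd_diff / np.sqrt(n_pairs))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(t_crit, df, ncp)
    lower = stats.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(lower):  # negligible far tail can underflow to NaN
        lower = 0.0
    return float(upper + lower)


def sd_for_power(
    target_power: float,
    n_pairs: int,
    delta_beta: float,
    alpha: float = 0.05,
) -> float:
    """Within-pair difference SD at which power crosses ``target_power``.

    Root-finds the monotone power curve in ``sd_diff``; useful for reading a
    power statement backwards into its implied variance assumption.
    """
    if not (0.0 < target_power < 1.0):
        raise ValueError("target_power must lie in (0, 1)")

    def gap(sd):
        return ewas_power(n_pairs, delta_beta, sd, alpha) - target_power

    return float(optimize.brentq(gap, 1e-6, 10.0))
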