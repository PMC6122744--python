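"""Probe-level QC, beta/M transforms, probe-type normalization and covariate screens.

The filters mirror standard 450K practice: probes failing the detection
p-value, probes on the sex chromosomes, probes with a SNP within two base
pairs of the interrogated CpG, published cross-reactive probes, and probes
with a low bead count in too many samples are removed before analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterThresholds",
    "QCReport",
    "PCAssociation",
    "filter_probes",
    "compute_beta",
    "beta_to_m",
    "m_to_beta",
    "normalize_type_bias",
    "pca_covariate_screen",
    "mds_top_variable",
    "sample_intensity_medians",
]


@dataclass
class FilterThresholds:
    """Probe-filter settings.

    ``detection_rule='any'`` removes a probe if its detection p-value is at
    or above ``detection_p`` in any sample (the strict reading of a
    "failed detection p" filter); ``'fraction'`` requires failure in at least
    ``detection_frac`` of samples.
    """

    detection_p: float = 0.01
    detection_rule: str = "any"  # 'any' or 'fraction'
    detection_frac: float = 0.05
    bead_min: int = 3
    bead_frac: float = 0.05
    drop_sex_chromosomes: bool = True
    drop_snp_probes: bool = True
    drop_cross_reactive: bool = True


@dataclass
class QCReport:
    """Per-reason removal counts from probe filtering.

    ``removed_counts`` itemizes each filter independently; a probe failing
    several filters appears in several counts, so the counts sum to at least
    ``n_initial - n_retained``.
    """

    n_initial: int
    n_retained: int
    removed_counts: Dict[str, int]
    removed_probes: List[str]
    sample_medians: Optional[pd.DataFrame] = None

    def to_json(self) -> str:
        payload = {
            "n_initial": self.n_initial,
            "n_retained": self.n_retained,
            "removed_counts": self.removed_counts,
            "n_removed": len(self.removed_probes),
        }
        if self.sample_medians is not None:
            payload["sample_medians"] = self.sample_medians.round(4).to_dict()
        return json.dumps(payload, indent=2, sort_keys=True)


def sample_intensity_medians(meth: pd.DataFrame, unmeth: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median log2 intensity in both channels (sample-QC view)."""
    return pd.DataFrame(
        {
            "median_log2_meth": np.log2(meth.clip(lower=1.0)).median(axis=0),
            "median_log2_unmeth": np.log2(unmeth.clip(lower=1.0)).median(axis=0),
        }
    )


def _check_aligned(beta: pd.DataFrame, other: Optional[pd.DataFrame], name: str) -> None:
    if other is None:
        return
    if other.shape != beta.shape or not other.index.equals(beta.index) or not (
        other.columns.equals(beta.columns)
    ):
        raise ValueError(f"{name} is not aligned with the beta matrix")


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: Optional[pd.DataFrame] = None,
    bead_count: Optional[pd.DataFrame] = None,
    thresholds: Optional[FilterThresholds] = None,
    cross_reactive_ids: Optional[Iterable[str]] = None,
    intensities=None,
) -> Tuple[pd.DataFrame, QCReport]:
    """Apply the probe QC filters and report per-reason removal counts.

    ``cross_reactive_ids`` supplies a published cross-reactive probe list;
    when absent, the annotation's ``Cross_reactive`` flag column is used.
    """
    thresholds = thresholds or FilterThresholds()
    if not beta.index.isin(annotation.index).all():
        raise ValueError("beta matrix contains probes missing from the annotation")
    ann = annotation.loc[beta.index]
    if intensities is not None:
        detection_p = detection_p if detection_p is not None else intensities.detection_p
        bead_count = bead_count if bead_count is not None else intensities.bead_count
    _check_aligned(beta, detection_p, "detection_p")
    _check_aligned(beta, bead_count, "bead_count")

    n = len(beta)
    reasons: Dict[str, np.ndarray] = {}

    if detection_p is not None:
        failed = detection_p.values >= thresholds.detection_p
        if thresholds.detection_rule == "any":
            reasons["detection_p"] = failed.any(axis=1)
        elif thresholds.detection_rule == "fraction":
            reasons["detection_p"] = (
                failed.mean(axis=1) >= thresholds.detection_frac
            )
        else:
            raise ValueError("detection_rule must be 'any' or 'fraction'")
    else:
        reasons["detection_p"] = np.zeros(n, dtype=bool)

    if thresholds.drop_sex_chromosomes and "CHR" in ann:
        reasons["sex_chromosome"] = ann["CHR"].astype(str).isin(["X", "Y"]).values
    else:
        reasons["sex_chromosome"] = np.zeros(n, dtype=bool)

    if thresholds.drop_snp_probes and "SNP_within_2bp" in ann:
        reasons["snp_within_2bp"] = ann["SNP_within_2bp"].astype(bool).values
    else:
        reasons["snp_within_2bp"] = np.zeros(n, dtype=bool)

    if thresholds.drop_cross_reactive:
        if cross_reactive_ids is not None:
            reasons["cross_reactive"] = beta.index.isin(set(cross_reactive_ids))
        elif "Cross_reactive" in ann:
            reasons["cross_reactive"] = ann["Cross_reactive"].astype(bool).values
        else:
            reasons["cross_reactive"] = np.zeros(n, dtype=bool)
    else:
        reasons["cross_reactive"] = np.zeros(n, dtype=bool)

    if bead_count is not None:
        low = bead_count.values < thresholds.bead_min
        reasons["low_bead_count"] = low.mean(axis=1) >= thresholds.bead_frac
    else:
        reasons["low_bead_count"] = np.zeros(n, dtype=bool)

    drop = np.zeros(n, dtype=bool)
    for mask in reasons.values():
        drop |= mask
    retained = beta.loc[~drop]
    report = QCReport(
        n_initial=n,
        n_retained=len(retained),
        removed_counts={k: int(v.sum()) for k, v in reasons.items()},
        removed_probes=list(beta.index[drop]),
    )
    return retained, report


def compute_beta(meth, unmeth, offset: float = 100.0):
    """beta = meth / (meth + unmeth + offset); platform convention offset 100."""
    m = np.asarray(meth, dtype=float)
    u = np.asarray(unmeth, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be nonnegative")
    beta = m / (m + u + offset)
    if isinstance(meth, pd.DataFrame):
        return pd.DataFrame(beta, index=meth.index, columns=meth.columns)
    return beta


def beta_to_m(beta, epsilon: float = 1e-6):
    """M = log2(beta / (1 - beta)) after clipping beta to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse logit2 transform."""
    b = 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    return b


def normalize_type_bias(
    beta: pd.DataFrame, annotation: pd.DataFrame, min_probes: int = 10
) -> pd.DataFrame:
    """Quantile-average normalization of Infinium type I vs type II probes.

    Per sample, the empirical quantile functions of the two probe types are
    averaged and each type is mapped onto the average; within-type rank order
    is preserved.  A lightweight surrogate for subset-quantile within-array
    normalization that removes the type-II compression of the beta scale.
    """
    types = annotation.loc[beta.index, "Infinium_Design_Type"].astype(str)
    idx1 = np.flatnonzero((types == "I").values)
    idx2 = np.flatnonzero((types == "II").values)
    if len(idx1) < min_probes or len(idx2) < min_probes:
        warnings.warn(
            "fewer than %d probes in one Infinium type; normalization skipped"
            % min_probes
        )
        return beta.copy()

    out = beta.values.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        v1, v2 = np.sort(col[idx1]), np.sort(col[idx2])
        g1 = np.linspace(0.0, 1.0, len(v1))
        g2 = np.linspace(0.0, 1.0, len(v2))

        def qbar(p):
            return 0.5 * (np.interp(p, g1, v1) + np.interp(p, g2, v2))

        r1 = (stats.rankdata(col[idx1], method="average") - 1.0) / (len(idx1) - 1.0)
        r2 = (stats.rankdata(col[idx2], method="average") - 1.0) / (len(idx2) - 1.0)
        col[idx1] = qbar(r1)
        col[idx2] = qbar(r2)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


@dataclass
class PCAssociation:
    """Principal-component covariate screen result."""

    variance_explained: np.ndarray
    pvalues: pd.DataFrame  # PCs x factors
    selected: List[str]
    notes: List[str] = field(default_factory=list)
    scores: Optional[pd.DataFrame] = None


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == bool
    )


def pca_covariate_screen(
    m_values: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    n_pcs: int = 20,
    factors: Optional[Sequence[str]] = None,
    n_select_pcs: int = 4,
    alpha: float = 0.05,
) -> PCAssociation:
    """Sample-space PCA on centered M values with per-factor association tests.

    Categorical factors are tested against each PC with one-way ANOVA,
    continuous ones with a Pearson correlation test.  A factor is selected as
    a model covariate when it associates (p < alpha, unadjusted) with any of
    the first ``n_select_pcs`` components.
    """
    if m_values.shape[1] < 3:
        raise ValueError("need at least 3 samples for a PCA screen")
    factors = list(factors) if factors is not None else list(sample_sheet.columns)
    sheet = sample_sheet.loc[m_values.columns]

    x = m_values.values
    xc = x - x.mean(axis=1, keepdims=True)
    # samples x samples Gram matrix keeps the decomposition cheap at array scale
    gram = xc.T @ xc
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    n_pcs = min(n_pcs, m_values.shape[1] - 1)
    scores = eigvec[:, :n_pcs] * np.sqrt(eigval[:n_pcs])
    var_explained = eigval[:n_pcs] / eigval.sum()

    pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
    pvals = pd.DataFrame(np.nan, index=pc_names, columns=factors)
    notes: List[str] = []
    for factor in factors:
        series = sheet[factor]
        if series.nunique(dropna=True) < 2:
            notes.append(f"factor '{factor}' is constant; association skipped")
            continue
        for i, pc in enumerate(pc_names):
            y = scores[:, i]
            if _is_categorical(series):
                groups = [y[(series == lev).values] for lev in series.unique()]
                groups = [g for g in groups if len(g) > 0]
                try:
                    pvals.loc[pc, factor] = stats.f_oneway(*groups).pvalue
                except ValueError:  # degenerate grouping
                    pvals.loc[pc, factor] = np.nan
            else:
                vals = series.astype(float).values
                if np.std(vals) == 0:
                    continue
                pvals.loc[pc, factor] = stats.pearsonr(vals, y).pvalue

    head = pvals.iloc[: min(n_select_pcs, n_pcs)]
    selected = [f for f in factors if (head[f].dropna() < alpha).any()]
    return PCAssociation(
        variance_explained=var_explained,
        pvalues=pvals,
        selected=selected,
        notes=notes,
        scores=pd.DataFrame(scores, index=m_values.columns, columns=pc_names),
    )


def mds_top_variable(
    beta: pd.DataFrame,
    k: int = 1000,
    group_labels: Optional[Sequence] = None,
) -> Tuple[pd.DataFrame, float]:
    """Classical MDS of samples on the k most variable probes.

    Classical (Torgerson) MDS on Euclidean distances coincides with PCA
    scores of the centered data, which is how it is computed here.  Returns
    2-D coordinates and, when labels are given, a silhouette separation
    score (near zero for unstructured labels).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(beta):
        raise ValueError("k exceeds the number of probes")
    variances = beta.var(axis=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:k]
    x = beta.loc[top].values.T  # samples x probes
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    coords = pd.DataFrame(
        u[:, :2] * s[:2], index=beta.columns, columns=["MDS1", "MDS2"]
    )
    score = float("nan")
    if group_labels is not None:
        labels = np.asarray(group_labels)
        values, counts = np.unique(labels, return_counts=True)
        if len(values) >= 2 and (counts >= 2).all():
            from sklearn.metrics import silhouette_score

            score = float(silhouette_score(coords.values, labels))
    return coords, score
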