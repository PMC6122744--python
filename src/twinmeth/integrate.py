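"""Overlap testing against external signatures and independent-cohort assessment.

Gene-level overlaps use the exact hypergeometric tail on a stated universe;
probe-level overlaps use permutation testing that redraws the target set
uniformly from the analysis background while conditioning on the published
external list.  The signature-assessment routine recomputes per-probe
variance and range of a DVP signature in case twins, control twins and an
independent cohort, stratified by the direction of hypervariability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "SignatureSummary",
    "gene_overlap_test",
    "probe_overlap_permutation",
    "annotate_known_loci",
    "variability_signature_assessment",
]


@dataclass
class OverlapResult:
    """Outcome of a set-overlap test."""

    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float
    method: str
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def to_dict(self) -> Dict:
        return {
            "overlap": self.overlap,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "universe": self.universe,
            "p_value": self.p_value,
            "method": self.method,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def gene_overlap_test(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> OverlapResult:
    """Upper-tail hypergeometric p for the overlap of two gene sets."""
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return OverlapResult(
        overlap=k,
        size_a=len(a),
        size_b=len(b),
        universe=len(universe),
        p_value=min(p, 1.0),
        method="hypergeometric",
    )


def probe_overlap_permutation(
    target_probes: Iterable,
    external_probes: Iterable,
    background: Sequence,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> OverlapResult:
    """Permutation p-value for a probe-set overlap.

    The target set is redrawn uniformly without replacement from the
    background ``n_perm`` times with the external set held fixed;
    ``p = (1 + #{perm overlap >= observed}) / (n_perm + 1)``.
    """
    background = pd.Index(background)
    target = set(target_probes)
    external = set(external_probes)
    if not target <= set(background) or not external <= set(background):
        raise ValueError("both probe sets must be subsets of the background")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value")
    rng = np.random.default_rng(seed)

    observed = len(target & external)
    is_external = np.asarray(background.isin(external))
    m = len(target)
    n_bg = len(background)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(n_bg, size=m, replace=False)
        if int(is_external[draw].sum()) >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return OverlapResult(
        overlap=observed,
        size_a=m,
        size_b=len(external),
        universe=n_bg,
        p_value=p,
        method="permutation",
        n_perm=n_perm,
        seed=seed,
    )


def annotate_known_loci(
    dvp_table: pd.DataFrame,
    annotation: pd.DataFrame,
    known_genes: Iterable[str],
) -> pd.DataFrame:
    """Known susceptibility genes containing at least one DVP, with counts."""
    known = list(dict.fromkeys(known_genes))
    if len(known) == 0:
        raise ValueError("known gene list must be nonempty")
    counts: Dict[str, int] = {}
    if len(dvp_table) > 0:
        entries = annotation.loc[dvp_table.index, "UCSC_RefGene_Name"]
        for entry in entries:
            for gene in set(g.strip() for g in str(entry).split(";") if g.strip()):
                counts[gene] = counts.get(gene, 0) + 1
    rows = [
        {"gene": g, "n_dvps": counts[g]} for g in known if counts.get(g, 0) > 0
    ]
    return pd.DataFrame(rows, columns=["gene", "n_dvps"]).sort_values(
        ["n_dvps", "gene"], ascending=[False, True], ignore_index=True
    )


@dataclass
class SignatureSummary:
    """Variance/range profile of a DVP signature across comparison groups.

    ``per_probe`` holds one row per DVP with variance and range (max - min of
    beta) in each group plus the hypervariability stratum; ``aggregate``
    holds quartiles per group x stratum x metric.
    """

    per_probe: pd.DataFrame
    aggregate: pd.DataFrame
    excluded_probes: list = field(default_factory=list)


def variability_signature_assessment(
    dvp_table: pd.DataFrame,
    beta_case: pd.DataFrame,
    beta_control: pd.DataFrame,
    beta_independent: pd.DataFrame,
) -> SignatureSummary:
    """Per-probe variance and range of the DVP signature in three groups."""
    probes = dvp_table.index
    present = probes[
        probes.isin(beta_case.index)
        & probes.isin(beta_control.index)
        & probes.isin(beta_independent.index)
    ]
    excluded = list(probes.difference(present))
    if excluded:
        warnings.warn(f"{len(excluded)} DVP probes missing from a matrix; excluded")

    frames = {}
    for name, mat in (
        ("case", beta_case),
        ("control", beta_control),
        ("independent", beta_independent),
    ):
        sub = mat.loc[present]
        frames[f"var_{name}"] = sub.var(axis=1, ddof=1)
        frames[f"range_{name}"] = sub.max(axis=1) - sub.min(axis=1)
    per_probe = pd.DataFrame(frames)
    per_probe.insert(
        0, "stratum", dvp_table.loc[present, "hypervariable_group"].values
    )

    rows = []
    for stratum, grp in per_probe.groupby("stratum", sort=True):
        for metric in ("var", "range"):
            for group in ("case", "control", "independent"):
                col = grp[f"{metric}_{group}"]
                rows.append(
                    {
                        "stratum": stratum,
                        "metric": metric,
                        "group": group,
                        "q25": col.quantile(0.25),
                        "median": col.median(),
                        "q75": col.quantile(0.75),
                    }
                )
    aggregate = pd.DataFrame(
        rows, columns=["stratum", "metric", "group", "q25", "median", "q75"]
    )
    return SignatureSummary(
        per_probe=per_probe, aggregate=aggregate, excluded_probes=excluded
    )
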