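"""Feature enrichment and probe-number-bias-corrected gene-set testing.

Array platforms distribute probes very unevenly over genes (1 to 1299 per
gene on the 450K manifest), so a gene covered by many probes is far more
likely to be hit by any probe-level selection.  The gene-set test here
corrects for that bias in the style of the gometh procedure: a monotone
(isotonic) estimate of the per-gene selection probability as a function of
probe count supplies weights for a Wallenius noncentral hypergeometric
over-representation test.  No multiplicity correction is applied across
gene sets, as sets overlap and the tests are not independent.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "feature_enrichment",
    "map_probes_to_genes",
    "gene_probe_counts",
    "probe_bias_gene_test",
]

DEFAULT_FEATURE_COLUMNS = ("Relation_to_UCSC_CpG_Island", "UCSC_RefGene_Group")


def _category_codes(annotation: pd.DataFrame, column: str) -> Tuple[np.ndarray, List[str]]:
    labels = annotation[column].astype(str).replace("", "intergenic")
    codes, cats = pd.factorize(labels, sort=True)
    return codes, list(cats)


def feature_enrichment(
    target_probes: Iterable[str],
    background_annotation: pd.DataFrame,
    columns: Sequence[str] = DEFAULT_FEATURE_COLUMNS,
    n_draws: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Empirical category enrichment by repeated random sampling.

    Draws ``n_draws`` probe sets of the target's size uniformly without
    replacement from the background and compares per-category counts.  The
    one-sided empirical p-values use the add-one estimator
    ``(1 + #{draws at least as extreme}) / (n_draws + 1)``.
    """
    target = pd.Index(pd.unique(pd.Series(list(target_probes))))
    if not target.isin(background_annotation.index).all():
        raise ValueError("target probes must be a subset of the background")
    m = len(target)
    n_bg = len(background_annotation)
    if m > n_bg:
        raise ValueError("target larger than background")
    rng = np.random.default_rng(seed)
    target_pos = background_annotation.index.get_indexer(target)

    tables = []
    for column in columns:
        codes, cats = _category_codes(background_annotation, column)
        n_cat = len(cats)
        observed = np.bincount(codes[target_pos], minlength=n_cat)
        counts = np.empty((n_draws, n_cat), dtype=np.int64)
        for d in range(n_draws):
            draw = rng.choice(n_bg, size=m, replace=False)
            counts[d] = np.bincount(codes[draw], minlength=n_cat)
        expected = counts.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(expected > 0, observed / expected, np.nan)
        p_enr = (1 + (counts >= observed).sum(axis=0)) / (n_draws + 1)
        p_dep = (1 + (counts <= observed).sum(axis=0)) / (n_draws + 1)
        tables.append(
            pd.DataFrame(
                {
                    "feature_type": column,
                    "category": cats,
                    "observed": observed,
                    "expected": expected,
                    "fold": fold,
                    "p_enriched": p_enr,
                    "p_depleted": p_dep,
                    "direction": np.where(fold >= 1.0, "enriched", "depleted"),
                }
            )
        )
    return pd.concat(tables, ignore_index=True)


def map_probes_to_genes(
    probes: Iterable[str], annotation: pd.DataFrame
) -> Set[str]:
    """Union of gene symbols annotated to the probes.

    Multi-gene annotations are semicolon-delimited; intergenic probes (empty
    annotation) contribute nothing.
    """
    probes = list(probes)
    missing = [p for p in probes if p not in annotation.index]
    if missing:
        raise ValueError(f"{len(missing)} probes missing from the annotation")
    genes: Set[str] = set()
    for entry in annotation.loc[probes, "UCSC_RefGene_Name"]:
        for gene in str(entry).split(";"):
            gene = gene.strip()
            if gene:
                genes.add(gene)
    return genes


def gene_probe_counts(annotation: pd.DataFrame) -> pd.Series:
    """Number of array probes annotated to each gene."""
    counts: Dict[str, int] = {}
    for entry in annotation["UCSC_RefGene_Name"]:
        for gene in set(g.strip() for g in str(entry).split(";") if g.strip()):
            counts[gene] = counts.get(gene, 0) + 1
    return pd.Series(counts, name="n_probes").sort_index()


def probe_bias_gene_test(
    selected_probes: Iterable[str],
    annotation: pd.DataFrame,
    gene_sets: Dict[str, Iterable[str]],
    weight_floor: float = 1e-6,
) -> pd.DataFrame:
    """Gene-set over-representation corrected for probe-number bias.

    The per-gene selection probability is estimated by isotonic regression
    of the selection indicator on the gene's probe count; each set's odds
    parameter is the mean weight inside the set over the mean weight
    outside, and the over-representation p comes from the Wallenius
    noncentral hypergeometric tail.  When the weight function is constant
    the test reduces exactly to the central hypergeometric.  Results are
    ranked by p with no FDR correction (gene sets are not independent).
    """
    counts = gene_probe_counts(annotation)
    universe = counts.index
    selected_genes = map_probes_to_genes(selected_probes, annotation)
    n_universe = len(universe)
    n_selected = len(selected_genes)
    indicator = universe.isin(selected_genes).astype(float)

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    weights = iso.fit_transform(counts.values.astype(float), indicator)
    weights = np.clip(weights, weight_floor, None)
    weight_by_gene = pd.Series(weights, index=universe)

    rows = []
    for name, genes in gene_sets.items():
        in_set = universe.intersection(pd.Index(list(genes)))
        if len(in_set) == 0:
            logger.info("gene set '%s' has no genes in the universe; skipped", name)
            continue
        k = len(set(in_set) & selected_genes)
        n_in = len(in_set)
        w_in = weight_by_gene.loc[in_set].mean()
        out_mask = ~universe.isin(in_set)
        w_out = weight_by_gene.loc[universe[out_mask]].mean() if out_mask.any() else w_in
        odds = float(w_in / w_out) if w_out > 0 else 1.0
        if abs(odds - 1.0) < 1e-9:
            p = float(stats.hypergeom.sf(k - 1, n_universe, n_in, n_selected))
        else:
            p = float(
                stats.nchypergeom_wallenius.sf(
                    k - 1, n_universe, n_in, n_selected, odds
                )
            )
        rows.append(
            {
                "set_name": name,
                "n_set_genes": n_in,
                "n_selected_in_set": k,
                "odds": odds,
                "p_value": min(max(p, 0.0), 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["set_name", "n_set_genes", "n_selected_in_set", "odds", "p_value"]
    )
    return result.sort_values(
        ["p_value", "set_name"], kind="mergesort", ignore_index=True
    )
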