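"""End-to-end pipeline orchestration on synthetic or file-based inputs.

Stages run in study order: simulate -> QC -> cell composition -> covariate
screen -> DMP -> DVP -> enrichment -> overlap/assessment -> report.  A
single global seed is fanned out to per-stage generators through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))`` so each stage is
individually reproducible; rerunning a config writes byte-identical output
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .cells import compare_composition, estimate_cell_fractions, select_discriminating_probes
from .dmp import fit_dmp_model
from .dvp import ievora, summarize_dvp_directionality
from .enrich import feature_enrichment, map_probes_to_genes, probe_bias_gene_test
from .integrate import (
    gene_overlap_test,
    probe_overlap_permutation,
    variability_signature_assessment,
    annotate_known_loci,
)
from .preprocess import (
    FilterThresholds,
    beta_to_m,
    filter_probes,
    normalize_type_bias,
    pca_covariate_screen,
    sample_intensity_medians,
)
from .report import cohort_summary
from .synthetic import (
    SyntheticConfig,
    generate_cell_reference,
    generate_independent_cohort,
    generate_probe_annotation,
    generate_twin_cohort,
    _stage_int,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "synthetic_gene_sets"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    normalize: bool = True
    dvp_q_thresh: float = 1e-3
    dvp_p_thresh: float = 0.05
    fdr_threshold: float = 0.05
    enrich_n_draws: int = 1000
    n_gene_sets: int = 20
    gene_set_size: int = 50
    overlap_n_perm: int = 2000
    n_independent: int = 156
    n_known_genes: int = 98
    outdir: str = "twinmeth_results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        syn_raw = raw.pop("synthetic", {})
        for key in ("smoking_probs",):
            if key in syn_raw and isinstance(syn_raw[key], list):
                syn_raw[key] = tuple(syn_raw[key])
        syn = SyntheticConfig(**syn_raw)
        known = {f.name for f in dataclasses.fields(cls)} - {"synthetic"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=syn, **raw)

    def to_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        return yaml.safe_dump(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All artifacts of one pipeline run, plus run metadata."""

    qc_report: object
    beta_filtered: pd.DataFrame
    composition: pd.DataFrame
    composition_comparison: pd.DataFrame
    pc_association: object
    dmp_table: pd.DataFrame
    dvp_table: pd.DataFrame
    dvp_directionality: Dict[str, int]
    enrichment: pd.DataFrame
    gene_set_results: pd.DataFrame
    overlap_probe: object
    overlap_gene: object
    known_loci: pd.DataFrame
    signature: object
    summary: Dict
    truth_recovery: Dict
    metadata: Dict


def synthetic_gene_sets(
    annotation: pd.DataFrame,
    n_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
    enriched_genes: Optional[List[str]] = None,
) -> Dict[str, set]:
    """Random gene sets over the annotation's gene universe.

    When ``enriched_genes`` is given, one extra set is seeded with those
    genes (topped up randomly) so over-representation has a positive control.
    """
    from .enrich import gene_probe_counts

    rng = np.random.default_rng(seed)
    universe = list(gene_probe_counts(annotation).index)
    sets: Dict[str, set] = {}
    for i in range(n_sets):
        size = min(set_size, len(universe))
        sets[f"SET{i + 1:03d}"] = set(rng.choice(universe, size=size, replace=False))
    if enriched_genes:
        base = [g for g in enriched_genes if g in set(universe)][:set_size]
        fill = set_size - len(base)
        if fill > 0:
            base = base + list(rng.choice(universe, size=fill, replace=False))
        sets["SET_SEEDED"] = set(base)
    return sets


def _truth_recovery(dvp_table: pd.DataFrame, truth: pd.DataFrame) -> Dict:
    true_dvps = set(truth.index[truth["is_dvp"]])
    called = set(dvp_table.index)
    tp = len(called & true_dvps)
    sensitivity = tp / len(true_dvps) if true_dvps else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return {
        "n_true_dvps": len(true_dvps),
        "n_called": len(called),
        "n_true_positive": tp,
        "sensitivity": sensitivity,
        "empirical_fdr": fdr,
    }


def run_pipeline(config, outdir: Optional[str] = None) -> ResultBundle:
    """Run the full pipeline for a config (path to YAML or PipelineConfig).

    Writes all tables, reports and signatures into ``outdir`` and returns the
    in-memory bundle.  Fully deterministic given the config.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.synthetic.seed
    timings: Dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s finished in %.2fs", name, timings[name])

    # --- simulate -------------------------------------------------------
    stage("simulate")
    syn = config.synthetic
    annotation = generate_probe_annotation(syn.n_probes, seed=_stage_int(seed, 10))
    intensities, beta, sheet, truth = generate_twin_cohort(syn, annotation)
    reference = generate_cell_reference(
        annotation, syn.n_celltypes, seed=_stage_int(seed, 1),
        frac_informative=syn.frac_cell_informative,
    )
    beta_independent = generate_independent_cohort(
        syn, annotation, n_samples=config.n_independent, seed=_stage_int(seed, 11)
    )
    done("simulate")

    # --- QC -------------------------------------------------------------
    stage("qc")
    beta_f, qc = filter_probes(
        beta,
        annotation,
        detection_p=intensities.detection_p,
        bead_count=intensities.bead_count,
    )
    qc.sample_medians = sample_intensity_medians(intensities.meth, intensities.unmeth)
    for reason, count in qc.removed_counts.items():
        logger.info("filter %-16s removed %d probes", reason, count)
    if config.normalize:
        beta_f = normalize_type_bias(beta_f, annotation)
    m_f = beta_to_m(beta_f)
    done("qc")

    # --- cell composition ----------------------------------------------
    stage("cells")
    probes_cells = select_discriminating_probes(reference.loc[beta_f.index], n_per_type=50)
    composition = estimate_cell_fractions(beta_f, reference, probes_cells)
    comp_compare = compare_composition(composition, sheet)
    done("cells")

    # --- covariate screen ------------------------------------------------
    stage("pca_screen")
    factors = sheet.drop(columns=["status", "pair_id"]).join(composition)
    screen = pca_covariate_screen(m_f, factors, n_pcs=min(20, len(sheet) - 1))
    done("pca_screen")

    # --- DMP -------------------------------------------------------------
    stage("dmp")
    covariates = [c for c in screen.selected if c in sheet.columns]
    dmp_table = fit_dmp_model(
        beta_f, sheet, covariates=covariates, annotation=annotation
    )
    n_dmp_sig = int((dmp_table["q_value"] < config.fdr_threshold).sum())
    logger.info("DMPs at q<%.2g: %d", config.fdr_threshold, n_dmp_sig)
    done("dmp")

    # --- DVP -------------------------------------------------------------
    stage("dvp")
    dvp_table = ievora(
        beta_f,
        sheet,
        q_thresh=config.dvp_q_thresh,
        p_thresh=config.dvp_p_thresh,
        annotation=annotation,
    )
    directionality = summarize_dvp_directionality(dvp_table)
    recovery = _truth_recovery(dvp_table, truth)
    done("dvp")

    # --- enrichment ------------------------------------------------------
    stage("enrich")
    ann_f = annotation.loc[beta_f.index]
    if len(dvp_table) > 0:
        enrichment = feature_enrichment(
            dvp_table.index,
            ann_f,
            n_draws=config.enrich_n_draws,
            seed=_stage_int(seed, 12),
        )
    else:
        enrichment = pd.DataFrame()
    dvp_genes = sorted(map_probes_to_genes(dvp_table.index, annotation))
    gene_sets = synthetic_gene_sets(
        ann_f,
        n_sets=config.n_gene_sets,
        set_size=config.gene_set_size,
        seed=_stage_int(seed, 13),
        enriched_genes=dvp_genes,
    )
    gene_set_results = probe_bias_gene_test(dvp_table.index, ann_f, gene_sets)
    done("enrich")

    # --- overlap & signature assessment ---------------------------------
    stage("integrate")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(14,)))
    background = beta_f.index
    # synthetic external signature: half drawn from the true DVPs, half random,
    # standing in for a published disease signature
    true_dvps = [p for p in truth.index[truth["is_dvp"]] if p in set(background)]
    n_half = max(1, len(true_dvps) // 2)
    external = set(rng.choice(true_dvps, size=n_half, replace=False)) if true_dvps else set()
    external |= set(rng.choice(background, size=4 * n_half, replace=False))
    overlap_probe = probe_overlap_permutation(
        [p for p in dvp_table.index],
        external,
        background,
        n_perm=config.overlap_n_perm,
        seed=_stage_int(seed, 15),
    )
    gene_universe = map_probes_to_genes(background, annotation)
    external_genes = map_probes_to_genes(external, annotation)
    overlap_gene = gene_overlap_test(set(dvp_genes) & gene_universe,
                                     external_genes, gene_universe)
    known = sorted(
        set(rng.choice(sorted(gene_universe), size=min(config.n_known_genes,
                                                       len(gene_universe)),
                       replace=False))
        | set(dvp_genes[: min(5, len(dvp_genes))])
    )
    known_loci = annotate_known_loci(dvp_table, annotation, known)
    case_cols = sheet.index[(sheet["status"] == "case").values]
    control_cols = sheet.index[(sheet["status"] == "control").values]
    signature = variability_signature_assessment(
        dvp_table, beta_f[case_cols], beta_f[control_cols],
        beta_independent.loc[beta_f.index],
    )
    done("integrate")

    # --- report ----------------------------------------------------------
    stage("report")
    summary = cohort_summary(sheet, composition)
    metadata = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "package_version": __import__("twinmeth").__version__,
        "n_probes_initial": qc.n_initial,
        "n_probes_retained": qc.n_retained,
        "n_dmp_significant": n_dmp_sig,
        "n_dvps": len(dvp_table),
        "timings_s": {k: round(v, 3) for k, v in timings.items() if v < 1e6},
    }

    tio.write_matrix_tsv(beta_f, out / "beta_filtered.tsv")
    tio.write_sample_sheet(sheet, out / "sample_sheet.csv")
    tio.write_annotation(annotation, out / "annotation.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    (out / "qc_report.json").write_text(qc.to_json() + "\n")
    tio.write_table(composition, out / "cell_composition.tsv")
    tio.write_table(comp_compare, out / "cell_comparison.tsv")
    tio.write_table(screen.pvalues, out / "pc_associations.tsv")
    tio.write_table(dmp_table, out / "dmp_table.tsv")
    tio.write_table(dvp_table, out / "dvp_table.tsv")
    tio.write_table(enrichment, out / "feature_enrichment.tsv")
    tio.write_table(gene_set_results, out / "gene_set_results.tsv")
    tio.write_table(signature.aggregate, out / "signature_aggregate.tsv")
    known_loci.to_csv(out / "known_loci.tsv", sep="\t", index=False)
    tio.write_json(
        {
            "dvp_directionality": directionality,
            "truth_recovery": recovery,
            "overlap_probe": overlap_probe.to_dict(),
            "overlap_gene": overlap_gene.to_dict(),
            "cohort_summary": summary,
            "metadata": metadata,
        },
        out / "summary.json",
    )
    done("report")
    metadata["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    return ResultBundle(
        qc_report=qc,
        beta_filtered=beta_f,
        composition=composition,
        composition_comparison=comp_compare,
        pc_association=screen,
        dmp_table=dmp_table,
        dvp_table=dvp_table,
        dvp_directionality=directionality,
        enrichment=enrichment,
        gene_set_results=gene_set_results,
        overlap_probe=overlap_probe,
        overlap_gene=overlap_gene,
        known_loci=known_loci,
        signature=signature,
        summary=summary,
        truth_recovery=recovery,
        metadata=metadata,
    )
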