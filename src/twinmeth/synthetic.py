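"""Synthetic twin-cohort methylation data with known injected effects.

The generator emulates a 450K-style array experiment on monozygotic twin
pairs discordant for disease: per-probe beta baselines drawn from the
characteristic bimodal-plus-intermediate mixture, a shared pair effect on the
M (logit) scale producing a chosen intra-pair correlation, cell-type mixing
through per-sample Dirichlet weights over a purified-cell reference, chip
batch offsets, and injected mean-shift (DMP) and hypervariability (DVP)
effects recorded in a truth table.  Methylated/unmethylated intensities,
detection p-values and bead counts are emitted so that probe-level QC can be
exercised end to end.

Hypervariability is injected as an outlier subpopulation: a fraction of the
samples in the hypervariable group is shifted to one side (usually towards
hypomethylation), calibrated so that the group's marginal beta variance is
inflated by the configured factor.  This is the signature that
variance-plus-mean gating procedures are designed to detect; a symmetric,
mean-preserving variance inflation would be indistinguishable from noise for
the t-test gate and does not occur in array data, where excess variance is
carried by subgroups of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "BLOOD_FRACTIONS",
    "SyntheticConfig",
    "IntensityData",
    "generate_probe_annotation",
    "generate_cell_reference",
    "generate_twin_cohort",
    "generate_independent_cohort",
    "logit2",
    "expit2",
]

#: Leukocyte subtypes of a whole-blood reference panel.
CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

#: Typical whole-blood proportions used as the Dirichlet mean.
BLOOD_FRACTIONS = {
    "CD8T": 0.05,
    "CD4T": 0.21,
    "NK": 0.06,
    "Bcell": 0.06,
    "Mono": 0.08,
    "Gran": 0.54,
}

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
ISLAND_PROBS = (0.31, 0.13, 0.11, 0.05, 0.05, 0.35)

GENE_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
FEATURE_PROBS = (0.14, 0.10, 0.12, 0.07, 0.49, 0.08)


def logit2(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """M value: log2(beta / (1 - beta)) with clipping to (eps, 1 - eps)."""
    b = np.clip(beta, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def expit2(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`logit2`: beta = 2**M / (1 + 2**M)."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic twin cohort.

    Defaults mirror the discordant-twin design the package targets: 79
    monozygotic pairs on a 450K-style array (down-scaled to 20,000 probes),
    86% female, two recruitment cohorts, an intra-pair M-value correlation of
    0.8, no true mean-methylation effects (``frac_dmp = 0``) and a small set
    of hypervariable positions with a four-fold variance inflation.
    """

    n_pairs: int = 79
    n_probes: int = 20_000
    frac_dmp: float = 0.0
    frac_dvp: float = 0.005
    delta_beta: float = 0.05
    var_inflation: float = 4.0
    rho: float = 0.8
    n_celltypes: int = 6
    dirichlet_alpha: float = 5.0
    n_chips: int = 14
    seed: int = 0

    # cohort composition (Table-1-style descriptives)
    female_frac: float = 0.86
    cohort_frac: float = 62 / 79  # fraction of pairs from the larger cohort
    mean_age: float = 54.2
    sd_age: float = 12.2
    smoking_probs: tuple = (0.18, 0.31, 0.51)  # current, past, never

    # probe model
    frac_cell_informative: float = 0.02
    batch_sd: float = 0.05
    sigma_m_log_mean: float = float(np.log(0.25))
    sigma_m_log_sd: float = 0.4

    # hypervariability injection
    outlier_fraction: float = 0.2
    hyper_case_prob: float = 0.65
    hypo_trend_prob_case: float = 0.74
    hypo_trend_prob_control: float = 0.98

    # QC layers
    frac_fail_detection: float = 0.003
    frac_low_bead: float = 0.003

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.n_probes < 10:
            raise ValueError("n_probes must be >= 10")
        if not (0.0 <= self.frac_dmp and 0.0 <= self.frac_dvp):
            raise ValueError("effect fractions must be nonnegative")
        if self.frac_dmp + self.frac_dvp > 1.0:
            raise ValueError("frac_dmp + frac_dvp must be <= 1")
        if self.var_inflation <= 0.0:
            raise ValueError("var_inflation must be > 0")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie strictly between 0 and 1")
        if self.n_celltypes < 2:
            raise ValueError("n_celltypes must be >= 2")
        if self.n_chips < 1:
            raise ValueError("n_chips must be >= 1")
        if not (0.0 < self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must lie in (0, 1)")


@dataclass
class IntensityData:
    """Raw-intensity view of an array experiment.

    All four matrices are probes x samples with identical index/columns and
    satisfy ``beta = meth / (meth + unmeth + 100)`` exactly.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        shape = self.meth.shape
        for mat in (self.unmeth, self.detection_p, self.bead_count):
            if mat.shape != shape:
                raise ValueError("intensity matrices must share dimensions")
            if not mat.index.equals(self.meth.index) or not mat.columns.equals(
                self.meth.columns
            ):
                raise ValueError("intensity matrices must share probe/sample order")


def _stage_seed(seed: int, stage: int) -> np.random.Generator:
    """Per-stage generator derived from the global seed.

    Stages spawn from ``SeedSequence(seed, spawn_key=(stage,))`` so that each
    pipeline stage is independently reproducible from one integer.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _stage_int(seed: int, stage: int) -> int:
    return int(
        np.random.SeedSequence(seed, spawn_key=(stage,)).generate_state(1)[0] % (2**31)
    )


def generate_probe_annotation(
    n_probes: int,
    seed: int,
    frac_sex: float = 0.02,
    frac_snp: float = 0.01,
    frac_cross_reactive: float = 0.01,
    frac_intergenic: float = 0.25,
) -> pd.DataFrame:
    """Manifest-style probe annotation table.

    Columns follow 450K manifest naming (``IlmnID`` as index, ``CHR``,
    ``MAPINFO``, ``Infinium_Design_Type``, ``Relation_to_UCSC_CpG_Island``,
    ``UCSC_RefGene_Name``, ``UCSC_RefGene_Group``) plus boolean
    ``SNP_within_2bp`` and ``Cross_reactive`` flags.  Probes-per-gene counts
    are heavy-tailed (Zipf), mimicking the 1-1299 range of the real manifest
    so that gene-set tests can exercise probe-number bias.
    """
    if n_probes < 10:
        raise ValueError("n_probes must be >= 10")
    rng = np.random.default_rng(seed)

    # unique cg identifiers
    ids = np.unique(rng.integers(0, 10**8, size=int(n_probes * 2.5)))
    rng.shuffle(ids)
    ids = np.sort(ids[:n_probes])
    if ids.size < n_probes:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to draw unique probe identifiers")
    probe_ids = [f"cg{i:08d}" for i in ids]

    is_sex = rng.random(n_probes) < frac_sex
    chrom = rng.integers(1, 23, size=n_probes).astype(str)
    chrom[is_sex] = rng.choice(["X", "Y"], size=int(is_sex.sum()), p=[0.85, 0.15])
    position = rng.integers(1, 240_000_000, size=n_probes)
    design = rng.choice(["I", "II"], size=n_probes, p=[0.28, 0.72])
    island = rng.choice(ISLAND_RELATIONS, size=n_probes, p=ISLAND_PROBS)

    # heavy-tailed probes-per-gene: Zipf block sizes capped at the manifest max
    n_genic = n_probes - int(round(frac_intergenic * n_probes))
    sizes = []
    total = 0
    while total < n_genic:
        s = int(min(rng.zipf(2.0), 1299))
        sizes.append(s)
        total += s
    sizes[-1] -= total - n_genic
    if sizes[-1] == 0:
        sizes.pop()
    gene_names = [f"GENE{i:05d}" for i in range(len(sizes))]
    gene_col = np.full(n_probes, "", dtype=object)
    feature_col = np.full(n_probes, "", dtype=object)
    genic_idx = rng.permutation(n_probes)[:n_genic]
    pos = 0
    for gene, size in zip(gene_names, sizes):
        block = genic_idx[pos : pos + size]
        gene_col[block] = gene
        feature_col[block] = rng.choice(GENE_FEATURES, size=size, p=FEATURE_PROBS)
        pos += size
    # a minority of probes annotate to two genes (overlapping transcripts)
    multi = (gene_col != "") & (rng.random(n_probes) < 0.06)
    for i in np.flatnonzero(multi):
        other = gene_names[rng.integers(0, len(gene_names))]
        if other != gene_col[i]:
            gene_col[i] = gene_col[i] + ";" + other

    annotation = pd.DataFrame(
        {
            "CHR": chrom,
            "MAPINFO": position,
            "Infinium_Design_Type": design,
            "Relation_to_UCSC_CpG_Island": island,
            "UCSC_RefGene_Name": gene_col,
            "UCSC_RefGene_Group": feature_col,
            "SNP_within_2bp": rng.random(n_probes) < frac_snp,
            "Cross_reactive": rng.random(n_probes) < frac_cross_reactive,
        },
        index=pd.Index(probe_ids, name="IlmnID"),
    )
    return annotation


def generate_cell_reference(
    annotation: pd.DataFrame,
    n_celltypes: int = 6,
    seed: int = 0,
    frac_informative: float = 0.02,
) -> pd.DataFrame:
    """Purified-cell reference beta matrix (probes x cell types).

    Most probes carry a common baseline beta drawn from the three-component
    (low / intermediate / high methylation) mixture typical of 450K data; a
    designated informative subset discriminates one cell type from the rest
    with a between-type beta gap of at least 0.5.
    """
    if n_celltypes < 2:
        raise ValueError("n_celltypes must be >= 2")
    rng = np.random.default_rng(seed)
    n_probes = len(annotation)
    names = list(CELL_TYPES[:n_celltypes])
    for extra in range(len(names), n_celltypes):
        names.append(f"Cell{extra + 1}")

    component = rng.choice(3, size=n_probes, p=[0.38, 0.17, 0.45])
    baseline = np.empty(n_probes)
    baseline[component == 0] = rng.beta(1.5, 15.0, size=int((component == 0).sum()))
    baseline[component == 1] = rng.beta(6.0, 6.0, size=int((component == 1).sum()))
    baseline[component == 2] = rng.beta(15.0, 1.5, size=int((component == 2).sum()))
    baseline = np.clip(baseline, 0.01, 0.99)

    ref = np.tile(baseline[:, None], (1, n_celltypes))
    n_inf = int(round(frac_informative * n_probes))
    informative = rng.permutation(n_probes)[:n_inf]
    for j, probe in enumerate(informative):
        t = j % n_celltypes
        high = 0.85 + rng.uniform(0.0, 0.1)
        low = 0.10 + rng.uniform(0.0, 0.1)
        ref[probe, :] = low
        ref[probe, t] = high
    return pd.DataFrame(ref, index=annotation.index.copy(), columns=names)


def _probe_model(config: SyntheticConfig, annotation: pd.DataFrame):
    """Deterministic per-probe parameters shared by all cohorts of a config."""
    ref_seed = _stage_int(config.seed, 1)
    reference = generate_cell_reference(
        annotation,
        config.n_celltypes,
        seed=ref_seed,
        frac_informative=config.frac_cell_informative,
    )
    rng = _stage_seed(config.seed, 2)
    sigma_m = np.clip(
        rng.lognormal(config.sigma_m_log_mean, config.sigma_m_log_sd, len(annotation)),
        0.05,
        1.0,
    )
    return reference, sigma_m


def _draw_truth(config: SyntheticConfig, annotation: pd.DataFrame) -> pd.DataFrame:
    rng = _stage_seed(config.seed, 3)
    n = len(annotation)
    n_dmp = int(round(config.frac_dmp * n))
    n_dvp = int(round(config.frac_dvp * n))
    chosen = rng.permutation(n)[: n_dmp + n_dvp]
    dmp_idx, dvp_idx = chosen[:n_dmp], chosen[n_dmp:]

    truth = pd.DataFrame(
        {
            "is_dmp": np.zeros(n, dtype=bool),
            "is_dvp": np.zeros(n, dtype=bool),
            "dvp_hypervariable_group": np.full(n, "", dtype=object),
            "true_delta": np.zeros(n),
            "true_v": np.ones(n),
        },
        index=annotation.index.copy(),
    )
    truth.iloc[dmp_idx, truth.columns.get_loc("is_dmp")] = True
    signs = rng.choice([-1.0, 1.0], size=n_dmp)
    truth.iloc[dmp_idx, truth.columns.get_loc("true_delta")] = signs * config.delta_beta

    truth.iloc[dvp_idx, truth.columns.get_loc("is_dvp")] = True
    groups = np.where(rng.random(n_dvp) < config.hyper_case_prob, "case", "control")
    truth.iloc[dvp_idx, truth.columns.get_loc("dvp_hypervariable_group")] = groups
    truth.iloc[dvp_idx, truth.columns.get_loc("true_v")] = config.var_inflation
    return truth


def _make_sample_sheet(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_pairs = config.n_pairs
    pair_ids = [f"P{i + 1:03d}" for i in range(n_pairs)]
    sample_ids, rows = [], []
    ages = np.clip(rng.normal(config.mean_age, config.sd_age, n_pairs), 18, 90)
    female = rng.random(n_pairs) < config.female_frac
    cohorts = np.where(rng.random(n_pairs) < config.cohort_frac, "Manchester", "TwinsUK")
    pairs_per_chip = int(np.ceil(n_pairs / config.n_chips))
    for i, pair in enumerate(pair_ids):
        chip = f"chip{i // pairs_per_chip + 1:02d}"
        for j, status in enumerate(("case", "control")):
            sample_ids.append(f"{pair}_{status}")
            rows.append(
                {
                    "pair_id": pair,
                    "status": status,
                    "age": float(ages[i]),
                    "sex": "F" if female[i] else "M",
                    "smoking": rng.choice(
                        ["current", "past", "never"], p=config.smoking_probs
                    ),
                    "cohort": cohorts[i],
                    "chip_id": chip,
                    "chip_position": (2 * (i % pairs_per_chip) + j) % 12 + 1,
                }
            )
    sheet = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    return sheet


def _sample_m_matrix(
    config: SyntheticConfig,
    reference: pd.DataFrame,
    sigma_m: np.ndarray,
    sheet: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """M-value matrix before effect injection: mixture + pair + batch + noise."""
    n_probes = len(reference)
    n_samples = len(sheet)
    n_pairs = n_samples // 2

    alpha = np.array(
        [BLOOD_FRACTIONS.get(c, 1.0 / len(reference.columns)) for c in reference.columns]
    )
    alpha = alpha / alpha.sum() * config.dirichlet_alpha * len(reference.columns)
    weights = rng.dirichlet(alpha, size=n_samples)  # samples x celltypes
    beta_mix = reference.values @ weights.T
    m = logit2(beta_mix)

    pair_codes = pd.factorize(sheet["pair_id"])[0]
    pair_eff = rng.normal(0.0, 1.0, size=(n_probes, n_pairs)) * (
        np.sqrt(config.rho) * sigma_m[:, None]
    )
    m += pair_eff[:, pair_codes]
    m += rng.normal(0.0, 1.0, size=(n_probes, n_samples)) * (
        np.sqrt(1.0 - config.rho) * sigma_m[:, None]
    )

    chip_codes, chips = pd.factorize(sheet["chip_id"])
    batch = rng.normal(0.0, config.batch_sd, size=(n_probes, len(chips)))
    m += batch[:, chip_codes]
    return m


def _inject_dvp(
    beta: np.ndarray,
    truth: pd.DataFrame,
    sheet: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    """Outlier-subpopulation hypervariability injection, in place.

    For each DVP probe a fraction ``pi`` of the hypervariable group is
    shifted by ``delta = s * sqrt((v - 1) / (pi (1 - pi)))`` where ``s`` is
    the probe's pre-injection beta SD, so the group's marginal variance is
    inflated by ``v``.  The shift direction encodes the hypo/hyper trend and
    flips when it would run into the [0, 1] boundary.
    """
    case_mask = (sheet["status"] == "case").values
    ctrl_mask = ~case_mask
    pi = config.outlier_fraction
    v = config.var_inflation
    scale = np.sqrt((v - 1.0) / (pi * (1.0 - pi)))
    dvp_rows = np.flatnonzero(truth["is_dvp"].values)
    groups = truth["dvp_hypervariable_group"].values

    for row in dvp_rows:
        group_mask = case_mask if groups[row] == "case" else ctrl_mask
        hypo_p = (
            config.hypo_trend_prob_case
            if groups[row] == "case"
            else config.hypo_trend_prob_control
        )
        vals = beta[row, group_mask]
        s = vals.std(ddof=1)
        delta = scale * s
        hypo = rng.random() < hypo_p
        center = vals.mean()
        if hypo and center - delta < 0.02:
            hypo = center + delta <= 0.98  # flip only if the other side fits
        elif not hypo and center + delta > 0.98:
            hypo = center - delta >= 0.02
        shift = -delta if hypo else delta

        members = np.flatnonzero(group_mask)
        n_out = max(1, int(round(pi * members.size)))
        outliers = rng.choice(members, size=n_out, replace=False)
        beta[row, outliers] = np.clip(beta[row, outliers] + shift, 0.001, 0.999)


def _emit_intensities(
    beta: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> IntensityData:
    b = beta.values
    n_probes, n_samples = b.shape
    total = rng.lognormal(np.log(3000.0), 0.25, size=b.shape)
    # keep U nonnegative: beta = M / (S + 100) requires S >= 100 b / (1 - b)
    floor = 100.0 * b / np.maximum(1.0 - b, 1e-6) + 50.0
    total = np.maximum(total, floor)
    meth = b * (total + 100.0)
    unmeth = total - meth

    det = rng.uniform(1e-6, 5e-3, size=b.shape)
    n_fail = int(round(config.frac_fail_detection * n_probes))
    fail_rows = rng.permutation(n_probes)[:n_fail]
    for row in fail_rows:
        bad = rng.random(n_samples) < 0.5
        if not bad.any():
            bad[rng.integers(n_samples)] = True
        det[row, bad] = rng.uniform(0.011, 0.5, size=int(bad.sum()))

    beads = rng.poisson(14.0, size=b.shape)
    n_low = int(round(config.frac_low_bead * n_probes))
    low_rows = rng.permutation(n_probes)[:n_low]
    for row in low_rows:
        weak = rng.random(n_samples) < 0.15
        beads[row, weak] = rng.poisson(1.5, size=int(weak.sum()))

    idx, cols = beta.index, beta.columns
    return IntensityData(
        meth=pd.DataFrame(meth, index=idx, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=idx, columns=cols),
        detection_p=pd.DataFrame(det, index=idx, columns=cols),
        bead_count=pd.DataFrame(beads, index=idx, columns=cols),
    )


def generate_twin_cohort(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    with_intensities: bool = True,
):
    """Simulate a discordant twin cohort.

    Returns ``(intensities, beta, sample_sheet, truth)``.  ``intensities`` is
    ``None`` when ``with_intensities=False`` (beta-only runs are cheaper for
    large simulation studies).  Everything is reproducible from
    ``config.seed``.
    """
    config.validate()
    if len(annotation) != config.n_probes:
        raise ValueError(
            f"annotation has {len(annotation)} rows, config.n_probes={config.n_probes}"
        )

    reference, sigma_m = _probe_model(config, annotation)
    truth = _draw_truth(config, annotation)
    rng = _stage_seed(config.seed, 4)

    sheet = _make_sample_sheet(config, rng)
    m = _sample_m_matrix(config, reference, sigma_m, sheet, rng)

    # mean-shift (DMP) injection on the M scale, sized on the beta scale
    if truth["is_dmp"].any():
        case_mask = (sheet["status"] == "case").values
        dmp_rows = np.flatnonzero(truth["is_dmp"].values)
        base = reference.values[dmp_rows].mean(axis=1)
        delta = truth["true_delta"].values[dmp_rows]
        shift = logit2(np.clip(base + delta, 0.01, 0.99)) - logit2(base)
        m[np.ix_(dmp_rows, np.flatnonzero(case_mask))] += shift[:, None]

    beta = expit2(m)
    if truth["is_dvp"].any():
        _inject_dvp(beta, truth, sheet, config, rng)

    beta_df = pd.DataFrame(beta, index=annotation.index.copy(), columns=sheet.index)
    intensities = None
    if with_intensities:
        intensities = _emit_intensities(beta_df, config, _stage_seed(config.seed, 5))
    return intensities, beta_df, sheet, truth


def generate_independent_cohort(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    n_samples: int = 156,
    seed: int = 1,
) -> pd.DataFrame:
    """Unpaired healthy cohort drawn from the same per-probe baseline model.

    No disease effects are injected; per-probe marginal variance matches the
    healthy twins (the individual-level effect absorbs the pair component).
    """
    config.validate()
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if len(annotation) != config.n_probes:
        raise ValueError("annotation does not match config.n_probes")

    reference, sigma_m = _probe_model(config, annotation)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(6,)))

    alpha = np.array(
        [BLOOD_FRACTIONS.get(c, 1.0 / len(reference.columns)) for c in reference.columns]
    )
    alpha = alpha / alpha.sum() * config.dirichlet_alpha * len(reference.columns)
    weights = rng.dirichlet(alpha, size=n_samples)
    m = logit2(reference.values @ weights.T)
    m += rng.normal(0.0, 1.0, size=m.shape) * sigma_m[:, None]
    m += rng.normal(0.0, config.batch_sd, size=m.shape)

    samples = pd.Index([f"IND{i + 1:04d}" for i in range(n_samples)], name="sample_id")
    return pd.DataFrame(expit2(m), index=annotation.index.copy(), columns=samples)
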