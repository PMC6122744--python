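# Methods

`twinmeth` implements the analysis stack of a disease-discordant
monozygotic-twin methylation study on Illumina-450K-style data, together
with a synthetic cohort generator that carries ground truth for every
injected effect. This note records the models, the defaults and why they
were chosen, and what the synthetic experiments do and do not demonstrate.

## The study design being modelled

Monozygotic twin pairs discordant for a disease share genotype, age, sex
and early environment, so per-pair contrasts of whole-blood DNA methylation
remove most confounding that plagues unrelated case-control designs. Two
complementary signals are tested at every CpG:

- **DMPs** (differentially methylated positions): a shift in *mean*
  methylation between affected and unaffected co-twins.
- **DVPs** (differentially variable positions): a difference in methylation
  *variance* between the groups, typically carried by a subgroup of
  affected individuals rather than by a uniform shift.

## Synthetic cohort generator

### Baseline model

Per-probe baseline beta values are drawn from a three-component mixture
(low, intermediate, high methylation; weights 0.38/0.17/0.45, Beta(1.5,15),
Beta(6,6), Beta(15,1.5)) reproducing the bimodal marginal distribution of
450K arrays. All structure is added on the M scale
(M = log2(beta/(1-beta))) and mapped back through the logistic, so beta
values stay in [0,1] by construction.

For sample *s* in pair *i* at probe *p*:

    M_ps = logit2( sum_k w_sk R_pk ) + b_pi + c_p,chip(s) + e_ps

- `R` is a purified-cell reference (probes x 6 blood cell types: CD8T,
  CD4T, NK, B cells, monocytes, granulocytes). Two percent of probes are
  cell-type informative with a between-type beta gap >= 0.5; `w_s` is a
  per-sample Dirichlet weight vector centred on realistic whole-blood
  proportions (granulocytes ~0.54) with concentration `dirichlet_alpha`
  (default 5).
- `b_pi ~ N(0, rho * sigma_p^2)` is the shared pair effect and
  `e_ps ~ N(0, (1-rho) * sigma_p^2)` the individual residual, giving an
  intra-pair M-value correlation of `rho` (default 0.8, the hallmark of MZ
  twins). Per-probe scales `sigma_p` are lognormal (median 0.25 M units,
  log-SD 0.4, clipped to [0.05, 1]); the source study reports no per-probe
  variance magnitudes, so these are chosen to give beta-scale SDs of
  roughly 0.005-0.05 across the baseline range, the order seen on blood
  450K data.
- `c` are chip batch offsets (SD 0.05 M units). Co-twins share a chip, as
  pairs are hybridised together; a two-level recruitment-cohort label and
  an 86% female fraction mirror the target study's composition so the
  covariate screen has realistic structure to find.

Default study conditions: 79 pairs, 20,000 probes (a desk-scale stand-in
for the ~485k-probe array), no true mean effects (`frac_dmp = 0`), 0.5%
hypervariable probes (`frac_dvp = 0.005`) at variance inflation
`v = 4`, 65% of them hypervariable in cases.

### Effect injection

**DMPs** shift the case group by `delta_beta` on the beta scale (converted
to an M-scale offset at the probe's baseline), sign random per probe.

**DVPs** are injected as an *outlier subpopulation*: a fraction
`pi = 0.2` of the hypervariable group is shifted by
`delta = s * sqrt((v-1)/(pi*(1-pi)))`, where `s` is the probe's
pre-injection beta SD, which inflates that group's marginal variance by
exactly `v` in expectation. The shift is directed towards hypomethylation
with probability 0.74 (case stratum) / 0.98 (control stratum), flipping
only when the [0,1] boundary leaves no room. This is a deliberate modelling
choice: excess methylation variance in real arrays is carried by subgroups
of samples whose means move with them — which is precisely the signature
the Bartlett-plus-t gating procedure was designed to keep, while rejecting
single-outlier artifacts. A symmetric, mean-preserving variance inflation
would be removed by the t-test gate with probability ~0.95 and is not a
realistic disease signature.

Consequence worth knowing: the hypomethylation trend attached to a DVP is a
(weak) mean effect. At 450k-probe scale such trends never survive BH
correction in the DMP test; at the 20,000-probe desk scale the BH threshold
is ~21x looser and some do. The "no DMPs under the null" property is
therefore a statement about cohorts with no injected effects of either
kind.

### Auxiliary layers

Intensities satisfy `beta = M/(M + U + 100)` exactly (offset 100 is the
platform convention), with lognormal total intensity (median 3000). A
configurable 0.3% of probes fail detection p (values >= 0.01 in ~half the
samples) and another 0.3% carry low bead counts (<3 in >=10-15% of
samples), so every QC filter has real work to do. The annotation emulates a
450K manifest: ~2% sex-chromosome probes, 1% SNP-within-2bp, 1%
cross-reactive, island relation and gene-feature categories at realistic
frequencies, and heavy-tailed probes-per-gene counts (Zipf exponent 2,
capped at the manifest maximum 1299) so probe-number bias is present in
gene-set tests.

### What the generator does not emulate

No genotype or mQTL structure, no probe-design chemistry beyond the type
I/II label, no dye or background effects, no missing values, no real CpG
spatial correlation (probes are independent given the model). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under a known truth, not performance on real arrays, where
effect sizes, dependence and artifact structure are harsher.

## Quality control

Probes are removed for: detection p >= 0.01 (default rule: in *any*
sample — the strictest reading of a "failed detection p" filter; a
fraction-of-samples rule is available), sex-chromosome location, SNP within
2 bp of the CpG, presence on a cross-reactive list (supplied as a flag
column or an external ID file; the published lists are inputs, never
recomputed), and bead count < 3 in >= 5% of samples. Counts are itemized
per reason (a probe can fail several). Filtering is idempotent.

The optional probe-type normalization maps type I and type II probes onto
the average of their per-sample empirical quantile functions — a
lightweight surrogate for subset-quantile within-array normalization that
removes the type-II compression while preserving within-type ranks. Full
SWAN from raw intensities is out of scope.

The covariate screen runs sample-space PCA on probe-centred M values (via
the samples-by-samples Gram matrix) and tests each candidate factor against
each PC: one-way ANOVA for categorical factors, Pearson correlation test
for continuous ones. A factor associating at p < 0.05 (unadjusted; no
threshold is standard) with any of the first four PCs is carried into the
DMP model. Note the implied null selection rate for a noise factor is
1 - 0.95^4 ~ 0.185, not 0.05 — screening against several PCs is
deliberately liberal.

## DMP model

Per probe, methylation (beta scale by default; M optional) is modelled as
disease status plus fixed covariates plus a sibling-pair random intercept.
Because every pair contributes exactly one case and one control (enforced),
the REML mixed model reduces *exactly* to OLS on within-pair differences:
the pair effect cancels in the case-control contrast, and the REML residual
variance equals the within-pair residual mean square, so the Wald t with
n_pairs - 1 - k degrees of freedom is identical to the paired t-test when
k = 0. The implementation fits that reduction — one closed-form solve
shared by all probes — which is fast, exact and cannot fail to converge.
Pair-constant covariates (age, sex, cohort, chip when co-twins share one)
are aliased with the pair effect and dropped with a log note, as are
covariate columns collinear in the difference design. BH q-values are
appended; tables are sorted by p with deterministic tie-breaks.

Power uses the two-sided paired noncentral-t formulation. The within-pair
difference SD is a required input, not a hidden default: per-probe
variances span orders of magnitude, so a single power number is only
meaningful relative to a stated variance. `sd_for_power` inverts the curve
(e.g. 79 pairs reach 80% power for a 4% beta difference at alpha = 0.05
when the within-pair SD is <= 0.125).

## DVP detection (iEVORA-style gating)

Stage 1: classical two-group Bartlett statistic per probe (vectorized;
zero variances floored at 1e-12), chi-square(1) p, BH-corrected across
*all* tested probes; retain q < 0.001. Stage 2: Welch t-test on the means
of retained probes; retain p < 0.05; rank ascending by the t-test p (ties:
smaller Bartlett p, then probe ID — output files are deterministic). The
"modification" of Bartlett's test in this procedure is taken to be the
t-gate itself, which suppresses single-outlier false positives; no other
regularization is applied. Each DVP is labelled with its hypervariable
group (larger sample variance) and trend (sign of case minus control mean).
Variability is tested on beta values, consistent with how such signatures
are visualised; an M-scale flag exists.

Under the global null (79+79 samples, 20,000 probes, no injections) the
q < 0.001 gate calls zero DVPs in >= 95% of seeds; with the default
injections it recovers ~90% of true DVPs at zero-to-few false positives.
Bartlett's test is kurtosis-sensitive, and beta values are platykurtic
(bounded), which if anything makes the gate conservative here.

## Cell composition

Houseman-style reference-based deconvolution: probes are ranked per cell
type by the one-vs-rest standardized mean gap (top 100 per type by default;
the original probe-selection recipe is under-specified, and an F-statistic
ranking gives the same probes on clean references); each sample is then
projected onto the reference by nonnegative least squares and renormalized
to the simplex. Sum-to-one by renormalization rather than a constrained QP
matches common practice and keeps the solver contract simple. On Dirichlet
mixtures with noise SD 0.02 the per-type RMSE is ~0.005, comfortably below
the 0.05 recovery contract. Group comparisons use Welch's t-test with the
conventions: identical degenerate groups give p = 1; zero variance with
unequal means is an error.

## Enrichment

Feature enrichment compares a probe set's island-relation and gene-feature
composition against `n_draws` (default 1000) uniform same-size draws from
the QC-passed background, with add-one empirical p-values
`(1 + #{draws >= obs})/(n_draws + 1)` reported one-sided in both
directions. The empirical p converges to the hypergeometric tail, which is
the test oracle.

Gene-set over-representation corrects probe-number bias in the gometh
style: the per-gene selection probability is estimated by isotonic
regression of the selection indicator on the gene's probe count (floored at
1e-6) — monotonicity is the only assumption worth making about the bias
curve, and the exact smoother in the original package is not documented —
and each set is tested with the Wallenius noncentral hypergeometric tail
with odds = mean weight inside / outside the set. With constant weights
this reduces exactly to the central hypergeometric (implemented as an
explicit branch). No FDR is applied across sets: gene sets overlap, and
step-up procedures assume independence.

## Overlap and independent-cohort assessment

Gene-level overlaps use the exact upper-tail hypergeometric on the universe
of genes represented on the QC-passed array (the universe choice is stated
because it is not canonical). Probe-level overlaps use permutation: the
target set is redrawn uniformly from the analysis background (default
10,000 iterations), conditioning on the fixed external list; uniform
sampling is the default, annotation-stratified sampling being a possible
refinement. The permutation p converges to the hypergeometric tail on toy
instances (law of large numbers), which is tested at n_perm = 10,000 with
tolerance 0.02.

Signature assessment recomputes, per DVP, the variance and range
(max - min beta) in case twins, control twins and an independent unpaired
healthy cohort drawn from the same baseline model, stratified by
hypervariability direction, with quartile aggregates. On synthetic truth
the case stratum shows its largest variance in case twins, exceeding both
control twins and the independent cohort — the directional contract of a
disease-specific variability signature.

## Pipeline and reproducibility

`run_pipeline` executes simulate -> QC -> cells -> PCA screen -> DMP ->
DVP -> enrichment -> overlap/assessment -> report. One global seed is
fanned out through `numpy.random.SeedSequence(seed, spawn_key=(stage,))`;
reruns produce byte-identical outputs (fixed float formats: 6 significant
digits, p/q columns in 3-digit scientific notation). Problem sizes in the
shipped tests and the acceptance script — 20,000 probes, 79 pairs, 20
null seeds, 10,000 permutations — were chosen so the whole battery runs in
a few minutes on one core while keeping every statistical contract
measurable at its stated tolerance.

## Known limitations

- Probes are independent in the generator; genome-wide BH behaves slightly
  differently under real inter-probe correlation.
- The mixed model is exact only for the balanced discordant design; general
  pedigrees or incomplete pairs are rejected rather than approximated.
- The Bartlett gate's calibration on real (non-simulated) beta
  distributions depends on kurtosis; the t-gate mitigates but does not
  remove this.
- The isotonic bias curve needs a reasonable spread of probe counts; with
  few genes it can be step-like and the Wallenius odds coarse.
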