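# Methods

This note documents the statistical procedures implemented in `tapelift`,
the defaults chosen where the design was genuinely open, and what the
synthetic cohorts do and do not demonstrate.

## Data model

A cohort is a probe × sample matrix of methylation β-values (fraction of
methylated alleles, in [0, 1]) paired with a detection p-value matrix of the
same shape and per-sample metadata (donor, age in years, sex, qPCR ΔCt,
replicate group, cohort label, tissue label). All alignment is by
identifier; matrices whose probe or sample id sets differ are rejected with
the offending ids named, and matching ids in a different order are silently
realigned. Matrices are stored as TSV with `NA` for missing values, written
at `%.17g` precision and parsed with round-trip float handling, so write →
read is bit-exact — QC counts do not depend on serialization.

The pipeline deliberately starts from β and detection-p matrices. Raw IDAT
parsing, background subtraction, dye-bias correction and out-of-band
detection-p computation are upstream preprocessing concerns and out of
scope.

## Sample gates

* **Integrity gate.** Samples pass when their ΔCt (qPCR cycle difference
  against an intact reference DNA; a degradation proxy) is strictly below
  3.0 cycles. The relaxed variant used for replicate cohorts is inclusive at
  3.5 cycles. Both the threshold and the comparator are configurable because
  the two gates differ in strictness; samples with a missing ΔCt pass only
  when their cohort is marked as pre-gated (e.g. published reference
  panels). 
* **Detection gate.** A probe-sample cell is *detected* iff its detection
  p-value is present and strictly < 0.05 (a cell at exactly 0.05 fails, and
  a missing p-value fails — the conservative reading for a high-confidence
  workflow). A sample passes when its detected fraction over all probes is
  ≥ 0.75 (relaxed 0.70; the boundary is inclusive).

## Serial probe subsetting

Stages run in a fixed order, each recorded with its in/out counts:

1. remove probes overlapping known SNPs;
2. remove probes on chromosomes X and Y;
3. remove cross-reactive probes;
4. **replicate-variance filter**: for each probe and each replicate donor,
   compute the *unbiased* (n−1) sample variance of the donor's replicate β
   values; flag the (probe, donor) pair when variance > 0.1 (strict); drop
   the probe when flagged in at least 2 donors. A donor with any missing β
   among its replicates contributes no flag for that probe. The (n−1)
   estimator was chosen because it is the default in mainstream statistical
   environments; with three replicates the distinction matters
   (n−1 variance is 1.5× the population variance).
5. **detection filter**: keep only probes with every cell (all samples, all
   datasets) detected.

The first three stages are set intersections, so the retained set is
invariant to their order (the per-stage counts are not); the test suite
asserts this by permutation, and the full serial procedure is checked
against an independent one-shot boolean-mask implementation on random
cohorts.

## Age association

Per probe, β is regressed on age by OLS with case deletion for missing
cells (vectorized over probes); probes with fewer than three usable samples
get missing results. Residual variances are moderated by the standard
empirical-Bayes construction: s²ᵢ with dᵢ degrees of freedom are modeled as
scaled-F around a prior s₀² with d₀ df. The prior is estimated by moment
matching on zᵢ = log s²ᵢ:

    E[zᵢ] = log s₀² + ψ(dᵢ/2) − log(dᵢ/2) − ψ(d₀/2) + log(d₀/2)
    Var[zᵢ] = ψ′(dᵢ/2) + ψ′(d₀/2)

d₀ is obtained by inverting the trigamma function (Newton), s₀² from the
mean equation, and the posterior variance is s̃²ᵢ = (d₀s₀² + dᵢs²ᵢ)/(d₀+dᵢ).
When the observed spread of log s² does not exceed what χ² sampling noise
alone explains, d₀ is infinite and all probes pool to s₀²; when all s² are
zero the procedure falls back to unmoderated variances with a warning, and
`d0=0` can be passed to disable shrinkage explicitly. The implementation is
cross-checked in the test suite against `limma::squeezeVar` through Rscript
on a shared fixture. Moderated t = slope/(s̃·SE-factor) is referred to a t
distribution with d₀ + dᵢ df, two-sided; Benjamini–Hochberg adjustment uses
`statsmodels.multipletests` (verified against a brute-force step-up oracle).

Probes at q < 0.01 are called age-associated. For visualization, the top
1000 of those ranked by across-sample β variance (computed over **all**
retained samples, not only within group — the natural reading of "most
variable"; ties broken by probe id) are exported row-standardized
((x − mean)/sd with n−1; constant rows map to zeros with a warning). No
covariates are fitted: the design is age-only by construction.

## Clocks

**Objective convention.** Both clocks minimize

    ½‖y − Xw − b‖² + λ·[α‖w‖₁ + (1−α)/2·‖w‖₂²]

with the penalty λ in residual-*sum*-of-squares units. Under this
convention the α = 0 solution at fixed λ is exactly the ridge closed form
(XᵀX + λI)⁻¹Xᵀy, which is what the test suite asserts; internally λ maps to
scikit-learn's per-sample parameterization as alpha = λ/n. When λ is not
supplied it is selected on an automatic path by k-fold cross-validation
(default 10 folds, shuffled with a persisted seed) at the **minimum mean CV
error** — not the 1-SE rule; both the grid size and folds are configurable.

**DirectClock** (α = 0.1) standardizes predictors internally and returns
coefficients on the original β scale; `n_active_cpgs_` counts nonzero probe
weights. Missing β must be imputed before training (probe means over the
training samples are the recommended neutral choice); prediction through a
saved model imputes absent probes at the stored training means.

**PCClock** (α = 0.5) centers probes at training means, takes principal
components, and fits the same elastic net on the component scores. Two
choices matter and are deliberate:

* *Scores are not re-standardized.* Trailing components have near-zero
  variance; forcing them to unit variance amplifies pure noise directions
  and destabilizes the fit. The scores keep their natural PCA scale.
* *Age-associated pre-selection is the default* (`preselect="auto"`): the
  PCA is restricted to probes at q < 0.01 in an age-association fit on the
  training data. Restricting the basis to age-informative probes is what
  lets component averaging cancel probe-level technical noise instead of
  spending components on modeling it; without pre-selection
  (`preselect=None`) the PC clock degrades toward the direct clock under
  independent probe noise. `n_active_cpgs_` for a PC clock is the number of
  CpGs entering the PCA — with dense loadings every input CpG contributes
  to the predictor.

All components up to min(n_train − 1, n_probes) are retained by default
(requests beyond the feasible rank are clipped with a warning); the
penalized regression performs the effective component selection. For
prediction the basis projection collapses into an equivalent probe-space
weight vector (mathematically identical for a linear predictor), so direct,
PC and external clocks share one portable `ClockModel` record: probe ids,
weights, intercept, training means, optional age transform. Models
serialize to a TSV weight table plus JSON header; save → load → predict is
bit-identical. External clock definitions may declare the
`horvath-log-linear` transform (adult age 20), applied only at prediction;
clocks trained here model age directly with no transform.

The train/test split is a uniform random partition with
round(fraction·n) training samples (0.8 by default), persisted with its
seed. Accuracy is summarized as RMSE (years) and Pearson r; constant
predictions yield r = NaN with a warning rather than an error.

## Markers

**Mitotic age.** A clock definition names its probes and one of two
aggregations. `rate_normalized_mean` scores sample j as the mean over
usable probes of (βᵢⱼ − β₀ᵢ)/(δᵢ(1 − β₀ᵢ)) — the estimated number of
accumulated division-years given each probe's ground-state β₀ and per-year
gain rate δ — with the final score clamped at 0. `upper_quantile` takes the
empirical q-quantile (linear interpolation between order statistics; stated
because quantile conventions differ) of the clock probes' β. Published
coefficient sets are inputs in the definition format, not shipped; the
synthetic generator provides definitions with known truth. Probe coverage
against the supplied high-confidence set is always reported, since clock
probes lost to filtering are the known failure mode of external clocks on
low-input data.

**TSG promoter hypermethylation.** Gene-level promoter methylation is the
mean β over the gene's TSS200/TSS1500 probes inside the high-confidence set
(≥ 2 probes required; a probe linked to several genes contributes to each).
Old (≥ 60 y) vs young (18–29 y) group means are compared by Welch's
two-sided unequal-variance t-test — chosen as the safe default where the
test is otherwise unspecified, and configurable. Genes with old > young and
raw p < 0.05 are ranked by the difference of group means (not fold change),
top 50 reported. **No multiple-testing correction is applied in this
ranking**; that mirrors the screening character of the analysis and is a
fidelity choice, not a statistical endorsement.

**nv-probe outliers.** Non-variable probes are designed to move only when an
underlying genetic variant is present. Per probe, the across-sample median
and MAD (floored at 0.01 so near-constant probes still yield finite scores)
define a modified z-score 0.6745·(β − median)/MAD; cells with |z| strictly
greater than 3.5 are flagged. At least 5 samples are required for the
robust statistics.

## Tissue identity

PCA is computed on β directly (no M-value transform), centered per probe,
over the probes shared by all datasets (≥ 10 required, missing-containing
probes dropped); component signs follow the convention that each
component's largest-magnitude loading is positive, making embeddings
reproducible across sample orderings. Marker clustering restricts to the
union of each cell type's top-25 marker probes, computes pairwise-complete
Pearson correlations between samples (minimum overlap 10 probes), and
clusters with average linkage on 1 − r (the linkage is configurable; average
is the default where the choice is otherwise open). The dendrogram is
serialized as Newick. Compartment composition tallies chromatin-state
fractions (16 keratinocyte segmentation states plus `unassigned`) for a
probe subset against the full annotation; both fraction vectors sum to 1.

## Synthetic cohorts

The generator emulates the data regime the pipeline targets, with all
randomness drawn from one seed through fixed stream ids (annotation 0,
cohort 1, reference panels 2):

* **Baseline β**: equal mixture of Beta(2, 18) and Beta(18, 2) — the
  canonical bimodal shape with modes near 0.06 and 0.94.
* **Cohort**: 89 donors by default, ages uniform on [18, 85], ~60% female;
  a replicate cohort of 4 donors × 3 samples sharing per-donor effect
  vectors (SD 0.01) plus technical noise.
* **Age CpGs** (default 400): β = base + slope·(age − 18), slope magnitude
  uniform on [0.002, 0.004] β/yr with random sign; bases are placed so the
  drift stays inside [0, 1].
* **Mitotic CpGs** (default 150): start near the unmethylated mode
  (base ∈ [0.03, 0.08]) and gain δ·age with δ ∈ [0.001, 0.003] β/yr —
  division-linked drift accumulates from birth, so age rather than
  age − 18 multiplies the rate.
* **TSG genes** (default 100, 2–5 promoter probes each): 60% of genes get a
  total promoter methylation gain uniform on [0.1, 0.3] across the age
  range; the rest stay flat, giving the ranking true negatives.
* **nv probes** (default 40): flat near 0.02 with 5 planted outlier cells
  shifted by +0.4–0.7, emulating somatic variants.
* **Markers**: 25 probes per cell type, unmethylated (0.05) in the owning
  tissue and methylated (0.9) elsewhere; reference panels per tissue carry
  the corresponding pattern plus a tissue-specific random baseline.
* **Degradation**: per-donor quality q ~ Beta(3.8, 1.3); a cell fails
  detection with probability expit(20·(0.24 − q)) (failed cells get
  p ~ U(0.05, 1), detected cells p ~ U(0, 0.05) — only the p < 0.05
  dichotomy matters downstream), and β noise is inflated by 1 + (1 − q).
  These constants were set so the default cohort reproduces the regime the
  workflow is designed for: a small percentage of samples fails the
  detection gate and roughly 60% of probes survive the all-datasets
  detection filter. ΔCt is generated as 0.2 + 3.6·(1 − q) + N(0, 0.3),
  clamped at 0, tying the integrity gate to the same quality scalar.
  β values are clamped to [0, 1] after noise (clamping, not resampling,
  preserves determinism).

**What passing tests show — and what they do not.** The generator plants
linear, probe-independent signal with Gaussian noise and a clean logistic
failure model. Real epidermal data adds nonlinear age trajectories, probe-
and batch-correlated technical structure, cell-composition shifts, bisulfite
conversion artifacts and genotype effects, none of which are simulated.
Parameter-recovery results (clock RMSE near one year, near-perfect marker
correlations) therefore demonstrate correctness of the implementation under
its assumed model, not expected accuracy on tissue; on real low-input
epidermal methylomes, held-out clock errors in the 4–6-year range are the
realistic scale.

## Orchestration

`run_pipeline` executes simulate → integrity gate → detection gate → probe
subsetting → age association → clocks → markers → identity in fixed order,
records every threshold and stage count in a JSON run report, and derives
all stage seeds from the single mandatory config seed (SeedSequence
children), so identical configurations reproduce identical outputs. When a
gate leaves too few samples (fewer than three) the downstream stages are
skipped with explicit report entries rather than erroring. Stages are cheap
at desk scale, so the pipeline runs single-process without caching;
reproducibility comes from seeding, not memoization. The default test-suite
and acceptance problem sizes (≤ 6,000 probes, ≤ 120 donors) were chosen as
the smallest cohorts at which every planted effect is comfortably
detectable.

## Known limitations

* Covariate-free age models: sex and batch effects are not adjusted.
* The TSG ranking reports raw p-values by design (see above).
* The replicate-variance filter treats any missing replicate value as
  "no evidence", which is permissive for probes with missing data.
* External clock application can only be as good as its probe coverage;
  the coverage report quantifies, but cannot repair, lost CpGs.
* `FilterReport` counts depend on stage order for the annotation filters
  even though the final set does not.
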