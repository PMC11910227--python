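# Methods

This note documents the statistical models, the synthetic-data generator, and
the design decisions behind `epimmune`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Methylation model

A CpG's methylation level is the proportion β = M/(M+U) ∈ [0,1] of methylated
signal. Differential testing is done on the logit scale,
M = log2(β/(1−β)), which decouples mean and variance better than the bounded
β scale; clipping at ε = 10⁻⁶ keeps the transform defined at {0,1}. Effect
sizes are always reported back as Δβ (on-treatment − baseline) because a
"25% methylation decrease" means an absolute β change in this field's usage.

**Probe QC.** A probe is excluded when it fails detection (p > 0.01) or has a
bead count below 3 in strictly more than 5% of samples, or is SNP-overlapping,
multi-mapping, or on chrX/chrY. The removal log attributes each probe to the
first firing rule so counts sum exactly to the number removed. The pipeline
assumes its input β matrix is already normalized and batch-corrected; array
preprocessing is deliberately out of scope and stated as a precondition.

**Paired probe test.** For each probe, within-pair M differences d₁…dₙ give
t = d̄ / (s/√n). With moderation (default), per-probe variances are shrunk
toward a scaled-inverse-χ² prior fitted by the method of moments on log s²
(digamma/trigamma identities; trigamma inverted by Newton iteration), and the
moderated t is referred to t with n−1+d₀ degrees of freedom. At 8 pairs this
roughly doubles the effective degrees of freedom and is what keeps the test's
size near nominal on beta-distributed noise (the acceptance suite checks
type-I error ∈ [0.04, 0.06] on 10,000 null probes). With moderation off the
test reduces exactly to the ordinary paired t (verified against
`scipy.stats.ttest_rel` to 1e-10). Probes with zero variance across pair
differences carry no within-probe evidence scale and are flagged; without
moderation their p is set to 1.

**Regions.** CpGs on the same chromosome within 500 bp of their neighbor form
clusters; a candidate region is a maximal sign-consistent run of ≥ 3 probes
with |mean Δβ| ≥ 0.1, scored by its area Σ|mean Δβ|. This is a deliberately
simplified bump-hunting scheme — no loess smoothing — because at 8 pairs the
smoother adds variance tuning without changing which planted regions are
found. The null flips on/baseline labels within pairs: for ≤ 10 pairs all 2ⁿ
assignments are enumerated, so the permutation p is exact with resolution
1/2ⁿ (the identity assignment is included, bounding p away from 0, and the
mirrored all-flip makes the smallest attainable p equal 2/2ⁿ); beyond 10
pairs random flips are drawn. The permutation p compares each region's area
to the *genome-wide maximum* null area, a family-wise comparison that keeps
the scan honest over many candidates; BH is applied across regions on top.
Region coordinates are 1-based closed (array-manifest convention, strand
ignored since CpG methylation is symmetric); the BED writer converts to
0-based half-open at the boundary.

**Gene-level promoter statistic.** Per participant, promoter (TSS200/5′UTR)
probe Δβ values are standardized to Z-scores using the mean and SD over all
promoter CpGs of that comparison — the standardization population is a
genuine free choice; the whole-promoter-universe reference makes the gene
statistic interpretable as "relative to this participant's global promoter
shift", and it is configurable by passing differently standardized scores.
Gene-level combination is a Stouffer sum Z = Σzᵢ/√n with a two-sided normal
p. Under independent N(0,1) probe scores the statistic is standard normal
regardless of n (checked by KS test at 10,000 genes).

## Expression model

Counts are normalized as RPKM = count·10⁹/(length·library size); log2RPKM
uses a pseudocount of 1. Signature scores are geometric means of RPKM + 0.1
over member genes; the 0.1 offset keeps logs defined at zero counts while
perturbing expressed genes negligibly, and scores are exactly multiplicative-
scale equivariant at offset 0. Paired fold changes are ratios on the linear
scale with the same offset. Differential expression for enrichment ranking
uses the per-gene paired t on log2RPKM rather than a count-model
quasi-likelihood fit: at n = 8 pairs the paired t on log-scale normalized
values is a standard, transparent choice, and the enrichment stage only
consumes (p, sign) pairs, so the ranking model is swappable.

## Deconvolution

A bulk methylome restricted to signature CpGs is modeled as b ≈ R·f with
cell-type reference profiles R, f ≥ 0, Σf = 1 (ten cell types). The default
solver is non-negative least squares on an augmented system carrying the
sum-to-one constraint as a heavily weighted (10⁴) equality row — effectively
a hard constraint with a deterministic, testable optimum; a final
renormalization removes the ~10⁻⁹ residual slack. On noiseless mixtures the
solution is exact (≤ 10⁻⁶, the oracle being the generator's own mixing
weights); on beta-noise mixtures at precision 50 the per-type RMSE stays
under 0.05 with ~100 signature probes per cell type. A ν-SVR solver
(linear kernel, ν ∈ {0.25, 0.5, 0.75}, lowest reconstruction RMSE, negative
coefficients clipped and renormalized) is provided for fidelity to
CIBERSORT-style estimators; its result records the method tag. No
cross-platform harmonization is attempted — reference and samples must share
the β scale. Relative fraction changes divide by the baseline fraction and
are reported missing when that baseline is 0.

## Enrichment

Genes carry (p, direction); the signed score is s = direction·(−ln p) —
natural log rather than log₁₀, which only rescales the slope, not its test.
Set membership is regressed on s by logistic regression. The fit is Firth's
bias-reduced penalized likelihood because strongly enriched sets separate
members from background perfectly, where the ordinary MLE diverges and the
Wald statistic collapses (Hauck-Donner); the set p-value is therefore a
penalized likelihood-ratio test (null model: slope 0, intercept maximizing
the penalized likelihood under the full design's penalty, as in standard
Firth-logistic practice). Away from separation this agrees with the plain
logistic LR/Wald tests (verified against statsmodels within 10%), and null
sets remain uniformly distributed. Set-size bounds of 10–500 after
intersection stabilize the fits. The joint "hypomethylated and upregulated"
table intersects sets at FDR < 0.05 in both inputs with methylation direction
down and expression direction up.

## Endpoint rules

All endpoint rules are strict, printed predicates and are property-tested
against brute-force re-evaluation:

- responder ⟺ IFN-γ signature FC > 2 **and** CD274 FC > 2 (the conjunction is
  the default because the trial applied both criteria to the same
  participants; a disjunction toggle exists);
- BED met ⟺ ≥ 10% marker decrease in ≥ 50% of the dose cohort, both
  comparisons inclusive ("at least"). The marker is configurable; the default
  is the relative decrease in mean promoter β, recorded in the run report,
  since the protocol's exact marker panel is not published;
- TSG reversal ⟺ promoter Δβ < −0.25 and expression FC > 2 (both strict),
  counted over TSGs with ≥ 1 hypermethylated promoter probe
  (Δβ ≥ +0.10 at FDR < 0.05) in a tumor-vs-normal compendium; when no
  compendium table is supplied the pipeline treats the provided TSG list as
  pre-filtered and says so in the report;
- NLR = absolute neutrophils / lymphocytes, missing at zero lymphocytes;
  cohort summaries are available-case;
- H-score = 1·(%1) + 2·(%2) + 3·(%3) ∈ [0, 300].

The exact Wilcoxon rank-sum test enumerates the permutation distribution of
the rank sum (midranks for ties) by a subset-sum dynamic program over doubled
ranks; two-sidedness is by distance from the null mean. Enumeration is exact
up to a combined n of 30 — beyond that a tie-corrected normal approximation
is used and flagged — chosen because the DP is effectively instant there
while covering every comparison a trial of this size can produce.
Kaplan-Meier estimation (lifelines) reports the product-limit curve with
Greenwood-based log-log confidence intervals; the median is reported missing
when S(t) never reaches 0.5.

## Synthetic cohort

The generator emulates the trial geometry: 8 participants (5 in a 5-day dose
cohort, 3 in a 10-day cohort), one baseline and one on-treatment biopsy each,
20,000 CpGs, 5,000 genes, and three planted responders (two 5-day, one
10-day).

**Methylome.** Probes live in "units" (gene promoters with 3 promoter CpGs,
single signature CpGs, a 5-probe plantable region, filler blocks) scattered
over the 22 autosomes with small intra-unit gaps (50–300 bp) and large
inter-unit gaps, producing the clustered CpG geography region detection
expects; a few chrX/chrY, SNP-flagged, multi-mapping and QC-failing probes
exercise the filter. Baseline probe means are bimodal (most CpGs near 0 or
1). Cell-type structure enters through 933 signature CpGs whose reference
profiles are near-one in a marker cell type and low elsewhere (spread > 0.3,
full rank); the reference carries 1,197 probes of which only those 933 occur
in the data, so the intersection step is exercised. Observed β is drawn from
Beta(mβ·φ, (1−m)·φ) around the mixed mean with precision φ = 50 (per-probe SD
≤ 0.07), parameterized by (mean, precision) because mean-level effects are
what the planted biology manipulates.

**Planted effects.** Responder on-treatment samples carry: IFN-γ genes ×3.0,
CD274 ×2.8, STING genes ×1.8, M1 genes ×1.3, 20 reversal TSGs ×3.0 in
expression; promoter Δβ −0.25 on those TSGs; Treg fraction ×0.65 and CD8⁺ T
×1.5. A promoter-wide Δβ of −0.08 (≈15% relative decrease against a mean
promoter β of ~0.5) is carried by the responders plus one additional 5-day
non-responder — trials of hypomethylating agents see demethylation in
non-responders too — which makes the 5-day cohort (3/5 qualifying) and not
the 10-day cohort (1/3) meet the BED rule. One 5-probe region on chr1 shifts
by −0.3 in all participants, the planted DMR. The 6-gene IFN-γ list is the
published one; STING (44), M1 (188), M2 (159), APM (15), CTA (1,019) and TSG
(1,217) sets are synthetic stand-ins at the published sizes, since the
memberships are not printed — they are inputs, not constants.

**Transcriptome.** Gene base weights are log-normal; biomarker genes are
floored to quantifiable expression. Biological variation enters as a gamma
gene × participant latent with CV² equal to the dispersion (0.1), shared by
the two samples of a pair; counts are Poisson around library-size-scaled
expected means (libraries uniform in 1–3 M). Marginally across participants
counts are negative binomial with dispersion 0.1; within a pair, fold changes
carry only counting noise — which is precisely why paired designs are
powerful, and why an 8-pair trial can see a 3-fold planted effect as a
2.8–3.0-fold observed fold change. Simulating the dispersion as independent
per-sample noise instead would make within-pair fold changes so noisy that
no 8-participant design (simulated or real) could classify responders
reliably; the latent-sharing model is the faithful reading of a paired
biopsy. Clinical survival is exponential with a responder/non-responder
hazard ratio of 0.4 (censoring at 36 months) — enough to produce the
qualitative responder-survival association without claiming any particular
trial's numbers. NLR improves on treatment for responders; IHC intensity
percentages are Dirichlet with a hotter CD8 profile in responder on-treatment
samples, summing to exactly 100.

**What the generator does not emulate.** Raw IDAT intensities or FASTQ reads;
array batch structure (inputs are assumed batch-corrected); compositional
library effects at realistic scale (at 5,000 genes the planted bumps are a
negligible library share, but heavily scaled-down gene universes exaggerate
this dilution — test configurations use ≥ 400 genes for that reason);
HPV status, WES mutations, ERV expression. Passing tests on this cohort
demonstrate the pipeline's statistical behaviour under its stated noise
model, not performance on real arrays with probe cross-reactivity, batch
residue, or reference/sample platform mismatch.

## Problem sizes

The default test run uses the trial-scale cohort (20,000 probes × 16 samples,
5,000 genes) for end-to-end checks, a 1,800-probe/400-gene cohort for
pipeline plumbing, 10,000 probes/genes for calibration suites, 100 mixtures
for deconvolution accuracy, 1,000 random tables for endpoint-rule property
tests, and n = 500 for the survival closed-form check — sizes at which every
statistical claim tested is stable across seeds while the whole suite stays
fast.

## Known limitations

- The DMR scanner is not a full bump-hunter (no smoothing, no per-cluster
  candidate p-values); its null is exact but conservative for short regions
  adjacent to long ones because the genome-wide max-area reference is
  family-wise.
- The moderated test assumes exchangeable per-probe variances around one
  prior; strong variance strata (e.g. Infinium I/II chemistry) would call for
  covariate-dependent priors.
- Deconvolution accuracy depends entirely on the supplied reference; no
  feature selection from purified profiles is performed.
- The exact rank-sum test's two-sided definition (distance from the null
  mean) can differ from doubled-one-sided definitions in asymmetric tie
  configurations; it matches `scipy.stats.mannwhitneyu(method="exact")`
  wherever ties are absent.
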