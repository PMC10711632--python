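# Methods

`epidrift` analyses a probe x subject matrix of methylation beta values
for three signals: group-level differential methylation, per-subject
stochastic epigenetic mutation (SEM) burden, and rare per-subject
epivariations. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Input model and quality control

The pipeline consumes *normalized* beta values with covariates already
attached: phenotype, sex, age, batch and blood cell-type fractions per
subject. Normalization, batch correction and reference-based cell
deconvolution are upstream of this package and out of scope; detection
p-value and beadcount QC are consumed as precomputed boolean flags in the
probe annotation.

Probe exclusion applies five flag classes **sequentially** (poor
detection, low beadcount, not at a CpG start, published mask list, sex
chromosomes), so per-class removal counts are disjoint and sum with the
retained count to the input count. A probe flagged twice is counted under
the first matching class.

Age and cell fractions are collinear by construction (fractions sum to 1),
so models adjust for their leading principal components rather than the
raw features. Features are standardized; components are retained up to 95%
cumulative explained variance (configurable); the sign convention (largest
loading positive) makes scores deterministic. Constant features are
dropped with a warning.

Missing betas are tolerated: they are mean-imputed within phenotype group
for the regression stages only, and excluded (never imputed) for SEM
calling and fence estimation.

## Differential methylation and meta-analysis

Per-probe regression runs on M-values, log2(β/(1−β)) with β clipped to
[1e-3, 1−1e-3] — the variance-stabilized scale; effects are also reported
as mean delta-beta for interpretability. The design is intercept +
phenotype + sex + covariate PCs, fitted by OLS probe-by-probe
(vectorized). Residual variances are shrunk towards a scaled
inverse-chi-square prior fitted across probes by moment matching on the
log scale (trigamma inversion), giving a moderated t with d0 + d degrees
of freedom; `prior_df=0` reproduces plain OLS exactly (tested to 1e-10).
A probe with zero residual variance and zero effect reports t = 0, p = 1.

Multiple testing uses Benjamini–Hochberg throughout (one implementation,
reused by every stage). Studies are combined by the sample-size-weighted
z scheme: z_i is the signed probit of each study's one-sided p,
w_i = sqrt(n_i), z_meta = Σw_i z_i / sqrt(Σw_i²); a `concordant` flag
records whether all study effects share a sign. Inverse-variance weighting
is deliberately not used: summary statistics from heterogeneous array
platforms are more safely combined on the p-value/direction scale.

## SEM calling and the Global epi-mutation load

A SEM is a beta value beyond the Tukey-style fence of the **control**
distribution at that CpG: below Q1 − 3·IQR or above Q3 + 3·IQR. Choices
that matter:

* Quartiles use linear interpolation of order statistics ("type 7"),
  recorded in the output because fences move with the convention.
* Calls are made on the beta scale (the rule concerns methylation level,
  not a transformed scale), with **strict** inequalities — ties, including
  the degenerate IQR = 0 case, are never calls.
* All subjects are scored, controls included. Control calls are mildly
  in-sample (a control's own value influences its fence); at n = 61
  controls this gives cases a slightly higher *natural* outlier call rate
  than controls (~5e-4 vs ~2e-4 per cell under the default simulator
  noise). This asymmetry is a known property of the fence approach and is
  deliberately retained.
* Probes with fewer than 8 non-missing control values (configurable) are
  excluded and reported.

Global-EML is ln(count + 1) of a subject's genome-wide SEM calls. The
association model is `logit(phenotype = case) ~ log_eml + sex + PCs`. Two
robustness choices replace a plain Wald test:

* Under (quasi-)separation the MLE diverges; the fallback is **Firth
  bias-reduced logistic regression** (Jeffreys-prior penalty), which keeps
  estimates and standard errors finite. A small-ridge fallback was
  considered and rejected: its Wald p badly understates strong effects.
* The headline p-value for the burden term is a **likelihood-ratio test**
  (penalized LR under Firth). With 122 subjects and a genuinely doubled
  SEM rate, the burden separates the groups almost completely, and Wald
  statistics collapse exactly when the effect is strongest (the
  Hauck–Donner effect); the LR test does not. Per-predictor Wald p-values
  are still reported in the summary table.

## Gene-level burden (SKAT)

Within a gene, SEM calls (absolute value; direction optionally split) form
the subject x probe 0/1 matrix G. With null fit μ̂ from
`phenotype ~ sex + PCs`:

    Q = (y − μ̂)ᵀ G W² Gᵀ (y − μ̂),  W = diag(Beta(1,25) pdf at SEM frequency)

Zero-frequency probes get weight zero; genes need ≥ 2 probes and ≥ 1
carrier. Under the null Q is a mixture Σλ_i χ²₁ with λ the eigenvalues of
Zᵀ P Z, Z = D^{1/2} G W, P the D-weighted projection off the null design,
D = diag(μ̂(1−μ̂)).

The analytic tail is computed **exactly** (to ~1e-6), not by moment
matching: a single eigenvalue is a scaled chi-square; two eigenvalues
reduce to a smooth one-dimensional conditional integral; three or more use
Imhof's characteristic-function inversion on a vectorized Simpson grid
with an integration-by-parts truncation bound. The Liu–Tang–Zhang
four-moment approximation is retained only as a fallback for degenerate
spectra. This matters: an adaptive quadrature on the oscillatory Imhof
integrand mis-estimated mid-range p-values by up to 0.3 during
development, which is easily mistaken for miscalibration of the test
itself.

The permutation p permutes the null residuals y − μ̂ across subjects
(covariates held fixed): p = (1 + #{Q* ≥ Q}) / (B + 1), resolution
1/(B+1). **Analytic and permutation p-values agree only coarsely in small
samples.** With 20 subjects the permutation null of Q is discrete — binary
residuals near ±0.5 and sparse carrier patterns create atoms of
probability mass up to ~0.3 — so no continuous chi-square mixture can
track it closely; measured mean |p_analytic − p_perm| is 0.1–0.3 across
toy designs. At cohort scale (122 subjects, SEM frequencies ~1e-3) the
analytic test is well calibrated: measured null rejection at 0.05 is
5.2–5.4% with uniform permutation p-values. Practical guidance follows the
structure of the output: trust the permutation column when genes are small
or carriers very few.

## Epivariation scan

Per subject with K genome-wide SEMs over N analyzed probes, every window
of n consecutive probes (default n = 10, step 1, never spanning
chromosomes) with k SEMs is scored with the cumulative hypergeometric
upper tail P(X ≥ k) — computed by direct pmf summation, which matches a
rational-arithmetic oracle to 1e-12. N and K are genome-wide by design:
the null hypothesis is that the subject's SEMs are scattered uniformly
over the analyzed probe universe.

Significance uses per-subject Bonferroni over all window positions
(default; fixed-alpha mode available). Significant windows that overlap or
abut are merged; the merged span is **trimmed to its first and last SEM**
and must contain ≥ 3 SEMs (`min_sems`). Without trimming, windows that
partially overlap a true region would always stretch the span up to
n − 1 probes into flanking genes. Direction is hyper/hypo when ≥ 80% of
the region's SEMs agree, else mixed.

Regions map to every gene with ≥ 1 probe in the span; intergenic regions
are kept. The case-exclusive list contains genes with ≥ 1 epivariated case
and zero epivariated controls — which requires the scan to have been run
on controls too.

One behaviour deserves a caveat: a lone background SEM immediately
upstream/downstream of a true region can fall inside a significant window
and extend the merged region into the neighbouring gene. That is correct
merging behaviour, but it means gene lists are resolution-limited to about
one window width at region boundaries.

## Synthetic cohorts: what they emulate, and what they don't

The generator mirrors a 61-case / 61-control blood methylation study:
bimodal betas (60% of probes around 0.10, 40% around 0.85, Beta
concentration 100 → SD ≈ 0.03, with mild probe-level jitter), ages ~
Normal(50.6, 10) for cases vs Normal(48, 10) for controls, a configurable
male fraction (default 0.6), Dirichlet blood-cell fractions with a
group-shifted NK concentration, two batches, and QC flags at realistic
rates (~1–3% combined). All signal is injected on top and recorded in
truth tables; identical seeds give bit-identical cohorts, and the
cells differing pre/post injection equal the truth set exactly.

* `inject_sems` places values at least 0.05 beyond the pre-injection
  control fence (towards the extreme with more headroom), so recovery by
  the caller is exact by construction when controls are uninjected;
  infeasible cells (fence spanning the unit interval) are logged, not
  dropped silently.
* `inject_epivariation` shifts contiguous probe runs by ±shift with
  clipping. `align_to_genes` aligns runs to gene starts;
  `avoid_clipping` restricts placement to runs where no carrier value
  saturates — a saturating hyper shift at a near-fully-methylated CpG is
  not representable on the beta scale, which mirrors real arrays, where
  such loci cannot show hyper-outliers.
* `inject_dmps` shifts case means at random probes.

Defaults for the recovery experiments are chosen to match paper-scale
densities rather than paper values (which are not reported): a per-cell
SEM rate of 1e-3 gives 122 x 1e-3 ≈ 0.12 expected carriers per probe, the
same per-gene carrier density a 450k-probe cohort with a few hundred SEMs
per subject exhibits. Simulation sizes in the test-suite (2,500–5,000
probes per chromosome, 2–4 chromosomes) are the package's scaling choice
for routine runs; the structure, not the probe count, carries the
statistics being tested.

What passing tests do **not** show about real data: the generator draws
probes independently (no co-methylation blocks, so window statistics on
real arrays are locally correlated where ours are not), betas are not
coupled to age, sex or cell composition (covariate adjustment is exercised
for confounding structure, not for real covariate effects), there are no
probe-type chemistry artefacts or batch effects, and injected signal has
sharp boundaries that real epivariations lack.

## Known limitations

* Control SEM calls are in-sample (see above); leave-one-out fences would
  remove the asymmetry but deviate from the reference approach.
* The analytic SKAT p is an asymptotic quantity; at very small n or for
  near-empty genes, use the permutation column.
* The epivariation gene lists are boundary-limited to roughly one window
  width; genes adjacent to a strong region can be dragged in by a single
  nearby SEM.
* The meta-analysis combines p-values and directions only; it does not
  model between-study heterogeneity.
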