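# Methods

`kernomics` implements a complete multi-omics analysis of quantitative
traits in a small panel of inbred lines measured under two contrasting
water treatments: quality control of the omic layers, construction of
similarity kernels, a multi-kernel Bayesian linear mixed model with
posterior variance partitioning, replicated cross-validated prediction,
and a genome-wide mediation scan.  This note records the models, the
defaults and the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Study design assumed throughout

One observation per line per treatment: `n` lines (default 75), two
treatments (`control`, `water_scarce`), four traits (grain yield in
mg ha^-1, thousand kernel weight in g, protein content in % of dry
matter, grain nitrogen uptake in g N m^-2).  Genotypes are per-line
(inbred, homozygous, dosage 0/2); expression is per sample
(line x treatment, composite ids `line:treatment`); methylation is
treated as per-line in the synthetic design (see below).  All omics
matrices are samples x features.

## Quality-control filters

* **SNPs** — three sequential rules, counted at removal time:
  missingness > 20%; monomorphic (zero variance; required because a
  zero-variance column is undefined after centering/scaling); linkage
  disequilibrium r^2 > 0.9.  The LD prune is a greedy left-to-right
  scan in input order within a sliding window of 50 markers
  (`window=0` = all pairs): the later member of an offending pair is
  dropped.  This is deterministic and order-stable; permuting input
  columns can change *which* member of an exactly tied pair survives,
  never how many survive.  r^2 is computed on mean-imputed dosages.
* **Methylation** — a site x sample level is methylated/total reads
  when total >= 5 (below that, the cell is missing); sites observed in
  < 80% of samples are dropped; an optional low-information filter
  removes sites with > 90% zeros or > 20% missing (both thresholds are
  unavoidably a choice; they are arguments, not constants).  Sites
  split into CG/CHG/CHH contexts for context-wise analysis.
* **Expression** — transcripts with median TPM zero AND mean TPM < 1
  are excluded (the conjunction is deliberate; an OR variant sits
  behind `connective="or"`).

## Kernels

K = W W' / p with W the column-centered, column-scaled (sample SD,
n-1 denominator) feature matrix, missing cells imputed to the column
mean (zero after centering), zero-variance columns dropped, and p the
retained feature count.  This is the VanRaden-style additive
relationship matrix for SNP dosages and its direct analogue for
expression and methylation.  Note the exact mean diagonal is
(n-1)/n, not 1, under n-1 scaling.  For expression, the kernel can be
built from a truncated principal-component reconstruction of W
(`pca_var` = fraction of variance retained, default 1.0 = exact
kernel) to de-noise individual profiles; with all components the
kernel is unchanged, and the component count is an open modelling
choice surfaced as an argument.  Kernels whose smallest eigenvalue
falls below -1e-8 are repaired by clipping negative eigenvalues at
zero (logged).

## Baseline mixed model and the scan engine

The descriptive model y_ij = T_j t + l_i + e_ij (fixed treatment,
random line, iid residual) is estimated by REML.  Implementation: the
covariance is diagonalized once per grouping by an eigendecomposition
of ZZ', and beta and sigma_e^2 are profiled out, leaving a
one-dimensional REML/ML criterion in lambda = sigma_l^2/sigma_e^2.

* **Single fits** (`fit_lmm`) minimize with bounded Brent on
  log-lambda in [-16, 16] plus an explicit lambda = 0 boundary check.
  Fixed-effect p-values are likelihood-ratio tests between nested ML
  fits (chi-square, 1 df).  The LRT choice avoids denominator-df
  approximations and is reproducible; it is mildly conservative in the
  extreme tail at n = 150, which the permutation threshold (below)
  automatically absorbs.
* **Genome-wide scans** evaluate the profiled criterion on a fixed
  log-spaced lambda grid (lambda = 0 plus e^-14..e^14, spacing 0.2)
  shared across features — and, inside the permutation null, across
  label permutations — with parabolic refinement of the per-feature
  minimum.  The grid minimum agrees with Brent to ~1e-3 in
  -2 log-likelihood, and grid errors largely cancel in the LRT because
  full and null fits share the grid.  This makes a 20,000-feature scan
  a handful of BLAS passes.
* Degenerate features (zero variance, or collinear with the design in
  path B, detected via the Schur complement falling below 1e-8 of the
  feature's weighted norm) are skipped with p = 1 and flagged, never
  allowed to abort a scan.

## Mediation scan

Paths, per trait and omic layer: C (trait ~ treatment), A (feature ~
treatment), B (trait ~ treatment + feature), all with a random line
effect.  Reported per feature: REML betas, LRT p-values, BH q-values.
A feature is a mediator when its path-B feature term is significant
(BH at 0.05, or the permutation rule) and |beta_treatmentB| <
|beta_treatmentC|.  Path-A significance is informative but not
required for the flag (`strict=True` requires it).  The two-mediator
path is deliberately not implemented: with no detectable methylation
mediation in this design a joint two-mediator model has nothing to
estimate.

Permutation nulls, 1000 permutations each, threshold = 0.05-quantile
of the per-permutation minimum p-values.  What exactly should be
resampled is underdetermined in this kind of design, and the right
answer differs by path.  Path A (treatment -> feature): treatment
labels are swapped (or not, with equal probability) within each line,
preserving the paired design; a free shuffle is available via
`unit="free"`.  Path B (feature -> trait | treatment): label
permutation is *not* a valid null here — the tested feature term is
the feature-trait association, which survives relabelled treatments —
so whole (control, water-scarce) response pairs are reassigned across
lines instead, which preserves the treatment contrast and the pairing
while severing every feature-trait and line-identity link; on
independent null features the resulting threshold reproduces the
Beta(1, m) minimum-order-statistic quantile.  Because each threshold
is a quantile of the *realized* null scan distribution, it calibrates
family-wise error even where the asymptotic LRT tail is imperfect
(verified by the FWER acceptance test: realized FWER in [0.02, 0.09]).

## Multi-kernel Bayesian model

y_ij = mu_j + L_i + u_i + g_ij + m_ij + e_ij with flat priors on the
treatment means, L_i ~ N(0, sigma_L^2), u ~ MVN(0, K_SNP sigma_u^2),
g ~ MVN(0, K_GE sigma_g^2), m ~ MVN(0, K_M sigma_m^2), iid Gaussian
residuals.  Seven nested variants (M_L, M_L,G, M_L,M, M_L,T, M_L,G,M,
M_L,G,T, M_L,G,M,T) select component subsets.  Missing trait values
are excluded from the likelihood, not imputed.

* **Priors** — every variance carries a scaled-inverse chi-square
  prior with 5 prior degrees of freedom.  Prior scales put the prior
  *mode* (df S/(df+2)) of each random component at an equal share of
  R^2 = 0.5 of the phenotypic variance (divided by the kernel's mean
  diagonal), and the residual mode at (1-R^2) var(y) — the convention
  of the standard Bayesian genomic-regression software this model
  family comes from.  With n >= 150 observations the prior carries
  roughly 5/(5+n) of the posterior weight; the single-component
  limiting test quantifies the residual pull (~0.6% at n = 600 lines).
* **Sampling** — each kernel effect is parameterized as
  alpha = U Lam^{1/2} c over *all* kernel rows (eigenvalues <= 1e-10
  truncated), and a second, one-time eigendecomposition of the
  observed design's Gram matrix diagonalizes the full conditional of
  the rotated coefficients, so a Gibbs update costs two matrix-vector
  products for any pattern of missingness or imbalance.  Treatment
  means and line effects use their closed-form Gaussian conditionals;
  variances their scaled-inverse-chi-square conditionals.  Chains are
  bitwise reproducible given the seed.
* **Chain lengths** — full fits default to 30,000 iterations, 5,000
  burn-in, thinning 5 (no convergence guidance exists for this model
  family at this scale beyond inspection; these defaults give ESS in
  the hundreds for every variance in the test problems).  Inside
  cross-validation the package uses 6,000/1,000/5 per fold — the
  posterior means that predictions need stabilize far earlier than
  the variance quantiles — with any override available per
  `ModelSpec`.
* **Prediction** — posterior-mean mu_j plus the stored effect rows for
  the target (line, treatment).  Because alpha is defined over every
  kernel row, lines without phenotypes are predicted through the
  kernel cross-block with zero iid line effect contribution; only
  training phenotypes enter the likelihood (verified bitwise by a
  leakage test).

## Variance partitioning (PV^2)

Per stored draw: the variance attributed to a component is the sample
variance, across phenotyped observations, of the component's realized
values in that draw (treatment uses mu_j mapped to observations);
the residual contribution is the sampled sigma_e^2 itself.  PV^2 is
each contribution over the per-draw total, so the partition sums to
one exactly within every draw; means and SDs are taken over draws.
Using realized values rather than the variance *parameters* makes the
partition invariant to kernel rescaling and lets collinear omics
layers share credit instead of double-counting it — the joint model's
omic PV^2s sum to less than the single-model values when kernels
overlap.  The SNP component's PV^2 is the narrow-sense heritability
estimate.  Pooling both treatments (rather than partitioning within
treatment) is deliberate: line-constant effects have the same variance
either way, and pooling gives the treatment term its variance; a
per-treatment variant would zero the treatment row by construction.

Two estimator properties worth knowing.  First, per-draw realized
variances are non-negative, so small components (notably the treatment
term, whose per-draw variance is the squared sampled mean contrast)
carry an upward bias of roughly the component's posterior sampling
variance; at n = 75 a true 5% treatment share typically reads as
8–13%.  Second, at n = 75–150 observations the iid line effect and the
line-constant kernel effects are only weakly separable (they differ only through the
kernel's off-diagonal structure); their *sum* is well identified.
Recovery tests therefore check per-component fractions at n = 300
lines (±0.10 achieved) and joint line+kernel shares at n = 60.

## Cross-validation

Lines, not observations, are randomized into k = 5 folds (balanced to
±1, deterministic per seed); both treatment records of a held-out line
leave training together.  Kernels are built once on all lines: omics
profiles are predictors and only phenotypes are held out.  The same
fold assignment is reused across model variants within a replicate, so
model contrasts are paired.  Accuracy is the Pearson correlation
between predicted and observed phenotypes pooled across folds within a
replicate, computed separately within each treatment, averaged over
200 replicates (tests and the acceptance script use 20–50 replicates).
Variants are compared by Tukey HSD on the Fisher z-transform of the
per-replicate correlations, treating replicates as independent
observations — they share data, so the letters are descriptive rather
than strictly error-controlled — with a compact letter display.

Caveat worth knowing: pooled CV correlations carry the classic
negative "leave-out-mean" bias for models whose predictions are
constant within a fold.  A pure-noise trait scores ~ -0.25 (not 0)
under the baseline variant at 40–75 lines, and part of any
kernel-vs-baseline gap is this artifact.  The package reports the
procedure's numbers as defined; the null-trait test asserts the
defensible property (no spurious *positive* skill).

## Synthetic data generator

What it emulates: 75 inbred lines x 2 treatments; homozygous biallelic
SNPs (dosage 0/2) in LD blocks (latent Gaussian per block, within-block
correlation 0.8, MAF ~ U(0.05, 0.5), thresholded), with the panel
organized into 4 kinship families sharing a quarter of each block
factor — breeding panels cluster into a handful of relatedness groups,
and without any relatedness cross-line genomic prediction would be
impossible by construction; methylation levels
with bimodal Beta(0.5, 0.5) site baselines and logit-normal line
deviations in three contexts (0.40/0.35/0.25 CG/CHG/CHH); log-normal
TPM expression with a per-gene genetic component (trans-heritability
0.3 via random SNP subsets), ~10% unexpressed transcripts (zero in
most samples, trace values otherwise — the population the median-zero
TPM filter exists to remove) and treatment-responsive mediator genes;
traits assembled from the additive multi-kernel model with *exact*
realized variance fractions (draws are rescaled so sample variances
hit the requested proportions — this makes recovery tests sharp at
small n, at the cost of a slightly non-Gaussian tail in the scaling).
Treatment effect signs default negative (water scarcity lowers yield,
TKW and nitrogen uptake; protein rises).

What it does not emulate: real LD maps and allele-frequency spectra,
read-level noise (a Poisson/binomial count layer exists only for
exercising the coverage filters), methylation-expression coupling,
genotype-by-treatment interaction, and any treatment effect on
methylation (none was detectable in this design, so the synthetic
methylation is a line-level property and K_M is a line kernel; the
model itself accepts per-sample methylation kernels).  Passing tests
demonstrate correctness of the machinery under the assumed generative
model, not biological fidelity.

The causal-chain scenario for mediation gives the mediator genes a
shared latent pathway (treatment effect a = 1.5 on log expression,
shared factor SD 0.8, trait coefficient b = 1.0, direct treatment
effect -0.2), so conditioning on any one mediator proxies the pathway
— the regime in which the attenuation criterion is informative.  The
mediated signal carries well over 30% of trait variance.

## Problem sizes in tests and the acceptance script

Simulation-heavy checks are sized to be decisive yet quick: variance
recovery at 300 lines x 2 with 30,000-iteration chains; FDR/FWER
calibration at 200 replicates (2,000 and 100 features respectively);
CV ordering at 50 replicates with 6,000-iteration per-fold chains; the
acceptance script runs the full pipeline on 75 lines with 1,500 SNPs,
4,000 methylation sites and 3,000 transcripts, 20 CV replicates and
1,000 permutations.  Feature counts scale the kernels' effective rank,
not the estimators, so these sizes exercise the same code paths as a
full-scale experiment.
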