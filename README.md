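# kernomics

Multi-kernel Bayesian multi-omics trait prediction and genome-wide
mediation analysis for small plant panels.

## What this is for

Breeding programs increasingly profile the same lines at several
molecular levels — genome-wide SNPs, the transcriptome, the DNA
methylome — and want to know (i) how much of the variation in complex
agronomic traits each layer explains, (ii) whether adding regulatory
layers to a genomic prediction model buys accuracy, and (iii) whether
individual molecular features *mediate* an environmental effect on the
trait.  `kernomics` implements that full analysis for the hardest
common setting: a small panel (tens of inbred lines) measured once
under each of two contrasting treatments (here: well-watered vs
water-scarce barley).

The core model regresses a trait on treatment plus up to three
kernel-structured random effects:

    y_ij = mu_j + L_i + u_i + g_ij + m_ij + e_ij

with treatment means mu_j (flat priors), iid line effects
L_i ~ N(0, sigma_L^2), and u ~ MVN(0, K_SNP sigma_u^2),
g ~ MVN(0, K_GE sigma_g^2), m ~ MVN(0, K_M sigma_m^2), where each K is
a VanRaden-style similarity matrix K = WW'/p built from the
centered-scaled omics matrix.  Variances carry scaled-inverse-chi^2
priors (5 df) and the model is fitted by Gibbs sampling; seven nested
variants (M_L ... M_L,G,M,T) toggle the omic components.  From the
posterior, the package computes the proportion of phenotypic variance
explained per component (PV^2, per-draw realized-value variances, so
collinear omics share credit), replicated 5-fold cross-validated
within-treatment prediction accuracy with Tukey HSD comparison on
Fisher-z correlations, and a genome-wide three-path mediation scan
(treatment -> trait, treatment -> feature, feature -> trait | treatment)
with BH-FDR and permutation min-p control.

Everything runs against a synthetic-data generator that reproduces the
study design (75 lines x 2 treatments, block-LD SNPs, CG/CHG/CHH
methylation, TPM expression with treatment-responsive genes, traits
with exact user-specified variance fractions), so the whole pipeline is
testable end to end with recorded ground truth.

## Worked example

```python
from kernomics.bayes import ModelSpec, fit_bayesian
from kernomics.kernels import similarity
from kernomics.simulate import (SyntheticTruth, simulate_expression,
                                simulate_genotypes, simulate_methylation,
                                simulate_phenotypes)
from kernomics.variance import pv2

geno = simulate_genotypes(150, 800, seed=1)
meth = simulate_methylation(150, 1000, seed=2)
expr, _ = simulate_expression(150, 800, genotypes=geno, seed=3)
truth = SyntheticTruth(pv2={"treatment": .05, "line": .15, "snp": .30,
                            "meth": .10, "expr": .20, "resid": .20})
pheno = simulate_phenotypes(truth, genotypes=geno, methylation=meth,
                            expression=expr, seed=4)
kernels = {"snp": similarity(geno), "meth": similarity(meth),
           "expr": similarity(expr)}
spec = ModelSpec.variant("LGMT", n_iter=6000, burn_in=1000, thin=5, seed=7)
samples = fit_bayesian(pheno, "grain_yield", kernels, spec)
print(pv2(samples).round(3))
```

prints

```
            mean     sd
treatment  0.051  0.015
line       0.138  0.058
snp        0.279  0.075
meth       0.140  0.052
expr       0.147  0.054
resid      0.245  0.046
```

Each row is the posterior mean (and SD) of the fraction of phenotypic
variance attributed to that model component; the rows sum to one within
every posterior draw.  The trait was simulated with fractions
.05/.15/.30/.10/.20/.20, so the full model recovers the designed
partition to within posterior uncertainty at 150 lines — the `snp` row
is the narrow-sense heritability estimate, and the slight spread
between `meth`/`expr` and their targets reflects the covariance the
three kernels share.

The `examples/` directory holds one short script per capability:
simulating and writing a full dataset, QC filters and kernels, the
mediation scan, variance partitioning across all seven model variants,
and cross-validated model comparison.

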