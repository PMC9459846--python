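"""Synthetic multi-omics datasets with recorded ground truth.

The generator emulates the statistical structure of a small spring
barley panel: ~75 fully homozygous inbred lines grown once under each
of two water treatments, genotyped at a few thousand biallelic SNPs
with block linkage disequilibrium, profiled for cytosine methylation in
three sequence contexts (CG/CHG/CHH) and for TPM-scale gene expression
with a subset of treatment-responsive genes, and phenotyped for four
agronomic traits built from the additive multi-kernel model with
user-specified variance fractions.

Everything is a pure function of its arguments including the seed.
Realized component draws are rescaled so their sample variances hit the
requested proportions exactly, which makes variance-recovery tests
sharp even at n = 75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import CONTEXTS, MethylationCounts, OmicsMatrix, PhenotypeTable, TREATMENTS, sample_id
from .kernels import similarity

PV2_COMPONENTS = ("treatment", "line", "snp", "meth", "expr", "resid")


@dataclass
class SyntheticTruth:
    """Ground-truth generating parameters for one simulated trait."""

    pv2: dict[str, float]
    treatment_effect: float | None = None
    treatment_sign: float = -1.0  # water scarcity lowers most traits
    mediators: list[str] = field(default_factory=list)
    mediator_a: float = 0.0
    mediator_b: float = 0.0
    ld_block: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.pv2) - set(PV2_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown PV2 components {sorted(unknown)}")
        vals = np.array([self.pv2.get(c, 0.0) for c in PV2_COMPONENTS])
        if (vals < 0).any():
            raise ValueError("PV2 fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"PV2 fractions must sum to 1 (got {vals.sum():.6f})")


def _line_ids(n_lines: int) -> list[str]:
    return [f"line_{i + 1:03d}" for i in range(n_lines)]


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block: int = 10,
    r_within: float = 0.8,
    missing_rate: float = 0.0,
    n_families: int = 4,
    family_r: float = 0.25,
    seed: int = 0,
) -> OmicsMatrix:
    """Homozygous 0/2 dosages with block LD and family structure.

    Each block of ``ld_block`` adjacent SNPs shares a latent Gaussian
    factor with within-block correlation ``r_within``; the latent value
    is thresholded at the MAF quantile, so dosage 2 is the minor allele
    (no heterozygotes: inbred lines).  Lines belong to ``n_families``
    relatedness groups (breeding panels cluster into a handful of
    kinship families); ``family_r`` is the share of the block factor
    shared within a family, giving within-family genomic relatedness of
    roughly ``family_r * r_within``.  Set ``n_families=0`` or
    ``family_r=0`` for a fully unstructured panel.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_range {maf_range}")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    n_blocks = int(np.ceil(n_snps / max(ld_block, 1)))
    factors = rng.standard_normal((n_lines, n_blocks))
    if n_families > 0 and family_r > 0:
        fam_of = rng.integers(0, n_families, size=n_lines)
        fam_factors = rng.standard_normal((n_families, n_blocks))
        factors = (
            np.sqrt(family_r) * fam_factors[fam_of]
            + np.sqrt(1.0 - family_r) * factors
        )
    block_of = np.arange(n_snps) // max(ld_block, 1)
    noise = rng.standard_normal((n_lines, n_snps))
    latent = np.sqrt(r_within) * factors[:, block_of] + np.sqrt(1 - r_within) * noise
    from scipy.stats import norm

    dosage = np.where(latent < norm.ppf(maf), 2.0, 0.0)
    if missing_rate > 0:
        mask = rng.random((n_lines, n_snps)) < missing_rate
        dosage = np.where(mask, np.nan, dosage)
    frame = pd.DataFrame(
        dosage,
        index=_line_ids(n_lines),
        columns=[f"snp_{j + 1:05d}" for j in range(n_snps)],
    )
    meta = pd.DataFrame(
        {"chrom": "chr1H", "start": np.arange(n_snps) * 100, "end": np.arange(n_snps) * 100 + 1},
        index=frame.columns,
    )
    return OmicsMatrix(frame, "snp", meta)


def simulate_methylation(
    n_lines: int,
    n_sites: int,
    context_proportions: tuple[float, float, float] = (0.40, 0.35, 0.25),
    line_effect_sd: float = 0.8,
    seed: int = 0,
) -> OmicsMatrix:
    """Per-line methylation proportions in three contexts.

    Site baselines are Beta(0.5, 0.5) (bimodal, as plant cytosine
    methylation is); line deviations are normal on the logit scale.  No
    treatment effect is simulated: in the study design methylation is a
    line-level property.
    """
    rng = np.random.default_rng(seed)
    props = np.asarray(context_proportions, dtype=float)
    props = props / props.sum()
    contexts = rng.choice(list(CONTEXTS), size=n_sites, p=props)
    baseline = rng.beta(0.5, 0.5, size=n_sites)
    baseline = np.clip(baseline, 1e-4, 1 - 1e-4)
    dev = rng.standard_normal((n_lines, n_sites)) * line_effect_sd
    levels = expit(logit(baseline)[None, :] + dev)
    frame = pd.DataFrame(
        levels,
        index=_line_ids(n_lines),
        columns=[f"meth_{j + 1:05d}" for j in range(n_sites)],
    )
    starts = np.arange(n_sites) * 50
    meta = pd.DataFrame(
        {"chrom": "chr2H", "start": starts, "end": starts + 1, "context": contexts},
        index=frame.columns,
    )
    return OmicsMatrix(frame, "methylation", meta)


def methylation_to_counts(
    meth: OmicsMatrix, mean_coverage: float = 20.0, seed: int = 0
) -> MethylationCounts:
    """Long-format read counts whose proportions realize a level matrix.

    Coverage is Poisson around ``mean_coverage``; methylated reads are
    binomial at the site x sample level.  Useful for exercising the
    coverage/presence filters on file-shaped input.
    """
    rng = np.random.default_rng(seed)
    meta = meth.feature_meta
    rows = []
    levels = meth.values.to_numpy()
    n, m = levels.shape
    total = rng.poisson(mean_coverage, size=(n, m))
    methylated = rng.binomial(total, np.clip(levels, 0, 1))
    for j, fid in enumerate(meth.values.columns):
        info = meta.loc[fid]
        for i, sample in enumerate(meth.values.index):
            rows.append(
                (info["chrom"], int(info["start"]), int(info["end"]), info["context"],
                 sample, int(methylated[i, j]), int(total[i, j]))
            )
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "sample", "methylated", "total"]
    )
    return MethylationCounts(frame)


def simulate_expression(
    n_lines: int,
    n_genes: int,
    genotypes: OmicsMatrix | None = None,
    n_mediators: int = 0,
    a: float = 0.0,
    trans_h2: float = 0.3,
    noise_sd: float = 0.6,
    zero_gene_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[OmicsMatrix, list[str]]:
    """TPM-scale expression per sample (line x treatment), with mediators.

    Log-scale expression is a genetic component (linear in a random SNP
    subset per gene, tuned so it carries ``trans_h2`` of the log-scale
    variance), plus a treatment effect ``a`` on ``n_mediators`` genes
    only, plus Gaussian noise; values are exponentiated so TPM >= 0.
    A ``zero_gene_fraction`` of non-mediator genes is essentially off
    (TPM zero in most samples, trace values otherwise), mimicking the
    unexpressed transcripts a real quantification produces.  Returns
    the matrix (rows ``line:treatment``) and the mediator ids.
    """
    rng = np.random.default_rng(seed)
    lines = _line_ids(n_lines)
    samples = [sample_id(l, t) for l in lines for t in TREATMENTS]
    t_ind = np.array([1.0 if s.endswith(TREATMENTS[1]) else 0.0 for s in samples])
    line_rows = np.repeat(np.arange(n_lines), 2)

    base = rng.normal(1.0, 1.5, size=n_genes)
    log_expr = np.tile(base, (len(samples), 1))
    if trans_h2 > 0 and genotypes is not None:
        G = genotypes.values.to_numpy(dtype=float)
        G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
        G = (G - G.mean(axis=0)) / np.where(G.std(axis=0) == 0, 1.0, G.std(axis=0))
        n_causal = min(20, G.shape[1])
        genetic = np.empty((n_lines, n_genes))
        for g in range(n_genes):
            idx = rng.choice(G.shape[1], size=n_causal, replace=False)
            score = G[:, idx] @ rng.standard_normal(n_causal)
            sd = score.std()
            genetic[:, g] = score / (sd if sd > 0 else 1.0)
        log_expr += np.sqrt(trans_h2) * noise_sd / np.sqrt(max(1e-12, 1 - trans_h2)) \
            * genetic[line_rows]
    mediators = [f"gene_{j + 1:05d}" for j in range(min(n_mediators, n_genes))]
    if mediators and a != 0.0:
        log_expr[:, : len(mediators)] += a * t_ind[:, None]
    log_expr += rng.standard_normal(log_expr.shape) * noise_sd
    tpm = np.exp(log_expr)
    if zero_gene_fraction > 0:
        candidates = np.arange(len(mediators), n_genes)
        n_off = int(round(zero_gene_fraction * n_genes))
        off = rng.choice(candidates, size=min(n_off, len(candidates)), replace=False)
        dropout = rng.random((len(samples), len(off))) < 0.9
        trace = np.exp(rng.normal(-2.0, 0.5, size=(len(samples), len(off))))
        tpm[:, off] = np.where(dropout, 0.0, trace)
    frame = pd.DataFrame(
        tpm,
        index=samples,
        columns=[f"gene_{j + 1:05d}" for j in range(n_genes)],
    )
    return OmicsMatrix(frame, "expression"), mediators


def _exact_scale(x: np.ndarray, target_var: float, ddof: int = 1) -> np.ndarray:
    """Center and rescale a draw so its sample variance is exactly target."""
    x = x - x.mean()
    v = x.var(ddof=ddof)
    if v <= 0:
        if target_var == 0:
            return x
        raise ValueError("degenerate draw cannot be scaled to positive variance")
    return x * np.sqrt(target_var / v)


def _mvn_draw(rng, K: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    return U @ (np.sqrt(w) * rng.standard_normal(len(w)))


def simulate_phenotypes(
    truth: SyntheticTruth,
    genotypes: OmicsMatrix | None = None,
    methylation: OmicsMatrix | None = None,
    expression: OmicsMatrix | None = None,
    n_lines: int | None = None,
    trait: str = "grain_yield",
    total_var: float = 1.0,
    seed: int = 0,
    return_components: bool = False,
) -> PhenotypeTable:
    """One trait from the additive multi-kernel model with exact fractions.

    Kernel components are drawn as MVN(0, K) from kernels built on the
    supplied omics matrices and rescaled so each component's realized
    sample variance equals its requested fraction of the total.  When
    ``truth.treatment_effect`` is given explicitly, the total variance is
    implied by that effect and the treatment fraction; otherwise the
    effect magnitude is derived from the fraction (sign from
    ``truth.treatment_sign``) and recorded back onto ``truth``.
    """
    frac = {c: truth.pv2.get(c, 0.0) for c in PV2_COMPONENTS}
    for name, om in (("snp", genotypes), ("meth", methylation), ("expr", expression)):
        if frac[name] > 0 and om is None:
            raise ValueError(f"PV2 fraction for {name!r} > 0 but no matrix supplied")
    if n_lines is None:
        for om in (genotypes, methylation, expression):
            if om is not None:
                ids = om.values.index
                n_lines = len({s.split(":")[0] for s in ids})
                break
        if n_lines is None:
            raise ValueError("n_lines needed when no omics matrix is supplied")
    lines = _line_ids(n_lines)
    rng = np.random.default_rng(seed)

    records = [(l, t) for l in lines for t in TREATMENTS]
    n = len(records)
    t_ind = np.array([1.0 if t == TREATMENTS[1] else 0.0 for _, t in records])
    line_rows = np.repeat(np.arange(n_lines), 2)

    # implied total variance when the treatment effect is explicit
    if truth.treatment_effect is not None:
        if frac["treatment"] <= 0:
            raise ValueError("explicit treatment effect needs a positive treatment fraction")
        var_t = (truth.treatment_effect * (t_ind - t_ind.mean())).var(ddof=1)
        total_var = var_t / frac["treatment"]
        effect = truth.treatment_effect
    else:
        contrast = t_ind - t_ind.mean()
        effect = truth.treatment_sign * np.sqrt(
            frac["treatment"] * total_var / contrast.var(ddof=1)
        ) if frac["treatment"] > 0 else 0.0
        truth.treatment_effect = float(effect)

    components: dict[str, np.ndarray] = {"treatment": effect * t_ind}
    if frac["line"] > 0:
        components["line"] = _exact_scale(
            rng.standard_normal(n_lines)[line_rows], frac["line"] * total_var
        )
    for name, om in (("snp", genotypes), ("meth", methylation), ("expr", expression)):
        if frac[name] <= 0:
            continue
        kern = similarity(om)
        draw = _mvn_draw(rng, kern.K)
        index = pd.Index(kern.sample_ids)
        composite = [sample_id(l, t) for l, t in records]
        if all(c in index for c in composite):
            vals = draw[index.get_indexer(composite)]
        else:
            vals = draw[index.get_indexer([l for l, _ in records])]
        components[name] = _exact_scale(vals, frac[name] * total_var)
    components["resid"] = _exact_scale(rng.standard_normal(n), frac["resid"] * total_var)
    y = np.sum(list(components.values()), axis=0)

    if truth.mediators and truth.mediator_b != 0.0:
        if expression is None:
            raise ValueError("mediator chain requires the expression matrix")
        expr_vals = expression.values
        composite = [sample_id(l, t) for l, t in records]
        sub = np.log(expr_vals.loc[composite, truth.mediators].to_numpy())
        sub = sub - sub.mean(axis=0)
        y = y + truth.mediator_b * sub.mean(axis=1)

    frame = pd.DataFrame(
        {"line": [l for l, _ in records], "treatment": [t for _, t in records], trait: y}
    )
    table = PhenotypeTable(frame)
    if return_components:
        full = {c: components.get(c, np.zeros(n)) for c in PV2_COMPONENTS}
        table.components = full  # realized generating components, obs-aligned
    return table


def simulate_mediation_dataset(
    n_lines: int = 75,
    n_genes: int = 2000,
    n_mediators: int = 20,
    a: float = 1.5,
    b: float = 1.0,
    direct_effect: float = -0.2,
    shared_sd: float = 0.8,
    unique_sd: float = 0.3,
    noise_sd: float = 0.6,
    trait: str = "grain_yield",
    seed: int = 0,
):
    """Causal-chain scenario: treatment -> mediator genes -> trait.

    Mediator genes share a latent per-sample factor (so conditioning on
    any one of them proxies the mediated pathway) and respond to
    treatment with log-scale effect ``a``; the trait is the mediated
    signal times ``b`` plus a small direct treatment effect and noise.
    Returns (phenotypes, expression, mediator ids).
    """
    rng = np.random.default_rng(seed)
    lines = _line_ids(n_lines)
    samples = [sample_id(l, t) for l in lines for t in TREATMENTS]
    n = len(samples)
    t_ind = np.array([1.0 if s.endswith(TREATMENTS[1]) else 0.0 for s in samples])
    line_rows = np.repeat(np.arange(n_lines), 2)

    gene_ids = [f"gene_{j + 1:05d}" for j in range(n_genes)]
    mediator_ids = list(rng.choice(gene_ids, size=n_mediators, replace=False))
    med_mask = np.isin(gene_ids, mediator_ids)

    base = rng.normal(1.0, 1.2, size=n_genes)
    line_dev = rng.standard_normal((n_lines, n_genes)) * 0.4
    log_expr = base[None, :] + line_dev[line_rows]
    shared = rng.standard_normal(n) * shared_sd  # latent mediated pathway
    pathway = a * t_ind + shared
    log_expr[:, med_mask] += pathway[:, None]
    log_expr += rng.standard_normal((n, n_genes)) * unique_sd
    expr = OmicsMatrix(pd.DataFrame(np.exp(log_expr), index=samples, columns=gene_ids),
                       "expression")

    line_eff = rng.standard_normal(n_lines) * 0.4
    y = direct_effect * t_ind + b * pathway + line_eff[line_rows] \
        + rng.standard_normal(n) * noise_sd
    pheno = PhenotypeTable(pd.DataFrame({
        "line": [s.split(":")[0] for s in samples],
        "treatment": [s.split(":")[1] for s in samples],
        trait: y,
    }))
    return pheno, expr, mediator_ids


#: per-trait variance fractions and effect signs for the paper-like preset;
#: the fractions are invented but echo the reported pattern (SNPs strongest,
#: methylation weakest, yield/N-uptake more environment-driven)
PAPER_LIKE_TRAITS = {
    "grain_yield": ({"treatment": 0.05, "line": 0.15, "snp": 0.25, "meth": 0.08,
                     "expr": 0.15, "resid": 0.32}, -1.0),
    "tkw": ({"treatment": 0.03, "line": 0.25, "snp": 0.40, "meth": 0.05,
             "expr": 0.07, "resid": 0.20}, -1.0),
    "protein": ({"treatment": 0.04, "line": 0.30, "snp": 0.30, "meth": 0.05,
                 "expr": 0.10, "resid": 0.21}, 1.0),
    "nitrogen_uptake": ({"treatment": 0.06, "line": 0.15, "snp": 0.20, "meth": 0.10,
                         "expr": 0.15, "resid": 0.34}, -1.0),
}


def make_paper_like_dataset(
    seed: int = 0,
    n_lines: int = 75,
    n_snps: int = 7800,
    n_meth_sites: int = 30000,
    n_genes: int = 20000,
    n_mediators: int = 50,
    mediator_a: float = 1.0,
):
    """Full synthetic study: 75 lines x 2 treatments, four traits.

    Mimics from the study design: the sample sizes (75 lines, two water
    treatments), the SNP count scale (~7k polymorphic markers after QC),
    the three methylation contexts, TPM-scale expression with a minority
    of treatment-responsive genes, and four traits named and signed like
    the agronomic ones.  Invented: the LD landscape, all variance
    fractions (recorded in the returned truths), and every effect size.

    Returns a dict with genotypes, methylation, expression, phenotypes
    (one table with all four traits) and the per-trait truths.
    """
    rng = np.random.default_rng(seed)
    geno = simulate_genotypes(
        n_lines, n_snps, ld_block=10, r_within=0.8, missing_rate=0.05,
        seed=int(rng.integers(2**31 - 1)),
    )
    meth = simulate_methylation(n_lines, n_meth_sites, seed=int(rng.integers(2**31 - 1)))
    expr, mediators = simulate_expression(
        n_lines, n_genes, genotypes=geno, n_mediators=n_mediators, a=mediator_a,
        trans_h2=0.3, seed=int(rng.integers(2**31 - 1)),
    )
    tables = []
    truths = {}
    for trait, (frac, sign) in PAPER_LIKE_TRAITS.items():
        truth = SyntheticTruth(pv2=dict(frac), treatment_sign=sign, seed=seed)
        tab = simulate_phenotypes(
            truth, genotypes=geno, methylation=meth, expression=expr,
            trait=trait, seed=int(rng.integers(2**31 - 1)),
        )
        truths[trait] = truth
        tables.append(tab.data.set_index(["line", "treatment"]))
    pheno = PhenotypeTable(pd.concat(tables, axis=1).reset_index())
    return {
        "genotypes": geno,
        "methylation": meth,
        "expression": expr,
        "phenotypes": pheno,
        "truths": truths,
        "mediators": mediators,
    }
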