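"""Quality-control filters for the three omic layers.

SNPs: drop markers with more than 20% missing calls, drop monomorphic
markers (zero-variance columns are undefined after centering/scaling),
then greedily prune one member of every pair in high linkage
disequilibrium (squared Pearson correlation of dosages > 0.9) within a
sliding window.  Methylation: compute per-site methylation levels
(methylated / total reads) requiring at least 5x coverage per cell and
site presence in at least 80% of samples, then optionally drop sites
dominated by zeros or missing values.  Expression: exclude transcripts
whose median TPM is zero AND whose mean TPM is below 1.

Filters are idempotent and never modify retained values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CONTEXTS, FilterReport, MethylationCounts, OmicsMatrix

log = logging.getLogger(__name__)


def filter_snps(
    geno: OmicsMatrix,
    max_missing: float = 0.20,
    ld_r2: float = 0.9,
    window: int = 50,
) -> tuple[OmicsMatrix, FilterReport]:
    """Missingness, monomorphism and LD filters for a dosage matrix.

    The LD prune is a greedy left-to-right scan in feature (input) order:
    each candidate marker is compared against already-retained markers no
    more than ``window`` input positions to its left, and is dropped when
    any such pair exceeds ``ld_r2`` (the later marker of the pair loses).
    ``window=0`` compares against all retained markers (all-pairs prune).
    r^2 is computed on mean-imputed dosages.
    """
    if geno.omic_kind != "snp":
        raise ValueError("filter_snps expects a SNP matrix")
    values = geno.values
    n_in = values.shape[1]

    miss_frac = values.isna().mean(axis=0)
    keep_missing = miss_frac <= max_missing
    n_missing = int((~keep_missing).sum())
    values = values.loc[:, keep_missing]

    with np.errstate(invalid="ignore"):
        variances = values.var(axis=0, ddof=1)
    keep_poly = variances.fillna(0.0) > 0.0
    n_mono = int((~keep_poly).sum())
    values = values.loc[:, keep_poly]

    # standardize mean-imputed columns once so r^2 is a plain dot product
    arr = values.to_numpy(dtype=float)
    col_mean = np.nanmean(arr, axis=0)
    inds = np.where(np.isnan(arr))
    arr[inds] = np.take(col_mean, inds[1])
    arr -= arr.mean(axis=0)
    norms = np.sqrt((arr**2).sum(axis=0))
    arr /= norms

    kept: list[int] = []
    n_ld = 0
    positions = np.arange(arr.shape[1])
    for j in range(arr.shape[1]):
        if window > 0:
            candidates = [i for i in kept if positions[j] - positions[i] <= window]
        else:
            candidates = kept
        if candidates and np.max((arr[:, candidates].T @ arr[:, j]) ** 2) > ld_r2:
            n_ld += 1
        else:
            kept.append(j)

    values = values.iloc[:, kept]
    if values.shape[1] == 0:
        raise ValueError("no SNPs left after filtering")
    report = FilterReport(
        omic_kind="snp",
        n_features_in=n_in,
        n_features_out=values.shape[1],
        removals={"missingness": n_missing, "monomorphic": n_mono, "ld_prune": n_ld},
    )
    meta = None if geno.feature_meta is None else geno.feature_meta.loc[values.columns]
    return OmicsMatrix(values, "snp", meta), report


def methylation_levels(
    counts: MethylationCounts,
    min_coverage: int = 5,
    min_presence: float = 0.80,
) -> OmicsMatrix:
    """Per-site methylation levels with coverage and presence filters.

    A cell is methylated/total reads where total >= ``min_coverage``,
    missing otherwise; sites observed (non-missing) in fewer than
    ``min_presence`` of the samples are dropped.
    """
    df = counts.data
    if df.empty:
        raise ValueError("empty methylation count table")
    site = counts.site_ids
    level = np.where(df["total"] >= min_coverage, df["methylated"] / df["total"].replace(0, np.nan), np.nan)
    long = pd.DataFrame({"site": site, "sample": df["sample"], "level": level})
    wide = long.pivot_table(
        index="sample", columns="site", values="level", aggfunc="first", dropna=False
    )
    # preserve first-appearance site/sample order from the file
    wide = wide.reindex(index=pd.unique(df["sample"]), columns=pd.unique(site))
    presence = wide.notna().mean(axis=0)
    wide = wide.loc[:, presence >= min_presence]

    meta_rows = df.loc[~site.duplicated(), ["chrom", "start", "end", "context"]].copy()
    meta_rows.index = pd.Index(site[~site.duplicated()])
    meta = meta_rows.reindex(wide.columns)
    return OmicsMatrix(wide, "methylation", meta)


def split_contexts(meth: OmicsMatrix) -> dict[str, OmicsMatrix]:
    """Partition a methylation matrix into CG / CHG / CHH sub-matrices."""
    if meth.omic_kind != "methylation":
        raise ValueError("split_contexts expects a methylation matrix")
    if meth.feature_meta is None or "context" not in meth.feature_meta.columns:
        raise ValueError("methylation features carry no context annotation")
    ctx = meth.feature_meta["context"]
    if ctx.isna().any():
        missing = list(ctx.index[ctx.isna()])[:5]
        raise ValueError(f"features without context: {missing}")
    out = {}
    for c in CONTEXTS:
        cols = ctx.index[ctx == c]
        out[c] = OmicsMatrix(meth.values.loc[:, cols], "methylation", meth.feature_meta.loc[cols])
    return out


def filter_low_information_methylation(
    meth: OmicsMatrix,
    max_zero_fraction: float = 0.9,
    max_missing: float = 0.2,
) -> tuple[OmicsMatrix, FilterReport]:
    """Drop sites with a high proportion of zero or missing levels."""
    if meth.omic_kind != "methylation":
        raise ValueError("expects a methylation matrix")
    values = meth.values
    n_in = values.shape[1]
    zero_frac = (values == 0.0).mean(axis=0)
    miss_frac = values.isna().mean(axis=0)
    drop_zero = zero_frac > max_zero_fraction
    drop_missing = (miss_frac > max_missing) & ~drop_zero  # count each site once
    keep = ~(drop_zero | drop_missing)
    out = meth.subset_features(values.columns[keep])
    report = FilterReport(
        omic_kind="methylation",
        n_features_in=n_in,
        n_features_out=int(keep.sum()),
        removals={"zero_heavy": int(drop_zero.sum()), "missing_heavy": int(drop_missing.sum())},
    )
    return out, report


def filter_expression(
    expr: OmicsMatrix, connective: str = "and"
) -> tuple[OmicsMatrix, FilterReport]:
    """Exclude transcripts with median TPM zero and mean TPM < 1.

    Both statistics are computed over non-missing cells.  The exclusion
    connective is AND by default; ``connective="or"`` excludes on either
    condition alone.
    """
    if expr.omic_kind != "expression":
        raise ValueError("expects an expression matrix")
    values = expr.values
    med = values.median(axis=0, skipna=True)
    mean = values.mean(axis=0, skipna=True)
    if connective == "and":
        drop = (med == 0) & (mean < 1)
    elif connective == "or":
        drop = (med == 0) | (mean < 1)
    else:
        raise ValueError(f"unknown connective {connective!r}")
    out = expr.subset_features(values.columns[~drop])
    report = FilterReport(
        omic_kind="expression",
        n_features_in=values.shape[1],
        n_features_out=int((~drop).sum()),
        removals={"low_expression": int(drop.sum())},
    )
    return out, report
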