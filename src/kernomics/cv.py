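"""Replicated five-fold cross-validation and Tukey HSD model comparison.

Lines (not observations) are randomly assigned to folds, so both
treatment records of a held-out line leave the training set together;
kernels are built once on all lines -- omics profiles of test lines are
legitimate predictors, only their phenotypes are held out.  Prediction
accuracy is the Pearson correlation between predicted and observed
phenotypes, computed separately within the control and water-scarce
test observations of a replicate, and averaged over replicates.

Model variants are compared by a one-way Tukey honest-significant-
difference test on the Fisher z-transform of the per-replicate
correlations, summarized as a compact letter display (models sharing a
letter are not significantly different).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .bayes import ModelSpec, fit_bayesian, predict
from .io import PhenotypeTable, TREATMENTS
from .kernels import SimilarityMatrix

log = logging.getLogger(__name__)


@dataclass
class CVResult:
    """Per-(model, replicate, treatment) accuracies plus summaries."""

    records: pd.DataFrame  # model, replicate, treatment, pearson_r
    trait: str
    k: int
    n_replicates: int

    def mean_accuracy(self) -> pd.DataFrame:
        """Mean Pearson r by (model, treatment), NaN replicates dropped."""
        return (
            self.records.groupby(["model", "treatment"])["pearson_r"]
            .mean()
            .unstack("treatment")
        )


@dataclass
class TukeyGroups:
    """Compact letter display and pairwise adjusted p-values."""

    letters: dict[str, str]  # model -> letter group(s)
    pairwise: pd.DataFrame  # model_a, model_b, mean_diff, p_adj, reject
    alpha: float


def assign_folds(line_ids, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Random balanced partition of lines into k folds (sizes differ by <=1)."""
    lines = list(line_ids)
    if k > len(lines):
        raise ValueError(f"k={k} exceeds the number of lines ({len(lines)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lines))
    folds = {}
    for pos, idx in enumerate(order):
        folds[lines[idx]] = pos % k
    return folds


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing atanh transform; |r| >= 1 - 1e-12 is clipped."""
    arr = np.asarray(r, dtype=float)
    clipped = np.clip(arr, -1 + 1e-12, 1 - 1e-12)
    if np.any(np.abs(arr) > 1 - 1e-12):
        log.info("fisher_z clipped %d correlation(s) at |r| ~ 1", int(np.sum(np.abs(arr) > 1 - 1e-12)))
    out = np.arctanh(clipped)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def run_cv(
    pheno: PhenotypeTable,
    trait: str,
    kernels: dict[str, SimilarityMatrix],
    specs: dict[str, ModelSpec],
    k: int = 5,
    reps: int = 200,
    seed: int = 0,
    min_group: int = 3,
) -> CVResult:
    """Replicated k-fold CV of several model variants on one trait.

    The same fold assignment is reused for every variant within a
    replicate, so accuracies are paired across models.  A replicate x
    treatment cell with fewer than ``min_group`` observed test values is
    recorded as missing.  MCMC chain lengths come from each ``ModelSpec``;
    per-replicate chain seeds are derived deterministically from ``seed``.
    """
    obs = pheno.observations(trait)
    lines = list(pd.unique(obs["line"]))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        chain_seed = int(rng.integers(0, 2**31 - 1))
        folds = assign_folds(lines, k=k, seed=fold_seed)
        preds = {name: pd.Series(index=obs.index, dtype=float) for name in specs}
        for fold in range(k):
            test_lines = {l for l, f in folds.items() if f == fold}
            train_mask = ~obs["line"].isin(test_lines)
            train = PhenotypeTable(
                obs[train_mask].rename(columns={"y": trait}).reset_index(drop=True)
            )
            test = obs[~train_mask]
            targets = list(zip(test["line"], test["treatment"]))
            for name, spec0 in specs.items():
                spec = ModelSpec(
                    components=spec0.components,
                    n_iter=spec0.n_iter,
                    burn_in=spec0.burn_in,
                    thin=spec0.thin,
                    seed=chain_seed + fold,
                    df0=spec0.df0,
                    r2=spec0.r2,
                )
                samples = fit_bayesian(train, trait, kernels, spec)
                preds[name].loc[test.index] = predict(samples, targets)
        for name in specs:
            for treatment in TREATMENTS:
                mask = (obs["treatment"] == treatment) & preds[name].notna()
                y_obs = obs.loc[mask, "y"].to_numpy()
                y_hat = preds[name].loc[mask].to_numpy()
                if len(y_obs) < min_group:
                    log.warning(
                        "replicate %d %s/%s: only %d test observations; accuracy missing",
                        rep, name, treatment, len(y_obs),
                    )
                    r = np.nan
                elif np.std(y_hat) == 0 or np.std(y_obs) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(y_obs, y_hat)[0, 1])
                rows.append(
                    {"model": name, "replicate": rep, "treatment": treatment, "pearson_r": r}
                )
    records = pd.DataFrame(rows)
    return CVResult(records=records, trait=trait, k=k, n_replicates=reps)


def _compact_letters(models: list[str], means: dict[str, float], reject) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a significance map.

    ``reject[(a, b)]`` is True when models a and b differ significantly.
    """
    ordered = sorted(models, key=lambda mdl: -means[mdl])
    groups: list[set[str]] = [set(ordered)]
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if not reject.get((a, b), reject.get((b, a), False)):
                continue
            new_groups = []
            for g in groups:
                if a in g and b in g:
                    new_groups.extend([g - {a}, g - {b}])
                else:
                    new_groups.append(g)
            # absorb subsets
            groups = []
            for g in sorted(new_groups, key=len, reverse=True):
                if g and not any(g <= h for h in groups):
                    groups.append(g)
    groups.sort(key=lambda g: -max(means[mdl] for mdl in g))
    letters = {mdl: "" for mdl in models}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for mdl in g:
            letters[mdl] += letter
    return letters


def tukey_compare(cv: CVResult, treatment: str, alpha: float = 0.05) -> TukeyGroups:
    """Tukey HSD across models on Fisher-z accuracies for one treatment."""
    sub = cv.records[(cv.records["treatment"] == treatment) & cv.records["pearson_r"].notna()]
    models = sorted(sub["model"].unique())
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    counts = sub.groupby("model").size()
    if (counts < 2).any():
        raise ValueError("need at least two replicates per model")
    z = fisher_z(sub["pearson_r"].to_numpy())
    labels = sub["model"].to_numpy()
    within_var = pd.DataFrame({"z": z, "model": labels}).groupby("model")["z"].var(ddof=1)
    if np.allclose(within_var.fillna(0.0), 0.0):
        raise ValueError("zero within-model variance; run more CV replicates")
    res = pairwise_tukeyhsd(z, labels, alpha=alpha)
    uniq = list(res.groupsunique)
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    pairwise = pd.DataFrame(
        {
            "model_a": [a for a, _ in pairs],
            "model_b": [b for _, b in pairs],
            "mean_diff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )
    means = {mdl: float(np.mean(z[labels == mdl])) for mdl in models}
    reject = {
        (row.model_a, row.model_b): bool(row.reject) for row in pairwise.itertuples()
    }
    letters = _compact_letters(models, means, reject)
    return TukeyGroups(letters=letters, pairwise=pairwise, alpha=alpha)
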