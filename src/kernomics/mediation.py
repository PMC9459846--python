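"""Genome-wide three-path mediation scan.

For a trait y, a binary water treatment T and an omic feature f measured
on the same samples, three regressions are fitted, each a linear mixed
model with a random line effect:

* path C:  y ~ T            -- does treatment move the trait?
* path A:  f ~ T            -- does treatment move the feature?
* path B:  y ~ T + f        -- does the feature move the trait once
                               treatment is adjusted for?

A feature is flagged as a mediator when its path-B feature term is
significant (BH-FDR at 0.05, or a permutation min-p threshold) and the
treatment coefficient in path B is attenuated relative to path C in
absolute value (|beta_treatmentB| < |beta_treatmentC|).  Path-A
significance is reported but not required for the flag; ``strict=True``
requires it.  The two-mediator path (D) is intentionally not provided.

Permutation nulls: for path A, treatment labels are shuffled within
line (each line contributes one control and one water-scarce record,
and the paired design is preserved by swapping the two labels of a
line or not, with equal probability).  For path B the null must break
the feature-trait link instead, so whole (control, water-scarce)
response pairs are reassigned across lines.  In both cases the
smallest p-value of each permuted scan is collected and the threshold
is the alpha-quantile of that min-p distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix, PhenotypeTable, TREATMENTS, sample_id
from .lmm import (
    GroupRotation,
    _optimize_lambda,
    fit_lmm,
    scan_feature_design,
    scan_shared_design,
)

_MIN_PERM = 100


@dataclass
class MediationScanResult:
    """Per-feature path A/B statistics plus the scan-level path C fit."""

    trait: str
    table: pd.DataFrame  # feature_id index; beta_A p_A q_A beta_mediatorB p_B q_B beta_treatmentB
    beta_treatmentC: float
    p_C: float
    alpha: float = 0.05
    permutation_threshold_A: float | None = None
    permutation_threshold_B: float | None = None

    def significant_A(self, rule: str = "bh") -> set[str]:
        return self._significant("A", rule)

    def significant_B(self, rule: str = "bh") -> set[str]:
        return self._significant("B", rule)

    def _significant(self, path: str, rule: str) -> set[str]:
        t = self.table
        if rule == "bh":
            mask = t[f"q_{path}"] <= self.alpha
        elif rule == "permutation":
            thr = getattr(self, f"permutation_threshold_{path}")
            if thr is None:
                raise ValueError(f"no permutation threshold computed for path {path}")
            mask = t[f"p_{path}"] < thr
        else:
            raise ValueError(f"unknown rule {rule!r}")
        return set(t.index[mask])


@dataclass
class OverlapSummary:
    """Within-trait path overlaps and cross-trait mediator overlaps."""

    sets: dict[str, dict[str, set[str]]]  # trait -> {A, B, attenuated}
    within_trait: pd.DataFrame = field(default=None)
    cross_trait: pd.DataFrame = field(default=None)


def _treatment_indicator(treatment) -> np.ndarray:
    t = np.asarray(treatment)
    if t.dtype.kind in "OU":
        bad = set(t) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels {sorted(bad)}")
        return (t == "water_scarce").astype(float)
    return t.astype(float)


def _align_omics(omics: OmicsMatrix, lines, treatments) -> np.ndarray:
    """Row of the omics matrix for each (line, treatment) observation.

    Sample ids may be plain line ids (per-line omics) or composite
    ``line:treatment`` ids (per-sample omics).
    """
    index = pd.Index(omics.values.index)
    composite = [sample_id(l, t) for l, t in zip(lines, treatments)]
    if all(c in index for c in composite):
        rows = index.get_indexer(composite)
    else:
        missing = [l for l in set(lines) if l not in index]
        if missing:
            raise ValueError(f"samples not found in omics matrix: {sorted(missing)[:5]}")
        rows = index.get_indexer(lines)
    return omics.values.to_numpy(dtype=float)[rows]


def path_C(pheno: PhenotypeTable, trait: str) -> tuple[float, float]:
    """Treatment effect on the trait: y ~ treatment + (random line)."""
    obs = pheno.observations(trait)
    if set(obs["treatment"]) != set(TREATMENTS):
        raise ValueError("path C needs observations under both treatments")
    t = _treatment_indicator(obs["treatment"])
    X = np.column_stack([np.ones(len(obs)), t])
    fit = fit_lmm(obs["y"], X, obs["line"], term_names=["intercept", "treatment"])
    return fit.beta["treatment"], fit.p_values["treatment"]


class PathAScanEngine:
    """Vectorized path-A scans: every feature regressed on treatment.

    Built once per omics matrix; ``pvalues`` scans one treatment labelling
    and ``min_p_many`` scans a whole batch of permuted labellings at once
    (used by the permutation null).
    """

    def __init__(self, omics: OmicsMatrix, pheno: PhenotypeTable | None = None,
                 lines=None, treatments=None):
        if pheno is not None:
            recs = pheno.data
            lines = recs["line"].to_numpy()
            treatments = recs["treatment"].to_numpy()
        if lines is None or treatments is None:
            # derive from composite sample ids
            parts = [s.split(":") for s in omics.values.index]
            if not all(len(p) == 2 for p in parts):
                raise ValueError("cannot derive (line, treatment) from sample ids; pass pheno")
            lines = np.array([p[0] for p in parts])
            treatments = np.array([p[1] for p in parts])
        self.lines = np.asarray(lines)
        self.treatments = np.asarray(treatments)
        Y = _align_omics(omics, self.lines, self.treatments)
        self.feature_ids = list(omics.values.columns)
        self.n, self.m = Y.shape
        if np.isnan(Y).any():
            col_mean = np.nanmean(np.where(np.isnan(Y), np.nan, Y), axis=0)
            inds = np.where(np.isnan(Y))
            Y = Y.copy()
            Y[inds] = np.take(col_mean, inds[1])
        self.constant = Y.std(axis=0) == 0.0
        self.rot = GroupRotation(self.lines)
        self.Yr = self.rot.rotate(Y)
        ones = np.ones((self.n, 1))
        self.ones_r = self.rot.rotate(ones)
        # null model f ~ 1 + (line): independent of treatment labels
        self.crit_null, _, _ = scan_shared_design(self.Yr, self.ones_r, self.rot.d, reml=False)

    def scan(self, treatment=None) -> pd.DataFrame:
        """beta_A (REML) and LRT p_A per feature for one labelling."""
        t = _treatment_indicator(self.treatments if treatment is None else treatment)
        X = np.column_stack([np.ones(self.n), t])
        Xr = self.rot.rotate(X)
        crit_full, _, _ = scan_shared_design(self.Yr, Xr, self.rot.d, reml=False)
        _, _, beta = scan_shared_design(self.Yr, Xr, self.rot.d, reml=True)
        lrt = np.maximum(self.crit_null - crit_full, 0.0)
        p = stats.chi2.sf(lrt, df=1)
        p = np.where(self.constant, 1.0, p)
        beta_A = np.where(self.constant, 0.0, beta[1])
        return pd.DataFrame({"beta_A": beta_A, "p_A": p}, index=self.feature_ids)

    def pvalues(self, treatment) -> np.ndarray:
        return self.scan(treatment)["p_A"].to_numpy()

    def min_p_many(self, label_matrix: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Smallest path-A p-value for each column of permuted labels.

        ``label_matrix`` is (n, P) of 0/1 treatment indicators.  Fully
        vectorized over the shared lambda grid, features and permutation
        chunks.
        """
        from .lmm import LAM_GRID, _grid_xs, _parabolic_min, _weights

        T = np.asarray(label_matrix, dtype=float)
        n, P = T.shape
        m = self.m
        Y, Yr = None, self.Yr
        Tr = self.rot.rotate(T)
        onesr = self.ones_r[:, 0]
        d = self.rot.d
        L = len(LAM_GRID)
        xs = _grid_xs()
        Y2 = Yr**2
        out = np.empty(P)
        for lo in range(0, P, chunk):
            hi = min(lo + chunk, P)
            Tc = Tr[:, lo:hi]  # (n, Pc)
            Pc = hi - lo
            crit = np.empty((L, Pc, m))
            for k, lam in enumerate(LAM_GRID):
                w = _weights(lam, d)
                wY = Yr * w[:, None]
                S0 = float(w @ (onesr**2))
                So1 = Tc.T @ (w * onesr)  # (Pc,)
                Stt = ((Tc**2) * w[:, None]).sum(axis=0)  # (Pc,)
                q0 = onesr @ wY  # (m,)
                q1 = Tc.T @ wY  # (Pc, m)
                yWy = w @ Y2  # (m,)
                det = S0 * Stt - So1**2
                det = np.where(np.abs(det) < 1e-12, np.nan, det)
                b0 = (Stt[:, None] * q0[None, :] - So1[:, None] * q1) / det[:, None]
                b1 = (S0 * q1 - So1[:, None] * q0[None, :]) / det[:, None]
                rss = np.maximum(yWy[None, :] - b0 * q0[None, :] - b1 * q1, 1e-300)
                ldet = float(np.log1p(lam * d).sum())
                crit[k] = n * np.log(rss / n) + ldet
            fmin, _ = _parabolic_min(xs, crit.reshape(L, Pc * m))
            crit_full = fmin.reshape(Pc, m) + n * (1.0 + np.log(2.0 * np.pi))
            lrt = np.maximum(self.crit_null[None, :] - crit_full, 0.0)
            pvals = stats.chi2.sf(lrt, df=1)
            pvals[:, self.constant] = 1.0
            pvals = np.where(np.isnan(pvals), 1.0, pvals)
            out[lo:hi] = pvals.min(axis=1)
        return out


class PathBScanEngine:
    """Batched path-B permutation scans: y ~ treatment + feature + (line).

    Holds the rotated response and feature matrix once; ``min_p_many``
    evaluates the feature-term LRT p-value for every (permutation,
    feature) pair on the shared lambda grid with a streaming parabolic
    minimum, so a 1000-permutation null over thousands of features is a
    few dozen BLAS passes.  Only ML criteria are computed (the
    permutation null needs p-values, not coefficient estimates).
    """

    def __init__(self, pheno: PhenotypeTable, trait: str, omics: OmicsMatrix):
        obs = pheno.observations(trait)
        self.lines = obs["line"].to_numpy()
        self.treatments = obs["treatment"].to_numpy()
        y = obs["y"].to_numpy(dtype=float)
        F = _align_omics(omics, self.lines, self.treatments)
        if np.isnan(F).any():
            col_mean = np.nanmean(F, axis=0)
            inds = np.where(np.isnan(F))
            F[inds] = np.take(col_mean, inds[1])
        self.rot = GroupRotation(self.lines)
        self.n, self.m = F.shape
        self.yr = self.rot.rotate(y)
        self.Fr = self.rot.rotate(F)
        self.ones_r = self.rot.rotate(np.ones(self.n))

    def pvalues(self, treatment) -> np.ndarray:
        """Feature-term p-values for one treatment labelling."""
        t = _treatment_indicator(treatment)
        return self._pvalues_chunk(self.rot.rotate(t[:, None]))[0]

    def min_p_many(self, label_matrix: np.ndarray, chunk: int = 128) -> np.ndarray:
        """Smallest path-B p-value per column of permuted 0/1 labels."""
        T = np.asarray(label_matrix, dtype=float)
        Tr = self.rot.rotate(T)
        P = T.shape[1]
        out = np.empty(P)
        for lo in range(0, P, chunk):
            pvals = self._pvalues_chunk(Tr[:, lo:lo + chunk])
            out[lo:lo + pvals.shape[0]] = pvals.min(axis=1)
        return out

    def permutation_threshold(self, n_perm: int = 1000, alpha: float = 0.05,
                              seed: int = 0, chunk: int = 128) -> float:
        """Min-p threshold from a line-permutation null of the response.

        Treatment-label permutation cannot serve as the path-B null: the
        feature term tests the feature-trait association, which survives
        relabelled treatments.  Instead each permutation reassigns whole
        (control, water-scarce) response pairs across lines, preserving
        the treatment contrast and the paired structure while breaking
        every feature-trait and line-identity link.
        """
        if n_perm < _MIN_PERM:
            raise ValueError(f"n_perm must be >= {_MIN_PERM}")
        rng = np.random.default_rng(seed)
        t = _treatment_indicator(self.treatments)
        uniq, codes = np.unique(self.lines, return_inverse=True)
        q = len(uniq)
        # observation slots per (line, treatment-arm)
        slot = {}
        for i, (c, tv) in enumerate(zip(codes, t)):
            slot[(c, tv)] = i
        if len(slot) != 2 * q:
            raise ValueError(
                "response permutation requires both treatment records per line"
            )
        y = self.rot.Q @ self.yr  # un-rotated response
        min_p = np.empty(n_perm)
        for lo in range(0, n_perm, chunk):
            hi = min(lo + chunk, n_perm)
            cols = []
            for _ in range(lo, hi):
                perm = rng.permutation(q)
                y_perm = np.empty_like(y)
                for c in range(q):
                    for tv in (0.0, 1.0):
                        y_perm[slot[(c, tv)]] = y[slot[(perm[c], tv)]]
                cols.append(y_perm)
            Yc = self.rot.rotate(np.column_stack(cols))
            pvals = self._pvalues_chunk_response(Yc, self.rot.rotate(t))
            min_p[lo:hi] = pvals.min(axis=1)
        return float(np.quantile(min_p, alpha))

    def _pvalues_chunk_response(self, Yc: np.ndarray, tr: np.ndarray) -> np.ndarray:
        """(P, m) ML-LRT p-values for permuted rotated responses, fixed t."""
        from .lmm import LAM_GRID, RollingGridMin, _weights

        n = self.n
        d = self.rot.d
        Fr, er = self.Fr, self.ones_r
        F2 = Fr**2
        P = Yc.shape[1]
        full = RollingGridMin((P, self.m))
        null = RollingGridMin((P,))
        aliased = np.zeros(self.m, dtype=bool)
        for lam in LAM_GRID:
            w = _weights(lam, d)
            ldet = float(np.log1p(lam * d).sum())
            wF = Fr * w[:, None]
            a11 = float(w @ (er**2))
            a1t = float((w * er) @ tr)
            att = float(w @ (tr**2))
            C1 = er @ wF  # (m,)
            Ctv = tr @ wF  # (m,)
            fWf = (w[:, None] * F2).sum(axis=0)
            wY = Yc * w[:, None]  # (n, P)
            b1 = er @ wY  # (P,)
            bt = tr @ wY  # (P,)
            bf = wF.T @ Yc  # (m, P) -- dominant matmul
            yWy = (w[:, None] * Yc**2).sum(axis=0)  # (P,)
            det = a11 * att - a1t**2
            if abs(det) < 1e-12:
                continue
            i00, i01, i11 = att / det, -a1t / det, a11 / det
            quad0 = i00 * b1**2 + 2.0 * i01 * b1 * bt + i11 * bt**2
            rss0 = np.maximum(yWy - quad0, 1e-300)
            null.update(n * np.log(rss0 / n) + ldet)
            Ac1 = i00 * C1 + i01 * Ctv  # (m,)
            Ac2 = i01 * C1 + i11 * Ctv
            s = fWf - (C1 * Ac1 + Ctv * Ac2)
            bad = s <= 1e-8 * np.maximum(fWf, 1e-300)
            aliased |= bad
            s_safe = np.where(bad, 1.0, s)
            beta_f = (bf - (Ac1[:, None] * b1[None, :] + Ac2[:, None] * bt[None, :])) \
                / s_safe[:, None]  # (m, P)
            rss = np.maximum(rss0[None, :] - s_safe[:, None] * beta_f**2, 1e-300)
            crit = (n * np.log(rss / n) + ldet).T  # (P, m)
            full.update(np.where(bad[None, :], np.inf, crit))
        lrt = np.maximum(null.finish()[:, None] - full.finish(), 0.0)
        pvals = stats.chi2.sf(lrt, df=1)
        return np.where(aliased[None, :] | ~np.isfinite(lrt), 1.0, pvals)

    def _pvalues_chunk(self, Tc: np.ndarray) -> np.ndarray:
        """(Pc, m) ML-LRT p-values for a chunk of rotated label columns."""
        from .lmm import LAM_GRID, RollingGridMin, _weights

        n = self.n
        d = self.rot.d
        yr, Fr, er = self.yr, self.Fr, self.ones_r
        F2 = Fr**2
        Pc = Tc.shape[1]
        full = RollingGridMin((Pc, self.m))
        null = RollingGridMin((Pc,))
        aliased = np.zeros((Pc, self.m), dtype=bool)
        for lam in LAM_GRID:
            w = _weights(lam, d)
            ldet = float(np.log1p(lam * d).sum())
            wF = Fr * w[:, None]  # (n, m)
            a11 = float(w @ (er**2))
            a1t = Tc.T @ (w * er)  # (Pc,)
            att = ((Tc**2) * w[:, None]).sum(axis=0)  # (Pc,)
            C1 = er @ wF  # (m,)
            Ct = Tc.T @ wF  # (Pc, m)  -- dominant matmul
            fWf = (w[:, None] * F2).sum(axis=0)  # (m,)
            b1 = float((w * er) @ yr)
            bt = Tc.T @ (w * yr)  # (Pc,)
            bf = (w * yr) @ Fr  # (m,)
            yWy = float(w @ (yr**2))
            det = a11 * att - a1t**2
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            i00 = att / det
            i01 = -a1t / det
            i11 = a11 / det
            # null model y ~ [1, t] + (line)
            quad0 = i00 * b1**2 + 2.0 * i01 * b1 * bt + i11 * bt**2  # (Pc,)
            rss0 = np.maximum(yWy - quad0, 1e-300)
            null.update(n * np.log(rss0 / n) + ldet)
            # full model adds the feature column via the Schur complement
            Ac1 = i00[:, None] * C1[None, :] + i01[:, None] * Ct  # (Pc, m)
            Ac2 = i01[:, None] * C1[None, :] + i11[:, None] * Ct
            s = fWf[None, :] - (C1[None, :] * Ac1 + Ct * Ac2)
            bad = s <= 1e-8 * np.maximum(fWf[None, :], 1e-300)
            aliased |= bad
            s_safe = np.where(bad, 1.0, s)
            beta_f = (bf[None, :] - (Ac1 * b1 + Ac2 * bt[:, None])) / s_safe
            rss = np.maximum(rss0[:, None] - s_safe * beta_f**2, 1e-300)
            crit = n * np.log(rss / n) + ldet
            full.update(np.where(bad, np.inf, crit))
        lrt = np.maximum(null.finish()[:, None] - full.finish(), 0.0)
        pvals = stats.chi2.sf(lrt, df=1)
        return np.where(aliased | ~np.isfinite(lrt), 1.0, pvals)


def path_A_scan(omics: OmicsMatrix, pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-feature treatment effect: feature ~ treatment + (random line)."""
    return PathAScanEngine(omics, pheno).scan()


def path_B_scan(pheno: PhenotypeTable, trait: str, omics: OmicsMatrix,
                treatment=None) -> pd.DataFrame:
    """Per-feature trait model: y ~ treatment + feature + (random line).

    Returns beta_mediatorB, p_B (LRT on the feature term), beta_treatmentB
    and an ``aliased`` flag (features collinear with the design are skipped
    with p_B = 1).
    """
    obs = pheno.observations(trait)
    lines = obs["line"].to_numpy()
    treatments = obs["treatment"].to_numpy()
    y = obs["y"].to_numpy(dtype=float)
    F = _align_omics(omics, lines, treatments)
    if np.isnan(F).any():
        col_mean = np.nanmean(F, axis=0)
        inds = np.where(np.isnan(F))
        F[inds] = np.take(col_mean, inds[1])
    t = _treatment_indicator(treatment if treatment is not None else treatments)
    n = len(y)
    rot = GroupRotation(lines)
    X0 = np.column_stack([np.ones(n), t])
    X0r = rot.rotate(X0)
    yr = rot.rotate(y)
    Fr = rot.rotate(F)
    crit_full, _, _, aliased = scan_feature_design(yr, X0r, Fr, rot.d, reml=False)
    _, crit_null = _optimize_lambda(rot.d, yr, X0r, reml=False)
    _, _, beta, _ = scan_feature_design(yr, X0r, Fr, rot.d, reml=True)
    lrt = np.maximum(crit_null - crit_full, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    p = np.where(aliased | ~np.isfinite(crit_full), 1.0, p)
    return pd.DataFrame(
        {
            "beta_mediatorB": np.where(aliased, 0.0, beta[2]),
            "p_B": p,
            "beta_treatmentB": np.where(aliased, np.nan, beta[1]),
            "aliased": aliased,
        },
        index=omics.values.columns,
    )


def bh_adjust(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance calls."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    significant, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, significant


def _within_line_permutations(lines, t, n_perm, rng) -> np.ndarray:
    """(n, n_perm) 0/1 labels with treatment swapped or not within line."""
    lines = np.asarray(lines)
    t = np.asarray(t, dtype=float)
    uniq, codes = np.unique(lines, return_inverse=True)
    flips = rng.integers(0, 2, size=(len(uniq), n_perm)).astype(float)
    F = flips[codes]  # (n, n_perm)
    return np.where(F == 1.0, 1.0 - t[:, None], t[:, None])


def _free_permutations(t, n_perm, rng) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.empty((len(t), n_perm))
    for j in range(n_perm):
        out[:, j] = rng.permutation(t)
    return out


def permutation_threshold(
    scan_fn,
    labels,
    line_ids,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    unit: str = "within_line",
) -> float:
    """alpha-quantile of per-permutation minimum p-values.

    ``scan_fn`` maps a permuted 0/1 treatment vector to a vector of
    p-values; objects exposing ``min_p_many`` (e.g. ``PathAScanEngine``)
    are batched for speed.  ``unit`` is ``"within_line"`` (swap the two
    labels of a line, preserving the paired design) or ``"free"``.
    """
    if n_perm < _MIN_PERM:
        raise ValueError(f"n_perm must be >= {_MIN_PERM}")
    t = _treatment_indicator(labels)
    rng = np.random.default_rng(seed)
    if unit == "within_line":
        T = _within_line_permutations(line_ids, t, n_perm, rng)
    elif unit == "free":
        T = _free_permutations(t, n_perm, rng)
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    if hasattr(scan_fn, "min_p_many"):
        min_p = scan_fn.min_p_many(T)
    else:
        min_p = np.array([np.min(scan_fn(T[:, j])) for j in range(n_perm)])
    return float(np.quantile(min_p, alpha))


def run_mediation_scan(
    pheno: PhenotypeTable,
    trait: str,
    omics: OmicsMatrix,
    alpha: float = 0.05,
    n_perm: int = 0,
    seed: int = 0,
) -> MediationScanResult:
    """Full three-path scan for one trait and one omic layer.

    BH q-values are always computed; permutation min-p thresholds for
    paths A and B are added when ``n_perm`` >= 100 (0 disables them).
    """
    beta_C, p_C = path_C(pheno, trait)
    engine = PathAScanEngine(omics, pheno)
    a_tab = engine.scan()
    b_tab = path_B_scan(pheno, trait, omics)
    table = a_tab.join(b_tab)
    table["q_A"], _ = bh_adjust(table["p_A"].to_numpy(), alpha)
    table["q_B"], _ = bh_adjust(table["p_B"].to_numpy(), alpha)
    result = MediationScanResult(
        trait=trait,
        table=table[
            ["beta_A", "p_A", "q_A", "beta_mediatorB", "p_B", "q_B", "beta_treatmentB", "aliased"]
        ],
        beta_treatmentC=beta_C,
        p_C=p_C,
        alpha=alpha,
    )
    if n_perm:
        obs = pheno.observations(trait)
        t = _treatment_indicator(obs["treatment"])
        result.permutation_threshold_A = permutation_threshold(
            engine, t, obs["line"].to_numpy(), n_perm=n_perm, alpha=alpha, seed=seed
        )
        b_engine = PathBScanEngine(pheno, trait, omics)
        result.permutation_threshold_B = b_engine.permutation_threshold(
            n_perm=n_perm, alpha=alpha, seed=seed + 1
        )
    return result


def classify_mediators(result: MediationScanResult, rule: str = "bh",
                       strict: bool = False) -> set[str]:
    """Features significant on path B whose path-B treatment coefficient is
    attenuated below |beta_treatmentC|; ``strict`` additionally requires
    path-A significance."""
    sig_b = result.significant_B(rule)
    t = result.table
    atten = set(t.index[np.abs(t["beta_treatmentB"]) < abs(result.beta_treatmentC)])
    out = sig_b & atten
    if strict:
        out &= result.significant_A(rule)
    return out


def overlap_summary(scans: dict[str, MediationScanResult], rule: str = "bh") -> OverlapSummary:
    """Within-trait path overlaps and cross-trait mediator overlaps."""
    if not scans:
        raise ValueError("need at least one scan")
    sets = {}
    rows = []
    for trait, res in scans.items():
        A = res.significant_A(rule)
        B = res.significant_B(rule)
        t = res.table
        att = set(t.index[np.abs(t["beta_treatmentB"]) < abs(res.beta_treatmentC)]) & B
        sets[trait] = {"A": A, "B": B, "attenuated": att}
        rows.append(
            {
                "trait": trait,
                "n_A": len(A),
                "n_B": len(B),
                "n_attenuated": len(att),
                "n_A_and_B": len(A & B),
                "n_A_and_att": len(A & att),
                "n_A_B_att": len(A & B & att),
                "n_A_or_B": len(A | B),
            }
        )
    within = pd.DataFrame(rows).set_index("trait")
    traits = list(scans)
    cross_rows = []
    for i, ta in enumerate(traits):
        for tb in traits[i + 1:]:
            med_a = sets[ta]["attenuated"]
            med_b = sets[tb]["attenuated"]
            cross_rows.append({"trait_a": ta, "trait_b": tb, "n_shared": len(med_a & med_b)})
    cross = pd.DataFrame(cross_rows)
    return OverlapSummary(sets=sets, within_trait=within, cross_trait=cross)


def path_D(*args, **kwargs):
    """Two-mediator chain (methylation -> expression -> trait)."""
    raise NotImplementedError(
        "the two-mediator path (D) is not implemented: no significant "
        "methylation mediation was detectable in this design, so a joint "
        "two-mediator model is not supported"
    )
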