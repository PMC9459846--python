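"""Multi-kernel Bayesian linear mixed model fitted by Gibbs sampling.

The model for the phenotype of line i under water treatment j is

    y_ij = mu_j + L_i + u_i + g_ij + m_ij + e_ij

with flat priors on the two treatment means mu_j, iid line effects
L_i ~ N(0, sigma_L^2), kernel-structured effects u ~ MVN(0, K_SNP
sigma_u^2), g ~ MVN(0, K_GE sigma_g^2), m ~ MVN(0, K_M sigma_m^2) and
iid residuals.  Every variance parameter carries a scaled-inverse
chi-square prior with 5 prior degrees of freedom; prior scales follow
the convention of putting the prior mode of each random component at an
equal share of half the phenotypic variance (see docs).  Seven nested
variants (M_L ... M_L,G,M,T) are obtained by choosing the component
subset.

Kernel effects are sampled in an orthogonalized coordinate system: with
K = U Lam U' (eigenvalues below 1e-10 truncated) the effect is
alpha = U Lam^{1/2} c with c ~ N(0, sigma^2 I), and a second fixed
eigendecomposition of the observed design Gram matrix makes the full
conditional of the rotated coefficients diagonal, so one Gibbs update
costs two matrix-vector products regardless of how unbalanced the
design is.  Because alpha is defined over every kernel row -- including
lines with no phenotype -- cross-validation predictions for held-out
lines come directly from the posterior mean of alpha at their rows,
using only training phenotypes (the K cross-block extension).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhenotypeTable, TREATMENTS, sample_id
from .kernels import SimilarityMatrix

#: model variant -> component subset (paper's M_L .. M_L,G,M,T ladder)
MODEL_VARIANTS = {
    "L": ("line",),
    "LG": ("line", "snp"),
    "LM": ("line", "meth"),
    "LT": ("line", "expr"),
    "LGM": ("line", "snp", "meth"),
    "LGT": ("line", "snp", "expr"),
    "LGMT": ("line", "snp", "meth", "expr"),
}

EIG_TOL = 1e-10


@dataclass
class ModelSpec:
    """Component subset, chain settings and priors for one model variant."""

    components: tuple[str, ...] = ("line",)
    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    df0: float = 5.0
    r2: float = 0.5  # total prior R^2 split equally among random components

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.df0 <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        known = {"line", "snp", "meth", "expr"}
        unknown = set(self.components) - known
        if unknown:
            raise ValueError(f"unknown component(s) {sorted(unknown)}")

    @classmethod
    def variant(cls, name: str, **kwargs) -> "ModelSpec":
        """Spec for a named variant: L, LG, LM, LT, LGM, LGT or LGMT."""
        if name not in MODEL_VARIANTS:
            raise KeyError(f"unknown model variant {name!r}; have {list(MODEL_VARIANTS)}")
        return cls(components=MODEL_VARIANTS[name], **kwargs)

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Stored Gibbs draws for one fitted model variant."""

    spec: ModelSpec
    treatments: tuple[str, str]
    mu: np.ndarray  # (S, 2)
    sigma2: dict[str, np.ndarray]  # component/"resid" -> (S,)
    line_ids: list[str]
    line_draws: np.ndarray  # (S, n_lines)
    kernel_draws: dict[str, np.ndarray]  # component -> (S, n_kernel_rows)
    kernel_ids: dict[str, list[str]]
    obs: pd.DataFrame  # line, treatment, y used in the fit
    loglik: np.ndarray  # (S,) Gaussian data log-likelihood trace

    @property
    def n_stored(self) -> int:
        return self.mu.shape[0]

    def component_values(self, component: str) -> np.ndarray:
        """Realized per-observation values of one component, (S, n_obs)."""
        if component == "treatment":
            j = (self.obs["treatment"].to_numpy() == self.treatments[1]).astype(int)
            return self.mu[:, j]
        if component == "line":
            idx = pd.Index(self.line_ids).get_indexer(self.obs["line"])
            return self.line_draws[:, idx]
        if component in self.kernel_draws:
            rows = _kernel_rows(self.kernel_ids[component], self.obs["line"], self.obs["treatment"])
            return self.kernel_draws[component][:, rows]
        raise KeyError(f"no realized values stored for component {component!r}")


def _kernel_rows(kernel_ids, lines, treatments) -> np.ndarray:
    """Kernel row index for each observation (composite id wins over line id)."""
    index = pd.Index(kernel_ids)
    composite = [sample_id(l, t) for l, t in zip(lines, treatments)]
    if all(c in index for c in composite):
        return index.get_indexer(composite)
    rows = index.get_indexer(lines)
    if (rows < 0).any():
        missing = sorted(set(np.asarray(lines)[rows < 0]))[:5]
        raise ValueError(f"lines absent from kernel: {missing}")
    return rows


class _KernelComponent:
    """Per-kernel sampling state: orthogonalized coordinates and maps."""

    def __init__(self, name: str, kernel: SimilarityMatrix, lines, treatments):
        self.name = name
        self.ids = list(kernel.sample_ids)
        K = kernel.K
        w, U = np.linalg.eigh(K)
        if w.min() < -1e-6:
            raise ValueError(
                f"kernel {name!r} has negative eigenvalue {w.min():.3g}; "
                "repair it in the kernels module first"
            )
        keep = w > EIG_TOL
        self.map_all = U[:, keep] * np.sqrt(np.clip(w[keep], 0, None))  # rows -> alpha
        rows = _kernel_rows(self.ids, lines, treatments)
        B = self.map_all[rows]
        G = B.T @ B
        S, V = np.linalg.eigh(G)
        self.S = np.clip(S, 0.0, None)
        self.BV = B @ V  # (n_obs, r)
        self.MV = self.map_all @ V  # (n_rows, r)
        self.r = self.S.shape[0]
        self.e = np.zeros(self.r)  # rotated coefficients, prior N(0, sigma^2 I)
        self.values_obs = np.zeros(B.shape[0])

    def gibbs_update(self, resid, sigma2_e, sigma2_c, rng):
        """Sample rotated coefficients from their diagonal full conditional."""
        t = self.BV.T @ resid  # residual here excludes this component
        prec = self.S / sigma2_e + 1.0 / sigma2_c
        mean = t / sigma2_e / prec
        self.e = mean + rng.standard_normal(self.r) / np.sqrt(prec)
        self.values_obs = self.BV @ self.e
        return self.values_obs

    @property
    def alpha(self) -> np.ndarray:
        return self.MV @ self.e


def _scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    """Draw sigma^2 ~ ScInvChi2: scale_sum / chi2(df)."""
    return scale_sum / rng.chisquare(df)


def fit_bayesian(
    pheno: PhenotypeTable,
    trait: str,
    kernels: dict[str, SimilarityMatrix],
    spec: ModelSpec,
) -> PosteriorSamples:
    """Run the Gibbs sampler for one trait and one model variant.

    ``kernels`` maps component names ("snp", "expr", "meth") to
    similarity matrices; only components named in ``spec.components``
    are used.  Missing trait values are dropped from the likelihood.
    The chain is fully reproducible given ``spec.seed``.
    """
    obs = pheno.observations(trait)
    n = len(obs)
    if n < 10:
        raise ValueError(f"trait {trait!r} has only {n} non-missing observations")
    y = obs["y"].to_numpy(dtype=float)
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("phenotype has zero variance; nothing to model")
    lines = obs["line"].to_numpy()
    treats = obs["treatment"].to_numpy()
    t_codes = (treats == TREATMENTS[1]).astype(int)
    n_by_t = np.bincount(t_codes, minlength=2).astype(float)
    if (n_by_t == 0).any():
        raise ValueError("need observations under both treatments")

    kernel_names = [c for c in spec.components if c != "line"]
    missing = [c for c in kernel_names if c not in kernels]
    if missing:
        raise ValueError(f"spec names kernel component(s) {missing} not supplied")
    comps = [_KernelComponent(c, kernels[c], lines, treats) for c in kernel_names]

    line_index = pd.Index(pd.unique(lines))
    line_codes = line_index.get_indexer(lines)
    q_lines = len(line_index)
    n_by_line = np.bincount(line_codes, minlength=q_lines).astype(float)

    rng = np.random.default_rng(spec.seed)
    df0 = spec.df0
    has_line = "line" in spec.components
    n_rand = int(has_line) + len(comps)
    if n_rand == 0:
        raise ValueError("model needs at least one random component")
    # prior modes: equal split of r2 * var(y) among random components,
    # (1 - r2) * var(y) for the residual; mode(df, S) = df*S/(df+2)
    def scale_from_mode(mode):
        return mode * (df0 + 2.0) / df0

    s0 = {}
    if has_line:
        s0["line"] = scale_from_mode(spec.r2 * vy / n_rand)
    for c in comps:
        mean_diag = float(np.mean((c.map_all**2).sum(axis=1)))
        s0[c.name] = scale_from_mode(spec.r2 * vy / n_rand / max(mean_diag, 1e-12))
    s0_resid = scale_from_mode((1.0 - spec.r2) * vy)

    # initial state
    mu = np.array([y[t_codes == 0].mean(), y[t_codes == 1].mean()])
    line_eff = np.zeros(q_lines)
    sigma2 = {"resid": (1.0 - spec.r2) * vy}
    if has_line:
        sigma2["line"] = spec.r2 * vy / n_rand
    for c in comps:
        sigma2[c.name] = spec.r2 * vy / n_rand
    resid = y - mu[t_codes]

    S_stored = spec.n_stored
    if S_stored < 1:
        raise ValueError("chain settings store no draws")
    out_mu = np.empty((S_stored, 2))
    out_sigma2 = {k: np.empty(S_stored) for k in sigma2}
    out_line = np.empty((S_stored, q_lines))
    out_alpha = {c.name: np.empty((S_stored, c.map_all.shape[0])) for c in comps}
    out_loglik = np.empty(S_stored)

    s = 0
    for it in range(spec.n_iter):
        s2e = sigma2["resid"]
        # treatment means (flat prior)
        resid += mu[t_codes]
        sums = np.bincount(t_codes, weights=resid, minlength=2)
        mu = sums / n_by_t + rng.standard_normal(2) * np.sqrt(s2e / n_by_t)
        resid -= mu[t_codes]
        # line effects
        if has_line:
            resid += line_eff[line_codes]
            prec = n_by_line / s2e + 1.0 / sigma2["line"]
            mean = np.bincount(line_codes, weights=resid, minlength=q_lines) / s2e / prec
            line_eff = mean + rng.standard_normal(q_lines) / np.sqrt(prec)
            resid -= line_eff[line_codes]
            sigma2["line"] = _scaled_inv_chi2(
                rng, df0 + q_lines, df0 * s0["line"] + float(line_eff @ line_eff)
            )
        # kernel components
        for c in comps:
            resid += c.values_obs
            vals = c.gibbs_update(resid, s2e, sigma2[c.name], rng)
            resid -= vals
            sigma2[c.name] = _scaled_inv_chi2(
                rng, df0 + c.r, df0 * s0[c.name] + float(c.e @ c.e)
            )
        # residual variance
        rss = float(resid @ resid)
        sigma2["resid"] = _scaled_inv_chi2(rng, df0 + n, df0 * s0_resid + rss)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == spec.thin - 1:
            out_mu[s] = mu
            for k in sigma2:
                out_sigma2[k][s] = sigma2[k]
            out_line[s] = line_eff
            for c in comps:
                out_alpha[c.name][s] = c.alpha
            out_loglik[s] = -0.5 * (n * np.log(2 * np.pi * sigma2["resid"]) + rss / sigma2["resid"])
            s += 1

    assert s == S_stored
    return PosteriorSamples(
        spec=spec,
        treatments=TREATMENTS,
        mu=out_mu,
        sigma2=out_sigma2,
        line_ids=list(line_index),
        line_draws=out_line,
        kernel_draws=out_alpha,
        kernel_ids={c.name: c.ids for c in comps},
        obs=obs,
        loglik=out_loglik,
    )


def predict(samples: PosteriorSamples, targets, kernels=None) -> np.ndarray:
    """Posterior-mean prediction for (line, treatment) targets.

    Kernel effects extend to lines without phenotypes through the kernel
    cross-blocks (their rows of the stored effect vectors); the iid line
    effect contributes only for lines seen in training.  ``kernels`` is
    accepted for interface symmetry but predictions use the effect
    vectors stored during fitting.
    """
    lines = [t[0] for t in targets]
    treats = [t[1] for t in targets]
    bad = set(treats) - set(samples.treatments)
    if bad:
        raise ValueError(f"unknown treatment(s) {sorted(bad)}")
    j = np.array([samples.treatments.index(t) for t in treats])
    pred = samples.mu.mean(axis=0)[j]
    line_mean = samples.line_draws.mean(axis=0)
    lidx = pd.Index(samples.line_ids).get_indexer(lines)
    pred += np.where(lidx >= 0, line_mean[np.clip(lidx, 0, None)], 0.0)
    for name, draws in samples.kernel_draws.items():
        rows = _kernel_rows(samples.kernel_ids[name], lines, treats)
        pred += draws.mean(axis=0)[rows]
    return pred
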