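"""Similarity-kernel construction from centered-scaled omics matrices.

For an n x p omics matrix X the kernel is K = W W' / p where W is X with
each column centered to mean zero and scaled to unit sample standard
deviation (n-1 denominator), missing cells mean-imputed (zero after
centering) and zero-variance columns dropped.  Dividing by the retained
feature count makes the mean diagonal (n-1)/n ~ 1 for unit-variance
columns, i.e. the VanRaden-style additive relationship matrix when X
holds SNP dosages; the same construction applied to expression or
methylation matrices yields the transcriptomic and methylomic kernels.

For expression data the kernel may optionally be built from a truncated
principal-component reconstruction of W (``pca_var < 1``), which
de-noises individual expression profiles; with all components retained
the kernel is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import OmicsMatrix

log = logging.getLogger(__name__)

#: eigenvalues below this (relative to none) trigger a PSD repair clip
PSD_TOL = -1e-8


@dataclass
class SimilarityMatrix:
    """Symmetric PSD sample x sample kernel with the ids it was built on."""

    K: np.ndarray
    sample_ids: list[str]
    source_omic: str
    n_features_used: int

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel must be square")
        if K.shape[0] != len(self.sample_ids):
            raise ValueError("kernel size does not match sample ids")
        if np.max(np.abs(K - K.T)) > 1e-10:
            raise ValueError("kernel is not symmetric")
        self.K = (K + K.T) / 2.0

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def reorder(self, ids: list[str]) -> "SimilarityMatrix":
        idx = [self.sample_ids.index(i) for i in ids]
        return SimilarityMatrix(self.K[np.ix_(idx, idx)], list(ids), self.source_omic, self.n_features_used)


def center_scale(X: OmicsMatrix) -> tuple[np.ndarray, int]:
    """Center and scale columns; returns (W, number of columns dropped).

    Each retained column of W has mean 0 and sample standard deviation 1
    (n-1 denominator).  Missing cells are imputed to the column mean
    (exactly 0 after centering).  Zero-variance or all-missing columns
    are dropped with a logged count.
    """
    arr = X.values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("center_scale needs at least 2 samples")
    cnt = (~np.isnan(arr)).sum(axis=0)
    mean = np.divide(np.nansum(arr, axis=0), cnt, out=np.zeros(arr.shape[1]), where=cnt > 0)
    filled = np.where(np.isnan(arr), mean, arr)
    sd = filled.std(axis=0, ddof=1)
    keep = np.isfinite(sd) & (sd > 0)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all columns are zero-variance; cannot center-scale")
    if n_dropped:
        log.info("center_scale dropped %d zero-variance column(s)", n_dropped)
    W = (filled[:, keep] - mean[keep]) / sd[keep]
    return W, n_dropped


def similarity(X: OmicsMatrix, pca_var: float = 1.0) -> SimilarityMatrix:
    """Build K = W W' / p from the centered-scaled matrix W.

    ``pca_var`` in (0, 1] keeps the leading principal components of W
    explaining at least that fraction of variance and reconstructs W from
    them before forming the kernel; 1.0 keeps everything (exact kernel).
    """
    W, _ = center_scale(X)
    p = W.shape[1]
    if not 0 < pca_var <= 1:
        raise ValueError("pca_var must be in (0, 1]")
    if pca_var < 1.0:
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        var = s**2
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, pca_var) + 1)
        W = U[:, :k] * s[:k]  # reconstruction in component space: WW' unchanged by Vt
    K = W @ W.T / p
    eigvals = np.linalg.eigvalsh(K)
    if eigvals.min() < PSD_TOL:
        log.warning("kernel min eigenvalue %.3g < 0; clipping for PSD repair", eigvals.min())
        w, V = np.linalg.eigh(K)
        K = (V * np.clip(w, 0.0, None)) @ V.T
        K = (K + K.T) / 2.0
    return SimilarityMatrix(
        K=K,
        sample_ids=list(X.values.index),
        source_omic=X.omic_kind,
        n_features_used=p,
    )
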