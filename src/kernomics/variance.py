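"""Posterior variance partitioning (PV^2) from stored Gibbs draws.

For each stored draw s, the variance attributed to a model component is
the sample variance, across the phenotyped observations, of that
component's realized values in the draw (treatment uses the two
treatment means mapped onto observations; line and kernel effects use
the realized effect vectors).  The residual contribution is the sampled
residual variance parameter itself.  The proportion of variance
explained is each contribution divided by the per-draw total, so the
proportions sum to one exactly within every draw; posterior means and
SDs are reported over draws.  The PV^2 of the SNP component doubles as
the narrow-sense heritability estimate.

Because realized-value variances (not the prior variance parameters)
are used, the partition automatically accounts for covariance between
omics layers: collinear kernels share credit instead of double-counting
it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bayes import PosteriorSamples


def pv2_draws(samples: PosteriorSamples, ddof: int = 1) -> pd.DataFrame:
    """Per-draw PV^2 of every component; rows sum to 1 exactly."""
    parts = {}
    parts["treatment"] = samples.component_values("treatment").var(axis=1, ddof=ddof)
    if "line" in samples.sigma2:
        parts["line"] = samples.component_values("line").var(axis=1, ddof=ddof)
    for name in samples.kernel_draws:
        parts[name] = samples.component_values(name).var(axis=1, ddof=ddof)
    parts["resid"] = samples.sigma2["resid"]
    frame = pd.DataFrame(parts)
    total = frame.sum(axis=1)
    return frame.div(total, axis=0)


def pv2(samples: PosteriorSamples, ddof: int = 1) -> pd.DataFrame:
    """Posterior mean and SD of PV^2 per component.

    Returns a DataFrame indexed by component with columns ``mean`` and
    ``sd``.  The ``snp`` row, when present, is the narrow-sense
    heritability estimate.
    """
    draws = pv2_draws(samples, ddof=ddof)
    return pd.DataFrame({"mean": draws.mean(axis=0), "sd": draws.std(axis=0, ddof=1)})


def plot_pv2(tables: dict[str, pd.DataFrame], path=None, ax=None):
    """Stacked-bar chart of PV^2 by model variant (one bar per variant).

    ``tables`` maps a variant label to the output of :func:`pv2`.
    Returns the matplotlib axes; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(tables) + 2, 4))
    components: list[str] = []
    for tab in tables.values():
        for c in tab.index:
            if c not in components:
                components.append(c)
    bottoms = np.zeros(len(tables))
    xs = np.arange(len(tables))
    for comp in components:
        heights = np.array([t["mean"].get(comp, 0.0) for t in tables.values()])
        ax.bar(xs, heights, bottom=bottoms, label=comp)
        bottoms += heights
    ax.set_xticks(xs, list(tables))
    ax.set_ylabel("proportion of phenotypic variance (PV$^2$)")
    ax.legend(fontsize="small")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
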