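import numpy as np
import pandas as pd
import pytest

from kernomics.io import OmicsMatrix, PhenotypeTable, TREATMENTS, sample_id
from kernomics.kernels import similarity
from kernomics.simulate import (
    SyntheticTruth,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
    simulate_phenotypes,
)


def make_lines(n):
    return [f"line_{i + 1:03d}" for i in range(n)]


def paired_samples(lines):
    return [sample_id(l, t) for l in lines for t in TREATMENTS]


@pytest.fixture(scope="session")
def small_study():
    """75-line study bundle with known variance fractions, shared read-only."""
    geno = simulate_genotypes(75, 400, ld_block=5, missing_rate=0.05, seed=101)
    meth = simulate_methylation(75, 500, seed=102)
    expr, mediators = simulate_expression(
        75, 400, genotypes=geno, n_mediators=10, a=1.2, seed=103
    )
    truth = SyntheticTruth(
        pv2={"treatment": 0.05, "line": 0.15, "snp": 0.30, "meth": 0.10, "expr": 0.20,
             "resid": 0.20}
    )
    pheno = simulate_phenotypes(
        truth, genotypes=geno, methylation=meth, expression=expr, seed=104
    )
    return {
        "geno": geno,
        "meth": meth,
        "expr": expr,
        "pheno": pheno,
        "truth": truth,
        "mediators": mediators,
        "kernels": {"snp": similarity(geno), "meth": similarity(meth), "expr": similarity(expr)},
    }


@pytest.fixture()
def tiny_pheno():
    lines = make_lines(2)
    rows = []
    for l in lines:
        for t in TREATMENTS:
            rows.append({"line": l, "treatment": t, "grain_yield": 1.0, "tkw": 40.0})
    return PhenotypeTable(pd.DataFrame(rows))


def balanced_pheno(y, lines=None, trait="grain_yield"):
    """Phenotype table from a vector ordered (line1 ctrl, line1 ws, ...)."""
    n = len(y) // 2
    lines = lines if lines is not None else make_lines(n)
    rows = []
    for i, l in enumerate(lines):
        for j, t in enumerate(TREATMENTS):
            rows.append({"line": l, "treatment": t, trait: y[2 * i + j]})
    return PhenotypeTable(pd.DataFrame(rows))


def sample_matrix(values, lines, kind="expression", prefix="f"):
    """OmicsMatrix on paired line:treatment sample rows."""
    samples = paired_samples(lines)
    cols = [f"{prefix}{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=samples, columns=cols), kind)
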