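"""Readers and writers for the tabular formats the pipeline touches.

Three external tables are supported:

* a phenotype table (one row per line x treatment observation, four
  agronomic traits: grain yield, thousand kernel weight, protein content,
  grain nitrogen uptake),
* a BED-like long-format methylation count file (one row per cytosine
  site x sample, with methylated / total read counts),
* dense numeric omics matrices (genotype dosages, methylation levels or
  TPM expression) with sample ids on the rows and feature ids on the
  columns.

Coordinates follow the BED convention: 0-based, half-open.  The missing
token is ``NA`` (case sensitive) or the empty string; both are read back
as missing.  All writers emit TSV with a single ``#``-prefixed comment
line recording the package version so that outputs are self-describing;
readers skip comment lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

TREATMENTS = ("control", "water_scarce")
CONTEXTS = ("CG", "CHG", "CHH")
OMIC_KINDS = ("snp", "methylation", "expression")
MISSING_TOKENS = ("NA", "")

#: column order of the long-format methylation count dialect
METH_COLUMNS = ("chrom", "start", "end", "context", "sample", "methylated", "total")


def sample_id(line_id: str, treatment: str) -> str:
    """Composite id for a per-sample (line x treatment) omics row."""
    return f"{line_id}:{treatment}"


@dataclass
class PhenotypeTable:
    """Per (line, treatment) observations of the agronomic traits.

    ``data`` has columns ``line``, ``treatment`` and one column per trait;
    missing trait values are NaN.  (line, treatment) pairs are unique and
    treatment takes only the two declared levels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"line", "treatment"}
        if not required.issubset(self.data.columns):
            raise ValueError("phenotype table needs 'line' and 'treatment' columns")
        bad = set(self.data["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment label(s): {sorted(bad)}")
        dup = self.data.duplicated(subset=["line", "treatment"])
        if dup.any():
            first = self.data.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate (line, treatment) pair: ({first['line']}, {first['treatment']})"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("line", "treatment")]

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.data["line"]))

    def observations(self, trait: str) -> pd.DataFrame:
        """Non-missing records for one trait: columns line, treatment, y."""
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}; have {self.traits}")
        sub = self.data[["line", "treatment", trait]].rename(columns={trait: "y"})
        return sub.dropna(subset=["y"]).reset_index(drop=True)

    def sorted(self) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data.sort_values(["line", "treatment"], kind="mergesort").reset_index(drop=True)
        )


@dataclass
class OmicsMatrix:
    """Samples x features numeric matrix with per-feature metadata.

    ``values`` is a DataFrame indexed by sample id (line id, or
    ``line:treatment`` for per-sample omics) with feature ids as columns.
    ``feature_meta`` is indexed by feature id and may carry ``chrom``,
    ``start``, ``end`` and ``context`` columns.
    """

    values: pd.DataFrame
    omic_kind: str
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.omic_kind not in OMIC_KINDS:
            raise ValueError(f"omic_kind must be one of {OMIC_KINDS}, got {self.omic_kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if self.omic_kind == "methylation" and np.nanmin(arr, initial=1.0) < 0:
                raise ValueError("methylation levels must lie in [0, 1]")
            if self.omic_kind == "methylation" and np.nanmax(arr, initial=0.0) > 1:
                raise ValueError("methylation levels must lie in [0, 1]")
            if self.omic_kind == "expression" and np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("TPM values must be non-negative")
        if self.feature_meta is not None:
            if not self.feature_meta.index.equals(self.values.columns):
                self.feature_meta = self.feature_meta.reindex(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, keep) -> "OmicsMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.loc[keep]
        return OmicsMatrix(self.values.loc[:, keep], self.omic_kind, meta)


@dataclass
class MethylationCounts:
    """Long-format per (site, sample) bisulfite read counts."""

    data: pd.DataFrame  # columns METH_COLUMNS

    def __post_init__(self) -> None:
        missing = set(METH_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"methylation counts missing columns {sorted(missing)}")
        bad_ctx = set(self.data["context"]) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown methylation context(s): {sorted(bad_ctx)}")
        over = self.data["methylated"] > self.data["total"]
        if over.any():
            row = int(np.flatnonzero(over.to_numpy())[0])
            raise ValueError(f"methylated_reads > total_reads at record {row}")
        if (self.data[["methylated", "total"]] < 0).any().any():
            raise ValueError("read counts must be non-negative")

    @property
    def site_ids(self) -> pd.Series:
        d = self.data
        return (
            d["chrom"].astype(str)
            + ":"
            + d["start"].astype(str)
            + "-"
            + d["end"].astype(str)
            + ":"
            + d["context"].astype(str)
        )


@dataclass
class FilterReport:
    """Sequential feature-filter accounting for one omic layer."""

    omic_kind: str
    n_features_in: int
    n_features_out: int
    removals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_features_out + sum(self.removals.values()) != self.n_features_in:
            raise ValueError("filter report does not balance: in != out + removed")


# ---------------------------------------------------------------------------
# readers


def _read_table(path, sep="\t"):
    return pd.read_csv(
        path,
        sep=sep,
        comment="#",
        dtype=str,
        keep_default_na=False,
        na_values=list(MISSING_TOKENS),
    )


def _to_numeric(frame: pd.DataFrame, context: str, on_bad: str = "error") -> pd.DataFrame:
    """Convert string cells to float; unparseable non-missing cells either
    raise with coordinates or become missing with a warning."""
    out = {}
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            where = frame.index[bad][0]
            token = frame.loc[where, col]
            if on_bad == "error":
                raise ValueError(
                    f"{context}: non-numeric cell {token!r} at row {where!r}, column {col!r}"
                )
            warnings.warn(
                f"{context}: unparseable cell {token!r} at row {where!r}, column {col!r} "
                "treated as missing",
                stacklevel=3,
            )
        out[col] = converted
    return pd.DataFrame(out, index=frame.index)


def read_phenotypes(path, sep="\t") -> PhenotypeTable:
    """Read a phenotype table (columns: line, treatment, >=1 trait)."""
    raw = _read_table(path, sep=sep)
    if "line" not in raw.columns or "treatment" not in raw.columns:
        raise ValueError(f"{path}: phenotype header must declare 'line' and 'treatment'")
    traits = [c for c in raw.columns if c not in ("line", "treatment")]
    if not traits:
        raise ValueError(f"{path}: no trait columns found")
    numeric = _to_numeric(raw[traits], context=str(path), on_bad="warn")
    frame = pd.concat([raw[["line", "treatment"]], numeric], axis=1)
    return PhenotypeTable(frame)


def read_methylation_bed(path) -> MethylationCounts:
    """Read long-format BED-like methylation counts (tab-separated).

    Columns: chrom, start, end, context, sample, methylated, total.
    Coordinates are 0-based half-open.  Records are returned in file order.
    """
    raw = _read_table(path, sep="\t")
    missing = set(METH_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = raw.copy()
    for col in ("start", "end", "methylated", "total"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValueError(f"{path}: non-integer {col!r} at line {int(bad.idxmax()) + 2}")
        df[col] = vals.astype(int)
    over = df["methylated"] > df["total"]
    if over.any():
        raise ValueError(f"{path}: methylated > total at line {int(over.idxmax()) + 2}")
    return MethylationCounts(df[list(METH_COLUMNS)])


def read_matrix(path, omic_kind: str, sep="\t", orientation="samples_by_features") -> OmicsMatrix:
    """Read a dense omics matrix.

    ``orientation`` is ``"samples_by_features"`` (first column sample ids)
    or ``"features_by_samples"`` (first column feature ids; transposed on
    read so the two orientations yield the same matrix).
    """
    raw = _read_table(path, sep=sep)
    index_col = raw.columns[0]
    frame = raw.set_index(index_col)
    frame.index.name = None
    numeric = _to_numeric(frame, context=str(path), on_bad="error")
    if orientation == "features_by_samples":
        numeric = numeric.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    return OmicsMatrix(numeric, omic_kind)


# ---------------------------------------------------------------------------
# writers


def _header_comment() -> str:
    return f"# kernomics v{__version__}\n"


def write_phenotypes(table: PhenotypeTable, path, sep="\t") -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        table.data.to_csv(fh, sep=sep, index=False, na_rep="NA")


def write_methylation_bed(counts: MethylationCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        counts.data.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_matrix(matrix: OmicsMatrix, path, sep="\t") -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment())
        out = matrix.values.copy()
        out.insert(0, "sample", out.index)
        out.to_csv(fh, sep=sep, index=False, na_rep="NA")
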