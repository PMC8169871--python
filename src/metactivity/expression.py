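"""Expression matrices, covariate handling, and per-gene differential tests.

The matrix container pairs a genes-x-samples table of normalized log-scale
intensities with per-sample metadata (group, sex, age, batch, region).  The
differential-expression stage fits one ordinary least-squares model per gene
(expression ~ group + covariates) and reports the group coefficient with a
two-sided t-test and Benjamini-Hochberg adjustment across all tested genes.
Optional residualization on covariates (sex/age correction) is provided for
the discretization arm of the activity pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples values plus aligned per-sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)}")
        if self.metadata.index.duplicated().any():
            dupes = self.metadata.index[self.metadata.index.duplicated()].unique()
            raise ValueError(f"duplicate metadata sample ids: {list(dupes)}")
        only_matrix = set(self.values.columns) - set(self.metadata.index)
        only_meta = set(self.metadata.index) - set(self.values.columns)
        if only_matrix or only_meta:
            raise ValueError(
                "sample mismatch between matrix and metadata: "
                f"matrix-only={sorted(only_matrix)} "
                f"metadata-only={sorted(only_meta)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        # align metadata row order to matrix column order
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_values(self, sample: str) -> dict[str, float]:
        return self.values[sample].to_dict()


def load_expression(matrix_path: str | Path,
                    metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV and a sample-metadata TSV, align and check.

    The matrix has gene ids in its first column and sample ids in the header;
    the metadata is keyed by sample id.  Non-numeric cells and duplicate or
    mismatched ids raise with coordinates / names.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for col in matrix.columns:
        converted = pd.to_numeric(matrix[col], errors="coerce")
        bad = converted.isna() & matrix[col].notna()
        if bad.any():
            gene = matrix.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric expression value at gene={gene!r}, "
                f"sample={col!r} in {matrix_path}")
        matrix[col] = converted
    if matrix.isna().any().any():
        raise ValueError(f"missing expression values in {matrix_path}")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=matrix, metadata=metadata)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _design_matrix(metadata: pd.DataFrame, columns: Sequence[str],
                   drop_first: bool = True) -> pd.DataFrame:
    """Intercept + dummy-coded categoricals + numeric covariates."""
    parts = [pd.Series(1.0, index=metadata.index, name="intercept")]
    for col in columns:
        if col not in metadata.columns:
            raise ValueError(f"covariate {col!r} missing from metadata")
        series = metadata[col]
        if series.dtype.kind in "ifu":
            parts.append(series.astype(float))
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=col,
                                     drop_first=drop_first, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
    return pd.concat(parts, axis=1)


def residualize(matrix: ExpressionMatrix,
                covariates: Sequence[str] = ("sex", "age")) -> ExpressionMatrix:
    """Remove covariate-explained variation gene-wise, keeping gene means.

    Implements sex/age correction before discretization: each gene is
    regressed on the covariates and replaced by residual + gene mean, so
    pooled quantiles stay on the original intensity scale.
    """
    usable = [c for c in covariates
              if c in matrix.metadata.columns
              and matrix.metadata[c].nunique() > 1]
    if not usable:
        return matrix
    X = _design_matrix(matrix.metadata, usable).to_numpy(dtype=float)
    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    corrected = resid.T + matrix.values.mean(axis=1).to_numpy()[:, None]
    return ExpressionMatrix(
        values=pd.DataFrame(corrected, index=matrix.values.index,
                            columns=matrix.values.columns),
        metadata=matrix.metadata.copy())


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    matrix: ExpressionMatrix,
    group_col: str = "group",
    covariates: Sequence[str] = ("sex", "age", "batch"),
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of expression on a two-level group plus covariates.

    Returns a DataFrame indexed by gene with columns ``lfc`` (group
    coefficient: non-reference minus reference), ``se``, ``p`` (two-sided t),
    ``q`` (BH across all tested genes) and ``flag`` ("constant" marks genes
    with no residual variance, reported at p = 1).
    """
    from scipy import stats

    meta = matrix.metadata
    levels = sorted(meta[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not a group level")
    other = [l for l in levels if l != ref][0]
    counts = meta[group_col].value_counts()
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per group")

    usable = [c for c in covariates
              if c in meta.columns and meta[c].nunique() > 1]
    design = _design_matrix(meta, usable)
    design["group_effect"] = (meta[group_col].astype(str) == other).astype(float)
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "collinear design: group indicator is confounded with covariates "
            f"({list(design.columns)})")

    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x genes
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    g_idx = list(design.columns).index("group_effect")
    lfc = beta[g_idx]
    var = sigma2 * xtx_inv[g_idx, g_idx]

    constant = sigma2 < 1e-12
    se = np.sqrt(np.where(constant, np.nan, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = lfc / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(constant, 1.0, pvals)
    flags = np.where(constant, "constant", "")

    result = pd.DataFrame({
        "lfc": lfc,
        "se": np.where(constant, 0.0, se),
        "p": np.clip(pvals, 0.0, 1.0),
        "flag": flags,
    }, index=matrix.values.index)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result.index.name = "gene"
    return result[["lfc", "se", "p", "q", "flag"]]


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def write_de_tsv(result: pd.DataFrame, path: str | Path) -> None:
    out = result.reset_index()[["gene", "lfc", "se", "p", "q"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
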