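"""Expression-matrix ingestion and normalization.

The central container is :class:`ExpressionMatrix`: a gene x sample table of
nonnegative linear-scale values (microarray intensities or RNA-seq gene-level
counts) plus a platform label and the list of control sample ids.  Files are
tab-separated with a ``gene`` column followed by one column per sample; lines
beginning with ``!`` (GEO series-matrix metadata) are skipped.

Quantile normalization follows the standard sort / average / re-map scheme:
every sample's distribution is forced onto the across-sample mean of the
per-rank values, preserving within-sample rank order.  Tied values receive the
mean of the reference values their positions span, which keeps the transform
deterministic and symmetric.  It is exposed both as the
:func:`quantile_normalize` function and as the scikit-learn style
:class:`QuantileNormalizer` transformer (samples as rows).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .pathway_db import canonical_gene

__all__ = [
    "ExpressionError",
    "ExpressionMatrix",
    "QuantileNormalizer",
    "read_expression",
    "write_expression",
    "aggregate_probes",
    "quantile_normalize",
    "intersect_genes",
]


class ExpressionError(ValueError):
    """Raised for malformed expression inputs."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values on the platform-native linear scale.

    Parameters
    ----------
    data
        DataFrame indexed by canonical gene symbol, one column per sample id.
    platform_label
        Free-text platform tag.  Labels containing ``seq``/``ngs`` mark
        sequencing data, which by default is not quantile normalized.
    control_ids
        Subset of the sample ids designated as the control (normal) group.
    """

    data: pd.DataFrame
    platform_label: str = ""
    control_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        genes = [canonical_gene(g) for g in self.data.index]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ExpressionError(f"duplicate gene symbols after canonicalization: {dupes[:5]}")
        self.data = self.data.copy()
        self.data.index = pd.Index(genes, name="gene")
        self.data.columns = [str(c) for c in self.data.columns]
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ExpressionError("duplicate sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ExpressionError("expression values must be finite")
        if (values < 0).any():
            raise ExpressionError("expression values must be nonnegative")
        self.data = self.data.astype(float)
        self.control_ids = tuple(str(c) for c in self.control_ids)
        missing = [c for c in self.control_ids if c not in self.data.columns]
        if missing:
            raise ExpressionError(f"control ids not present in matrix: {missing}")

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    @property
    def case_ids(self) -> Tuple[str, ...]:
        ctrl = set(self.control_ids)
        return tuple(s for s in self.samples if s not in ctrl)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def controls_frame(self) -> pd.DataFrame:
        if not self.control_ids:
            raise ExpressionError("no control ids designated")
        return self.data.loc[:, list(self.control_ids)]

    def cases_frame(self) -> pd.DataFrame:
        return self.data.loc[:, list(self.case_ids)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data.loc[list(genes)])


def aggregate_probes(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated gene rows (multiple probes) to their arithmetic mean.

    Aggregation happens on the linear scale, before any normalization; row
    order follows the first occurrence of each gene.
    """
    if not frame.index.has_duplicates:
        return frame
    first_order = frame.index.drop_duplicates()
    out = frame.groupby(level=0, sort=False).mean()
    return out.loc[first_order]


def read_expression(
    path: str | Path,
    control_ids: Iterable[str] = (),
    platform_label: str = "",
) -> ExpressionMatrix:
    """Read a gene x sample TSV into an :class:`ExpressionMatrix`.

    First column holds gene symbols (header ``gene``), remaining columns one
    sample each.  Duplicate gene rows are averaged (probe aggregation); gene
    symbols are canonicalized; ``!``-prefixed metadata lines are skipped so GEO
    series-matrix exports load directly.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        text = "".join(line for line in fh if not line.startswith("!"))
    raw = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ExpressionError(f"{path}: no sample columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ExpressionError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ExpressionError(
            f"{path}: missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ExpressionError(
            f"{path}: negative value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    # re-parse through strtod for exact binary round-trips of repr() output
    numeric = pd.DataFrame(
        raw.to_numpy(dtype=float), index=raw.index, columns=raw.columns
    )
    numeric.index = pd.Index([canonical_gene(g) for g in numeric.index], name="gene")
    numeric = aggregate_probes(numeric)
    control_ids = tuple(str(c) for c in control_ids)
    missing = [c for c in control_ids if c not in numeric.columns]
    if missing:
        raise ExpressionError(f"{path}: control ids not found in header: {missing}")
    return ExpressionMatrix(data=numeric, platform_label=platform_label, control_ids=control_ids)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as a gene x sample TSV (full float precision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(m.samples) + "\n")
        for gene, row in zip(m.genes, m.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# -- quantile normalization ----------------------------------------------------

def _reference_distribution(columns: np.ndarray) -> np.ndarray:
    """Across-sample mean of the sorted columns (rows = genes, cols = samples)."""
    return np.sort(columns, axis=0).mean(axis=1)


def _map_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace each value by the reference value at its rank.

    Tied values share the mean of the reference entries their sorted positions
    span.
    """
    n = col.shape[0]
    order = np.argsort(col, kind="mergesort")
    sorted_col = col[order]
    grp = np.concatenate(([0], np.cumsum(sorted_col[1:] != sorted_col[:-1])))
    grp_mean = np.bincount(grp, weights=ref) / np.bincount(grp)
    out = np.empty(n, dtype=float)
    out[order] = grp_mean[grp]
    return out


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization as a scikit-learn transformer.

    Orientation follows scikit-learn: ``X`` has shape (n_samples, n_features),
    i.e. one row per sample (array/library) and one column per gene.  ``fit``
    learns the reference distribution as the across-sample mean of each
    sample's sorted values; ``transform`` replaces each sample's values by the
    reference value at the corresponding rank (ties averaged).

    ``fit_transform`` on a single matrix is classic within-dataset quantile
    normalization; fitting on one cohort and transforming another maps new
    samples onto a frozen reference.
    """

    def __init__(self) -> None:
        pass

    def fit(self, X, y=None) -> "QuantileNormalizer":
        X = self._validate(X)
        if X.shape[0] < 2:
            raise ExpressionError(
                "quantile normalization needs >=2 samples; skip normalization "
                "for single-sample data"
            )
        self.n_features_in_ = X.shape[1]
        self.reference_ = _reference_distribution(X.T)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ExpressionError(
                f"X has {X.shape[1]} features, fitted with {self.n_features_in_}"
            )
        return np.stack([_map_to_reference(row, self.reference_) for row in X])

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ExpressionError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ExpressionError("X must be finite")
        return X


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples of an expression matrix.

    Thin wrapper over :class:`QuantileNormalizer` (samples are the matrix
    columns here, so the data is transposed into scikit-learn orientation and
    back).
    """
    if len(m.samples) < 2:
        raise ExpressionError(
            "quantile normalization needs >=2 samples; skip normalization "
            "for single-sample data"
        )
    qn = QuantileNormalizer().fit(m.values.T)
    normalized = qn.transform(m.values.T).T
    data = pd.DataFrame(normalized, index=m.data.index, columns=m.data.columns)
    return replace(m, data=data)


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, in lexicographic order."""
    shared = sorted(set(a.genes) & set(b.genes))
    if not shared:
        raise ExpressionError("gene sets are disjoint; nothing to compare")
    return a.subset_genes(shared), b.subset_genes(shared)
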