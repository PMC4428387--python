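"""Cross-platform concordance of gene-level and pathway-level profiles.

The analysis design: the same biological samples are profiled on two
expression platforms (e.g. a microarray and an RNA-seq run).  For each sample
we correlate, between the platforms,

* the per-gene decimal-log case-to-normal ratios (transcriptome level), and
* the per-pathway activation strengths (signalome level),

plus an ``averaged`` row that first averages the profiles across the listed
samples and then correlates the mean profiles.  Per-measurement platform
error is independent between platforms, so gene-level correlation is bounded
by the noise, while the pathway sum pools many genes and averages much of
that error out — pathway-level correlations come out systematically higher.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, intersect_genes, quantile_normalize
from .pathway_db import PathwayDB
from .scoring import BTIFConfig, CNRTable, PASMatrix, score_matrix

__all__ = [
    "ConcordanceError",
    "PairedSampleResult",
    "ConcordanceReport",
    "TwoPlatformScores",
    "pearson",
    "correlate",
    "paired_concordance",
    "scatter_export",
    "platform_concordance",
]


class ConcordanceError(ValueError):
    """Raised for invalid concordance inputs."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConcordanceError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ConcordanceError("need two 1-d vectors of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Correlation with selectable estimator (``pearson`` or ``spearman``)."""
    if method == "pearson":
        return pearson(x, y)
    if method == "spearman":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ConcordanceError(f"length mismatch: {x.shape} vs {y.shape}")
        if np.std(x) == 0 or np.std(y) == 0:
            return math.nan
        return float(stats.spearmanr(x, y).statistic)
    raise ConcordanceError(f"unknown correlation method {method!r}")


@dataclass
class PairedSampleResult:
    """Gene- and pathway-level cross-platform correlations for one sample.

    ``r_gene``/``r_pas`` are NaN when the correlation is undefined (constant
    profile or fewer than two points).
    """

    sample_id: str
    r_gene: float
    r_pas: float
    n_genes: int
    n_pathways: int


@dataclass
class ConcordanceReport:
    """Per-sample results plus the averaged-profile row."""

    per_sample: List[PairedSampleResult]
    averaged: Optional[PairedSampleResult] = None

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.per_sample)
        if self.averaged is not None:
            rows = rows + [self.averaged]
        return pd.DataFrame(
            [
                {
                    "sample": r.sample_id,
                    "r_gene": r.r_gene,
                    "r_pas": r.r_pas,
                    "n_genes": r.n_genes,
                    "n_pathways": r.n_pathways,
                }
                for r in rows
            ]
        )

    def to_dict(self) -> Dict:
        frame = self.to_frame()
        return {
            "per_sample": frame.to_dict(orient="records"),
        }

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True)

    @property
    def mean_r_gene(self) -> float:
        return float(np.nanmean([r.r_gene for r in self.per_sample]))

    @property
    def mean_r_pas(self) -> float:
        return float(np.nanmean([r.r_pas for r in self.per_sample]))


def _paired_vectors(
    a: pd.DataFrame, b: pd.DataFrame, col_a: str, col_b: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Columns of two aligned tables, dropped pairwise where either is NaN."""
    x = a[col_a].to_numpy(dtype=float)
    y = b[col_b].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if x.size < 2:
        return math.nan
    return correlate(x, y, method=method)


def paired_concordance(
    cnr_a: CNRTable,
    cnr_b: CNRTable,
    pas_a: PASMatrix,
    pas_b: PASMatrix,
    sample_pairs: Sequence[Tuple[str, str]],
    method: str = "pearson",
) -> ConcordanceReport:
    """Correlate lg CNR and PAS profiles between two platforms, per sample pair.

    The CNR tables must already be restricted to a common gene set (see
    :func:`pascore.expression.intersect_genes`) and both PAS matrices must
    come from the same pathway database.  The ``averaged`` row correlates the
    across-pair mean profiles.
    """
    if cnr_a.genes != cnr_b.genes:
        raise ConcordanceError(
            "CNR tables have different gene sets; intersect genes before scoring"
        )
    if pas_a.pathways != pas_b.pathways:
        raise ConcordanceError("PAS matrices come from different pathway sets")
    unknown = [
        (ia, ib)
        for ia, ib in sample_pairs
        if ia not in cnr_a.log_cnr.columns or ib not in cnr_b.log_cnr.columns
    ]
    if unknown:
        raise ConcordanceError(f"unknown sample ids in pairs: {unknown}")
    if not sample_pairs:
        raise ConcordanceError("no sample pairs supplied")

    per_sample: List[PairedSampleResult] = []
    for ia, ib in sample_pairs:
        gx, gy = _paired_vectors(cnr_a.log_cnr, cnr_b.log_cnr, ia, ib)
        px, py = _paired_vectors(pas_a.pas, pas_b.pas, ia, ib)
        label = ia if ia == ib else f"{ia}|{ib}"
        per_sample.append(
            PairedSampleResult(
                sample_id=label,
                r_gene=_safe_corr(gx, gy, method),
                r_pas=_safe_corr(px, py, method),
                n_genes=int(gx.size),
                n_pathways=int(px.size),
            )
        )

    ids_a = [ia for ia, _ in sample_pairs]
    ids_b = [ib for _, ib in sample_pairs]
    mean_gene_a = cnr_a.log_cnr[ids_a].mean(axis=1).to_numpy()
    mean_gene_b = cnr_b.log_cnr[ids_b].mean(axis=1).to_numpy()
    mean_pas_a = pas_a.pas[ids_a].mean(axis=1).to_numpy()
    mean_pas_b = pas_b.pas[ids_b].mean(axis=1).to_numpy()
    keep_g = np.isfinite(mean_gene_a) & np.isfinite(mean_gene_b)
    keep_p = np.isfinite(mean_pas_a) & np.isfinite(mean_pas_b)
    averaged = PairedSampleResult(
        sample_id=f"averaged_{len(sample_pairs)}",
        r_gene=_safe_corr(mean_gene_a[keep_g], mean_gene_b[keep_g], method),
        r_pas=_safe_corr(mean_pas_a[keep_p], mean_pas_b[keep_p], method),
        n_genes=int(keep_g.sum()),
        n_pathways=int(keep_p.sum()),
    )
    return ConcordanceReport(per_sample=per_sample, averaged=averaged)


def scatter_export(
    cnr_a: CNRTable,
    cnr_b: CNRTable,
    pas_a: PASMatrix,
    pas_b: PASMatrix,
    sample_pairs: Sequence[Tuple[str, str]],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format tables of paired (lg CNR, lg CNR) and (PAS, PAS) values.

    One row per (sample, gene) and per (sample, pathway); ready for plotting
    the platform-vs-platform clouds whose tightness the correlations
    summarize.
    """
    if cnr_a.genes != cnr_b.genes:
        raise ConcordanceError("CNR tables have different gene sets")
    gene_rows = []
    pathway_rows = []
    for ia, ib in sample_pairs:
        label = ia if ia == ib else f"{ia}|{ib}"
        for gene, va, vb in zip(
            cnr_a.genes, cnr_a.log_cnr[ia].to_numpy(), cnr_b.log_cnr[ib].to_numpy()
        ):
            gene_rows.append((label, gene, va, vb))
        for pw, va, vb in zip(
            pas_a.pathways, pas_a.pas[ia].to_numpy(), pas_b.pas[ib].to_numpy()
        ):
            pathway_rows.append((label, pw, va, vb))
    gene_df = pd.DataFrame(gene_rows, columns=["sample", "gene", "lg_cnr_a", "lg_cnr_b"])
    pathway_df = pd.DataFrame(
        pathway_rows, columns=["sample", "pathway", "pas_a", "pas_b"]
    )
    return gene_df, pathway_df


@dataclass
class TwoPlatformScores:
    """Everything the two-platform pipeline produced, plus the report."""

    cnr_a: CNRTable
    cnr_b: CNRTable
    pas_a: PASMatrix
    pas_b: PASMatrix
    report: ConcordanceReport


def _wants_normalization(m: ExpressionMatrix) -> bool:
    """Default policy: quantile-normalize arrays, leave sequencing counts as-is."""
    label = m.platform_label.lower()
    return not any(tok in label for tok in ("seq", "ngs"))


def platform_concordance(
    platform_a: ExpressionMatrix,
    platform_b: ExpressionMatrix,
    db: PathwayDB,
    normalize: str | bool | Tuple[bool, bool] = "auto",
    cfg: BTIFConfig = BTIFConfig(),
    floor: Optional[float] = None,
    control_average: str = "arithmetic",
    btif_all_on: bool = False,
    method: str = "pearson",
    sample_pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> TwoPlatformScores:
    """Run both platforms through scoring and compare them sample by sample.

    Genes are intersected first; each platform's CNR uses its own control
    samples.  ``normalize`` is ``"auto"`` (quantile-normalize unless the
    platform label marks sequencing data), a single bool for both platforms,
    or a (bool, bool) pair.  When ``sample_pairs`` is omitted, case sample ids
    shared by both platforms are paired by identity.
    """
    if isinstance(normalize, tuple):
        norm_a, norm_b = normalize
    elif normalize == "auto":
        norm_a, norm_b = _wants_normalization(platform_a), _wants_normalization(platform_b)
    else:
        norm_a = norm_b = bool(normalize)
    a, b = intersect_genes(platform_a, platform_b)
    if norm_a:
        a = quantile_normalize(a)
    if norm_b:
        b = quantile_normalize(b)
    cnr_a, pas_a = score_matrix(
        a, db, cfg=cfg, floor=floor, control_average=control_average,
        btif_all_on=btif_all_on,
    )
    cnr_b, pas_b = score_matrix(
        b, db, cfg=cfg, floor=floor, control_average=control_average,
        btif_all_on=btif_all_on,
    )
    if sample_pairs is None:
        shared = [s for s in a.case_ids if s in set(b.case_ids)]
        if not shared:
            raise ConcordanceError("platforms share no case sample ids")
        sample_pairs = [(s, s) for s in shared]
    report = paired_concordance(cnr_a, cnr_b, pas_a, pas_b, sample_pairs, method=method)
    return TwoPlatformScores(cnr_a=cnr_a, cnr_b=cnr_b, pas_a=pas_a, pas_b=pas_b, report=report)
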