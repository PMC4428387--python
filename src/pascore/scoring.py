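"""Pathway activation scoring: CNR, BTIF and the PAS sum.

For a case sample and a gene *n*, the case-to-normal ratio

    CNR_n = expression(case) / mean(expression over control samples)

is computed on the linear scale, with both numerator and denominator floored
at a small positive value so ratios and logarithms stay defined for dropouts.
A gene is marked significantly perturbed with the beyond-tolerance-interval
flag BTIF_n = 1 when its log10 case expression falls outside the control
tolerance interval mean +/- z * sd (default z = 1.96, the two-sided p > 0.05
band under a normal approximation), optionally gated by a minimum fold change.
The pathway activation strength of pathway *p* is then the weighted sum

    PAS_p = sum_n ARR_np * BTIF_n * lg(CNR_n)

over member genes, where ARR is the activator/repressor role weight and lg the
decimal logarithm.  A positive PAS marks an up-regulated pathway, a negative
one a down-regulated pathway; genes flagged as unperturbed contribute nothing,
which is what lets the sum average out platform measurement error.

The estimator :class:`PathwayActivationScorer` carries the whole procedure in
scikit-learn form — ``fit`` on the control samples, ``transform`` case samples
into pathway scores — and the module-level ``compute_*`` functions expose the
individual steps on the gene x sample containers used by the file formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .expression import ExpressionMatrix
from .pathway_db import PathwayDB

__all__ = [
    "BTIFConfig",
    "CNRTable",
    "PASMatrix",
    "PathwayActivationScorer",
    "ScoringError",
    "compute_cnr",
    "compute_btif",
    "compute_pas",
    "pas_sum",
    "score_matrix",
    "default_floor",
]

logger = logging.getLogger(__name__)

#: Relative factor for the automatic CNR floor (times the matrix-wide median
#: of nonzero values).
FLOOR_FACTOR = 1e-6


class ScoringError(ValueError):
    """Raised for invalid scoring inputs or configuration."""


@dataclass(frozen=True)
class BTIFConfig:
    """Tolerance-interval settings for the BTIF flag.

    z_threshold
        Half-width of the tolerance interval in control standard deviations;
        the default 1.96 corresponds to the two-sided p > 0.05 band.
    min_fold
        Optional extra gate: require |lg CNR| >= lg(min_fold).  The default
        1.0 disables the gate.
    """

    z_threshold: float = 1.96
    min_fold: float = 1.0

    def __post_init__(self) -> None:
        if not self.z_threshold > 0:
            raise ScoringError("z_threshold must be positive")
        if not self.min_fold >= 1:
            raise ScoringError("min_fold must be >= 1")


@dataclass
class CNRTable:
    """Per-gene case-to-normal ratios for the case samples.

    ``cnr`` and ``log_cnr`` are gene x case-sample DataFrames with
    ``log_cnr = log10(cnr)``; ``btif`` holds the 0/1 perturbation flags once
    :func:`compute_btif` has filled them.
    """

    genes: List[str]
    case_samples: List[str]
    cnr: pd.DataFrame
    log_cnr: pd.DataFrame
    btif: Optional[pd.DataFrame] = None


@dataclass
class PASMatrix:
    """Pathway x case-sample activation scores.

    ``n_contributing`` counts, per cell, the member genes present in the data
    that carried BTIF = 1 (the genes that actually entered the sum).
    """

    pathways: List[str]
    case_samples: List[str]
    pas: pd.DataFrame
    n_contributing: pd.DataFrame


def pas_sum(terms) -> float:
    """The pathway activation sum over explicit (ARR, BTIF, lg CNR) terms.

    The formula in its rawest form: ``sum(arr * btif * lg_cnr)`` over an
    iterable of member terms.  Linear by construction — repeating a member
    repeats its contribution.  The matrix pipelines reduce to this.
    """
    return float(sum(float(a) * float(b) * float(l) for a, b, l in terms))


def default_floor(values: np.ndarray) -> float:
    """Automatic CNR floor: 1e-6 times the matrix-wide median of nonzero values.

    Keeps ratios and logarithms finite for dropout zeros while being far below
    any genuine signal.  Falls back to 1e-6 if the matrix is all zeros.
    """
    nz = values[values > 0]
    if nz.size == 0:
        return FLOOR_FACTOR
    return FLOOR_FACTOR * float(np.median(nz))


class PathwayActivationScorer(TransformerMixin, BaseEstimator):
    """Scikit-learn estimator for pathway activation scoring.

    ``X`` follows scikit-learn orientation: shape (n_samples, n_genes), as a
    DataFrame whose columns are gene symbols.  ``fit`` learns the control
    group's per-gene statistics (linear-scale mean for the CNR denominator,
    log10 mean and sd for the tolerance interval); ``transform`` maps case
    samples to a (n_samples, n_pathways) DataFrame of PAS values.

    Parameters
    ----------
    pathways
        The :class:`~pascore.pathway_db.PathwayDB` to score against.  May be
        omitted when only CNR/BTIF tables are needed.
    z_threshold, min_fold
        See :class:`BTIFConfig`.
    floor
        Absolute positive floor applied to all linear expression values before
        ratios/logarithms; ``None`` derives it from the fit data via
        :func:`default_floor`.
    control_average
        ``"arithmetic"`` (default) or ``"geometric"`` mean over control
        samples for the CNR denominator.
    btif_all_on
        Force every BTIF flag to 1 — for single-control designs and
        sensitivity analysis.

    Attributes
    ----------
    feature_names_in_ : ndarray of gene symbols seen at fit
    control_mean_ : per-gene control average on the linear scale (floored)
    control_log_mean_, control_log_sd_ : per-gene stats of log10 control
        expression (sd with ddof=1; 0 for a single control)
    floor_ : resolved absolute floor
    pathway_ids_ : pathway ids in scoring order (when ``pathways`` given)
    """

    def __init__(
        self,
        pathways: Optional[PathwayDB] = None,
        z_threshold: float = 1.96,
        min_fold: float = 1.0,
        floor: Optional[float] = None,
        control_average: str = "arithmetic",
        btif_all_on: bool = False,
    ) -> None:
        self.pathways = pathways
        self.z_threshold = z_threshold
        self.min_fold = min_fold
        self.floor = floor
        self.control_average = control_average
        self.btif_all_on = btif_all_on

    # -- plumbing -------------------------------------------------------------
    def _check_config(self) -> BTIFConfig:
        if self.control_average not in ("arithmetic", "geometric"):
            raise ScoringError(
                f"control_average must be 'arithmetic' or 'geometric', got {self.control_average!r}"
            )
        if self.floor is not None and not self.floor > 0:
            raise ScoringError("floor must be positive")
        return BTIFConfig(z_threshold=self.z_threshold, min_fold=self.min_fold)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ScoringError("X must be 2-dimensional (samples x genes)")
        return pd.DataFrame(X, columns=[f"G{i}" for i in range(X.shape[1])])

    def _aligned(self, X) -> pd.DataFrame:
        check_is_fitted(self, "control_mean_")
        frame = self._as_frame(X)
        if list(frame.columns) != list(self.feature_names_in_):
            raise ScoringError(
                "gene set/order of X does not match the fitted control matrix"
            )
        return frame.astype(float)

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y=None) -> "PathwayActivationScorer":
        """Learn control-group statistics from X (controls x genes)."""
        cfg = self._check_config()
        frame = self._as_frame(X).astype(float)
        values = frame.to_numpy()
        if values.shape[0] < 1:
            raise ScoringError("need at least one control sample")
        if not np.all(np.isfinite(values)) or (values < 0).any():
            raise ScoringError("control expression must be finite and nonnegative")
        if values.shape[0] < 2 and not self.btif_all_on:
            raise ScoringError(
                "tolerance interval needs >=2 control samples; use btif_all_on "
                "mode for single-control designs"
            )
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = values.shape[1]
        self.floor_ = self.floor if self.floor is not None else default_floor(values)
        floored = np.maximum(values, self.floor_)
        if self.control_average == "arithmetic":
            self.control_mean_ = np.maximum(values.mean(axis=0), self.floor_)
        else:
            self.control_mean_ = 10.0 ** np.log10(floored).mean(axis=0)
        logs = np.log10(floored)
        self.control_log_mean_ = logs.mean(axis=0)
        if values.shape[0] >= 2:
            self.control_log_sd_ = logs.std(axis=0, ddof=1)
        else:
            self.control_log_sd_ = np.zeros(values.shape[1])
        if self.pathways is not None:
            self.pathway_ids_ = list(self.pathways.ids)
            self._weights_, self._membership_ = _pathway_matrices(
                self.pathways, list(self.feature_names_in_)
            )
        self._btif_cfg_ = cfg
        return self

    def log_cnr(self, X) -> pd.DataFrame:
        """Decimal-log case-to-normal ratios, samples x genes."""
        frame = self._aligned(X)
        case = np.maximum(frame.to_numpy(), self.floor_)
        out = np.log10(case) - np.log10(self.control_mean_)[None, :]
        return pd.DataFrame(out, index=frame.index, columns=frame.columns)

    def cnr(self, X) -> pd.DataFrame:
        """Linear case-to-normal ratios, samples x genes."""
        lc = self.log_cnr(X)
        return pd.DataFrame(10.0 ** lc.to_numpy(), index=lc.index, columns=lc.columns)

    def btif(self, X) -> pd.DataFrame:
        """0/1 beyond-tolerance-interval flags, samples x genes."""
        frame = self._aligned(X)
        if self.btif_all_on:
            flags = np.ones(frame.shape, dtype=int)
            return pd.DataFrame(flags, index=frame.index, columns=frame.columns)
        case_log = np.log10(np.maximum(frame.to_numpy(), self.floor_))
        dev = np.abs(case_log - self.control_log_mean_[None, :])
        sd = self.control_log_sd_[None, :]
        outside = np.where(sd > 0, dev > self._btif_cfg_.z_threshold * sd, dev > 0)
        fold_ok = (
            np.abs(case_log - np.log10(self.control_mean_)[None, :])
            >= np.log10(self._btif_cfg_.min_fold)
        )
        return pd.DataFrame(
            (outside & fold_ok).astype(int), index=frame.index, columns=frame.columns
        )

    def transform(self, X) -> pd.DataFrame:
        """Pathway activation strengths, samples x pathways."""
        check_is_fitted(self, "control_mean_")
        if self.pathways is None:
            raise ScoringError("no PathwayDB supplied; cannot compute PAS")
        lc = self.log_cnr(X)
        flags = self.btif(X)
        pas = (flags.to_numpy() * lc.to_numpy()) @ self._weights_.T
        return pd.DataFrame(pas, index=lc.index, columns=self.pathway_ids_)

    def contributing_counts(self, X) -> pd.DataFrame:
        """Per pathway, the number of member genes with BTIF = 1 (samples x pathways)."""
        check_is_fitted(self, "control_mean_")
        if self.pathways is None:
            raise ScoringError("no PathwayDB supplied")
        flags = self.btif(X)
        counts = flags.to_numpy() @ self._membership_.T
        return pd.DataFrame(
            counts.astype(int), index=flags.index, columns=self.pathway_ids_
        )


def _pathway_matrices(
    db: PathwayDB, genes: List[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """ARR weight and membership matrices, pathways x genes, for genes in data."""
    index = {g: i for i, g in enumerate(genes)}
    weights = np.zeros((len(db), len(genes)))
    membership = np.zeros((len(db), len(genes)))
    for k, pathway in enumerate(db):
        present = 0
        for gene, role in pathway.members.items():
            i = index.get(gene)
            if i is not None:
                weights[k, i] = float(role)
                membership[k, i] = 1.0
                present += 1
        if present == 0:
            logger.warning(
                "pathway %s has no member genes in the expression data; PAS will be 0",
                pathway.id,
            )
    return weights, membership


# -- functional surface on gene x sample containers ---------------------------

def _check_same_genes(case: ExpressionMatrix, controls: ExpressionMatrix) -> None:
    if case.genes != controls.genes:
        raise ScoringError("case and control matrices must share gene set and order")


def compute_cnr(
    case: ExpressionMatrix,
    controls: ExpressionMatrix,
    floor: Optional[float] = None,
    control_average: str = "arithmetic",
) -> CNRTable:
    """Case-to-normal ratios of each case sample against the control average.

    ``floor=None`` derives the floor from the combined case+control values via
    :func:`default_floor`.
    """
    _check_same_genes(case, controls)
    if floor is None:
        floor = default_floor(np.concatenate([case.values, controls.values], axis=1))
    scorer = PathwayActivationScorer(
        floor=floor, control_average=control_average, btif_all_on=True
    ).fit(controls.data.T)
    log_cnr = scorer.log_cnr(case.data.T).T
    cnr = 10.0 ** log_cnr
    return CNRTable(
        genes=case.genes, case_samples=case.samples, cnr=cnr, log_cnr=log_cnr
    )


def compute_btif(
    case: ExpressionMatrix,
    controls: ExpressionMatrix,
    cnr: CNRTable,
    cfg: BTIFConfig = BTIFConfig(),
    floor: Optional[float] = None,
    all_on: bool = False,
    control_average: str = "arithmetic",
) -> CNRTable:
    """Fill the BTIF flags of a CNR table.

    Needs >=2 control samples (the tolerance interval is otherwise undefined);
    pass ``all_on=True`` to flag every gene instead, e.g. for single-control
    designs.
    """
    _check_same_genes(case, controls)
    if len(controls.samples) < 2 and not all_on:
        raise ScoringError(
            "tolerance interval needs >=2 control samples; use all_on=True "
            "(btif_all_on mode) for single-control designs"
        )
    if floor is None:
        floor = default_floor(np.concatenate([case.values, controls.values], axis=1))
    scorer = PathwayActivationScorer(
        z_threshold=cfg.z_threshold,
        min_fold=cfg.min_fold,
        floor=floor,
        control_average=control_average,
        btif_all_on=all_on,
    ).fit(controls.data.T)
    flags = scorer.btif(case.data.T).T
    return CNRTable(
        genes=cnr.genes,
        case_samples=cnr.case_samples,
        cnr=cnr.cnr,
        log_cnr=cnr.log_cnr,
        btif=flags,
    )


def compute_pas(cnr: CNRTable, db: PathwayDB) -> PASMatrix:
    """Evaluate PAS_p = sum_n ARR_np * BTIF_n * lg(CNR_n) for every pathway and case.

    Member genes absent from the expression data contribute nothing; a pathway
    with no members in the data scores 0 (with a logged warning).
    """
    if cnr.btif is None:
        raise ScoringError("BTIF flags not filled; run compute_btif first")
    weights, membership = _pathway_matrices(db, cnr.genes)
    signal = cnr.btif.to_numpy() * cnr.log_cnr.to_numpy()  # genes x cases
    pas = weights @ signal
    counts = (membership @ cnr.btif.to_numpy()).astype(int)
    ids = db.ids
    return PASMatrix(
        pathways=ids,
        case_samples=cnr.case_samples,
        pas=pd.DataFrame(pas, index=ids, columns=cnr.case_samples),
        n_contributing=pd.DataFrame(counts, index=ids, columns=cnr.case_samples),
    )


def score_matrix(
    m: ExpressionMatrix,
    db: PathwayDB,
    cfg: BTIFConfig = BTIFConfig(),
    floor: Optional[float] = None,
    control_average: str = "arithmetic",
    btif_all_on: bool = False,
) -> Tuple[CNRTable, PASMatrix]:
    """Run the full CNR -> BTIF -> PAS chain on one annotated matrix.

    The matrix must carry control ids; all remaining samples are scored as
    cases.  Returns both the audit-level CNR table and the PAS matrix.
    """
    if not m.control_ids:
        raise ScoringError("expression matrix has no designated control samples")
    if not m.case_ids:
        raise ScoringError("expression matrix has no case samples to score")
    from dataclasses import replace

    controls = replace(m, data=m.controls_frame(), control_ids=m.control_ids)
    case = replace(m, data=m.cases_frame(), control_ids=())
    if floor is None:
        floor = default_floor(m.values)
    table = compute_cnr(case, controls, floor=floor, control_average=control_average)
    table = compute_btif(
        case, controls, table, cfg=cfg, floor=floor, all_on=btif_all_on,
        control_average=control_average,
    )
    return table, compute_pas(table, db)
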