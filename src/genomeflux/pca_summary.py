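"""PCA of the defense-vs-all relative event rates.

The four per-event-type ratio columns (gain, loss, expansion, reduction)
are the input variables; the derived all-GDE total is excluded. The
default is PCA of the standardized ratios (correlation matrix), which
reproduces the published variance shares for the 36-cluster table;
covariance-matrix PCA and a log transform are available as options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ValidationError

logger = logging.getLogger("genomeflux")

__all__ = ["PCAResult", "pca_relative_rates", "PCA_INPUT_COLUMNS"]

PCA_INPUT_COLUMNS = ("gain_ratio", "loss_ratio", "expansion_ratio",
                     "reduction_ratio")


@dataclass
class PCAResult:
    """Eigendecomposition summary of the relative-rate table.

    ``variance_explained`` is in percent and sums to 100; ``loadings``
    has one column per component over the four input variables; ``scores``
    has one row per ATGC. ``transformed`` is the centered (and scaled,
    under the correlation option) data the decomposition acted on, so
    ``scores @ loadings.T`` reconstructs it exactly.
    """

    variance_explained: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    transformed: pd.DataFrame


def pca_relative_rates(table: pd.DataFrame, *, log_transform: bool = False,
                       use_correlation: bool = True) -> PCAResult:
    """PCA of the four relative-rate columns.

    Rows with a non-positive or missing ratio are dropped with a warning
    when the log transform is requested (log of the ratio is undefined
    there); otherwise only missing rows are dropped. Components are
    ordered by decreasing eigenvalue and each loading vector is oriented
    so its largest-magnitude entry is positive.
    """
    cols = list(PCA_INPUT_COLUMNS)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"table missing ratio columns: {missing}")
    data = table[cols].astype(float)
    keep = data.notna().all(axis=1)
    if log_transform:
        keep &= (data > 0).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("pca_relative_rates: dropping %d unusable rows", dropped)
    data = data.loc[keep]
    if len(data) <= len(cols):
        raise ValidationError("need more rows than input columns for PCA")
    X = np.log(data.to_numpy()) if log_transform else data.to_numpy()
    X = X - X.mean(axis=0)
    if use_correlation:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("constant column: correlation PCA undefined")
        X = X / sd
    cov = np.cov(X.T, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|.| entry of each loading positive
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(len(cols))])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    explained = eigval / eigval.sum() * 100.0
    comp = [f"PC{i + 1}" for i in range(len(cols))]
    loadings = pd.DataFrame(eigvec, index=cols, columns=comp)
    scores = pd.DataFrame(X @ eigvec, index=data.index, columns=comp)
    transformed = pd.DataFrame(X, index=data.index, columns=cols)
    return PCAResult(variance_explained=explained, loadings=loadings,
                     scores=scores, transformed=transformed)
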