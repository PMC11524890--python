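"""Cell-line expression featurization.

Cell lines are described by log-scale expression over a fixed gene
panel. Raw input is a genes x cells TPM matrix; preprocessing is
``z-score per gene of log2(TPM + 1)``, with the scaler statistics fitted
on training cells only and frozen for prediction. Genes on the panel but
absent from the matrix are dropped with a warning; zero-variance genes
map to 0 rather than NaN.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def load_gene_panel(path) -> list[str]:
    """Read a one-symbol-per-line gene panel file."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(genes) != len(set(genes)):
        raise ValueError("gene panel contains duplicate symbols")
    return genes


def load_expression(path) -> pd.DataFrame:
    """Read a genes x cells TPM matrix (first column = gene symbol)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


class ExpressionScaler(BaseEstimator, TransformerMixin):
    """Panel subsetting + log2(TPM+1) + per-gene z-scoring transformer.

    Parameters
    ----------
    panel : list of str, optional
        Ordered gene symbols to keep. ``None`` uses every gene in the
        fitted matrix, in matrix order. The fitted order is frozen in
        ``genes_`` and reused verbatim at transform time.

    Attributes
    ----------
    genes_ : list of str
        Panel genes present in the fitted matrix, in panel order.
    mean_, scale_ : ndarray
        Per-gene mean and standard deviation of log2(TPM+1) over the
        fitted (training) cells; zero-variance genes get ``scale_ = 1``
        so their z-scores are exactly 0.
    """

    def __init__(self, panel: list[str] | None = None):
        self.panel = panel

    def fit(self, X: pd.DataFrame, y=None) -> "ExpressionScaler":
        """Fit per-gene statistics on a genes x cells TPM DataFrame."""
        if self.panel is not None:
            missing = [g for g in self.panel if g not in X.index]
            if missing:
                warnings.warn(
                    f"{len(missing)} panel genes absent from expression matrix "
                    f"and dropped (e.g. {missing[:5]})"
                )
            genes = [g for g in self.panel if g in X.index]
        else:
            genes = list(X.index)
        if not genes:
            raise ValueError("no overlap between gene panel and expression matrix")
        logged = np.log2(X.loc[genes].to_numpy(dtype=float) + 1.0)
        self.genes_ = genes
        self.mean_ = logged.mean(axis=1)
        sd = logged.std(axis=1)  # population SD over training cells
        self.zero_variance_ = sd == 0.0
        self.scale_ = np.where(self.zero_variance_, 1.0, sd)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return a cells x panel-genes z-scored DataFrame."""
        check_is_fitted(self, "genes_")
        missing = [g for g in self.genes_ if g not in X.index]
        if missing:
            raise ValueError(f"matrix lacks fitted panel genes: {missing[:5]}")
        logged = np.log2(X.loc[self.genes_].to_numpy(dtype=float) + 1.0)
        z = (logged - self.mean_[:, None]) / self.scale_[:, None]
        return pd.DataFrame(z.T, index=list(X.columns), columns=self.genes_)

    def profiles(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """Transform and return per-cell vectors keyed by cell id."""
        z = self.transform(X)
        return {cell: z.loc[cell].to_numpy() for cell in z.index}
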