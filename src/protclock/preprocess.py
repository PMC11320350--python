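"""Preprocessing: missingness filter, k-NN imputation, standardization.

The imputation is the usual k-nearest-neighbours scheme for expression
matrices: Euclidean distance over jointly observed proteins scaled by the
number of shared dimensions, missing cells replaced by the
distance-weighted mean of the k nearest participants (delegated to
scikit-learn's ``KNNImputer``, which implements exactly this metric).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import KNNImputer

from .containers import ProteinMatrix

__all__ = [
    "filter_high_missingness",
    "knn_impute",
    "inverse_normal",
    "age_adjusted_residuals",
    "reverse_sign",
]

log = logging.getLogger(__name__)


def filter_high_missingness(matrix: ProteinMatrix, threshold: float = 0.5):
    """Drop proteins whose missing fraction exceeds ``threshold``.

    Returns the filtered matrix and the list of removed protein ids.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if matrix.values.size == 0:
        raise ValueError("empty protein matrix")
    frac = matrix.missing_fraction
    removed = list(frac.index[frac > threshold])
    kept = [p for p in matrix.protein_ids if p not in set(removed)]
    log.info("missingness filter: removed %d of %d proteins (threshold %.2f)",
             len(removed), len(frac), threshold)
    return matrix.subset_proteins(kept), removed


def knn_impute(matrix: ProteinMatrix, k: int = 10) -> ProteinMatrix:
    """Impute missing cells by the distance-weighted mean of the k nearest rows.

    Observed cells are never altered; the output has no missing values.  If
    fewer than ``k`` usable neighbours exist the imputer falls back to all
    available neighbours (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values
    if not bool(vals.isna().any().any()):
        return matrix.copy()
    if (~vals.isna()).sum(axis=1).min() < 1:
        raise ValueError("every participant must have at least one observed protein")
    n = len(vals)
    k_eff = k
    if k >= n:
        log.warning("k=%d >= %d rows; falling back to %d neighbours", k, n, n - 1)
        k_eff = max(1, n - 1)
    imputer = KNNImputer(n_neighbors=k_eff, weights="distance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns per column when neighbours run short
        imputed = imputer.fit_transform(vals.to_numpy(dtype=float))
    out = pd.DataFrame(imputed, index=vals.index, columns=vals.columns)
    # keep observed cells bit-identical
    mask = vals.notna()
    out = out.where(~mask, vals)
    return ProteinMatrix(out, dict(matrix.gene_map))


def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset, average ranks for ties).

    z_i = Phi^{-1}((r_i - c) / (n + 1 - 2c)) with c = 3/8; NaNs are ignored
    in the ranking and propagated to the output.
    """
    x = np.asarray(values, dtype=float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("need at least two observed values")
    xo = x[obs]
    if np.all(xo == xo[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(xo, method="average")
    z = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    out = np.full_like(x, np.nan)
    out[obs] = z
    return out


def age_adjusted_residuals(measure, age) -> np.ndarray:
    """Residuals of an OLS regression of ``measure`` on ``age`` (with intercept)."""
    y = np.asarray(measure, dtype=float)
    a = np.asarray(age, dtype=float)
    if y.shape != a.shape:
        raise ValueError("measure and age must have equal length")
    if len(y) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(a) == 0:
        raise ValueError("age is constant; residuals undefined")
    design = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def reverse_sign(values) -> np.ndarray:
    """Elementwise negation (e.g. telomere length -> 'short telomere' score)."""
    return -np.asarray(values, dtype=float)
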