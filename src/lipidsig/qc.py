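"""Feature-matrix preprocessing for MS lipidomics.

Fixed order: QC-pool presence/CV filter -> KNN imputation -> probabilistic
quotient normalization (PQN).  Matrices are samples x features DataFrames;
QC pools are identified by a boolean sample mask.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = ["qc_filter", "knn_impute", "pqn_normalize", "preprocess"]

log = logging.getLogger(__name__)


def qc_filter(matrix: pd.DataFrame, is_qc_pool, presence: float = 0.5,
              cv_max: float = 20.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep features present in at least ``presence`` of the QC pools and with
    a pool coefficient of variation (100 * sd / mean, sample sd over observed
    pool values) no greater than ``cv_max`` percent.

    Returns the filtered matrix and a report of dropped features with the
    reason (``presence`` or ``cv``).
    """
    is_qc_pool = np.asarray(is_qc_pool, dtype=bool)
    n_pools = int(is_qc_pool.sum())
    if n_pools == 0:
        raise ValueError("qc_filter requires at least one QC pool sample")
    pools = matrix.loc[is_qc_pool]
    need = math.ceil(presence * n_pools)

    dropped = []
    keep = []
    for feat in matrix.columns:
        obs = pools[feat].dropna()
        if len(obs) < need:
            dropped.append({"feature": feat, "reason": "presence"})
            continue
        if len(obs) >= 2 and obs.mean() != 0:
            cv = 100.0 * obs.std() / obs.mean()
        else:
            cv = 0.0 if len(obs) == 1 else np.inf
        if cv > cv_max:
            dropped.append({"feature": feat, "reason": "cv"})
            continue
        keep.append(feat)
    report = pd.DataFrame(dropped, columns=["feature", "reason"])
    return matrix[keep], report


def knn_impute(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute each missing value from the k most similar features.

    Features are treated as the imputation rows (a feature's N/A in a sample
    is filled with the average of the k nearest features' values in that
    sample, nearest by Euclidean distance over mutually observed samples).
    Observed values are never altered.
    """
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)]
        raise ValueError(f"feature(s) with no observed values: {list(bad)[:5]}")
    if (matrix.notna().sum(axis=0) < 2).any():
        bad = matrix.columns[matrix.notna().sum(axis=0) < 2]
        raise ValueError(f"feature(s) with fewer than 2 observed values: {list(bad)[:5]}")
    if not matrix.isna().any().any():
        return matrix.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(matrix.T.to_numpy())  # rows = features
    return pd.DataFrame(filled.T, index=matrix.index, columns=matrix.columns)


def pqn_normalize(matrix: pd.DataFrame, is_qc_pool) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization against the QC-pool reference.

    The reference is the feature-wise median over QC pools; each sample's
    quotient is the median over features of sample/reference, and the sample
    is divided by it.  Features with a zero reference are excluded from the
    quotient computation (but still rescaled).
    """
    is_qc_pool = np.asarray(is_qc_pool, dtype=bool)
    if is_qc_pool.sum() < 2:
        raise ValueError("PQN requires at least 2 QC pool samples")
    if matrix.isna().any().any():
        raise ValueError("PQN requires a complete (imputed) matrix")
    reference = matrix.loc[is_qc_pool].median(axis=0)
    usable = reference != 0
    if not usable.all():
        log.info("excluding %d zero-reference features from quotients",
                 int((~usable).sum()))
    if not usable.any():
        raise ValueError("all reference features are zero")
    quotients = matrix.loc[:, usable].div(reference[usable], axis=1).median(axis=1)
    normalized = matrix.div(quotients, axis=0)
    return normalized, quotients


def preprocess(matrix: pd.DataFrame, is_qc_pool, presence: float = 0.5,
               cv_max: float = 20.0, k: int = 5):
    """Full QC chain: filter -> impute -> normalize."""
    filtered, report = qc_filter(matrix, is_qc_pool, presence=presence, cv_max=cv_max)
    imputed = knn_impute(filtered, k=k)
    normalized, quotients = pqn_normalize(imputed, is_qc_pool)
    return normalized, report, quotients
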