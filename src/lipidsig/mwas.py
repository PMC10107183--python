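"""Metabolome-wide association study (MWAS) with a permutation FWER threshold.

Each SNP's additive dosage is regressed against every metabolomic feature
with adjustment for age, sex and cohort, after residualizing features on
per-cohort genomic principal components (population stratification).
Because features are strongly correlated, Bonferroni over the feature count
is far too strict; the metabolome-wide significance level (MWSL) is instead
the ``fwer``-quantile of the minimum p-value over permutations of the
genotype vector — permuting genotypes leaves the feature correlation
structure intact, so the threshold adapts to the effective number of tests
(reported as ``fwer / MWSL``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MwasDesign", "residualize", "associate", "mwsl", "summarize"]

log = logging.getLogger(__name__)


@dataclass
class MwasDesign:
    genotypes: pd.DataFrame          # individuals x SNPs, additive dosages in [0, 2]
    covariates: pd.DataFrame         # columns: age, sex, cohort
    features: pd.DataFrame           # individuals x features
    pcs: pd.DataFrame | None = None  # genomic PCs (aligned rows; used per cohort)
    class_map: dict = field(default_factory=dict)  # feature -> metabolite class

    def __post_init__(self):
        idx = self.genotypes.index
        for name, df in (("covariates", self.covariates), ("features", self.features)):
            if not df.index.equals(idx):
                raise ValueError(f"{name} rows are not aligned with genotypes")
        if self.pcs is not None and not self.pcs.index.equals(idx):
            raise ValueError("pcs rows are not aligned with genotypes")
        d = self.genotypes.to_numpy(dtype=float)
        if np.nanmin(d) < 0 or np.nanmax(d) > 2:
            raise ValueError("dosages must lie in [0, 2]")


def residualize(features: pd.DataFrame, pcs: pd.DataFrame, cohort) -> pd.DataFrame:
    """Within each cohort, replace every feature by its residual from a
    least-squares regression on that cohort's PCs (intercept included)."""
    cohort = pd.Series(np.asarray(cohort), index=features.index)
    out = features.astype(float).copy()
    for c in pd.unique(cohort):
        rows = features.index[cohort == c]
        Z = np.column_stack([np.ones(len(rows)), pcs.loc[rows].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError(f"PC matrix for cohort {c!r} is rank-deficient")
        F = out.loc[rows].to_numpy()
        beta, *_ = np.linalg.lstsq(Z, F, rcond=None)
        out.loc[rows] = F - Z @ beta
    return out


def _covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex + cohort indicator columns."""
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    if "age" in covariates:
        cols.append(covariates["age"].to_numpy(dtype=float)); names.append("age")
    if "sex" in covariates:
        s = covariates["sex"]
        cols.append(pd.factorize(s)[0].astype(float) if s.dtype == object
                    else s.to_numpy(dtype=float))
        names.append("sex")
    if "cohort" in covariates:
        dummies = pd.get_dummies(covariates["cohort"], drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float)); names.append(f"cohort[{c}]")
    C = np.column_stack(cols)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        corr = np.corrcoef(C[:, 1:].T)
        for i in range(corr.shape[0]):
            for j in range(i + 1, corr.shape[0]):
                if abs(corr[i, j]) > 1 - 1e-12:
                    raise ValueError(f"collinear covariates: {names[i+1]} and {names[j+1]}")
        raise ValueError("covariate matrix is rank-deficient")
    return C


def associate(design: MwasDesign) -> pd.DataFrame:
    """Per (SNP, feature) linear-model scan.

    Fits ``feature ~ intercept + dosage + age + sex + cohort`` and reports
    the dosage effect, its standard error and the two-sided t-test p-value.
    """
    C = _covariate_matrix(design.covariates)
    F = design.features.to_numpy(dtype=float)
    n, m = F.shape
    rows = []
    for snp in design.genotypes.columns:
        g = design.genotypes[snp].to_numpy(dtype=float)
        D = np.column_stack([C, g])
        k = D.shape[1]
        DtD_inv = np.linalg.inv(D.T @ D)
        B = DtD_inv @ (D.T @ F)                 # (k, m)
        resid = F - D @ B
        dof = n - k
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * DtD_inv[-1, -1])
        beta = B[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        for j, feat in enumerate(design.features.columns):
            rows.append({"snp": snp, "feature": feat, "beta": beta[j],
                         "se": se[j], "p": p[j]})
    return pd.DataFrame(rows)


def _residualizer(C: np.ndarray):
    """Return a function projecting vectors/matrices off the span of C."""
    pinv = np.linalg.pinv(C)

    def project_off(M: np.ndarray) -> np.ndarray:
        return M - C @ (pinv @ M)

    return project_off


def mwsl(design: MwasDesign, snp: str, n_perm: int = 1000, fwer: float = 0.05,
         seed: int = 0) -> dict:
    """Permutation-estimated metabolome-wide significance level for one SNP.

    The SNP's dosage vector is permuted across individuals (features and
    covariates fixed), the full feature scan is rerun per permutation via the
    partial-correlation identity (equal to the covariate-adjusted regression
    t-test), and the minimum p is recorded.  MWSL is the empirical
    ``fwer``-quantile of that min-p distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    C = _covariate_matrix(design.covariates)
    project_off = _residualizer(C)
    F_res = project_off(design.features.to_numpy(dtype=float))
    F_norm = np.linalg.norm(F_res, axis=0)
    F_unit = F_res / np.where(F_norm > 0, F_norm, 1.0)

    g = design.genotypes[snp].to_numpy(dtype=float)
    n = len(g)
    dof = n - (C.shape[1] + 1)

    G = np.empty((n, n_perm))
    for b in range(n_perm):
        G[:, b] = g[rng.permutation(n)]
    G_res = project_off(G)
    G_norm = np.linalg.norm(G_res, axis=0)
    G_unit = G_res / np.where(G_norm > 0, G_norm, 1.0)

    r = np.clip(F_unit.T @ G_unit, -1.0, 1.0)       # (m features, n_perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    min_p = p.min(axis=0)

    k = max(int(fwer * (n_perm + 1)), 1)
    threshold = float(np.sort(min_p)[k - 1])
    return {
        "snp": snp,
        "mwsl": threshold,
        "fwer": fwer,
        "n_perm": n_perm,
        "effective_tests": fwer / threshold if threshold > 0 else np.inf,
    }


def summarize(results: pd.DataFrame, class_map: dict) -> dict:
    """Counts of significant associations per SNP and proportions per
    metabolite class.  Features missing from the class map count as other."""
    sig = results[results["significant"].astype(bool)] if len(results) else results
    per_snp = sig.groupby("snp").size().to_dict() if len(sig) else {}
    classes = []
    for feat in sig["feature"]:
        if feat not in class_map:
            log.info("feature %s missing from class map; counted as other", feat)
        classes.append(class_map.get(feat, "other"))
    if classes:
        counts = pd.Series(classes).value_counts()
        proportions = (counts / counts.sum() * 100.0).round(2).to_dict()
    else:
        proportions = {}
    return {
        "n_significant": int(len(sig)),
        "per_snp": per_snp,
        "class_proportions_percent": proportions,
        "proportions_defined": bool(classes),
    }
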