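"""Univariate screens over lipidomic features.

The genotype screen runs both a Student t test and a Mann-Whitney test per
feature on raw intensities and flags features with p < alpha in both tests
and a relative fold change |rFC| = |mean_case/mean_control - 1| above a
floor (default 0.5).  The four-group genotype x sex analysis is a one-way
ANOVA over the crossed cells with BH correction across features and pairwise
Welch contrasts for the significant ones.  Significant features are then
organised by average-linkage hierarchical clustering on 1 - Spearman rho.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrich import bh_adjust

__all__ = ["univariate_screen", "anova_genotype_sex", "spearman_cluster"]

log = logging.getLogger(__name__)


def univariate_screen(matrix: pd.DataFrame, groups, control,
                      rfc_min: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
    """Two-test genotype screen on a raw samples x features matrix.

    ``groups`` labels each sample; ``control`` names the reference level.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.index)
    levels = [l for l in pd.unique(groups) if l != control]
    if control not in set(groups) or len(levels) != 1:
        raise ValueError("need exactly two groups including the control")
    case = levels[0]
    a = matrix.loc[groups == case]
    b = matrix.loc[groups == control]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 samples")

    rows = []
    for feat in matrix.columns:
        x, y = a[feat].to_numpy(), b[feat].to_numpy()
        t_p = stats.ttest_ind(x, y).pvalue
        mw_p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        ctrl_mean = y.mean()
        rfc = x.mean() / ctrl_mean - 1.0 if ctrl_mean != 0 else np.nan
        rows.append({"feature": feat, "t_p": t_p, "mw_p": mw_p, "rfc": rfc,
                     "rfc_undefined": ctrl_mean == 0})
    out = pd.DataFrame(rows)
    out["significant"] = ((out["t_p"] < alpha) & (out["mw_p"] < alpha)
                          & (np.abs(out["rfc"]) > rfc_min)
                          & ~out["rfc_undefined"])
    return out


def anova_genotype_sex(matrix: pd.DataFrame, genotype, sex,
                       alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across the four genotype x sex cells, BH over features.

    For BH-significant features the pairwise Welch-t contrast p-values
    between all cell pairs are reported, with the largest-gap pair named.
    """
    genotype = pd.Series(np.asarray(genotype), index=matrix.index)
    sex = pd.Series(np.asarray(sex), index=matrix.index)
    cell = genotype.astype(str) + ":" + sex.astype(str)
    cells = sorted(cell.unique())
    if len(cells) != 4:
        raise ValueError(f"expected 4 genotype x sex cells, got {cells}")
    groups = {c: matrix.index[cell == c] for c in cells}
    for c, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty cell {c!r}")

    pvals = []
    for feat in matrix.columns:
        arrays = [matrix.loc[groups[c], feat].to_numpy() for c in cells]
        pvals.append(stats.f_oneway(*arrays).pvalue)
    out = pd.DataFrame({"feature": matrix.columns, "p": pvals})
    out["q"] = bh_adjust(out["p"].fillna(1.0).to_numpy())
    out["significant"] = out["q"] < alpha

    contrasts = []
    for feat, sig in zip(out["feature"], out["significant"]):
        if not sig:
            contrasts.append("")
            continue
        best_pair, best_p = "", 1.1
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                x = matrix.loc[groups[cells[i]], feat]
                y = matrix.loc[groups[cells[j]], feat]
                pp = stats.ttest_ind(x, y, equal_var=False).pvalue
                if pp < best_p:
                    best_pair, best_p = f"{cells[i]} vs {cells[j]}", pp
        contrasts.append(best_pair)
    out["top_contrast"] = contrasts
    return out


def spearman_cluster(matrix: pd.DataFrame):
    """Spearman correlation + average-linkage clustering of features.

    Returns (rho DataFrame, linkage matrix, leaf order as feature names).
    Constant features have no defined rank correlation and are dropped.
    """
    x = matrix.astype(float)
    constant = x.nunique(axis=0) <= 1
    if constant.any():
        log.info("dropping constant feature(s): %s", list(x.columns[constant])[:5])
        x = x.loc[:, ~constant]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 non-constant features")
    rho = x.corr(method="spearman")
    dist = 1.0 - rho.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [rho.columns[i] for i in hierarchy.leaves_list(linkage)]
    return rho, linkage, order
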