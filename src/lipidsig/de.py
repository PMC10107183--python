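"""Permutation-based differential expression.

Two workflows are covered:

* microarray transcriptomics — a SAM-style moderated statistic
  ``d_i = (mean_2 - mean_1) / (s_i + s0)`` with a permutation null, where the
  threshold ``delta`` on the sorted-statistic deviation is tuned so the
  estimated global false discovery proportion stays below a target (default
  3%) and the upper-tail (90th percentile of permutation false-positive
  counts) estimate stays below a second target (default 5%);
* label-free / iTRAQ proteomics — decoy/contaminant and missingness
  filtering, down-shifted-normal imputation of the remaining N/As (missing
  values are treated as censored low-abundance observations), a two-tailed
  t test with a permutation FDR, and for iTRAQ an extra fold-change band
  (proteins with linear fold change inside 0.83-1.17 are treated as
  unchanged regardless of significance).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SamParams",
    "sam_test",
    "proteomics_clean",
    "impute_downshifted_normal",
    "perm_ttest",
    "itraq_fc_filter",
]


@dataclass
class SamParams:
    n_perm: int = 200
    s0: float | None = None          # None -> median of gene-wise denominators
    delta: float | None = None       # None -> tuned to the FDR targets
    target_fdr: float = 0.03         # cap on median-based FDR estimate
    target_fdr_q90: float = 0.05     # cap on 90th-percentile FP based estimate
    n_delta_grid: int = 200

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be >= 0")


def _two_group_index(labels) -> tuple[np.ndarray, np.ndarray, list]:
    """Split labels into two groups, lexicographically ordered (first =
    reference), so that swapping the labels negates the statistics."""
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {list(groups)}")
    i1 = np.flatnonzero(labels == groups[0])
    i2 = np.flatnonzero(labels == groups[1])
    if len(i1) < 3 or len(i2) < 3:
        raise ValueError("each group needs at least 3 samples")
    return i1, i2, list(groups)


def _label_permutations(n: int, n1: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Index sets (rows) assigning n1 of n samples to group 1.

    All C(n, n1) distinct assignments are enumerated when there are no more
    than ``n_perm`` of them; otherwise ``n_perm`` assignments are sampled
    without replacement.
    """
    total = math.comb(n, n1)
    if total <= n_perm:
        return np.array(list(itertools.combinations(range(n), n1)), dtype=int)
    seen: set[tuple[int, ...]] = set()
    while len(seen) < n_perm:
        seen.add(tuple(sorted(rng.choice(n, size=n1, replace=False))))
    return np.array(sorted(seen), dtype=int)


def _d_stat(x: np.ndarray, i1: np.ndarray, i2: np.ndarray, s0: float | None):
    """SAM statistic for every row; returns (d, s_i, s0_used, fc)."""
    n1, n2 = len(i1), len(i2)
    m1 = x[:, i1].mean(axis=1)
    m2 = x[:, i2].mean(axis=1)
    ss1 = ((x[:, i1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x[:, i2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    if s0 is None:
        s0 = float(np.median(s))
        if s0 == 0.0:
            s0 = 1e-8  # all-constant matrix floor
    d = (m2 - m1) / (s + s0)
    return d, s, s0, m1, m2


def sam_test(matrix, labels, params: SamParams | None = None, seed: int = 0) -> pd.DataFrame:
    """SAM-style two-class differential expression on a log2 matrix.

    ``matrix`` is a DataFrame (rows = genes, columns = samples) with no N/As.
    Returns a per-gene table with the statistic ``d``, linear fold change and
    the ``called`` flag; the tuned ``delta`` and the two FDR estimates are
    stored in ``result.attrs``.
    """
    params = params or SamParams()
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("sam_test requires a complete (no N/A) matrix")
    i1, i2, groups = _two_group_index(labels)
    rng = np.random.default_rng(seed)

    d, _, s0, m1, m2 = _d_stat(x, i1, i2, params.s0)
    order = np.argsort(d)
    d_sorted = d[order]

    perms = _label_permutations(x.shape[1], len(i1), params.n_perm, rng)
    all_idx = np.arange(x.shape[1])
    perm_sorted = np.empty((len(perms), x.shape[0]))
    for b, p1 in enumerate(perms):
        p2 = np.setdiff1d(all_idx, p1, assume_unique=True)
        db, *_ = _d_stat(x, p1, p2, s0)
        perm_sorted[b] = np.sort(db)
    dbar = perm_sorted.mean(axis=0)

    dev = d_sorted - dbar

    def _evaluate(delta: float):
        pos = np.flatnonzero(dev > delta)
        neg = np.flatnonzero(dev < -delta)
        # cut lines: smallest called d on the positive side, largest on the negative
        cut_up = d_sorted[pos].min() if pos.size else np.inf
        cut_low = d_sorted[neg].max() if neg.size else -np.inf
        called_mask_sorted = (d_sorted >= cut_up) | (d_sorted <= cut_low)
        n_called = int(called_mask_sorted.sum())
        fp = (perm_sorted >= cut_up).sum(axis=1) + (perm_sorted <= cut_low).sum(axis=1)
        denom = max(n_called, 1)
        fdr = min(float(np.median(fp)) / denom, 1.0)
        fdr90 = min(float(np.percentile(fp, 90)) / denom, 1.0)
        return called_mask_sorted, n_called, fdr, fdr90

    if params.delta is not None:
        delta = params.delta
        called_sorted, n_called, fdr, fdr90 = _evaluate(delta)
    else:
        # smallest delta on a quantile grid meeting both FDR targets
        grid = np.unique(np.quantile(np.abs(dev), np.linspace(0, 1, params.n_delta_grid)))
        delta, called_sorted, n_called, fdr, fdr90 = None, None, 0, 1.0, 1.0
        for cand in grid:
            cs, nc, f, f90 = _evaluate(cand)
            if f <= params.target_fdr and f90 <= params.target_fdr_q90:
                delta, called_sorted, n_called, fdr, fdr90 = float(cand), cs, nc, f, f90
                break
        if delta is None:  # nothing satisfies the targets: call nothing
            delta = float(np.abs(dev).max()) + 1.0
            called_sorted, n_called, fdr, fdr90 = _evaluate(delta)

    called = np.zeros(x.shape[0], dtype=bool)
    called[order] = called_sorted
    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else list(range(x.shape[0]))
    out = pd.DataFrame({
        "id": ids,
        "stat": d,
        "mean_control": m1,
        "mean_treatment": m2,
        "fc": 2.0 ** (m2 - m1),
        "called": called,
    })
    out.attrs.update({"delta": delta, "s0": s0, "fdr": fdr, "fdr90": fdr90,
                      "n_called": n_called, "groups": groups})
    return out


def proteomics_clean(matrix: pd.DataFrame, flags: pd.DataFrame, groups,
                     na_fraction: float = 2 / 3, strict: bool = False) -> pd.DataFrame:
    """Decoy/contaminant and missingness filter, then log2 transform.

    Rows flagged reverse-decoy / only-identified-by-site / contaminant are
    dropped; a row is dropped for missingness when the N/A count reaches
    ``ceil(na_fraction * n_g)`` in every group (``strict=True``: in any
    group).  Raw intensities in, log2 intensities out.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    for g, n_g in groups.value_counts().items():
        if n_g < 3:
            raise ValueError(f"group {g!r} has {n_g} replicates; need >= 3")
    flagged = flags.reindex(matrix.index).fillna(False).astype(bool).any(axis=1)
    kept = matrix.loc[~flagged]

    na_by_group = {}
    for g in groups.unique():
        cols = groups.index[groups == g]
        thresh = math.ceil(na_fraction * len(cols))
        na_by_group[g] = kept[cols].isna().sum(axis=1) >= thresh
    na_table = pd.DataFrame(na_by_group)
    too_missing = na_table.any(axis=1) if strict else na_table.all(axis=1)
    kept = kept.loc[~too_missing]
    return np.log2(kept)


def impute_downshifted_normal(matrix: pd.DataFrame, width: float = 0.3,
                              shift: float = 1.8, seed: int = 0) -> pd.DataFrame:
    """Replace N/As with draws from a down-shifted normal, per sample column.

    Missing intensities are assumed to sit below the detection limit, so each
    N/A in sample ``j`` is drawn from ``Normal(mean_j - shift * sd_j,
    width * sd_j)`` where the moments come from the observed log2 values of
    that column.  Observed values are untouched.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        v = out[col]
        obs = v.dropna()
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        n_missing = int(v.isna().sum())
        if n_missing:
            mu = obs.mean() - shift * obs.std()
            sd = width * obs.std()
            out.loc[v.isna(), col] = rng.normal(mu, sd, size=n_missing)
    return out


def perm_ttest(matrix, labels, n_perm: int = 200, alpha: float = 0.05,
               seed: int = 0) -> pd.DataFrame:
    """Row-wise two-tailed t test with a permutation-estimated FDR.

    For each row the q-value is the average count of permutation statistics
    at least as extreme as the observed one, divided by the observed count at
    that threshold, capped at 1 and monotonized; rows with ``q < alpha`` are
    called.
    """
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("perm_ttest requires a complete matrix")
    i1, i2, groups = _two_group_index(labels)
    rng = np.random.default_rng(seed)
    n, m = x.shape[1], x.shape[0]

    def tstat(a1, a2):
        n1, n2 = len(a1), len(a2)
        m1 = x[:, a1].mean(axis=1)
        m2 = x[:, a2].mean(axis=1)
        v1 = x[:, a1].var(axis=1, ddof=1)
        v2 = x[:, a2].var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
        denom = np.where(denom == 0, np.inf, denom)
        return (m2 - m1) / denom, m1, m2

    t_obs, m1, m2 = tstat(i1, i2)
    from scipy import stats
    df = len(i1) + len(i2) - 2
    p = 2.0 * stats.t.sf(np.abs(t_obs), df)

    perms = _label_permutations(n, len(i1), n_perm, rng)
    all_idx = np.arange(n)
    abs_perm = np.empty((len(perms), m))
    for b, p1 in enumerate(perms):
        p2 = np.setdiff1d(all_idx, p1, assume_unique=True)
        abs_perm[b] = np.abs(tstat(p1, p2)[0])
    pooled = np.sort(abs_perm.ravel())
    abs_obs = np.abs(t_obs)
    obs_sorted = np.sort(abs_obs)

    # mean permutation exceedance count / observed exceedance count
    n_perm_eff = len(perms)
    exceed_perm = (len(pooled) - np.searchsorted(pooled, abs_obs, side="left")) / n_perm_eff
    exceed_obs = len(obs_sorted) - np.searchsorted(obs_sorted, abs_obs, side="left")
    q = np.minimum(exceed_perm / np.maximum(exceed_obs, 1), 1.0)

    # monotonize: q non-increasing in |t|
    order = np.argsort(-abs_obs)
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_mon = np.empty_like(q)
    q_mon[order] = q_sorted

    ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else list(range(m))
    out = pd.DataFrame({
        "id": ids,
        "stat": t_obs,
        "p": p,
        "q": q_mon,
        "fc": 2.0 ** (m2 - m1),
        "called": q_mon < alpha,
    })
    out.attrs["groups"] = groups
    return out


def itraq_fc_filter(results: pd.DataFrame, upper: float = 1.17,
                    lower: float = 0.83) -> pd.DataFrame:
    """Keep a protein called only if its linear fold change leaves the
    unchanged band [lower, upper] (boundaries count as outside-the-band)."""
    out = results.copy()
    out["called"] = results["called"] & ((results["fc"] >= upper) | (results["fc"] <= lower))
    return out
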