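"""Expression-weighted cell-type enrichment (EWCE).

A gene's specificity for a cell type is its mean expression there divided by
its summed mean expression over all cell types; a gene list's score in a cell
type is the sum of its members' specificities.  Enrichment is tested against
bootstrap lists of the same size drawn uniformly without replacement from all
genes, with the plus-one rule ``p = (1 + #{boot >= observed}) / (n_boot + 1)``
and the effect size S.D.f.M = (observed - bootstrap mean) / bootstrap sd.
The conditional variant controls for a second cell type by sampling bootstrap
lists that match the gene list's distribution over quantile bins of the
control cell type's specificity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrich import bh_adjust

__all__ = ["specificity", "ewce_test", "conditional_ewce"]

log = logging.getLogger(__name__)


def specificity(mean_expr: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a genes x cell-types mean-expression matrix.

    All-zero gene rows are dropped (their specificity is undefined).
    """
    x = mean_expr.astype(float)
    if (x.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    totals = x.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.info("dropping %d all-zero gene rows: %s", int(zero.sum()),
                 list(x.index[zero])[:5])
        x = x.loc[~zero]
        totals = totals[~zero]
    return x.div(totals, axis=0)


def _boot_indices(rng: np.random.Generator, n_boot: int, pool_size: int,
                  set_size: int) -> np.ndarray:
    """(n_boot, set_size) indices into the pool, each row sampled without
    replacement (argpartition over random keys)."""
    keys = rng.random((n_boot, pool_size))
    return np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]


def _finalize(spec: pd.DataFrame, observed: np.ndarray, boot: np.ndarray,
              n_boot: int) -> pd.DataFrame:
    mean = boot.mean(axis=0)
    sd = boot.std(axis=0, ddof=1)
    # tie tolerance: summation order must not break boot == observed ties
    tol = 1e-9 * np.maximum(np.abs(observed), 1.0)
    p = (1.0 + (boot >= (observed - tol)[None, :]).sum(axis=0)) / (n_boot + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sdfm = np.where(sd > 0, (observed - mean) / sd, np.nan)
    return pd.DataFrame({
        "celltype": spec.columns,
        "score": observed,
        "boot_mean": mean,
        "boot_sd": sd,
        "sdfm": sdfm,
        "p": p,
        "q": bh_adjust(p),
        "n_boot": n_boot,
    })


def _prepare_set(gene_set, spec: pd.DataFrame) -> list[str]:
    gene_set = set(gene_set)
    dropped = gene_set - set(spec.index)
    if dropped:
        log.info("dropping %d genes absent from the specificity matrix", len(dropped))
    members = sorted(gene_set & set(spec.index))
    if not members:
        raise ValueError("gene set empty after intersecting with the specificity matrix")
    if len(members) < 2:
        raise ValueError("gene set must contain at least 2 scored genes")
    return members


def ewce_test(gene_set, spec: pd.DataFrame, n_boot: int = 10000,
              seed: int = 0) -> pd.DataFrame:
    """Bootstrap cell-type enrichment of a gene list."""
    members = _prepare_set(gene_set, spec)
    rng = np.random.default_rng(seed)
    s = spec.to_numpy()
    observed = spec.loc[members].sum(axis=0).to_numpy()
    idx = _boot_indices(rng, n_boot, len(spec), len(members))
    boot = s[idx].sum(axis=1)  # (n_boot, n_celltypes)
    return _finalize(spec, observed, boot, n_boot)


def conditional_ewce(gene_set, spec: pd.DataFrame, control_celltype: str,
                     n_boot: int = 10000, n_bins: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """EWCE with bootstrap lists matched, per quantile bin of the control
    cell type's specificity, to the gene list's bin occupancy."""
    if control_celltype not in spec.columns:
        raise KeyError(f"unknown control cell type {control_celltype!r}")
    members = _prepare_set(gene_set, spec)
    rng = np.random.default_rng(seed)
    s = spec.to_numpy()
    observed = spec.loc[members].sum(axis=0).to_numpy()

    control = spec[control_celltype]
    bins = pd.qcut(control.rank(method="first"), q=n_bins, labels=False,
                   duplicates="drop")
    if control.nunique() == 1:
        bins = pd.Series(0, index=spec.index)  # constant control: one bin
    member_bins = bins.loc[members]

    boot = np.zeros((n_boot, spec.shape[1]))
    for b, count in member_bins.value_counts().items():
        pool = np.flatnonzero((bins == b).to_numpy())
        if pool.size == 0:
            raise ValueError(f"specificity bin {b} has no candidate genes")
        idx = _boot_indices(rng, n_boot, pool.size, int(count))
        boot += s[pool[idx]].sum(axis=1)
    return _finalize(spec, observed, boot, n_boot)
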