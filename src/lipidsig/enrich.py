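"""Over-representation analysis: right-tailed hypergeometric / EASE tests
with Benjamini-Hochberg correction.

One engine serves pathway enrichment on the metabolic network, GO-like term
libraries and TF-target libraries; they differ only in the gene-set
collection and background.  The EASE variant recomputes the tail with one
overlap gene removed (a conservative penalty for small overlaps).
A term is significant under the dual rule: raw p < alpha AND BH q < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "hypergeom_enrich",
    "pathway_gene_sets",
]


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.background:
            self.background = set().union(*self.sets.values()) if self.sets else set()
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"term {term!r} is empty")
            extra = members - self.background
            if extra:
                raise ValueError(f"term {term!r} has members outside the background: {sorted(extra)[:5]}")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(filter(None, parts[2:]))
    return GeneSetCollection(name=str(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\tna\t{members}\n")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(query, collection: GeneSetCollection, ease: bool = False,
                     min_count: int = 2, alpha: float = 0.05,
                     ease_screen: float | None = None) -> pd.DataFrame:
    """Right-tailed over-representation of ``query`` in each term of the
    collection.

    With a background of N ids, a term of K members and n query ids in the
    background, the p-value for an overlap of k is ``P(X >= k)`` for
    ``X ~ Hypergeometric(N, K, n)``; the EASE score instead takes the tail
    from ``k - 1``.  Terms with overlap below ``min_count`` are skipped.
    ``ease_screen`` (e.g. 0.1) drops terms whose EASE p exceeds it before the
    BH correction.  Significance requires both raw p and BH q below alpha.
    """
    query = set(query)
    n_outside = len(query - collection.background)
    query &= collection.background
    if not query:
        raise ValueError("query is empty after intersecting with the background")

    N = len(collection.background)
    n = len(query)
    rows = []
    for term, members in collection.sets.items():
        k = len(query & members)
        if k < min_count:
            continue
        K = len(members)
        successes = k - 1 if ease else k
        p = float(stats.hypergeom.sf(successes - 1, N, K, n))  # P(X >= successes)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0), "coverage": k / K})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "coverage"])
    if ease_screen is not None and len(out):
        out = out[out["p"] <= ease_screen].reset_index(drop=True)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = (out["p"] < alpha) & (out["q"] < alpha)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["dropped_query_ids"] = n_outside
    return out


def pathway_gene_sets(network, name: str = "gsmn-pathways") -> GeneSetCollection:
    """Pathway -> gene sets via gene -> reaction -> pathway incidence, with
    all network-mapped genes as background."""
    reaction_genes: dict[str, set[str]] = {}
    for g, r in network.gene_reaction:
        reaction_genes.setdefault(r, set()).add(g)
    sets = {}
    for pwy, reactions in network.pathways.items():
        genes = set().union(*(reaction_genes.get(r, set()) for r in reactions)) \
            if reactions else set()
        if genes:
            sets[pwy] = genes
    return GeneSetCollection(name=name, sets=sets, background=set(network.genes))
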