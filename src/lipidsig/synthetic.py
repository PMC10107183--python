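"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's data, not
its chemistry or raw spectra: two-group log-normal expression with planted
differential genes, label-free proteomics with missing-not-at-random
censoring, a crossed genotype x sex lipidomics design with pooled QC
samples, an equicorrelated-block metabolome cohort with Hardy-Weinberg
genotypes, and a cell-type mean-expression reference with a planted
specific gene set.  All effects are planted as additive shifts on the log2
scale (multiplicative on raw intensities).  One global seed drives fixed
per-generator substreams, so adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.special import expit

from .mwas import MwasDesign
from .network import MetabolicNetwork, Metabolite

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_gsmn",
    "gen_expression",
    "gen_proteomics",
    "gen_lipidomics",
    "gen_mwas_cohort",
    "gen_celltype_reference",
]

# fixed substream offsets (do not renumber: determinism contract)
_STREAMS = {"gsmn": 1, "expression": 2, "proteomics": 3, "lipidomics": 4,
            "mwas": 5, "celltype": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimConfig:
    seed: int = 0
    # --- metabolic network ---
    n_pathways: int = 6
    reactions_per_pathway: int = 4
    genes_per_reaction: int = 2
    metabolites_per_reaction: int = 2
    n_lipid_pathways: int = 2
    n_lipid_terms: int = 3          # class-level lipid terms, in lipid pathways
    species_per_term: int = 3       # detected species each term expands to
    # --- transcriptomics ---
    n_genes: int = 1000
    n_samples_per_group: int = 5
    n_de_genes: int = 50
    de_effect: float = 2.0          # log2 shift in the treatment group
    expr_sd: float = 1.0
    # --- proteomics ---
    n_proteins: int = 500
    n_contaminants: int = 10
    n_de_proteins: int = 25
    protein_effect: float = 2.0
    missing_rate: float = 0.2
    mnar_slope: float = 1.0         # logistic link on true log2 intensity
    # --- lipidomics (crossed genotype x sex design) ---
    n_lipid_features: int = 200
    n_per_genotype: int = 7
    n_females_per_genotype: int = 3
    n_qc_pools: int = 3
    n_signature_effects: int = 10   # annotated species given a genotype effect
    genotype_effect: float = 1.5    # log2
    interaction_effect: float = 0.0 # extra log2 shift in KO females
    biological_sd: float = 0.4      # log2
    technical_cv: float = 0.05      # QC pool relative noise
    # --- MWAS cohort ---
    n_individuals: int = 500
    n_snps: int = 1
    maf: float = 0.3
    n_mwas_features: int = 200
    n_blocks: int = 20
    block_rho: float = 0.7
    snp_beta: float = 0.0
    n_planted_assoc: int = 1
    n_pcs: int = 10
    n_cohorts: int = 2
    # --- cell-type reference ---
    n_celltypes: int = 5
    n_celltype_genes: int = 500
    planted_set_size: int = 20
    specificity_boost: float = 4.0  # fold-increase in the target cell type

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("n_") and v < 0:
                raise ValueError(f"invalid configuration: {f.name} must be non-negative, got {v}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("invalid configuration: missing_rate must lie in [0, 1]")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("invalid configuration: block_rho must lie in [0, 1)")
        if self.n_pathways < 2:
            raise ValueError("invalid configuration: n_pathways must be >= 2")
        if self.n_lipid_pathways < 1 or self.n_lipid_pathways > self.n_pathways:
            raise ValueError("invalid configuration: n_lipid_pathways out of range")
        if self.n_lipid_terms < 1:
            raise ValueError("invalid configuration: n_lipid_terms must be >= 1")


@dataclass
class SimTruth:
    seed: int
    de_elements: set = field(default_factory=set)
    enriched_pathways: set = field(default_factory=set)
    signature_species: set = field(default_factory=set)
    effect_table: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------

def gen_gsmn(config: SimConfig):
    """Synthetic gene-reaction-metabolite network with lipid pathways.

    Returns (network, xref, expansion):

    * ``xref`` — metabolite cross-reference table (metabolite_id, lipid_id,
      label, is_lipid);
    * ``expansion`` — detected-species expansion of each class-level lipid
      term (term_metabolite_id, label, lipid_id).
    """
    c = config
    genes, reactions, mets = [], [], {}
    pathways: dict[str, list[str]] = {}
    gene_reaction, reaction_metabolite = set(), set()
    xref_rows, expansion_rows = [], []

    lipid_pwys = [f"PWY{p:03d}" for p in range(c.n_lipid_pathways)]
    species_counter = term_counter = 0
    rxn_global = 0
    all_rxns: list[str] = []
    for p in range(c.n_pathways):
        pwy = f"PWY{p:03d}"
        is_lipid_pwy = pwy in lipid_pwys
        pathways[pwy] = []
        for _ in range(c.reactions_per_pathway):
            rxn = f"RXN{rxn_global:04d}"
            rxn_global += 1
            reactions.append(rxn)
            pathways[pwy].append(rxn)
            all_rxns.append(rxn)
            for gi in range(c.genes_per_reaction):
                g = f"G{rxn}_{gi}"
                genes.append(g)
                gene_reaction.add((g, rxn))
            for mi in range(c.metabolites_per_reaction):
                # lipid pathways carry class-level terms first, then species
                if is_lipid_pwy and term_counter < c.n_lipid_terms:
                    mid = f"TERM{term_counter:03d}"
                    label = f"lipid term {term_counter}"
                    mets[mid] = Metabolite(mid, is_class=True)
                    xref_rows.append({"metabolite_id": mid, "lipid_id": "",
                                      "label": label, "is_lipid": True})
                    for s in range(c.species_per_term):
                        expansion_rows.append({
                            "term_metabolite_id": mid, "label": label,
                            "lipid_id": f"LMX{term_counter:03d}{s:02d}"})
                    term_counter += 1
                elif is_lipid_pwy:
                    mid = f"LSP{species_counter:04d}"
                    lid = f"LMS{species_counter:04d}"
                    mets[mid] = Metabolite(mid, is_class=False, xref=(lid,))
                    xref_rows.append({"metabolite_id": mid, "lipid_id": lid,
                                      "label": "", "is_lipid": True})
                    species_counter += 1
                else:
                    mid = f"MET{rxn}_{mi}"
                    mets[mid] = Metabolite(mid, is_class=False)
                    xref_rows.append({"metabolite_id": mid, "lipid_id": "",
                                      "label": "", "is_lipid": False})
                reaction_metabolite.add((rxn, mid))
    # chain all reactions through shared link metabolites -> connected graph
    for i in range(len(all_rxns) - 1):
        link = f"LINK{i:04d}"
        mets[link] = Metabolite(link, is_class=False)
        xref_rows.append({"metabolite_id": link, "lipid_id": "", "label": "",
                          "is_lipid": False})
        reaction_metabolite.add((all_rxns[i], link))
        reaction_metabolite.add((all_rxns[i + 1], link))

    net = MetabolicNetwork(
        genes=set(genes), reactions=set(reactions), metabolites=mets,
        pathways=pathways, gene_reaction=gene_reaction,
        reaction_metabolite=reaction_metabolite,
    )
    net.validate()
    xref = pd.DataFrame(xref_rows).sort_values("metabolite_id").reset_index(drop=True)
    expansion = pd.DataFrame(expansion_rows,
                             columns=["term_metabolite_id", "label", "lipid_id"])
    return net, xref, expansion


def gen_expression(config: SimConfig, gene_ids: list[str] | None = None,
                   de_gene_ids: list[str] | None = None):
    """Two-group log2 expression matrix with planted DE genes.

    ``gene_ids`` overrides the synthetic row names (e.g. to reuse network
    gene ids); ``de_gene_ids`` pins the planted genes to specific rows,
    otherwise ``n_de_genes`` rows are chosen at random.
    """
    c = config
    if c.n_samples_per_group < 3:
        raise ValueError("inclusion rule: a minimum of three samples per "
                         "condition is required")
    rng = _rng(c.seed, "expression")
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(c.n_genes)]
    elif len(gene_ids) != c.n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    base = rng.uniform(4, 12, size=c.n_genes)
    n = c.n_samples_per_group
    x = base[:, None] + rng.normal(0, c.expr_sd, size=(c.n_genes, 2 * n))
    de_ids: set[str] = set()
    effects = []
    if c.de_effect != 0.0:
        if de_gene_ids is not None:
            missing = set(de_gene_ids) - set(gene_ids)
            if missing:
                raise ValueError(f"de_gene_ids not in gene_ids: {sorted(missing)[:5]}")
            pos = {g: i for i, g in enumerate(gene_ids)}
            idx = np.array([pos[g] for g in de_gene_ids], dtype=int)
        elif c.n_de_genes > 0:
            idx = rng.choice(c.n_genes, size=min(c.n_de_genes, c.n_genes), replace=False)
        else:
            idx = np.array([], dtype=int)
        x[np.ix_(idx, np.arange(n, 2 * n))] += c.de_effect
        de_ids = {gene_ids[i] for i in idx}
        effects = [{"element": gene_ids[i], "effect": c.de_effect} for i in sorted(idx)]
    samples = [f"CTL{j:02d}" for j in range(n)] + [f"TRT{j:02d}" for j in range(n)]
    labels = ["control"] * n + ["treatment"] * n
    matrix = pd.DataFrame(x, index=gene_ids, columns=samples)
    truth = SimTruth(seed=c.seed, de_elements=de_ids,
                     effect_table=pd.DataFrame(effects, columns=["element", "effect"]))
    return matrix, labels, truth


def gen_proteomics(config: SimConfig):
    """Label-free intensities with MNAR censoring and decoy/contaminant flags.

    The probability that a measurement is censored follows a logistic link
    decreasing in the true log2 intensity, so low-abundance proteins go
    missing more often.  Returns (raw intensity matrix with N/As, flags,
    labels, truth).
    """
    c = config
    rng = _rng(c.seed, "proteomics")
    ids = [f"P{i:05d}" for i in range(c.n_proteins)]
    n = c.n_samples_per_group
    base = rng.uniform(20, 30, size=c.n_proteins)
    x = base[:, None] + rng.normal(0, 0.8, size=(c.n_proteins, 2 * n))
    de_ids: set[str] = set()
    if c.protein_effect != 0.0 and c.n_de_proteins > 0:
        idx = rng.choice(c.n_proteins, size=min(c.n_de_proteins, c.n_proteins),
                         replace=False)
        x[np.ix_(idx, np.arange(n, 2 * n))] += c.protein_effect
        de_ids = {ids[i] for i in idx}
    raw = np.power(2.0, x)
    if c.missing_rate > 0:
        pivot = np.quantile(x, c.missing_rate)
        p_miss = expit(c.mnar_slope * (pivot - x))
        # rescale so the overall expected rate matches the configured rate
        p_miss *= c.missing_rate / max(p_miss.mean(), 1e-12)
        raw = np.where(rng.random(x.shape) < np.clip(p_miss, 0, 1), np.nan, raw)
    samples = [f"CTL{j:02d}" for j in range(n)] + [f"TRT{j:02d}" for j in range(n)]
    labels = ["control"] * n + ["treatment"] * n
    matrix = pd.DataFrame(raw, index=ids, columns=samples)
    n_flag = min(c.n_contaminants, c.n_proteins)
    flag_idx = rng.choice(c.n_proteins, size=n_flag, replace=False) if n_flag else []
    flags = pd.DataFrame(False, index=ids,
                         columns=["contaminant", "reverse", "site"])
    flags.iloc[list(flag_idx), 0] = True
    truth = SimTruth(seed=c.seed, de_elements=de_ids - set(flags.index[flags.any(axis=1)]))
    return matrix, flags, labels, truth


def gen_lipidomics(config: SimConfig, expansion: pd.DataFrame | None = None,
                   species_xref: pd.DataFrame | None = None):
    """Crossed genotype x sex lipidomics with QC pools and annotations.

    Features are log-normal; the first ``n_signature_effects`` annotated
    species carry a multiplicative genotype effect (KO vs WT), the next
    block a genotype x sex interaction (extra shift in KO females).  If a
    term ``expansion`` table and/or first-order ``species_xref`` table from
    :func:`gen_gsmn` are given, their lipid ids are used for the annotation
    table so the predicted signature is discoverable downstream.

    Returns (matrix samples x features, metadata, annotation, truth).
    """
    c = config
    if c.n_qc_pools < 2:
        raise ValueError("need at least 2 QC pool samples")
    rng = _rng(c.seed, "lipidomics")
    n_f = c.n_lipid_features

    # annotation: modes alternate; lipid ids from the network tables first
    lipid_ids: list[str] = []
    classes: list[str] = []
    if expansion is not None and len(expansion):
        lipid_ids += list(expansion["lipid_id"])
        classes += list(expansion["label"])
    if species_xref is not None and len(species_xref):
        sp = species_xref[(species_xref["is_lipid"]) & (species_xref["lipid_id"] != "")]
        lipid_ids += list(sp["lipid_id"])
        classes += ["unassigned"] * len(sp)
    extra = max(0, n_f // 2 - len(lipid_ids))
    lipid_ids += [f"LMD{i:04d}" for i in range(extra)]
    classes += ["decoy class"] * extra
    n_annot = min(len(lipid_ids), n_f)
    annotation = pd.DataFrame({
        "feature_id": [f"F{i:04d}" for i in range(n_annot)],
        "mode": ["negative" if i % 2 == 0 else "positive" for i in range(n_annot)],
        "lipid_id": lipid_ids[:n_annot],
        "lipid_class": classes[:n_annot],
        "level": 2,
    })

    # design
    n_g, n_fem = c.n_per_genotype, c.n_females_per_genotype
    sample_rows = []
    for geno in ("WT", "KO"):
        for j in range(n_g):
            sample_rows.append({
                "sample": f"{geno}{j:02d}", "genotype": geno,
                "sex": "F" if j < n_fem else "M", "is_qc_pool": False})
    for q in range(c.n_qc_pools):
        sample_rows.append({"sample": f"QC{q:02d}", "genotype": "pool",
                            "sex": "pool", "is_qc_pool": True})
    meta = pd.DataFrame(sample_rows).set_index("sample")

    base = rng.uniform(14, 22, size=n_f)
    bio = meta.index[~meta["is_qc_pool"]]
    log2x = base[None, :] + rng.normal(0, c.biological_sd, size=(len(bio), n_f))

    # planted effects on annotated species
    n_eff = c.n_signature_effects
    if n_eff > n_annot:
        raise ValueError("cannot plant effects on more species than are annotated")
    geno_feats = list(range(0, n_eff))
    inter_feats = list(range(n_eff, min(2 * n_eff, n_annot))) \
        if c.interaction_effect != 0.0 else []
    ko = (meta.loc[bio, "genotype"] == "KO").to_numpy()
    female = (meta.loc[bio, "sex"] == "F").to_numpy()
    effects = []
    if c.genotype_effect != 0.0:
        for f_i in geno_feats:
            log2x[ko, f_i] += c.genotype_effect
            effects.append({"element": annotation["lipid_id"].iloc[f_i],
                            "effect": c.genotype_effect, "kind": "genotype"})
    for f_i in inter_feats:
        log2x[ko & female, f_i] += c.interaction_effect
        effects.append({"element": annotation["lipid_id"].iloc[f_i],
                        "effect": c.interaction_effect, "kind": "genotype_x_sex"})

    raw_bio = np.power(2.0, log2x)
    grand = raw_bio.mean(axis=0)
    qc = grand[None, :] * rng.lognormal(0.0, np.log1p(c.technical_cv),
                                        size=(c.n_qc_pools, n_f))
    raw = np.vstack([raw_bio, qc])
    matrix = pd.DataFrame(raw, index=list(bio) + list(meta.index[meta["is_qc_pool"]]),
                          columns=[f"F{i:04d}" for i in range(n_f)])
    matrix = matrix.loc[meta.index]
    truth = SimTruth(
        seed=c.seed,
        signature_species={annotation["lipid_id"].iloc[i] for i in geno_feats}
        if c.genotype_effect != 0.0 else set(),
        effect_table=pd.DataFrame(effects, columns=["element", "effect", "kind"]),
    )
    return matrix, meta, annotation, truth


def gen_mwas_cohort(config: SimConfig):
    """Genotype/covariate/feature cohort with equicorrelated feature blocks.

    Genotypes are Hardy-Weinberg additive dosages at the configured minor
    allele frequency; features are block-equicorrelated Gaussian noise plus
    age/sex/cohort effects plus the planted SNP betas.
    """
    c = config
    if not 0.0 < c.maf <= 0.5:
        raise ValueError(f"minor allele frequency {c.maf} outside (0, 0.5]")
    rng = _rng(c.seed, "mwas")
    n = c.n_individuals
    idx = pd.Index([f"I{i:05d}" for i in range(n)], name="individual")

    geno = pd.DataFrame(
        rng.binomial(2, c.maf, size=(n, c.n_snps)).astype(float),
        index=idx, columns=[f"SNP{j:03d}" for j in range(c.n_snps)])
    cov = pd.DataFrame({
        "age": rng.normal(50, 8, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "cohort": [f"C{k}" for k in rng.integers(0, c.n_cohorts, size=n)],
    }, index=idx)
    pcs = pd.DataFrame(rng.normal(0, 1, size=(n, c.n_pcs)), index=idx,
                       columns=[f"PC{k + 1}" for k in range(c.n_pcs)])

    m = c.n_mwas_features
    block = np.arange(m) % max(c.n_blocks, 1)
    z = rng.normal(0, 1, size=(n, max(c.n_blocks, 1)))
    eps = rng.normal(0, 1, size=(n, m))
    feats = np.sqrt(c.block_rho) * z[:, block] + np.sqrt(1 - c.block_rho) * eps
    # covariate structure
    cohort_codes = pd.factorize(cov["cohort"])[0]
    feats += 0.01 * (cov["age"].to_numpy()[:, None] - 50)
    feats += 0.2 * cov["sex"].to_numpy()[:, None]
    feats += 0.3 * cohort_codes[:, None]

    effects = []
    assoc: set = set()
    feat_names = [f"M{j:04d}" for j in range(m)]
    if c.snp_beta != 0.0 and c.n_planted_assoc > 0:
        for j in range(min(c.n_planted_assoc, m)):
            feats[:, j] += c.snp_beta * geno.iloc[:, 0].to_numpy()
            effects.append({"element": f"{geno.columns[0]}:{feat_names[j]}",
                            "effect": c.snp_beta})
            assoc.add((geno.columns[0], feat_names[j]))
    features = pd.DataFrame(feats, index=idx, columns=feat_names)
    class_map = {f: ("lipid" if j % 10 < 7 else "amino acid")
                 for j, f in enumerate(feat_names)}
    design = MwasDesign(genotypes=geno, covariates=cov, features=features,
                        pcs=pcs, class_map=class_map)
    truth = SimTruth(seed=c.seed, de_elements={f"{s}:{f}" for s, f in assoc},
                     effect_table=pd.DataFrame(effects, columns=["element", "effect"]))
    return design, truth


def gen_celltype_reference(config: SimConfig):
    """Mean-expression-by-cell-type matrix with a planted specific gene set.

    The planted genes have their expression multiplied by
    ``specificity_boost`` in the last (target) cell type.
    """
    c = config
    if c.n_celltypes < 2:
        raise ValueError("need at least 2 cell types")
    rng = _rng(c.seed, "celltype")
    genes = [f"G{i:05d}" for i in range(c.n_celltype_genes)]
    celltypes = [f"CT{k}" for k in range(c.n_celltypes)]
    expr = rng.lognormal(1.0, 0.5, size=(c.n_celltype_genes, c.n_celltypes))
    planted = sorted(rng.choice(c.n_celltype_genes,
                                size=min(c.planted_set_size, c.n_celltype_genes),
                                replace=False))
    expr[planted, -1] *= c.specificity_boost
    matrix = pd.DataFrame(expr, index=genes, columns=celltypes)
    gene_set = {genes[i] for i in planted}
    truth = SimTruth(seed=c.seed, de_elements=gene_set)
    return matrix, gene_set, celltypes[-1], truth
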