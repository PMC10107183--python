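import numpy as np
import pandas as pd
import pytest

from lipidsig import synthetic as syn


class TestConfigValidation:
    def test_negative_count_named_in_error(self):
        with pytest.raises(ValueError, match="n_genes"):
            syn.SimConfig(n_genes=-1)

    @pytest.mark.parametrize("kwargs,field", [
        ({"missing_rate": 1.5}, "missing_rate"),
        ({"block_rho": 1.0}, "block_rho"),
        ({"n_pathways": 1}, "n_pathways"),
        ({"n_lipid_pathways": 9, "n_pathways": 4}, "n_lipid_pathways"),
    ])
    def test_invalid_rates_and_counts(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            syn.SimConfig(**kwargs)


class TestDeterminism:
    """Same seed must give byte-identical artifacts for every generator."""

    def test_gsmn(self, small_config):
        n1, x1, e1 = syn.gen_gsmn(small_config)
        n2, x2, e2 = syn.gen_gsmn(small_config)
        assert n1 == n2
        assert x1.equals(x2) and e1.equals(e2)

    @pytest.mark.parametrize("gen", [
        lambda c: syn.gen_expression(c)[0],
        lambda c: syn.gen_proteomics(c)[0],
        lambda c: syn.gen_lipidomics(c)[0],
        lambda c: syn.gen_mwas_cohort(c)[0].features,
        lambda c: syn.gen_celltype_reference(c)[0],
    ])
    def test_matrix_generators(self, small_config, gen):
        a = gen(small_config)
        b = gen(small_config)
        assert a.to_csv() == b.to_csv()  # byte-identical serialization

    def test_substreams_independent(self, small_config):
        # consuming one generator does not perturb another
        before = syn.gen_expression(small_config)[0]
        syn.gen_proteomics(small_config)
        after = syn.gen_expression(small_config)[0]
        assert before.equals(after)


class TestGsmn:
    def test_requested_topology(self):
        cfg = syn.SimConfig(seed=0, n_pathways=2, n_lipid_pathways=1,
                            n_lipid_terms=1, species_per_term=3)
        net, xref, expansion = syn.gen_gsmn(cfg)
        assert len(net.pathways) == 2
        terms = [m for m in net.metabolites.values() if m.is_class]
        assert len(terms) == 1
        assert (expansion["term_metabolite_id"] == terms[0].id).sum() == 3

    def test_every_pathway_owns_reactions(self, small_config):
        net, _, _ = syn.gen_gsmn(small_config)
        assert all(len(rs) >= 1 for rs in net.pathways.values())

    def test_connected_graph(self, small_config):
        import networkx as nx
        net, _, _ = syn.gen_gsmn(small_config)
        g = nx.Graph()
        g.add_edges_from(net.gene_reaction)
        g.add_edges_from(net.reaction_metabolite)
        assert nx.is_connected(g)

    def test_species_count_equals_set_union_oracle(self, small_config):
        _, xref, expansion = syn.gen_gsmn(small_config)
        first = set(xref.loc[(xref["is_lipid"]) & (xref["lipid_id"] != ""),
                             "lipid_id"])
        second = set(expansion["lipid_id"])
        assert len(first | second) == len(first) + len(second) - len(first & second)
        assert first.isdisjoint(second)  # generator never reuses ids


class TestExpression:
    def test_zero_effect_means_empty_truth(self):
        _, _, truth = syn.gen_expression(syn.SimConfig(seed=3, de_effect=0.0))
        assert truth.de_elements == set()

    def test_minimum_group_size_rule(self):
        with pytest.raises(ValueError, match="three samples per"):
            syn.gen_expression(syn.SimConfig(seed=0, n_samples_per_group=2))

    def test_planted_shift_recovered(self):
        # realized group-mean difference within 3 standard errors at n=50
        cfg = syn.SimConfig(seed=5, n_genes=300, n_samples_per_group=50,
                            n_de_genes=30, de_effect=2.0, expr_sd=1.0)
        m, labels, truth = syn.gen_expression(cfg)
        labels = np.asarray(labels)
        diffs = (m.loc[sorted(truth.de_elements), labels == "treatment"].mean(axis=1)
                 - m.loc[sorted(truth.de_elements), labels == "control"].mean(axis=1))
        se = 1.0 * np.sqrt(2 / 50)
        assert (np.abs(diffs - 2.0) < 3 * se).all()

    def test_truth_ids_resolvable(self, small_config):
        m, _, truth = syn.gen_expression(small_config)
        assert truth.de_elements <= set(m.index)


class TestProteomics:
    def test_zero_missing_rate(self):
        m, _, _, _ = syn.gen_proteomics(syn.SimConfig(seed=0, missing_rate=0.0))
        assert not m.isna().any().any()

    def test_missingness_anticorrelated_with_intensity(self):
        cfg = syn.SimConfig(seed=4, n_proteins=1000, missing_rate=0.3)
        m, _, _, _ = syn.gen_proteomics(cfg)
        frac_na = m.isna().mean(axis=1)
        mean_obs = np.log2(m).mean(axis=1)
        r = np.corrcoef(frac_na, mean_obs.fillna(mean_obs.mean()))[0, 1]
        assert r < -0.2

    def test_contaminant_count_matches_config(self, small_config):
        _, flags, _, _ = syn.gen_proteomics(small_config)
        assert int(flags["contaminant"].sum()) == small_config.n_contaminants


class TestLipidomics:
    def test_qc_pools_are_near_replicates(self):
        cfg = syn.SimConfig(seed=6, technical_cv=0.01)
        m, meta, _, _ = syn.gen_lipidomics(cfg)
        pools = m.loc[meta["is_qc_pool"]]
        cv = 100 * pools.std() / pools.mean()
        assert (cv < 10).all()

    def test_no_interaction_means_pure_main_effect(self):
        # with the interaction off, KO females and KO males shift equally
        cfg = syn.SimConfig(seed=7, n_per_genotype=60,
                            n_females_per_genotype=30, genotype_effect=1.0,
                            interaction_effect=0.0, biological_sd=0.3)
        m, meta, annot, truth = syn.gen_lipidomics(cfg)
        feat = annot.loc[annot["lipid_id"].isin(truth.signature_species),
                         "feature_id"].iloc[0]
        bio = meta[~meta["is_qc_pool"]]
        lx = np.log2(m.loc[bio.index, feat])
        ko_f = lx[(bio["genotype"] == "KO") & (bio["sex"] == "F")].mean()
        ko_m = lx[(bio["genotype"] == "KO") & (bio["sex"] == "M")].mean()
        wt_f = lx[(bio["genotype"] == "WT") & (bio["sex"] == "F")].mean()
        wt_m = lx[(bio["genotype"] == "WT") & (bio["sex"] == "M")].mean()
        mc_err = 3 * 0.3 * np.sqrt(2 / 30)
        assert abs((ko_f - wt_f) - (ko_m - wt_m)) < 2 * mc_err
        assert abs((ko_f - wt_f) - 1.0) < 2 * mc_err

    def test_truth_species_are_annotated(self, small_config):
        _, _, annot, truth = syn.gen_lipidomics(small_config)
        assert truth.signature_species <= set(annot["lipid_id"])


class TestMwasCohort:
    def test_maf_out_of_range(self):
        with pytest.raises(ValueError, match="allele frequency"):
            syn.gen_mwas_cohort(syn.SimConfig(seed=0, maf=0.6))

    def test_zero_beta_means_empty_truth(self, small_config):
        _, truth = syn.gen_mwas_cohort(small_config)
        assert truth.de_elements == set()

    def test_allele_frequency_within_binomial_error(self):
        cfg = syn.SimConfig(seed=8, n_individuals=2000, maf=0.3)
        design, _ = syn.gen_mwas_cohort(cfg)
        af = design.genotypes.to_numpy().mean() / 2
        se = np.sqrt(0.3 * 0.7 / (2 * 2000))
        assert abs(af - 0.3) < 3 * se

    def test_block_correlation_near_target(self):
        cfg = syn.SimConfig(seed=9, n_individuals=2000, n_mwas_features=40,
                            n_blocks=4, block_rho=0.7)
        design, _ = syn.gen_mwas_cohort(cfg)
        x = design.features.to_numpy()
        block = np.arange(40) % 4
        within = []
        for b in range(4):
            cols = np.flatnonzero(block == b)
            c = np.corrcoef(x[:, cols].T)
            within.append(c[np.triu_indices_from(c, 1)].mean())
        assert abs(np.mean(within) - 0.7) < 0.05


class TestCelltypeReference:
    def test_planted_set_more_specific_in_target(self, small_config):
        from lipidsig.ewce import specificity
        expr, gene_set, target, _ = syn.gen_celltype_reference(small_config)
        spec = specificity(expr)
        planted = spec.loc[sorted(gene_set), target].mean()
        background = spec[target].mean()
        assert planted > background
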