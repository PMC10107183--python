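import numpy as np
import pandas as pd
import pytest

from lipidsig import synthetic as syn
from lipidsig.network import MetabolicNetwork, Metabolite


@pytest.fixture
def tiny_network() -> MetabolicNetwork:
    """Two pathways; PWY_L is a lipid pathway with one term + one species."""
    net = MetabolicNetwork(
        genes={"GeneA", "GeneB", "GeneC"},
        reactions={"R1", "R2", "R3"},
        metabolites={
            "M1": Metabolite("M1"),
            "SP1": Metabolite("SP1", is_class=False, xref=("LM001",)),
            "T1": Metabolite("T1", is_class=True),
        },
        pathways={"PWY_L": ["R1", "R2"], "PWY_X": ["R3"]},
        gene_reaction={("GeneA", "R1"), ("GeneB", "R2"), ("GeneC", "R3")},
        reaction_metabolite={("R1", "SP1"), ("R1", "M1"), ("R2", "T1"),
                             ("R3", "M1")},
    )
    net.validate()
    return net


@pytest.fixture
def small_config() -> syn.SimConfig:
    return syn.SimConfig(seed=11, n_genes=200, n_de_genes=10,
                         n_proteins=150, n_lipid_features=60,
                         n_individuals=200, n_mwas_features=40, n_blocks=4,
                         n_celltype_genes=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
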