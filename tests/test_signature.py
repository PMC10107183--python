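import pandas as pd
import pytest

from lipidsig import synthetic as syn
from lipidsig.network import extract_subnetwork
from lipidsig.signature import (
    build_signature,
    normalize_label,
    select_lipid_pathways,
    validate_signature,
)


def enrichment_table(rows):
    return pd.DataFrame(rows, columns=["term", "p", "q", "significant"])


class TestPathwaySelection:
    def test_no_significant_pathways(self):
        table = enrichment_table([("P1", 0.4, 0.6, False)])
        assert select_lipid_pathways(table, ["P1"]) == set()

    def test_lipid_label_intersection(self):
        table = enrichment_table([("P1", 0.001, 0.01, True),
                                  ("P2", 0.002, 0.01, True),
                                  ("P3", 0.003, 0.02, True),
                                  ("P4", 0.5, 0.7, False)])
        assert select_lipid_pathways(table, ["P1", "P3", "P4"]) == {"P1", "P3"}

    def test_unknown_label_warns_and_skips(self):
        table = enrichment_table([("P1", 0.001, 0.01, True)])
        with pytest.warns(UserWarning, match="P9"):
            out = select_lipid_pathways(table, ["P1", "P9"])
        assert out == {"P1"}

    def test_matches_brute_force_filter(self, small_config):
        import numpy as np
        r = np.random.default_rng(0)
        terms = [f"P{i}" for i in range(20)]
        table = pd.DataFrame({"term": terms,
                              "p": r.random(20),
                              "q": r.random(20)})
        table["significant"] = (table["p"] < 0.05) | (table["q"] < 0.3)
        labels = terms[::2]
        oracle = {t for t, s in zip(table["term"], table["significant"])
                  if s and t in set(labels)}
        assert select_lipid_pathways(table, labels) == oracle


@pytest.fixture
def toy_inputs(tiny_network):
    sub = extract_subnetwork(tiny_network, ["PWY_L"])
    xref = pd.DataFrame([
        {"metabolite_id": "SP1", "lipid_id": "LM001", "label": "", "is_lipid": True},
        {"metabolite_id": "T1", "lipid_id": "", "label": "Lyso-PC", "is_lipid": True},
        {"metabolite_id": "M1", "lipid_id": "", "label": "", "is_lipid": False},
    ])
    annotations = pd.DataFrame([
        {"feature_id": "F1", "mode": "negative", "lipid_id": "LM100",
         "lipid_class": "lyso pc"},
        {"feature_id": "F2", "mode": "negative", "lipid_id": "LM101",
         "lipid_class": "Lyso-PC"},
        {"feature_id": "F3", "mode": "positive", "lipid_id": "LM102",
         "lipid_class": "LYSO PC!"},
        {"feature_id": "F4", "mode": "positive", "lipid_id": "LM001",
         "lipid_class": "other class"},
        {"feature_id": "F5", "mode": "negative", "lipid_id": "LM999",
         "lipid_class": "unrelated"},
    ])
    return sub, xref, annotations


class TestBuildSignature:
    def test_first_and_second_order_counts(self, toy_inputs):
        sub, xref, annot = toy_inputs
        sig = build_signature(sub, xref, annot)
        c = sig.counts
        # SP1 -> LM001 (first); T1 "Lyso-PC" expands to LM100/LM101/LM102
        assert c["first_order_species"] == 1
        assert c["second_order_species"] == 3
        assert c["unique_species"] == 4
        assert c["terms_expanded"] == 1

    def test_label_matching_is_normalized(self, toy_inputs):
        sub, xref, annot = toy_inputs
        sig = build_signature(sub, xref, annot)
        second = set(sig.entries.loc[sig.entries["order"] == "second", "lipid_id"])
        assert second == {"LM100", "LM101", "LM102"}  # punctuation/case ignored

    def test_non_lipid_metabolites_excluded(self, toy_inputs):
        sub, xref, annot = toy_inputs
        sig = build_signature(sub, xref, annot)
        assert "M1" not in set(sig.entries["metabolite_id"])

    def test_dual_order_species_counted_once(self, toy_inputs):
        sub, xref, annot = toy_inputs
        # make the first-order species also a member of the expanded class
        annot.loc[annot["lipid_id"] == "LM001", "lipid_class"] = "Lyso-PC"
        sig = build_signature(sub, xref, annot)
        c = sig.counts
        assert c["first_order_species"] == 1
        assert c["second_order_species"] == 4
        assert c["unique_species"] == 4  # union deduplicates LM001
        orders = set(sig.entries.loc[sig.entries["lipid_id"] == "LM001", "order"])
        assert orders == {"first", "second"}  # dual provenance retained

    def test_row_order_invariance(self, toy_inputs):
        sub, xref, annot = toy_inputs
        sig1 = build_signature(sub, xref, annot)
        sig2 = build_signature(sub, xref.iloc[::-1].reset_index(drop=True),
                               annot.iloc[::-1].reset_index(drop=True))
        assert sig1.entries.equals(sig2.entries)

    def test_matches_brute_force_two_pass_oracle(self, small_config):
        net, xref, expansion = syn.gen_gsmn(small_config)
        _, _, annot, _ = syn.gen_lipidomics(small_config, expansion=expansion,
                                            species_xref=xref[xref["lipid_id"] != ""])
        pwys = sorted(net.pathways)[:small_config.n_lipid_pathways]
        sub = extract_subnetwork(net, pwys)
        sig = build_signature(sub, xref, annot)

        # independent matcher: pass 1 exact ids, pass 2 label expansion
        lipid_flag = dict(zip(xref["metabolite_id"], xref["is_lipid"]))
        first = set()
        second = set()
        for mid, met in sub.metabolites.items():
            if not lipid_flag.get(mid, False):
                continue
            row = xref[xref["metabolite_id"] == mid]
            if not met.is_class:
                first |= {l for l in row["lipid_id"] if l}
            else:
                labels = {normalize_label(l) for l in row["label"] if l}
                for _, a in annot.iterrows():
                    if normalize_label(a["lipid_class"]) in labels:
                        second.add(a["lipid_id"])
        assert sig.counts["unique_species"] == len(first | second)
        assert sig.counts["first_order_species"] == len(first)
        assert sig.counts["second_order_species"] == len(second)


class TestValidateSignature:
    def test_disjoint_annotation_gives_empty_lists(self, toy_inputs):
        sub, xref, annot = toy_inputs
        sig = build_signature(sub, xref, annot)
        other = annot.copy()
        other["lipid_id"] = "LMZZ" + other["feature_id"]
        val = validate_signature(sig, other)
        assert all(len(v) == 0 for v in val.feature_ids.values())

    def test_both_mode_species_in_both_lists(self, toy_inputs):
        sub, xref, annot = toy_inputs
        extra = pd.DataFrame([{"feature_id": "F9", "mode": "positive",
                               "lipid_id": "LM100", "lipid_class": "lyso pc"}])
        annot = pd.concat([annot, extra], ignore_index=True)
        sig = build_signature(sub, xref, annot)
        val = validate_signature(sig, annot)
        assert "LM100" in val.lipid_ids["negative"]
        assert "LM100" in val.lipid_ids["positive"]

    def test_counts_equal_set_intersection_oracle(self, toy_inputs):
        sub, xref, annot = toy_inputs
        sig = build_signature(sub, xref, annot)
        val = validate_signature(sig, annot)
        species = set(sig.species)
        for mode, df in annot.groupby("mode"):
            oracle = set(df["lipid_id"]) & species
            assert set(val.lipid_ids[mode]) == oracle
            # validation is contractive
            assert len(oracle) <= len(species)
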