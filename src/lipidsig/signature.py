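"""Predicted lipid signature: first/second-order identifier matching.

From the lipid subnetwork (every metabolite in the significantly enriched
lipid pathways) a predicted signature of concrete lipid species is built:

* first-order — a species-level subnetwork metabolite whose cross-reference
  carries an exact external lipid identifier contributes that identifier;
* second-order — a class-level metabolite ("lipid term", e.g. a lipid
  subclass) expands to every detected lipid whose annotated class label
  matches the term's label.

The signature is the deduplicated union with provenance, and is validated
against the per-ionization-mode annotation tables of an acquired lipidomics
data set, yielding the feature lists used to filter the intensity matrices.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import pandas as pd

from .network import Subnetwork

__all__ = [
    "PredictedSignature",
    "ValidatedSignature",
    "select_lipid_pathways",
    "build_signature",
    "validate_signature",
    "normalize_label",
]

log = logging.getLogger(__name__)

_PUNCT = re.compile(r"[^a-z0-9]+")


def normalize_label(label: str) -> str:
    """Canonical matching key for a lipid class/term label."""
    return _PUNCT.sub(" ", str(label).lower()).strip()


@dataclass
class PredictedSignature:
    # one row per (metabolite, lipid id, order[, source term]) match
    entries: pd.DataFrame  # columns: metabolite_id, lipid_id, order, source_term

    @property
    def species(self) -> list[str]:
        return sorted(self.entries["lipid_id"].unique())

    @property
    def counts(self) -> dict[str, int]:
        first = set(self.entries.loc[self.entries["order"] == "first", "lipid_id"])
        second = set(self.entries.loc[self.entries["order"] == "second", "lipid_id"])
        return {
            "unique_species": len(first | second),
            "first_order_species": len(first),
            "second_order_species": len(second),
            "terms_expanded": int(self.entries.loc[self.entries["order"] == "second",
                                                   "metabolite_id"].nunique()),
        }


@dataclass
class ValidatedSignature:
    matched: dict[str, pd.DataFrame]  # mode -> annotation rows matching the signature

    @property
    def feature_ids(self) -> dict[str, list[str]]:
        return {mode: sorted(df["feature_id"].unique()) for mode, df in self.matched.items()}

    @property
    def lipid_ids(self) -> dict[str, list[str]]:
        return {mode: sorted(df["lipid_id"].unique()) for mode, df in self.matched.items()}

    @property
    def counts(self) -> dict[str, int]:
        all_ids = set().union(*(set(v["lipid_id"]) for v in self.matched.values())) \
            if self.matched else set()
        out = {f"species_{mode}": df["lipid_id"].nunique() for mode, df in self.matched.items()}
        out["species_total"] = len(all_ids)
        return out


def select_lipid_pathways(enrichment: pd.DataFrame, lipid_pathway_labels) -> set[str]:
    """Significant (dual-rule) pathways restricted to the lipid-labelled set."""
    labels = set(lipid_pathway_labels)
    known = set(enrichment["term"])
    for missing in sorted(labels - known):
        warnings.warn(f"lipid pathway label {missing!r} absent from enrichment results",
                      stacklevel=2)
    sig = set(enrichment.loc[enrichment["significant"], "term"])
    return sig & labels


def build_signature(subnetwork: Subnetwork, xref: pd.DataFrame,
                    detected_annotations: pd.DataFrame) -> PredictedSignature:
    """Two-pass matcher over the subnetwork metabolites.

    ``xref`` columns: metabolite_id, lipid_id (species rows), label
    (class/term rows), is_lipid.  ``detected_annotations`` columns:
    feature_id, mode, lipid_id, lipid_class.  Non-lipid metabolites are
    excluded via the explicit ``is_lipid`` flag.
    """
    xref = xref.set_index("metabolite_id", drop=False) if xref.index.name != "metabolite_id" else xref
    rows = []
    detected = detected_annotations.assign(
        _class_key=detected_annotations["lipid_class"].map(normalize_label))
    for met_id in sorted(subnetwork.metabolites):
        met = subnetwork.metabolites[met_id]
        hits = xref[xref["metabolite_id"] == met_id]
        if hits.empty or not bool(hits["is_lipid"].iloc[0]):
            continue
        if not met.is_class:
            lipid_ids = [l for l in hits["lipid_id"].dropna() if l]
            if not lipid_ids:
                log.info("species-level metabolite %s has no lipid id; skipped", met_id)
                continue
            for lid in lipid_ids:
                rows.append({"metabolite_id": met_id, "lipid_id": lid,
                             "order": "first", "source_term": ""})
        else:
            labels = {normalize_label(l) for l in hits["label"].dropna() if l}
            expanded = detected[detected["_class_key"].isin(labels)]
            for lid in sorted(expanded["lipid_id"].unique()):
                rows.append({"metabolite_id": met_id, "lipid_id": lid,
                             "order": "second", "source_term": met_id})
    entries = pd.DataFrame(rows, columns=["metabolite_id", "lipid_id", "order", "source_term"])
    entries = entries.drop_duplicates().sort_values(
        ["lipid_id", "order", "metabolite_id"]).reset_index(drop=True)
    return PredictedSignature(entries=entries)


def validate_signature(signature: PredictedSignature,
                       annotations: pd.DataFrame) -> ValidatedSignature:
    """Intersect the predicted species with each ionization mode's annotated
    lipids; species annotated in both modes appear in both feature lists."""
    species = set(signature.species)
    matched = {}
    for mode, df in annotations.groupby("mode"):
        matched[str(mode)] = df[df["lipid_id"].isin(species)].reset_index(drop=True)
    return ValidatedSignature(matched=matched)
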