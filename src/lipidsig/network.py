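"""Genome-scale metabolic network (GSMN) model, I/O, mapping and subnetworks.

The network is the gene -> reaction -> metabolite graph of a genome-scale
metabolic reconstruction, with reactions grouped into pathways and
metabolites split into concrete species and class-level "lipid terms"
(subclasses such as a CDP-diacylglycerol that stand for many species).
Omics gene lists are mapped onto it by intersection with the network's
gene set; subnetworks are extracted pathway-wise by taking every member
reaction together with its incident genes and metabolites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Metabolite",
    "MetabolicNetwork",
    "MappedOmicsSet",
    "Subnetwork",
    "OrthologRecord",
    "NetworkError",
    "read_network",
    "write_network",
    "map_elements",
    "filter_orthologs",
    "extract_subnetwork",
]


class NetworkError(ValueError):
    """Raised when a network file violates the structural invariants."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    is_class: bool = False          # True = class-level lipid term
    xref: tuple[str, ...] = ()      # external lipid ids (LIPID MAPS-style)


@dataclass
class MetabolicNetwork:
    """Gene-reaction-metabolite graph with pathway groupings.

    Invariants (enforced by :meth:`validate`): every edge endpoint exists,
    pathway members are reactions, ids are unique within each namespace.
    """

    genes: set[str] = field(default_factory=set)
    reactions: set[str] = field(default_factory=set)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    pathways: dict[str, list[str]] = field(default_factory=dict)
    gene_reaction: set[tuple[str, str]] = field(default_factory=set)
    reaction_metabolite: set[tuple[str, str]] = field(default_factory=set)

    def validate(self) -> None:
        for g, r in self.gene_reaction:
            if g not in self.genes:
                raise NetworkError(f"gene_reaction edge ({g}, {r}): unknown gene {g!r}")
            if r not in self.reactions:
                raise NetworkError(f"gene_reaction edge ({g}, {r}): unknown reaction {r!r}")
        for r, m in self.reaction_metabolite:
            if r not in self.reactions:
                raise NetworkError(f"reaction_metabolite edge ({r}, {m}): unknown reaction {r!r}")
            if m not in self.metabolites:
                raise NetworkError(f"reaction_metabolite edge ({r}, {m}): unknown metabolite {m!r}")
        for pwy, members in self.pathways.items():
            for r in members:
                if r not in self.reactions:
                    raise NetworkError(f"pathway {pwy!r}: member {r!r} is not a reaction")
            if len(set(members)) != len(members):
                raise NetworkError(f"pathway {pwy!r}: duplicate member reactions")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "genes": sorted(self.genes),
            "reactions": sorted(self.reactions),
            "metabolites": [
                {"id": m.id, "is_class": m.is_class, "xref": list(m.xref)}
                for m in sorted(self.metabolites.values(), key=lambda m: m.id)
            ],
            "pathways": {p: sorted(rs) for p, rs in sorted(self.pathways.items())},
            "gene_reaction": sorted(list(e) for e in self.gene_reaction),
            "reaction_metabolite": sorted(list(e) for e in self.reaction_metabolite),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetabolicNetwork":
        genes = list(d.get("genes", []))
        reactions = list(d.get("reactions", []))
        mets = [
            Metabolite(m["id"], bool(m.get("is_class", False)), tuple(m.get("xref", ())))
            for m in d.get("metabolites", [])
        ]
        for name, ids in (("genes", genes), ("reactions", reactions),
                          ("metabolites", [m.id for m in mets])):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise NetworkError(f"duplicate {name} id(s): {dup}")
        net = cls(
            genes=set(genes),
            reactions=set(reactions),
            metabolites={m.id: m for m in mets},
            pathways={p: list(rs) for p, rs in d.get("pathways", {}).items()},
            gene_reaction={(g, r) for g, r in d.get("gene_reaction", [])},
            reaction_metabolite={(r, m) for r, m in d.get("reaction_metabolite", [])},
        )
        net.validate()
        return net

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return self.to_dict() == other.to_dict()


@dataclass
class MappedOmicsSet:
    """An omics gene list intersected with the network ("all-mapped" set)."""

    layer: str
    input_ids: list[str]
    mapped: list[str]
    unmapped: list[str]


@dataclass
class Subnetwork:
    genes: set[str]
    reactions: set[str]
    metabolites: dict[str, Metabolite]
    source_pathways: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "genes": len(self.genes),
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "class_level": sum(m.is_class for m in self.metabolites.values()),
        }


@dataclass(frozen=True)
class OrthologRecord:
    human_gene: str
    mouse_gene: str
    forward_similarity: float  # percent, human -> mouse
    reverse_similarity: float  # percent, mouse -> human
    homology_type: str         # "one-to-one" or anything else

    def __post_init__(self):
        for v in (self.forward_similarity, self.reverse_similarity):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"similarity {v} outside [0, 100]")


# ---------------------------------------------------------------------------

def read_network(path) -> MetabolicNetwork:
    """Load a network from its JSON file (or the 3-column TSV triple dialect).

    TSV rows are (subject, predicate, object) with predicates gene_reaction,
    reaction_metabolite, pathway_member, is_class, xref.
    """
    path = str(path)
    if path.endswith((".tsv", ".txt")):
        return _read_triples(path)
    with open(path) as fh:
        return MetabolicNetwork.from_dict(json.load(fh))


def write_network(network: MetabolicNetwork, path) -> None:
    network.validate()
    with open(path, "w") as fh:
        json.dump(network.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_triples(path: str) -> MetabolicNetwork:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["subject", "predicate", "object"], dtype=str)
    d: dict = {"genes": [], "reactions": [], "metabolites": [], "pathways": {},
               "gene_reaction": [], "reaction_metabolite": []}
    mets: dict[str, dict] = {}
    for subj, pred, obj in df.itertuples(index=False):
        if pred == "gene_reaction":
            d["gene_reaction"].append([subj, obj])
            d["genes"].append(subj)
            d["reactions"].append(obj)
        elif pred == "reaction_metabolite":
            d["reaction_metabolite"].append([subj, obj])
            d["reactions"].append(subj)
            mets.setdefault(obj, {"id": obj, "is_class": False, "xref": []})
        elif pred == "pathway_member":
            d["pathways"].setdefault(subj, []).append(obj)
            d["reactions"].append(obj)
        elif pred == "is_class":
            mets.setdefault(subj, {"id": subj, "is_class": False, "xref": []})
            mets[subj]["is_class"] = obj.lower() in ("1", "true", "yes")
        elif pred == "xref":
            mets.setdefault(subj, {"id": subj, "is_class": False, "xref": []})
            mets[subj]["xref"].append(obj)
        else:
            raise NetworkError(f"unknown predicate {pred!r} in {path}")
    d["genes"] = sorted(set(d["genes"]))
    d["reactions"] = sorted(set(d["reactions"]))
    d["metabolites"] = [mets[k] for k in sorted(mets)]
    return MetabolicNetwork.from_dict(d)


def _normalize(gid: str) -> str:
    return gid.strip().casefold()


def map_elements(ids, network: MetabolicNetwork, layer: str) -> MappedOmicsSet:
    """Intersect an omics id list with the network genes ("all-mapped" data).

    Ids are trimmed and compared case-insensitively; the network's canonical
    spelling is reported for mapped ids.  Elements not present in the network
    fall into ``unmapped``.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("map_elements: empty input id list")
    canonical = {_normalize(g): g for g in network.genes}
    mapped, unmapped = [], []
    for i in ids:
        hit = canonical.get(_normalize(str(i)))
        (mapped if hit is not None else unmapped).append(hit if hit is not None else i)
    return MappedOmicsSet(layer=layer, input_ids=ids, mapped=mapped, unmapped=unmapped)


def filter_orthologs(records, min_similarity: float = 60.0) -> list[str]:
    """High-quality ortholog filter: one-to-one homology with bidirectional
    protein sequence similarity at or above ``min_similarity`` percent.

    Returns the retained mouse gene ids, input order preserved.
    """
    kept = []
    for rec in records:
        if (rec.homology_type == "one-to-one"
                and rec.forward_similarity >= min_similarity
                and rec.reverse_similarity >= min_similarity):
            kept.append(rec.mouse_gene)
    return kept


def extract_subnetwork(network: MetabolicNetwork, pathway_ids) -> Subnetwork:
    """Mine the subnetwork spanned by a set of pathways.

    Reactions = union of the pathways' member reactions; metabolites and
    genes = everything incident to those reactions.
    """
    pathway_ids = list(pathway_ids)
    unknown = [p for p in pathway_ids if p not in network.pathways]
    if unknown:
        raise KeyError(f"unknown pathway id(s): {unknown}")
    reactions: set[str] = set()
    for p in pathway_ids:
        reactions.update(network.pathways[p])
    genes = {g for g, r in network.gene_reaction if r in reactions}
    met_ids = {m for r, m in network.reaction_metabolite if r in reactions}
    return Subnetwork(
        genes=genes,
        reactions=reactions,
        metabolites={m: network.metabolites[m] for m in sorted(met_ids)},
        source_pathways=sorted(pathway_ids),
    )
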