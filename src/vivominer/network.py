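"""Bipartite drug–animal-model network.

Approved drugs are linked to the animal models (genetic strains, induced and
transgenic models) mentioned in the assays that tested them: an edge connects
a drug to a model iff they co-occur in at least ``min_assays`` distinct assays
(default 5), weighted by that count. General-purpose strains (outbred stocks
like Wistar rat or Swiss mouse, screened indiscriminately across indications)
are excluded so the graph keeps only models tied to disease phenotypes, and
synonymous experimental-model names ("hot plate" / "hotplate") are merged via
an editable consolidation map. Isolated nodes are dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "DEFAULT_EXCLUSIONS",
    "DEFAULT_MERGES",
    "build_network",
    "export_network",
    "read_network",
]

#: general-purpose (mostly outbred) strains excluded from the network
DEFAULT_EXCLUSIONS = frozenset({
    "Sprague Dawley", "Wistar", "Swiss", "ICR", "CD-1", "NMRI", "CF-1",
    "Long Evans", "Holtzman",
})

#: synonym consolidation applied to experimental-model names
DEFAULT_MERGES: dict[str, str] = {
    "maximum electric shock": "maximal electroshock",
    "maximum electroshock": "maximal electroshock",
    "hotplate": "hot plate",
    "pentylenetetrazole (ptz)": "pentylenetetrazole",
    "ptz": "pentylenetetrazole",
}

MODEL_CLASSES = ("genetic_strain", "experimental_model", "transgenic_model")


def build_network(
    mentions: pd.DataFrame,
    assays,
    compounds,
    links: Sequence[tuple[str, str]] | None = None,
    min_assays: int = 5,
    exclusions: frozenset[str] = DEFAULT_EXCLUSIONS,
    merges: Mapping[str, str] | None = None,
    approved_phase: int = 4,
) -> nx.Graph:
    """Build the bipartite drug–model graph from the mention table.

    Node attributes: ``kind`` ("drug"/"model"), ``n_assays``; drugs carry
    ``atc`` (level-2 prefixes, comma-joined) for coloring, models carry
    ``model_class``. Edge attribute ``weight`` is the shared distinct-assay
    count. Bipartiteness is verified structurally before returning.
    """
    merges = DEFAULT_MERGES if merges is None else dict(merges)
    excl = {e.lower() for e in exclusions}

    by_id = {c.compound_id: c for c in compounds}
    assay_compounds: dict[str, set[str]] = {a.assay_id: set(a.compound_ids) for a in assays}
    for aid, cid in links or ():
        if aid in assay_compounds:
            assay_compounds[aid].add(cid)

    # model name (merged) -> distinct assays; remember the mention class
    model_assays: dict[str, set[str]] = {}
    model_class: dict[str, str] = {}
    sub = mentions[mentions["class"].isin(MODEL_CLASSES)]
    for row in sub.itertuples(index=False):
        name = merges.get(row.normalized.lower(), row.normalized)
        name = merges.get(name.lower(), name)
        if row[1] == "genetic_strain" and name.lower() in excl:
            continue
        model_assays.setdefault(name, set()).add(str(row.assay_id))
        model_class.setdefault(name, row[1])

    # approved drug -> distinct assays
    drug_assays: dict[str, set[str]] = {}
    for aid, cids in assay_compounds.items():
        for cid in cids:
            comp = by_id.get(cid)
            if comp is None or comp.max_phase < approved_phase or not comp.atc_codes:
                continue
            drug_assays.setdefault(comp.compound_id, set()).add(aid)

    G = nx.Graph()
    for drug, d_assays in sorted(drug_assays.items()):
        comp = by_id[drug]
        for model, m_assays in sorted(model_assays.items()):
            shared = len(d_assays & m_assays)
            if shared >= min_assays:
                if drug not in G:
                    G.add_node(
                        f"drug:{drug}",
                        kind="drug",
                        label=comp.name or drug,
                        atc=",".join(sorted({c[:3] for c in comp.atc_codes})),
                        n_assays=len(d_assays),
                        bipartite=0,
                    )
                if f"model:{model}" not in G:
                    G.add_node(
                        f"model:{model}",
                        kind="model",
                        label=model,
                        model_class=model_class[model],
                        n_assays=len(m_assays),
                        bipartite=1,
                    )
                G.add_edge(f"drug:{drug}", f"model:{model}", weight=shared)

    # structural bipartiteness check
    for u, v in G.edges():
        if G.nodes[u]["kind"] == G.nodes[v]["kind"]:
            raise AssertionError(f"non-bipartite edge {u} -- {v}")
    return G


def export_network(G: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the graph as GraphML, GML or a TSV edge list (attributes kept)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gml":
        nx.write_gml(G, path)
    elif fmt in ("edgelist", "tsv"):
        rows = [
            (u, v, d.get("weight", 1)) for u, v, d in sorted(G.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["drug", "model", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gml":
        return nx.read_gml(path)
    raise ValueError(f"unknown import format {fmt!r}")
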