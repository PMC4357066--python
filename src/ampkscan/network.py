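"""Functional-category summaries and association-network centrality.

Given scanned targets, a protein → functional-category annotation table and
a protein–protein association table, this module computes category
representation (the pie-chart numbers), builds an undirected target
network, ranks "central node" substrates by degree within a functional
category, and exports the graph in Cytoscape-loadable formats (SIF,
GraphML) or as a plain edge-list TSV.

Degree is the operative notion of interconnectivity here: a central-node
substrate is simply the protein with the most associations among the
targets that share its functional category.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

UNCATEGORIZED = "uncategorized"
GRAPH_FORMATS = ("sif", "graphml", "tsv")
#: Node-attribute separator for multi-category labels (GraphML stores strings).
CATEGORY_SEP = ";"


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a protein annotation TSV (protein_id, category[, evidence])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "category"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if "evidence" not in df.columns:
        df["evidence"] = ""
    bad = df["category"].str.strip() == ""
    if bad.any():
        raise ValueError(
            f"empty category label on data row(s) {[i + 2 for i in df.index[bad]]}"
        )
    return df[["protein_id", "category", "evidence"]]


def read_associations(path: str | Path) -> pd.DataFrame:
    """Read a protein association TSV (protein_a, protein_b[, type]).

    Malformed rows (missing an endpoint) are reported with their 1-based
    file line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_a", "protein_b"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"association table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if "type" not in df.columns:
        df["type"] = "association"
    df["type"] = df["type"].fillna("association")
    bad = df["protein_a"].isna() | df["protein_b"].isna()
    if bad.any():
        # +2: 1-based lines, counting the header
        raise ValueError(
            f"malformed association row(s) at line(s) {[i + 2 for i in df.index[bad]]}"
        )
    return df[["protein_a", "protein_b", "type"]]


def _categories_of(annotations: pd.DataFrame | None) -> dict[str, list[str]]:
    if annotations is None or annotations.empty:
        return {}
    out: dict[str, list[str]] = {}
    for pid, cat in zip(annotations["protein_id"], annotations["category"]):
        cats = out.setdefault(pid, [])
        if cat not in cats:
            cats.append(cat)
    return out


def category_counts(
    target_ids: Iterable[str],
    annotations: pd.DataFrame | None = None,
    policy: str = "fractional",
) -> pd.DataFrame:
    """Per-category representation of the scanned targets.

    Parameters
    ----------
    target_ids : iterable of str
        Distinct target proteins (duplicates are collapsed).
    annotations : DataFrame, optional
        ``protein_id, category[, evidence]``; proteins absent from it fall
        into the ``uncategorized`` bin.  Rows naming proteins that are not
        targets are ignored with a warning.
    policy : {"fractional", "each"}
        How a multi-category protein is counted: split equally across its
        categories (default; proportions of distinct proteins then sum
        to 1) or counted fully in each category.

    Returns
    -------
    DataFrame with columns ``category, n_proteins, weight, proportion``,
    sorted by descending weight then category label.
    """
    if policy not in ("fractional", "each"):
        raise ValueError(f"unknown multi-category policy {policy!r}")
    targets = list(dict.fromkeys(target_ids))
    cats_by_protein = _categories_of(annotations)
    unknown = set(cats_by_protein) - set(targets)
    if unknown:
        logger.warning(
            "%d annotation protein id(s) are not scanned targets (e.g. %s)",
            len(unknown),
            sorted(unknown)[0],
        )
    n_proteins: dict[str, int] = {}
    weight: dict[str, float] = {}
    for pid in targets:
        cats = cats_by_protein.get(pid) or [UNCATEGORIZED]
        w = 1.0 / len(cats) if policy == "fractional" else 1.0
        for cat in cats:
            n_proteins[cat] = n_proteins.get(cat, 0) + 1
            weight[cat] = weight.get(cat, 0.0) + w
    total = sum(weight.values())
    rows = [
        {
            "category": cat,
            "n_proteins": n_proteins[cat],
            "weight": weight[cat],
            "proportion": weight[cat] / total if total else 0.0,
        }
        for cat in weight
    ]
    df = pd.DataFrame(rows, columns=["category", "n_proteins", "weight", "proportion"])
    return df.sort_values(
        ["weight", "category"], ascending=[False, True], ignore_index=True
    )


def build_network(
    target_ids: Iterable[str],
    annotations: pd.DataFrame | None = None,
    associations: pd.DataFrame | None = None,
    tiers: Mapping[str, str] | None = None,
    include_neighbors: bool = False,
) -> nx.Graph:
    """Build the undirected target association network.

    Nodes are the scanned targets (plus, optionally, their first-neighbor
    non-targets, flagged with ``is_target=False``).  Self-loops are dropped
    with a warning and duplicate pairs — in either order — collapse to a
    single edge carrying the first association-type label seen.

    Node attributes: ``is_target`` (bool), ``tier`` (best tier, if given),
    ``categories`` (";"-joined sorted labels, empty string if none).
    """
    targets = list(dict.fromkeys(target_ids))
    target_set = set(targets)
    cats_by_protein = _categories_of(annotations)
    graph = nx.Graph()
    for pid in targets:
        graph.add_node(
            pid,
            is_target=True,
            tier=(tiers or {}).get(pid, ""),
            categories=CATEGORY_SEP.join(sorted(cats_by_protein.get(pid, []))),
        )
    if associations is not None:
        for row in associations.itertuples(index=False):
            a, b, etype = row.protein_a, row.protein_b, row.type
            if a == b:
                logger.warning("dropping self-association for %s", a)
                continue
            in_a, in_b = a in target_set, b in target_set
            if not (in_a and in_b):
                if not include_neighbors or not (in_a or in_b):
                    continue
                for pid, is_t in ((a, in_a), (b, in_b)):
                    if not graph.has_node(pid):
                        graph.add_node(
                            pid,
                            is_target=False,
                            tier="",
                            categories=CATEGORY_SEP.join(
                                sorted(cats_by_protein.get(pid, []))
                            ),
                        )
            if not graph.has_edge(a, b):
                graph.add_edge(a, b, type=etype)
    return graph


def rank_central_nodes(
    graph: nx.Graph, category: str | None = None
) -> list[tuple[str, int]]:
    """Rank proteins by degree, optionally within one functional category.

    With a category, the ranking is computed on the subgraph induced by
    the proteins carrying that category (degree counts only within-category
    associations).  Ties break lexicographically by protein id.  An
    unknown category yields an empty list with a warning.
    """
    if category is not None:
        members = [
            n
            for n, data in graph.nodes(data=True)
            if category in (data.get("categories") or "").split(CATEGORY_SEP)
        ]
        if not members:
            logger.warning("no protein carries category %r", category)
            return []
        graph = graph.subgraph(members)
    return sorted(
        ((n, int(d)) for n, d in graph.degree()), key=lambda nd: (-nd[1], nd[0])
    )


def export_graph(graph: nx.Graph, path: str | Path, fmt: str) -> None:
    """Write the network as SIF, GraphML, or an edge-list TSV.

    SIF lines are ``a <type> b`` for every edge, with one bare node id per
    isolated node so no target is lost on import into Cytoscape.  GraphML
    carries the node attributes.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as out:
            for a, b, data in sorted(graph.edges(data=True)):
                out.write(f"{a}\t{data.get('type', 'association')}\t{b}\n")
            for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
                out.write(f"{node}\n")
    elif fmt == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif fmt == "tsv":
        pd.DataFrame(
            [
                {"protein_a": a, "protein_b": b, "type": data.get("type", "association")}
                for a, b, data in sorted(graph.edges(data=True))
            ],
            columns=["protein_a", "protein_b", "type"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; expected one of {GRAPH_FORMATS}")
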