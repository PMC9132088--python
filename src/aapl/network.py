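"""Assembly of the annotated interaction graph and cross-bait merging.

Nodes are the bait, its L1/L2 interactors, and oxidized non-interactor
("grey") proteins that connect to an interactor or the bait through a
known-interaction edge.  Edge rendering attributes follow the convention
used for the published maps: solid lines for edges among the bait and
T1/T2-typed proteins, dashed when a T3-typed endpoint is involved,
backslash for T4; edge opacity encodes the combined-score band
([0.9, 1] high, [0.7, 0.9) mid, [0.4, 0.7) low).  Node fill is exported as
the numeric EPO fold change — rendering is the consumer's job.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

OPACITY_BANDS = (("high", 0.9), ("mid", 0.7), ("low", 0.4))


def opacity_band(score: float) -> str:
    for band, floor in OPACITY_BANDS:
        if score >= floor:
            return band
    return "below_floor"


def _edge_style(type_a: str, type_b: str) -> str:
    """Style from the lower-confidence endpoint: T4 beats T3 beats direct/bait."""
    ranks = {"bait": 0, "T1": 1, "T2": 1, "T3": 2, "T4": 3, "NA": 3}
    worst = max(ranks.get(type_a, 3), ranks.get(type_b, 3))
    return {0: "solid", 1: "solid", 2: "dashed", 3: "backslash"}[worst]


def build_network(
    results: pd.DataFrame, edges: pd.DataFrame, bait_id: str
) -> nx.Graph:
    """Annotated single-bait interaction graph.

    ``results`` is the classification table (protein_id, aapl_score,
    epo_fc, level, string_type, n_sites); ``edges`` the normalized
    known-interaction list.  Grey (non-interactor) nodes enter only through
    an edge to the bait or to an L1/L2 interactor; edges among grey nodes
    are kept only when both endpoints are already in the graph.
    """
    if (results["protein_id"] == bait_id).any():
        raise ValueError("bait must not appear in the interactor results")
    info = results.set_index("protein_id")
    interactors = set(info.index[info["level"].isin(("L1", "L2"))])
    scored = set(info.index)

    graph = nx.Graph()
    graph.add_node(bait_id, is_bait=True, level="bait", string_type="NA", epo_fc=math.nan)

    def node_attrs(pid: str) -> dict:
        r = info.loc[pid]
        fc = float(r["epo_fc"]) if pd.notna(r["epo_fc"]) else math.nan
        return {
            "is_bait": False,
            "level": str(r["level"]),
            "string_type": str(r["string_type"]),
            "epo_fc": fc,
            "aapl_score": float(r["aapl_score"]),
        }

    for pid in sorted(interactors):
        graph.add_node(pid, **node_attrs(pid))

    anchor = interactors | {bait_id}
    edge_rows = list(
        edges[["protein_a", "protein_b", "combined_score"]].itertuples(index=False)
    )
    # first pass: pull in grey nodes adjacent to the bait or an interactor
    for a, b, s in edge_rows:
        for grey, other in ((a, b), (b, a)):
            if grey in scored and grey not in interactors and other in anchor:
                if grey not in graph:
                    graph.add_node(grey, **node_attrs(grey))
    # second pass: add every edge whose endpoints are both present
    for a, b, s in edge_rows:
        if a in graph and b in graph:
            ta = "bait" if a == bait_id else str(info.loc[a, "string_type"])
            tb = "bait" if b == bait_id else str(info.loc[b, "string_type"])
            graph.add_edge(
                a,
                b,
                combined_score=float(s),
                style=_edge_style(ta, tb),
                opacity_band=opacity_band(float(s)),
            )
    logger.info(
        "network for %s: %d nodes (%d interactors), %d edges",
        bait_id,
        graph.number_of_nodes(),
        len(interactors),
        graph.number_of_edges(),
    )
    return graph


def merge_networks(graph_a: nx.Graph, graph_b: nx.Graph) -> nx.Graph:
    """Union of two single-bait graphs with shared-node bookkeeping.

    Shared nodes carry both baits' attribute sets (``level_a``/``level_b``,
    ``epo_fc_a``/``epo_fc_b``) and ``shared=True``; duplicate edges keep the
    maximum combined score (and that edge's rendering attributes).
    """
    merged = nx.Graph()
    for suffix, graph in (("a", graph_a), ("b", graph_b)):
        for node, attrs in graph.nodes(data=True):
            if node not in merged:
                merged.add_node(node, shared=False)
            else:
                merged.nodes[node]["shared"] = True
            merged.nodes[node][f"level_{suffix}"] = attrs.get("level", "absent")
            merged.nodes[node][f"epo_fc_{suffix}"] = attrs.get("epo_fc", math.nan)
            if attrs.get("is_bait", False):
                merged.nodes[node]["is_bait"] = True
        for a, b, attrs in graph.edges(data=True):
            if merged.has_edge(a, b):
                if attrs["combined_score"] > merged.edges[a, b]["combined_score"]:
                    merged.edges[a, b].update(attrs)
            else:
                merged.add_edge(a, b, **attrs)
    for node in merged.nodes:
        merged.nodes[node].setdefault("is_bait", False)
        merged.nodes[node].setdefault("level_a", "absent")
        merged.nodes[node].setdefault("level_b", "absent")
    return merged


def node_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"protein_id": n, **attrs} for n, attrs in graph.nodes(data=True)]
    return pd.DataFrame(rows).sort_values("protein_id", ignore_index=True)


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {"protein_a": min(a, b), "protein_b": max(a, b), **attrs}
        for a, b, attrs in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["protein_a", "protein_b", "combined_score", "style", "opacity_band"]
        )
    return df.sort_values(["protein_a", "protein_b"], ignore_index=True)
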