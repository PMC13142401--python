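"""Similarity networks, gene cluster families, and novelty scoring.

BGCs are nodes in a per-class similarity network whose edges carry raw
pairwise distances; only pairs at or below the clustering cutoff (default
0.5, inclusive) are retained.  Gene cluster families (GCFs) are the connected
components of that thresholded network.  A family is "putatively known" when
it contains at least one reference cluster; otherwise it is putatively novel.
Per-BGC novelty is the distance along a retained edge to the closest
reference node, with a sentinel (default 0.51, just above the cutoff) when no
such edge exists — a pair absent from a BiG-SCAPE network file has unknown
distance above the cutoff, which is exactly what the sentinel encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("thermobgc.network")

DEFAULT_CUTOFF = 0.5
DEFAULT_SENTINEL = 0.51

#: Classes with their own novelty regressions; hybrid/other are processed
#: through dereplication but excluded from the per-class regressions.
MAJOR_CLASSES = ("NRPS", "PKS", "RiPP", "terpene")


@dataclass
class SimilarityNetwork:
    """A distance-thresholded BGC similarity network for one class."""

    graph: nx.Graph
    cutoff: float = DEFAULT_CUTOFF
    bgc_class: str | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class GCF:
    """A gene cluster family: one connected component of the network."""

    family_id: str
    members: frozenset[str]
    bgc_class: str | None = None
    is_known: bool | None = None

    def __len__(self) -> int:
        return len(self.members)


def build_network(
    edges: pd.DataFrame,
    nodes: Iterable[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    bgc_class: str | None = None,
) -> SimilarityNetwork:
    """Build the thresholded similarity network from an edge list.

    Edges with distance strictly above *cutoff* are discarded (the cutoff is
    inclusive: an edge at exactly the cutoff is kept).  When *nodes* is
    supplied, isolated nodes are retained as singletons and an edge naming an
    unknown node is an error; otherwise the node set is the edge endpoints.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    g = nx.Graph(cutoff=cutoff, bgc_class=bgc_class)
    known: set[str] | None = None
    if nodes is not None:
        node_list = sorted(set(nodes))
        g.add_nodes_from(node_list)
        known = set(node_list)
    for a, b, d in edges[["bgc_a", "bgc_b", "distance"]].itertuples(index=False):
        if known is not None and (a not in known or b not in known):
            bad = a if a not in known else b
            raise ValueError(f"edge ({a}, {b}) references unknown node {bad!r}")
        if d <= cutoff:
            prev = g.get_edge_data(a, b)
            if prev is None or d < prev["distance"]:
                g.add_edge(a, b, distance=float(d))
    return SimilarityNetwork(graph=g, cutoff=cutoff, bgc_class=bgc_class)


def connected_components(net: SimilarityNetwork) -> list[GCF]:
    """Derive GCFs as connected components.

    The family id is the lexicographically smallest member id, which makes
    labels reproducible without a global counter; families are returned
    sorted by id.
    """
    fams = [
        GCF(family_id=min(comp), members=frozenset(comp), bgc_class=net.bgc_class)
        for comp in nx.connected_components(net.graph)
    ]
    return sorted(fams, key=lambda f: f.family_id)


def classify_novelty(gcfs: Sequence[GCF], reference_ids: Iterable[str]) -> list[GCF]:
    """Set ``is_known`` on each family: known iff it holds >= 1 reference.

    Reference ids absent from the networks are ignored (logged).
    """
    refs = set(reference_ids)
    seen = set().union(*(f.members for f in gcfs)) if gcfs else set()
    extra = refs - seen
    if extra:
        logger.info("%d reference ids not present in any family (ignored)", len(extra))
    return [
        GCF(f.family_id, f.members, f.bgc_class, is_known=bool(f.members & refs))
        for f in gcfs
    ]


def min_reference_distance(
    net: SimilarityNetwork,
    reference_ids: Iterable[str],
    sentinel: float = DEFAULT_SENTINEL,
) -> pd.DataFrame:
    """Per-BGC novelty: distance to the closest reference along direct edges.

    Only direct retained edges count — a BGC linked to a reference solely
    through intermediate nodes scores the sentinel, because the pairwise
    distance of the unconnected pair is unknown but above the cutoff.
    Reference nodes themselves are excluded from the output.

    Returns a frame with columns ``bgc_id, distance_to_reference``.
    """
    if sentinel <= net.cutoff:
        raise ValueError(f"sentinel ({sentinel}) must exceed the cutoff ({net.cutoff})")
    refs = set(reference_ids)
    rows = []
    for node in net.nodes:
        if node in refs:
            continue
        dists = [
            d["distance"]
            for _, nbr, d in net.graph.edges(node, data=True)
            if nbr in refs
        ]
        rows.append((node, min(dists) if dists else sentinel))
    return pd.DataFrame(rows, columns=["bgc_id", "distance_to_reference"])


def sample_min_novelty(
    scores: pd.DataFrame,
    inventory: pd.DataFrame,
    bgc_class: str,
) -> pd.Series:
    """Minimum novelty per sample for one biosynthetic class.

    For each sample, the smallest distance-to-closest-reference among that
    sample's BGCs of *bgc_class*.  Samples with no BGC of the class are
    absent from the output (not zero-filled).
    """
    inv = inventory[inventory["bgc_class"] == bgc_class]
    merged = inv.merge(scores, on="bgc_id", how="inner")
    out = merged.groupby("sample_id")["distance_to_reference"].min()
    out.name = f"min_novelty_{bgc_class}"
    return out


def novel_fraction(gcfs: Sequence[GCF]) -> float:
    """Fraction of families with no reference member (putatively novel)."""
    if not gcfs:
        raise ValueError("no families")
    if any(f.is_known is None for f in gcfs):
        raise ValueError("families not classified; run classify_novelty first")
    return sum(not f.is_known for f in gcfs) / len(gcfs)


def modularity_communities(net: SimilarityNetwork) -> tuple[list[set[str]], float]:
    """Greedy modularity communities on the unweighted retained-edge graph.

    Used for reporting/plot parity only; GCF definition always comes from
    connected components.  An edgeless graph yields singleton communities
    with Q = 0.  Ties in the greedy merge are broken by node id via the
    sorted node order of the underlying graph.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    g.add_edges_from(sorted(map(tuple, map(sorted, net.graph.edges()))))
    if g.number_of_edges() == 0:
        return [{n} for n in sorted(g.nodes)], 0.0
    comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    q = nx.community.modularity(g, comms)
    return comms, q


def family_table(gcfs: Sequence[GCF]) -> pd.DataFrame:
    """Tidy family table: family_id, n_members, bgc_class, is_known."""
    return pd.DataFrame(
        [(f.family_id, len(f), f.bgc_class, f.is_known) for f in gcfs],
        columns=["family_id", "n_members", "bgc_class", "is_known"],
    )


def family_membership(gcfs: Sequence[GCF]) -> dict[str, str]:
    """Mapping bgc_id -> family_id over all families."""
    out: dict[str, str] = {}
    for f in gcfs:
        for m in f.members:
            out[m] = f.family_id
    return out
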