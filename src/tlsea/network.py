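"""Thresholded chemical-protein association networks.

The compound x protein P_Z matrix becomes a bipartite graph by retaining
cells with P_Z strictly below a cutoff (default 1e-4); each retained edge is
weighted by the reciprocal of the negative common logarithm of P_Z, so
stronger associations (smaller P_Z) get smaller weights, matching
force-directed layouts where weight acts as an ideal edge length. Exports
are Cytoscape-friendly: SIF, GraphML, and node/edge attribute TSVs.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .core import AssociationResult

logger = logging.getLogger(__name__)

COMPOUND = "compound"
PROTEIN = "protein"


def edge_weight(p_z: float) -> float:
    """1 / (-log10 P_Z); defined and positive for P_Z in (0, 1)."""
    if not 0 < p_z < 1:
        raise ValueError("edge weight requires P_Z in (0, 1)")
    return 1.0 / (-math.log10(p_z))


def build_network(result: AssociationResult, pz_cutoff: float = 1e-4) -> nx.Graph:
    """Bipartite compound-protein graph of all P_Z cells strictly below the
    cutoff. An empty network is allowed (and logged), not an error."""
    g = nx.Graph(pz_cutoff=pz_cutoff)
    for p in result.proteins:
        for cid, pz in zip(result.col_ids, p.p_z):
            if pz < pz_cutoff:
                g.add_node(cid, kind=COMPOUND)
                g.add_node(p.protein_id, kind=PROTEIN)
                g.add_edge(cid, p.protein_id, p_z=float(pz), weight=edge_weight(float(pz)))
    if g.number_of_edges() == 0:
        logger.info("network is empty at P_Z < %g", pz_cutoff)
    return g


def build_network_from_table(pz_table: pd.DataFrame, pz_cutoff: float = 1e-4) -> nx.Graph:
    """Same construction as :func:`build_network`, from a long-format table
    with columns compound_id, protein_id, P_Z."""
    g = nx.Graph(pz_cutoff=pz_cutoff)
    for row in pz_table.itertuples(index=False):
        pz = float(row.P_Z)
        if pz < pz_cutoff:
            g.add_node(str(row.compound_id), kind=COMPOUND)
            g.add_node(str(row.protein_id), kind=PROTEIN)
            g.add_edge(str(row.compound_id), str(row.protein_id), p_z=pz, weight=edge_weight(pz))
    return g


def is_bipartite_chem_prot(g: nx.Graph) -> bool:
    return all(
        g.nodes[u]["kind"] != g.nodes[v]["kind"] for u, v in g.edges
    )


def protein_degree_table(g: nx.Graph, min_degree: int = 15) -> pd.DataFrame:
    """Proteins linked to strictly more than ``min_degree`` compounds, sorted
    by degree descending (ties by protein_id)."""
    rows = [
        (n, g.degree(n))
        for n, data in g.nodes(data=True)
        if data.get("kind") == PROTEIN and g.degree(n) > min_degree
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "degree"])
    return df.sort_values(
        ["degree", "protein_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def extract_subnetwork(g: nx.Graph, seed_node: str) -> nx.Graph:
    """The star around one node: the seed, its direct neighbors, and the
    connecting edges only."""
    if seed_node not in g:
        raise KeyError(f"node {seed_node!r} not in network")
    sub = nx.Graph()
    sub.add_node(seed_node, **g.nodes[seed_node])
    for nbr in g.neighbors(seed_node):
        sub.add_node(nbr, **g.nodes[nbr])
        sub.add_edge(seed_node, nbr, **g.edges[seed_node, nbr])
    return sub


def multi_condition_overlay(nets: Mapping[str, nx.Graph]) -> nx.Graph:
    """Union graph over >= 2 condition networks sharing an identifier space;
    each node and edge is annotated with the set of conditions containing it."""
    if len(nets) < 2:
        raise ValueError("overlay needs at least two condition networks")
    union = nx.Graph(conditions=sorted(nets))
    for name, g in nets.items():
        for n, data in g.nodes(data=True):
            if n not in union:
                union.add_node(n, **data, conditions=set())
            union.nodes[n]["conditions"].add(name)
        for u, v, data in g.edges(data=True):
            if not union.has_edge(u, v):
                union.add_edge(u, v, conditions=set())
            union.edges[u, v]["conditions"].add(name)
            union.edges[u, v][f"p_z_{name}"] = data.get("p_z")
    for _, data in union.nodes(data=True):
        data["conditions"] = frozenset(data["conditions"])
    for _, _, data in union.edges(data=True):
        data["conditions"] = frozenset(data["conditions"])
    return union


# ---------------------------------------------------------------------------
# export


def write_sif(g: nx.Graph, path: str | Path, relation: str = "binds") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges):
            c, p = (u, v) if g.nodes[u]["kind"] == COMPOUND else (v, u)
            fh.write(f"{c}\t{relation}\t{p}\n")
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")


def write_edge_attributes(g: nx.Graph, path: str | Path) -> None:
    rows = []
    for u, v, data in sorted(g.edges(data=True)):
        c, p = (u, v) if g.nodes[u]["kind"] == COMPOUND else (v, u)
        rows.append((c, p, data.get("p_z"), data.get("weight")))
    pd.DataFrame(rows, columns=["compound_id", "protein_id", "p_z", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    h = g.copy()
    # GraphML cannot carry sets; flatten condition annotations
    for _, data in h.nodes(data=True):
        if isinstance(data.get("conditions"), frozenset):
            data["conditions"] = ",".join(sorted(data["conditions"]))
    for _, _, data in h.edges(data=True):
        if isinstance(data.get("conditions"), frozenset):
            data["conditions"] = ",".join(sorted(data["conditions"]))
        for k in [k for k, v in data.items() if v is None]:
            del data[k]
    nx.write_graphml(h, path)
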