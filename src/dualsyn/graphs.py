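"""Joint drug-pair graphs.

A drug pair is represented as a single graph built from the two drugs'
molecular graphs so that message passing can cross the drug boundary.
Four constructions are supported:

``super_edge`` (default)
    One virtual edge between the highest-betweenness-centrality atom of
    each drug. Betweenness identifies the atom most central to shortest
    paths within its own molecule.
``all_nodes``
    Full bipartite connection: every atom of drug A to every atom of B.
``one_super_node``
    One virtual node connected to every atom of both drugs.
``three_super_nodes``
    A virtual node per drug connected to that drug's atoms, plus a third
    virtual node bridging the two.

Drug B's atoms are offset by ``nA`` in the joint index space and both
drugs' bond sets are preserved verbatim. Virtual (super) nodes carry an
all-zero feature row; their role is purely topological.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import networkx as nx
import numpy as np

from .chem import MolecularGraph, N_ATOM_FEATURES


class JoinMethod(str, Enum):
    SUPER_EDGE = "super_edge"
    ALL_NODES = "all_nodes"
    ONE_SUPER_NODE = "one_super_node"
    THREE_SUPER_NODES = "three_super_nodes"


#: provenance labels for joint-graph nodes
PROV_A, PROV_B, PROV_SUP, PROV_SUP1, PROV_SUP2 = "A", "B", "SUP", "SUP1", "SUP2"


@dataclass(frozen=True)
class JointGraph:
    node_features: np.ndarray              # ((nA+nB+n_super) x 78)
    edges: frozenset[tuple[int, int]]      # unordered joint-index pairs
    provenance: tuple[str, ...]            # per-node label
    method: JoinMethod

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge lists (both directions plus self-loops)."""
        if self.edges:
            e = np.array(sorted(self.edges), dtype=np.intp)
            src = np.concatenate([e[:, 0], e[:, 1], np.arange(self.n_nodes)])
            dst = np.concatenate([e[:, 1], e[:, 0], np.arange(self.n_nodes)])
        else:
            src = dst = np.arange(self.n_nodes, dtype=np.intp)
        return src, dst


def betweenness_centrality(graph: MolecularGraph) -> np.ndarray:
    """Betweenness centrality C_B(v) of every atom.

    C_B(v) = sum over unordered node pairs {s, t} (s != v != t) of the
    fraction of shortest s–t paths passing through v, with unit edge
    weights and no normalization. Disconnected pairs contribute zero.
    """
    if graph.n_atoms == 0:
        raise ValueError("empty molecular graph")
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from(graph.edges)
    scores = nx.betweenness_centrality(g, normalized=False)
    return np.array([scores[i] for i in range(graph.n_atoms)])


def _anchor_atom(graph: MolecularGraph) -> int:
    """Index of the maximum-centrality atom; ties go to the lowest index."""
    return int(np.argmax(betweenness_centrality(graph)))


def _base(gA: MolecularGraph, gB: MolecularGraph, n_super: int):
    nA, nB = gA.n_atoms, gB.n_atoms
    feats = np.zeros((nA + nB + n_super, N_ATOM_FEATURES))
    feats[:nA] = gA.node_features
    feats[nA:nA + nB] = gB.node_features
    edges = {tuple(sorted(e)) for e in gA.edges}
    edges |= {tuple(sorted((i + nA, j + nA))) for i, j in gB.edges}
    prov = [PROV_A] * nA + [PROV_B] * nB
    return feats, edges, prov


def join_super_edge(gA: MolecularGraph, gB: MolecularGraph) -> JointGraph:
    """Join by one virtual edge between the two centrality anchors."""
    nA = gA.n_atoms
    feats, edges, prov = _base(gA, gB, 0)
    v1 = _anchor_atom(gA)
    v2 = _anchor_atom(gB) + nA
    edges.add(tuple(sorted((v1, v2))))
    return JointGraph(feats, frozenset(edges), tuple(prov), JoinMethod.SUPER_EDGE)


def join_all_nodes(gA: MolecularGraph, gB: MolecularGraph) -> JointGraph:
    """Join by the full bipartite product of the two atom sets."""
    nA, nB = gA.n_atoms, gB.n_atoms
    feats, edges, prov = _base(gA, gB, 0)
    for i in range(nA):
        for j in range(nB):
            edges.add((i, j + nA))
    return JointGraph(feats, frozenset(edges), tuple(prov), JoinMethod.ALL_NODES)


def join_one_super_node(gA: MolecularGraph, gB: MolecularGraph) -> JointGraph:
    """Join through a single virtual node adjacent to every atom."""
    nA, nB = gA.n_atoms, gB.n_atoms
    feats, edges, prov = _base(gA, gB, 1)
    sup = nA + nB
    for v in range(nA + nB):
        edges.add((v, sup))
    prov.append(PROV_SUP)
    return JointGraph(feats, frozenset(edges), tuple(prov), JoinMethod.ONE_SUPER_NODE)


def join_three_super_nodes(gA: MolecularGraph, gB: MolecularGraph) -> JointGraph:
    """Join through per-drug virtual nodes bridged by a third."""
    nA, nB = gA.n_atoms, gB.n_atoms
    feats, edges, prov = _base(gA, gB, 3)
    sup1, sup2, sup = nA + nB, nA + nB + 1, nA + nB + 2
    for i in range(nA):
        edges.add((i, sup1))
    for j in range(nB):
        edges.add((j + nA, sup2))
    edges.add((sup1, sup))
    edges.add((sup2, sup))
    prov.extend([PROV_SUP1, PROV_SUP2, PROV_SUP])
    return JointGraph(feats, frozenset(edges), tuple(prov), JoinMethod.THREE_SUPER_NODES)


_JOINERS = {
    JoinMethod.SUPER_EDGE: join_super_edge,
    JoinMethod.ALL_NODES: join_all_nodes,
    JoinMethod.ONE_SUPER_NODE: join_one_super_node,
    JoinMethod.THREE_SUPER_NODES: join_three_super_nodes,
}


def build_joint_graph(gA: MolecularGraph, gB: MolecularGraph,
                      method: JoinMethod | str = JoinMethod.SUPER_EDGE) -> JointGraph:
    """Build the joint graph of a drug pair with the chosen construction."""
    if gA.n_atoms == 0 or gB.n_atoms == 0:
        raise ValueError("cannot join an empty molecular graph")
    return _JOINERS[JoinMethod(method)](gA, gB)
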