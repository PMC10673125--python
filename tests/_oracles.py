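"""Independent oracles used by the test suite.

The atom-color canonicalizer is checked against a brute-force rooted
neighborhood comparison: the k-bond neighborhood of an atom is expanded
into its explicit tree of simple paths (never revisiting an atom on the
current path, hydrogens excluded beyond the root), and two neighborhoods
are considered equivalent exactly when those rooted labeled trees are
isomorphic under networkx's VF2 matcher with categorical node and edge
attributes.  This takes a completely different route from the
canonical-string construction it validates.
"""

from __future__ import annotations

import networkx as nx
from networkx.algorithms import isomorphism

from metpath.chem_graph import MolecularGraph


def build_path_tree(
    g: MolecularGraph, root: int, k: int, include_stereo: bool = True
) -> nx.DiGraph:
    """Explicit tree of simple paths of length <= k starting at ``root``."""
    atoms = g.atoms
    adj = g.adjacency()
    t = nx.DiGraph()

    def node_label(i: int) -> str:
        a = atoms[i]
        return f"{a.element}|{a.chirality}" if include_stereo else a.element

    root_key = (root,)
    t.add_node(root_key, label=node_label(root), is_root=True)
    frontier = [root_key]
    for _ in range(k):
        nxt = []
        for path in frontier:
            tip = path[-1]
            for j, bond in adj[tip]:
                if j in path or atoms[j].element == "H":
                    continue
                child = path + (j,)
                t.add_node(child, label=node_label(j), is_root=False)
                ek = (bond.order, bond.stereo) if include_stereo else (bond.order,)
                t.add_edge(path, child, bond=ek)
                nxt.append(child)
        frontier = nxt
    return t


def rooted_neighborhoods_isomorphic(
    g1: MolecularGraph, a1: int, g2: MolecularGraph, a2: int, k: int
) -> bool:
    t1 = build_path_tree(g1, a1, k)
    t2 = build_path_tree(g2, a2, k)
    if t1.number_of_nodes() != t2.number_of_nodes():
        return False
    nm = isomorphism.categorical_node_match(["label", "is_root"], [None, None])
    em = isomorphism.categorical_edge_match("bond", None)
    return isomorphism.DiGraphMatcher(t1, t2, node_match=nm, edge_match=em).is_isomorphic()
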