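"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: path enumeration
and substructure matching go through networkx on a hand-built labelled
graph, not through the package's DFS or RDKit substructure machinery.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

_BOND_CHAR = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def atom_label(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    q = atom.GetFormalCharge()
    return sym + ("+" * q if q > 0 else "-" * (-q))


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        try:
            hs = atom.GetTotalNumHs()
        except RuntimeError:  # unsanitized pattern atom: only explicit H known
            hs = atom.GetNumExplicitHs()
        g.add_node(
            atom.GetIdx(),
            label=atom_label(atom),
            hs=hs,
            explicit_hs=atom.GetNumExplicitHs(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            char=_BOND_CHAR.get(bond.GetBondType(), "~"),
        )
    return g


def enumerate_path_codes(mol: Chem.Mol, max_atoms: int = 7) -> set[str]:
    """All canonical simple-path codes via exhaustive networkx enumeration."""
    g = mol_to_graph(mol)
    codes: set[str] = set()
    for node in g.nodes:
        codes.add(g.nodes[node]["label"])

    def extend(path: list[int]) -> None:
        if 1 < len(path) <= max_atoms:
            tokens: list[str] = [g.nodes[path[0]]["label"]]
            for a, b in zip(path, path[1:]):
                tokens.append(g.edges[a, b]["char"])
                tokens.append(g.nodes[b]["label"])
            forward = "".join(tokens)
            codes.add(min(forward, "".join(reversed(tokens))))
        if len(path) == max_atoms:
            return
        for nbr in g.neighbors(path[-1]):
            if nbr not in path:
                extend(path + [nbr])

    for node in g.nodes:
        extend([node])
    return codes


def has_substructure(target: Chem.Mol, pattern_smiles: str) -> bool:
    """VF2 subgraph-monomorphism check of a fragment SMILES in a molecule.

    Mirrors the SMARTS conventions the fingerprint relies on: lowercase
    atoms match aromatic and uppercase aliphatic; an unmarked bond matches
    single or aromatic; a bracket hydrogen count is an exact constraint.
    """
    pattern = Chem.MolFromSmiles(pattern_smiles, sanitize=False)
    if pattern is None:
        raise ValueError(f"unparsable pattern {pattern_smiles!r}")
    tg = mol_to_graph(target)
    pg = mol_to_graph(pattern)

    def node_match(t, p):
        if t["label"] != p["label"]:
            return False
        if p["explicit_hs"] > 0 and t["hs"] != p["explicit_hs"]:
            return False
        return True

    def edge_match(t, p):
        if p["char"] == "-":
            return t["char"] in ("-", ":")
        return t["char"] == p["char"]

    gm = nx.algorithms.isomorphism.GraphMatcher(tg, pg, node_match=node_match, edge_match=edge_match)
    return gm.subgraph_is_monomorphic()
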