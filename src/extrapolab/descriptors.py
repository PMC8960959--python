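"""Three topological molecule descriptors.

* ``FragFp`` — 512-bit dictionary fingerprint.  The dictionary holds 512
  substructure fragments selected from a build corpus for (a) high match
  frequency and (b) mutual linear independence of their match patterns; bit i
  is set when fragment i occurs in the molecule.
* ``PathFp`` — 512-bit hashed fingerprint over all distinguishable simple
  paths of up to 7 atoms.
* ``SkelSpheres`` — 1024-bin count vector over canonically-encoded circular
  atom environments (radii 0..3 bonds) counted twice: once on the molecule
  itself and once on its carbon skeleton, i.e. with every heteroatom replaced
  by carbon.  The skeleton pass makes similarity partially insensitive to the
  exact placement of heteroatoms, mimicking a chemist's notion of scaffold
  similarity.

Hashing uses 32-bit FNV-1a on the fragment/path code string, reduced modulo
the vector length — a fixed, documented, roughly uniform binning function.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule

log = logging.getLogger(__name__)

DESCRIPTOR_KINDS = ("FragFp", "PathFp", "SkelSpheres")
DESCRIPTOR_LENGTHS = {"FragFp": 512, "PathFp": 512, "SkelSpheres": 1024}

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193


def fnv1a_32(text: str) -> int:
    """32-bit FNV-1a hash of a UTF-8 encoded string."""
    h = _FNV_OFFSET
    for byte in text.encode("utf-8"):
        h = ((h ^ byte) * _FNV_PRIME) & 0xFFFFFFFF
    return h


@dataclass(frozen=True)
class DescriptorVector:
    """Fixed-length non-negative integer vector with a descriptor-kind tag.

    FragFp and PathFp are binary; SkelSpheres holds counts.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in DESCRIPTOR_KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))
        if self.values.shape != (DESCRIPTOR_LENGTHS[self.kind],):
            raise ValueError(
                f"{self.kind} vector must have length {DESCRIPTOR_LENGTHS[self.kind]}"
            )
        if (self.values < 0).any():
            raise ValueError("descriptor values must be non-negative")


def tanimoto(a: DescriptorVector, b: DescriptorVector) -> float:
    """Tanimoto similarity; the min/max generalization for count vectors
    reduces to |and|/|or| on binary vectors.  Two all-zero vectors are
    defined as identical (similarity 1)."""
    if a.kind != b.kind:
        raise ValueError(f"descriptor kind mismatch: {a.kind} vs {b.kind}")
    return tanimoto_raw(a.values, b.values)


def tanimoto_raw(a: np.ndarray, b: np.ndarray) -> float:
    num = np.minimum(a, b).sum()
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 1.0
    return float(num) / float(denom)


# ---------------------------------------------------------------------------
# Path fingerprint


_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_symbol(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    if atom.GetIsAromatic():
        sym = sym.lower()
    charge = atom.GetFormalCharge()
    if charge > 0:
        sym += "+" * charge
    elif charge < 0:
        sym += "-" * (-charge)
    return sym


def canonical_path_codes(mol: Molecule, max_atoms: int = 7) -> set[str]:
    """All distinguishable simple paths of 1..max_atoms atoms.

    A path is encoded as alternating atom and bond symbols; the code is the
    lexicographic minimum of the forward and reverse encodings, so each
    undirected path contributes exactly one code.
    """
    atom_syms = [_atom_symbol(a) for a in mol.GetAtoms()]
    bond_syms = {}
    adjacency: list[list[tuple[int, str]]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        s = _BOND_SYMBOL.get(bond.GetBondType(), "~")
        adjacency[i].append((j, s))
        adjacency[j].append((i, s))
    codes: set[str] = set()

    def dfs(path: list[int], tokens: list[str]) -> None:
        forward = "".join(tokens)
        backward = "".join(reversed(tokens))
        codes.add(min(forward, backward))
        if len(path) == max_atoms:
            return
        last = path[-1]
        on_path = set(path)
        for nbr, bsym in adjacency[last]:
            if nbr in on_path:
                continue
            path.append(nbr)
            tokens.append(bsym)
            tokens.append(atom_syms[nbr])
            dfs(path, tokens)
            tokens.pop()
            tokens.pop()
            path.pop()

    for start in range(mol.GetNumAtoms()):
        dfs([start], [atom_syms[start]])
    return codes


def path_fp(mol: Molecule, length: int = 512, max_atoms: int = 7) -> DescriptorVector:
    """Binary fingerprint over hashed canonical simple-path codes."""
    values = np.zeros(DESCRIPTOR_LENGTHS["PathFp"] if length == 512 else length, dtype=np.int64)
    for code in canonical_path_codes(mol, max_atoms):
        values[fnv1a_32(code) % len(values)] = 1
    return DescriptorVector("PathFp", values)


# ---------------------------------------------------------------------------
# Skeleton spheres


def carbon_skeleton(mol: Molecule) -> Molecule:
    """Copy of *mol* with every heteroatom replaced by neutral carbon.

    Bond orders that would exceed carbon's valence are downgraded to single
    bonds deterministically: highest bond order first, lowest canonical atom
    rank first (canonical ranks of the unclipped skeleton, so the result is
    invariant under input atom reordering).  Stereo descriptors are dropped
    (they are generally invalidated by the replacement).  Aromaticity is
    re-perceived afterwards.
    """
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    rw = Chem.RWMol(kek)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for bond in rw.GetBonds():
        bond.SetStereo(Chem.BondStereo.STEREONONE)
    try:
        rank = list(Chem.CanonicalRankAtoms(rw.GetMol(), breakTies=True))
    except Exception:  # pathological intermediate: fall back to input order
        rank = list(range(rw.GetNumAtoms()))
    for atom in sorted(rw.GetAtoms(), key=lambda a: rank[a.GetIdx()]):
        while sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds()) > 4:
            over = [b for b in atom.GetBonds() if b.GetBondTypeAsDouble() > 1]
            if not over:
                break
            over.sort(
                key=lambda b: (
                    -b.GetBondTypeAsDouble(),
                    min(rank[b.GetBeginAtomIdx()], rank[b.GetEndAtomIdx()]),
                    max(rank[b.GetBeginAtomIdx()], rank[b.GetEndAtomIdx()]),
                )
            )
            over[0].SetBondType(Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def sphere_codes(mol: Molecule, n_radii: int = 4) -> list[str]:
    """Canonical codes of the circular fragments at radii 0..n_radii-1 around
    every heavy atom (``n_radii`` fragments per atom).

    Each sphere is extracted as a standalone fragment and canonicalized on
    its own graph, so codes are invariant under atom reordering of the
    parent molecule.
    """
    if mol.GetNumAtoms() == 0:
        return []
    dmat = Chem.GetDistanceMatrix(mol)
    bond_ends = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetIdx()) for b in mol.GetBonds()
    ]
    codes: list[str] = []
    for i in range(mol.GetNumAtoms()):
        for r in range(n_radii):
            atoms = {int(j) for j in np.flatnonzero(dmat[i] <= r)}
            if len(atoms) == 1:
                codes.append(Chem.MolFragmentToSmiles(mol, atomsToUse=[i]))
                continue
            bond_ids = [bid for a, b, bid in bond_ends if a in atoms and b in atoms]
            sub = Chem.PathToSubmol(mol, bond_ids)
            codes.append(Chem.MolToSmiles(sub))
    return codes


def skeleton_spheres(mol: Molecule, length: int = 1024, n_radii: int = 4) -> DescriptorVector:
    """Count vector over hashed circular-fragment codes, two passes:
    the molecule itself and its carbon skeleton.  The vector total is always
    ``2 * n_radii * heavy_atom_count``."""
    values = np.zeros(length, dtype=np.int64)
    for pass_mol in (mol, carbon_skeleton(mol)):
        for code in sphere_codes(pass_mol, n_radii):
            values[fnv1a_32(code) % length] += 1
    return DescriptorVector("SkelSpheres", values)


# ---------------------------------------------------------------------------
# Fragment fingerprint


class FragmentDictionaryUnderfullError(RuntimeError):
    def __init__(self, found: int, requested: int):
        self.found = found
        self.requested = requested
        super().__init__(
            f"only {found} acceptable fragments found, {requested} requested"
        )


@dataclass
class FragmentDictionary:
    """Ordered list of substructure patterns backing the FragFp descriptor.

    Patterns are fragment SMILES interpreted as SMARTS queries (lowercase
    atoms match aromatic, uppercase aliphatic; bracket hydrogens are
    constraints).
    """

    patterns: list[str]
    build_metadata: dict = field(default_factory=dict)
    _queries: list[Chem.Mol] | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def queries(self) -> list[Chem.Mol]:
        if self._queries is None:
            self._queries = [Chem.MolFromSmarts(p) for p in self.patterns]
            if any(q is None for q in self._queries):
                bad = [p for p, q in zip(self.patterns, self._queries) if q is None]
                raise ValueError(f"unparsable fragment patterns: {bad[:5]}")
        return self._queries

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# extrapolab fragment dictionary\n")
            fh.write("# " + json.dumps(self.build_metadata) + "\n")
            for p in self.patterns:
                fh.write(p + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FragmentDictionary":
        meta: dict = {}
        patterns: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("{"):
                        meta = json.loads(body)
                    continue
                patterns.append(line)
        return cls(patterns, meta)


def enumerate_fragment_codes(mol: Molecule, max_atoms: int = 7) -> set[str]:
    """Canonical SMILES of all connected subgraphs of up to *max_atoms* heavy
    atoms occurring in *mol* (single atoms included)."""
    codes: set[str] = set()
    for i in range(mol.GetNumAtoms()):
        codes.add(Chem.MolFragmentToSmiles(mol, atomsToUse=[i], canonical=True))
    try:
        by_length = Chem.FindAllSubgraphsOfLengthMToN(mol, 1, max_atoms - 1)
    except Exception:
        return codes
    for group in by_length:
        for bond_ids in group:
            sub = Chem.PathToSubmol(mol, list(bond_ids))
            if sub.GetNumAtoms() > max_atoms:
                continue
            try:
                codes.add(Chem.MolToSmiles(sub))
            except Exception:
                continue
    return codes


def build_fragment_dictionary(
    corpus: Sequence[Molecule],
    size: int = 512,
    max_atoms: int = 7,
    corr_threshold: float = 0.8,
    min_frequency: float = 0.02,
    corpus_id: str = "",
) -> FragmentDictionary:
    """Greedy frequency-then-independence fragment selection.

    Candidates (all connected subgraphs of up to *max_atoms* heavy atoms seen
    in the corpus) are sorted by corpus match frequency; a candidate is
    accepted iff the absolute Pearson correlation of its binary match vector
    with every already-accepted fragment's match vector stays below
    *corr_threshold*.  Constant match vectors (fragments matching none or all
    of the corpus) carry no information and are excluded.  Deterministic for
    a fixed corpus.
    """
    n = len(corpus)
    if n < 500:
        raise ValueError(f"fragment dictionary requires a corpus of >= 500 molecules, got {n}")
    incidence: dict[str, list[int]] = {}
    for mi, mol in enumerate(corpus):
        for code in enumerate_fragment_codes(mol, max_atoms):
            incidence.setdefault(code, []).append(mi)
    candidates = []
    for code, rows in incidence.items():
        freq = len(rows) / n
        if freq < min_frequency or freq >= 1.0:
            continue
        candidates.append((code, freq, rows))
    candidates.sort(key=lambda t: (-t[1], t[0]))

    accepted: list[str] = []
    z_rows: list[np.ndarray] = []  # unit-norm centered match vectors
    z_matrix = np.empty((0, n))
    for code, freq, rows in candidates:
        if len(accepted) == size:
            break
        v = np.zeros(n)
        v[rows] = 1.0
        z = v - v.mean()
        z /= np.linalg.norm(z)
        if z_rows:
            if np.abs(z_matrix @ z).max() >= corr_threshold:
                continue
        accepted.append(code)
        z_rows.append(z)
        z_matrix = np.vstack([z_matrix, z])
    if len(accepted) < size:
        raise FragmentDictionaryUnderfullError(len(accepted), size)
    meta = {
        "corpus_id": corpus_id,
        "corpus_size": n,
        "max_atoms": max_atoms,
        "corr_threshold": corr_threshold,
        "min_frequency": min_frequency,
    }
    return FragmentDictionary(accepted, meta)


def fragment_fp(mol: Molecule, dictionary: FragmentDictionary | None = None) -> DescriptorVector:
    """Binary fingerprint: bit i set iff dictionary fragment i occurs in
    *mol* as a substructure."""
    if dictionary is None:
        dictionary = load_default_dictionary()
    values = np.zeros(DESCRIPTOR_LENGTHS["FragFp"], dtype=np.int64)
    if len(dictionary) > len(values):
        raise ValueError("dictionary larger than fingerprint length")
    for i, query in enumerate(dictionary.queries):
        if mol.HasSubstructMatch(query):
            values[i] = 1
    return DescriptorVector("FragFp", values)


@lru_cache(maxsize=1)
def load_default_dictionary() -> FragmentDictionary:
    """The packaged dictionary, built from the union of default generated
    sets for the three seed drugs (see ``scripts/build_fragment_dictionary.py``)."""
    path = importlib.resources.files("extrapolab.data").joinpath("fragfp_dictionary_v1.smarts")
    with importlib.resources.as_file(path) as p:
        return FragmentDictionary.load(p)


# ---------------------------------------------------------------------------
# Matrix helpers


def compute_descriptor(mol: Molecule, kind: str, dictionary: FragmentDictionary | None = None) -> DescriptorVector:
    if kind == "FragFp":
        return fragment_fp(mol, dictionary)
    if kind == "PathFp":
        return path_fp(mol)
    if kind == "SkelSpheres":
        return skeleton_spheres(mol)
    raise ValueError(f"unknown descriptor kind {kind!r}")


def descriptor_matrix(
    mols: Iterable[Molecule], kind: str, dictionary: FragmentDictionary | None = None
) -> np.ndarray:
    """Row-stack of descriptor vectors for a molecule sequence."""
    if kind == "FragFp" and dictionary is None:
        dictionary = load_default_dictionary()
    return np.vstack([compute_descriptor(m, kind, dictionary).values for m in mols])
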