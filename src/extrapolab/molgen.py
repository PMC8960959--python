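"""Synthetic molecule sets by structural degradation of seed drugs.

Drug-discovery project datasets contain close analogues of a few lead
structures.  This module emulates such datasets by walking downhill from a
seed drug: at each step either a peripheral (terminal, non-ring) heavy atom
is deleted and replaced by hydrogens, or a ring bond is cut open.  Repeated
seeded random walks of varying depth yield a set of a few hundred unique
connected molecules whose property distributions (molecular weight, sp3
count, cLogP) span a wide, project-like range below the seed.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import Molecule, canonical_code, heavy_atom_count, parse_smiles

log = logging.getLogger(__name__)

SEED_NAMES = ("apixaban", "rosuvastatin", "sofosbuvir")


class NoRemovableAtomError(RuntimeError):
    """The molecule admits no legal degradation move."""


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the degradation random walk.

    target_set_size
        Number of unique molecules per set (study condition: ~300).
    max_steps_per_molecule
        Walk lengths are drawn uniformly from 1..this.  The default of 30 is
        deep enough to degrade a ~34-heavy-atom drug down to ~8 heavy atoms,
        covering the intended molecular-weight range (roughly 110-450 Da).
    attempt_budget
        Total number of walks attempted before giving up on reaching the
        target size.
    seed
        RNG seed; the whole set is a deterministic function of the config.
    min_heavy_atoms
        Walks stop before shrinking a molecule to this floor.
    """

    target_set_size: int = 300
    max_steps_per_molecule: int = 30
    attempt_budget: int = 20000
    seed: int = 0
    min_heavy_atoms: int = 5

    def __post_init__(self) -> None:
        if self.target_set_size < 1:
            raise ValueError("target_set_size must be >= 1")
        if self.attempt_budget < self.target_set_size:
            raise ValueError("attempt_budget must be >= target_set_size")


@dataclass
class MoleculeSet:
    """A replicate set of degradation products of one seed molecule."""

    seed_name: str
    replicate_index: int
    molecules: list[Molecule]
    provenance: DegradationConfig
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.molecules)


def _legal_moves(mol: Molecule) -> tuple[Molecule, list[tuple[str, int]]]:
    """Kekulized copy of *mol* plus its legal moves.

    A move is ``("atom", atom_index)`` for deletion of a terminal heavy atom
    (the only non-ring atoms whose removal keeps the graph connected) or
    ``("bond", bond_index)`` for cutting a ring bond.  Aromatic systems are
    kekulized first so that cutting assigns integer bond orders.
    """
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    moves: list[tuple[str, int]] = []
    for atom in kek.GetAtoms():
        if atom.GetDegree() == 1:
            moves.append(("atom", atom.GetIdx()))
    for bond in kek.GetBonds():
        if bond.IsInRing():
            moves.append(("bond", bond.GetIdx()))
    return kek, moves


def _apply_move(kek: Molecule, move: tuple[str, int]) -> Molecule:
    """Apply one move to a kekulized molecule and re-sanitize.

    Valence is conserved by crediting each affected atom with implicit
    hydrogens equal to the removed bond order; atoms with frozen hydrogen
    counts (bracket atoms) get explicit hydrogens instead.
    """
    rw = Chem.RWMol(kek)
    kind, idx = move
    if kind == "atom":
        atom = rw.GetAtomWithIdx(idx)
        nbr = atom.GetNeighbors()[0]
        order = int(rw.GetBondBetweenAtoms(idx, nbr.GetIdx()).GetBondTypeAsDouble())
        if nbr.GetNoImplicit():
            nbr.SetNumExplicitHs(nbr.GetNumExplicitHs() + order)
        rw.RemoveAtom(idx)
    else:
        bond = rw.GetBondWithIdx(idx)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = int(bond.GetBondTypeAsDouble())
        for ai in (i, j):
            at = rw.GetAtomWithIdx(ai)
            if at.GetNoImplicit():
                at.SetNumExplicitHs(at.GetNumExplicitHs() + order)
        rw.RemoveBond(i, j)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    # Round-trip through SMILES to normalize hydrogen bookkeeping and
    # aromaticity perception, so canonical codes match freshly parsed input.
    return parse_smiles(Chem.MolToSmiles(out))


def degrade_once(mol: Molecule, rng: np.random.Generator) -> Molecule:
    """One uniformly random legal degradation move.

    Returns a connected, sanitized molecule with either one terminal heavy
    atom removed or one ring bond opened.  Raises
    :class:`NoRemovableAtomError` when no legal move exists (e.g. methane).
    """
    kek, moves = _legal_moves(mol)
    if mol.GetNumHeavyAtoms() <= 1:
        raise NoRemovableAtomError("single-atom molecule has no removable atom")
    while moves:
        pick = int(rng.integers(len(moves)))
        move = moves.pop(pick)
        try:
            return _apply_move(kek, move)
        except Exception:  # rare sanitization failure: treat move as illegal
            continue
    raise NoRemovableAtomError("no legal degradation move")


def generate_set(
    seed_mol: Molecule,
    cfg: DegradationConfig,
    seed_name: str = "user",
    replicate_index: int = 1,
) -> MoleculeSet:
    """Generate one replicate set of unique degradation products.

    Each attempt is a random walk of 1..``max_steps_per_molecule`` degradation
    steps from the seed; the endpoint is accepted if it is new (by canonical
    code), strictly smaller than the seed, and at least ``min_heavy_atoms``
    heavy atoms.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    seed_heavy = heavy_atom_count(seed_mol)
    seen: set[str] = set()
    molecules: list[Molecule] = []
    attempts = rejected = 0
    while len(molecules) < cfg.target_set_size and attempts < cfg.attempt_budget:
        attempts += 1
        steps = int(rng.integers(1, cfg.max_steps_per_molecule + 1))
        current = seed_mol
        for _ in range(steps):
            if heavy_atom_count(current) <= cfg.min_heavy_atoms:
                break
            try:
                current = degrade_once(current, rng)
            except NoRemovableAtomError:
                break
        code = canonical_code(current)
        if heavy_atom_count(current) < seed_heavy and code not in seen:
            seen.add(code)
            molecules.append(current)
        else:
            rejected += 1
    if len(molecules) < cfg.target_set_size:
        log.warning(
            "attempt budget exhausted: %d/%d unique molecules for %s",
            len(molecules),
            cfg.target_set_size,
            seed_name,
        )
    stats = {"attempts": attempts, "rejected": rejected, "accepted": len(molecules)}
    log.info("generated %s replicate %d: %s", seed_name, replicate_index, stats)
    return MoleculeSet(seed_name, replicate_index, molecules, cfg, stats)


def generate_replicates(
    seed_mol: Molecule,
    cfg: DegradationConfig,
    seed_name: str = "user",
    n_replicates: int = 3,
) -> list[MoleculeSet]:
    """Replicates 1..n use RNG seeds ``cfg.seed``, ``cfg.seed + 1``, ..."""
    out = []
    for rep in range(1, n_replicates + 1):
        rep_cfg = DegradationConfig(
            target_set_size=cfg.target_set_size,
            max_steps_per_molecule=cfg.max_steps_per_molecule,
            attempt_budget=cfg.attempt_budget,
            seed=cfg.seed + rep - 1,
            min_heavy_atoms=cfg.min_heavy_atoms,
        )
        out.append(generate_set(seed_mol, rep_cfg, seed_name, rep))
    return out


def seed_library() -> list[tuple[str, Molecule]]:
    """The three packaged seed drugs (apixaban, rosuvastatin, sofosbuvir)."""
    text = (
        importlib.resources.files("extrapolab.data")
        .joinpath("seed_molecules.smi")
        .read_text()
    )
    out: list[tuple[str, Molecule]] = []
    for line in text.strip().splitlines():
        smiles, name = line.split()
        mol = parse_smiles(smiles)
        mol.SetProp("_Name", name)
        out.append((name, mol))
    return out
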