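"""The three calculated molecular responses: MW, sp3-carbon count, cLogP.

All three are strictly linear in local atom environments — molecular weight
in the molecular formula, sp3 count trivially in per-atom indicators, and
cLogP as an additive atom-type increment system (Wildman-Crippen
contributions).  This linearity is the point: a descriptor that preserves
atom-environment counts makes a perfect ("semi-mechanistic") linear model
theoretically possible.
"""

from __future__ import annotations

import importlib.resources
import json
import logging

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from .chem import Molecule

log = logging.getLogger(__name__)

RESPONSE_KINDS = ("MW", "SP3", "LOGP")

with importlib.resources.files("extrapolab.data").joinpath("atomic_weights.json").open() as _fh:
    ATOMIC_WEIGHTS: dict[str, float] = json.load(_fh)

_PERIODIC = Chem.GetPeriodicTable()


def _atomic_weight(symbol: str) -> float:
    try:
        return ATOMIC_WEIGHTS[symbol]
    except KeyError:
        # Elements outside the frozen table are rare in drug-like molecules;
        # fall back to the toolkit's periodic table.
        log.warning("element %s missing from frozen weight table; using toolkit value", symbol)
        return _PERIODIC.GetAtomicWeight(symbol)


def mol_weight(mol: Molecule) -> float:
    """Molecular weight in Da: standard atomic weights summed over the
    molecular formula, implicit hydrogens included."""
    total = 0.0
    n_h = 0
    for atom in mol.GetAtoms():
        total += _atomic_weight(atom.GetSymbol())
        n_h += atom.GetTotalNumHs()
    return total + n_h * ATOMIC_WEIGHTS["H"]


def sp3_count(mol: Molecule) -> int:
    """Number of saturated carbons: carbon atoms with exactly four
    neighbours (heavy plus hydrogen) and no multiple or aromatic bond."""
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetDegree() + atom.GetTotalNumHs() != 4:
            continue
        if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
            continue
        count += 1
    return count


def clogp(mol: Molecule) -> float:
    """Calculated octanol/water logP by the Wildman-Crippen atom-contribution
    system: each atom is assigned a type and the typed contributions are
    summed, so the value is exactly linear in atom-type counts."""
    return Crippen.MolLogP(mol)


def clogp_contributions(mol: Molecule) -> list[float]:
    """Per-atom Wildman-Crippen logP contributions (sums to :func:`clogp`).

    Hydrogens are made explicit first: every atom, including hydrogen,
    carries its own typed increment.
    """
    with_h = Chem.AddHs(mol)
    return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(with_h)]


_RESPONSE_FN = {"MW": mol_weight, "SP3": sp3_count, "LOGP": clogp}


def compute_response(mol: Molecule, kind: str) -> float:
    try:
        fn = _RESPONSE_FN[kind]
    except KeyError:
        raise ValueError(f"unknown response kind {kind!r}; expected one of {RESPONSE_KINDS}")
    return float(fn(mol))


def compute_responses(mols, kinds=RESPONSE_KINDS) -> pd.DataFrame:
    """Response table, one row per molecule, one column per kind."""
    return pd.DataFrame({k: [compute_response(m, k) for m in mols] for k in kinds})
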