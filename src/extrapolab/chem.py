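"""Molecular graph plumbing shared by every other module.

Molecules are represented as sanitized :class:`rdkit.Chem.Mol` objects
throughout the package.  Canonical identity of a molecule or fragment is its
canonical isomeric SMILES, treated everywhere as an opaque deterministic
string: two molecules have equal codes iff their labelled graphs (elements,
charges, bond orders, stereo where present) are isomorphic.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

log = logging.getLogger(__name__)

# RDKit's C++-side parse chatter goes through its own logger; keep it quiet
# and surface failures as Python exceptions instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

Molecule = Chem.Mol


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""

    def __init__(self, text: str, position: int | None = None):
        self.text = text
        self.position = position
        where = f" near position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {text!r}{where}")


def _locate_parse_failure(text: str) -> int | None:
    """Best-effort location of the first offending SMILES token.

    Finds the longest prefix that still fails to parse lazily (RDKit does not
    expose token positions); returns the index of the first character whose
    inclusion cannot be completed into a valid parse.
    """
    for i in range(1, len(text) + 1):
        frag = text[:i]
        # A prefix may be an incomplete (but so far legal) SMILES; only
        # flag characters that RDKit rejects outright.
        if Chem.MolFromSmiles(frag, sanitize=False) is None and not _may_be_prefix(frag):
            return i - 1
    return None


def _may_be_prefix(frag: str) -> bool:
    # Open branches/rings/brackets make a prefix legally incomplete.
    return (
        frag.count("(") > frag.count(")")
        or frag.count("[") > frag.count("]")
        or frag.rstrip("0123456789%") != frag
        or frag.endswith(("=", "#", "/", "\\", "-", "+", "@", "["))
    )


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a sanitized molecule.

    Raises :class:`SmilesParseError` (with an approximate token position) for
    malformed input.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(text, _locate_parse_failure(text))
    return mol


def write_smiles(mol: Molecule) -> str:
    """Canonical isomeric SMILES for *mol*."""
    return Chem.MolToSmiles(mol)


def canonical_code(mol: Molecule) -> str:
    """Deterministic, permutation-invariant identity string for a molecule.

    Delegates to the toolkit's canonical isomeric SMILES; stereo descriptors
    are included whenever they are present on the input.
    """
    return Chem.MolToSmiles(mol)


def heavy_atom_count(mol: Molecule) -> int:
    return mol.GetNumHeavyAtoms()


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read an SDF (V2000) file, preserving record order.

    Unreadable records are skipped with a logged warning naming the record
    index.
    """
    if Path(path).stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    mols: list[Molecule] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("skipping unreadable SDF record %d in %s", i, path)
            continue
        mols.append(mol)
    return mols


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            writer.write(mol)
    finally:
        writer.close()


def write_smiles_table(
    mols: Sequence[Molecule],
    responses: dict[str, Sequence[float]] | None,
    path: str | Path,
    ids: Sequence[str] | None = None,
) -> None:
    """Write molecules (and optional response columns) as a CSV table.

    Columns: ``id``, ``smiles``, then one column per response kind.  Order
    preserving.
    """
    responses = responses or {}
    for name, col in responses.items():
        if len(col) != len(mols):
            raise ValueError(f"response column {name!r} length mismatch")
    if ids is None:
        ids = [mol.GetProp("_Name") if mol.HasProp("_Name") else str(i) for i, mol in enumerate(mols)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", *responses.keys()])
        for i, mol in enumerate(mols):
            writer.writerow([ids[i], write_smiles(mol), *(responses[k][i] for k in responses)])


def read_smiles_table(path: str | Path) -> tuple[list[Molecule], dict[str, list[float]], list[str]]:
    """Read a CSV written by :func:`write_smiles_table`.

    Returns (molecules, response columns, ids).  Rows whose SMILES fail to
    parse are skipped with a warning.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: expected a header with a 'smiles' column")
        extra = [c for c in reader.fieldnames if c not in ("id", "smiles")]
        mols: list[Molecule] = []
        ids: list[str] = []
        responses: dict[str, list[float]] = {k: [] for k in extra}
        for i, row in enumerate(reader):
            try:
                mol = parse_smiles(row["smiles"])
            except SmilesParseError:
                log.warning("skipping unparsable row %d in %s", i, path)
                continue
            mols.append(mol)
            ids.append(row.get("id", str(i)))
            for k in extra:
                responses[k].append(float(row[k]))
    return mols, responses, ids
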