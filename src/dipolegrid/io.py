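"""Reading and writing molecular structures and charge annotations.

SDF (V2000) handling is delegated to RDKit; this module adds the
package's conventions on top: explicit hydrogens required, the supported
element whitelist, dipole labels in a configurable SDF property field
(default ``DFT_DM``, Debye), and per-atom charge sets stored either as a
whitespace-separated SDF property (``ATOM_CHARGES_<scheme>``) or as a
separate CSV charge table with columns ``mol_id, atom_index, charge``
(atom indices 1-based, matching SDF atom-block order).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

from .structures import (
    SUPPORTED_ELEMENTS,
    Atom,
    LabeledRecord,
    Molecule3D,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_sdf",
    "write_sdf",
    "read_xyz",
    "attach_charges",
    "read_charges_csv",
    "DEFAULT_LABEL_FIELD",
    "CHARGE_FIELD_TEMPLATE",
]

DEFAULT_LABEL_FIELD = "DFT_DM"
CHARGE_FIELD_TEMPLATE = "ATOM_CHARGES_{scheme}"

# RDKit logs every rejected molblock to stderr; we log our own warnings.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


def _mol_to_molecule3d(mol: Chem.Mol, mol_id: str) -> Molecule3D:
    """Convert an RDKit molecule (explicit H, 3D conformer) to Molecule3D."""
    if mol.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol_id!r}: no coordinates")
    if any(a.GetNumImplicitHs() > 0 or a.GetNumExplicitHs() > 0 for a in mol.GetAtoms()):
        raise ValueError(
            f"molecule {mol_id!r}: hydrogens must be explicit atoms in the "
            "atom block (implicit hydrogen counts found)"
        )
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        if a.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise ValueError(
                f"molecule {mol_id!r}: unsupported element {a.GetSymbol()!r}"
            )
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), np.array([pos.x, pos.y, pos.z])))
    m3d = Molecule3D(mol_id, atoms, Chem.GetFormalCharge(mol), rdkit_mol=mol)
    if np.allclose(m3d.coords[:, 2], 0.0):
        m3d.flags.add("2D_suspect")
        logger.warning("molecule %r: all z-coordinates zero (2D suspect)", mol_id)
    return m3d


def read_sdf(
    path: Union[str, Path],
    label_field: str = DEFAULT_LABEL_FIELD,
    charge_schemes: Sequence[str] = ("N", "P"),
) -> List[LabeledRecord]:
    """Read a V2000 SDF with 3D coordinates into labeled records.

    One record is produced per well-formed molfile block. Blocks RDKit
    cannot parse, molecules with unsupported elements, and molecules whose
    hydrogens are implicit are skipped with a logged warning (the skip
    count is logged at the end). A dipole label (Debye) is read from
    ``label_field`` when present; per-atom charges are read from
    ``ATOM_CHARGES_<scheme>`` properties (whitespace-separated, atom order)
    for each scheme in ``charge_schemes`` that is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: List[LabeledRecord] = []
    n_skipped = 0
    i = -1
    for i, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            logger.warning("%s: block %d malformed, skipped", path.name, i + 1)
            continue
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        mol_id = mol_id or f"{path.stem}_{i + 1}"
        try:
            m3d = _mol_to_molecule3d(mol, mol_id)
            for scheme in charge_schemes:
                prop = CHARGE_FIELD_TEMPLATE.format(scheme=scheme)
                if mol.HasProp(prop):
                    values = [float(x) for x in mol.GetProp(prop).split()]
                    m3d = m3d.with_charges(scheme, values)
            label = float(mol.GetProp(label_field)) if mol.HasProp(label_field) else None
            records.append(LabeledRecord(m3d, label))
        except ValueError as exc:
            n_skipped += 1
            logger.warning("%s: block %d rejected: %s", path.name, i + 1, exc)
    if n_skipped:
        logger.warning("%s: skipped %d of %d blocks", path.name, n_skipped, i + 1)
    return records


def write_sdf(
    records: Iterable[Union[LabeledRecord, Molecule3D]],
    path: Union[str, Path],
    label_field: str = DEFAULT_LABEL_FIELD,
) -> None:
    """Write molecules (with charge sets and labels as properties) to SDF.

    Coordinates are written at V2000 precision (4 decimals). Point-cloud
    molecules without connectivity are written with an empty bond block.
    """
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rec in records:
            m3d = rec.molecule if isinstance(rec, LabeledRecord) else rec
            label = rec.dm_label if isinstance(rec, LabeledRecord) else None
            mol = Chem.Mol(m3d.to_rdkit())
            mol.SetProp("_Name", m3d.id)
            for scheme in sorted(m3d.schemes):
                mol.SetProp(
                    CHARGE_FIELD_TEMPLATE.format(scheme=scheme),
                    " ".join(f"{q:.6f}" for q in m3d.charge_array(scheme)),
                )
            if label is not None:
                mol.SetProp(label_field, f"{label:.6f}")
            writer.write(mol)
    finally:
        writer.close()


def read_xyz(path: Union[str, Path]) -> Molecule3D:
    """Read a standard XYZ file (count line, comment, element x y z rows).

    Atoms are kept in file order and carry no charges. A mismatch between
    the declared count and the number of atom rows raises an error naming
    the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n_declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1 must start with the atom count") from None
    atoms: List[Atom] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        if len(atoms) == n_declared:
            raise ValueError(
                f"{path}: line {lineno}: more atom rows than the declared "
                f"count {n_declared}"
            )
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {lineno}: expected 'element x y z'")
        atoms.append(Atom(parts[0], np.array([float(x) for x in parts[1:4]])))
    if len(atoms) != n_declared:
        raise ValueError(
            f"{path}: declared {n_declared} atoms on line 1 but found "
            f"{len(atoms)} atom rows"
        )
    return Molecule3D(path.stem, atoms)


def read_charges_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a charge table CSV with columns mol_id, atom_index, charge."""
    table = pd.read_csv(path)
    required = {"mol_id", "atom_index", "charge"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"charge table must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    return table


def attach_charges(
    mol: Molecule3D,
    table: pd.DataFrame,
    scheme: str,
    magnitude_warn: float = 2.0,
) -> Molecule3D:
    """Attach a charge scheme to every atom from a charge table.

    ``table`` has columns ``mol_id, atom_index, charge`` with 1-based atom
    indices in SDF atom-block order. Every atom must have exactly one row
    (partial charge sets violate the molecule invariant). Charges with
    magnitude above ``magnitude_warn`` (e) trigger a warning only.
    Idempotent for the same scheme and table; returns an annotated copy.
    """
    rows = table[table["mol_id"].astype(str) == mol.id]
    indices = rows["atom_index"].to_numpy()
    expected = np.arange(1, mol.n_atoms + 1)
    if sorted(indices.tolist()) != expected.tolist():
        missing = sorted(set(expected) - set(indices))
        extra = sorted(set(indices) - set(expected))
        raise ValueError(
            f"molecule {mol.id!r}: charge table must cover atom indices "
            f"1..{mol.n_atoms} exactly (missing {missing}, unexpected {extra})"
        )
    values = np.empty(mol.n_atoms)
    values[indices - 1] = rows["charge"].to_numpy()
    big = np.abs(values) > magnitude_warn
    if big.any():
        logger.warning(
            "molecule %r: %d charges exceed %.1f e in magnitude",
            mol.id, int(big.sum()), magnitude_warn,
        )
    return mol.with_charges(scheme, values)
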