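"""Per-atom partial charges: built-in PEOE and external charge ingestion.

Two charge provenances are supported, mirroring the two descriptor
suffixes used throughout the package:

* scheme ``"P"`` — PEOE (Gasteiger partial equalization of orbital
  electronegativity) charges computed here from the molecular topology,
  via RDKit's implementation of the classic 1980 parameterization;
* scheme ``"N"`` — NBO-style charges predicted by an external tool and
  ingested from a charge table or SDF property. This package never
  computes NBO charges itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from rdkit.Chem import AllChem

from . import io as _io
from .structures import Molecule3D

logger = logging.getLogger(__name__)

__all__ = ["ChargeSet", "assign_peoe", "external_charges", "SCHEME_NBO", "SCHEME_PEOE"]

#: Reserved scheme names mapping to the _NBO / _PEOE descriptor suffixes.
SCHEME_NBO = "N"
SCHEME_PEOE = "P"

#: Σq must match the formal charge this closely for internally assigned charges.
ASSIGN_SUM_TOL = 1e-3
#: Externally predicted charges may not conserve exactly; warn past this.
EXTERNAL_SUM_WARN = 0.02


@dataclass
class ChargeSet:
    """An ordered per-atom charge vector (e) under a named scheme."""

    scheme: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def attach(self, mol: Molecule3D) -> Molecule3D:
        """Return a copy of ``mol`` carrying these charges."""
        return mol.with_charges(self.scheme, self.values)


def assign_peoe(
    mol: Molecule3D,
    n_iterations: int = 6,
    damping: float = 0.5,
) -> ChargeSet:
    """Compute PEOE (Gasteiger) partial charges from the molecular topology.

    The iterative electronegativity-equalization scheme transfers charge
    along bonds, attenuated by ``damping**k`` at iteration ``k``; six
    iterations essentially converge it. Computation is delegated to
    RDKit's implementation of the classic parameterization, which fixes
    the damping factor at 1/2 — any other ``damping`` raises.

    Charges are deterministic, independent of atom ordering up to
    molecular symmetry, and sum to the formal charge within 1e-3 e.

    Raises
    ------
    ValueError
        If the molecule has no bond information (PEOE is topology-based),
        contains an atom type without PEOE parameters, or ``damping`` is
        not 0.5.
    """
    if damping != 0.5:
        raise ValueError(
            "the classic PEOE parameterization fixes damping at 0.5 per "
            f"iteration; got {damping}"
        )
    if mol.n_atoms == 1:
        # An isolated atom has nothing to equalize against: its charge is
        # the formal charge.
        return ChargeSet(SCHEME_PEOE, np.array([float(mol.formal_charge)]))
    rdmol = mol.rdkit_mol
    if rdmol is None or rdmol.GetNumBonds() == 0:
        raise ValueError(
            f"molecule {mol.id!r}: PEOE requires connectivity (SDF bond "
            "block); none available"
        )
    try:
        AllChem.ComputeGasteigerCharges(
            rdmol, nIter=n_iterations, throwOnParamFailure=True
        )
    except Exception as exc:  # RDKit raises a Boost-wrapped ValueError
        raise ValueError(
            f"molecule {mol.id!r}: atom without PEOE parameters ({exc})"
        ) from exc
    values = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in rdmol.GetAtoms()]
    )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"molecule {mol.id!r}: PEOE produced non-finite charges")
    total = values.sum()
    if abs(total - mol.formal_charge) > ASSIGN_SUM_TOL:
        raise ValueError(
            f"molecule {mol.id!r}: PEOE charges sum to {total:.4f} e, "
            f"expected formal charge {mol.formal_charge}"
        )
    return ChargeSet(SCHEME_PEOE, values)


def external_charges(
    mol: Molecule3D,
    table: pd.DataFrame,
    scheme: str = SCHEME_NBO,
) -> ChargeSet:
    """Ingest an externally computed charge set from a charge table.

    This is the path for NBO-style machine-learned charges. The table
    contract is that of :func:`dipolegrid.io.attach_charges` (1-based atom
    indices, one row per atom). Because external predictions need not
    conserve charge exactly, a deviation of Σq from the formal charge
    beyond 0.02 e logs a warning but the set is still returned.
    """
    annotated = _io.attach_charges(mol, table, scheme)
    values = annotated.charge_array(scheme)
    total = values.sum()
    if abs(total - mol.formal_charge) > EXTERNAL_SUM_WARN:
        logger.warning(
            "molecule %r: external %r charges sum to %.4f e "
            "(formal charge %d); attaching anyway",
            mol.id, scheme, total, mol.formal_charge,
        )
    return ChargeSet(scheme, values)
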