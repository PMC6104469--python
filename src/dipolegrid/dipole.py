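"""Point-charge molecular dipole moments about the center of mass.

The dipole vector is the first moment of the partial-charge distribution,

    mu = sum_i q_i (r_i - r_com),

with q_i the partial atomic charge (e) of atom i and r_i its position
(Angstrom); the magnitude is reported in Debye (1 e*Angstrom =
4.803205 D). For neutral molecules the vector is origin-independent; for
net-charged molecules it is not, and the center of mass is always used
as the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structures import Molecule3D

logger = logging.getLogger(__name__)

__all__ = ["DEBYE_PER_E_ANGSTROM", "DipoleResult", "center_of_mass", "point_charge_dipole"]

#: Conversion from e*Angstrom to Debye.
DEBYE_PER_E_ANGSTROM = 4.803205


@dataclass
class DipoleResult:
    """Dipole of one molecule under one charge scheme.

    Attributes
    ----------
    scheme : str
        Charge scheme the dipole was computed from.
    vector : ndarray, shape (3,)
        Dipole vector in e*Angstrom, center-of-mass origin.
    magnitude_debye : float
        |vector| converted to Debye.
    com : ndarray, shape (3,)
        Center of mass (Angstrom) used as the origin.
    """

    scheme: str
    vector: np.ndarray
    magnitude_debye: float
    com: np.ndarray


def center_of_mass(mol: Molecule3D) -> np.ndarray:
    """Mass-weighted mean position (Angstrom), using standard atomic weights."""
    masses = mol.masses
    return masses @ mol.coords / masses.sum()


def point_charge_dipole(mol: Molecule3D, scheme: str) -> DipoleResult:
    """Point-charge dipole vector and Debye magnitude for ``scheme``.

    Raises ``KeyError`` if the scheme is not attached to the molecule.
    """
    charges = mol.charge_array(scheme)
    com = center_of_mass(mol)
    vector = charges @ (mol.coords - com)
    if mol.formal_charge != 0:
        logger.info(
            "molecule %r carries net charge %+d e: the dipole magnitude is "
            "origin-dependent (center of mass used)",
            mol.id, mol.formal_charge,
        )
    magnitude = float(np.linalg.norm(vector)) * DEBYE_PER_E_ANGSTROM
    return DipoleResult(scheme, vector, magnitude, com)
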