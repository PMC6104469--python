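"""Core molecular data model: atoms with coordinates and named charge sets.

The package operates on explicit-hydrogen 3D structures drawn from a
small-organic-molecule envelope (elements H, C, N, O, F, S, Cl, Br, P).
Every descriptor and dipole computation consumes a :class:`Molecule3D`,
which carries, per atom, the element, a standard atomic weight, Cartesian
coordinates in Angstrom, and any number of named partial-charge sets in
elementary charge units (e.g. ``"N"`` for NBO-style machine-learned charges,
``"P"`` for PEOE charges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

__all__ = [
    "SUPPORTED_ELEMENTS",
    "ATOMIC_MASSES",
    "Atom",
    "Molecule3D",
    "LabeledRecord",
    "UnsupportedElementError",
]

#: Element set of the target chemical space (small neutral organics).
SUPPORTED_ELEMENTS: Set[str] = {"H", "C", "N", "O", "F", "S", "Cl", "Br", "P"}

#: IUPAC conventional standard atomic weights (amu). Isotope labels are
#: deliberately ignored; the center of mass uses these values throughout.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "P": 30.973761998,
}


class UnsupportedElementError(ValueError):
    """Raised when a structure contains an element outside the supported set."""


def _check_element(element: str) -> str:
    if element not in SUPPORTED_ELEMENTS:
        raise UnsupportedElementError(
            f"element {element!r} is outside the supported set "
            f"{sorted(SUPPORTED_ELEMENTS)}"
        )
    return element


@dataclass
class Atom:
    """One atom: element, standard atomic weight, position, charge sets.

    Parameters
    ----------
    element : str
        Chemical symbol; must belong to :data:`SUPPORTED_ELEMENTS`.
    coords : sequence of 3 floats
        Cartesian position in Angstrom; must be finite.
    charges : dict, optional
        Map from charge-scheme name to partial charge in elementary
        charge units.
    mass : float, optional
        Atomic mass in amu; defaults to the standard atomic weight of
        ``element``.
    """

    element: str
    coords: np.ndarray
    charges: Dict[str, float] = field(default_factory=dict)
    mass: float = 0.0

    def __post_init__(self) -> None:
        _check_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.mass == 0.0:
            self.mass = ATOMIC_MASSES[self.element]
        if self.mass <= 0 or not math.isfinite(self.mass):
            raise ValueError(f"mass must be positive and finite, got {self.mass}")

    def copy(self) -> "Atom":
        return Atom(self.element, self.coords.copy(), dict(self.charges), self.mass)


@dataclass
class Molecule3D:
    """An explicit-hydrogen 3D molecule with named per-atom charge sets.

    A charge scheme, when present, must be present on *every* atom
    (partially charged molecules are invalid). Connectivity is optional
    and carried as an RDKit molecule in :attr:`rdkit_mol`; it is required
    only by topology-based operations (PEOE assignment, MACCS keys on
    bonded structures).
    """

    id: str
    atoms: List[Atom]
    formal_charge: int = 0
    rdkit_mol: Optional[object] = None  # rdkit.Chem.Mol, when read from SDF
    flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        self._validate_schemes()

    def _validate_schemes(self) -> None:
        all_schemes = set().union(*(a.charges.keys() for a in self.atoms))
        for scheme in all_schemes:
            missing = [i for i, a in enumerate(self.atoms) if scheme not in a.charges]
            if missing:
                raise ValueError(
                    f"molecule {self.id!r}: charge scheme {scheme!r} missing on "
                    f"atoms {missing} (schemes must cover all atoms)"
                )

    # -- array views ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> List[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def schemes(self) -> Set[str]:
        return set(self.atoms[0].charges.keys())

    def charge_array(self, scheme: str) -> np.ndarray:
        """Per-atom charges (e) for ``scheme``, in atom order."""
        if scheme not in self.schemes:
            raise KeyError(
                f"molecule {self.id!r} has no charge scheme {scheme!r}; "
                f"available: {sorted(self.schemes)}"
            )
        return np.array([a.charges[scheme] for a in self.atoms], dtype=float)

    # -- construction helpers ------------------------------------------

    def copy(self) -> "Molecule3D":
        return Molecule3D(
            self.id,
            [a.copy() for a in self.atoms],
            self.formal_charge,
            self.rdkit_mol,
            set(self.flags),
        )

    def with_charges(self, scheme: str, values: Sequence[float]) -> "Molecule3D":
        """Return a copy carrying ``values`` as charge scheme ``scheme``."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_atoms,):
            raise ValueError(
                f"charge vector length {values.size} != atom count {self.n_atoms}"
            )
        out = self.copy()
        for atom, q in zip(out.atoms, values):
            atom.charges[scheme] = float(q)
        return out

    def to_rdkit(self):
        """RDKit view of this molecule.

        Returns the stored SDF-derived molecule when available; otherwise
        builds a bond-less point-cloud molecule (sufficient for
        substructure fingerprints of atom-typed patterns).
        """
        if self.rdkit_mol is not None:
            return self.rdkit_mol
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        conf = Chem.Conformer(self.n_atoms)
        for i, atom in enumerate(self.atoms):
            conf.SetAtomPosition(i, Point3D(*map(float, atom.coords)))
        rw.AddConformer(conf)
        mol = rw.GetMol()
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
        return mol


@dataclass
class LabeledRecord:
    """A molecule together with its reference dipole magnitude, if known.

    ``dm_label`` is the DFT-quality dipole-moment magnitude in Debye used
    as the regression target; it is absent for prediction-only structures.
    """

    molecule: Molecule3D
    dm_label: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dm_label is not None:
            self.dm_label = float(self.dm_label)
            if self.dm_label < 0:
                raise ValueError(
                    f"molecule {self.molecule.id!r}: dipole label must be >= 0, "
                    f"got {self.dm_label}"
                )


def molecules(records: Iterable[LabeledRecord]) -> List[Molecule3D]:
    """Convenience: extract the molecules from a list of labeled records."""
    return [r.molecule for r in records]
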