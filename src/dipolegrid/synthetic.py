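"""Synthetic charged point-cloud molecules and brute-force oracles.

The generator emulates the envelope of a small-organic DFT dipole
database — 3 to 19 atoms drawn from H/C/N/O/F/S/Cl/Br/P with
organic-like frequencies, coordinates rejection-sampled inside a
12-Angstrom extent with a 0.9-Angstrom minimum separation, and per-atom
charges in the organic partial-charge range (centered Gaussian, scale
0.3 e) shifted to hit the molecular net charge exactly. Two independent
charge schemes "N" and "P" are attached, so the two dipole scalars are
correlated but distinct, as with real NBO vs PEOE charges.

Molecules are bond-less point clouds: sufficient for every geometric
descriptor; topology-dependent operations (PEOE, substructure-rich MACCS
keys) are exercised on hand-written bonded fixtures in the test suite.

The module also hosts deliberately naive, loop-based re-implementations
of the RDF and dipole sums, used as independent oracles by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .dipole import DEBYE_PER_E_ANGSTROM
from .structures import Atom, LabeledRecord, Molecule3D

__all__ = [
    "SynthConfig",
    "generate_molecule",
    "generate_labeled_dataset",
    "oracle_rdf",
    "oracle_dipole",
]

#: Organic-like element frequencies (H-rich, carbon backbone, sparse
#: heteroatoms/halogens), normalized at draw time.
DEFAULT_PALETTE: Tuple[Tuple[str, float], ...] = (
    ("H", 0.42),
    ("C", 0.32),
    ("N", 0.08),
    ("O", 0.10),
    ("F", 0.02),
    ("S", 0.02),
    ("Cl", 0.02),
    ("Br", 0.01),
    ("P", 0.01),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator envelope for synthetic molecules."""

    n_atoms_min: int = 3
    n_atoms_max: int = 19
    palette: Tuple[Tuple[str, float], ...] = DEFAULT_PALETTE
    min_distance: float = 0.9
    max_extent: float = 12.0
    charge_scale: float = 0.3
    net_charge: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if self.max_extent > 30.0:
            raise ValueError("extent must fit inside the projection range (+-15 A)")


def _place_atoms(
    rng: np.random.Generator, n: int, cfg: SynthConfig, max_attempts: int = 10_000
) -> np.ndarray:
    """Rejection-sample n positions in a cube of side max_extent, all
    pairwise distances >= min_distance."""
    half = cfg.max_extent / 2.0
    coords = np.empty((n, 3))
    placed = 0
    for _ in range(max_attempts):
        candidate = rng.uniform(-half, half, size=3)
        if placed == 0 or np.all(
            np.linalg.norm(coords[:placed] - candidate, axis=1) >= cfg.min_distance
        ):
            coords[placed] = candidate
            placed += 1
            if placed == n:
                return coords
    raise RuntimeError(
        f"could not place {n} atoms at min distance {cfg.min_distance} A "
        f"within {max_attempts} attempts; increase max_extent"
    )


def _draw_charges(rng: np.random.Generator, n: int, cfg: SynthConfig) -> np.ndarray:
    q = rng.normal(0.0, cfg.charge_scale, size=n)
    return q + (cfg.net_charge - q.sum()) / n


def generate_molecule(cfg: Optional[SynthConfig] = None, mol_id: str = "synth") -> Molecule3D:
    """One synthetic molecule with both charge schemes attached.

    Deterministic per config seed; charge schemes "N" and "P" are drawn
    independently and each sums exactly to the configured net charge.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(rng.integers(cfg.n_atoms_min, cfg.n_atoms_max + 1))
    symbols, weights = zip(*cfg.palette)
    probs = np.array(weights) / np.sum(weights)
    elements = rng.choice(symbols, size=n, p=probs)
    coords = _place_atoms(rng, n, cfg)
    atoms = [Atom(el, xyz) for el, xyz in zip(elements, coords)]
    mol = Molecule3D(mol_id, atoms, cfg.net_charge)
    mol = mol.with_charges("N", _draw_charges(rng, n, cfg))
    mol = mol.with_charges("P", _draw_charges(rng, n, cfg))
    return mol


def generate_labeled_dataset(
    n: int,
    cfg: Optional[SynthConfig] = None,
    noise_sd: float = 0.3,
    seed: Optional[int] = None,
) -> List[LabeledRecord]:
    """Planted-signal dataset: label = |point-charge DM, scheme N| + noise.

    Labels are in Debye, perturbed by centered Gaussian noise of standard
    deviation ``noise_sd`` (default 0.3 D) and clipped at zero. ``seed``
    overrides the config seed as the master seed.
    """
    cfg = cfg or SynthConfig()
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    records = []
    for i in range(n):
        sub_cfg = SynthConfig(
            **{
                **{f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
                "seed": int(master.integers(2**31 - 1)),
            }
        )
        mol = generate_molecule(sub_cfg, mol_id=f"synth_{i + 1}")
        dm = np.linalg.norm(oracle_dipole(mol, "N")) * DEBYE_PER_E_ANGSTROM
        label = max(0.0, dm + master.normal(0.0, noise_sd)) if noise_sd > 0 else dm
        records.append(LabeledRecord(mol, label))
    return records


# ---------------------------------------------------------------------------
# Brute-force oracles (no vectorization, no shared code with the
# descriptor or dipole modules)
# ---------------------------------------------------------------------------

def oracle_rdf(
    mol: Molecule3D, scheme: str, pair_class: str, r: float, B: float = 100.0
) -> float:
    """Naive double-loop evaluation of the sign-partitioned RDF at one r."""
    total = 0.0
    n = mol.n_atoms
    for i in range(n - 1):
        qi = mol.atoms[i].charges[scheme]
        for j in range(i + 1, n):
            qj = mol.atoms[j].charges[scheme]
            if pair_class == "mixed":
                keep = (qi > 0 and qj < 0) or (qi < 0 and qj > 0)
            elif pair_class == "both_positive":
                keep = qi > 0 and qj > 0
            elif pair_class == "both_negative":
                keep = qi < 0 and qj < 0
            else:
                raise ValueError(f"unknown pair class {pair_class!r}")
            if not keep:
                continue
            dx = mol.atoms[i].coords - mol.atoms[j].coords
            r_ij = (dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2) ** 0.5
            total += qi * qj * np.exp(-B * (r - r_ij) ** 2)
    return float(total)


def oracle_dipole(mol: Molecule3D, scheme: str) -> np.ndarray:
    """Naive per-atom summation of the point-charge dipole (e*Angstrom)."""
    total_mass = 0.0
    com = np.zeros(3)
    for atom in mol.atoms:
        com = com + atom.mass * atom.coords
        total_mass += atom.mass
    com = com / total_mass
    mu = np.zeros(3)
    for atom in mol.atoms:
        mu = mu + atom.charges[scheme] * (atom.coords - com)
    return mu
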