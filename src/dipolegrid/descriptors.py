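"""Descriptor families for dipole-moment QSPR and their assembly.

Three families are computed from a charged 3D structure:

* **Sign-partitioned charge-weighted RDF.** The radial distribution
  function over unordered atom pairs,

      RDF(r) = sum_{i<j} p_i p_j exp(-B (r - r_ij)^2),

  sampled on a radial grid, with the pair sum restricted to one of three
  charge-sign classes: a positive and a negative charge (*mixed*), two
  positive charges, or two negative charges. Raw signed products are
  kept, so the mixed block is everywhere <= 0. Defaults: 128 grid points
  r_k = k * 0.1 Angstrom (k = 1..128) and fuzziness B = 100 / Angstrom^2,
  giving 3 x 128 = 384 values per charge scheme.

* **PchmDM dipole-axis projections.** Each atom is projected onto the
  axis of the point-charge dipole (same charge scheme, center-of-mass
  origin) and its charge (or mass) accumulated into 0.5-Angstrom bins
  spanning [-15, 15) Angstrom. Six series of 60 bins: all charges,
  positive charges, negative charges, non-H charges, H charges, masses —
  360 values per scheme.

* **MACCS keys.** The standard 166-bit substructure fingerprint,
  delegated to RDKit.

Feature recipes combine these with the two empirical dipole-magnitude
scalars DM_N and DM_P (Debye): recipe ``C`` = RDF(N) + PchmDM(N) + both
DMs (746 columns); recipe ``F`` adds MACCS (912); recipe ``MACCS_DM`` is
MACCS + both DMs (168).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dipole import DipoleResult, center_of_mass, point_charge_dipole
from .structures import Molecule3D

logger = logging.getLogger(__name__)

__all__ = [
    "RDFConfig",
    "PchmConfig",
    "DescriptorBlock",
    "PAIR_CLASSES",
    "PCHM_SERIES",
    "RECIPES",
    "rdf_pair_block",
    "rdf_full",
    "dm_axis",
    "pchm_block",
    "maccs_block",
    "assemble_features",
    "MoleculeFeaturizer",
]

PAIR_CLASSES = ("mixed", "both_positive", "both_negative")
PCHM_SERIES = ("desc", "desc_plus", "desc_minus", "desc_noH", "desc_H", "desc_mass")
RECIPES = ("C", "F", "MACCS_DM")

#: Dipole magnitudes below this (e*Angstrom) trigger the principal-axis
#: fallback when defining the projection axis.
AXIS_DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class RDFConfig:
    """Radial grid and fuzziness for the RDF descriptors.

    The grid is r_k = k * (r_max / n_points) for k = 1..n_points; r = 0 is
    excluded since no atom pair can sit at zero distance.
    """

    n_points: int = 128
    r_max: float = 12.8
    fuzziness_B: float = 100.0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.r_max <= 0 or self.fuzziness_B <= 0:
            raise ValueError("r_max and fuzziness_B must be positive")

    @property
    def grid(self) -> np.ndarray:
        step = self.r_max / self.n_points
        return step * np.arange(1, self.n_points + 1)


@dataclass(frozen=True)
class PchmConfig:
    """Binning of the dipole-axis projections.

    ``n_bins`` half-open intervals [lo, lo + bin_width) of width
    ``bin_width`` must tile [range_min, range_max) exactly; the origin is
    the center of mass.
    """

    n_bins: int = 60
    bin_width: float = 0.5
    range_min: float = -15.0
    range_max: float = 15.0

    def __post_init__(self) -> None:
        span = self.range_max - self.range_min
        if abs(self.n_bins * self.bin_width - span) > 1e-9:
            raise ValueError(
                f"n_bins * bin_width = {self.n_bins * self.bin_width} must "
                f"span the range exactly ({span})"
            )


@dataclass
class DescriptorBlock:
    """A named, ordered, fixed-length numeric feature vector."""

    labels: List[str]
    values: np.ndarray
    provenance: Tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError(
                f"{len(self.labels)} labels but {self.values.size} values"
            )

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels)


def _concat_blocks(blocks: Sequence[DescriptorBlock], provenance: Tuple) -> DescriptorBlock:
    labels = [l for b in blocks for l in b.labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate feature labels in assembled vector")
    return DescriptorBlock(
        labels, np.concatenate([b.values for b in blocks]), provenance
    )


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def _pair_products_distances(
    mol: Molecule3D, scheme: str, pair_class: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Charge products p_i p_j and distances r_ij for pairs in a sign class.

    Atoms with charge exactly zero belong to no class (strict inequalities).
    """
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"pair_class must be one of {PAIR_CLASSES}, got {pair_class!r}")
    q = mol.charge_array(scheme)
    coords = mol.coords
    iu, ju = np.triu_indices(mol.n_atoms, k=1)
    qi, qj = q[iu], q[ju]
    if pair_class == "mixed":
        mask = (qi * qj) < 0
    elif pair_class == "both_positive":
        mask = (qi > 0) & (qj > 0)
    else:
        mask = (qi < 0) & (qj < 0)
    products = qi[mask] * qj[mask]
    dists = np.linalg.norm(coords[iu[mask]] - coords[ju[mask]], axis=1)
    return products, dists


def rdf_pair_block(
    mol: Molecule3D,
    scheme: str,
    pair_class: str,
    cfg: Optional[RDFConfig] = None,
) -> DescriptorBlock:
    """Charge-weighted Gaussian RDF over one charge-sign pair class.

    Value at grid point r_k is the sum over unordered atom pairs {i, j}
    in ``pair_class`` of p_i p_j exp(-B (r_k - r_ij)^2). Signed products
    are used, so the mixed block is <= 0 and the like-sign blocks >= 0.
    """
    cfg = cfg or RDFConfig()
    products, dists = _pair_products_distances(mol, scheme, pair_class)
    grid = cfg.grid
    if products.size == 0:
        values = np.zeros(cfg.n_points)
    else:
        gauss = np.exp(-cfg.fuzziness_B * (grid[:, None] - dists[None, :]) ** 2)
        values = gauss @ products
    labels = [f"RDF_{scheme}_{pair_class}_{k}" for k in range(1, cfg.n_points + 1)]
    return DescriptorBlock(labels, values, ("RDF", scheme, pair_class, cfg))


def rdf_full(
    mol: Molecule3D, scheme: str, cfg: Optional[RDFConfig] = None
) -> DescriptorBlock:
    """All three pair-class RDF blocks, in order mixed, both_positive,
    both_negative (3 x n_points values; 384 by default)."""
    cfg = cfg or RDFConfig()
    return _concat_blocks(
        [rdf_pair_block(mol, scheme, pc, cfg) for pc in PAIR_CLASSES],
        ("RDF", scheme, "full", cfg),
    )


# ---------------------------------------------------------------------------
# PchmDM
# ---------------------------------------------------------------------------

def dm_axis(dm: DipoleResult, mol: Molecule3D) -> np.ndarray:
    """Unit vector along the dipole, with a principal-axis fallback.

    When the dipole magnitude is below 1e-10 e*Angstrom the projection
    axis is taken as the eigenvector of the largest eigenvalue of the
    mass gyration tensor, its sign fixed so the first nonzero component
    is positive. A fully degenerate mass distribution (single atom) maps
    to (1, 0, 0) by convention.
    """
    norm = np.linalg.norm(dm.vector)
    if norm >= AXIS_DEGENERACY_TOL:
        return dm.vector / norm
    centered = mol.coords - center_of_mass(mol)
    gyration = (mol.masses[:, None] * centered).T @ centered
    eigvals, eigvecs = np.linalg.eigh(gyration)
    if eigvals[-1] < 1e-12:
        return np.array([1.0, 0.0, 0.0])
    axis = eigvecs[:, -1]
    for component in axis:
        if abs(component) > 1e-12:
            if component < 0:
                axis = -axis
            break
    return axis


def pchm_block(
    mol: Molecule3D,
    scheme: str,
    cfg: Optional[PchmConfig] = None,
) -> DescriptorBlock:
    """Charges and masses binned along the dipole axis (PchmDM).

    Projections t_i = (r_i - com) . axis use the dipole axis of the SAME
    charge scheme. Bins are half-open [lo, lo + width) from range_min
    inclusive; projections outside the range are clamped into the
    terminal bins (with a warning), which preserves the conservation
    identities. Series order: desc, desc_plus, desc_minus, desc_noH,
    desc_H, desc_mass.
    """
    cfg = cfg or PchmConfig()
    dm = point_charge_dipole(mol, scheme)
    axis = dm_axis(dm, mol)
    t = (mol.coords - dm.com) @ axis
    bins = np.floor((t - cfg.range_min) / cfg.bin_width).astype(int)
    out_of_range = (bins < 0) | (bins >= cfg.n_bins)
    if out_of_range.any():
        logger.warning(
            "molecule %r: %d projections outside [%g, %g) clamped to "
            "terminal bins",
            mol.id, int(out_of_range.sum()), cfg.range_min, cfg.range_max,
        )
        bins = np.clip(bins, 0, cfg.n_bins - 1)

    q = mol.charge_array(scheme)
    is_h = np.array([a.element == "H" for a in mol.atoms])
    weight_sets = {
        "desc": q,
        "desc_plus": np.where(q > 0, q, 0.0),
        "desc_minus": np.where(q < 0, q, 0.0),
        "desc_noH": np.where(~is_h, q, 0.0),
        "desc_H": np.where(is_h, q, 0.0),
        "desc_mass": mol.masses,
    }
    values = np.concatenate(
        [
            np.bincount(bins, weights=weight_sets[series], minlength=cfg.n_bins)
            for series in PCHM_SERIES
        ]
    )
    labels = [
        f"PCHM_{scheme}_{series}_{k}"
        for series in PCHM_SERIES
        for k in range(1, cfg.n_bins + 1)
    ]
    return DescriptorBlock(labels, values, ("PCHM", scheme, cfg))


# ---------------------------------------------------------------------------
# MACCS
# ---------------------------------------------------------------------------

def maccs_block(mol: Molecule3D) -> DescriptorBlock:
    """Standard 166-key MACCS substructure fingerprint as 0/1 values.

    Delegated to RDKit (bit 0 of its 167-bit vector is unused and
    dropped). Works on bond-less point clouds too, where only atom-typed
    keys can fire.
    """
    from rdkit.Chem import MACCSkeys

    try:
        fp = MACCSkeys.GenMACCSKeys(mol.to_rdkit())
    except Exception as exc:
        raise RuntimeError(f"MACCS fingerprint failed for molecule {mol.id!r}: {exc}")
    bits = np.zeros(166)
    for b in fp.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1.0
    labels = [f"MACCS_{k}" for k in range(1, 167)]
    return DescriptorBlock(labels, bits, ("MACCS",))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _dm_block(mol: Molecule3D) -> DescriptorBlock:
    """The two empirical dipole-magnitude scalars DM_N and DM_P (Debye)."""
    values = [point_charge_dipole(mol, s).magnitude_debye for s in ("N", "P")]
    return DescriptorBlock(["DM_N", "DM_P"], np.array(values), ("DM",))


#: Charge schemes each recipe needs attached.
_RECIPE_SCHEMES: Dict[str, Tuple[str, ...]] = {
    "C": ("N", "P"),
    "F": ("N", "P"),
    "MACCS_DM": ("N", "P"),
}


def assemble_features(
    mol: Molecule3D,
    recipe: str = "C",
    rdf_cfg: Optional[RDFConfig] = None,
    pchm_cfg: Optional[PchmConfig] = None,
) -> DescriptorBlock:
    """Assemble the fixed-order feature vector for one recipe.

    * ``C``: RDF (scheme N, 384) + PchmDM (scheme N, 360) + DM_N + DM_P
      -> 746 columns.
    * ``F``: as C plus MACCS (166) before the DM scalars -> 912 columns.
    * ``MACCS_DM``: MACCS (166) + DM_N + DM_P -> 168 columns.

    Raises ``ValueError`` listing the missing charge schemes, if any.
    """
    if recipe not in RECIPES:
        raise ValueError(f"recipe must be one of {RECIPES}, got {recipe!r}")
    missing = sorted(set(_RECIPE_SCHEMES[recipe]) - mol.schemes)
    if missing:
        raise ValueError(
            f"molecule {mol.id!r}: recipe {recipe!r} requires charge "
            f"schemes {missing} which are not attached"
        )
    blocks: List[DescriptorBlock] = []
    if recipe in ("C", "F"):
        blocks.append(rdf_full(mol, "N", rdf_cfg))
        blocks.append(pchm_block(mol, "N", pchm_cfg))
    if recipe in ("F", "MACCS_DM"):
        blocks.append(maccs_block(mol))
    blocks.append(_dm_block(mol))
    return _concat_blocks(blocks, ("recipe", recipe))


class MoleculeFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer mapping molecules to a recipe's feature matrix.

    Parameters
    ----------
    recipe : {"C", "F", "MACCS_DM"}, default "C"
        Which descriptor recipe to assemble (see :func:`assemble_features`).
    rdf_cfg, pchm_cfg : RDFConfig / PchmConfig, optional
        Descriptor-family configurations; package defaults when None.

    Attributes
    ----------
    feature_names_ : list of str
        Fixed column order of the produced feature matrix.
    n_features_ : int
        Number of feature columns (746 / 912 / 168 at default configs).

    ``transform`` takes a sequence of :class:`Molecule3D` (with the
    required charge schemes attached) and returns a ``DataFrame`` indexed
    by molecule id.
    """

    def __init__(
        self,
        recipe: str = "C",
        rdf_cfg: Optional[RDFConfig] = None,
        pchm_cfg: Optional[PchmConfig] = None,
    ):
        self.recipe = recipe
        self.rdf_cfg = rdf_cfg
        self.pchm_cfg = pchm_cfg

    def fit(self, X: Sequence[Molecule3D], y=None) -> "MoleculeFeaturizer":
        if self.recipe not in RECIPES:
            raise ValueError(f"recipe must be one of {RECIPES}, got {self.recipe!r}")
        rdf_cfg = self.rdf_cfg or RDFConfig()
        pchm_cfg = self.pchm_cfg or PchmConfig()
        labels: List[str] = []
        if self.recipe in ("C", "F"):
            labels += [
                f"RDF_N_{pc}_{k}"
                for pc in PAIR_CLASSES
                for k in range(1, rdf_cfg.n_points + 1)
            ]
            labels += [
                f"PCHM_N_{series}_{k}"
                for series in PCHM_SERIES
                for k in range(1, pchm_cfg.n_bins + 1)
            ]
        if self.recipe in ("F", "MACCS_DM"):
            labels += [f"MACCS_{k}" for k in range(1, 167)]
        labels += ["DM_N", "DM_P"]
        self.feature_names_ = labels
        self.n_features_ = len(labels)
        return self

    def transform(self, X: Sequence[Molecule3D]) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = []
        ids = []
        for mol in X:
            block = assemble_features(mol, self.recipe, self.rdf_cfg, self.pchm_cfg)
            if block.labels != self.feature_names_:
                raise ValueError(
                    f"molecule {mol.id!r} produced unexpected feature columns"
                )
            rows.append(block.values)
            ids.append(mol.id)
        return pd.DataFrame(np.vstack(rows), index=ids, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
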