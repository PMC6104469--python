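# Methods

## Point-charge dipoles

The dipole vector is the first moment of the partial-charge distribution
about the center of mass, μ = Σᵢ qᵢ(rᵢ − r_com), with charges in
elementary charge units and coordinates in Å; magnitudes are reported in
Debye via 1 e·Å = 4.803205 D. Masses are IUPAC conventional standard
atomic weights; isotope labels in input files are ignored. For neutral
molecules the vector is origin-independent; net-charged molecules are
accepted, with the center of mass fixed as the origin (the magnitude is
then origin-dependent, which is logged).

## Charge schemes

Scheme `"P"` (PEOE) is computed from the bond graph with the classic
iterative partial-equalization scheme: per iteration k the charge flowing
along each bond is attenuated by (1/2)ᵏ; six iterations are the default
and effectively converged. The computation is delegated to RDKit's
implementation of the original parameterization, which fixes the damping
factor — the `damping` argument exists for interface clarity and
validates to 0.5. Assigned charges must conserve the formal charge to
1e-3 e (hard error otherwise).

Scheme `"N"` (NBO-style) is always ingested, never computed: an external
predictor supplies per-atom charges as a CSV table (`mol_id, atom_index,
charge`, 1-based indices in SDF atom-block order) or as a whitespace-
separated SDF property `ATOM_CHARGES_N`. Because such predictors need
not conserve charge exactly, deviations of Σq from the formal charge
beyond 0.02 e warn rather than reject. Charges of magnitude above 2 e
also warn — they are almost certainly unit mistakes.

## Descriptors

**RDF.** The charge-weighted radial distribution is evaluated on the
grid r_k = k·0.1 Å, k = 1…128. The grid choice excludes r = 0 (no atom
pair can sit at distance zero) and makes the nominal 12.8 Å range an
exact 128-point lattice; both grid and fuzziness B (default 100 Å⁻²)
are configurable. Unordered pairs are counted once. Signed charge
products are retained, so the mixed-sign block is ≤ 0 everywhere and
the like-sign blocks ≥ 0; atoms with charge exactly 0 belong to no sign
class (strict inequalities). Block order: mixed, both_positive,
both_negative.

**PchmDM.** Atoms are projected onto the unit vector along the
point-charge dipole *of the same charge scheme*; projections fall into
sixty half-open bins [lo, lo + 0.5 Å) tiling [−15, 15) Å, lower edge
inclusive. Projections outside the range are clamped into the terminal
bins with a warning — this preserves the conservation identities
(per-bin desc = desc_plus + desc_minus = desc_noH + desc_H; bin sums
equal Σq and the molecular weight) and cannot trigger for molecules
within the supported ~13 Å extent. When the dipole magnitude is below
1e-10 e·Å the projection axis is undefined; the fallback is the
principal axis of the mass gyration tensor (largest eigenvalue), sign
fixed so the first nonzero component is positive, and a single atom
(fully degenerate) maps to (1, 0, 0) by convention — all charge series
are then zero anyway and only the mass bin is populated.

**MACCS.** RDKit's 167-bit MACCS vector, dropping the unused bit 0,
yields the standard 166 keys labeled `MACCS_1..166`.

**Assembly.** Feature columns are named `<family>_<scheme>_<series>_<k>`
plus the scalars `DM_N`, `DM_P`, so serialized models can be re-applied
safely. Column order is fixed per recipe: RDF, PchmDM, (MACCS), DM_N,
DM_P. Recipes use scheme-N blocks; both DM scalars are always included
— empirically they are complementary (the two charge schemes correlate
only weakly), and they dominate every importance ranking.

## Random-forest workflow

Forests have 500 trees by default. The per-node feature-subset size
(mtry) is selected from the grid {p/3, √p, p/2} by out-of-bag RMSE —
the grid is a deliberately small bracket around the regression default
p/3, and ties go to the smaller value. R² is reported as the squared
Pearson correlation between predicted and observed values (a constant
prediction vector reports 0); the coefficient of determination is
available via `r2_definition="cod"`. Predictions hard-error on missing
or renamed feature columns — silent imputation could corrupt the
dipole-scalar columns that carry most of the signal.

Feature importance is the mean decrease in accuracy computed out of bag
per tree: for each tree, the increase in mean squared error on its
out-of-bag rows when one column is permuted within those rows, averaged
over trees; ties in the ranking break by column order.

y-randomization retrains on label-scrambled training rows (descriptor
matrix untouched) and evaluates on the untouched test rows, five rounds
by default. Scrambled rounds reuse the real model's selected mtry rather
than re-running the OOB grid: re-tuning a null model cannot improve it
and would only add variance to the null distribution.

## Synthetic data

The generator emulates the *envelope* of a small-organic dipole
database: 3–19 atoms from H/C/N/O/F/S/Cl/Br/P at organic-like
frequencies, coordinates rejection-sampled in a 12 Å cube with ≥ 0.9 Å
separation, independent Gaussian charge sets (scale 0.3 e) for schemes
N and P, each shifted to hit the net charge exactly. Planted-signal
labels are |point-charge DM, scheme N| + N(0, 0.3 D), clipped at zero.

What it does **not** emulate: covalent geometry (molecules are bond-less
point clouds, so PEOE and bond-dependent MACCS keys are exercised on
hand-written bonded fixtures instead), realistic charge–position
correlation, or the label scale of DFT databases — uncorrelated charges
across a 12 Å extent produce dipoles averaging ≈ 25 D versus ≈ 3 D for
real small organics, with a heavier right tail. Passing the planted-signal
study therefore demonstrates that the pipeline recovers a dipole-borne
signal through the descriptor path, not that real-database accuracies
transfer; those require real structures and externally predicted charges.

The desk-scale study uses 500 molecules with a one-third test split, a
size at which the full pipeline (featurization, three tuning fits,
importance, five null rounds) completes in well under a minute. One
caveat at this size: the y-randomization null R² is itself a random
variable with much larger spread than at database scale (forest
predictions are smooth random functions of DM_N, and the heavy-tailed
labels inflate Pearson correlations), so occasional null rounds can
reach R² ≈ 0.1 where a 10,000-molecule study sits near 0.001.

## Degenerate inputs and edge cases

Single-atom molecules: zero dipole, all RDF blocks zero, conventional
projection axis. All-zero charge sets are valid and degrade every
descriptor gracefully to zeros. SDF blocks that fail to parse, contain
unsupported elements, or carry implicit-only hydrogens are skipped with
counted warnings rather than aborting the batch; structures whose
z-coordinates are all zero are flagged `2D_suspect` but kept. XYZ input
is strict about the declared atom count and names the offending line.
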