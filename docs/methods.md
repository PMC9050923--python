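# Methods

## The modelling problem

The library is a congeneric series: every member shares the aromatic
1,3,5-triazine-2,4-diamine core (triazine ring, exocyclic NH₂, anilino NH,
and the C6-aryl attachment carbon — nine shared heavy atoms) and differs only
in the R¹/R² aryl substituents. Activity is growth inhibition of MDA-MB231
triple-negative breast-cancer cells, modelled as
pGI50 = −log₁₀(GI50 in mol/L) = 6 − log₁₀(GI50 in µM). Field-based
(CoMFA-style) 3D-QSAR assumes that, once the series is superposed on its
common scaffold, differences in activity are a linear function of the
steric and electrostatic fields the molecules present to their surroundings,
sampled on a common grid.

## Library assembly and oracles

Substituent tokens map one-to-one onto SMILES fragments whose first atom is
the attachment point; regiochemistry follows the token name (e.g. 2-F is the
ring atom adjacent to the attachment), 2-thienyl attaches at ring position 2
and 3-pyridyl at position 3, and the tautomer is fixed as the aromatic
triazine with exocyclic NH₂/NH. Assembled molecules are sanitized and
canonicalized by RDKit. Two structure-level oracles guard the assembly:
Hill-order molecular formulas and elemental mass percentages computed from
IUPAC standard atomic weights (≥ 4 significant figures — enough to reproduce
2-decimal combustion-analysis figures). All sixteen published C/H/N analyses
are reproduced within ±0.02 percentage points.

## Activity preparation

The viability filter (≤ 50% at 10 µM on MDA-MB231) selects 24 compounds; the
dose–response panel additionally contains compound 110 (viability 51%), which
the default configuration adds through an explicit `include_override` rather
than by loosening the rule. Censored GI50 bounds (">20", ">25") are kept as
flagged bounds and never imputed or modelled. One row of the published
prediction table is printed with the id 71 but carries the experimental
pGI50 of compound 81 (GI50 14.01 µM → 4.85), with 81 otherwise absent; the
packaged fixture stores both readings and the default mapping reads the row
as 81, flagged in an `id_remapped` column.

## Conformers, charges and alignment

One conformer per compound: `n_starts` (default 20) seeded ETKDG embeddings,
each minimized with MMFF94 (UFF for molecules outside MMFF's
parameterization), keeping the lowest-energy result. The pipeline is
deterministic for a fixed seed on one platform. Charges are
Gasteiger–Marsili by default (MMFF optional): fast, deterministic, and
adequate for relative electrostatic fields within a congeneric series.
Alignment is rigid-body least-squares (Kabsch, proper rotations only) of the
nine scaffold atoms onto those of the reference — by default compound 101,
the most potent member. Scaffold RMSDs after superposition are ≤ 0.05 Å
across the set, since the mapped substructure is rigid and aromatic.
Substituent torsions keep their minimized values; no conformational
averaging is attempted.

The original protocol aligned molecules with a commercial field-consensus
method (50% steric / 50% electrostatic weighting). That algorithm is not
public; for a series sharing nine rigid scaffold atoms, common-scaffold
superposition is the standard, well-posed alternative, and the 50/50
weighting is applied instead where it is unambiguous: in the descriptor
assembly.

## Fields and descriptors

Grid: the union bounding box of all aligned atoms, padded by 4 Å on every
face and snapped outward to a 2 Å lattice (classic CoMFA defaults; both
exposed in config). Point order is fixed: x fastest, then y, then z.

* Electrostatic: +1 e probe, distance-dependent dielectric ε(r) = r
  (dimensionless, r in Å — the standard RDIE convention), Coulomb constant
  332.06 kcal·Å/(mol·e²), i.e. E(p) = Σᵢ 332.06 qᵢ/r²ᵢₚ.
* Steric: 12-6 Lennard-Jones with a carbon probe of radius 1.5 Å and well
  depth 0.105 kcal/mol (sp³ carbon); per-element parameters are UFF-derived
  (half the homonuclear minimum distance, the corresponding well depth),
  combined by Lorentz–Berthelot rules.
* Distances are floored at 0.05 Å; both fields are clamped to ±30 kcal/mol,
  which makes the exact floor irrelevant.

Descriptor rows are [0.5·steric | 0.5·electrostatic]; columns with standard
deviation below 10⁻⁶ kcal/mol across compounds (constant, mostly far-field
or deep-core points) are dropped, with a retained (field, grid-point) index
for contour back-mapping. On the default run the 25 compounds give a
15×12×8 grid and a 25 × 2836 matrix after filtering.

## PLS model and statistics

PLS1 (NIPALS, via scikit-learn's `PLSRegression` with `scale=False`) on
column-centered X and centered y; the coefficient vector is recoverable so
that predict(X) = (X − x̄)·b + ȳ. At full rank PLS equals the minimum-norm
least-squares solution, which the tests verify against the pseudoinverse.

The published protocol does not state its component count. Leave-one-out q²
(explicit refit loop) is implemented for component selection, but on this
dataset q² is negative and monotonically worsening for k = 1…10 (−0.26 at
k = 1 down to −4.2), so q²-argmax selection degenerates to a 1-component
model (training r² = 0.26) that cannot correspond to the published training
statistics. The default is therefore a fixed five-component model — the
fixed-component convention of CoMFA-style protocols, and the cap this
package would have applied anyway — with q²-based selection available via
`n_components: 0`. Training r²/RMSE per k on the default run: 0.26/0.53,
0.67/0.36, 0.80/0.28, 0.84/0.25, 0.89/0.21 (k = 1…5).

r² is reported as the squared Pearson correlation between observed and
predicted response (with the explained-variance form 1 − SSres/SStot
reported alongside; they coincide on the training set of a centered linear
fit). RMSE is √mean((y − ŷ)²). Train, test and pooled statistics are
reported separately, since a pooled value is sensitive to the large test
residuals typical of small-series field models. The 19/6 split defaults to
the published explicit test membership; a seeded greedy-maximin
("diverse") split in descriptor space is provided for fresh datasets.

## Contour maps

Displayed values are STDEV×COEFF: the PLS coefficient of each retained
column times that column's standard deviation over the training compounds —
raw coefficients are scale-dominated by high-variance near-surface columns.
Favorable/unfavorable regions are the points above/below the 80th/20th
percentile of the nonzero values (the original iso-levels are not published;
percentiles are the scale-free replacement and are configurable). Dropped
columns carry value 0 and never enter a mask. Grids export to Gaussian cube
(lengths in Bohr, canonical z-fastest order, a placeholder atom for strict
readers) and OpenDX; round-trips are exact to 10⁻⁶.

## Synthetic data

The generator emulates the descriptor/response pair handed to PLS, not the
molecules: each "molecule" is a random linear mix of `n_latent` spatially
smoothed (3-point moving-average) unit-variance basis fields, scaled so
entries sit around ±6 kcal/mol and the ±30 clamp is a real but rare event,
and the response is y = Xw + ε with w supported on a BFS-grown contiguous
grid region and ε Gaussian. Defaults mirror the real problem's shape: 25
molecules, 5×5×5 grid, 10-point support, unit effect scale, noise 0.3.

The latent-factor construction reflects the dominant property of congeneric
field matrices — low intrinsic rank (a series explores few structural
directions) with strong short-range spatial correlation. It has two tested
consequences. With noise 0 and rank below the training size, held-out rows
lie in the training row space and an adequate-rank PLS fit reproduces them
exactly (residuals ≈ 10⁻¹⁴). Conversely, at the 25-molecule default the
planted 10-point support is *not* identifiable (any coefficient vector is
confined to a 15-dimensional row space), so support-recovery claims are
asserted in the identifiable 200-molecule regime — where top-10 STDEV×COEFF
points recover the support completely at noise 0.3, and recovery improves
monotonically as noise falls through 1.0 → 0.3 → 0.1 — while the
default-setting overlap is pinned only as a seeded regression constant.
What the synthetic tests do **not** show: anything about conformer quality,
charge models or alignment on real molecules; those stages have their own
geometric and analytic oracles.

## What the defaults do and do not reproduce

Charges, force field, grid placement and alignment are open-source stand-ins
for the original commercial tooling, so published model statistics are
treated as quality floors rather than equalities: the default run reaches
training r² 0.89 / RMSE 0.21 against the published 0.81 / 0.31. Direct
arithmetic on the published prediction table's 19 training pairs gives
r² = 0.8123, RMSE = 0.2817 (frozen as regression constants for the
statistics code), indicating the published RMSE was computed on unrounded
predictions or a different pooling.

## Known limitations

* Single-conformer, rigid-alignment treatment; no conformational ensembles,
  tautomer/protomer enumeration or docking-based poses.
* Gasteiger charges ignore conformation; MMFF charges are the only
  alternative wired in.
* Only steric and electrostatic fields; no hydrophobic or H-bond fields.
* Negative LOO q² on the real dataset means the model interpolates the
  training series far better than it predicts — consistent with the large
  published test residuals — so the maps should guide design hypotheses,
  not rank candidates.
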