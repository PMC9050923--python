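# triazqsar

A 3D-QSAR (CoMFA-style) pipeline for a combinatorial library of
6,*N*²-diaryl-1,3,5-triazine-2,4-diamines screened against the triple-negative
breast-cancer cell line MDA-MB231.

The package is aimed at computational medicinal chemists who want a fully
open, scriptable re-implementation of the classic field-based QSAR workflow
for this congeneric series:

1. **Library enumeration** — the 126 library members are defined by two
   substituent tokens (R¹ on the C6-aryl ring, R² on the *N*²-aryl ring) on a
   fixed 2-amino-4-(*N*-aryl-amino)-6-aryl-1,3,5-triazine scaffold. Structures
   are assembled and canonicalized with RDKit, and validated against
   combustion-analysis oracles (Hill formulas and C/H/N mass percentages).
2. **Activity preparation** — the 10 µM viability screen selects actives
   (viability ≤ 50%), and dose–response GI50 values (µM) become the response
   pGI50 = −log₁₀ GI50[M] = 6 − log₁₀ GI50[µM]. The modelling set has 25
   compounds with pGI50 from 4.82 (GI50 15.24 µM) to 7.22 (GI50 0.06 µM).
3. **Structure preparation** — one minimum-energy conformer per compound
   (multi-start ETKDG embedding + MMFF94 minimization), Gasteiger–Marsili
   partial charges, and rigid least-squares (Kabsch) superposition of the nine
   shared scaffold heavy atoms onto the most active compound.
4. **Molecular interaction fields** — on a common rectangular grid (2 Å
   spacing, 4 Å margin), a +1 *e* point probe with distance-dependent
   dielectric ε(r) = r gives the electrostatic field
   E(p) = Σᵢ 332.06 · qᵢ / r²ᵢₚ, and a carbon probe (R = 1.5 Å,
   ε = 0.105 kcal/mol) gives the steric 12-6 Lennard-Jones field
   E(p) = Σᵢ εᵢⱼ[(Rᵢⱼ/rᵢₚ)¹² − 2(Rᵢⱼ/rᵢₚ)⁶]. Both are truncated to
   ±30 kcal/mol and combined 50/50 into the descriptor matrix **X**.
5. **PLS model** — with the published 19-train / 6-test split
   (test = {58, 73, 78, 99, 101, 120}), a 5-component PLS1 regression of
   pGI50 on **X**; r² (squared Pearson correlation) and RMSE summarize the
   fit, and leave-one-out q² is available for component selection.
6. **Contour maps** — per-grid-point STDEV×COEFF products locate regions
   where added steric bulk or electron density favors (upper percentile) or
   disfavors (lower percentile) activity, exported as Gaussian cube / OpenDX
   grids.

A synthetic-data generator plants a known sparse field–activity relationship
in low-rank, spatially correlated pseudo-field descriptors so every modelling
stage is testable against ground truth.

## Worked example

```python
from triazqsar import RunConfig, run_pipeline
from triazqsar.pipeline import report_stats

result = run_pipeline(RunConfig())          # the default study configuration
print(report_stats(result.report))
```

prints (seed 2020):

```
{'n_components': 5,
 'r2_train': 0.8863008832955418,  'rmse_train': 0.20789451974895204,
 'r2_ss_train': 0.886300883295542,
 'r2_test': 0.7177375735710362,   'rmse_test': 0.7358363078958466,
 'r2_pooled': 0.7115385715638438, 'rmse_pooled': 0.4034805039948298}
```

Training r² = 0.89 and RMSE = 0.21 pGI50 units: the five-component field
model explains the training activities well (clearing the usual r² > 0.5,
RMSE < 0.5 quality rule), while the weaker test-set statistics show the
familiar optimism of small-series CoMFA models. Per-compound rows, e.g.

```
compound_id  experimental_pgi50  predicted_pgi50  residual   split
14           5.0357              5.0525           -0.0168    train
56           6.7696              6.7042            0.0654    train
```

are in `result.report.rows` (residual = experimental − predicted).

The same pipeline is available from a shell:

```bash
triazqsar --outdir out run            # everything + manifest.json
triazqsar --outdir out build-library  # ... or stage by stage
triazqsar --outdir out prepare-activities
triazqsar --outdir out align
triazqsar --outdir out fields
triazqsar --outdir out fit
triazqsar --outdir out contours
triazqsar show-config                 # all defaults as YAML
```

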