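# claysorb

Adsorption analysis for nucleotide–phyllosilicate systems.

Clay minerals expose two chemically distinct surfaces — large, mostly inert
basal (siloxane) faces and small lateral (edge) faces carrying pH-dependent
metal hydroxyls — and nucleotides in salt solutions adsorb preferentially on
the edges through their phosphate group.  Demonstrating that from bench data
requires a chain of quantitative steps that this package implements as a
reusable, tested pipeline for geochemists and surface scientists:

1. **Batch isotherms** (`claysorb.isotherm`) — Beer–Lambert calibration and
   mass balance, q = (C0 − Ceq)·V/m, turn raw supernatant measurements into
   quality-checked isotherms with replicate statistics.
2. **Normalization** (`claysorb.normalization`) — the concentration axis is
   reduced by the solute solubility (x = Ceq/S) and the uptake axis by a
   specific surface area (d = q/SSA, basis total/basal/edge).  A dimensionless
   collapse score (mean cross-curve coefficient of variation on a common log
   grid) quantifies when a family of curves superimposes — the signature of
   homologous molecules and of the surface that actually binds them.
3. **Langmuir models** (`claysorb.langmuir`) — classic
   q = q_max·K·C/(1 + K·C) and the solid/liquid modified form
   q = q_max·K_ML·C/(C_s − C + K_ML·C) with C_s fixed to the solubility, so
   K_ML is dimensionless and ΔG° = −RT·ln K_ML is convention-free.
4. **DIS** (`claysorb.dis`) — Derivative Isotherm Summation of low-pressure
   quasi-equilibrium argon adsorption: dV/d ln(P/P0) is decomposed into
   Bragg–Williams local-domain derivatives, yielding monolayer capacities,
   adsorption-energy positions, and the edge/basal surface proportions.
5. **MD post-processing** (`claysorb.md`) — minimum-image distances in
   periodic boxes, three-state adsorption classification (free / adsorbed
   non-parallel / adsorbed parallel, cutoff 4 Å inclusive), residence
   (duration-ratio) statistics, and the complexed-molecule charge that
   diagnoses cation bridging.
6. **Synthetic data** (`claysorb.synthetic`) — seeded generators for every
   input above with stored ground truth, used throughout the test suite.

A thin CLI (`claysorb simulate|process|normalize|fit|dis|md|pipeline`) wraps
the library for shell use; all file formats are plain text (CSV, JSON,
extended XYZ) and round-trip bit-identically.

## Worked example

Generate a synthetic batch experiment, process it, and fit the modified
Langmuir model:

```sh
claysorb simulate --kind isotherm --seed 7 --out-dir demo
claysorb process --batch demo/batch.csv --specs demo/specs.json --out demo/isotherm.csv
claysorb fit --isotherm demo/isotherm.csv --model modified --out demo/fit.json
```

prints

```
model=modified
q_max=0.00010236994705224505
k=None
k_ml=92.29105620429716
c_s=0.02
delta_g_kJ_per_mol=-11.216525639101542
residual_rms=2.7061463141254455e-06
n_points=20
```

The generator's truth for this scenario is q_max = 1e-4 mol/g and
K_ML = 100 at a solubility of 0.02 mol/L: from one 20-point isotherm with 2%
readout noise the fit recovers the monolayer capacity within ~2% and the
dimensionless affinity within ~8%, giving a standard free energy of
adsorption of −11.2 kJ/mol (truth −11.4 kJ/mol).  `residual_rms` is in mol/g
on the uptake axis.

The same objects are available as a library:

```python
from claysorb import fit_langmuir, to_density, collapse_score
from claysorb.io import read_isotherm_csv

iso = read_isotherm_csv("demo/isotherm.csv")
result = fit_langmuir(iso, model="modified", c_s=iso.nucleotide.solubility)
density = to_density(iso, "edge")          # mol/m^2 of lateral surface
```

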