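# lamindyn

Quantitative comparison of a wild-type protein domain with a disease
mutant, built around the lamin A/C immunoglobulin-like (Ig) fold domain
(residues 428–552) and its skeletal-muscle-dystrophy mutant W514R. The
package is aimed at structural biologists and biophysicists who have
per-residue NMR intensity tables, backbone chemical shift assignments,
DSC thermograms, or coordinate ensembles for two protein variants and want
the standard comparative statistics with honest error bars — plus
synthetic-data generators with known ground truth for every input kind, so
the whole chain is testable end to end.

## What it computes

**¹⁵N backbone relaxation.** Per-residue R1 and R2 from single-exponential
fits I(t) = I₀e^(−Rt) of peak-intensity decays, with Monte-Carlo errors
driven by the spectral RMS noise; the steady-state {¹H}-¹⁵N NOE as
I_sat/I_ref with propagated uncertainty; summaries as mean ± SD with R2/R1
averaged per residue.

**Rotational correlation time.** The rigid isotropic rotor model with
J(ω) = (2/5)τc/(1+(ωτc)²) and the standard dipolar + CSA rate expressions
(R_ex = 0) links τc to R2/R1. After the ±1-SD exclusion rules (ratio
outliers → local dynamics/exchange; low NOE → fast motion), the surviving
mean ratio is inverted to τc by a bracketed root search.

**Chemical shift perturbation.** Δδ_amide = √(Δδ_HN² + (Δδ_N/5)²) per
residue, signed Δδ_Cα differences with their Pearson r², threshold
classification (default 0.15 ppm), and mapping onto a PDB structure via the
B-factor column.

**Two-state DSC.** Excess heat capacity
Cp_exc = (ΔH_cal·ΔH_vH/RT²)·K/(1+K)², K = exp[−(ΔH_vH/R)(1/T − 1/Tm)];
calorimetric enthalpy by trapezoidal integration above an iteratively
determined linear baseline; Tm by parabolic peak refinement; full nonlinear
two-state fits with independent ΔH_cal and ΔH_vH.

**Ensemble statistics.** Kabsch superposition, per-frame RMSD, per-atom
RMSF about the refined ensemble mean, mass-weighted radius of gyration, Cα
PCA (essential dynamics) with variance fractions, and porcupine-style
two-model export of any principal mode.

## Worked example

```python
from lamindyn.diffusion import estimate_tauc, estimate_tauc_quadratic
from lamindyn.dsc import TwoStateModel, find_tm, integrate_enthalpy
from lamindyn.ensemble import pca
from lamindyn.synthetic import make_ensemble, make_thermogram, planted_mode_spec

# invert the wild-type mean R2/R1 ratio measured at 600.13 MHz
print(round(estimate_tauc(12.18), 2), "ns")            # 10.72 ns
print(round(estimate_tauc_quadratic(12.18), 2), "ns")  # 10.63 ns (closed-form check)

# two-state thermogram at the wild-type transition parameters
model = TwoStateModel(tm_K=61.9 + 273.15, dh_vh=110.1, dh_cal=110.1)
tg = make_thermogram(model, 16.0, 80.0, 0.05)
print(round(integrate_enthalpy(tg, baseline=0.0), 2))  # 110.08 kcal/mol
tg_fine = make_thermogram(model, 16.0, 80.0, 0.01)
print(round(find_tm(tg_fine, baseline=0.0), 2))        # 61.85 C (curve peak)

# ensemble with one dominant collective mode
spec = planted_mode_spec(n_atoms=50, n_frames=1000, seed=1)
result = pca(make_ensemble(spec))
print(round(100 * result.variance_fractions[0], 1), "%")  # 75.4 %
```

The τc of ~10.7 ns says the domain tumbles more slowly than a 12 kDa
monomer should, consistent with a monomer–oligomer mixture; the thermogram
integral returning its generating enthalpy and the peak sitting within a
tenth of a degree of the 61.9 °C midpoint confirm the two-state machinery
is self-consistent (the small peak–midpoint offset is the 1/T² skew of the
excess heat capacity, see `docs/methods.md`); and the first principal
component carrying ~75% of the Cα variance reproduces the planted
dominant-mode fraction.

There is also a CLI for the full workflow:

```bash
lamindyn simulate --out data --seed 1          # synthetic wild-type + mutant inputs
lamindyn compare --wildtype-dir data/wildtype --mutant-dir data/mutant --out reports
lamindyn dsc data/wildtype/dsc.tsv --out fit.csv
```

`compare` writes per-stage CSVs, an annotated summary table (NOE, R2/R1,
τc, Tm, ΔH, Rg, PC1 fraction per arm) and a reproducibility log; it exits
nonzero when stages had to be skipped for missing inputs.

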