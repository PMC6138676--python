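# Methods

`lamindyn` implements the quantitative analysis chain used to compare a
wild-type protein domain with a point mutant — here the lamin A/C Ig-fold
domain (residues 428–552) and its muscular-dystrophy mutant W514R — from
four kinds of input: ¹⁵N relaxation decay intensities, backbone chemical
shift tables, DSC thermograms, and coordinate ensembles. This note records
the models, their assumptions, the defaults that matter, and the numerical
choices, in enough detail to audit every number the package produces.

## ¹⁵N relaxation rates (`lamindyn.relaxation`)

Per-residue longitudinal (R1) and transverse (R2) rates come from
least-squares fits of peak intensities to a single exponential
I(t) = I₀·exp(−R·t). The model has two parameters; no offset term is
included by default because integrated cross-peak intensities decay to the
noise floor, not to a plateau (an offset is available behind
`with_offset=True` for pathological baselines). Initial guesses come from a
log-linear regression on the positive intensities; if no intensity is
positive, a logarithmic grid of rates spanning the delay range seeds the
fit instead. A fit that does not converge, or converges to a non-positive
rate, marks the component absent for that residue and is logged — it never
aborts the pipeline.

Rate uncertainties use Monte-Carlo resampling rather than the
covariance matrix: Gaussian noise with the spectral RMS amplitude is added
to the best-fit curve, the synthetic series is refit, and the SD over draws
(default 500, minimum 100) is the error bar. For the short series typical of
relaxation experiments (6–8 delays) this is more honest than the local
quadratic approximation, and it matches how spectral-noise-driven errors
are normally propagated in this field. The steady-state heteronuclear NOE
is the ratio of saturated to reference intensities with first-order error
propagation using one shared noise RMS for the spectrum pair.

Summary statistics (means ± sample SD, n−1) are taken over residues where
the component is defined; R2/R1 is averaged as a **mean of per-residue
ratios**, never the ratio of mean rates — the two differ whenever rates
covary across residues. With a single contributing residue the SD is
reported as 0 with the count making the degeneracy visible.

## Rotational correlation time (`lamindyn.diffusion`)

The rigid isotropic rotor model connects τc to the rates through
J(ω) = (2/5)·τc/(1+(ωτc)²) and the standard dipolar + CSA expressions
(Rex = 0). Defaults: ν_H = 600.13 MHz, r_NH = 1.02 Å, Δσ = −160 ppm,
γ_H = 2.67522×10⁸, γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹ — the community values
used by the standard R2/R1 ratio-analysis tools; all overridable via
`SpinParameters` / the run config. R2/R1 is verified to be strictly
increasing on the search bracket ([0.1, 100] ns by default) before a
bracketed root search (Brent, relative tolerance 1e−9) inverts the mean
ratio to a single global τc. The closed-form high-field approximation
τc ≈ √(6·ratio − 7)/(4π·ν_N) serves as an independent cross-check (it
agrees with the full inversion within 5% over 5–20 ns at 14.1 T).

Before inversion, residues dominated by internal motion or exchange are
removed by the standard ±1-SD rules: R2/R1 more than one sample SD above
(`ratio_high`, exchange) or below (`ratio_low`, fast motion) the mean, or
NOE more than one SD below the mean NOE (`low_noe`). Both rules are applied
independently on the full-input statistics, strict inequalities, ties kept;
records lacking both rates are tagged `missing`. Exchange is never fitted
(no Rex term, no Lipari–Szabo model-free analysis, no anisotropic tensors);
high ratios are interpreted qualitatively through the exclusion tags.

## Chemical shift perturbation (`lamindyn.csp`)

The combined amide perturbation is Δδ_amide = √(Δδ_HN² + (Δδ_N/5)²); the
1/5 nitrogen scaling is part of the statistic's definition and deliberately
not configurable. Cα differences are reported signed (variant A − variant
B) together with the Pearson r² of the two Cα shift sets, which stays near
1 when secondary structure is unchanged. Classification flags residues with
Δδ_amide strictly above the threshold (default 0.15 ppm). Missing
assignments propagate as absent values — zero-filling would fabricate
"unperturbed" signal exactly at exchange-broadened residues, which are the
interesting ones in an aggregating mutant. Structure mapping writes the
per-residue value into the B-factor field of every atom of the residue
(fixed-width %6.2f), sentinel −1.00 for residues without a value; residues
are matched by number with name mismatches warned, not fatal.

## Two-state DSC analysis (`lamindyn.dsc`)

A reversible folded↔unfolded equilibrium with van't Hoff enthalpy ΔH_vH and
midpoint Tm gives K(T) = exp[−(ΔH_vH/R)(1/T − 1/Tm)] and the excess molar
heat capacity Cp_exc = (ΔH_cal·ΔH_vH/(RT²))·K/(1+K)², evaluated through
1/(4 cosh²(ln K/2)) for overflow safety. The defining conservation law
∫Cp_exc dT = ΔH_cal holds for any parameters and is enforced by a
quadrature property test. ΔH_cal and ΔH_vH are independent fit parameters:
their ratio is the standard two-state diagnostic, and ΔH_vH ≠ ΔH_cal (e.g.
unfolding coupled to oligomer dissociation) must remain expressible. R =
1.9872×10⁻³ kcal mol⁻¹ K⁻¹; kelvin internally, Celsius at every interface.

**Peak vs midpoint.** The maximum of Cp_exc does *not* sit at Tm: the 1/T²
prefactor shifts it below by approximately 4Tm³R²/ΔH_vH² (stationarity
condition tanh(x/2) = −2TR/ΔH_vH). The shift is negligible for sharp
transitions (0.05 °C at Tm = 335 K, ΔH_vH = 110 kcal/mol) but reaches
0.26 °C for a broad one (ΔH_vH = 45.6 kcal/mol) — `find_tm`, which locates
the grid maximum of baseline-subtracted Cp and refines it by parabolic
interpolation through the three surrounding points, therefore reads
slightly below the thermodynamic midpoint by construction. The property
suite pins this skew to its closed form. For real data the midpoint
estimator of choice is the full nonlinear fit (`fit_twostate`), which
recovers Tm exactly on noiseless synthetic curves.

The automatic baseline is a single line fit to pre- and post-transition
data. Because two-state tails decay only exponentially (scale RTm²/ΔH_vH,
i.e. several kelvin for a broad transition), a naive outer-15%-flank fit
absorbs part of the tail and can clip ~5% of the area. The fit therefore
iterates: fit the flanks, find the contiguous region where the excess
exceeds 0.1% of the peak, refit the line outside that region (keeping at
least ~2% of points per flank), three passes. On noiseless synthetic curves
with a known linear baseline this recovers ΔH_cal within 1%. `fit_twostate`
is initialised from `find_tm` and the integral, bounded, with up to three
perturbed restarts; persistent failure returns the initial estimates
flagged unconverged. A transition peaking within 3 points of a scan edge is
flagged truncated. Scan rate and concentration are carried as metadata only
(equilibrium assumption).

## Ensemble statistics (`lamindyn.ensemble`)

Kabsch superposition (SVD of the weighted 3×3 covariance, determinant sign
correction for a proper rotation) underlies everything; degenerate
configurations (collinear/coincident, second singular value ~0) are
rejected because the optimal rotation is not unique there. RMSD is computed
per frame against an explicit reference; RMSF and PCA superpose onto the
ensemble mean with one refinement iteration (fit → recompute mean → fit),
a deterministic reference that privileges no frame. All statistics are
invariant under a global rigid motion of every frame.

PCA diagonalises the 3N×3N covariance of the selected atoms (Cα by
default — mass weighting is immaterial for a single atom type and off by
default; Rg uses standard atomic masses inferred from the atom name's first
letter, unit masses when unknown). Eigenvalues are sorted descending with
negative round-off clipped at zero; variance fractions are eigenvalues over
their sum. Porcupine export writes the mean structure and the mean
displaced by scale·√λ along a chosen eigenvector as a two-model ensemble so
any viewer can draw per-atom arrows. Coordinates are nanometres everywhere;
PDB I/O converts from/to Ångström at the boundary.

Because rigid-body fitting precedes the covariance, ~6 of the 3N degrees of
freedom are absorbed: isotropic jitter of SD σ per coordinate yields
RMSF → σ√(3(1−2/N)) rather than σ√3, and a planted collective mode must be
drawn orthogonal to the rigid-body subspace of the reference (translations
plus infinitesimal rotations, see `rigid_body_basis`) or the fit strips the
~6/3N of its variance that leaks into that subspace. The generator does
exactly that.

## Synthetic data (`lamindyn.synthetic`)

The generators emulate the study conditions so every stage can be tested
against known ground truth:

- **Relaxation**: residues 428–552 (the cloned domain), rigid core at the
  typical wild-type means (R1 1.682 s⁻¹, R2 20.09 s⁻¹, NOE 0.793) with 5%
  smooth per-residue variation; the flexible stretches 444–448 and 471–479
  get R2×0.55, NOE−0.35, R1×1.15 — a standard fast-loop signature. The
  per-residue true profile is a plausible modelling choice, not a
  reconstruction of any measured profile. Default delay schedules: R1
  5–1200 ms (8 points), R2 8.5–101.8 ms (8 points). Mutant-like behaviour
  is emulated through the `missing` set (defaults to the exchange-broadened
  stretches 486–488, 500–503, 513–520 in the CLI simulator) — missing
  residues produce no data rather than zeros.
- **Shifts**: variant A uniform in the typical backbone ranges (HN 7.5–9.5,
  N 105–130, Cα 40–65 ppm); variant B adds iid Gaussian baseline noise
  everywhere plus an amide-¹H offset inside the perturbed cluster, so the
  cluster perturbs the tertiary-fold reporter but not the Cα one.
- **DSC**: Cp = linear baseline + Cp_exc + Gaussian noise on a Celsius grid
  (default 16–80 °C, matching the experimental scan window).
- **Ensembles**: frames = reference + Σ aₘ·modeₘ + jitter with
  aₘ ~ N(0, varₘ), modes orthonormal (tolerance 1e−8) and rigid-body-free.
  `planted_mode_spec` sets the mode variance to 3× the summed jitter
  variance, giving an expected PC1 fraction of (9n+1)/(12n) ≈ 75% for n
  atoms — the dominant-mode regime reported for this domain's essential
  dynamics.

All randomness flows through one integer seed per call via
`numpy.random.default_rng`; fixed seeds give bit-identical outputs. What
the generators do **not** emulate: spectral line shapes and peak overlap,
scan-rate kinetics, force-field physics, or anisotropic tumbling — passing
tests demonstrate correctness of the analysis chain, not fidelity of these
physical processes.

## Problem sizes and defaults

The test suite and the acceptance script run at desk scale by design: DSC
grids of 0.05 °C (integration) and 0.01 °C (peak location) over 16–80 °C,
ensembles of 1000–3000 frames × 40–60 atoms, 125-residue relaxation sets
with 150–500 Monte-Carlo draws, and 1000-replica refit oracles. These sizes
keep every statistical tolerance (2–5%) comfortably above sampling noise.

## Known limitations

- Isotropic tumbling only; no diffusion-tensor or model-free analysis.
- Single-chain residue matching by number; insertion codes unsupported.
- The DSC baseline is a single line; curved (ΔCp ≠ 0) baselines and
  multi-transition deconvolution are out of scope.
- `find_tm` reads the curve maximum, which for broad transitions sits a
  few tenths of a degree below the thermodynamic midpoint (see above).
- Only multi-model PDB is read for ensembles; no binary trajectory formats.
- Wild type and mutant measured at different temperatures in the emulated
  experiments; no temperature/viscosity correction is applied to either.
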