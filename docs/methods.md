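# Methods

## Scope

`lipidkit` implements desk-scale analysis of sum-composition LC-MS
lipidomics for longitudinal case/control studies with donor-line structure:
candidate database construction, accurate-mass annotation, internal-standard
semi-quantification, trajectory summaries, per-lipid mixed-model testing,
and seeded synthetic-data generation with ground truth. It does not perform
raw spectral processing (peak picking, alignment, deconvolution); its input
is a picked feature table.

## Masses and formulas

Elemental formulas are immutable element->count maps supporting addition,
subtraction and non-negative integer scaling; deuterium is tracked as its
own symbol `D` so labelled standards keep their mass shift. Monoisotopic
isotope masses (most abundant isotope, CODATA/IUPAC rounded to 1e-6 Da) are
stored as **integer micro-Dalton**, so mass additivity commutes exactly with
formula addition — IEEE floats alone would break the "mass(a+b) =
mass(a)+mass(b)" invariant in the last ulp. The float API divides by 1e6 at
the boundary. The electron mass (0.000549 Da) enters the adduct m/z rule

```
m/z = (n_M * M + sign * mass(delta) - z * m_e) / |z|
```

## Class model and expansion

A lipid class is a generic base formula anchored at zero radyl carbons plus
enumeration ranges. A concrete species `CLASS(C:db)` is
`base + C*CH2 - db*H2`. The default double-bond constraint caps `db` at
`C // 2`. The 29 shipped classes (TSV, user-editable) cover
glycerophospholipids (incl. ether `[O]` and plasmalogen `[P]` subclasses),
lysophospholipids, sphingolipids, sulfatides, gangliosides, neutral storage
lipids, cholesteryl esters, cardiolipin and free fatty acids, with per-class
adduct lists and an assigned internal standard.

Shipped PE and LPE annotate in negative mode only: in positive mode
`PE(C+3:db) [M+H]+` is an exact isobar of `PC(C:db) [M+H]+`, so mass-only
positive-mode PE annotation is undecidable. Other exact isobars remain:
an ether class at `(C:db)` shares the formula of its lyso counterpart, a
plasmalogen is the ether at `db+1`, and `PS(C:db) [M-H]-` equals
`PC(C-3:db+1) [M+HCOO]-` atom for atom. These are separable only by
retention time; the matcher therefore accepts optional per-class RT windows.

## Annotation

The candidate database holds one entry per (species, adduct), sorted by m/z
within each polarity; tolerance queries are binary searches. A feature is
assigned the in-tolerance candidate with minimal |ppm error| (default
5 ppm); exact ties break lexicographically on (class, adduct) for
determinism, and the number of in-tolerance candidates is reported as
`ambiguity_count`. With RT windows, candidates of classes whose window
excludes the feature's RT are rejected first.

## Semi-quantification

`A.U. = analyte_area / IS_area x IS_nmol` per sample against the class's
internal standard (16-component mix shipped as TSV with compositions and
spiked amounts). The estimate is invariant to per-sample detector drift that
scales analyte and standard alike. Classes whose standard is not annotated
among the features are dropped with a warning; a zero standard area yields
NaN for that sample. Replicates collapse to line medians per
(line, region, timepoint).

## Trajectory summaries

- **Class Z-scores**: species are summed per class; each class row is
  Z-scored across all samples (sample SD, n-1); constant rows are zeroed and
  flagged.
- **Chain-property fold change**: per-species log2 FC between two sample
  groups (means of line medians), binned by total carbons or double bonds
  within each chain count, smoothed by LOESS.
- **LOESS**: own implementation — for each evaluation point the
  `k = floor(span*n)` nearest inputs are tricube-weighted by distance scaled
  to the neighborhood radius, and a weighted polynomial (default degree 2,
  span 0.75) is fitted on centered x via least squares. Deterministic, no
  robustness iterations. At degree 1 it matches `statsmodels` `lowess`
  (`it=0`) to ~1e-14; `statsmodels` is kept as the independent reference
  oracle, not a dependency of the estimator.
- **PCA**: species-wise half-minimum replacement of zeros, log transform,
  species-centering, full SVD (scikit-learn).

## Differential testing

Per lipid: `log(y) ~ genotype` (per-timepoint mode) or
`log(y) ~ genotype + C(timepoint)` (overall mode) with a random intercept
per donor line, REML via `statsmodels MixedLM`. Zeros/NaN are replaced by
half the smallest positive value of the lipid before the log; all-constant
lipids (e.g. internal standards) are skipped. On a singular or
non-convergent mixed fit the model falls back to OLS and the row is flagged
`ols_fallback`. BH-FDR is applied within each contrast across species.

**Inference choice (deviation from "Wald z").** The genotype contrast is
estimated *between donor lines*; with a dozen lines the asymptotic normal
reference is anti-conservative (measured ~6.6-9% null rejection at
alpha = 0.05). The Wald statistic is therefore referred to a t distribution
with containment degrees of freedom `n_lines - 2`. Measured calibration:
5.2% null rejection over 500 simulated null lipids (9 vs 3 lines, 3
replicates), unbiased effect recovery (mean estimate 1.00 for a true effect
of 1.0 over 200 replicates). The API presents this module statsmodels-style:
`LipidMixedModel(table).fit() -> LipidDifferentialResults` with `summary()`,
`significant()`, `volcano_table()` and `bubble_table()`.

## Synthetic data

`simulate_study` draws
`log y = ln2*(baseline + trajectory(class, t) + effect_log2(C) * 1[case]) +
line_intercept + eps` with `eps ~ N(0, sigma_e^2)` and
`line_intercept ~ N(0, sigma_line^2)`, exponentiated to A.U. The genotype
effect is the VLCFA signature: `vlcfa_effect * max(0, C - C0(n_chains))`
log2 per carbon, with thresholds C26/C46/C62 for 1/2/3 chains. Defaults
mirror a 3-control / 9-case, 3-replicate, 4-timepoint design with
`sigma_line = 0.2`, `sigma_e = 0.3`, `vlcfa_effect = 0.1`.

`simulate_feature_spectra` converts abundances into a raw-like feature
table: one feature per species at its primary adduct, observed
`m/z = theoretical x (1 + N(0, ppm_sigma*1e-6))`, internal-standard features
carrying a per-sample lognormal detector drift **shared** with the analytes,
so quantification inverts the generator exactly; optional decoy features are
uniform in m/z but kept >= 15 ppm from every candidate; optional per-class
RT centers with Gaussian jitter. One seeded `numpy` generator drives every
draw, so (seed, params) reproduce tables bit for bit.

Known limitation: the generator emits one feature per species (no adduct
multiplicity, no isotopologue peaks), lognormal noise only, and drift that
is perfectly shared between analyte and standard — the idealization that
makes quantification exactly invertible.

### A note on the chain-length flatness check

In a between-line contrast the donor intercepts do not cancel: their group
mean difference is a global log2 offset with SD
`sigma_line*sqrt(1/9 + 1/3)/ln2 ~= 0.19` per simulated study, which alone
exceeds a +/-0.1 flatness band below C0. The signature is defined in
expectation, so the acceptance check averages LOESS curves over 25
replicate studies (measured: max |FC| below C0 = 0.05-0.09, slopes
0.097-0.100 vs true 0.1). Curve negation under contrast swap is algebraic
and is asserted exactly per single study.

## Pipeline and determinism

`run_pipeline(PipelineConfig)` executes build-db -> annotate -> normalize ->
trajectory -> stats, writing TSV artifacts plus `manifest.json` (tool,
version, seed, config hash, per-stage counters; no timestamps). Unknown
config keys are rejected at load; every stage failure is re-raised tagged
with its stage name. All stages are deterministic for fixed inputs, so
reruns are bit-identical — verified by the acceptance suite. CLI exit codes:
0 success, 2 invalid configuration, 3 stage failure, 4 missing input.

The pipeline's default annotation is mass-only (no RT gate), since real RT
windows are instrument-specific; the library-level matcher accepts windows
and the synthetic round-trip demonstrates their effect on exact isobars.

## Default parameters

| Parameter | Default | Where |
| --- | --- | --- |
| mass tolerance | 5 ppm | annotation, pipeline |
| LOESS span / degree | 0.75 / 2 | trajectory, pipeline |
| LMM mode / level | per-timepoint / replicate | pipeline |
| FDR threshold | 0.05 | pipeline |
| ppm noise (simulator) | 2 ppm | synthetic spectra |
| decoy avoidance | 15 ppm | synthetic spectra |
| RT centers / windows | 1.0 min spacing / +/-0.45 min | tests, acceptance |
| sigma_line / sigma_e | 0.2 / 0.3 (natural log) | simulator |
| vlcfa_effect | 0.1 log2 per carbon above C0 | simulator |
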