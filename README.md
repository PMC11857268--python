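# matlm — matrix linear models for annotation-aware metabolomics

`matlm` fits bilinear **matrix linear models** (MLMs)

```
Y = X B Zᵀ + E,          E rows i.i.d., mean 0, Var(vec(E)) = Σ ⊗ I
```

where `Y` (n samples × m metabolites) is an abundance matrix, `X` (n × p)
encodes sample characteristics (treatment, sex, age, …), `Z` (m × q)
encodes metabolite characteristics (lipid class, binned triglyceride
carbon count or double-bond count, pathway, co-expression module), and
`B` (p × q) holds the interaction coefficients: how each sample covariate
relates to each metabolite category.

The conventional workflow answers "which metabolite *characteristics* are
associated with which sample characteristics?" in two steps — per-metabolite
regressions followed by overrepresentation analysis (ORA) — which ignores
metabolite–metabolite correlation and cannot handle quantitative
annotations. The MLM answers it in a single model with closed-form least
squares

```
B̂ = (XᵀX)⁻¹ Xᵀ Y Z (ZᵀZ)⁻¹
Var(vec(B̂ᵀ)) = (XᵀX)⁻¹ ⊗ (ZᵀZ)⁻¹ ZᵀΣ̂Z (ZᵀZ)⁻¹,   Σ̂ = RᵀR/(n−p)
```

giving per-coefficient t statistics, confidence intervals and FDR
q-values, and — crucially — *adjusted* models in which correlated
annotations (e.g. triglyceride chain length and degree of unsaturation)
are estimated controlling for each other.

The library covers the full workflow: CSV I/O for the three tabular
inputs, preprocessing (half-minimum/KNN imputation, probabilistic
quotient normalization, log transform), X/Z design construction with
cell-means and reference codings, Wald and permutation inference,
standard and adaptive (lowest-slope) Benjamini–Hochberg FDR, cross-study
coefficient contrasts, the two-step univariate+ORA comparator, Pearson
chi-square utilities, and a synthetic-data generator with diagonal,
compound-symmetric and AR(1) residual covariance families. A `matlm`
command-line interface wires these into reproducible runs (every output
gets a machine-readable manifest).

## Worked example: disentangling carbon count from double bonds

Triglyceride chain length (total carbons) and unsaturation (double
bonds) are correlated across lipid species, so a real effect on
polyunsaturated species masquerades as a chain-length effect when chain
length is analyzed alone. The bundled generator reproduces exactly this
situation: 98 samples × 770 triglycerides, annotation pairs drawn from a
copula with rank correlation 0.7, and a true fish-oil effect of
(0, 0.5, 0.8) on the three double-bond bins only:

```
matlm simulate --out demo --preset triglyceride --seed 1
matlm fit --config examples/tilapia_style.toml \
    --y demo/abundance.csv --samples demo/samples.csv \
    --annotations demo/annotations.csv --out demo/fit_carbon_only.csv
matlm fit --config examples/sams_style.toml \
    --y demo/abundance.csv --samples demo/samples.csv \
    --annotations demo/annotations.csv --out demo/fit_adjusted.csv
```

The **unadjusted carbon-only** model (`fish_oil:yes` row) shows a strong,
entirely spurious carbon gradient:

```
              z_label  effect    se        p        q
 total_carbon:[40,45)  0.0449 0.123    0.715    0.255
 total_carbon:[50,55)   0.298 0.121   0.0137  0.00573
 total_carbon:[60,65)   0.503 0.126 6.91e-05 3.79e-05
total_carbon:[70,inf)   0.615 0.125 9.49e-07 5.93e-07
```

The **adjusted** model (double-bond cell-means block plus carbon bins
reference-coded against `[40,45)`) attributes the signal to unsaturation
and shrinks the carbon effects toward zero:

```
              z_label  effect     se        p        q
   double_bonds:[3,6)  -0.134  0.123    0.275    0.275
   double_bonds:[6,9)   0.345  0.124  0.00527   0.0119
 double_bonds:[9,inf)    0.64  0.125 2.79e-07 1.25e-06
 total_carbon:[50,55)  0.0596 0.0251   0.0177   0.0265
 total_carbon:[60,65)  0.0835 0.0246 0.000674  0.00202
total_carbon:[70,inf)  0.0407 0.0219   0.0633   0.0814
```

The double-bond estimates bracket the true (0, 0.5, 0.8) up to a common
shift from the shared residual factor; the carbon effects — truly zero
after adjustment — drop by an order of magnitude. Averaged over 100
replicates the adjusted carbon 95% CIs cover zero at their nominal rate
(~94%) while the unadjusted model flags at least one spurious carbon
category in every replicate (`matlm.confounding_experiment`).

Other entry points: `matlm permtest` (permutation p-values),
`matlm contrast` (differences/averages of coefficients shared by two
cohorts; see `examples/two_cohort_style.toml`), `matlm enrich` (the
two-step ORA comparator) and `matlm chi2`.

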