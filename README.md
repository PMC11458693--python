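# scftir — single-cell infrared phenomics and drug-combination analysis

`scftir` is a Python toolkit for quantifying cell-to-cell heterogeneity from
single-cell mid-infrared (FTIR) microspectroscopy and for classifying
drug-combination effects from viability/inhibition assays. It is aimed at
vibrational-spectroscopy and pharmacology groups who collect cohorts of
single-cell absorbance spectra (4,000–650 cm⁻¹) under different drug
treatments and want a reproducible, scriptable version of the standard
analysis chain.

## What it computes

**Spectral pipeline.** Raw single-cell absorbance spectra A(ν̃) are processed
by 9-point smoothing, linear automatic baseline correction, EMSC-based Mie
scattering correction, and Savitzky–Golay second differentiation
(d²A/dν̃²). Absorption bands appear as sharp minima in the second
derivative; the pipeline detects a consensus set of 14 minima on the
cohort-mean second derivative — 4 in the fatty-acid region (3,000–2,800 and
1,480–1,300 cm⁻¹), 7 in the protein region (1,800–1,480 cm⁻¹), 3 in the
carbohydrate/nucleic-acid region (1,300–900 cm⁻¹) — and extracts one value
per cell per peak, giving a k × 14 **spectral absorption matrix**.

**Heterogeneity.** For cells *p*, *q* with n-dimensional feature vectors,
the cell-to-cell Euclidean distance

    D_Eu(p, q) = sqrt( Σᵢ (pᵢ − qᵢ)² )

is computed for all k² ordered pairs (heatmap) and all C(k,2) = k(k−1)/2
unique pairs (histogram, summary indices), on the full 14-dimensional matrix
and on its 4/7/3-dimensional subregional views. Larger distances mean lower
cell-to-cell similarity. Mean-centered PCA of the second-derivative spectra
(full range or per region) gives score plots in which treatment groups may
cluster or disperse.

**Drug combinations.** From single-agent responses Pa, Pb and the combined
response P(a+b), three null models classify one dose pair:

| model | statistic | synergy when |
|---|---|---|
| additivity (CDI) | CDI = P(a+b)/(Pa·Pb) | CDI < 1 |
| statistical independence (Bliss) | P(a+b) − [1 − (1−Pa)(1−Pb)] | observed > expected |
| pharmacological independence (HSA) | P(a+b) − max(Pa, Pb) | observed > expected |

plus a 2-of-3 majority consensus, mass↔molar dose conversion, and
four-parameter-logistic (4PL) IC50 fitting. A built-in synthetic cohort
generator (Gaussian bands, log-normal per-cell variability, van de Hulst
Mie baselines, additive noise) makes the whole chain testable end to end.

## Worked example

Classify the interaction of two drugs from inhibition fractions
(Pa = Pb = 0.60, combined 0.88):

```bash
$ scftir interaction --pa 0.6 --pb 0.6 --pab 0.88 --kind inhibition
additivity_cdi                 statistic=2.4444 expected=1.0000 call=antagonism
statistical_independence       statistic=0.0400 expected=0.8400 call=synergy
pharmacological_independence   statistic=0.2800 expected=0.6000 call=synergy
consensus (2-of-3 majority): synergy
```

The Bliss expectation 1 − (1−0.6)(1−0.6) = 0.84 is exceeded by the observed
0.88 (excess +0.04 → synergy); the combination also beats the better single
agent by 0.28 (HSA synergy); the CDI on these fractions is above 1
(antagonism), and the majority consensus is synergy.

Run the full spectral pipeline on a simulated two-group cohort:

```bash
$ scftir run --out-dir demo_run --n-cells 10 --groups untreated,resveratrol --seed 7
```

This writes the cohort, processed spectra, the detected peak table
(14 positions, e.g. 2956/2922/2876/2850 cm⁻¹ in the fatty-acid region), the
20 × 14 feature matrix, four distance matrices with histograms, and four PCA
score tables. The heterogeneity summary (`heterogeneity.json`) reports, per
region scope, the mean/median/IQR of the 190 unique pair distances:

```
full_14        mean 0.204  median 0.196  iqr 0.069
fatty_acid_4   mean 0.104  median 0.099  iqr 0.054
protein_7      mean 0.141  median 0.129  iqr 0.067
carbohydrate_3 mean 0.089  median 0.085  iqr 0.048
```

i.e. in this cohort most cell-to-cell dissimilarity lies in the protein
bands, and the subregional squared distances sum exactly to the full-matrix
squared distances. Reruns with the same seed reproduce every output
bitwise.

The same stages are available as library calls (`simulate_cohort`,
`preprocess_cohort`, `detect_peaks`, `build_feature_matrix`,
`distance_matrix`, `pca_spectra`, `cdi_additivity`, `fit_ic50_4pl`, …) and
as scikit-learn transformers/estimators (`MovingAverageSmoother`,
`EMSCMieCorrector`, `SavitzkyGolaySecondDerivative`,
`FourParamLogisticIC50`) that compose with sklearn pipelines.

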