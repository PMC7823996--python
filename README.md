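# metabodyn

Time-course metabolomics of CD8+ T cell activation, as a tested, reusable
pipeline. When naïve T cells are activated they rewire their metabolism over
roughly four days; profiling that transition with flow-injection (FIA) and
LC-QTOF mass spectrometry every 12 h for 96 h produces thousands of m/z
features per method whose processing — from raw peak lists to pathway-level
statements — involves a long chain of small, easy-to-get-wrong steps. This
package implements that chain end to end and ships a synthetic-study
generator with embedded ground truth, so every stage can be validated without
any raw data download. It is written for computational metabolomics
researchers and immunometabolism groups who want the analysis logic as an
importable, tested library.

## What it computes

**FIA MS1 feature extraction** (`metabodyn.fia`). Tune-mix reference ions
drive a quadratic recalibration of the mass axis — the drift polynomial
d(m) = c₀ + c₁m + c₂m² is fit to (observed − reference) and inverted so
corrected masses are exact to < 1e−9 Da on polynomial drift — and an
intensity normalization (all intensities / Σ reference-ion intensities). Per
sample the 1000 most intense peaks are detected, combined across samples into
a consensus feature list by single-linkage m/z clustering (default 5 ppm),
and gaps are filled from the raw spectra at the consensus m/z. Isotopologue
chains spaced Δ = 1.00335 Da (one ¹³C substitution) with carbon-plausible
intensity ratios — I(M+1)/I(M) ≤ 1.5·0.0107·(m/12) — are collapsed onto the
monoisotopic feature, conserving summed intensity. Features are annotated by
exact mass against a compound database as [M+H]⁺ / [M−H]⁻ ions (proton mass
1.007276 Da, default tolerance 3 mDa).

**Normalization and blank filtering** (`metabodyn.preprocess`). Quantile
normalization maps every sample onto the across-sample mean of order
statistics (ties receive the mean of the quantile values they span),
compensating for cell growth. A feature is *above blank* if, at ≥ 1 time
point, a one-tailed equal-variance two-sample t-test finds its normalized
intensity greater than the sterile-well blank at p < 0.05.

**Time-trend statistics** (`metabodyn.timecourse`). Per feature, a Gaussian
likelihood ratio test compares intensity ~ natural-cubic-spline(time, df = 5)
against an intercept-only null; the statistic is 2ΔlogL = n·log(RSS₀/RSS₁),
with finite-sample-exact p-values from the equivalent F(df, n − df − 1)
statistic and a Bonferroni threshold α/n_features. PCA runs on square-root
scaled intensities; PLS1 (NIPALS, deterministic) regresses sampling time on
log intensities, and features are ranked by Σ|loading| over components —
a measure of how much each feature contributes to time-dependent change.

**Pathway enrichment** (`metabodyn.enrichment`). Feature importances
propagate to every exact-mass annotation candidate (a compound hit by several
features keeps the maximum); pathways are scored by the weighted
Kolmogorov–Smirnov running-sum enrichment score (weight 1) with a
member-label permutation null, p = (b + 1)/(n_perm + 1), and
NES = ES / mean(|null ES| of the same sign).

**Lipid analytics** (`metabodyn.lipids`). A parser for shorthand lipid names
(`PC 36:4`, chain-resolved `PC 16:0_20:4`), class × time intensity totals,
phosphatidylcholine saturation profiles over double-bond bins
{0, 1–2, 3, ≥4}, and filtering of chain-resolved species by constituent
fatty acid (e.g. FA 20:4, observable via [M+HCOO]⁻ formate adducts at
M + 44.998204 Da in negative mode).

**Synthetic studies** (`metabodyn.synthetic`). The generator emulates the
study design — 9 time points (0–96 h every 12 h), 3 biological replicates, a
3-replicate sterile blank — and plants monotone (logistic) and transient
(Gaussian bump) trends, ¹³C isotope chains, quadratic mass drift,
multiplicative log-normal noise, an annotation database with formula-derived
masses, a planted-enriched pathway, and a lipid table whose polyunsaturated
PC fraction falls 0.6 → 0.25 over 48 h.

## Worked example

```sh
python examples/03_time_trends.py
```

```
significant time trends: 244/500 (Bonferroni threshold p < 1.00e-04)
planted trended features detected: 244/250
PCA: PC1 explains 69.1% of variance
PLS component 1 scores vs sampling time: Spearman rho = 0.969
planted trended features in the top decile of the loading ranking: 50/50
```

On a 500-feature synthetic study with half the features trended, the spline
LRT recovers 244 of the 250 planted trends at the Bonferroni threshold (and
nothing else), the first principal component carries most of the intensity
variance, and the PLS scores order the samples almost perfectly along
sampling time — the loading ranking puts planted trenders in the entire top
decile. The other scripts in `examples/` walk through spectral extraction,
blank filtering, pathway enrichment, lipid profiles, and the per-method
accounting table in the same style; each prints the numbers it computes and
a line on what they mean.

The CLI mirrors the pipeline for shell use:

```sh
metabodyn simulate --seed 1 --n-features 500 --out table.csv --spectra spectra.tsv
metabodyn fia-process --spectra spectra.tsv --refs refs.txt --out features.csv
metabodyn report
```

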