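# Methods

This note documents the models, defaults and numerical choices behind
metabodyn, and what the synthetic studies do and do not establish.

## Study design and the synthetic generator

The generator reproduces the sampling layout of a 4-day T cell activation
time course: time points 0–96 h every 12 h (9 points), 3 biological
replicates per point, and a sterile-well blank. The real experiment had a
single blank well; the generator defaults to 3 blank replicates because the
above-blank filter is a two-sample t-test and needs at least two
observations per group. This is a deliberate deviation from the original
design, recorded here.

Planted intensity for feature *f* in a cell sample at time *t* is

    I = base_intensity · trend(t) · exp(ε),   ε ~ N(0, log(1 + cv))

with `noise_cv = 0.1` by default — multiplicative log-normal noise, because
MS intensities are positive with roughly constant coefficient of variation.
Base intensities are log-uniform over 10^4.7–10^7.7 (the span a QTOF covers
between noise floor and detector saturation). Trend shapes:

- **monotone up/down** — logistic in time, `1 + a·σ((t − t₀)/w)` (or its
  mirror), with amplitude *a* ~ U(1, 3), midpoint t₀ ~ U(12, 48) h, width
  w ~ U(6, 10) h. This matches the plateauing profiles of metabolites such
  as the polyamines: a sharp rise in the first one to two days, then a
  plateau.
- **transient** — a Gaussian bump `1 + a·exp(−(t − t₀)²/2w²)` with
  t₀ ~ U(24, 60) h and w ~ U(8, 14) h, matching cofactor byproducts that
  rise and fall with peak biosynthetic flux.
- Exactly `round(frac_trend · n_features)` features are non-flat, split
  cyclically between the three shapes, so truth counts are deterministic.

Blank columns of cell-derived features draw from a background at 5% of
base_intensity (clearly separable from cells but nonzero, so the t-test
filter is exercised nontrivially); medium-derived features show the same
level in blanks as in cells. Because this background is proportional to the
feature's own intensity, it preserves feature ranks within the blank column,
and quantile normalization (which operates purely on ranks) deliberately
erodes part of the contrast — the filter therefore passes a realistic
fraction of features rather than all of them.

Spectra add, per sample: the tune-mix reference ions (Agilent ESI-L masses
within the 20–1050 scan range), every planted monoisotopic peak, ¹³C
isotopologues at +k·1.00335 Da with binomial ratios
I(M+k)/I(M) = C(n,k)·(p/(1−p))^k (p = 0.0107, n = carbon count), uniform
noise peaks padding each spectrum to ≥ 1200 peaks so the top-1000 detection
is a real filter, a per-sample injection-efficiency factor (log-normal,
σ = 0.2) that reference normalization must remove, and a quadratic mass
drift (defaults a = 1e−3, b = 2e−6, c = 5e−10, i.e. a few mDa / few ppm
across the scan range — typical TOF drift between calibrations).

The compound database draws CHNOPS formulas from metabolite-like templates
and computes monoisotopic masses from the formulas (pyteomics mass tables).
When a table is generated against a database, planted m/z values are the
[M−H]⁻/[M+H]⁺ adduct masses of randomly chosen compounds, so exact-mass
annotation closes the loop from features back to compounds. The planted
pathway's members are the compounds of the strongest planted trenders,
scored by the standard deviation of the log trend multiplier over the design
time points — truth-side information only: a coherently regulated pathway is
enriched precisely because its members all change strongly.

**What the generator does not emulate:** chromatographic peak shape and
retention time, profile-mode spectra, ion suppression and matrix effects,
correlated noise across features, adducts beyond M±H (except the formate
adduct handled in the lipid module), charge states > 1, and missing-ness
mechanisms other than falling below the top-1000 cut. Passing tests
therefore demonstrate the correctness of the processing logic under the
stated noise model, not robustness to every artifact of real acquisitions.

## FIA extraction chain

- **Recalibration.** The drift polynomial is fit by least squares to
  (observed − reference) *as a function of the reference mass*, and
  corrected masses solve m + d(m) = x by fixed-point iteration (three steps;
  the drift is mDa-scale, so convergence is far below 1e−9 Da). Fitting
  against the reference rather than the observed mass is what makes
  planted-coefficient recovery exact on noise-free quadratic drift: drift
  that is polynomial in the true mass is *not* exactly polynomial in the
  observed mass, and a fit in observed-mass coordinates leaves ~1e−8 Da
  residuals from the δ·d′(m) cross term. At least 3 matched references are
  required (a quadratic needs 3 points); the error names unmatched
  references.
- **Top-N detection.** Ties at rank N break toward the lower m/z, for
  determinism.
- **Consensus features.** Peaks of all samples are pooled, m/z-sorted and
  single-linkage clustered: a gap > tol_ppm (default 5 ppm, consistent with
  a > 50,000-resolution QTOF) splits clusters. Each sample contributes at
  most one (the most intense) peak per cluster; the representative m/z is
  the intensity-weighted mean. The pooled sort makes the result independent
  of sample order.
- **Gap filling** sums raw-spectrum intensity within tol_ppm of the
  representative m/z wherever a sample lacks a detected member peak; truly
  absent signals become 0, and the table has no missing entries.
- **Isotope collapsing.** Chains are grown greedily from the lowest m/z:
  feature B extends the chain ending at A if |mz_B − mz_A − 1.00335| ≤
  delta_tol (default 5 mDa) and the median per-sample ratio I_B/I_A lies in
  (0, 1.5·0.0107·(mz_A/12)] — 1.5× the M+1 ratio of an all-carbon molecule
  of that mass, a conservative carbon-count bound. Collapsed intensity is
  the sum over chain members (conserving total signal); `keep="mono"`
  retains the monoisotopic row only. Member ids and counts are recorded.
- **Annotation** considers [M+H]⁺ in positive mode and [M−H]⁻ in negative
  mode only (appropriate for singly charged polar metabolites in FIA), with
  a 3 mDa default tolerance (the wide setting used for QTOF batch
  annotation); features may carry zero, one or many candidates, and an
  optional retention-time tolerance further filters LC data.

## Normalization, blank filter

Quantile normalization maps column ranks onto the across-column mean of
order statistics; tied values receive the mean of the quantile values they
span, matching the canonical reference implementation. Gap-filled zeros
participate as ordinary values (their absence is informative). Blanks are
normalized together with the samples but excluded from ordination and trend
testing downstream.

The above-blank filter runs one t-test per feature and time point (equal
variance, one-tailed: cells > blank) and flags features with min-p < α
(default 0.05, uncorrected by design — the filter is a screen, not an
inference).

## Time-trend test

Each feature is fit by ordinary least squares on an intercept +
natural-cubic-spline basis of time (patsy `cr`, `spline_df` basis columns)
and compared with the intercept-only null via 2ΔlogL = n·log(RSS₀/RSS₁).
Because both models are nested linear Gaussian fits, the statistic is a
monotone function of F = ((RSS₀ − RSS₁)/df)/(RSS₁/(n − df − 1)), and the
default p-value uses that exact F reference: at n = 27 samples and df = 5
the asymptotic χ²(df) reference is visibly anticonservative (empirical size
≈ 0.09–0.10 at nominal 0.05), while the F reference is exactly calibrated
under the Gaussian model (and within Monte-Carlo error of nominal under the
generator's log-normal noise). `reference="chisq"` restores the asymptotic
p-values for comparison.

`spline_df` defaults to **5**. Four basis functions were the first
candidate (and remain available), but a df = 4 natural spline on 9 design
points cannot represent a transient bump of half-width ≈ one sampling
interval — it leaves ~40% of such a signal in the residual, capping the F
statistic regardless of noise level and costing substantial power against
exactly the transient profiles the design was built to catch. df = 5
resolves those bumps (< 13% unexplained) while keeping 21 residual degrees
of freedom and exact calibration. The null is intercept-only ("no time
trend" in the strict sense); testing against a linear null instead is a
one-line change of the null design matrix.

Significance applies Bonferroni at α / n_tested. Degenerate features
(constant, RSS₀ ≈ 0) get statistic 0 and p = 1.

## Ordination and ranking

PCA: square-root scaling (limits leverage of high-intensity features),
feature-centering over samples, SVD. PLS1: natural-log scaling (+1 offset
only when zeros are present), feature-centering, NIPALS with the weight
vector started from the X–y covariance — no randomness anywhere. Components
are sign-oriented so the mean score at the latest time point is ≥ the mean
score at 0 h, making plots reproducible. Feature importance is
Σ|loading| over the retained components (default 2, the two plotted
dimensions), ties broken by feature id.

## Enrichment

Subramanian-style weighted KS with weight 1 by default: hits advance the
running sum by |importance|^w (normalized over pathway hits), misses retreat
by 1/(N − n_hits); ES is the signed extremum. The null permutes member
labels (random same-size sets) with a fixed seed; p honors the +1
correction, so it is never 0 and never below 1/(n_perm + 1). NES divides by
the mean |null ES| of the matching sign. With w = 0 the ES depends on ranks
only; with w = 1 it inherits a documented dependence on the importance
scale. Pathways need `min_size = 3` ranked members to avoid degenerate
scores. A compound hit by several features keeps the maximum importance
(avoids double counting while retaining the strongest evidence; summation
is available).

## Lipid analytics

The shorthand grammar is `CLASS C:D` or `CLASS C1:D1_C2:D2[_C3:D3]`;
recognized classes are LPC, LPE, PC, PE, SM, TAG, HexCer, and anything else
parses as `other` with a warning (ether/oxidized prefixes are out of the
grammar by design). Chain-resolved names must sum to their totals — the
parser enforces it. Class totals use **raw** intensities (class growth
tracks cell growth, which is part of that signal); saturation fractions use
**quantile-normalized** intensities (a within-sample ratio is scale-free).
Double-bond bins {0, 1–2, 3, ≥4} partition the PC pool; fractions are
computed per sample and averaged over replicates, so they sum to 1 at every
time point by construction. The profile is intensity-weighted by default
(count weighting is available). Note that quantile normalization biases the
recovered polyunsaturated fraction upward by ~0.02–0.03 relative to the
planted raw-scale value; the acceptance tolerance accounts for this.

## Problem sizes and defaults

The test and acceptance workloads use 200–500 planted features, 30 spectra
of ≈ 1200 peaks, 2000 features for the null calibration, 600 database
compounds, 10 pathways of 15 members and 1000 permutations — sizes at which
every property of interest (recovery, calibration, power, enrichment) is
measurable with comfortable Monte-Carlo margins while a full run completes
in seconds.

## Known limitations

- The trend test treats replicates as independent Gaussian observations;
  there is no mixed-effects replicate term and no penalized smoothness
  selection (a penalized smoother would blur the exact F calibration).
- Exact-mass annotation is inherently ambiguous; the enrichment stage
  propagates that ambiguity (every candidate inherits the importance) rather
  than resolving it.
- The consensus tolerance and the "plausible isotope ratio" bound are
  heuristics with documented defaults; both are configurable.
- PCA loading directions are only duplication-invariant for (near) low-rank
  tables; duplicating a sample reweights the covariance in general.
- Lipid chain positions (sn-1/sn-2) and MS2-based identification are out of
  scope.
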