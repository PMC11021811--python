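# Methods

This note records the models, estimators and design choices behind
`osteophen`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design emulated by the generator

The synthetic cohort mirrors a strain-panel phenomics study: 8 inbred
founder strains of the Diversity Outbred population × 2 sexes × 9 animals
per cell (144 founders), plus 25 DO animals per sex.  Each trait follows an
additive model

    y = μ + a(strain) + b(sex) + s·(mass − μ_mass) + ε,

with strain effects shared by strain-mates, sex effects ±d (males positive
for size-related traits), an allometric mass slope `s` and Gaussian
residuals.  Trait correlations arise from latent factors: a "size" factor
drives body mass, bone mass, cross-sectional morphology and whole-bone
strength; a "material" factor drives TMD, cortical thickness and
beam-theory material properties; a "lacunar" factor groups the osteocyte
lacunar morphometry traits.  A trait with loading ρ on its factor draws
both its strain effects and its residuals as
ρ·z_shared + √(1−ρ²)·independent, so within- and between-strain
correlation structures agree.

Fasting blood glucose receives optional per-(strain, sex) mean shifts,
defaulting to +180 mg/dL (SD 60) for NOD females and NZO males — the two
diabetes-prone groups — so roughly a tenth of the panel crosses the
250 mg/dL hyperglycemia threshold.  The shift magnitudes are free
parameters, not measured values.

DO animals draw one Dirichlet(α = 0.5) weight vector over the 8 founders
(shared across traits, preserving correlations); their strain effect for
every trait is the corresponding convex combination of the founder effects,
which bounds it inside the founder effect range exactly.  α → 0 degenerates
to copying a single founder; large α concentrates all animals at the
centroid.  α = 0.5 keeps individual animals dominated by a few founders,
which reproduces outbred animals that overlap several strain clusters and
fill the gaps between them.  Admixture weights are a phenotypic proxy; no
genome or pedigree is simulated.

### Calibration of effect scales

The heritability estimator below divides SS_strain by the average group
size n_avg rather than by df_strain·n_avg, so for a balanced S-strain
design its between-strain component has expectation
(S−1)·τ² + (S−1)·σ_e²/n_avg — roughly (S−1)× the generative between-strain
variance — and its sex component SS_sex/df_sex can never fall below σ_e².
A generator that naively set τ² = f_strain·σ_T² would therefore be
estimated far above its nominal fraction.  The generator instead treats the
`var_frac_*` targets as *estimator-scale* quantities and calibrates the raw
scales (τ, d, σ_e) so that the estimator recovers them:

* σ_e² ∝ f_res (the residual component is unbiased);
* N·d² ∝ max(f_sex − f_res, 0) (the sex effect floors at zero when
  f_sex < f_res — under this estimator a sex component below the residual
  variance is unobservable);
* τ is found by monotone bisection so that E[H²] equals f_strain, where the
  expectation of the nonlinear ratio is evaluated against the exact
  sampling distributions of the three components for a balanced design
  (scaled χ²_{S−1}, a shifted-normal square, and χ²_{df}/df) on a fixed
  60 000-draw quadrature grid.  A first-order calibration that only matched
  component expectations leaves a visible upward bias at low targets
  because the 1-df sex component is strongly skewed; solving the ratio
  expectation directly removes it.

Finally the whole column is rescaled so its total variance is `total_sd²`;
H² is scale-invariant, so calibration and variance bookkeeping hold
simultaneously.  One consequence worth remembering: the generative
intraclass correlation is *lower* than the nominal H² target (e.g. a target
of 0.8 corresponds to an intraclass fraction near 0.5 in the 8×2×9
design), which matches how this estimator behaves on real panel data.

Bending curves are piecewise linear with known knots — elastic slope K to
(F_y/K, F_y), hardening to F_u over the first 60% of PYD, softening to
0.45·F_u over the remainder, then an abrupt fracture drop to 2% F_u — with
additive Gaussian force noise; the sampling grid contains the knots
exactly, so noiseless constructions reproduce F_u and K to machine
precision.  Raman spectra are sums of Gaussian bands at canonical bone
centers (ν2 phosphate 431, proline 855, ν1 phosphate 959, ν1 carbonate
1070, amide III 1256 cm⁻¹) with specified integrated areas, a polynomial
baseline and Gaussian noise on a 300–1800 cm⁻¹ grid.

## Heritability estimation

`anova_ss` fits the two-factor model by least squares (statsmodels OLS with
sum-to-zero contrasts).  Defaults, chosen where the workflow leaves room:

* **Additive model (strain + sex)** for the H² decomposition, so the
  three-way SS partition matches the printed quotient formula exactly; the
  interaction model is available separately for significance testing.
* **Type III** sums of squares on unbalanced data (equal to Type II in the
  additive model; matching commercial-package defaults for the interaction
  model), Types I/II selectable.
* **n_avg = animals-with-trait / number of strains** (strain-level groups),
  configurable to strain×sex cells.
* Missing trait values are dropped listwise per trait.

H² = σ²_strain/(σ²_strain + σ²_sex + σ²_res) with the quotient components;
it is a ratio of non-negative terms, hence always in [0, 1].  Zero total
variance yields a flagged degenerate result with H² = 0.

Post hoc contrasts (each strain vs B6 within sex; pooled founders vs DO
within sex) are t-type comparisons on the pooled within-cell residual
variance with Šidák adjustment p_adj = 1 − (1−p)^m inside each declared
family.  Hyperglycemia is classified by the strict rule FBG > 250 mg/dL.

## Body-mass adjustment

Per-strain OLS slope of trait on mass; a slope whose two-sided p exceeds
0.20 (strictly) is set to 0, and a strain with fewer than 3 usable animals
is zeroed with a distinct `insufficient_n` flag.  Adjustment subtracts
slope·(mass − grand mean mass) with the grand mean taken as the unweighted
mean of the strain mean masses.  Under the null, the retention rate equals
P(p ≤ 0.20) ≈ 0.20 — a property the acceptance script measures.  A
strain + sex + mass general linear model provides the covariate p-value.

## Mechanics

The acquisition protocol this emulates reports only which parameters were
extracted, not how, so the extraction criteria are explicit parameters:

* **Stiffness**: maximum least-squares slope over sliding windows of 20% of
  the pre-ultimate samples — standard practice for rodent bending data and
  robust to the compliant toe created by the −0.1 N preload.
* **Yield**: offset-line criterion.  With section geometry available the
  offset displacement maps a 0.2% strain offset through beam theory,
  d₀ = 0.002·L²/(6c); without geometry a fixed 0.01 mm offset is used.  A
  curve that never violates the offset line is brittle: F_y = F_u, PYD = 0.
* **Failure**: first post-ultimate sample below 10% of F_u, else the last
  sample (flagged).  **Work**: trapezoidal integral to the failure point
  with preload-negative forces clipped at zero.

The offset criterion is intentionally not an unbiased estimator of the
generator's kink force: on noiseless piecewise-linear curves it lands
(K·d₀)/(K−H) past the kink (H the hardening slope), a ~2% overshoot of F_y
at the default offset, and proportionally more when PYD is small — which is
why batch recovery of PYD on realistic cohorts (PYD down to 0.02 mm) shows
larger relative errors than the controlled benchmark at PYD = 0.3 mm.

## Multivariate analysis

Correlations are pairwise-complete Pearson r with two-sided t-test p and a
mask at p > 0.05 (pairwise maximizes per-panel n; PCA, by contrast,
requires complete cases).  Clustering uses d = 1 − r — not 1 − |r|, because
traits whose biological signs agree should cluster together — under the
Ward.D2 (squared-distance Lance–Williams) update; `scipy`'s `ward` linkage
on a condensed distance matrix implements exactly R's
`hclust(method = "ward.D2")`, and the test suite freezes an R-computed
dendrogram (heights and 3-group cut) as the oracle.  Cluster labels are
renumbered by first appearance so runs are deterministic.

PCA standardizes each trait to mean 0, SD 1 (ddof = 1) over founder
complete cases and takes the SVD; explained variance is λ_j/Σλ; each
loading column is sign-flipped so its largest-magnitude entry is positive
(signs are otherwise arbitrary).  Projection centers and scales new rows
with the *founder* parameters and applies the founder weightings — no
refitting — so training rows reproduce their fitted scores identically.
Four PCs are reported by default; all are stored.  Group ellipses are the
Mahalanobis level-1 contour of each group's fitted bivariate normal.

## Raman processing

Band windows are not standardized across instruments; the defaults follow
common bone-Raman assignments (ν1 phosphate 930–980, ν2 phosphate 410–460,
amide III 1215–1300, proline/hydroxyproline 840–898, ν1 carbonate
1050–1100 cm⁻¹) and are configurable — the config is the single source of
truth.  Baseline subtraction optionally removes a least-squares-scaled
embedding-medium (PMMA) reference first, then fits an 11th-order polynomial
iteratively (≤ 20 passes), excluding points more than 2σ above the current
fit, with σ estimated from the *negative* residuals only: peaks never
contribute there, so the baseline tracks the noise mean rather than its
lower envelope (a pure lower-envelope iteration systematically inflates
small band areas).  Residual negative intensities are clipped at zero and
the clipped fraction logged.

Crystallinity is 1/FWHM of the ν1 phosphate band from a single-Gaussian
least-squares fit (robust to noise; a direct half-maximum search is
available for cross-checking).  Spot grids are aggregated per animal by the
median (configurable), ignoring unavailable spots.

## Pipeline and problem sizes

The driver runs simulate/ingest → mechanics → Raman → heritability →
adjustment → correlations/clustering → PCA + DO projection → post hoc, each
stage writing CSV and recording itself in a JSON report; a fixed seed gives
bit-identical outputs.  In simulation mode the mechanics and Raman stages
synthesize per-animal raw data from that animal's traits (bending truth
clamped to F_y ≤ 0.95·F_u, PYD ≥ 0.02 mm; section properties approximated
as I = pMOI/2 and c = √(Tt.Ar/π); Raman areas anchored at ν1 = 10, amide
III = 4 since spectra are defined only up to intensity normalization) and
the measured values replace the generative ones downstream, as in the real
experiment.

Default benchmark sizes — 100 cohorts per heritability target, 500 random
ANOVA designs, 200 curves, 800 null regressions, 50 replicate studies for
the projection benchmark, 20 spectra — keep the full acceptance run around
a minute while leaving Monte-Carlo standard errors well inside the
tolerances checked.

## What passing tests do and do not show

The generator reproduces the *structure* of a strain-panel study: variance
shares, trait correlations through a handful of latent factors, admixed
outbred phenotypes, curve and spectrum shapes.  It does not reproduce real
biology: effects are Gaussian (real strain distributions are not), traits
can stray into implausible tails (a very small simulated pMOI can be
non-positive, in which case downstream geometry is skipped), lacunar and
composition values are plausible magnitudes rather than measured ones, and
admixture weights stand in for genomes — so no epistasis, linkage or
genotype–environment interaction.  Recovery tests therefore validate the
estimators, not the biology.

Two containment caveats deserve emphasis.  The DO strain-*effect* hull
bound is exact (convexity).  Realized DO *trait values*, however, carry the
same residual noise as founders, so a cohort of 50 DO animals leaks past
the 144-founder extremes at an expected ~1–2% of animals — concentrated in
the low-heritability directions (ductility, material properties) — and the
chance that *every* animal of a replicate stays inside the PC1–PC2 hull is
only moderate even though the aggregate containment rate exceeds 95%.
Shrinking DO residual variance below the founders' would make containment
look perfect but has no basis in the study design, so the package reports
both numbers instead.

## Known limitations

* The H² quotient estimator is implemented as printed; it is not an
  unbiased variance-component estimator (no REML/mixed-model alternative is
  provided, by scope).
* Beam-theory material properties inherit every bias of the section
  approximation used for I and c.
* The baseline algorithm assumes peaks are positive excursions on a smooth
  background; derivative-shaped artifacts (cosmic rays are out of scope)
  would corrupt the fit.
* Unbalanced designs are supported through the SS-type options, but n_avg
  as total/strains is a convention; with severe imbalance the estimator's
  meaning degrades with it.
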