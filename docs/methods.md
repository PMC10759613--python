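# Methods

This note documents the statistical procedures implemented in `gwinet`, the
assumptions behind them, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not demonstrate.

## Study design being modeled

The pipeline targets a three-arm cohort of male veterans: healthy controls
(HC, n = 44) and Gulf War Illness cases split by comorbid-PTSD probability
into GWI_L (n = 29) and GWI_H (n = 47). Subjects come from two kinds of
recruitment site. Exercise-site subjects complete a maximal graded exercise
test with blood draws at rest (T0), peak exercise (T1) and four hours post
(T2), and their PTSD probability is scored with the Davidson Trauma Scale
(DTS, 17 items, total 0–136). Rest-only-site subjects contribute T0 data
only and carry a structured-clinical-interview PTSD diagnosis instead of a
DTS total. Symptom questionnaires (five MFI and eight SF-36 composites in
the full design; six representative composites in the shipped demo catalog)
are administered once per subject.

## Subgrouping

GWI subjects with DTS total ≥ 70 are labeled GWI_H, below 70 GWI_L; the cut
is inclusive at 70. Rest-only subjects are labeled by the diagnosis flag.
Controls are HC regardless of trauma evidence. The two evidence sources are
treated as equivalent for labeling — no probability weighting — because all
downstream analysis pools the resulting groups. Each subject must carry
exactly one evidence source; anything else is a validation error rather
than a silent preference.

## Assay calibration

Two multiplex panel generations are supported, matching their historical
calibration software: a second-order polynomial for the 16-plex batch and a
five-parameter logistic (5PL) for the 18-plex batch.

The 5PL is parameterized as y = d + (a − d)/(1 + (x/c)^b)^g with a the
upper asymptote, d the lower asymptote, c the inflection concentration,
b the slope and g the asymmetry (g = 1 recovers the symmetric 4PL). Note
the sign convention this form implies: a curve that rises with
concentration — the usual sandwich-immunoassay orientation — has b < 0, so
the fitter leaves b unconstrained in sign and chooses start signs from the
data's orientation. Weighted fitting minimizes Σ wᵢ(yᵢ − f(xᵢ))² with
wᵢ = 1/yᵢ ("1/y weighting"), which balances *relative* rather than absolute
residuals and therefore stabilizes back-calculation at the low end of the
curve; it requires strictly positive signals, so blank wells with
non-positive signal are rejected at fit time. Initialization is multi-start:
asymptotes from the signal extremes, c from the signal-midpoint crossing,
slope magnitudes {0.5, 1, 2}, g = 1; the lowest final cost wins and
convergence diagnostics (per-start costs, residual summary) are attached to
the fitted curve. Five free parameters on a handful of standards is an
ill-conditioned problem — the c and g estimates trade off strongly — so
precision depends on plate design: with standards run in duplicate (as the
assays here run all wells) the median recovered c under 5% multiplicative
noise is within a few percent of truth, while single wells roughly double
the spread.

Inverse prediction uses the closed-form 5PL inverse on its monotone branch
and quadratic root selection for the polynomial, restricted to the
calibrated range. Signals outside the attainable range raise a flag that
distinguishes above-top from below-bottom, and a polynomial with two
admissible roots in range raises an ambiguity error; out-of-range wells are
*flagged, not imputed*, because the later min–max normalization is
sensitive to imputed zeros. Duplicate (or quadruplicate) wells are averaged
on the concentration scale after back-calculation, with the count of
contributing wells recorded; an all-missing sample stays missing.

## Cross-panel harmonization

The two panels share 15 analytes but report on different effective scales,
so per analyte: (1) z-score each panel separately using the sample SD
(ddof = 1); (2) map 16-plex z-scores onto the 18-plex scale as
z·sd₁₈ + mean₁₈; (3) concatenate and min–max normalize to [0, 1]. Every
step is univariate and affine on non-missing entries, which gives the three
properties the downstream analysis relies on: within-panel rank order is
preserved exactly (Spearman statistics unchanged), between-panel location
and scale differences are removed, and Welch/Games-Howell/Hedges statistics
are invariant because they are location-scale equivariant. Analytes present
on only one panel (e.g. the TNF receptors, 18-plex only) are carried
through from the populated panel with a warning; zero-spread analytes are
withheld as degenerate rather than mapped to a constant. Min–max is applied
per analyte over the combined data (all subjects and timepoints pooled) —
pooling per analyte bounds each cytokine to [0, 1] while preserving
timepoint contrasts; a global (all-analytes-jointly) switch is provided.
Missing values pass through untouched at every step, since imputation would
contaminate the correlation stage.

## Measure screening

Groups are unbalanced with unequal variances, so the omnibus test is
Welch's heteroscedastic one-way ANOVA: with wᵢ = nᵢ/sᵢ², W = Σwᵢ and the
precision-weighted grand mean, F* = [Σwᵢ(x̄ᵢ − x̄_w)²/(k−1)] /
[1 + 2(k−2)/(k²−1)·A] where A = Σ(1 − wᵢ/W)²/(nᵢ−1), referred to
F(k−1, (k²−1)/(3A)). For k = 2 this reduces exactly to the squared Welch t.
Classical ANOVA is not offered as the default.

Measures with omnibus p < 0.05 proceed to Games-Howell pairwise contrasts:
t = Δx̄/√(sᵢ²/nᵢ + sⱼ²/nⱼ) with Welch–Satterthwaite df, adjusted p from the
studentized-range distribution with k groups evaluated at q = |t|·√2
(scipy's implementation; the test suite checks it against an independent
double-integration of the studentized-range density to 1e-6). No further
alpha adjustment is applied across the many screened measures, matching the
two-stage screen-then-report style; the number of tests performed is
surfaced in the results so readers can judge the multiplicity burden.

Effect sizes are the small-sample bias-corrected Hedges
g = J·(x̄₁ − x̄₂)/s_pooled with s_pooled over df = n₁ + n₂ − 2 and
J = 1 − 3/(4·df − 1). The pooled SD is the classical homoscedastic pooling
even though the accompanying test is heteroscedastic — that is the
conventional definition of the corrected estimator. |g| is binned as
negligible < 0.01, very small 0.01–0.20, small 0.20–0.50, medium 0.50–0.80,
large 0.80–1.20, very large 1.20–2.00, huge ≥ 2.00. A summary-statistic
entry point accepts published means/SDs/ns directly. Missing values are
dropped pairwise per measure, so per-measure group sizes are reported
alongside every test. Categorical demographics use Pearson's χ² without
continuity correction; marginal significance (p < 0.10) is a reporting
tier, not a gate.

## Correlation networks

Per condition × timepoint slice, every measure pair with at least
`min_pairs` (default 10) pairwise-complete observations is tested with a
tie-aware Spearman ρ (Pearson correlation of average ranks). The two-sided
p uses the t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df — standard at
these group sizes (≥ 15); an exact permutation option exists for very small
n. ρ = ±1 maps to p = 0. Pairs below the floor are recorded as *untested*
rather than entering the correction family as p = 1.

Multiplicity is controlled with Storey q-values computed within each
condition × timepoint family (nine families), matching the unit at which
graphs are built and filtered, rather than pooling globally — both options
are exposed since the original unit of correction is not documented
anywhere authoritative. π₀ is estimated from the flat tail of the p-value
histogram, π₀(λ) = #{p > λ}/(m(1−λ)) over λ ∈ {0, 0.05, …, 0.90}, smoothed
with a cubic polynomial evaluated at the largest λ and clamped to (0, 1]
(a bootstrap MSE-minimizing variant is available). q-values follow the
step-up rule q(p₍ᵢ₎) = min_{j≥i} π₀·m·p₍ⱼ₎/j, so forcing π₀ = 1 reproduces
Benjamini-Hochberg exactly and Storey q ≤ BH q always; ties share a q.
Edges are retained at q < 0.05. T0 graphs use both sites; T1/T2 graphs
contain only exercise-site subjects by construction. Symptom scores, being
measured once, enter every timepoint's graph with their single value.

## Graph edit distance

The compared graphs share a measure catalog, so node correspondence is
fixed by labels. That collapses the generally NP-hard edit-distance search
to an exact per-edge decomposition over the union of edge supports: shared
edges contribute substitute_cost(ρ₁, ρ₂), unmatched edges contribute
insert/delete cost. The default scheme — substitution |ρ₁ − ρ₂|, insertion/
deletion |ρ| — makes the distance the L1 norm between edge-weight vectors
(absent edges as 0), hence a true metric; the test suite verifies symmetry,
identity and the triangle inequality on random triples and checks the
decomposition against brute-force enumeration over node bijections with
infinite relabel cost. A unit-cost scheme (all operations cost 1,
substitution only on sign flips) is available; the scheme name is recorded
in every output. Isolated nodes carry no cost. Distances are reported only
between conditions within a timepoint by default, because the exercise
timepoints exist for a subset of the cohort; cross-time comparison is a
flag. Distances scale with graph size and density, so they are comparable
within one analysis, not across catalogs.

## Synthetic cohort generator

Marginals are Gaussian with optional clipping to physiological bounds
(percentages to [0, 100], counts to [0, ∞)); group/timepoint deviations are
programmed as standardized shifts plus SD ratios, so heteroscedastic
designs are first-class. Dependence is a Gaussian copula: target Spearman
matrices are mapped to Pearson via ρ_P = 2·sin(πρ_S/6), projected to the
nearest PSD correlation matrix, and applied per group × timepoint.
Within-subject dependence across timepoints uses a shared subject-level
factor with weight 0.5 by default — the study's true longitudinal
autocorrelation is unknown, so it is a parameter, not an assertion.
Symptom draws are made once per subject and repeated across timepoints.
DTS totals are drawn on the correct side of the cut per group (optional
label noise, default 0). Missingness is missing-at-random at a configurable
cell rate (demo default 5%), on top of the structural missingness of
rest-only subjects at T1/T2 and panel-exclusive analytes.

The shipped demo configuration programs the group means that separated the
arms in the motivating study — IL-15 depressed in GWI_L at all timepoints
with GWI_H at control level; basophil % roughly halved in both GWI arms at
peak exercise; RDW, CD2⁺%, and CD3⁻CD56⁺ counts shifted at rest; HCT and
the CD26 coactivation markers at peak exercise — with SDs recovered from
reported SEMs as SD = SEM·√n. The exercise-site subgroup sizes at T1/T2
are not separately published and are taken proportional to the overall
GWI_H:GWI_L split (31/20 of 51 exercise-site GWI). HC baselines that the
source tables do not print (symptom composites, unshifted cytokines) are
set to typical values for sedentary middle-aged male veterans. Latent
networks couple the fatigue scales, the NK axis (IL-15 → NK counts →
cytotoxicity) and blood indices, with a few group-specific immune–symptom
edges so the three condition graphs are genuinely different objects.

What passing tests on this generator demonstrate: the statistics are
computed correctly, the screen controls its error rates at the study's
exact group sizes, programmed effects of the published magnitudes are
recoverable at realistic power, and network differences of plausible size
separate cleanly in the edit distance. What they do not demonstrate:
robustness to skewed or heavy-tailed marginals (real cytokine
distributions are log-normal-ish; the Gaussian-with-clipping model
approximates censoring at zero but not skew), assay drift beyond a static
batch shift, informative missingness, or exercise-physiology dynamics
beyond a shared subject factor.

## Numerical choices and degenerate inputs

- Zero-variance groups, analytes, or pooled SDs raise typed degenerate
  flags and are excluded with a log entry — never silently imputed.
- PSD projection clips eigenvalues at 1e-10 and renormalizes the diagonal;
  latent matrices whose requested weights move by more than half their
  magnitude under projection are retried with shrunken weights and fail
  loudly after 50 retries.
- 5PL optimization runs to xtol = ftol = gtol = 1e-14 with analytic-free
  Jacobians; non-convergence is recorded in the diagnostics, not raised.
- The studentized-range tail probability comes from
  `scipy.stats.studentized_range`; p-values are clipped to [0, 1].
- Out-of-range signals at inversion are clipped only within a 1e-9
  relative tolerance band at the range edges; beyond that they are flagged.
- Pipeline determinism: one global seed fans out to per-stage child seeds
  via `numpy.random.SeedSequence`, so disabling a later stage never
  perturbs an earlier one, and identical config + seed yields
  byte-identical reports (paths aside).

## Problem sizes used in the shipped experiments

The simulation experiments run at the study's own scale: 10,000 parallel
null measures at n = (44, 29, 47) for the type-I check; 200 independent
cohorts for pattern recovery; 200 seeds × 40 measures × 44 subjects for
false-edge control; 200 seeds × 12 measures for the perturbed-network
separation; 500 subjects per panel for the batch-shift residual. These
sizes give Monte-Carlo standard errors comfortably below the decision
margins they feed.

## Known limitations

- The analysis is cross-sectional per timepoint; no repeated-measures or
  mixed models across the exercise challenge (deliberately matching the
  timepoint-by-timepoint reporting it mirrors).
- Correlation graphs are marginal Spearman networks, not partial
  correlations; hub structure partly reflects shared latent drivers.
- The edit-distance scheme is declared, not estimated; published distance
  values from any particular study cannot adjudicate the scheme without
  the underlying data.
- Per-analyte min–max normalization ties the [0, 1] endpoints to the
  realized sample extremes, so harmonized values are comparable within a
  dataset, not across datasets.
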