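# Methods

This note documents the models and procedures `mixoniche` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's numerical conventions.

## Copy-number correction

Gene counts from 18S rRNA amplicon surveys confound cell abundance with
per-cell gene copy number, which spans orders of magnitude across
eukaryotic groups and correlates with cell biovolume. The correction model
is an ordinary least-squares line of copies-per-cell on biovolume (µm³),
fit separately for dinoflagellates, diatoms and all other eukaryotes —
the three groups with clearly distinct copy-number regimes in the
small-protist size window (≈65–523 µm³) the pipeline targets. The
correction factor C.F. is the fitted line evaluated at a reference
biovolume, default 65 µm³ (the small-flagellate end of the calibration
range, appropriate for 0.8–5 µm size-fractionated communities); cell
abundance = gene count / C.F. of the lineage's group.

Choices and caveats:

* The fit is on linear axes with a free intercept. A through-origin or
  log-log refit is advised (via the raised error) when the free-intercept
  line goes non-positive at the reference volume.
* C.F. is applied at group granularity; a per-lineage override table is
  supported for taxa with known copy numbers.
* Dividing by a group constant preserves within-group relative composition
  exactly; only between-group proportions change.
* The shipped default C.F. map is {dinoflagellate: 59.3, diatom: 10.5,
  other: 4.7}; `martin2022` ({27.1, 4.4, 0.9}) is included as a published
  alternative for sensitivity analysis. The two differ by factors of 2–5,
  which is a fair indication of the structural uncertainty in any
  copy-number correction.

## Exclusions and trophic annotation

Ciliophora, Radiolaria and Foraminifera are removed before analysis: they
derive mostly from large-size-fraction populations and would dilute the
focus on small constitutive mixotrophs. Fungi, Amoebozoa, Syndiniales and
unresolved eukaryotes are removed as trophically unannotatable; parasitic
dinoflagellates are covered by the Syndiniales rule, while other
Dinoflagellata are retained (a per-lineage blocklist handles finer cases).

Annotation is a dictionary lookup with rank fallback: species first, then
genus, then family; the first hit wins and the resolving rank is recorded.
Matching is by exact string after whitespace normalization and is
case-sensitive, because reference-database placeholder names
("Chrysophyceae_Clade_G_sp.") are only meaningful verbatim. Lineages with
no hit are labelled `unknown`; they stay in the community total but are
never counted in M/A/H. The shipped demo database covers a handful of
well-known open-ocean taxa and exists for demos and tests; real analyses
must supply a curated database.

## Trophic indices

TI_g = Σ(abundance of mode-g lineages) / Σ(denominator lineages), per
sample. The default denominator (`all_retained`) includes unknown-mode
lineages, so TI_M + TI_A + TI_H ≤ 1, with the deficit equal to the
unannotated share; `annotated_only` restricts the denominator to annotated
lineages and makes the indices sum to exactly 1. The default reflects the
view that T is the whole (retained) eukaryotic community, not just its
annotatable part. Indices are invariant to any per-sample rescaling of
abundances, hence identical for proportions and counts.

Surface-vs-CML comparisons pair samples by station and run a paired t-test
on within-station SUR−CML differences (df = pairs − 1; statistic positive
when the surface mean is larger), with a paired Wilcoxon signed-rank test
reported alongside since index distributions can be skewed. Regional
summaries use the median across stations by default (means also emitted).

## Environmental table and ordination

The environmental registry covers 29 variables (physics, climatology,
biogeochemistry and picoplankton stocks). Preprocessing imputes missing
values with the column mean of the dataset under analysis (surface-only
and surface+CML analyses are imputed separately), then log10-transforms;
variables containing non-positive values use log10(x + ε) with ε = half
the smallest positive observed value, recorded per variable. Imputation
happens before the transform, so it never changes a variable's raw mean.
Whether to additionally z-score is exposed as a flag; PCA defaults to
z-scoring because the variables carry incommensurate units.

PCA is a plain SVD of the centered (optionally standardized) matrix with
a deterministic sign convention — each component's largest-magnitude
loading is positive — so loading tables are reproducible across runs and
platforms.

TI-vs-gradient trends use a penalized cubic B-spline smoother (basis
dimension 10, shrunk with a warning when n is small) with the penalty
weight selected by generalized cross-validation, plus a pointwise 95%
confidence band. When the data sit exactly in the basis span (noise-free
input), the GLM scale estimate degenerates and the smoother falls back to
the unpenalized least-squares interpolant with a zero-width band. The
shape summary (increasing / decreasing / unimodal / flat, `complex` as a
fallback) is classified from the sign pattern of the fitted derivative on
the evaluation grid, with a dead zone of 5% of the fitted range per unit
x, never from the raw data.

Single-variable regressions are OLS with an optional log10 predictor
transform; the 29-variable screening battery additionally reports
Benjamini–Hochberg q-values because raw p-values over dozens of tests
inflate false positives. Stepwise selection is bidirectional from the
intercept-only model, minimizing AIC by default (BIC by flag), with the
full add/drop trace recorded; it degrades to forward-only when there are
more candidates than observations, and stops early if a step achieves an
effectively exact fit (AIC comparisons are degenerate there). AIC is
deliberately liberal: under a pure-noise response it admits several of 29
candidates (per-variable null entry probability ≈ 0.16); use BIC when
false selections matter more than misses.

RDA regresses the Hellinger-transformed community (square root of
row-relative abundances, giving every sample unit L2 norm) on centered
environmental variables and decomposes the fitted matrix by SVD. Before
the regression, (i) the species matrix is reduced by Escoufier
equivalent-vectors selection — greedily adding the species that maximizes
the RV coefficient with the full matrix until RV ≥ 0.9; (ii) each
environmental variable must pass a marginal permutation test (999
seeded permutations of that variable against the selected species matrix,
α = 0.05) and a collinearity screen (variance inflation factor ≤ 10, the
worst offender dropped iteratively). These two screens are standard
practice; the thresholds are conventions, not estimates. If no variable
survives, the unconstrained ordination is returned with a warning. The
constrained-variance fraction is invariant to affine rescaling of the
environmental variables, and permutation p-values are bit-reproducible
given the seed.

Culture-rate ANOVAs: each single factor as a one-way F-test (numerator df
= levels − 1), factor combinations as the overall F of the additive
main-effects OLS model with categorical dummies. Zero between-group
variance returns F = 0, p = 1 even when the within-group variance is also
zero (the identical-samples null).

## Culture kinetics

Per sampling interval [t, t+1]: ingestion
I = (P_t − P_{t+1}) / (Δt · (G_t + G_{t+1})/2) in prey grazer⁻¹ h⁻¹;
clearance C = I / ((P_t + P_{t+1})/2) in mL grazer⁻¹ h⁻¹; biovolume-
specific clearance C · 10¹²/V in body volumes grazer⁻¹ h⁻¹ (1 mL = 10¹²
µm³). Clearance is the headline metric because at prey concentrations
around 2×10⁶ cells mL⁻¹ ingestion saturates, so clearance approximates
its maximal value. Reported means run over intervals before the grazer's
stationary phase — the first interval from which the local ln-slope stays
below 0.005 h⁻¹ (roughly 10% of typical maximal growth rates;
configurable). Negative per-interval ingestion (prey growth outpacing
grazing) is preserved and flagged, with the mean reported both with and
without negative intervals; clipping at zero is a flag, not the default.

Maximal growth rate is the steepest OLS slope of ln(grazer) vs time over
contiguous windows of ≥3 observations, reported in h⁻¹ and d⁻¹. Windows
containing zero counts are skipped.

The interval estimator assumes the intrinsic net rate of change of prey is
negligible over the assay — in batch cultures with non-growing prey this
is the standard identifiability condition. When prey decays measurably in
grazer-free controls, the `control_correction` flag projects each
interval's expected prey from the control's net exponential rate and
measures removal against that projection. Both behaviors are implemented
because published batch assays are often ambiguous about whether rates
were control-corrected; neither is asserted as canonical.

## Synthetic-data generator

The generator defines the study conditions the tests run under.

**Survey.** Stations are assigned to four latitudinal bands with
probability proportional to the band station counts (36/17/37/14). Band
medians: PAR 25.4/24.3/14.7/18.8 mol photons m⁻² d⁻¹, nitrate+nitrite
0.89/0.03/0.13/17.3 µmol L⁻¹, heterotrophic bacteria
4.9/3.9/5.3/4.5×10⁵ cells mL⁻¹, temperature 26.6/24.7/19.5/7.1 °C —
the broad open-ocean surface pattern (bright oligotrophic subtropics,
nutrient-rich high latitudes, near-constant bacterial stocks). Within-band
spreads are log-normal (σ_ln = 0.25 for PAR, 0.8 for N, 0.3 for
bacteria). The remaining registry variables are filled by plausible
covariation rules (e.g. oxygen anticorrelated with temperature, phosphate
tracking nitrate) plus noise; they provide realistic collinearity
structure for the PCA/stepwise/RDA machinery, not oceanographic realism.

The true mixotroph index follows a logistic link:
TI_M = (1 − u) · σ(α + β_PAR·z(log₁₀PAR) + β_N·z(log₁₀N) + δ·1[CML] + ε),
with defaults α = −0.85 (baseline near 0.30 at average gradients),
β_PAR = +0.5, β_N = −1.0 (light favors, nutrients disfavor mixotrophy —
the effect signs under study), CML offset δ = −0.6, logit noise
σ = 0.3, and unannotatable share u = 0.03 (so the three true indices sum
to 0.97). The remainder splits A:H as 0.31:0.69. Lineage abundances are
log-normal weights within each mode scaled to the mode's share of 10⁶
cells; gene counts multiply each lineage by its group C.F., optionally
jitter multiplicatively, and are multinomially resampled to 10⁵ reads per
sample (set depth to `None` for an exactly invertible noise-free table).
The lineage catalog alternates species-rank and genus-rank database
entries to exercise the annotation fallback, includes dinoflagellate and
diatom lineages to exercise all three correction groups, and withholds
`unknown` lineages from the database entirely.

What the generator does *not* emulate: spatial/seasonal autocorrelation,
compositional coupling between lineages beyond the mode-share constraint,
taxon-specific copy-number scatter within groups, chimeras/contamination,
and any feedback of community state on the environment. Passing tests
therefore demonstrate that the pipeline's estimators recover the
generating process they assume — not that real surveys satisfy those
assumptions.

**Cultures.** Prey and grazer follow
dP/dt = r_P·P − C·min(P, P_sat)·G, dG/dt = µ·G (logistic toward K when a
carrying capacity is set), integrated by fixed-step RK4 on a 0.1 h grid
and sampled every 12 h (configurable within 12–24 h); measurement noise is
mean-preserving log-normal with CV 10% by default in noisy configurations.
Defaults: C = 2×10⁻⁶ mL grazer⁻¹ h⁻¹, µ = 0.04 h⁻¹, prey₀ = 2×10⁶
cells mL⁻¹, grazer inoculum 5×10³ cells mL⁻¹, horizon 72 h, r_P = 0.
The inoculum and horizon were designed as the assay's operating window:
per-interval prey depletion must be large enough to resolve against
10% counting noise yet moderate enough that the endpoint-averaging
estimator stays within a few percent of the true clearance (grazers end
near 9×10⁴ cells mL⁻¹, within the 10⁴–10⁵ range such cultures reach).
Grazer growth is deliberately decoupled from ingestion so the truth stays
analytically simple; the saturating-response and logistic-grazer options
exist for realism tests, not for rate recovery.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use 104-station surveys
(plus 61 CML pairs), 100-seed power batteries, 500-seed OLS coverage
checks, 200-seed noisy-culture batteries and 999-permutation RDA screens;
the whole suite runs in well under a minute of CPU. All randomness flows
through `numpy.random.default_rng` seeds; identical seeds give
bit-identical outputs, including permutation p-values.

## Known limitations

* Trophic annotation is only as good as the supplied database; the demo
  database is illustrative.
* The copy-number model is linear in biovolume over a narrow size window;
  extrapolating the correction outside ≈65–523 µm³ is unsupported.
* The RDA screening defaults (marginal permutation test, VIF ≤ 10) are
  conventions; other screens (forward selection with adjusted R², partial
  tests) would select different variable sets.
* The interval clearance estimator carries an O((λΔt)²) discretization
  bias on steeply depleting intervals; at the default design it is a few
  percent, but very dense grazers or long intervals inflate it.
* GAM smoothness is selected by GCV, which can undersmooth small noisy
  samples; the basis dimension caps the damage.
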