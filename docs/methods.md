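# Methods

## The interaction variable

For one image with counted population A (default: CD8+ T cells) and anchor
population B (default: PD-L1+ TAMs), let k be the number of A-cells whose
nearest B-cell lies within radius r. The interaction variable is

    value = 100 · k / (n_A + n_B),

dimensionless on [0, 100]. Normalising by the combined population size
prevents sheer abundance of either cell type from inflating the statistic: a
field dense in T cells but with no spatial association scores low, as does a
field of abundant anchors with few T cells near them. When both populations
are empty the value is undefined (missing); when only one is empty it is 0.

Distances are Euclidean in the slide plane. Coordinates are read as µm in a
per-image Cartesian frame; origin and axis orientation are irrelevant since
every statistic is distance-based (rigid-motion invariance is property-tested
to 1e-9 relative tolerance). The boundary is inclusive (a cell exactly at
distance r counts) with a flag for strict inequality; for continuous
coordinates the choice has measure zero. No edge correction is applied to
the interaction variable; the generator's torus mode provides the edge-free
regime used for analytic validation.

The default radius is r = 25 µm — roughly two cell diameters, the
conventional "interacting" range for cell-contact-mediated signalling in
tissue sections — with 5 µm radial bins up to 25 µm for the proximity
profiles. Radial bins are half-open [e_i, e_{i+1}); the cumulative fraction
is computed exactly from the stored nearest-neighbor distances rather than
from the binned counts. Because the per-bin ("fraction") and cumulative
("sum of proportion") presentations are both in circulation, the profile
table emits both columns.

Nearest-neighbor queries use a KD-tree (`scipy.spatial.cKDTree`, with
`boxsize` for the toroidal metric); an exhaustive O(n²) all-pairs
implementation lives in the synthetic module and serves as the oracle the
tree-based path is checked against — exact equality, not tolerance.

## Phenotype gating

A gating rule is a set of required-positive and required-negative markers
with per-marker intensity cutoffs. A cell matches iff intensity ≥ cutoff for
every positive marker and < cutoff for every negative one; the half-open
split guarantees every cell classifies. Rules apply first-match-wins with an
"other" fallback: the standard panels are disjoint, but user configurations
need not be, and a deterministic order keeps overlapping rules well-defined.
There is no universal intensity scale across staining batches and scanners,
so cutoffs are configuration, not constants; the default of 1.0 is the scale
the synthetic intensity model is calibrated to. Gating is deterministic,
idempotent, and order-independent across cells (property-tested).

The default human panel: CD3+CD8+ → `CD8T`; CD68+CD163+PDL1+ → `PDL1_TAM`;
CD68+CD163+ → `TAM` (the PD-L1+ rule precedes the plain TAM rule, so the
latter catches PD-L1− macrophages).

## Patient-level aggregation and stratification

Per-image values are averaged (mean by default; median available) over a
patient's image fields within one tissue region, with the contributing image
count recorded; missing images (no cells of either population) are dropped.
Patients are then dichotomized at the sample median of the non-missing
values, ≥ median → "high". The ≥ convention is what makes an odd cohort
with distinct values split ⌊n/2⌋ low / ⌈n/2⌉ high — 56/57 at n = 113. An
all-equal cohort degenerates to all-high and triggers a warning.

Tissue regions (tumor T, subcapsular SC, peritumoral stroma PS, adjacent
normal A) are analysed fully independently, and no cross-region multiplicity
correction is applied — a deliberate mirroring of common practice in
per-region survival reporting; the run manifest states this prominently.

## Clinical scores

* H-score: 1·%weak + 2·%moderate + 3·%strong over the 4-bin intensity
  classification, range 0–300; percentages summing above 100 are rejected.
* ALBI: 0.66·log10(bilirubin µmol/L) − 0.085·albumin g/L. Grade boundaries
  use the ≤ convention: grade 1 ≤ −2.60 < grade 2 ≤ −1.39 < grade 3, with
  the modified grading splitting grade 2 at −2.270 (the boundary value
  itself assigned to 2a, mirroring the ≤ pattern of the published
  boundaries; the literature does not pin this tie down). Conventional
  units (mg/dL bilirubin × 17.1, g/dL albumin × 10) convert in the
  constructor so the formula stays in its published units.

## Survival machinery

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines`; subjects censored at an event time count as at risk at that
time, per the standard convention.

The Cox proportional-hazards fit is implemented in-package: Newton–Raphson
maximisation of the partial likelihood with step-halving, convergence when
the score max-norm falls below 1e-8 or the relative log-likelihood change
below 1e-10, a 100-iteration cap, and centered covariates for conditioning.
Efron tie handling is the default — median-split indicators produce heavily
tied risk sets, where Efron's correction is markedly more accurate — with
Breslow available because its score test at β = 0 for a single binary
covariate is algebraically the log-rank statistic, an equivalence the tests
assert to 1e-6 on tie-free fixtures. The in-package fit is cross-checked
against `lifelines.CoxPHFitter` (agreement to 1e-5 on β and SE). Wald 95%
CIs (exp(β ± 1.96·SE)) and two-sided Wald p-values match conventional
software output. A coefficient escaping |β| > 10 (hazard ratio beyond
~22000 for unit-scale covariates) is flagged as monotone likelihood
(complete separation).

Candidate prognostic factors are screened univariately; those with Cox
p < α (default 0.05) enter one multivariate model. For binary candidates
the log-rank p is reported alongside (both conventions are in circulation;
the Cox p is the selector). Continuous clinical covariates entering the
screen are median-dichotomized, matching the dichotomized-factor
presentation conventional in clinical screening tables. Collinear
selections are reduced to a maximal linearly independent subset and flagged.
Relapse-free survival treats recurrence within five years as the event;
patients recurrence-free at five years are administratively censored at 60
months.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not any
particular tissue:

* **Geometry** — one 600 × 600 µm field per image (a 20× mIHC field). TAM
  count ~ Poisson(50), placed uniformly; a fraction (default 0.8) are
  PD-L1+, by Bernoulli thinning, so the anchor pattern remains Poisson.
  CD8 count ~ Poisson(150). Each CD8 cell is, with probability
  `attraction_rho`, the offspring of a uniformly chosen anchor plus an
  isotropic Gaussian displacement (σ = 8 µm), else uniform — a Thomas-style
  parent–offspring mechanism, the simplest process with a single proximity
  dial. Defaults (ρ = 0.8, σ = 8 µm) were calibrated once so that the bulk
  (~85%) of attracted-population cells fall within 25 µm of an anchor,
  the proximity regime the analysis is designed to detect.
* **Boundaries** — `torus` wraps coordinates and makes the attraction-free
  interaction probability exactly 1 − exp(−λ_anchor·π·r²) (Poisson void
  probability), the closed form used by the acceptance checks; `rectangle`
  (the realistic default) resamples out-of-field offspring around their
  parent and is edge-biased, which is documented rather than corrected.
* **Intensities** — lognormal per marker: log-mean +2 for positive, −2 for
  negative cells, log-sd 0.5. At the default cutoff of 1.0 the
  misclassification probability per marker is Φ(−4) ≈ 3·10⁻⁵, so default
  gates recover the generating phenotypes for ≥ 99% of cells (tested).
* **Survival link** — patient heterogeneity enters only through
  ρ_i ~ Uniform(0.05, 0.95). The patient's ground-truth interaction value
  (mean over images, computed on the true populations) is standardised
  across the cohort to z_i; event times are exponential with rate
  λ0·exp(β_true·z_i) (λ0 = 0.02/month for RFS, 0.012/month for OS — median
  times of roughly 35 and 58 months at z = 0), censoring uniform on
  (0, 60] months, yielding ~40% observed RFS events. Null covariates (age,
  sex, AFP indicator) are drawn independently of the hazard so the screen
  has something to reject. A truth sidecar (JSON) records per-patient ρ, the
  interaction value, z, and β_true.
* **Determinism** — one integer seed drives a `SeedSequence` tree; identical
  config + seed produce byte-identical outputs (tested at file level).

What the generator does *not* emulate: tissue-region geometry (region codes
are labels, not shapes), tumor/stromal cell populations beyond the two
phenotypes, between-image staining batch effects, segmentation errors, and
cell-size exclusion effects. Passing tests therefore validate the
statistical machinery under the stated model, not the biology of any real
cohort; with real data the gating cutoffs in particular must be set per
staining batch.

## Problem sizes and numerical choices

The validation suite runs at the scales the checks were designed for: 50
images for exact oracle equivalence, 200 images for the closed-form and
monotonicity Monte-Carlo (3-standard-error acceptance band), 1000 null
simulations for log-rank type-I error (band [0.03, 0.07] at α = 0.05),
n = 500 with ~20% censoring for Cox recovery (|β̂ − 0.7| ≤ 0.15), and
2 × 100 pipeline replicates at 200 patients for the screen-then-model power
study (≥ 90% selection at β = 0.8, ≤ 10% at β = 0). Tolerances for exact
claims are exact (integer equality of counts, bitwise-equal distances);
stochastic claims state their bands above.

Degenerate inputs are handled explicitly: empty anchor sets yield missing
radial profiles and zero (or missing) interaction values; all-equal patient
values warn and assign everyone high; zero events make the log-rank
statistic a signalled error; constant covariates and event-deficient designs
are fit errors, and complete separation is flagged rather than silently
returned.
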