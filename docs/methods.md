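# Methods

## The weighted benefit index

Each of the 19 treatment goals is rated twice: importance before therapy
(PNQ) and achievement during/after therapy (PBQ), both on a 0–4 ordinal
scale with an additional "does/did not apply to me" option.  The global
score is

PBI = Σᵢ∈C bᵢwᵢ / Σᵢ∈C wᵢ,

where C is the set of items whose recoded importance wᵢ and benefit bᵢ
are both observed.  Subscale scores apply the identical formula
restricted to the subscale's items; restriction is the only reading
consistent with the global definition, and the per-score output reports
`n_items_used` and the denominator so any alternative convention can be
recomputed from the score file.

Recoding is part-specific and applied downstream of parsing, never at
ingestion (the raw three-state distinction must survive I/O because the
two parts treat "does not apply" differently):

* PNQ "does not apply" → importance 0 (a goal that does not apply cannot
  be important); PNQ missing stays missing.
* PBQ "did not apply" → missing (no achievement can be rated); PBQ
  missing stays missing.

Items failing to pair leave numerator and denominator together, which
keeps every defined score inside [0, 4] and makes the score invariant to
rescaling all importances by a positive constant.  A score is reported
undefined — never imputed — when the paired-importance sum is zero or
when fewer than half of the set's items (rounded up) pair.  The
minimum-items rule is a package convention: no published rule exists, a
half-set floor is conservative, and because `n_items_used` is always
reported the rule is fully transparent in the output.  Undefined scores
are excluded from means, medians and the relevance-rate denominator, with
counts reported.  The relevance threshold is inclusive: value ≥ 1.0.

Descriptive conventions: sample SD (n−1) throughout; the "quite/very"
column is the share of levels {3, 4}; the PNQ percentage base includes
not-apply answers (as zeros) while the PBQ base excludes them and a
separate `pct_did_apply` column reports the share of answering
respondents for whom the goal applied.

## Subscale derivation

Exploratory factor analysis runs on the recoded PNQ importance matrix
with listwise deletion (rows with any missing item dropped; at least
p + 1 complete rows required).  Extraction is principal components of the
Pearson correlation matrix — the natural companion of the Kaiser rule,
which retains eigenvalues *strictly* greater than 1 (equality does not
retain).  Iterated principal-axis extraction is available as a
configuration switch for sensitivity analysis.  Explained variance is
100 × (sum of retained eigenvalues)/p.

Varimax rotation uses Kaiser row-normalisation, a convergence tolerance
of 1e−6 on the rotation criterion and at most 200 sweeps; each rotated
factor is reflected so its largest-magnitude loading is positive, which
matches how salient loadings are conventionally printed.  Rotation is
orthogonal, so per-item communalities are invariant (checked to 1e−8 in
the tests).

Items are assigned to the factor with the highest *absolute* rotated
loading.  Exact ties are refused rather than broken arbitrarily: the
caller must supply an explicit override.  Content-based overrides
(assigning an item to a factor with the second-highest loading) and
factor merging (several factors feeding one content-defined subscale, as
in the adolescent three-subscale solution built from five retained
factors) are explicit inputs, recorded with reasons in the assignment
result — the package deliberately does not infer content similarity.
The bundled maps (children: treatment burden, fatigue/social life,
physical symptoms, being outdoors; adolescents: treatment burden,
physical symptoms, psychosocial burden) are the default for scoring;
EFA-derived maps are opt-in.

Cronbach's alpha uses the standard item-variance form with n−1 variances
and listwise deletion, requiring k ≥ 2 items and ≥ 3 complete rows.

## Convergent validity

Variable derivation from visit-1/visit-2 fields (per-respondent missing
values propagate; every cell uses pairwise deletion, so N varies by
cell):

* severity/frequency/duration changes: strict ordinal improvement
  (V2 < V1) → "decreased", ties → "no decrease";
* sleep/activities/performance: restricted to respondents impaired at
  visit 1; V2 normal → "normalised".  Respondents normal at visit 1 have
  no normalisation event to classify and are excluded; counting them as
  "normalised" would be the alternative reading, and the restriction is
  implemented as the single derivation rule of record;
* VAS impairment changes: V2 − V1, continuous in [−10, 10];
* global judgement (physician, patient): categorical, with a fixed
  per-population level configuration — children keep
  much/somewhat better and unchanged, adolescents keep much/somewhat
  better only — rather than data-driven small-cell pruning, keeping the
  battery deterministic.

Test selection by scale level: continuous → Pearson r; dichotomous →
t-test, pooled variance unless Levene's test (mean-centred) has
p < 0.1, then Welch; categorical with > 2 retained levels → one-way
ANOVA with η² = SS_between/SS_total (single-factor design, not partial
η²).  All tests two-sided, significance at p < 0.05, no multiplicity
adjustment.  Cohen's d always uses the pooled SD, whichever t branch
ran.  Group order for d is fixed: worse-outcome first (no-decrease,
not-normalised) so a benefit-sensitive scale yields negative d; for the
two-level global-judgement comparison the better category comes first,
so benefit tracking the judgement yields positive d.  Effect labels are
inclusive at each cut-off on the absolute value (d 0.2/0.5/0.8,
η² 0.01/0.06/0.14, r 0.1/0.3/0.5).

## The synthetic cohort

The generator emulates the structure the analysis assumes, not any real
dataset:

* **Needs.** Per population, item latents follow a simple-structure
  orthogonal factor model over the bundled subscale map with salient
  loading 0.7 (configurable per-item pattern), unique variance filling to
  1.  Latents are cut at thresholds (−1.5, −0.5, 0.5, 1.5) shared across
  items, giving marginal category shares of about
  0.067/0.242/0.383/0.242/0.067.  Optional per-population mean shifts
  (`need_mean_*`, default 0) move the whole profile, emulating the higher
  need level of younger patients.
* **Benefits.** A scalar latent treatment response θ ~ N(0.5, 1) drives
  all benefit items with loading 0.7; same discretisation.  A mean of
  0.5 on the latent scale puts typical benefit ratings in the
  "considerable benefit" region without saturating the scale.
* **Not-apply / missing.** Generated completely at random with
  probabilities 0.05 (PNQ not-apply), 0.05 (PBQ extra not-apply) and 0.02
  (missing) — modest contamination of the kind two-visit paper
  questionnaires show.  PBQ not-apply is additionally forced wherever the
  PNQ answer was not-apply: a goal that did not apply cannot later be
  achieved.  Informative (latent-dependent) non-response is out of scope.
* **Clinical course.** A latent baseline burden b ~ N(0,1) generates the
  visit-1 severity levels, dichotomies and VAS values through fixed
  threshold/affine-clip maps with noise SD 0.5; visit-2 values derive the
  same way from b − 0.8·θ (the `clinical_coupling`), and the global
  judgements derive from θ directly.  This makes clinical improvement
  and benefit ratings share exactly one source of common variance, which
  is what a convergent-validity battery is meant to detect.
* **Demographics.** Sex (male fraction 0.609, the validation study's
  overall share), asthma (0.35, between the two age groups' reported
  shares) and integer ages drawn independently.  Default sample sizes
  are the study's 223 children and 122 adolescents.

Everything is reproducible from the config seed (single `default_rng`
stream), and the two populations are always analysed separately — a
pooled mode is deliberately absent, since the two age groups have
different subscale structures.

What passing tests on this generator do *not* show: robustness to
informative non-response, proxy-response (parent-reported) bias,
non-normal latent distributions, correlated factor structures, or real
item-level behaviour; the generator's orthogonal factors also make the
*global* scale's alpha lower than a real, positively intercorrelated item
pool would show.

## Analytic oracles used in testing

* Boundary scores: all-maximum responses force the index to exactly 4,
  zero benefits to exactly 0.
* Block compound-symmetry correlation matrices have closed-form
  eigenstructure (1 + (k−1)ρ and 1 − ρ), fixing retention counts and
  rotated loadings for the extraction tests.
* Compound-symmetric items give alpha = kρ/(1 + (k−1)ρ)
  (Spearman–Brown); with loading 0.7, latent ρ = 0.49, so a 5-item
  subscale has a latent alpha bound of about 0.83, and discretisation
  attenuates observed alpha below it.
* An exhaustive 3-item grid over all raw response states checks the
  scoring implementation against an independently coded brute-force
  evaluation of recode + pairing + formula.

## Problem sizes

Simulation-based checks use the sizes at which their quantities
stabilise: n = 5000 respondents for factor recovery, n = 20 000 for the
alpha closed form and attenuation direction, 1000 replicates of n = 200
for the battery's null calibration and 200 replicates of n = 300 for its
power under coupling.

## Known limitations

* The generator's discretisation thresholds are shared across items;
  per-item thresholds (differing item difficulties) are possible through
  the config but not defaulted.
* Ordinal items are analysed with Pearson correlations and linear-model
  statistics throughout, mirroring standard practice for this instrument
  family; polychoric alternatives are out of scope.
* The EFA offers no oblique rotations, parallel analysis or confirmatory
  modelling; subscale derivation beyond the highest-loading rule requires
  explicit human overrides.
* Scores are cross-sectional; longitudinal scoring across repeated
  seasons and measurement-invariance testing are out of scope.
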