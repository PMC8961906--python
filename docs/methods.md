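# Methods

## The setting

A claims repository can tabulate, for each of thousands of candidate rare
diseases, the number of distinct patients per calendar year × sex × 5-year
age band, over about a decade. Publication is governed by a cell-size
suppression policy: a cell may not be shown if its count is between 0 and 9.
Everything in this package follows from working with such
disclosure-limited counts: prevalence must be estimated from rounded or
merged values, and natural history must be proxied by the shape of the
patient age distribution, because neither onset nor death age is observable
in claims.

## Disclosure control

**Rounded table.** Every true count is rounded half-up to the nearest 10
(so 14 → 10 and 15 → 20). A count of 0–4 rounds to 0, which may not be
published, so those cells are suppressed; every other cell is published
with its rounded value. The published value of a disclosed cell therefore
differs from the truth by at most 5.

**Coarsened table.** Within one disease-year slice (2 sexes × 18 bands):

1. cells with true count ≥ 10 are published exactly, never merged;
2. non-zero cells below 10 are merged greedily: the two sexes of one age
   band first, then growth across adjacent age bands, sweeping from the
   youngest band upward; a group is closed as soon as its total reaches 10
   and published as one exact merged value;
3. a leftover group that cannot reach 10 is folded into the preceding
   closed group of the same contiguous run if one exists, otherwise its
   cells are suppressed;
4. zero cells are never pulled into groups — a zero cannot help a group
   reach the threshold, and merging a zero with a publishable cell would
   destroy an unmerged disclosure.

The greedy policy is a deterministic choice among the "various merging
patterns" such data admit; its objective is the number of cells published
at original granularity (`disclosure_score`). Because cells ≥ 10 are never
merged, the greedy attains the theoretical maximum of that objective — the
test suite verifies this against a brute-force search over all set
partitions on small slices (exhaustive for up to 3 occupied cells,
seeded-random for 4–6). Merging never crosses disease or year boundaries.
No secondary-suppression audit against differencing the rounded and
coarsened products is attempted; treat the two products as alternative
releases of the same data, not independent ones.

## Name harmonization

Normalization: NFKC width folding and case folding (applied twice, since a
single casefold of rare Unicode can leave a non-normalized residue),
punctuation stripped to spaces, CJK-script synonym keys replaced by
substring (longest first, since such labels carry no token boundaries),
stop words dropped, token-level synonym standardization, whitespace
collapsed. The published order of operations lists case folding last;
folding early is output-equivalent for the specified transformations and
makes idempotence — which a property test enforces on arbitrary strings —
easy to guarantee. Synonym-map targets must be fixed points of
normalization (checked at rule construction), e.g. 遺伝的 → 遺伝.

Matching is exact equality of normalized labels. Expansion adds (i) all
hierarchy descendants of exactly matched terms and (ii) unmatched terms
sharing at least `min_shared_tokens` normalized tokens with an exactly
matched label. The default threshold is 2: a single shared token
("syndrome") would over-match. Tokens are whitespace tokens; spaceless
scripts additionally contribute character bigrams. Stop-word lists and
synonym maps are configuration, not code — real deployments need curated
lists far beyond the illustrative defaults.

## Prevalence

One-year prevalence = (sum of disclosed rounded values over sex and age for
the reference year) / (total national population that year); masked cells
contribute 0, and a disease with every cell masked is flagged
`below_disclosure` rather than dropped. Ten-year prevalence uses the
masked decade-total cube over the *mean annual* population — the decade
denominator convention is otherwise under-determined. Ten-year totals
default to the rounded product (configurable to coarsened). Re-counting
churn inflates the ten-year numerator; it is documented, not corrected.
Prevalence is crude (no age standardization) and carries no confidence
interval.

Ordinal categories use boundaries at 1/1,000,000, 1/100,000, 1/10,000,
6/10,000 and 1/1000, half-open and lower-inclusive (p = 1/1,000,000 falls
in "1–9/1,000,000"); the labels at the boundaries are ambiguous in prose,
so one documented rule is applied everywhere. When a disease carries
several annotated categories, the ordinal median represents them, with
even-length ties resolved to the lower (rarer) category.

Sex ratio is female/male on the two disclosed sex totals. When one sex is
suppressed (true count < 10) while the other is at least 10× the
suppression threshold (≥ 100), the ratio is reported as the qualitative
extreme `F>>M` or `M>>F`; one-sided suppression is the one mechanism by
which the ratio becomes too imbalanced to compute. Both sexes suppressed →
`undefined`.

## Age-distribution patterns

A disease's *diachronic age distribution* is the rounded, disclosed count
summed over the decade and both sexes per band, restricted to ages 0–84
(17 bands; the open 85+ band is dropped) and normalized to unit sum.
Profiles with a disclosed total below `min_total` (default 50) are "Not
applicable" and excluded from clustering: below roughly 50 rounded counts
the 17-band shape is dominated by rounding noise.

Clustering is k-means (Euclidean, 20 restarts, seeded) on the normalized
profiles; the cluster count is the candidate k (default 2–8) with the
highest mean silhouette, ties to the smaller k. k-means on short
equal-length series is the plainest instance of time-series clustering;
DTW-based variants would slot behind the same interface but are not
needed for 17-point profiles. Cluster → pattern labels come from centroid
mass: Congenital if band [0,5) holds the maximum, else Elderly if the
mass-weighted mean age is ≥ 60, else Childhood if the maximum lies in
[5,20), else Acquired; if two of four centroids collide on a label they are
re-ranked by mean age and assigned chronologically.

## Concordance with onset/death annotations

Annotated onset categories are ordered clinically: Antenatal < Neonatal <
Infancy < Childhood < Adolescent < Adult < Elderly (death analogously from
Embryofetal to Elderly). Each pattern owns a predefined range: onset
Congenital ↔ {Antenatal, Neonatal, Infancy}, Childhood ↔ {Childhood,
Adolescent}, Acquired ↔ {Adult}, Elderly ↔ {Elderly}; death Congenital ↔
{Embryofetal, Stillbirth, Infantile}, Childhood ↔ {Early childhood, Late
childhood, Adolescent}, Acquired ↔ {Young adult, Adult}, Elderly ↔
{Elderly}. These ranges are configuration: they are inferred from the
published discordance tables rather than printed as a table anywhere.

A disease is *concordant* on an axis when at least one of its annotated
categories falls inside the pattern's range ("more than one category
included" in the source prose is read as at-least-one, a translation
artifact), *excluded* when the pattern is Not applicable, when a
non-informative blanket category is present ("All ages" for onset, "Normal
life expectancy" or "Any age" for death), or when only "No data available"
/ "Not yet documented" remain; otherwise *discordant*. Every disease gets
exactly one verdict per axis (a partition property the tests enforce).

Strongly discordant diseases are partitioned into four case tables: onset
later / earlier and death later / earlier in the claims data than
annotated. A disease qualifies when the **maximum** ordinal gap between
its informative annotated categories and the pattern's range endpoints is
≥ 2; direction follows the side of that maximal gap. The
nearest-category-with-strict-inequality variant of this rule would reject
one of the published case rows (Childhood pattern with {Stillbirth,
Infantile} death annotations, whose nearest gap is 1), so the
maximum-gap-≥-2 reading is used; both the threshold and the ranges are
configurable.

## Synthetic data: what it emulates, what it does not

The generator defines the study conditions for every test:

* **Panel** — `n_diseases` with archetypes apportioned by largest
  remainder, prevalences log-uniform over a log10 range within [-7, -2]
  (default [-6, -3]: several orders of magnitude around "a few per
  100,000", where most rare diseases sit), sex ratios Beta(4,4) with an 8%
  tail at 0.02 and 0.98 to exercise the F>>M / M>>F sentinels.
* **Population** — a constant, rounded national age pyramid (elderly-heavy,
  ~126 M total, sexes balanced per band).
* **Counts** — independent Poisson per stratum with mean prevalence ×
  population × archetype weight × sex factor. The weight × factor product
  is normalized population-weighted over all strata per year, so the
  expected disease-year total equals prevalence × total population exactly
  for every archetype; a Monte-Carlo test holds the simulated mean to 3
  standard errors of that analytic value.
* **Archetype kernels** — Congenital: exponential decay from birth
  (scale 12 y); Childhood: Gaussian bump at age 10 (σ 7 y); Acquired:
  logistic plateau over ~30–65; Elderly: logistic rise centered at 72;
  Flat: constant. Idealized versions of the five published pattern shapes,
  deliberately well separated so that archetype recovery measures the
  clustering machinery rather than borderline shape ambiguity.
* **Churn** — every stratum mean is inflated by (1 + 2·churn): each
  patient-decade is re-counted K ~ Poisson(2·churn) extra times, so churn
  = 1 reproduces "counted about three times over ten years". The
  mechanism behind real re-counting is not documented anywhere; this is an
  assumption, and it inflates annual counts alongside decade totals.
  Default churn is 0 (annual extractions de-duplicate patients).
* **Vocabulary fixtures** — vocabulary B corrupts the canonical labels only
  with transformations normalization removes (width, punctuation, stop
  words, listed synonyms) plus an exact `unmatched_fraction` of genuinely
  unrelated labels, giving a ground truth on which exact matching must
  score precision = recall = 1.
* **Annotations** — onset/death categories drawn from the archetype's
  predefined range, with a configurable discordant fraction drawn outside
  it and Flat diseases annotated "All ages"/"Any age" (excluded).

Not emulated: patient-level longitudinal identity, insurance-system
artifacts (expense-exempt patients, temporary diagnoses, disease/subtype
double coding), translation error, and any correlation between prevalence
and archetype. Passing tests therefore demonstrate that the *pipeline*
recovers known generating structure through disclosure control — not that
real claims data are free of the biases above.

## Problem sizes and determinism

The reference checks run at desk scale, chosen so each completes in
seconds while retaining statistical power: 200 diseases × 1 year for
category recovery (recovery is ≥ 90% among diseases whose expected
disclosed reference-year count is ≥ 100, computed analytically from the
Poisson masking expectation), 160 diseases × 10 years for archetype
recovery (silhouette selects k = 4 over 2–8; label accuracy ≥ 80%), 1000
random disease-year slices for disclosure safety, and brute-force partition
comparison on ≤ 6-cell slices. Every stochastic step takes an explicit
seed; identical config + inputs give byte-identical outputs, which the CLI
tests assert.

## Known limitations

* The greedy merge is one deterministic policy; published coarsened tables
  produced by a different (e.g. manual) merge are reproduced in value
  semantics but not necessarily in group layout.
* Ten-year prevalence has no churn correction and no de-duplication.
* The concordance ranges and the case-gap threshold encode a reading of
  published discordance tables; other readings are one config edit away.
* Category recovery degrades near class boundaries for diseases whose
  expected counts sit close to the disclosure floor; the `below_disclosure`
  flag marks the extreme of that regime but intermediate attenuation is
  not corrected.
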