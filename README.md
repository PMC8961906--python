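# rareclaims

Cross-disease rare-disease epidemiology from claims-count tables, under
statistical disclosure control.

National health-insurance claims databases can report, for thousands of
rare diseases, the number of patients per calendar year, sex and 5-year age
band. Publishing those counts is constrained by a small-cell suppression
rule: no cell with fewer than 10 patients (including 0) may be shown.
`rareclaims` implements the full analysis pipeline a rare-disease
epidemiologist needs on top of such data:

* **Disclosure control** — two safe table products from one true count
  cube: a *rounded* table (counts rounded half-up to the nearest 10; counts
  0–4 suppressed) and a *coarsened* table (counts ≥ 10 published exactly;
  smaller cells greedily merged — sex pair first, then adjacent age bands —
  until the merged total reaches 10, maximizing the number of values
  published at original granularity).
* **Name harmonization** — label normalization (half-width folding, stop
  word/punctuation removal, synonym standardization such as the Japanese
  variants 遺伝 / 遺伝的 / 遺伝学的 → one "genetic" token), exact matching
  between vocabularies, and recall-oriented expansion via hierarchy
  descendants and shared-token overlap.
* **Prevalence** — one-year prevalence (reference-year disclosed counts /
  national population) and ten-year prevalence (decade totals / mean annual
  population), placed into the six ordinal Orphanet classes
  `<1/1,000,000 … >1/1000`; sex ratios F/M with the qualitative extremes
  `F>>M` / `M>>F` when one sex is suppressed.
* **Natural history** — each disease's decade-summed age distribution over
  ages 0–84 (17 bands) is classified into Congenital / Childhood /
  Acquired / Elderly (or Not applicable below a patient-count floor) by
  k-means clustering with the cluster count chosen by silhouette analysis,
  then scored for concordance against Orphanet-style onset and death
  annotations, including the four discordance-case tables (onset/death
  later/earlier in claims than annotated).
* **Synthetic claims** — a seeded generator of disease panels, population
  tables and Poisson count cubes with the five age-distribution archetypes,
  log-uniform prevalences, variable sex ratios and optional re-counting
  churn, so every stage is testable without restricted data.

## Worked example

```python
from rareclaims import (generate_panel, make_population, simulate_cube,
                        decade_totals, round_table, coarsen_table)
from rareclaims.prevalence import summarize

panel = generate_panel(6, {"Congenital": 0.5, "Acquired": 0.5},
                       prevalence_log_range=(-5.0, -4.0), seed=11)
years = list(range(2009, 2019))
pop = make_population(years)
cube = simulate_cube(panel, pop, years, seed=12)
summary = summarize(round_table(cube), round_table(decade_totals(cube)), pop, 2018)
print(summary.to_string(index=False))
```

```
disease_id  prev_1y  prev_10y    category sex_ratio flags
     D0000 0.000014  0.000133 1–9/100,000     57.33
     D0001 0.000032  0.000317 1–9/100,000    0.5765
     D0002 0.000039  0.000397 1–9/100,000   0.02268
     D0003 0.000011  0.000108 1–9/100,000     2.789
     D0004 0.000014  0.000140 1–9/100,000     3.667
     D0005 0.000084  0.000851 1–9/100,000     2.133
```

Each row is one disease: `prev_1y` is the 2018 prevalence estimated from
the disclosed rounded counts (e.g. D0005: 8.4 per 100,000 against a
generating rate of 8.5 per 100,000), `prev_10y` the decade prevalence
(≈ 10× the annual rate here because the same patients are re-drawn each
year), `category` the ordinal Orphanet class of `prev_1y`, and `sex_ratio`
the female/male ratio — D0000 was generated 98% female, hence 57; D0002 98%
male, hence 0.023.

The cell-merging rule on the canonical worked slice:

```python
# male = 6, female = 7 patients in age band 10-14: neither may be shown,
# but the merged total 13 may.
table = coarsen_table(cube_with_6_and_7)
```

yields one merged group of value 13 covering both cells, and nothing else
disclosed.

A command-line interface covers the same pipeline end to end:

```bash
rareclaims simulate --config config.json   # cube, population, vocabularies, annotations
rareclaims harmonize --config config.json  # normalized exact + expanded matches
rareclaims analyze --config config.json    # masked tables, summary, patterns, figures
```

All figures are also written as tidy TSVs.

## Layout

- `src/rareclaims/synthetic.py` — panels, populations, count cubes, fixtures
- `src/rareclaims/disclosure.py` — rounding, suppression, greedy merging
- `src/rareclaims/harmonize.py` — normalization and matching
- `src/rareclaims/prevalence.py` — prevalence, categories, sex ratios
- `src/rareclaims/age_patterns.py` — clustering, labeling, concordance
- `src/rareclaims/cli.py`, `config.py`, `plots.py` — CLI, config, figures
- `docs/methods.md` — model and design notes
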