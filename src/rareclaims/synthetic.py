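"""Seeded synthetic disease panels and claims-count cubes.

Nationwide claims extracts of rare-disease patient counts are restricted-use
data; this module generates stand-ins with the statistical structure the
downstream analysis assumes: ~10 years of annual counts, two sexes, 5-year
age bands, prevalences spanning several orders of magnitude, five
age-distribution archetypes (Congenital, Childhood, Acquired, Elderly, Flat),
variable sex ratios, and optional re-counting churn in decade totals.

Counts are sampled independently per stratum from a Poisson law whose mean is

    prevalence x population(year, sex, band) x archetype weight x sex factor,

with the weight x factor product normalized (population-weighted, per year)
so the expected disease-year total equals prevalence x total population
exactly. Churn inflates every mean by (1 + 2*churn): each patient-decade is
re-counted K ~ Poisson(2*churn) extra times, so at churn = 1 a surviving
patient is counted about three times over the decade.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AGE_BANDS, AGE_BAND_MID, CUBE_COLUMNS, POPULATION_COLUMNS, SEXES

ARCHETYPES: tuple[str, ...] = ("Congenital", "Childhood", "Acquired", "Elderly", "Flat")

#: Approximate national population (Japan-like, 2018) per 5-year band, millions.
_BAND_POP_MILLIONS = np.array(
    [4.9, 5.2, 5.4, 5.9, 6.1, 6.1, 7.0, 7.8, 8.9, 9.7, 8.4, 7.7, 7.5, 9.2, 8.0, 7.1, 5.4, 5.5]
)


@dataclass(frozen=True)
class DiseaseSpec:
    """Generating parameters of one synthetic disease.

    ``true_prevalence`` is patients per person per year; ``sex_ratio`` is the
    proportion of male patients; ``label_variants`` holds spelling/width/
    synonym variants of the canonical ``label`` (which is always included).
    """

    disease_id: str
    label: str
    true_prevalence: float
    archetype: str
    sex_ratio: float
    label_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.true_prevalence <= 0.01):
            raise ValueError(f"true_prevalence out of (0, 0.01]: {self.true_prevalence}")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError(f"sex_ratio out of [0, 1]: {self.sex_ratio}")
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype: {self.archetype}")
        if not self.label_variants:
            object.__setattr__(self, "label_variants", (self.label,))
        if self.label not in self.label_variants:
            raise ValueError("label_variants must include the canonical label")


def archetype_kernel(archetype: str) -> np.ndarray:
    """Unnormalized age weight per band for one archetype.

    Idealized natural-history shapes: Congenital decays exponentially from
    birth; Childhood peaks around age 10; Acquired is a broad adult plateau
    (ages ~30-65); Elderly rises monotonically from about 60; Flat is
    constant. Normalization happens against the population in
    :func:`simulate_cube`.
    """
    mids = np.asarray(AGE_BAND_MID)
    if archetype == "Congenital":
        return np.exp(-mids / 12.0)
    if archetype == "Childhood":
        return np.exp(-0.5 * ((mids - 10.0) / 7.0) ** 2)
    if archetype == "Acquired":
        rise = 1.0 / (1.0 + np.exp(-(mids - 30.0) / 4.0))
        fall = 1.0 / (1.0 + np.exp((mids - 65.0) / 4.0))
        return rise * fall
    if archetype == "Elderly":
        return 1.0 / (1.0 + np.exp(-(mids - 72.0) / 6.0))
    if archetype == "Flat":
        return np.ones_like(mids)
    raise ValueError(f"unknown archetype: {archetype}")


def make_population(
    years, total: float = 126_000_000, sex_balance: float = 0.5
) -> pd.DataFrame:
    """Constant-over-time population table with a realistic age pyramid.

    The pyramid follows a rounded national age structure (elderly-heavy, as
    in Japan); each band is split between the sexes by ``sex_balance``
    (male share). Counts are persons, positive in every stratum.
    """
    shares = _BAND_POP_MILLIONS / _BAND_POP_MILLIONS.sum()
    rows = []
    for year in years:
        for band, share in zip(AGE_BANDS, shares):
            band_total = total * share
            rows.append((year, "M", band, int(round(band_total * sex_balance))))
            rows.append((year, "F", band, int(round(band_total * (1 - sex_balance)))))
    return pd.DataFrame(rows, columns=POPULATION_COLUMNS)


DEFAULT_ARCHETYPE_MIX = {a: 0.2 for a in ARCHETYPES}


def generate_panel(
    n_diseases: int,
    archetype_mix: dict[str, float] | None = None,
    prevalence_log_range: tuple[float, float] = (-6.0, -3.0),
    seed: int = 0,
) -> list[DiseaseSpec]:
    """Draw a seeded panel of disease specs.

    Archetype counts follow ``archetype_mix`` by largest-remainder rounding;
    prevalences are log-uniform over ``prevalence_log_range`` (log10 scale,
    must lie within [-7, -2]). Sex ratios mix balanced diseases
    (Beta(4, 4)) with a small fraction of strongly sex-linked ones.
    """
    if n_diseases <= 0:
        raise ValueError(f"n_diseases must be positive, got {n_diseases}")
    mix = dict(archetype_mix) if archetype_mix is not None else dict(DEFAULT_ARCHETYPE_MIX)
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError(f"archetype_mix must sum to 1, got {sum(mix.values())!r}")
    lo, hi = prevalence_log_range
    if lo > hi or lo < -7.0 or hi > -2.0:
        raise ValueError(f"prevalence_log_range must lie within [-7, -2]: {prevalence_log_range}")

    # Largest-remainder apportionment in fixed archetype order.
    order = [a for a in ARCHETYPES if mix.get(a, 0.0) > 0.0]
    quotas = {a: n_diseases * mix[a] for a in order}
    counts = {a: int(np.floor(quotas[a])) for a in order}
    leftover = n_diseases - sum(counts.values())
    by_frac = sorted(order, key=lambda a: (-(quotas[a] - counts[a]), order.index(a)))
    for a in by_frac[:leftover]:
        counts[a] += 1

    rng = np.random.default_rng(seed)
    archetypes = [a for a in order for _ in range(counts[a])]
    log_prev = rng.uniform(lo, hi, size=n_diseases)
    u = rng.random(n_diseases)
    balanced = rng.beta(4.0, 4.0, size=n_diseases)
    sex_ratio = np.where(u < 0.08, 0.02, np.where(u > 0.92, 0.98, balanced))

    panel = []
    for i, archetype in enumerate(archetypes):
        label = f"{archetype.lower()} syndrome {i:04d}"
        panel.append(
            DiseaseSpec(
                disease_id=f"D{i:04d}",
                label=label,
                true_prevalence=float(10.0 ** log_prev[i]),
                archetype=archetype,
                sex_ratio=float(sex_ratio[i]),
            )
        )
    return panel


def _stratum_means(
    spec: DiseaseSpec, pop_matrix: np.ndarray, churn: float
) -> np.ndarray:
    """Poisson means for one disease-year, shape (2 sexes, 18 bands).

    Normalized so the total over strata is prevalence x total population
    x (1 + 2*churn).
    """
    kernel = archetype_kernel(spec.archetype)
    sex_factor = np.array([2.0 * spec.sex_ratio, 2.0 * (1.0 - spec.sex_ratio)])
    raw = sex_factor[:, None] * kernel[None, :] * pop_matrix
    total_pop = pop_matrix.sum()
    raw_sum = raw.sum()
    if raw_sum == 0.0:
        return np.zeros_like(raw)
    return spec.true_prevalence * (1.0 + 2.0 * churn) * total_pop * raw / raw_sum


def simulate_cube(
    panel: list[DiseaseSpec],
    population: pd.DataFrame,
    years,
    churn: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a true count cube (full cross-product, zeros stored explicitly)."""
    if not (0.0 <= churn <= 1.0):
        raise ValueError(f"churn must lie in [0, 1]: {churn}")
    years = list(years)
    pop_by_year: dict[int, np.ndarray] = {}
    pop_idx = population.set_index(["year", "sex", "age_band"])["count"]
    for year in years:
        matrix = np.empty((len(SEXES), len(AGE_BANDS)))
        for si, sex in enumerate(SEXES):
            for bi, band in enumerate(AGE_BANDS):
                try:
                    matrix[si, bi] = pop_idx.loc[(year, sex, band)]
                except KeyError:
                    raise ValueError(
                        f"population table missing stratum (year={year}, sex={sex}, "
                        f"age_band={band})"
                    ) from None
        pop_by_year[year] = matrix

    means = np.empty((len(panel), len(years), len(SEXES), len(AGE_BANDS)))
    for di, spec in enumerate(panel):
        for yi, year in enumerate(years):
            means[di, yi] = _stratum_means(spec, pop_by_year[year], churn)

    rng = np.random.default_rng(seed)
    counts = rng.poisson(means)

    index = pd.MultiIndex.from_product(
        [[s.disease_id for s in panel], years, SEXES, AGE_BANDS],
        names=["disease_id", "year", "sex", "age_band"],
    )
    cube = pd.DataFrame(index=index).reset_index()
    cube["count"] = counts.reshape(-1)
    return cube[CUBE_COLUMNS]


# ---------------------------------------------------------------------------
# Vocabulary fixtures


@dataclass
class NoiseRules:
    """How vocabulary B's labels are corrupted relative to the canonical labels.

    Every corruption is one the normalizer is specified to undo (character
    width, punctuation, stop-word insertion, listed synonyms), except for
    ``unmatched_fraction``: that fraction of B terms gets a genuinely
    unrelated label and is flagged unmatched in the ground truth.
    """

    width: bool = True
    punctuation: tuple[str, ...] = (",", ".", "-")
    stop_words: tuple[str, ...] = ("the", "of")
    synonym_variants: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"syndrome": ("disease", "disorder")}
    )
    unmatched_fraction: float = 0.0


@dataclass
class VocabularyFixture:
    """Two vocabularies plus the ground-truth correspondence between them."""

    vocab_a: "DiseaseVocabulary"
    vocab_b: "DiseaseVocabulary"
    truth: set[tuple[str, str]]
    unmatched_b: set[str]


def _to_fullwidth(s: str) -> str:
    out = []
    for ch in s:
        if ch in string.ascii_letters or ch in string.digits:
            out.append(chr(ord(ch) + 0xFEE0))
        else:
            out.append(ch)
    return "".join(out)


def emit_vocabulary_fixtures(
    panel: list[DiseaseSpec],
    noise_rules: NoiseRules | None = None,
    seed: int = 0,
) -> VocabularyFixture:
    """Build two vocabularies with a known correspondence.

    Vocabulary A carries the canonical labels; vocabulary B carries noised
    variants. The returned truth set pairs each A term with its B
    counterpart except for the configured unmatched fraction, whose B labels
    share no content with any canonical label.
    """
    from .harmonize import DiseaseVocabulary  # local import to avoid a cycle

    rules = noise_rules if noise_rules is not None else NoiseRules()
    rng = np.random.default_rng(seed)
    n = len(panel)
    n_unmatched = int(round(rules.unmatched_fraction * n))
    unmatched_idx = set(rng.choice(n, size=n_unmatched, replace=False)) if n_unmatched else set()

    terms_a: dict[str, str] = {}
    terms_b: dict[str, str] = {}
    truth: set[tuple[str, str]] = set()
    unmatched_b: set[str] = set()
    for i, spec in enumerate(panel):
        a_id, b_id = f"A{i:04d}", f"B{i:04d}"
        terms_a[a_id] = spec.label
        if i in unmatched_idx:
            terms_b[b_id] = f"unrelated condition {i:04d}"
            unmatched_b.add(b_id)
            continue
        label = spec.label
        # synonym substitution on whole tokens
        tokens = label.split()
        for ti, tok in enumerate(tokens):
            variants = rules.synonym_variants.get(tok)
            if variants and rng.random() < 0.5:
                tokens[ti] = variants[int(rng.integers(len(variants)))]
        label = " ".join(tokens)
        if rules.stop_words and rng.random() < 0.5:
            stop = rules.stop_words[int(rng.integers(len(rules.stop_words)))]
            tokens = label.split()
            pos = int(rng.integers(len(tokens) + 1))
            tokens.insert(pos, stop)
            label = " ".join(tokens)
        if rules.punctuation and rng.random() < 0.5:
            punct = rules.punctuation[int(rng.integers(len(rules.punctuation)))]
            label = label.replace(" ", punct + " ", 1)
        if rules.width and rng.random() < 0.5:
            label = _to_fullwidth(label)
        terms_b[b_id] = label
        truth.add((a_id, b_id))

    return VocabularyFixture(
        vocab_a=DiseaseVocabulary(terms=terms_a),
        vocab_b=DiseaseVocabulary(terms=terms_b),
        truth=truth,
        unmatched_b=unmatched_b,
    )


# ---------------------------------------------------------------------------
# Orphanet-style synthetic annotations

ONSET_BY_ARCHETYPE = {
    "Congenital": ("Antenatal", "Neonatal", "Infancy"),
    "Childhood": ("Childhood", "Adolescent"),
    "Acquired": ("Adult",),
    "Elderly": ("Elderly",),
}
DEATH_BY_ARCHETYPE = {
    "Congenital": ("Embryofetal", "Stillbirth", "Infantile"),
    "Childhood": ("Early childhood", "Late childhood", "Adolescent"),
    "Acquired": ("Young adult", "Adult"),
    "Elderly": ("Elderly",),
}


def emit_annotations(
    panel: list[DiseaseSpec],
    seed: int = 0,
    discordant_fraction: float = 0.1,
    category_jitter: float = 0.2,
) -> pd.DataFrame:
    """Orphanet-style annotation table for a synthetic panel.

    Onset/death categories are drawn from the archetype's predefined range
    (concordant) except for a ``discordant_fraction`` of diseases annotated
    with a remote category; Flat diseases get the non-informative
    "All ages"/"Any age" labels. The annotated prevalence category equals
    the generating one except for ``category_jitter`` moved one level.
    Multiple categories are pipe-separated in the TSV-ready frame.
    """
    from .age_patterns import DEATH_ORDER, ONSET_ORDER
    from .prevalence import categorize_prevalence

    rng = np.random.default_rng(seed)
    rows = []
    for spec in panel:
        if spec.archetype == "Flat":
            onset, death = ("All ages",), ("Any age",)
        else:
            onset_range = ONSET_BY_ARCHETYPE[spec.archetype]
            death_range = DEATH_BY_ARCHETYPE[spec.archetype]
            if rng.random() < discordant_fraction:
                onset = (
                    [c for c in ONSET_ORDER if c not in onset_range][
                        int(rng.integers(len(ONSET_ORDER) - len(onset_range)))
                    ],
                )
                death = (
                    [c for c in DEATH_ORDER if c not in death_range][
                        int(rng.integers(len(DEATH_ORDER) - len(death_range)))
                    ],
                )
            else:
                onset = (onset_range[int(rng.integers(len(onset_range)))],)
                death = (death_range[int(rng.integers(len(death_range)))],)
        level = int(categorize_prevalence(spec.true_prevalence))
        if rng.random() < category_jitter:
            level = min(6, max(1, level + (1 if rng.random() < 0.5 else -1)))
        rows.append(
            (
                spec.disease_id,
                level,
                "|".join(onset),
                "|".join(death),
            )
        )
    return pd.DataFrame(
        rows, columns=["disease_id", "prevalence_level", "onset_categories", "death_categories"]
    )
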