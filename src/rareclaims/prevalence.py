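"""Prevalence estimation and ordinal categorization from disclosed tables.

One-year prevalence divides a disease's disclosed patient count for a
reference year by the national population that year; ten-year prevalence
uses the decade-total counts over the mean annual population. Estimates are
then placed into the six ordinal Orphanet prevalence classes
(<1/1,000,000 up to >1/1000), boundaries lower-inclusive. Sex ratios are
female/male when both sex totals are publishable and collapse to the
qualitative extremes "F>>M"/"M>>F" when one side is suppressed while the
other is large.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

from .tables import (
    CUBE_COLUMNS,
    STATUS_DISCLOSED,
    STATUS_MERGED,
    TOTAL_YEAR,
    MaskedTable,
)


class PrevalenceCategory(enum.IntEnum):
    """Orphanet's six ordinal prevalence classes, level 1 = rarest."""

    UNDER_1_PER_MILLION = 1
    FROM_1_TO_9_PER_MILLION = 2
    FROM_1_TO_9_PER_100K = 3
    FROM_1_TO_5_PER_10K = 4
    FROM_6_TO_9_PER_10K = 5
    OVER_1_PER_1000 = 6

    @property
    def label(self) -> str:
        return _CATEGORY_LABELS[self]


_CATEGORY_LABELS = {
    PrevalenceCategory.UNDER_1_PER_MILLION: "<1/1,000,000",
    PrevalenceCategory.FROM_1_TO_9_PER_MILLION: "1–9/1,000,000",
    PrevalenceCategory.FROM_1_TO_9_PER_100K: "1–9/100,000",
    PrevalenceCategory.FROM_1_TO_5_PER_10K: "1–5/10,000",
    PrevalenceCategory.FROM_6_TO_9_PER_10K: "6–9/10,000",
    PrevalenceCategory.OVER_1_PER_1000: ">1/1000",
}

#: Lower-inclusive category boundaries (proportion per person).
CATEGORY_BOUNDS = (1e-6, 1e-5, 1e-4, 6e-4, 1e-3)

SEX_RATIO_F_EXTREME = "F>>M"
SEX_RATIO_M_EXTREME = "M>>F"
SEX_RATIO_UNDEFINED = "undefined"

FLAG_BELOW_DISCLOSURE = "below_disclosure"


def categorize_prevalence(p: float) -> PrevalenceCategory:
    """Map a prevalence proportion to its ordinal class (boundaries lower-inclusive)."""
    if p < 0 or not np.isfinite(p):
        raise ValueError(f"prevalence must be a non-negative finite proportion: {p}")
    level = int(np.searchsorted(CATEGORY_BOUNDS, p, side="right")) + 1
    return PrevalenceCategory(level)


def median_orphanet_category(categories) -> PrevalenceCategory:
    """Ordinal median; an even-length tie resolves to the lower category."""
    cats = sorted(PrevalenceCategory(c) for c in categories)
    if not cats:
        raise ValueError("median of an empty category list is undefined")
    return cats[(len(cats) - 1) // 2]


def category_difference(a, b) -> int:
    """Absolute difference of ordinal levels."""
    return abs(int(PrevalenceCategory(a)) - int(PrevalenceCategory(b)))


def _disclosed_totals(cells: pd.DataFrame) -> pd.Series:
    """Per-disease sum of published values; each merge group counted once."""
    disclosed = cells[cells["status"] == STATUS_DISCLOSED]
    direct = disclosed.groupby("disease_id")["value"].sum()
    merged = cells[cells["status"] == STATUS_MERGED]
    grouped = (
        merged.drop_duplicates(subset=["group_id"]).groupby("disease_id")["value"].sum()
        if len(merged)
        else pd.Series(dtype=float)
    )
    diseases = pd.Index(cells["disease_id"].unique(), name="disease_id")
    return direct.reindex(diseases, fill_value=0.0).add(
        grouped.reindex(diseases, fill_value=0.0), fill_value=0.0
    )


def one_year_prevalence(
    table: MaskedTable, population: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Per-disease prevalence for one calendar year from the rounded table.

    Masked cells contribute 0 to the numerator; a disease with every cell
    masked gets prevalence 0 with the ``below_disclosure`` flag. The
    denominator is the total national population of the year.
    """
    if table.kind != "rounded":
        raise ValueError(f"one-year prevalence requires a rounded table, got {table.kind!r}")
    pop_year = population[population["year"] == year]
    if pop_year.empty:
        raise ValueError(f"population table has no year {year}")
    cells = table.cells[table.cells["year"] == year]
    if cells.empty:
        raise ValueError(f"masked table has no year {year}")
    denominator = float(pop_year["count"].sum())
    totals = _disclosed_totals(cells)
    return pd.DataFrame(
        {
            "disease_id": totals.index,
            "prevalence": totals.to_numpy() / denominator,
            "below_disclosure": (totals == 0.0).to_numpy(),
        }
    ).reset_index(drop=True)


def decade_totals(cube: pd.DataFrame) -> pd.DataFrame:
    """Sum a cube over its years into a single pseudo-year (decade-total) cube."""
    totals = (
        cube.groupby(["disease_id", "sex", "age_band"], sort=False)["count"]
        .sum()
        .reset_index()
    )
    totals["year"] = TOTAL_YEAR
    return totals[CUBE_COLUMNS]


def ten_year_prevalence(totals_table: MaskedTable, population: pd.DataFrame) -> pd.DataFrame:
    """Decade prevalence from a masked decade-total table.

    The denominator is the mean annual total population over the decade. At
    churn > 0 re-counted patients inflate the numerator; the estimate is
    reported as-is (documented, not corrected).
    """
    annual_totals = population.groupby("year")["count"].sum()
    if annual_totals.empty:
        raise ValueError("population table is empty")
    denominator = float(annual_totals.mean())
    totals = _disclosed_totals(totals_table.cells)
    return pd.DataFrame(
        {
            "disease_id": totals.index,
            "prevalence": totals.to_numpy() / denominator,
            "below_disclosure": (totals == 0.0).to_numpy(),
        }
    ).reset_index(drop=True)


def sex_ratio(female, male, threshold: int = 10, extreme_factor: int = 10):
    """Female/male ratio, or a qualitative extreme when one side is suppressed.

    ``female``/``male`` are disclosed totals, or ``None`` when suppressed
    (true count below the disclosure threshold). If one side is suppressed
    while the other is at least ``extreme_factor`` times the threshold, the
    ratio is reported as "F>>M" or "M>>F"; with both suppressed (or
    otherwise incomputable) it is "undefined".
    """
    bar = threshold * extreme_factor
    if female is None and male is None:
        return SEX_RATIO_UNDEFINED
    if male is None or male == 0:
        return SEX_RATIO_F_EXTREME if (female or 0) >= bar else SEX_RATIO_UNDEFINED
    if female is None or female == 0:
        return SEX_RATIO_M_EXTREME if male >= bar else SEX_RATIO_UNDEFINED
    return float(female) / float(male)


def sex_totals(table: MaskedTable, year: int | None = None) -> pd.DataFrame:
    """Per-disease disclosed totals by sex; ``None`` when a sex is fully suppressed."""
    cells = table.cells if year is None else table.cells[table.cells["year"] == year]
    rows = []
    for disease, grp in cells.groupby("disease_id", sort=False):
        by_sex = {}
        for sex, sgrp in grp.groupby("sex"):
            disclosed = sgrp[sgrp["status"] == STATUS_DISCLOSED]["value"].sum()
            any_open = (sgrp["status"] == STATUS_DISCLOSED).any()
            by_sex[sex] = float(disclosed) if any_open else None
        rows.append((disease, by_sex.get("F"), by_sex.get("M")))
    return pd.DataFrame(rows, columns=["disease_id", "female", "male"])


def summarize(
    rounded_annual: MaskedTable,
    rounded_totals: MaskedTable,
    population: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Per-disease summary product: prevalences, ordinal category, sex ratio.

    Columns: disease_id, prev_1y, prev_10y, category (ordinal label),
    sex_ratio (number or sentinel), flags.
    """
    one = one_year_prevalence(rounded_annual, population, year).set_index("disease_id")
    ten = ten_year_prevalence(rounded_totals, population).set_index("disease_id")
    ratios = sex_totals(rounded_annual, year=year).set_index("disease_id")
    rows = []
    for disease in one.index:
        p1 = one.loc[disease, "prevalence"]
        flags = [FLAG_BELOW_DISCLOSURE] if one.loc[disease, "below_disclosure"] else []
        ratio = sex_ratio(ratios.loc[disease, "female"], ratios.loc[disease, "male"])
        rows.append(
            (
                disease,
                p1,
                ten.loc[disease, "prevalence"] if disease in ten.index else np.nan,
                categorize_prevalence(p1).label,
                ratio if isinstance(ratio, str) else f"{ratio:.4g}",
                ";".join(flags),
            )
        )
    return pd.DataFrame(
        rows, columns=["disease_id", "prev_1y", "prev_10y", "category", "sex_ratio", "flags"]
    )
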