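"""Shared table containers and TSV serialization.

The pipeline operates on three tidy tables:

* a *count cube* of true (unmasked) patient counts per
  disease x calendar year x sex x 5-year age band,
* a *population table* of person counts per year x sex x age band, and
* *masked tables*, the disclosure-safe views derived from a cube.

All tables travel as pandas DataFrames with fixed column sets; TSV is the
interchange format (masked values are rendered with the ``-`` sentinel used
in published claims tabulations).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: 5-year age bands [0,5) .. [80,85) plus the open-ended 85+ band.
AGE_BANDS: tuple[str, ...] = tuple(f"{5 * k}-{5 * k + 4}" for k in range(17)) + ("85+",)
AGE_BAND_INDEX: dict[str, int] = {b: i for i, b in enumerate(AGE_BANDS)}
#: Band midpoints in years (85+ represented by 90).
AGE_BAND_MID: tuple[float, ...] = tuple(5.0 * k + 2.5 for k in range(17)) + (90.0,)

SEXES: tuple[str, str] = ("M", "F")

#: Sentinel used for suppressed cells in emitted TSVs.
MASK_SENTINEL = "-"

#: Pseudo-year key for decade-total (summed) cubes.
TOTAL_YEAR = -1

CUBE_COLUMNS = ["disease_id", "year", "sex", "age_band", "count"]
POPULATION_COLUMNS = ["year", "sex", "age_band", "count"]
MASKED_COLUMNS = ["disease_id", "year", "sex", "age_band", "status", "value", "group_id"]

STATUS_DISCLOSED = "disclosed"
STATUS_MASKED = "masked"
STATUS_MERGED = "merged"


def validate_cube(cube: pd.DataFrame) -> None:
    """Check a count cube: schema, non-negative integer counts, full key cross-product."""
    missing = set(CUBE_COLUMNS) - set(cube.columns)
    if missing:
        raise ValueError(f"count cube missing columns: {sorted(missing)}")
    if len(cube) and (cube["count"] < 0).any():
        raise ValueError("count cube contains negative counts")
    if len(cube) and not (cube["count"] == cube["count"].astype(int)).all():
        raise ValueError("count cube contains non-integer counts")
    bad_bands = set(cube["age_band"]) - set(AGE_BANDS)
    if bad_bands:
        raise ValueError(f"unknown age bands: {sorted(bad_bands)}")
    n_expected = (
        cube["disease_id"].nunique() * cube["year"].nunique() * len(SEXES) * len(AGE_BANDS)
    )
    if len(cube) != n_expected:
        raise ValueError(
            f"count cube is not a full cross-product: {len(cube)} rows, expected {n_expected}"
        )


def validate_population(population: pd.DataFrame) -> None:
    missing = set(POPULATION_COLUMNS) - set(population.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    if (population["count"] <= 0).any():
        raise ValueError("population table contains non-positive counts")
    keys = population[["year", "sex", "age_band"]]
    if keys.duplicated().any():
        raise ValueError("population table has duplicate (year, sex, age_band) strata")
    for year, grp in population.groupby("year"):
        have = set(zip(grp["sex"], grp["age_band"]))
        want = {(s, b) for s in SEXES for b in AGE_BANDS}
        if have != want:
            lacking = sorted(want - have)
            raise ValueError(f"population table incomplete for year {year}: missing {lacking}")


@dataclass
class MaskedTable:
    """A disclosure-safe view of a count cube.

    ``cells`` holds one row per original cell with a ``status`` of
    ``disclosed`` (value shown at original granularity), ``masked``
    (suppressed, no value) or ``merged`` (value is the exact total of the
    merge group identified by ``group_id``; every member row repeats it).
    """

    kind: str  # "rounded" or "coarsened"
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("rounded", "coarsened"):
            raise ValueError(f"unknown masked-table kind: {self.kind!r}")
        missing = set(MASKED_COLUMNS) - set(self.cells.columns)
        if missing:
            raise ValueError(f"masked table missing columns: {sorted(missing)}")

    def to_tsv(self, path) -> None:
        out = self.cells.copy()
        out["value"] = out["value"].map(
            lambda v: MASK_SENTINEL if pd.isna(v) else str(int(v))
        )
        out["group_id"] = out["group_id"].fillna("")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, kind: str) -> "MaskedTable":
        df = pd.read_csv(path, sep="\t", dtype={"group_id": str}, keep_default_na=False)
        df["value"] = pd.to_numeric(df["value"].replace(MASK_SENTINEL, None), errors="coerce")
        df["group_id"] = df["group_id"].replace("", None)
        return cls(kind=kind, cells=df[MASKED_COLUMNS])


def write_cube_tsv(cube: pd.DataFrame, path) -> None:
    cube[CUBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cube_tsv(path) -> pd.DataFrame:
    cube = pd.read_csv(path, sep="\t")
    validate_cube(cube)
    return cube


def write_population_tsv(population: pd.DataFrame, path) -> None:
    population[POPULATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_population_tsv(path) -> pd.DataFrame:
    population = pd.read_csv(path, sep="\t")
    validate_population(population)
    return population


def band_sort_key(band_series: pd.Series) -> pd.Series:
    """Sort key mapping age-band labels to their chronological index."""
    return band_series.map(AGE_BAND_INDEX)
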