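import numpy as np
import pandas as pd
import pytest

from rareclaims.tables import AGE_BANDS, CUBE_COLUMNS, SEXES


def make_cube(slices: dict) -> pd.DataFrame:
    """Build a full-cross-product cube from sparse slice specs.

    ``slices`` maps (disease_id, year) -> {(sex, age_band): count}; all
    other cells are zero.
    """
    diseases = sorted({d for d, _ in slices})
    years = sorted({y for _, y in slices})
    rows = []
    for d in diseases:
        for y in years:
            cells = slices.get((d, y), {})
            for s in SEXES:
                for b in AGE_BANDS:
                    rows.append((d, y, s, b, cells.get((s, b), 0)))
    return pd.DataFrame(rows, columns=CUBE_COLUMNS)


def random_cube(rng: np.random.Generator, n_slices: int, p_zero=0.35, p_small=0.4,
                max_big=60) -> pd.DataFrame:
    """Cube of ``n_slices`` one-year disease slices with mixed small/large counts."""
    rows = []
    for i in range(n_slices):
        d = f"R{i:04d}"
        for s in SEXES:
            for b in AGE_BANDS:
                u = rng.random()
                if u < p_zero:
                    c = 0
                elif u < p_zero + p_small:
                    c = int(rng.integers(1, 10))
                else:
                    c = int(rng.integers(10, max_big))
                rows.append((d, 2018, s, b, c))
    return pd.DataFrame(rows, columns=CUBE_COLUMNS)


@pytest.fixture(scope="session")
def uniform_population():
    """One-year population with 1e6 persons in every stratum."""
    rows = [(2018, s, b, 1_000_000) for s in SEXES for b in AGE_BANDS]
    return pd.DataFrame(rows, columns=["year", "sex", "age_band", "count"])
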