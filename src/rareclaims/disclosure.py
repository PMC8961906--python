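"""Statistical disclosure control for small-count tables.

Claims-database regulations forbid publishing any cell whose patient count
is below 10 (a value of 0 may not be published either). From one true count
cube this module produces the two disclosable table products:

* **rounded** — every count rounded half-up to the nearest 10; cells whose
  true count rounds to 0 (true 0-4) are suppressed;
* **coarsened** — counts >= 10 published exactly at original granularity;
  smaller non-zero counts greedily merged with neighbors (sex pair within an
  age band first, then adjacent age bands) until the group total reaches 10,
  which is then published as one exact merged value; groups that cannot
  reach 10 are suppressed entirely.

The merge search is a deterministic greedy chosen to maximize the number of
cells published at original granularity: publishable cells (>= 10) are never
merged, zero cells are never pulled into groups (they cannot help a group
reach the threshold), and group growth sweeps age bands from youngest to
oldest, folding a short leftover into the preceding group of the same
contiguous run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    AGE_BANDS,
    MASKED_COLUMNS,
    SEXES,
    STATUS_DISCLOSED,
    STATUS_MASKED,
    STATUS_MERGED,
    MaskedTable,
    validate_cube,
)


def round_half_up(counts, base: int = 10):
    """Round non-negative integers half-up to the nearest multiple of ``base``."""
    arr = np.asarray(counts)
    return (arr + base // 2) // base * base


def round_table(cube: pd.DataFrame, base: int = 10) -> MaskedTable:
    """Rounded tabular product: half-up rounding with suppression of rounded zeros.

    True counts 0..base/2-1 (0-4 for the default base 10) round to 0, which
    may not be published, so those cells are masked; every other cell is
    disclosed with its rounded value.
    """
    validate_cube(cube)
    cells = cube.copy()
    rounded = round_half_up(cells["count"].to_numpy(), base=base)
    masked = rounded == 0
    cells["status"] = np.where(masked, STATUS_MASKED, STATUS_DISCLOSED)
    cells["value"] = np.where(masked, np.nan, rounded.astype(float))
    cells["group_id"] = pd.Series([None] * len(cells), dtype=object)
    return MaskedTable(kind="rounded", cells=cells[MASKED_COLUMNS])


def _coarsen_slice(counts: np.ndarray, threshold: int):
    """Greedy merge of one (disease, year) slice.

    ``counts`` has shape (2 sexes, 18 bands). Returns (status, value,
    group) arrays of the same shape; ``group`` holds -1 outside merge
    groups and a local group index inside them.
    """
    n_sex, n_band = counts.shape
    status = np.empty(counts.shape, dtype=object)
    value = np.full(counts.shape, np.nan)
    group = np.full(counts.shape, -1, dtype=int)

    big = counts >= threshold
    small = (counts >= 1) & (counts < threshold)
    status[big] = STATUS_DISCLOSED
    value[big] = counts[big]
    status[~big & ~small] = STATUS_MASKED  # zeros
    status[small] = STATUS_MASKED  # provisional; merged cells overwritten below

    bands_with_small = [b for b in range(n_band) if small[:, b].any()]
    # maximal runs of consecutive bands containing small cells
    runs: list[list[int]] = []
    for b in bands_with_small:
        if runs and b == runs[-1][-1] + 1:
            runs[-1].append(b)
        else:
            runs.append([b])

    groups: list[list[tuple[int, int]]] = []
    for run in runs:
        run_groups: list[list[tuple[int, int]]] = []
        current: list[tuple[int, int]] = []
        cur_sum = 0
        for b in run:
            for s in range(n_sex):
                if small[s, b]:
                    current.append((s, b))
                    cur_sum += counts[s, b]
            # close the group only at band boundaries so a sex pair merges together
            if cur_sum >= threshold:
                run_groups.append(current)
                current, cur_sum = [], 0
        if current:
            if run_groups:
                run_groups[-1].extend(current)  # fold leftover into the younger neighbor group
            # else: unmergeable remainder stays masked
        groups.extend(run_groups)

    for gid, members in enumerate(groups):
        total = sum(counts[s, b] for s, b in members)
        for s, b in members:
            status[s, b] = STATUS_MERGED
            value[s, b] = total
            group[s, b] = gid
    return status, value, group


def coarsen_table(cube: pd.DataFrame, threshold: int = 10) -> MaskedTable:
    """Coarsened tabular product via greedy cell merging within disease-year slices."""
    validate_cube(cube)
    years = sorted(cube["year"].unique())
    diseases = list(pd.unique(cube["disease_id"]))

    pivot = cube.set_index(["disease_id", "year", "sex", "age_band"])["count"]
    frames = []
    for disease in diseases:
        for year in years:
            counts = np.array(
                [[pivot.loc[(disease, year, s, b)] for b in AGE_BANDS] for s in SEXES],
                dtype=int,
            )
            status, value, group = _coarsen_slice(counts, threshold)
            rows = {
                "disease_id": disease,
                "year": year,
                "sex": np.repeat(SEXES, len(AGE_BANDS)),
                "age_band": np.tile(AGE_BANDS, len(SEXES)),
                "status": status.reshape(-1),
                "value": value.reshape(-1),
                "group_id": [
                    f"{disease}|{year}|g{g}" if g >= 0 else None for g in group.reshape(-1)
                ],
            }
            frames.append(pd.DataFrame(rows))
    cells = pd.concat(frames, ignore_index=True)
    return MaskedTable(kind="coarsened", cells=cells[MASKED_COLUMNS])


def disclosure_score(table: MaskedTable) -> int:
    """Number of cells published at original granularity (unmerged disclosures)."""
    return int((table.cells["status"] == STATUS_DISCLOSED).sum())


def expected_disclosed_rounded_total(means, base: int = 10, tail: float = 1e-12) -> float:
    """Expected sum of disclosed values in a rounded table, given Poisson means.

    For each stratum mean, computes E[round10(N) * 1{N >= base/2}] for
    N ~ Poisson(mean) and returns the sum over strata. Used to predict which
    diseases survive disclosure control with a usable signal.
    """
    means = np.asarray(means, dtype=float).reshape(-1)
    total = 0.0
    for lam in means:
        if lam == 0.0:
            continue
        hi = int(stats.poisson.ppf(1.0 - tail, lam)) + 1
        n = np.arange(base // 2, max(hi, base // 2) + 1)
        total += float((round_half_up(n, base) * stats.poisson.pmf(n, lam)).sum())
    return total
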