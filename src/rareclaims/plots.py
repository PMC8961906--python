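"""Figure and figure-data outputs.

Every figure is also emitted as its underlying tidy TSV so downstream
checks assert numbers, not pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .prevalence import PrevalenceCategory
from .tables import AGE_BANDS


def _save(fig, out_dir: Path, stem: str) -> None:
    fig.savefig(out_dir / f"{stem}.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def patients_histogram(totals: pd.Series, out_dir: Path, stem: str = "patients_histogram") -> pd.DataFrame:
    """Histogram of diseases per disclosed patient count (log10 bins)."""
    positive = totals[totals > 0]
    edges = np.arange(0.5, max(7.0, np.ceil(np.log10(positive.max() + 1))) + 0.5, 0.5) \
        if len(positive) else np.arange(0.5, 7.5, 0.5)
    hist, edges = np.histogram(np.log10(positive), bins=edges)
    data = pd.DataFrame(
        {"log10_count_lo": edges[:-1], "log10_count_hi": edges[1:], "n_diseases": hist}
    )
    data.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], hist, width=np.diff(edges), align="edge", edgecolor="white")
    ax.set_xlabel("log10 disclosed patients (reference year)")
    ax.set_ylabel("number of diseases")
    _save(fig, out_dir, stem)
    return data


def category_heatmap(
    estimated: pd.Series,
    annotated: pd.Series,
    out_dir: Path,
    stem: str = "prevalence_category_heatmap",
) -> pd.DataFrame:
    """Cross-tabulation of estimated vs annotated ordinal prevalence categories."""
    levels = [int(c) for c in PrevalenceCategory]
    cross = pd.crosstab(estimated, annotated).reindex(
        index=levels, columns=levels, fill_value=0
    )
    tidy = cross.stack().rename("n_diseases").reset_index()
    tidy.columns = ["estimated_level", "annotated_level", "n_diseases"]
    tidy.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    sns.heatmap(cross, annot=True, fmt="d", cmap="rocket_r", cbar=False, ax=ax)
    ax.set_xlabel("annotated category (level)")
    ax.set_ylabel("claims-derived category (level)")
    _save(fig, out_dir, stem)
    return tidy


def centroid_plot(centroids: np.ndarray, names: dict[int, str], out_dir: Path,
                  stem: str = "age_pattern_centroids") -> pd.DataFrame:
    """The idealized age-distribution shape of each cluster."""
    bands = AGE_BANDS[: centroids.shape[1]]
    rows = []
    for cid, centroid in enumerate(np.asarray(centroids)):
        for band, v in zip(bands, centroid):
            rows.append((cid, names.get(cid, str(cid)), band, float(v)))
    data = pd.DataFrame(rows, columns=["cluster_id", "pattern", "age_band", "weight"])
    data.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(7, 4))
    for cid, centroid in enumerate(np.asarray(centroids)):
        ax.plot(range(len(bands)), centroid, marker="o", ms=3,
                label=f"{names.get(cid, cid)} (c{cid})")
    ax.set_xticks(range(len(bands)))
    ax.set_xticklabels(bands, rotation=90, fontsize=7)
    ax.set_xlabel("age band")
    ax.set_ylabel("normalized weight")
    ax.legend(fontsize=8)
    _save(fig, out_dir, stem)
    return data


def concordance_heatmap(
    patterns: pd.Series,
    categories: pd.Series,
    order,
    out_dir: Path,
    stem: str,
) -> pd.DataFrame:
    """Cross-tab of claims-derived patterns vs annotated categories (one row per pair)."""
    from .age_patterns import NOT_APPLICABLE, PATTERNS

    cross = pd.crosstab(patterns, categories).reindex(
        index=list(PATTERNS) + [NOT_APPLICABLE], columns=list(order), fill_value=0
    )
    tidy = cross.stack().rename("n_diseases").reset_index()
    tidy.columns = ["pattern", "category", "n_diseases"]
    tidy.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(8, 4))
    sns.heatmap(cross, annot=True, fmt="d", cmap="rocket_r", cbar=False, ax=ax)
    ax.set_xlabel("annotated category")
    ax.set_ylabel("claims-derived pattern")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    _save(fig, out_dir, stem)
    return tidy


def prevalence_distribution(
    estimated: pd.Series,
    annotated_levels: pd.Series,
    out_dir: Path,
    stem: str = "prevalence_distribution",
) -> pd.DataFrame:
    """Compare the distribution of prevalence classes in claims vs annotations."""
    levels = [int(c) for c in PrevalenceCategory]
    est_counts = estimated.value_counts().reindex(levels, fill_value=0)
    ann_counts = annotated_levels.value_counts().reindex(levels, fill_value=0)
    data = pd.DataFrame(
        {"level": levels, "claims": est_counts.to_numpy(), "annotated": ann_counts.to_numpy()}
    )
    data.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(levels))
    ax.bar(x - 0.2, data["claims"], width=0.4, label="claims-derived")
    ax.bar(x + 0.2, data["annotated"], width=0.4, label="annotated")
    ax.set_xticks(x)
    ax.set_xticklabels([PrevalenceCategory(lv).label for lv in levels], rotation=30,
                       ha="right", fontsize=7)
    ax.set_ylabel("number of diseases")
    ax.legend()
    _save(fig, out_dir, stem)
    return data
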