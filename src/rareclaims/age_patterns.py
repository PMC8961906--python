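"""Natural-history classification of diachronic age distributions.

The decade-summed, rounded patient counts by 5-year age band (ages 0-84,
17 bands) form each disease's *diachronic age distribution*. Diseases with
enough disclosed patients are clustered (k-means on the unit-normalized
profiles, cluster count chosen by mean silhouette) and clusters are labeled
with one of four natural-history patterns — Congenital, Childhood, Acquired,
Elderly — by where the centroid's mass sits; diseases below the
applicability threshold are "Not applicable".

Each classified disease is then scored against Orphanet-style onset and
death annotations: concordant when at least one annotated category falls in
the pattern's predefined range, excluded when the annotation is
non-informative ("All ages", "Normal life expectancy", ...), discordant
otherwise. Strongly discordant diseases are partitioned into four case
tables (onset later/earlier, death later/earlier in the claims data than in
the annotations) by the ordinal gap between the annotated categories and
the pattern's range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .tables import AGE_BANDS, AGE_BAND_MID, STATUS_DISCLOSED, MaskedTable

PATTERNS = ("Congenital", "Childhood", "Acquired", "Elderly")
NOT_APPLICABLE = "Not applicable"

N_PROFILE_BANDS = 17  # ages 0-84; the open 85+ band is dropped
_PROFILE_MIDS = np.asarray(AGE_BAND_MID[:N_PROFILE_BANDS])

# Ordinal onset scale in clinical chronology.
ONSET_ORDER = ("Antenatal", "Neonatal", "Infancy", "Childhood", "Adolescent", "Adult", "Elderly")
ONSET_EXCLUDING = frozenset({"All ages"})
ONSET_UNINFORMATIVE = frozenset({"No data available"})
ONSET_VOCAB = frozenset(ONSET_ORDER) | ONSET_EXCLUDING | ONSET_UNINFORMATIVE

DEATH_ORDER = (
    "Embryofetal",
    "Stillbirth",
    "Infantile",
    "Early childhood",
    "Late childhood",
    "Adolescent",
    "Young adult",
    "Adult",
    "Elderly",
)
DEATH_EXCLUDING = frozenset({"Normal life expectancy", "Any age"})
DEATH_UNINFORMATIVE = frozenset({"Not yet documented", "No data available"})
DEATH_VOCAB = frozenset(DEATH_ORDER) | DEATH_EXCLUDING | DEATH_UNINFORMATIVE

#: Predefined correspondence between patterns and annotated category ranges
#: (the red-frame cells of the concordance heatmaps); endpoints inclusive.
ONSET_RANGES = {
    "Congenital": ("Antenatal", "Infancy"),
    "Childhood": ("Childhood", "Adolescent"),
    "Acquired": ("Adult", "Adult"),
    "Elderly": ("Elderly", "Elderly"),
}
DEATH_RANGES = {
    "Congenital": ("Embryofetal", "Infantile"),
    "Childhood": ("Early childhood", "Adolescent"),
    "Acquired": ("Young adult", "Adult"),
    "Elderly": ("Elderly", "Elderly"),
}

#: A discordant disease enters a case table when some informative annotated
#: category sits at least this many ordinal steps outside the pattern's range.
CASE_GAP_THRESHOLD = 2

VERDICT_CONCORDANT = "concordant"
VERDICT_DISCORDANT = "discordant"
VERDICT_EXCLUDED = "excluded"


@dataclass
class AgeProfile:
    """Decade-summed age distribution of one disease over bands [0,5)..[80,85).

    ``values`` is unit-normalized when ``total`` > 0, otherwise all zeros.
    """

    disease_id: str
    values: np.ndarray
    total: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_PROFILE_BANDS,):
            raise ValueError(f"profile must have {N_PROFILE_BANDS} bands")


@dataclass
class PatternAssignment:
    disease_id: str
    pattern: str
    cluster_id: int  # -1 for Not applicable
    silhouette: float  # NaN for Not applicable
    total: float


@dataclass
class OrphanetNaturalHistory:
    """Annotated onset/death categories of one disease."""

    disease_id: str
    onset_categories: frozenset[str] = frozenset()
    death_categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.onset_categories = frozenset(self.onset_categories)
        self.death_categories = frozenset(self.death_categories)
        bad = self.onset_categories - ONSET_VOCAB
        if bad:
            raise ValueError(f"unknown onset categories: {sorted(bad)}")
        bad = self.death_categories - DEATH_VOCAB
        if bad:
            raise ValueError(f"unknown death categories: {sorted(bad)}")


def build_age_profiles(table: MaskedTable, diseases=None) -> list[AgeProfile]:
    """Sum a rounded masked table over years and sexes into per-disease profiles.

    Masked cells contribute 0; the 85+ band is dropped; the recorded total
    is the disclosed rounded count over the 17 retained bands.
    """
    cells = table.cells
    if diseases is not None:
        cells = cells[cells["disease_id"].isin(list(diseases))]
    keep = (cells["status"] == STATUS_DISCLOSED) & (cells["age_band"] != "85+")
    sums = (
        cells[keep]
        .groupby(["disease_id", "age_band"])["value"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=AGE_BANDS[:N_PROFILE_BANDS], fill_value=0.0)
    )
    all_ids = list(pd.unique(cells["disease_id"]))
    profiles = []
    for disease in all_ids:
        if disease in sums.index:
            raw = sums.loc[disease].to_numpy(dtype=float)
        else:
            raw = np.zeros(N_PROFILE_BANDS)
        total = float(raw.sum())
        values = raw / total if total > 0 else raw
        profiles.append(AgeProfile(disease_id=disease, values=values, total=total))
    return profiles


def mark_not_applicable(profiles: list[AgeProfile], min_total: float = 50) -> dict[str, bool]:
    """True where a profile's disclosed total is below the applicability threshold."""
    if min_total <= 0:
        raise ValueError("min_total must be positive")
    return {p.disease_id: p.total < min_total for p in profiles}


@dataclass
class ClusteringResult:
    selected_k: int
    labels: np.ndarray  # per profile, in input order
    centroids: np.ndarray  # shape (selected_k, 17)
    silhouette_by_k: dict[int, float]
    silhouette_per_profile: np.ndarray


def cluster_profiles(
    profiles: list[AgeProfile],
    k_candidates=(2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusteringResult:
    """Centroid clustering of normalized profiles with silhouette-based k selection.

    Runs k-means (Euclidean, ``n_restarts`` initializations, deterministic
    given ``seed``) for each candidate k and keeps the k with the highest
    mean silhouette (ties to the smaller k).
    """
    n = len(profiles)
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("k_candidates is empty")
    if n < 2 or n <= min(k_candidates):
        raise ValueError(
            f"need more applicable profiles ({n}) than the smallest candidate k "
            f"({min(k_candidates)})"
        )
    if any(k < 2 or k > n - 1 for k in k_candidates):
        raise ValueError(f"k_candidates must lie within [2, {n - 1}]: {k_candidates}")
    X = np.vstack([p.values for p in profiles])

    best = None
    silhouette_by_k: dict[int, float] = {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = float("nan")
            continue
        score = float(silhouette_score(X, labels))
        silhouette_by_k[k] = score
        if best is None or score > best[0]:
            best = (score, k, labels, km.cluster_centers_)
    if best is None:
        raise ValueError("silhouette undefined for every candidate k")
    score, k, labels, centroids = best
    per_profile = silhouette_samples(X, labels)
    return ClusteringResult(
        selected_k=k,
        labels=labels,
        centroids=centroids,
        silhouette_by_k=silhouette_by_k,
        silhouette_per_profile=per_profile,
    )


def _mean_age(centroid: np.ndarray) -> float:
    w = np.clip(np.asarray(centroid, dtype=float), 0.0, None)
    total = w.sum()
    if total == 0:
        return float("nan")
    return float((w * _PROFILE_MIDS).sum() / total)


def _rule_label(centroid: np.ndarray) -> str:
    """Pattern by centroid mass location.

    Congenital if the [0,5) band holds the maximum; else Elderly if the
    mass-weighted mean age is >= 60; else Childhood if the maximum lies in
    [5,20); else Acquired.
    """
    peak = int(np.argmax(centroid))
    if peak == 0:
        return "Congenital"
    if _mean_age(centroid) >= 60.0:
        return "Elderly"
    if peak in (1, 2, 3):  # bands 5-9, 10-14, 15-19
        return "Childhood"
    return "Acquired"


def label_clusters(centroids: np.ndarray) -> dict[int, str]:
    """Deterministic cluster -> pattern labels from centroid shape.

    When the rule gives two clusters the same pattern, the colliding
    centroids are re-ordered by mass-weighted mean age and reassigned to the
    chronologically ordered patterns so that (with four clusters) each
    pattern is used once.
    """
    centroids = np.asarray(centroids, dtype=float)
    labels = {i: _rule_label(c) for i, c in enumerate(centroids)}
    if len(centroids) == len(PATTERNS) and len(set(labels.values())) < len(PATTERNS):
        order = sorted(range(len(centroids)), key=lambda i: _mean_age(centroids[i]))
        labels = {i: PATTERNS[rank] for rank, i in enumerate(order)}
    return labels


def assign_patterns(
    profiles: list[AgeProfile],
    k_candidates=(2, 3, 4, 5, 6, 7, 8),
    min_total: float = 50,
    seed: int = 0,
) -> tuple[list[PatternAssignment], ClusteringResult]:
    """Full classification: applicability, clustering, and cluster labeling."""
    na = mark_not_applicable(profiles, min_total=min_total)
    applicable = [p for p in profiles if not na[p.disease_id]]
    result = cluster_profiles(applicable, k_candidates=k_candidates, seed=seed)
    names = label_clusters(result.centroids)
    by_id = {
        p.disease_id: (int(result.labels[i]), float(result.silhouette_per_profile[i]))
        for i, p in enumerate(applicable)
    }
    assignments = []
    for p in profiles:
        if na[p.disease_id]:
            assignments.append(
                PatternAssignment(p.disease_id, NOT_APPLICABLE, -1, float("nan"), p.total)
            )
        else:
            cid, sil = by_id[p.disease_id]
            assignments.append(PatternAssignment(p.disease_id, names[cid], cid, sil, p.total))
    return assignments, result


# ---------------------------------------------------------------------------
# Concordance with Orphanet-style annotations


def _axis_concordance(pattern, categories, order, ranges, excluding, uninformative):
    vocab = frozenset(order) | excluding | uninformative
    cats = set(categories)
    unknown = cats - vocab
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if pattern == NOT_APPLICABLE:
        return VERDICT_EXCLUDED
    if pattern not in ranges:
        raise ValueError(f"unknown pattern: {pattern!r}")
    if cats & excluding:
        return VERDICT_EXCLUDED
    informative = cats - uninformative
    if not informative:
        return VERDICT_EXCLUDED
    idx = {c: i for i, c in enumerate(order)}
    lo, hi = (idx[ranges[pattern][0]], idx[ranges[pattern][1]])
    if any(lo <= idx[c] <= hi for c in informative):
        return VERDICT_CONCORDANT
    return VERDICT_DISCORDANT


def onset_concordance(assignment: PatternAssignment, annotation: OrphanetNaturalHistory) -> str:
    """Verdict for the onset axis: concordant / discordant / excluded."""
    return _axis_concordance(
        assignment.pattern,
        annotation.onset_categories,
        ONSET_ORDER,
        ONSET_RANGES,
        ONSET_EXCLUDING,
        ONSET_UNINFORMATIVE,
    )


def death_concordance(assignment: PatternAssignment, annotation: OrphanetNaturalHistory) -> str:
    """Verdict for the death axis: concordant / discordant / excluded."""
    return _axis_concordance(
        assignment.pattern,
        annotation.death_categories,
        DEATH_ORDER,
        DEATH_RANGES,
        DEATH_EXCLUDING,
        DEATH_UNINFORMATIVE,
    )


def _case_direction(pattern, categories, order, ranges, uninformative, threshold):
    """(direction, gap) for a discordant disease, or (None, gap) below threshold.

    direction "later" = the claims-derived pattern is older than the nearest
    strongly separated annotated category; "earlier" = younger. The gap is
    the maximum ordinal distance from the pattern's range over informative
    annotated categories.
    """
    idx = {c: i for i, c in enumerate(order)}
    lo, hi = (idx[ranges[pattern][0]], idx[ranges[pattern][1]])
    below = max((lo - idx[c] for c in categories if c not in uninformative and idx[c] < lo), default=0)
    above = max((idx[c] - hi for c in categories if c not in uninformative and idx[c] > hi), default=0)
    gap = max(below, above)
    if gap < threshold:
        return None, gap
    return ("later" if below >= above else "earlier"), gap


def discordance_cases(
    assignments: list[PatternAssignment],
    annotations: dict[str, OrphanetNaturalHistory],
    threshold: int = CASE_GAP_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Partition strongly discordant diseases into the four case tables.

    Case 1/2: onset later/earlier in the claims data than annotated;
    Case 3/4: death later/earlier. Only discordant diseases whose maximal
    ordinal gap reaches ``threshold`` are tabulated.
    """
    cases: dict[str, list] = {"case1": [], "case2": [], "case3": [], "case4": []}
    for assignment in assignments:
        annotation = annotations.get(assignment.disease_id)
        if annotation is None:
            continue
        if onset_concordance(assignment, annotation) == VERDICT_DISCORDANT:
            direction, gap = _case_direction(
                assignment.pattern,
                annotation.onset_categories,
                ONSET_ORDER,
                ONSET_RANGES,
                ONSET_UNINFORMATIVE,
                threshold,
            )
            if direction == "later":
                cases["case1"].append((assignment.disease_id, assignment.pattern,
                                       "|".join(sorted(annotation.onset_categories)), gap))
            elif direction == "earlier":
                cases["case2"].append((assignment.disease_id, assignment.pattern,
                                       "|".join(sorted(annotation.onset_categories)), gap))
        if death_concordance(assignment, annotation) == VERDICT_DISCORDANT:
            direction, gap = _case_direction(
                assignment.pattern,
                annotation.death_categories,
                DEATH_ORDER,
                DEATH_RANGES,
                DEATH_UNINFORMATIVE,
                threshold,
            )
            if direction == "later":
                cases["case3"].append((assignment.disease_id, assignment.pattern,
                                       "|".join(sorted(annotation.death_categories)), gap))
            elif direction == "earlier":
                cases["case4"].append((assignment.disease_id, assignment.pattern,
                                       "|".join(sorted(annotation.death_categories)), gap))
    columns = ["disease_id", "pattern", "annotated_categories", "gap"]
    return {name: pd.DataFrame(rows, columns=columns) for name, rows in cases.items()}


def concordance_table(
    assignments: list[PatternAssignment],
    annotations: dict[str, OrphanetNaturalHistory],
) -> pd.DataFrame:
    """Tidy per-disease, per-axis verdict table (columns: disease_id, axis, verdict)."""
    rows = []
    for assignment in assignments:
        annotation = annotations.get(assignment.disease_id)
        if annotation is None:
            continue
        rows.append((assignment.disease_id, "onset", onset_concordance(assignment, annotation)))
        rows.append((assignment.disease_id, "death", death_concordance(assignment, annotation)))
    return pd.DataFrame(rows, columns=["disease_id", "axis", "verdict"])
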