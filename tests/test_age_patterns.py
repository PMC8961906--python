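"""Age-distribution clustering, pattern labeling, and annotation concordance."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rareclaims.age_patterns import (
    CASE_GAP_THRESHOLD,
    DEATH_ORDER,
    NOT_APPLICABLE,
    ONSET_ORDER,
    PATTERNS,
    VERDICT_CONCORDANT,
    VERDICT_DISCORDANT,
    VERDICT_EXCLUDED,
    AgeProfile,
    OrphanetNaturalHistory,
    PatternAssignment,
    assign_patterns,
    build_age_profiles,
    cluster_profiles,
    concordance_table,
    death_concordance,
    discordance_cases,
    label_clusters,
    mark_not_applicable,
    onset_concordance,
)
from rareclaims.disclosure import round_table
from rareclaims.prevalence import decade_totals
from rareclaims.synthetic import DiseaseSpec, generate_panel, make_population, simulate_cube
from rareclaims.tables import AGE_BANDS, SEXES

from conftest import make_cube


def indicator_profile(disease_id, band_index, total=100.0):
    values = np.zeros(17)
    values[band_index] = 1.0
    return AgeProfile(disease_id=disease_id, values=values, total=total)


class TestProfiles:
    def test_single_band_gives_indicator_profile(self):
        cube = make_cube({("d", 2018): {(s, "10-14"): 30 for s in SEXES}})
        profiles = build_age_profiles(round_table(decade_totals(cube)))
        (p,) = profiles
        assert p.total == 60.0
        assert p.values[2] == 1.0 and p.values.sum() == 1.0

    def test_fully_masked_disease_has_zero_total(self):
        cube = make_cube({("d", 2018): {("M", "0-4"): 3}})
        profiles = build_age_profiles(round_table(decade_totals(cube)))
        (p,) = profiles
        assert p.total == 0.0 and not p.values.any()

    def test_open_85_plus_band_is_dropped(self):
        cube = make_cube({("d", 2018): {("M", "85+"): 500, ("M", "0-4"): 30}})
        profiles = build_age_profiles(round_table(decade_totals(cube)))
        (p,) = profiles
        assert p.total == 30.0 and p.values[0] == 1.0

    def test_congenital_disease_peaks_in_first_band(self):
        pop = make_population(range(2009, 2019))
        spec = DiseaseSpec("d", "x", 1e-4, "Congenital", 0.5)
        cube = simulate_cube([spec], pop, range(2009, 2019), seed=33)
        profiles = build_age_profiles(round_table(decade_totals(cube)))
        assert int(np.argmax(profiles[0].values)) == 0


class TestApplicability:
    def test_zero_total_not_applicable(self):
        flags = mark_not_applicable([indicator_profile("d", 0, total=0.0)], min_total=50)
        assert flags["d"]

    def test_boundary_total_is_applicable(self):
        flags = mark_not_applicable([indicator_profile("d", 0, total=50.0)], min_total=50)
        assert not flags["d"]

    def test_lowering_threshold_never_excludes(self):
        profiles = [indicator_profile(f"d{i}", 0, total=float(t)) for i, t in
                    enumerate([0, 10, 50, 500])]
        strict = mark_not_applicable(profiles, min_total=100)
        loose = mark_not_applicable(profiles, min_total=20)
        for d in strict:
            if not strict[d]:
                assert not loose[d]


def brute_force_mean_silhouette(X, labels):
    """Mean silhouette from the definition: a(i) within, b(i) nearest other."""
    D = cdist(X, X)
    scores = []
    for i in range(len(X)):
        same = (labels == labels[i])
        same[i] = False
        if not same.any():
            scores.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestClustering:
    def separated_profiles(self, per_group=6, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        profiles = []
        for g, band in enumerate([0, 4, 9, 15]):
            for j in range(per_group):
                values = np.zeros(17)
                values[band] = 1.0
                values = np.abs(values + rng.normal(0, noise, 17))
                values /= values.sum()
                profiles.append(AgeProfile(f"g{g}_{j}", values, total=1000.0))
        return profiles

    def test_silhouette_selects_true_group_count(self):
        profiles = self.separated_profiles()
        result = cluster_profiles(profiles, k_candidates=(2, 3, 4, 5, 6), seed=1)
        assert result.selected_k == 4
        # perfect recovery: profiles of one group share a cluster
        for g in range(4):
            labels = {result.labels[i] for i, p in enumerate(profiles)
                      if p.disease_id.startswith(f"g{g}_")}
            assert len(labels) == 1

    def test_mean_silhouette_matches_brute_force(self):
        profiles = self.separated_profiles(per_group=5)  # 20 <= 30 profiles
        result = cluster_profiles(profiles, k_candidates=(2, 3, 4), seed=2)
        X = np.vstack([p.values for p in profiles])
        expected = brute_force_mean_silhouette(X, result.labels)
        assert result.silhouette_by_k[result.selected_k] == pytest.approx(expected)
        assert result.silhouette_per_profile.mean() == pytest.approx(expected)

    def test_duplicated_profiles_share_a_cluster(self):
        profiles = self.separated_profiles()
        twin_a = AgeProfile("twin_a", profiles[0].values.copy(), 100.0)
        twin_b = AgeProfile("twin_b", profiles[0].values.copy(), 100.0)
        result = cluster_profiles(profiles + [twin_a, twin_b], k_candidates=(2, 3, 4), seed=3)
        assert result.labels[-1] == result.labels[-2]

    def test_same_seed_is_deterministic(self):
        profiles = self.separated_profiles()
        r1 = cluster_profiles(profiles, k_candidates=(2, 3, 4, 5), seed=4)
        r2 = cluster_profiles(profiles, k_candidates=(2, 3, 4, 5), seed=4)
        assert (r1.labels == r2.labels).all()
        assert r1.selected_k == r2.selected_k

    def test_too_few_profiles_rejected(self):
        profiles = self.separated_profiles(per_group=1)[:3]
        with pytest.raises(ValueError, match="applicable profiles"):
            cluster_profiles(profiles, k_candidates=(4, 5), seed=0)


class TestLabeling:
    def test_indicator_extremes(self):
        first = np.eye(17)[0]
        last = np.eye(17)[16]
        names = label_clusters(np.vstack([first, last]))
        assert names[0] == "Congenital"
        assert names[1] == "Elderly"

    def test_childhood_and_acquired_rules(self):
        child = np.eye(17)[2]  # band 10-14
        adult = np.zeros(17)
        adult[6:13] = 1 / 7  # ages 30-65
        names = label_clusters(np.vstack([child, adult]))
        assert names[0] == "Childhood"
        assert names[1] == "Acquired"

    def test_collision_resolved_by_mean_age_with_four_clusters(self):
        # two "Congenital-looking" centroids among four: chronological reassignment
        c1 = np.eye(17)[0]
        c2 = 0.6 * np.eye(17)[0] + 0.4 * np.eye(17)[3]
        c3 = np.zeros(17); c3[8:12] = 0.25
        c4 = np.eye(17)[16]
        names = label_clusters(np.vstack([c1, c2, c3, c4]))
        assert sorted(names.values()) == sorted(PATTERNS)
        assert names[0] == "Congenital" and names[3] == "Elderly"


class TestConcordance:
    def assignment(self, pattern):
        return PatternAssignment("d", pattern, 0, 0.5, 1000.0)

    def annotation(self, onset=(), death=()):
        return OrphanetNaturalHistory("d", frozenset(onset), frozenset(death))

    def test_red_frame_correspondences_are_concordant(self):
        assert onset_concordance(self.assignment("Congenital"),
                                 self.annotation(onset={"Neonatal"})) == VERDICT_CONCORDANT
        assert death_concordance(self.assignment("Elderly"),
                                 self.annotation(death={"Elderly"})) == VERDICT_CONCORDANT

    def test_remote_categories_are_discordant(self):
        assert onset_concordance(self.assignment("Elderly"),
                                 self.annotation(onset={"Antenatal"})) == VERDICT_DISCORDANT
        assert death_concordance(self.assignment("Childhood"),
                                 self.annotation(death={"Stillbirth", "Infantile"})) == VERDICT_DISCORDANT
        assert death_concordance(self.assignment("Congenital"),
                                 self.annotation(death={"Adult"})) == VERDICT_DISCORDANT

    def test_all_ages_and_not_applicable_are_excluded(self):
        assert onset_concordance(self.assignment("Acquired"),
                                 self.annotation(onset={"All ages"})) == VERDICT_EXCLUDED
        assert onset_concordance(self.assignment(NOT_APPLICABLE),
                                 self.annotation(onset={"Adult"})) == VERDICT_EXCLUDED
        assert death_concordance(self.assignment("Acquired"),
                                 self.annotation(death={"Normal life expectancy"})) == VERDICT_EXCLUDED

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            self.annotation(onset={"Midlife"})

    def test_invariant_to_order_and_duplication(self):
        a = self.annotation(onset={"Neonatal", "Adult"})
        b = OrphanetNaturalHistory("d", frozenset(["Adult", "Neonatal", "Adult"]))
        pat = self.assignment("Congenital")
        assert onset_concordance(pat, a) == onset_concordance(pat, b)

    def test_every_disease_gets_exactly_one_verdict_per_axis(self):
        rng = np.random.default_rng(9)
        onset_choices = list(ONSET_ORDER) + ["All ages", "No data available"]
        death_choices = list(DEATH_ORDER) + ["Any age", "Normal life expectancy"]
        assignments, annotations = [], {}
        for i in range(60):
            pattern = [*PATTERNS, NOT_APPLICABLE][int(rng.integers(5))]
            assignments.append(PatternAssignment(f"d{i}", pattern, 0, 0.1, 100.0))
            annotations[f"d{i}"] = OrphanetNaturalHistory(
                f"d{i}",
                frozenset(rng.choice(onset_choices, size=rng.integers(1, 4), replace=True)),
                frozenset(rng.choice(death_choices, size=rng.integers(1, 4), replace=True)),
            )
        table = concordance_table(assignments, annotations)
        per_axis = table.groupby(["disease_id", "axis"]).size()
        assert (per_axis == 1).all()
        assert len(table) == 120
        assert set(table["verdict"]) <= {VERDICT_CONCORDANT, VERDICT_DISCORDANT, VERDICT_EXCLUDED}


class TestDiscordanceCases:
    def run_cases(self, pattern, onset=(), death=()):
        assignment = PatternAssignment("d", pattern, 0, 0.5, 1000.0)
        annotation = OrphanetNaturalHistory("d", frozenset(onset), frozenset(death))
        cases = discordance_cases([assignment], {"d": annotation})
        return {name for name, df in cases.items() if len(df)}

    def test_onset_later_in_claims_data(self):
        assert self.run_cases("Elderly", onset={"Infancy"}) == {"case1"}
        assert self.run_cases("Acquired", onset={"Antenatal", "Neonatal", "Infancy"}) == {"case1"}

    def test_onset_earlier_in_claims_data(self):
        assert self.run_cases("Congenital", onset={"Adult"}) == {"case2"}
        assert self.run_cases("Congenital", onset={"Adolescent", "Adult", "Elderly"}) == {"case2"}

    def test_death_later_in_claims_data(self):
        assert self.run_cases("Childhood", death={"Stillbirth", "Infantile"}) == {"case3"}
        assert self.run_cases("Elderly", death={"Infantile", "Stillbirth", "Early childhood", "Adolescent"}) == {"case3"}

    def test_death_earlier_in_claims_data(self):
        assert self.run_cases("Congenital", death={"Adult", "Elderly"}) == {"case4"}
        assert self.run_cases("Childhood", death={"Elderly"}) == {"case4"}

    def test_concordant_disease_absent_from_all_cases(self):
        assert self.run_cases("Acquired", onset={"Adult"}, death={"Adult"}) == set()

    def test_mildly_discordant_disease_not_tabulated(self):
        # one ordinal step outside the range: discordant but below the gap threshold
        assert CASE_GAP_THRESHOLD == 2
        assert self.run_cases("Acquired", onset={"Adolescent"}) == set()


def test_end_to_end_archetype_recovery_small_panel():
    """Clustering + labeling recovers generating archetypes on a small panel."""
    mix = {"Congenital": 0.25, "Childhood": 0.25, "Acquired": 0.25, "Elderly": 0.25}
    panel = generate_panel(40, mix, (-5.0, -4.5), seed=55)
    years = list(range(2009, 2019))
    pop = make_population(years)
    cube = simulate_cube(panel, pop, years, seed=56)
    profiles = build_age_profiles(round_table(decade_totals(cube)))
    assignments, result = assign_patterns(profiles, k_candidates=(2, 3, 4, 5, 6), seed=57)
    truth = {s.disease_id: s.archetype for s in panel}
    applicable = [a for a in assignments if a.pattern != NOT_APPLICABLE]
    acc = np.mean([a.pattern == truth[a.disease_id] for a in applicable])
    assert result.selected_k == 4
    assert acc >= 0.8
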