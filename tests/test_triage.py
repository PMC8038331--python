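"""Docking-score triage: RMSD exclusion, ranking, frequencies, selection."""

import numpy as np
import pytest

from galfrag.triage import (
    ScreeningRecord,
    TriageError,
    compute_core_rmsd,
    fragment_frequency,
    parse_candidate_id,
    provenance_from_ids,
    select_representative,
    triage,
)


class TestCoreRMSD:
    def test_identical_points_give_zero(self):
        pts = np.arange(15, dtype=float).reshape(5, 3)
        assert compute_core_rmsd(pts, pts) == 0.0

    def test_rigid_translation_gives_shift_magnitude(self):
        pts = np.arange(15, dtype=float).reshape(5, 3)
        assert compute_core_rmsd(pts, pts + [1.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_matches_per_atom_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        oracle = np.sqrt(sum(np.sum((pa - pb) ** 2) for pa, pb in zip(a, b)) / 5)
        assert compute_core_rmsd(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(TriageError):
            compute_core_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def _records(scores_rmsd):
    return [
        ScreeningRecord(f"GAL-L1-A{i}", s, r) for i, (s, r) in enumerate(scores_rmsd)
    ]


class TestTriage:
    def test_study_statistics_fixture(self, study_score_table):
        report = triage(study_score_table)
        assert report.n_input == 199
        assert report.n_excluded == 8
        assert report.n_ranked == 191
        assert report.score_max == pytest.approx(115.38)
        assert report.score_min == pytest.approx(77.40)
        assert report.n_above_cut == 25
        assert report.n_below_cut == 166
        assert report.n_below_referent == 1

    def test_percentages_consistent_with_counts(self, study_score_table):
        report = triage(study_score_table)
        assert 100 * report.n_below_cut / report.n_ranked == pytest.approx(87, abs=0.5)
        assert 100 * report.n_above_cut / report.n_ranked == pytest.approx(13, abs=0.5)

    def test_boundary_rmsd_is_retained(self):
        report = triage(_records([(90.0, 1.5), (80.0, 1.5)]), rmsd_cut=1.5)
        assert report.n_excluded == 0
        assert report.n_ranked == 2

    def test_above_cut_matches_brute_force(self):
        rng = np.random.default_rng(0)
        recs = _records([(rng.uniform(60, 130), rng.uniform(0, 1.0)) for _ in range(20)])
        report = triage(recs, score_cut=100.0)
        assert report.n_above_cut == sum(1 for r in recs if r.score >= 100.0)

    def test_partition_is_disjoint_and_complete(self, study_score_table):
        report = triage(study_score_table)
        ranked_ids = {r.candidate_id for r in report.ranked}
        excluded_ids = {r.candidate_id for r in report.excluded}
        assert not ranked_ids & excluded_ids
        assert ranked_ids | excluded_ids == {r.candidate_id for r in study_score_table}

    def test_rank_order_non_increasing_and_ties_lexicographic(self):
        recs = _records([(90.0, 0.1), (95.0, 0.1)])
        recs.append(ScreeningRecord("GAL-L2-B0", 90.0, 0.1))
        report = triage(recs)
        scores = [r.score for r in report.ranked]
        assert scores == sorted(scores, reverse=True)
        tied = [r.candidate_id for r in report.ranked if r.score == 90.0]
        assert tied == sorted(tied)
        assert [r.rank for r in report.ranked] == [1, 2, 3]

    def test_excluded_records_carry_no_rank(self, study_score_table):
        report = triage(study_score_table)
        assert all(r.rank is None and r.excluded for r in report.excluded)

    def test_empty_input_rejected(self):
        with pytest.raises(TriageError, match="empty"):
            triage([])

    def test_duplicate_ids_rejected(self):
        recs = [ScreeningRecord("X", 90, 0.1), ScreeningRecord("X", 80, 0.2)]
        with pytest.raises(TriageError, match="duplicate"):
            triage(recs)

    def test_negative_rmsd_rejected(self):
        with pytest.raises(TriageError):
            ScreeningRecord("X", 90, -0.1)


STUDY_TOP = [
    "GAL-L10-Ar1a",
    "GAL-L10-Ar1b",
    "GAL-L10-Ar1c",
    "GAL-L10-Ar1d",
    "GAL-L10-Ar1e",
    "GAL-L10-Ar1f",
    "GAL-L10-Ar1g",
    "GAL-L2-Ar1h",
    "GAL-L3-Ar1i",
    "GAL-L4-Ar2a",
]


class TestFragmentFrequency:
    def test_study_composition(self):
        prov = provenance_from_ids(STUDY_TOP)
        groups, linkers = fragment_frequency(STUDY_TOP, prov)
        assert groups["Ar1"] == 9
        assert linkers["L10"] == 7
        assert sum(groups.values()) == sum(linkers.values()) == 10

    def test_single_candidate(self):
        top = ["GAL-L1-Ar5a"]
        groups, linkers = fragment_frequency(top, provenance_from_ids(top))
        assert dict(groups) == {"Ar5": 1}
        assert dict(linkers) == {"L1": 1}

    def test_matches_hand_tally(self):
        top = ["GAL-L1-Ar1a", "GAL-L1-Ar2a", "GAL-L2-Ar1b", "GAL-L2-Ar1c",
               "GAL-L3-Ar3a", "GAL-L1-Ar1d", "GAL-L2-Ar2b", "GAL-L1-Ar1e"]
        groups, linkers = fragment_frequency(top, provenance_from_ids(top))
        assert dict(groups) == {"Ar1": 5, "Ar2": 2, "Ar3": 1}
        assert dict(linkers) == {"L1": 4, "L2": 3, "L3": 1}

    def test_missing_provenance_rejected(self):
        with pytest.raises(TriageError, match="provenance"):
            fragment_frequency(["GAL-L1-Ar1a"], {})

    def test_candidate_id_parsing(self):
        assert parse_candidate_id("GAL-L10-Ar1a") == ("L10", "Ar1", "Ar1a")
        assert parse_candidate_id("GAL-L901-Xg1a") == ("L901", "Xg1", "Xg1a")
        with pytest.raises(TriageError):
            parse_candidate_id("not-an-id")


class TestSelectRepresentative:
    def test_study_fixture_selects_basic_variant_lead(self, registry):
        prov = provenance_from_ids(STUDY_TOP)
        assert select_representative(STUDY_TOP, prov, registry) == "GAL-L10-Ar1a"

    def test_single_candidate_top_list(self):
        top = ["GAL-L7-Ar3a"]
        assert select_representative(top, provenance_from_ids(top)) == "GAL-L7-Ar3a"

    def test_fallback_without_basic_variant(self):
        # modal group Ar1, modal linker L10, but no "a" variant anywhere:
        # documented fallback (3) picks the highest-ranked Ar1 member
        top = ["GAL-L10-Ar1b", "GAL-L10-Ar1c", "GAL-L2-Ar1d", "GAL-L10-Ar2b"]
        prov = provenance_from_ids(top)
        assert select_representative(top, prov) == "GAL-L10-Ar1b"

    def test_fallback_basic_variant_off_modal_linker(self):
        # "a" variant of the modal group exists but not on the modal linker:
        # fallback (2) prefers it over higher-ranked substituted variants
        top = ["GAL-L10-Ar1b", "GAL-L10-Ar1c", "GAL-L2-Ar1a", "GAL-L10-Ar2a"]
        prov = provenance_from_ids(top)
        assert select_representative(top, prov) == "GAL-L2-Ar1a"

    def test_empty_top_list_rejected(self):
        with pytest.raises(TriageError, match="empty"):
            select_representative([], {})
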