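"""Profile-weighted scoring, z-selection, enrichment, and reporting."""

import pytest

from qsalvage.association import FamilyAssociationStats, NeighborhoodRecord
from qsalvage.profiler import MarkerSet, classify_profile
from qsalvage.scoring import (
    annotate_selection, build_report, cluster_enrichment, score_candidates,
    select_candidates,
)
from qsalvage.ssn import SSNNode, build_network

MARKERS = MarkerSet()


def profile_for(genome, present):
    row = {m: (m in present) for m in MARKERS.all_markers()}
    return classify_profile(genome, row, MARKERS)


def gap_salvager(genome):
    return profile_for(genome, ("bTGT",))          # weight 2.0


def non_user(genome):
    return profile_for(genome, ())                 # weight 0.0


def neigh(family, protein, genome, distance=1, sig="s1"):
    return NeighborhoodRecord(sig, "bTGT", protein, frozenset({family}),
                              distance, genome)


def stats_for(families, passes=True, median=1.0, ratio=0.5):
    return [
        FamilyAssociationStats(f, 1, 1, median, 100, ratio, passes)
        for f in families
    ]


class TestScoreCandidates:
    def _four_family_setup(self):
        """Raw scores {10, 2, 2, 2} via gap-salvager occurrences (weight 2)."""
        profiles = [gap_salvager(f"g{i}") for i in range(5)]
        records = [neigh("FamA", f"a{i}", f"g{i}") for i in range(5)]
        for fam in ("FamB", "FamC", "FamD"):
            records.append(neigh(fam, f"{fam}_p", "g0"))
        return stats_for(["FamA", "FamB", "FamC", "FamD"]), records, profiles

    def test_hand_computed_z_scores(self):
        stats, records, profiles = self._four_family_setup()
        scores = score_candidates(stats, records, profiles)
        z = {c.family_accession: c.z_score for c in scores}
        assert z == {"FamA": 1.5, "FamB": -0.5, "FamC": -0.5, "FamD": -0.5}
        assert [c.selected for c in scores] == [True, False, False, False]
        assert scores[0].family_accession == "FamA"

    def test_equal_raw_scores_degenerate_to_zero(self):
        profiles = [gap_salvager("g0")]
        records = [neigh(f, f"{f}_p", "g0") for f in ("FamA", "FamB")]
        scores = score_candidates(stats_for(["FamA", "FamB"]), records, profiles)
        assert all(c.z_score == 0.0 and not c.selected for c in scores)

    def test_non_user_occurrences_score_zero(self):
        profiles = [non_user("g0"), gap_salvager("g1")]
        records = [neigh("FamA", "pA", "g0"), neigh("FamB", "pB", "g1")]
        scores = score_candidates(stats_for(["FamA", "FamB"]), records, profiles)
        raw = {c.family_accession: c.raw_score for c in scores}
        assert raw == {"FamA": 0.0, "FamB": 2.0}

    def test_duplicate_protein_counts_once(self):
        profiles = [gap_salvager("g0")]
        records = [neigh("FamA", "pA", "g0", sig="s1"),
                   neigh("FamA", "pA", "g0", sig="s2"),
                   neigh("FamB", "pB", "g0")]
        scores = score_candidates(stats_for(["FamA", "FamB"]), records, profiles)
        raw = {c.family_accession: c.raw_score for c in scores}
        assert raw["FamA"] == raw["FamB"] == 2.0

    def test_missing_profile_rejected(self):
        records = [neigh("FamA", "pA", "gX")]
        with pytest.raises(ValueError, match="gX"):
            score_candidates(stats_for(["FamA"]), records, [])

    def test_z_invariant_under_weight_rescaling(self):
        stats, records, profiles = self._four_family_setup()
        base = score_candidates(stats, records, profiles)
        scaled_weights = {"salvager_gap": 6.0, "salvager": 3.0,
                          "de_novo": 0.75, "non_user": 0.0}
        scaled = score_candidates(stats, records, profiles, scaled_weights)
        for a, b in zip(base, scaled):
            assert a.family_accession == b.family_accession
            assert a.z_score == pytest.approx(b.z_score)


class TestSelection:
    def _score(self, z, passes=True, median=1.0):
        from qsalvage.scoring import CandidateScore

        return CandidateScore(
            family_accession="Fam", raw_score=z, z_score=z, selected=passes,
            evidence=(), fused=False, passes_filters=passes,
            median_distance=median, clustering_ratio=0.01, n_occurrences=3,
        )

    def test_z_exactly_one_is_selected(self):
        assert select_candidates([self._score(1.0)]) != []

    def test_z_just_below_one_excluded(self):
        assert select_candidates([self._score(0.99)]) == []

    def test_filter_failure_excludes_and_records_reason(self):
        (annotated,) = annotate_selection([self._score(1.4, passes=False,
                                                       median=3.0)])
        assert not annotated.selected
        assert "filters" in annotated.exclusion_reason

    def test_known_transporters_kept_as_positive_controls(self):
        from dataclasses import replace

        s = replace(self._score(2.0), family_accession="PF02592")
        (kept,) = select_candidates([s])
        assert kept.positive_control


class TestClusterEnrichment:
    def _ssn(self, members):
        nodes = {m[0]: SSNNode(m[0], tuple(m), {}) for m in members}
        return build_network(nodes, [], 0)

    def test_percentages_from_counts(self):
        ssn = self._ssn([["s1"]])
        records = [neigh("FamA", f"a{i}", "g", sig="s1") for i in range(8)]
        records += [neigh("FamB", f"b{i}", "g", sig="s1") for i in range(2)]
        (e,) = cluster_enrichment(ssn, records, {"FamA", "FamB"})
        assert dict(e.per_family_percentage) == {"FamA": 80.0, "FamB": 20.0}
        assert e.total_candidate_occurrences == 10

    def test_single_family_is_hundred_percent(self):
        ssn = self._ssn([["s1"]])
        (e,) = cluster_enrichment(ssn, [neigh("FamA", "a", "g")], {"FamA"})
        assert dict(e.per_family_percentage) == {"FamA": 100.0}

    def test_cluster_without_candidates_reports_zero(self):
        ssn = self._ssn([["s1"]])
        (e,) = cluster_enrichment(ssn, [], {"FamA"})
        assert e.total_candidate_occurrences == 0
        assert e.per_family_percentage == ()

    def test_percentages_sum_to_hundred(self):
        ssn = self._ssn([["s1"], ["s2"]])
        records = [neigh("FamA", f"a{i}", "g", sig="s1") for i in range(3)]
        records += [neigh("FamB", f"b{i}", "g", sig="s1") for i in range(4)]
        records += [neigh("FamC", "c0", "g", sig="s2")]
        for e in cluster_enrichment(ssn, records, {"FamA", "FamB", "FamC"}):
            if e.total_candidate_occurrences:
                assert sum(p for _, p in e.per_family_percentage) == pytest.approx(
                    100.0, abs=0.01)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            cluster_enrichment(self._ssn([["s1"]]), [], set())


class TestBuildReport:
    def test_empty_report_keeps_header(self):
        df = build_report([], [], [], [])
        assert list(df.columns)[:3] == ["rank", "family_accession", "z_score"]
        assert df.empty

    def test_dominating_cluster_count(self):
        from qsalvage.scoring import ClusterEnrichment

        stats, records, profiles = TestScoreCandidates()._four_family_setup()
        scores = score_candidates(stats, records, profiles)
        enrich = [
            ClusterEnrichment(1, 10, (("FamA", 70.0), ("FamB", 30.0))),
            ClusterEnrichment(2, 10, (("FamA", 60.0), ("FamB", 40.0))),
            ClusterEnrichment(3, 10, (("FamB", 100.0),)),
        ]
        df = build_report(scores, enrich, [], profiles)
        assert df.loc[df.family_accession == "FamA", "dominates"].item() == "2/3"

    def test_planted_truth_run_ranks_planted_first(self, small_pangenome):
        from qsalvage.association import extract_neighborhoods, family_stats
        from qsalvage.profiler import call_presence, profile_table
        from qsalvage.synthetic import family_sizes_from_records

        pg = small_pangenome
        genomes = sorted({r.genome_id for r in pg.records})
        profiles = profile_table(call_presence(pg.hits, genomes, MARKERS), MARKERS)
        sig = {m: MARKERS.accessions_for(m) for m in MARKERS.signature_markers}
        records = extract_neighborhoods(pg.records, sig, 10)
        stats = family_stats(records, family_sizes_from_records(pg.records))
        scores = score_candidates(stats, records, profiles)
        assert scores[0].family_accession == pg.config.planted_family
        assert scores[0].selected
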