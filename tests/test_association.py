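"""Gene-neighborhood extraction, clustering statistics, and fusion detection."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from qsalvage.association import (
    detect_fusions, extract_neighborhoods, family_stats,
)
from qsalvage.records import DomainHit, ProteinRecord
from conftest import make_contig

SIG = {"bTGT": ["bTGT"]}


def brute_force_neighbors(records, sig_accs, window, circular=frozenset()):
    """O(n^2) all-pairs reference scan."""
    flat = set()
    by_contig = {}
    for r in records:
        by_contig.setdefault((r.genome_id, r.contig_id), []).append(r)
    acc_set = {a for accs in sig_accs.values() for a in accs}
    for (g, c), genes in by_contig.items():
        span = max(x.gene_index for x in genes) + 1
        for a in genes:
            if not (a.families & acc_set):
                continue
            for b in genes:
                if b.protein_id == a.protein_id:
                    continue
                d = abs(a.gene_index - b.gene_index)
                if c in circular:
                    d = min(d, span - d)
                if 1 <= d <= window:
                    flat.add((a.protein_id, b.protein_id, d))
    return flat


def as_set(neigh):
    return {(r.signature_protein_id, r.neighbor_protein_id, r.gene_distance)
            for r in neigh}


class TestExtractNeighborhoods:
    def test_window_two_around_signature(self):
        contig = make_contig("g", "c", [["A"], ["bTGT"], ["B"], ["C"]])
        neigh = extract_neighborhoods(contig, SIG, window=2)
        got = {(r.neighbor_protein_id, r.gene_distance) for r in neigh}
        assert got == {("g_c_p0", 1), ("g_c_p2", 1), ("g_c_p3", 2)}

    def test_contig_end_truncates_window(self):
        contig = make_contig("g", "c", [["bTGT"], ["A"]])
        neigh = extract_neighborhoods(contig, SIG, window=3)
        assert [(r.neighbor_protein_id, r.gene_distance) for r in neigh] == [
            ("g_c_p1", 1)
        ]

    def test_circular_contig_wraps_distances(self):
        contig = make_contig("g", "c", [["bTGT"], ["A"], ["B"], ["C"]])
        neigh = extract_neighborhoods(contig, SIG, window=2,
                                      circular_contigs={"c"})
        got = {(r.neighbor_protein_id, r.gene_distance) for r in neigh}
        assert got == {("g_c_p1", 1), ("g_c_p2", 2), ("g_c_p3", 1)}

    def test_signature_neighbors_are_flagged(self):
        contig = make_contig("g", "c", [["bTGT"], ["bTGT"], ["A"]])
        neigh = extract_neighborhoods(contig, SIG, window=2)
        flags = {r.neighbor_protein_id: r.neighbor_is_signature for r in neigh}
        assert flags["g_c_p1"] is True and flags["g_c_p2"] is False

    def test_unknown_marker_without_accessions_rejected(self):
        contig = make_contig("g", "c", [["bTGT"]])
        with pytest.raises(ValueError, match="QueX"):
            extract_neighborhoods(contig, {"QueX": []}, window=2)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), window=st.integers(1, 12),
           circular=st.booleans())
    def test_equals_brute_force_scan(self, seed, window, circular):
        rng = random.Random(seed)
        records = []
        circ = set()
        for g in range(3):
            n = rng.randint(2, 25)
            fams = [[rng.choice(["bTGT", "PF1", "PF2", ""])] for _ in range(n)]
            fams = [[f for f in fs if f] for fs in fams]
            records += make_contig(f"g{g}", f"c{g}", fams)
            if circular and rng.random() < 0.5:
                circ.add(f"c{g}")
        neigh = extract_neighborhoods(records, SIG, window, circ)
        assert as_set(neigh) == brute_force_neighbors(records, SIG, window, circ)

    @settings(max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 1000), w=st.integers(1, 8))
    def test_monotone_in_window(self, seed, w):
        rng = random.Random(seed)
        fams = [[rng.choice(["bTGT", "PF1"])] for _ in range(20)]
        records = make_contig("g", "c", fams)
        small = as_set(extract_neighborhoods(records, SIG, w))
        large = as_set(extract_neighborhoods(records, SIG, w + 3))
        assert small <= large


class TestFamilyStats:
    def _neigh(self, distances, family="PF1", distinct=True):
        contig = make_contig(
            "g", "c",
            [["bTGT"]] + [[] for _ in range(max(distances))],
        )
        from qsalvage.association import NeighborhoodRecord

        return [
            NeighborhoodRecord(
                signature_protein_id="g_c_p0",
                signature_marker="bTGT",
                neighbor_protein_id=f"n{i if distinct else 0}",
                neighbor_families=frozenset({family}),
                gene_distance=d,
                genome_id="g",
            )
            for i, d in enumerate(distances)
        ]

    def test_median_two_passes_distance_filter(self):
        (s,) = family_stats(self._neigh([1, 2, 5]), {"PF1": 1000})
        assert s.median_distance == 2.0

    def test_median_three_fails_distance_filter(self):
        (s,) = family_stats(self._neigh([1, 3, 5]), {"PF1": 3})
        assert s.median_distance == 3.0
        assert not s.passes_filters

    def test_even_count_median_is_mean_of_central_pair(self):
        (s,) = family_stats(self._neigh([1, 4]), {"PF1": 3})
        assert s.median_distance == 2.5

    def test_ratio_just_above_threshold_passes(self):
        (s,) = family_stats(self._neigh([1, 1, 2]), {"PF1": 1000})
        assert s.clustering_ratio == pytest.approx(0.003)
        assert s.passes_filters

    def test_ratio_exactly_at_threshold_fails(self):
        (s,) = family_stats(self._neigh([1, 2]), {"PF1": 1000})
        assert s.clustering_ratio == pytest.approx(0.002)
        assert not s.passes_filters

    def test_distinct_proteins_counted_once_in_ratio(self):
        (s,) = family_stats(self._neigh([1, 2, 2], distinct=False), {"PF1": 10})
        assert s.clustering_ratio == pytest.approx(0.1)
        assert s.n_neighbor_occurrences == 3

    def test_zero_family_size_rejected(self):
        with pytest.raises(ValueError, match="size 0"):
            family_stats(self._neigh([1]), {"PF1": 0})

    def test_permutation_invariant(self):
        neigh = self._neigh([5, 1, 2, 4, 3])
        a = family_stats(neigh, {"PF1": 100})
        b = family_stats(list(reversed(neigh)), {"PF1": 100})
        assert a == b


def protein_with_domains(pid, length, domains, genome="g"):
    return ProteinRecord(pid, genome, "c", 0, "+", length,
                         domains=tuple(DomainHit(*d) for d in domains))


class TestDetectFusions:
    SIGS = {"bTGT"}
    TRANS = {"PF07690", "PF03176"}

    def test_two_domain_protein_in_length_window_is_called(self):
        p = protein_with_domains(
            "Tp1", 800, [("bTGT", 10, 380), ("PF07690", 420, 790)])
        (call,) = detect_fusions([p], self.SIGS, self.TRANS)
        assert call.partner_domains == frozenset({"PF07690"})
        assert call.domain_order == ("bTGT", "PF07690")

    @pytest.mark.parametrize("length", [450, 2100])
    def test_length_bounds_exclude(self, length):
        p = protein_with_domains(
            "p", length, [("bTGT", 10, 200), ("PF07690", 250, length - 5)])
        assert detect_fusions([p], self.SIGS, self.TRANS) == []

    def test_signature_alone_is_not_a_fusion(self):
        p = protein_with_domains("p", 800, [("bTGT", 10, 380)])
        assert detect_fusions([p], self.SIGS, self.TRANS) == []

    def test_heavily_overlapping_domains_rejected_as_artifact(self):
        p = protein_with_domains(
            "p", 800, [("bTGT", 10, 400), ("PF07690", 50, 380)])
        assert detect_fusions([p], self.SIGS, self.TRANS) == []

    def test_order_independent_and_idempotent(self):
        ps = [
            protein_with_domains("a", 800, [("bTGT", 1, 300), ("PF07690", 350, 700)]),
            protein_with_domains("b", 600, [("PF03176", 1, 250), ("bTGT", 300, 590)]),
        ]
        once = detect_fusions(ps, self.SIGS, self.TRANS)
        again = detect_fusions(list(reversed(ps)), self.SIGS, self.TRANS)
        assert once == again
        assert [c.protein_id for c in once] == ["a", "b"]
        assert once[1].domain_order == ("PF03176", "bTGT")
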