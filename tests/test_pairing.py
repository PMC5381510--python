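import numpy as np
import pytest

from mapbridge.errors import MapValidationError
from mapbridge.linkage_io import MarkerAlignment, MarkerKey
from mapbridge.mapping import FilterMode, filter_alignments
from mapbridge.pairing import (
    MarkerPair,
    build_oxford_grid,
    pair_closest_without_replacement,
    pair_homeolog_mode,
    reciprocal_best_hit_pairs,
)
from tests.conftest import make_map


def aln(species, mid, contig="c1", start=0, lg="LG1", cm=0.0, mapq=60, n_hits=1):
    return MarkerAlignment(MarkerKey(species, lg, cm, mid), contig, start, mapq, n_hits)


def greedy_oracle(aln_a, aln_b, max_dist):
    """Independent simulation: repeatedly take the globally closest unused
    cross-species pair (ties by contig, lower coordinate, marker ids)."""
    used_a, used_b, pairs = set(), set(), []
    while True:
        best = None
        for a in aln_a:
            if a.marker_key in used_a:
                continue
            for b in aln_b:
                if b.marker_key in used_b or a.contig != b.contig:
                    continue
                d = abs(a.start_bp - b.start_bp)
                if d > max_dist:
                    continue
                key = (d, a.contig, min(a.start_bp, b.start_bp),
                       a.marker_key.marker_id, b.marker_key.marker_id)
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:
            return pairs
        _, a, b = best
        used_a.add(a.marker_key)
        used_b.add(b.marker_key)
        pairs.append((a.marker_key, b.marker_key))


def random_instance(rng, n_a, n_b, n_contigs=3, span=5000):
    A = [aln("a", f"a{i}", f"c{rng.integers(0, n_contigs)}",
             int(rng.integers(0, span)), cm=float(i)) for i in range(n_a)]
    B = [aln("b", f"b{i}", f"c{rng.integers(0, n_contigs)}",
             int(rng.integers(0, span)), cm=float(i)) for i in range(n_b)]
    return A, B


class TestClosestPairing:
    def test_disjoint_contigs_zero_pairs(self):
        res = pair_closest_without_replacement([aln("a", "a1", "c1")], [aln("b", "b1", "c2")])
        assert len(res) == 0 and len(res.unpaired_a) == 1 and len(res.unpaired_b) == 1

    def test_closest_of_two_wins_other_unpaired(self):
        A = [aln("a", "a1", start=100), aln("a", "a2", start=900)]
        B = [aln("b", "b1", start=450)]
        res = pair_closest_without_replacement(A, B)
        (p,) = res.pairs
        assert p.marker_a.marker_id == "a1" and p.distance_bp == 350
        assert [k.marker_id for k in res.unpaired_a] == ["a2"]

    def test_second_closest_discarded_without_replacement(self):
        # two A-markers flank one B-marker; only the closer pairs
        A = [aln("a", "a1", start=480), aln("a", "a2", start=530)]
        B = [aln("b", "b1", start=500)]
        res = pair_closest_without_replacement(A, B)
        assert [p.marker_a.marker_id for p in res.pairs] == ["a1"]

    def test_distance_cap_boundary(self):
        A = [aln("a", "a1", start=0)]
        B = [aln("b", "b1", start=10_000_001)]
        assert len(pair_closest_without_replacement(A, B)) == 0
        B = [aln("b", "b1", start=10_000_000)]
        assert len(pair_closest_without_replacement(A, B)) == 1

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            A, B = random_instance(rng, int(rng.integers(1, 40)), int(rng.integers(1, 40)))
            res = pair_closest_without_replacement(A, B, 2000)
            assert [(p.marker_a, p.marker_b) for p in res.pairs] == greedy_oracle(A, B, 2000)

    def test_injective_matching(self):
        rng = np.random.default_rng(7)
        A, B = random_instance(rng, 80, 60)
        res = pair_closest_without_replacement(A, B)
        assert len({p.marker_a for p in res.pairs}) == len(res)
        assert len({p.marker_b for p in res.pairs}) == len(res)

    def test_monotone_in_max_distance(self):
        rng = np.random.default_rng(5)
        A, B = random_instance(rng, 50, 50)
        counts = [
            len(pair_closest_without_replacement(A, B, d))
            for d in (10, 100, 1000, 5000, 10_000_000)
        ]
        assert counts == sorted(counts)


class TestHomeologPairing:
    def test_outgroup_marker_pairs_once_per_placement(self):
        og = [
            aln("og", "m1", "c1", 100, n_hits=2, mapq=0),
            aln("og", "m1", "c2", 200, n_hits=2, mapq=0),
        ]
        target = [
            aln("t", "t1", "c1", 120, lg="LGA"),
            aln("t", "t2", "c2", 180, lg="LGB"),
        ]
        res = pair_homeolog_mode(og, target)
        assert len(res) == 2
        assert {p.marker_b.linkage_group for p in res.pairs} == {"LGA", "LGB"}

    def test_single_placement_pairs_at_most_once(self):
        og = [aln("og", "m1", "c1", 100)]
        target = [aln("t", "t1", "c1", 90), aln("t", "t2", "c1", 120)]
        assert len(pair_homeolog_mode(og, target)) == 1

    def test_both_placements_near_same_target_lg(self):
        og = [
            aln("og", "m1", "c1", 100, n_hits=2, mapq=0),
            aln("og", "m1", "c1", 900, n_hits=2, mapq=0),
        ]
        target = [aln("t", "t1", "c1", 110), aln("t", "t2", "c1", 950)]
        res = pair_homeolog_mode(og, target)
        assert len(res) == 2  # same LG column; downstream caller resolves


class TestReciprocalBestHit:
    def test_identical_unique_sequences_pair(self):
        a = make_map("a", [("LG1", 0.0, "a1", "ACGTACGTACGTACGT")])
        b = make_map("b", [("LG1", 0.0, "b1", "ACGTACGTACGTACGT")])
        assert len(reciprocal_best_hit_pairs(a, b)) == 1

    def test_asymmetric_best_no_pair(self):
        # a1's best is b1, but b1 matches a2 exactly
        seq1 = "ACGTACGTACGTTTTT"
        a = make_map("a", [("LG1", 0.0, "a1", "ACGTACGTACGTAAAA"),
                           ("LG1", 1.0, "a2", seq1)])
        b = make_map("b", [("LG1", 0.0, "b1", seq1)])
        res = reciprocal_best_hit_pairs(a, b)
        assert [(p.marker_a.marker_id, p.marker_b.marker_id) for p in res.pairs] == [("a2", "b1")]

    def test_tied_best_targets_no_pair(self):
        dup = "ACGTACGTACGTACGT"
        a = make_map("a", [("LG1", 0.0, "a1", dup)])
        b = make_map("b", [("LG1", 0.0, "b1", dup), ("LG2", 1.0, "b2", dup)])
        assert len(reciprocal_best_hit_pairs(a, b)) == 0

    def test_matches_bruteforce_score_matrix(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))

        def rand_seq():
            return "".join(bases[rng.integers(0, 4, size=24)])

        a = make_map("a", [("LG1", float(i), f"a{i}", rand_seq()) for i in range(8)])
        b = make_map("b", [("LG1", float(i), f"b{i}", rand_seq()) for i in range(8)])
        from mapbridge.pairing import shared_kmer_score

        S = {(x.marker_id, y.marker_id): shared_kmer_score(x.sequence, y.sequence)
             for x in a for y in b}

        def unique_best(m, others, flip):
            scored = [(S[(m.marker_id, o.marker_id)] if not flip else S[(o.marker_id, m.marker_id)], o.marker_id)
                      for o in others]
            scored = [(s, o) for s, o in scored if s >= 1.0]
            if not scored:
                return None
            top = max(s for s, _ in scored)
            winners = [o for s, o in scored if s == top]
            return winners[0] if len(winners) == 1 else None

        expected = set()
        for x in a:
            bx = unique_best(x, list(b), flip=False)
            if bx is not None and unique_best([y for y in b if y.marker_id == bx][0], list(a), flip=True) == x.marker_id:
                expected.add((x.marker_id, bx))
        got = {(p.marker_a.marker_id, p.marker_b.marker_id)
               for p in reciprocal_best_hit_pairs(a, b).pairs}
        assert got == expected


class TestOxfordGrid:
    def test_empty_grid(self):
        a = make_map("a", [("LG1", 0.0, "a1", "ACGT")])
        b = make_map("b", [("LG1", 0.0, "b1", "ACGT")])
        grid = build_oxford_grid([], a, b)
        assert grid.n_pairs == 0 and grid.cells == {}

    def test_cell_counts_conserve_pairs(self):
        a = make_map("a", [("LG1", 0.0, "a1", ""), ("LG1", 1.0, "a2", ""), ("LG2", 0.0, "a3", "")])
        b = make_map("b", [("LG9", 0.0, "b1", ""), ("LG9", 1.0, "b2", ""), ("LG8", 0.0, "b3", "")])
        pairs = [
            MarkerPair(a.markers[0].key, b.markers[1].key, "c1", 0, 0),
            MarkerPair(a.markers[1].key, b.markers[2].key, "c1", 0, 0),
            MarkerPair(a.markers[2].key, b.markers[0].key, "c1", 0, 0),
        ]
        grid = build_oxford_grid(pairs, a, b)
        # three pairs over two LG combinations: cell counts {2, 1}, total 3
        assert grid.n_pairs == 3 and sorted(grid.cells.values()) == [1, 2]

    def test_unknown_marker_rejected(self):
        a = make_map("a", [("LG1", 0.0, "a1", "")])
        b = make_map("b", [("LG1", 0.0, "b1", "")])
        ghost = MarkerPair(MarkerKey("a", "LG1", 9.0, "nope"), b.markers[0].key, "c1", 0, 0)
        with pytest.raises(MapValidationError):
            build_oxford_grid([ghost], a, b)

    def test_collinear_fixture_dominant_diagonal(self, recovery_sim):
        res = recovery_sim["result"]
        pr = pair_closest_without_replacement(
            recovery_sim["kept"]["sp_a"], recovery_sim["kept"]["sp_b"]
        )
        grid = build_oxford_grid(pr, res.maps["sp_a"], res.maps["sp_b"])
        # every sp_a LG has one dominant counterpart cell holding all pairs
        per_lg = {}
        for (la, lb), n in grid.cells.items():
            per_lg.setdefault(la, []).append(n)
        assert all(max(v) / sum(v) == 1.0 for v in per_lg.values())


def test_proximate_pairing_beats_rbh_on_shared_inputs(recovery_sim):
    """MapComp's gain over direct homology: proximate pairs add to identical
    ones, so pair counts can only go up on the same inputs."""
    res = recovery_sim["result"]
    pr = pair_closest_without_replacement(
        recovery_sim["kept"]["sp_a"], recovery_sim["kept"]["sp_b"]
    )
    rbh = reciprocal_best_hit_pairs(res.maps["sp_a"], res.maps["sp_b"])
    assert len(pr) >= len(rbh)
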