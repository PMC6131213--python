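"""Gene homology scoring and tandem-array calling/comparison."""

import math
import random

import numpy as np
import pytest

from chromoscape import tandem
from chromoscape.core import AnnotationSet, GeneModel, Interval
from chromoscape.simulate import _mutate, _random_seq
from chromoscape.tandem import HomologyHit, NucleotideScoring


def rng(seed=0):
    return np.random.default_rng(seed)


def make_genes(ranks_by_chrom):
    """Gene models at every rank 0..max; ids of interest are '<chrom>:<rank>'.

    Filler genes occupy the intermediate ranks so that rank distance between
    the named genes is what the test intends.
    """
    genes = []
    for chrom, ranks in ranks_by_chrom.items():
        for r in range(max(ranks) + 1):
            genes.append(GeneModel(f"{chrom}:{r}", chrom, Interval(r * 1000, r * 1000 + 500)))
    return AnnotationSet(genes)


def hit(q, s, e=1e-20):
    return HomologyHit(q, s, 95.0, 500, 100.0, e)


def sw_oracle(a, b, match=1, mismatch=-2, gap_open=5, gap_extend=2):
    """Textbook Smith-Waterman with affine gaps (Gotoh), small inputs only."""
    n, m = len(a), len(b)
    neg = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (insertion)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestPairwiseHomology:
    def test_identical_genes_are_overwhelming(self):
        seq = _random_seq(rng(1), 300)
        h = tandem.pairwise_homology(seq, seq)
        assert h.e_value < 1e-50
        assert h.identity == pytest.approx(100.0)

    def test_random_pairs_rarely_reach_threshold(self):
        r = rng(2)
        fails = 0
        for _ in range(100):
            a, b = _random_seq(r, 300), _random_seq(r, 300)
            h = tandem.pairwise_homology(a, b, database_length=1_000_000)
            if h.e_value <= 1e-5:
                fails += 1
        assert fails <= 1

    def test_score_matches_dynamic_programming_oracle(self):
        r = rng(3)
        scoring = NucleotideScoring()
        lam = scoring.ungapped_lambda()
        for _ in range(20):
            a, b = _random_seq(r, 10), _random_seq(r, 12)
            h = tandem.pairwise_homology(a, b, scoring)
            raw = (h.score * math.log(2) + math.log(scoring.K)) / lam
            assert raw == pytest.approx(sw_oracle(a, b), abs=1e-6)

    def test_alphabet_checked(self):
        with pytest.raises(ValueError):
            tandem.pairwise_homology("ACGT", "ACGU")


class TestFastScorer:
    def test_agrees_with_smith_waterman_on_homologous_pairs(self):
        r = rng(4)
        scoring = NucleotideScoring()
        base = _random_seq(r, 400)
        for div in (0.0, 0.05, 0.1):
            variant = _mutate(base, div, r)
            fast = tandem._score_pair(base, variant, scoring, 0.5)
            assert fast is not None
            sw = sw_oracle(base, variant)
            # segment scoring bounds Smith-Waterman from below, tightly for
            # high-identity pairs
            assert 0.9 * sw <= fast[0] <= sw + 1e-9

    def test_reverse_complement_orientation_recovered(self):
        from chromoscape.core import reverse_complement

        r = rng(5)
        base = _random_seq(r, 400)
        fast = tandem._score_pair(base, reverse_complement(base), NucleotideScoring(), 0.5)
        assert fast is not None and fast[0] == pytest.approx(400)


class TestCallTandemArrays:
    def test_transitive_linkage_spans_long_distance(self):
        ann = make_genes({"c": [1, 3, 12]})
        hits = [hit("c:1", "c:3"), hit("c:3", "c:12")]
        arrays = tandem.call_tandem_arrays(ann, hits)
        assert len(arrays) == 1 and arrays[0].members == ["c:1", "c:3", "c:12"]

    def test_distance_rule_blocks_direct_pair(self):
        ann = make_genes({"c": [1, 12]})
        assert tandem.call_tandem_arrays(ann, [hit("c:1", "c:12")]) == []

    def test_planted_26_member_array_recovered(self, annotations, same_chrom_hits, truth):
        arrays = tandem.call_tandem_arrays(annotations, same_chrom_hits)
        planted = {f: len(ids) for f, _c, ids in truth.tandem_arrays}
        sizes = sorted(a.size for a in arrays)
        assert sizes == sorted(planted.values())
        assert max(sizes) == 26

    def test_matches_connected_components_oracle(self):
        """Single-linkage clustering equals a networkx connected-components
        oracle over 500 random instances."""
        import networkx as nx

        r = random.Random(7)
        for _ in range(500):
            n = r.randint(2, 50)
            ann = make_genes({"c": list(range(n))})
            hits = []
            for _h in range(r.randint(0, 3 * n)):
                i, j = r.sample(range(n), 2)
                hits.append(hit(f"c:{i}", f"c:{j}", e=10 ** -r.randint(0, 12)))
            e_max, dist_max = 1e-5, 10
            arrays = tandem.call_tandem_arrays(ann, hits, e_max, dist_max)
            g = nx.Graph()
            for h in hits:
                i, j = int(h.query.split(":")[1]), int(h.subject.split(":")[1])
                if h.e_value <= e_max and abs(i - j) <= dist_max:
                    g.add_edge(h.query, h.subject)
            oracle = sorted(
                tuple(sorted(c, key=lambda x: int(x.split(":")[1])))
                for c in nx.connected_components(g) if len(c) >= 2
            )
            assert sorted(tuple(a.members) for a in arrays) == oracle

    def test_invariant_to_hit_direction_and_duplicates(self):
        ann = make_genes({"c": [0, 1, 2]})
        fwd = tandem.call_tandem_arrays(ann, [hit("c:0", "c:1"), hit("c:1", "c:2")])
        rev = tandem.call_tandem_arrays(
            ann, [hit("c:1", "c:0"), hit("c:2", "c:1"), hit("c:1", "c:0"), hit("c:0", "c:0")])
        assert [a.members for a in fwd] == [a.members for a in rev]

    def test_stricter_e_value_never_merges(self):
        r = random.Random(8)
        for _ in range(50):
            n = r.randint(4, 30)
            ann = make_genes({"c": list(range(n))})
            hits = [
                hit(f"c:{i}", f"c:{j}", e=10 ** -r.randint(0, 12))
                for i, j in (r.sample(range(n), 2) for _ in range(2 * n))
            ]
            loose = tandem.call_tandem_arrays(ann, hits, e_value_max=1e-3)
            strict = tandem.call_tandem_arrays(ann, hits, e_value_max=1e-8)
            loose_of = {m: tuple(a.members) for a in loose for m in a.members}
            for a in strict:
                # every strict array sits inside exactly one loose array
                assert len({loose_of[m] for m in a.members}) == 1

    def test_unknown_gene_rejected(self):
        ann = make_genes({"c": [0, 1]})
        with pytest.raises(KeyError):
            tandem.call_tandem_arrays(ann, [hit("c:0", "nope")])


class TestCompareAssemblies:
    def test_identical_annotations_all_zero_delta(self, tandem_arrays_called):
        arrays = tandem_arrays_called
        gene_map = {m: m for a in arrays for m in a.members}
        comp = tandem.compare_assemblies(arrays, arrays, gene_map)
        assert all(m["delta"] == 0 for m in comp.matched)
        assert comp.novel_new_arrays == 0 and comp.old_only_genes == 0 and comp.new_only_genes == 0

    def test_collapse_shows_expected_delta_and_new_only_genes(
            self, preset_sim, annotations, same_chrom_hits, truth, genome):
        from chromoscape import simulate

        _dg, dann, dtruth = simulate.degrade_assembly(
            genome, annotations, truth, collapse_fraction=1.0, collapse_keep=4,
            inversion_count=0, seed=13)
        dseqs = tandem.extract_gene_sequences(_dg, dann)
        dhits = tandem.all_vs_all_hits(dann.genes, dseqs, same_chrom_only=True)
        arrays_old = tandem.call_tandem_arrays(dann, dhits)
        arrays_new = tandem.call_tandem_arrays(annotations, same_chrom_hits)
        comp = tandem.compare_assemblies(arrays_old, arrays_new, {g.id: g.id for g in dann.genes})
        deltas = sorted(m["delta"] for m in comp.matched)
        planted = sorted(orig - kept for _f, orig, kept in dtruth.collapsed_arrays)
        assert deltas[-len(planted):] == planted  # includes the 26 -> 4 (+22) case
        excised = sum(orig - kept for _f, orig, kept in dtruth.collapsed_arrays)
        assert comp.new_only_genes == excised

    def test_disjoint_annotations_fully_novel(self):
        a = [tandem.TandemArray("c", ["x1", "x2"])]
        b = [tandem.TandemArray("c", ["y1", "y2"])]
        comp = tandem.compare_assemblies(a, b, {})
        assert comp.novel_new_arrays == 1 and comp.fraction_novel_arrays == 1.0


class TestSizeClassGain:
    def test_single_array_gain(self):
        comp = tandem.AssemblyComparison(matched=[{"old_size": 4, "new_size": 6, "delta": 2}])
        assert tandem.size_class_gain(comp, 5, 9) == pytest.approx(50.0)

    def test_mean_over_class(self):
        comp = tandem.AssemblyComparison(matched=[
            {"old_size": 10, "new_size": 13, "delta": 3},
            {"old_size": 10, "new_size": 17, "delta": 7},
        ])
        assert tandem.size_class_gain(comp, 11, 100) == pytest.approx(50.0)

    def test_empty_class_is_none_not_zero(self):
        comp = tandem.AssemblyComparison(matched=[{"old_size": 2, "new_size": 2, "delta": 0}])
        assert tandem.size_class_gain(comp, 10, 20) is None
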