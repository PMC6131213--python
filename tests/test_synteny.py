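"""Anchor chaining, depth profiling, dot plots, and syntenic array classes."""

import itertools
import random

import pytest

from chromoscape import synteny, tandem
from chromoscape.core import AnnotationSet, GeneModel, Interval
from chromoscape.synteny import Anchor, GAP_PENALTY
from chromoscape.tandem import HomologyHit, TandemArray


def linear_genes(chrom, n, prefix):
    return AnnotationSet([
        GeneModel(f"{prefix}{i}", chrom, Interval(i * 1000, i * 1000 + 500)) for i in range(n)
    ])


def hits_between(ids_a, ids_b, e=1e-20):
    return [HomologyHit(a, b, 95.0, 500, 200.0, e) for a, b in zip(ids_a, ids_b)]


def exhaustive_best_chain(points, max_rank_gap):
    """Oracle: enumerate every anchor subset, keep the best valid chain
    (either orientation) under the same scoring as the implementation."""
    best = 0.0
    idx = range(len(points))
    for size in range(1, len(points) + 1):
        for combo in itertools.combinations(idx, size):
            pts = sorted(points[i] for i in combo)
            for direction in (1, -1):
                ok = True
                score = 1.0
                for (a1, b1), (a2, b2) in zip(pts, pts[1:]):
                    da = a2 - a1
                    db = direction * (b2 - b1)
                    if da <= 0 or db <= 0 or da > max_rank_gap or db > max_rank_gap:
                        ok = False
                        break
                    score += 1.0 - GAP_PENALTY * (da - 1 + db - 1)
                if ok:
                    best = max(best, score)
    return best


class TestAnchorPairs:
    def test_truth_orthologs_all_anchored(self, annotations, ortholog_sim):
        _og, oann, otruth = ortholog_sim
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        assert len(anchors) == len(otruth.orthology)

    def test_top1_is_partial_matching_and_order_invariant(self):
        ann_a = linear_genes("a", 3, "a")
        ann_b = linear_genes("b", 3, "b")
        hits = [
            HomologyHit("a0", "b0", 90, 500, 300, 1e-40),
            HomologyHit("a0", "b1", 90, 500, 250, 1e-30),
            HomologyHit("a1", "b0", 90, 500, 240, 1e-28),
            HomologyHit("a1", "b1", 90, 500, 220, 1e-25),
            HomologyHit("a2", "b2", 90, 500, 220, 1e-25),
        ]
        anchors = synteny.anchor_pairs(ann_a, ann_b, hits, top_k=1)
        pairs = {(an.gene_a.id, an.gene_b.id) for an in anchors}
        assert pairs == {("a0", "b0"), ("a1", "b1"), ("a2", "b2")}
        for perm in itertools.permutations(hits):
            got = synteny.anchor_pairs(ann_a, ann_b, list(perm), top_k=1)
            assert {(an.gene_a.id, an.gene_b.id) for an in got} == pairs


class TestChainBlocks:
    def test_self_synteny_single_forward_block_per_chromosome(self, annotations):
        mapping = {g.id: g.id for g in annotations.genes}
        anchors = synteny.anchors_from_orthology(mapping, annotations, annotations)
        blocks = synteny.chain_blocks(anchors, annotations, annotations)
        chroms = {g.chrom for g in annotations.genes}
        assert len(blocks) == len(chroms)
        assert all(b.orientation == "forward" for b in blocks)
        assert sum(len(b.anchors) for b in blocks) == len(annotations.genes)

    def test_planted_inversions_give_planted_inverted_block_count(
            self, annotations, ortholog_sim):
        _og, oann, otruth = ortholog_sim
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        inverted = [b for b in blocks if b.orientation == "inverted"]
        assert len(inverted) == len(otruth.inversions) == 2
        inv_chroms = {c for c, _iv in otruth.inversions}
        assert {b.chrom_b for b in inverted} == inv_chroms
        # flanking blocks on inverted chromosomes are forward
        for c in inv_chroms:
            orientations = [b.orientation for b in blocks if b.chrom_b == c]
            assert "forward" in orientations

    def test_random_scatter_rarely_chains(self):
        # sparse anchors over a large rank space: the rank-gap cap makes
        # spurious chains of 5+ essentially impossible
        r = random.Random(11)
        ann_a = linear_genes("a", 500, "a")
        ann_b = linear_genes("b", 500, "b")
        ids_a, ids_b = [g.id for g in ann_a.genes], [g.id for g in ann_b.genes]
        chained = 0
        for _ in range(100):
            hits = [
                HomologyHit(r.choice(ids_a), r.choice(ids_b), 90, 500, 200, 1e-20)
                for _ in range(20)
            ]
            anchors = synteny.anchor_pairs(ann_a, ann_b, hits, top_k=1)
            if synteny.chain_blocks(anchors, ann_a, ann_b):
                chained += 1
        assert chained <= 5

    def test_matches_exhaustive_chaining_oracle(self):
        r = random.Random(12)
        for _ in range(200):
            n = r.randint(1, 12)
            max_gap = r.choice([3, 5, 25])
            pts = set()
            while len(pts) < n:
                pts.add((r.randint(0, 14), r.randint(0, 14)))
            points = sorted(pts)
            # drop duplicate ranks so anchors are a matching, as produced
            # by anchor_pairs with top_k=1
            seen_a, seen_b, clean = set(), set(), []
            for a, b in points:
                if a in seen_a or b in seen_b:
                    continue
                seen_a.add(a)
                seen_b.add(b)
                clean.append((a, b))
            ann_a = linear_genes("a", 15, "a")
            ann_b = linear_genes("b", 15, "b")
            ids_a, ids_b = ann_a.by_id(), ann_b.by_id()
            anchors = [Anchor(ids_a[f"a{a}"], ids_b[f"b{b}"]) for a, b in clean]
            blocks = synteny.chain_blocks(anchors, ann_a, ann_b, min_anchors=1,
                                          max_rank_gap=max_gap)
            got = max((b.score for b in blocks), default=0.0)
            want = exhaustive_best_chain(clean, max_gap)
            assert got == pytest.approx(want)

    def test_no_anchor_in_two_blocks_and_monotone(self, annotations, ortholog_sim):
        _og, oann, otruth = ortholog_sim
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        seen = set()
        ids_a, ids_b = annotations.by_id(), oann.by_id()
        for b in blocks:
            ranks_a = [ids_a[ga].rank for ga, _gb in b.anchors]
            ranks_b = [ids_b[gb].rank for _ga, gb in b.anchors]
            assert ranks_a == sorted(ranks_a)
            expect = sorted(ranks_b) if b.orientation == "forward" else sorted(ranks_b, reverse=True)
            assert ranks_b == expect
            for pair in b.anchors:
                assert pair not in seen
                seen.add(pair)

    def test_no_interchromosomal_blocks_without_planting(self, annotations, ortholog_sim):
        _og, oann, otruth = ortholog_sim
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        pairs = {(b.chrom_a, b.chrom_b) for b in blocks}
        assert all(a[3:] == b[3:] for a, b in pairs)  # chrNN maps to ortNN


class TestSyntenicDepth:
    def test_unduplicated_ortholog_is_fully_one_to_one(self, annotations, genome, truth):
        from chromoscape import simulate

        _og, oann, otruth = simulate.generate_ortholog_genome(
            genome, annotations, truth, substitution_rate=0.1, inversion_count=0, seed=21)
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        depth = synteny.syntenic_depth(blocks)
        assert depth.fraction_1to1 == 100.0
        assert depth.fraction_1to1_bases == 100.0

    def test_duplicated_segment_raises_depth(self):
        ann_a = linear_genes("a", 20, "a")
        # genome b carries genes 0..9 twice: a segmental duplication
        ann_b = AnnotationSet([
            GeneModel(f"b{i}", "b", Interval(i * 1000, i * 1000 + 500)) for i in range(10)
        ] + [
            GeneModel(f"bdup{i}", "b", Interval((i + 12) * 1000, (i + 12) * 1000 + 500))
            for i in range(10)
        ])
        anchors = [Anchor(ann_a.by_id()[f"a{i}"], ann_b.by_id()[f"b{i}"]) for i in range(10)]
        anchors += [Anchor(ann_a.by_id()[f"a{i}"], ann_b.by_id()[f"bdup{i}"]) for i in range(10)]
        blocks = synteny.chain_blocks(anchors, ann_a, ann_b)
        depth = synteny.syntenic_depth(blocks)
        assert len(blocks) == 2
        assert all(r["depth_a"] == 2 for r in depth.per_block)
        assert depth.fraction_1to1 == 0.0

    def test_swap_symmetry(self, annotations, ortholog_sim):
        _og, oann, otruth = ortholog_sim
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        swapped = [
            synteny.SyntenyBlock(b.chrom_b, b.chrom_a, [(gb, ga) for ga, gb in b.anchors],
                                 b.orientation, b.span_b, b.span_a, b.score)
            for b in blocks
        ]
        assert synteny.syntenic_depth(blocks).fraction_1to1 == \
            synteny.syntenic_depth(swapped).fraction_1to1


class TestDotplotAndMicrosynteny:
    def test_self_synteny_points_on_diagonal(self, annotations):
        mapping = {g.id: g.id for g in annotations.genes}
        anchors = synteny.anchors_from_orthology(mapping, annotations, annotations)
        blocks = synteny.chain_blocks(anchors, annotations, annotations)
        table = synteny.dotplot_table(blocks, annotations, annotations)
        assert len(table) == sum(len(b.anchors) for b in blocks)
        assert (table["pos_a"] == table["pos_b"]).all()

    def test_inverted_block_runs_anti_diagonal(self, annotations, ortholog_sim):
        _og, oann, otruth = ortholog_sim
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        table = synteny.dotplot_table(blocks, annotations, oann)
        inv_ids = [i for i, b in enumerate(blocks) if b.orientation == "inverted"]
        for bid in inv_ids:
            sub = table[table["block"] == bid]
            assert (sub["pos_a"].diff().dropna() > 0).all()
            assert (sub["pos_b"].diff().dropna() < 0).all()

    def test_microsynteny_self_region_strand_concordant(self, annotations):
        mapping = {g.id: g.id for g in annotations.genes}
        anchors = synteny.anchors_from_orthology(mapping, annotations, annotations)
        blocks = synteny.chain_blocks(anchors, annotations, annotations)
        chrom = annotations.genes[0].chrom
        first10 = annotations.genes_on(chrom)[:10]
        region = Interval(first10[0].start, first10[-1].end)
        view = synteny.microsynteny_view(chrom, region, blocks, annotations, annotations)
        paired = view[view["status"] == "paired"]
        assert len(paired) == 10
        assert (paired["strand_a"] == paired["strand_b"]).all()

    def test_region_outside_blocks_warns_and_is_empty(self, annotations):
        with pytest.warns(UserWarning):
            view = synteny.microsynteny_view("chr01", Interval(0, 10), [], annotations, annotations)
        assert view.empty


class TestClassifySyntenicArrays:
    def test_identical_genomes_all_conserved(self, annotations, tandem_arrays_called):
        mapping = {g.id: g.id for g in annotations.genes}
        anchors = synteny.anchors_from_orthology(mapping, annotations, annotations)
        blocks = synteny.chain_blocks(anchors, annotations, annotations)
        cls = synteny.classify_syntenic_arrays(tandem_arrays_called, tandem_arrays_called, blocks)
        assert cls.n_conserved == len(tandem_arrays_called)
        assert cls.n_unique == 0
        assert all(c["size_a"] == c["size_b"] for c in cls.conserved)

    def test_contracted_array_counts_as_big_vs_single(
            self, annotations, gene_sequences, tandem_arrays_called, ortholog_sim):
        _og, oann, otruth = ortholog_sim  # fam02 (12 members) contracted to 1
        anchors = synteny.anchors_from_orthology(otruth.orthology, annotations, oann)
        blocks = synteny.chain_blocks(anchors, annotations, oann)
        oseqs = tandem.extract_gene_sequences(_og, oann)
        ohits = tandem.all_vs_all_hits(oann.genes, oseqs, same_chrom_only=True)
        oarrays = tandem.call_tandem_arrays(oann, ohits)
        cls = synteny.classify_syntenic_arrays(tandem_arrays_called, oarrays, blocks)
        assert cls.big_vs_single == 1
        assert cls.lineage_specific_a == 1
        assert cls.n_conserved == len(tandem_arrays_called) - 1

    def test_no_blocks_means_nothing_conserved(self):
        arrays = [TandemArray("a", ["x", "y"])]
        with pytest.warns(UserWarning):
            cls = synteny.classify_syntenic_arrays(arrays, arrays, [])
        assert cls.n_conserved == 0 and cls.n_unique == 2
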