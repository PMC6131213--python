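"""Collinearity: anchor chaining into synteny blocks, syntenic depth,
dot-plot/microsynteny tables, and conserved vs lineage-specific syntenic
tandem arrays.

Blocks are chained per chromosome pair by dynamic programming on gene-rank
pairs (longest increasing, or decreasing for inverted blocks, with bounded
rank gaps in both genomes), scoring +1 per anchor minus a small gap penalty.
Overlapping chains are resolved greedily by score: the best chain is
accepted, its anchors removed, and chaining repeats — an anchor belongs to
at most one block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .core import AnnotationSet, GeneModel, Interval
from .tandem import HomologyHit, TandemArray

GAP_PENALTY = 0.01  # per rank-gap unit; keeps anchor count dominant


@dataclass
class Anchor:
    gene_a: GeneModel
    gene_b: GeneModel


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]  # (gene_a id, gene_b id), ordered by rank in A
    orientation: str  # "forward" | "inverted"
    span_a: Interval
    span_b: Interval
    score: float = 0.0


def anchor_pairs(
    genes_a: AnnotationSet,
    genes_b: AnnotationSet,
    hits: list[HomologyHit],
    e_value_max: float = 1e-5,
    top_k: int = 1,
) -> list[Anchor]:
    """Anchor pairs from cross-genome hits: e-value filtered, then at most
    ``top_k`` hits retained per query AND per subject (so ``top_k=1`` yields
    a partial matching). Order-invariant in the input hit list."""
    ids_a = genes_a.by_id()
    ids_b = genes_b.by_id()
    oriented: list[tuple[float, float, str, str]] = []
    for h in hits:
        if h.e_value > e_value_max:
            continue
        if h.query in ids_a and h.subject in ids_b:
            qa, qb = h.query, h.subject
        elif h.query in ids_b and h.subject in ids_a:
            qa, qb = h.subject, h.query
        else:
            continue
        oriented.append((h.e_value, -h.score, qa, qb))
    oriented.sort()
    kept_a: dict[str, int] = {}
    kept_b: dict[str, int] = {}
    anchors: list[Anchor] = []
    seen: set[tuple[str, str]] = set()
    for _e, _s, qa, qb in oriented:
        if (qa, qb) in seen:
            continue
        if kept_a.get(qa, 0) >= top_k or kept_b.get(qb, 0) >= top_k:
            continue
        seen.add((qa, qb))
        kept_a[qa] = kept_a.get(qa, 0) + 1
        kept_b[qb] = kept_b.get(qb, 0) + 1
        anchors.append(Anchor(ids_a[qa], ids_b[qb]))
    anchors.sort(key=lambda an: (an.gene_a.chrom, an.gene_a.rank, an.gene_b.chrom, an.gene_b.rank))
    return anchors


def anchors_from_orthology(
    mapping: dict[str, str], genes_a: AnnotationSet, genes_b: AnnotationSet
) -> list[Anchor]:
    """Anchors straight from a known ortholog map (e.g. simulator truth)."""
    ids_a, ids_b = genes_a.by_id(), genes_b.by_id()
    anchors = [
        Anchor(ids_a[ga], ids_b[gb]) for ga, gb in mapping.items() if ga in ids_a and gb in ids_b
    ]
    anchors.sort(key=lambda an: (an.gene_a.chrom, an.gene_a.rank))
    return anchors


def _best_chain(points: list[tuple[int, int, int]], direction: int, max_rank_gap: int):
    """Best chain over (rank_a, rank_b, index) points, strictly increasing in
    rank_a and strictly increasing (direction=+1) or decreasing (-1) in
    rank_b, with rank gaps <= max_rank_gap in both genomes. Returns
    (score, [indices])."""
    pts = sorted(points)
    n = len(pts)
    best_score = [1.0] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            da = pts[i][0] - pts[j][0]
            db = direction * (pts[i][1] - pts[j][1])
            if da <= 0 or db <= 0 or da > max_rank_gap or db > max_rank_gap:
                continue
            cand = best_score[j] + 1.0 - GAP_PENALTY * (da - 1 + db - 1)
            if cand > best_score[i] + 1e-12:
                best_score[i] = cand
                prev[i] = j
    if not n:
        return 0.0, []
    end = max(range(n), key=lambda i: best_score[i])
    chain = []
    i = end
    while i != -1:
        chain.append(pts[i][2])
        i = prev[i]
    chain.reverse()
    return best_score[end], chain


def chain_blocks(
    anchors: list[Anchor],
    genes_a: AnnotationSet,
    genes_b: AnnotationSet,
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain anchors into maximal-scoring collinear blocks per chromosome
    pair; chains shorter than ``min_anchors`` are discarded and each anchor
    is assigned to at most one block."""
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for an in anchors:
        by_pair.setdefault((an.gene_a.chrom, an.gene_b.chrom), []).append(an)

    blocks: list[SyntenyBlock] = []
    for (ca, cb), pair_anchors in sorted(by_pair.items()):
        remaining = list(range(len(pair_anchors)))
        while True:
            points = [
                (pair_anchors[i].gene_a.rank, pair_anchors[i].gene_b.rank, i) for i in remaining
            ]
            fwd_score, fwd = _best_chain(points, +1, max_rank_gap)
            rev_score, rev = _best_chain(points, -1, max_rank_gap)
            # prefer forward on exact ties for determinism
            score, chain, orientation = (
                (fwd_score, fwd, "forward") if fwd_score >= rev_score else (rev_score, rev, "inverted")
            )
            if len(chain) < min_anchors:
                break
            chosen = [pair_anchors[i] for i in chain]
            blocks.append(_make_block(ca, cb, chosen, orientation, score))
            chain_set = set(chain)
            remaining = [i for i in remaining if i not in chain_set]
    blocks.sort(key=lambda b: (b.chrom_a, b.span_a.start, b.chrom_b, b.span_b.start))
    return blocks


def _make_block(ca: str, cb: str, chosen: list[Anchor], orientation: str, score: float) -> SyntenyBlock:
    chosen = sorted(chosen, key=lambda an: an.gene_a.rank)
    span_a = Interval(min(an.gene_a.start for an in chosen), max(an.gene_a.end for an in chosen))
    span_b = Interval(min(an.gene_b.start for an in chosen), max(an.gene_b.end for an in chosen))
    return SyntenyBlock(
        chrom_a=ca,
        chrom_b=cb,
        anchors=[(an.gene_a.id, an.gene_b.id) for an in chosen],
        orientation=orientation,
        span_a=span_a,
        span_b=span_b,
        score=score,
    )


@dataclass
class DepthProfile:
    per_block: list[dict] = field(default_factory=list)
    fraction_1to1: float = 0.0  # percent of blocks
    fraction_1to1_bases: float = 0.0  # percent of block-covered bases


def syntenic_depth(blocks: list[SyntenyBlock]) -> DepthProfile:
    """Depth of each block span in both genomes; a block is 1:1 when its
    span in each genome is covered by exactly one block (itself). Reported
    both as a percent of blocks and as a percent of block-covered bases —
    the two possible denominators."""
    profile = DepthProfile()
    if not blocks:
        return profile
    one_to_one_bases = 0
    total_bases = 0
    for b in blocks:
        depth_a = sum(
            1 for o in blocks if o.chrom_a == b.chrom_a and o.span_a.overlaps(b.span_a)
        )
        depth_b = sum(
            1 for o in blocks if o.chrom_b == b.chrom_b and o.span_b.overlaps(b.span_b)
        )
        is_1to1 = depth_a == 1 and depth_b == 1
        profile.per_block.append(
            {"chrom_a": b.chrom_a, "chrom_b": b.chrom_b, "depth_a": depth_a,
             "depth_b": depth_b, "one_to_one": is_1to1}
        )
        span = len(b.span_a) + len(b.span_b)
        total_bases += span
        if is_1to1:
            one_to_one_bases += span
    n11 = sum(1 for r in profile.per_block if r["one_to_one"])
    profile.fraction_1to1 = 100.0 * n11 / len(blocks)
    profile.fraction_1to1_bases = 100.0 * one_to_one_bases / total_bases if total_bases else 0.0
    return profile


def dotplot_table(blocks: list[SyntenyBlock], genes_a: AnnotationSet, genes_b: AnnotationSet) -> pd.DataFrame:
    """One row per anchor: positions in both genomes, block id, orientation."""
    ids_a, ids_b = genes_a.by_id(), genes_b.by_id()
    rows = []
    for bi, b in enumerate(blocks):
        for ga, gb in b.anchors:
            rows.append(
                {
                    "chrom_a": b.chrom_a,
                    "pos_a": (ids_a[ga].start + ids_a[ga].end) // 2,
                    "chrom_b": b.chrom_b,
                    "pos_b": (ids_b[gb].start + ids_b[gb].end) // 2,
                    "block": bi,
                    "orientation": b.orientation,
                }
            )
    return pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "block", "orientation"])


@dataclass
class SyntenicArrayClassification:
    conserved: list[dict] = field(default_factory=list)  # size pairs for conserved arrays
    lineage_specific_a: int = 0
    lineage_specific_b: int = 0
    big_vs_single: int = 0  # >= size_threshold copies in one species, 1 in the other

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)

    @property
    def n_unique(self) -> int:
        return self.lineage_specific_a + self.lineage_specific_b


def classify_syntenic_arrays(
    arrays_a: list[TandemArray],
    arrays_b: list[TandemArray],
    blocks: list[SyntenyBlock],
    size_threshold: int = 10,
) -> SyntenicArrayClassification:
    """Conserved vs lineage-specific syntenic tandem arrays.

    An array in genome A is conserved when one of its members anchors into a
    block whose partner gene belongs to an array in genome B (and vice
    versa); otherwise it is lineage-specific. ``big_vs_single`` counts
    lineage-specific arrays with more than ``size_threshold`` copies whose
    anchored partners collapse onto at most one gene in the other genome.
    """
    a_to_b: dict[str, str] = {}
    b_to_a: dict[str, str] = {}
    anchored_chroms_a = {b.chrom_a for b in blocks}
    anchored_chroms_b = {b.chrom_b for b in blocks}
    for b in blocks:
        for ga, gb in b.anchors:
            a_to_b[ga] = gb
            b_to_a[gb] = ga
    array_of_b: dict[str, TandemArray] = {g: arr for arr in arrays_b for g in arr.members}
    array_of_a: dict[str, TandemArray] = {g: arr for arr in arrays_a for g in arr.members}

    cls = SyntenicArrayClassification()
    conserved_b_ids: set[int] = set()
    for arr in arrays_a:
        if arr.chrom not in anchored_chroms_a:
            warnings.warn(f"array on {arr.chrom} lies outside all synteny blocks")
        partners = {a_to_b[g] for g in arr.members if g in a_to_b}
        partner_arrays = {id(array_of_b[p]) for p in partners if p in array_of_b}
        if partner_arrays:
            barr = next(x for x in arrays_b if id(x) in partner_arrays)
            cls.conserved.append({"chrom_a": arr.chrom, "size_a": arr.size,
                                  "chrom_b": barr.chrom, "size_b": barr.size})
            conserved_b_ids.update(partner_arrays)
        else:
            cls.lineage_specific_a += 1
            if arr.size > size_threshold and len(partners) <= 1:
                cls.big_vs_single += 1
    for arr in arrays_b:
        if arr.chrom not in anchored_chroms_b:
            warnings.warn(f"array on {arr.chrom} lies outside all synteny blocks")
        if id(arr) in conserved_b_ids:
            continue
        partners = {b_to_a[g] for g in arr.members if g in b_to_a}
        if any(p in array_of_a for p in partners):
            continue  # conserved, already counted from the A side
        cls.lineage_specific_b += 1
        if arr.size > size_threshold and len(partners) <= 1:
            cls.big_vs_single += 1
    return cls


def microsynteny_view(
    chrom_a: str,
    region_a: Interval,
    blocks: list[SyntenyBlock],
    genes_a: AnnotationSet,
    genes_b: AnnotationSet,
) -> pd.DataFrame:
    """Paired gene layout for a region: ordered genes of the region, their
    anchored partners, and unpaired extras on either side (status column:
    paired / a_only / b_only)."""
    cols = ["gene_a", "strand_a", "pos_a", "gene_b", "strand_b", "pos_b", "status"]
    hit_blocks = [b for b in blocks if b.chrom_a == chrom_a and b.span_a.overlaps(region_a)]
    if not hit_blocks:
        warnings.warn(f"region {chrom_a}:{region_a.start}-{region_a.end} overlaps no synteny block")
        return pd.DataFrame(columns=cols)
    ids_b = genes_b.by_id()
    pairing = {ga: gb for b in hit_blocks for ga, gb in b.anchors}
    region_genes = [g for g in genes_a.genes_on(chrom_a) if g.interval.overlaps(region_a)]
    partner_ivs = [ids_b[pairing[g.id]] for g in region_genes if g.id in pairing]
    rows = []
    for g in region_genes:
        gb = pairing.get(g.id)
        if gb is not None:
            pb = ids_b[gb]
            rows.append({"gene_a": g.id, "strand_a": g.strand, "pos_a": g.start,
                         "gene_b": gb, "strand_b": pb.strand, "pos_b": pb.start, "status": "paired"})
        else:
            rows.append({"gene_a": g.id, "strand_a": g.strand, "pos_a": g.start,
                         "gene_b": None, "strand_b": None, "pos_b": None, "status": "a_only"})
    if partner_ivs:
        chrom_b = partner_ivs[0].chrom
        lo = min(p.start for p in partner_ivs)
        hi = max(p.end for p in partner_ivs)
        paired_b = set(pairing.values())
        for g in genes_b.genes_on(chrom_b):
            if g.interval.overlaps(Interval(lo, hi)) and g.id not in paired_b:
                rows.append({"gene_a": None, "strand_a": None, "pos_a": None,
                             "gene_b": g.id, "strand_b": g.strand, "pos_b": g.start, "status": "b_only"})
    return pd.DataFrame(rows, columns=cols)
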