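"""Tandem gene array calling and cross-assembly comparison.

Tandem gene duplicates are called by the classic rule: same-chromosome gene
pairs with a homology hit at e-value <= 1e-5 and annotation-rank distance
<= 10 genes are linked, and arrays are the single-linkage (connected
component) clusters of size >= 2, matching MCScan's tandem convention.

The built-in pairwise aligner is a thin layer over Smith-Waterman local
alignment with affine gaps; bit scores and e-values follow the standard
Karlin-Altschul rescaling, with e = K * m * n * 2^(-bitscore). External
12-column (BLAST outfmt-6 compatible) hit tables are accepted anywhere a
hit list is expected.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .core import AnnotationSet, GeneModel


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    identity: float  # percent
    alignment_length: int
    score: float  # bits
    e_value: float


@dataclass
class TandemArray:
    chrom: str
    members: list[str]  # ordered by rank
    size: int = 0

    def __post_init__(self) -> None:
        self.size = len(self.members)


@dataclass
class NucleotideScoring:
    """BLASTN-like scoring: match/mismatch +1/-2, gap open 5, gap extend 2
    (a gap of length L costs 5 + 2L)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    K: float = 0.46  # gapped Karlin-Altschul K for this scoring

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a

    def ungapped_lambda(self) -> float:
        """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base
        frequencies by bisection."""
        def f(lam: float) -> float:
            return 0.25 * math.exp(lam * self.match) + 0.75 * math.exp(lam * self.mismatch) - 1.0

        lo, hi = 1e-6, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2


def pairwise_homology(
    seq_a: str,
    seq_b: str,
    scoring: NucleotideScoring | None = None,
    database_length: int | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> HomologyHit:
    """Local alignment of two nucleotide sequences with bit score and e-value.

    ``database_length`` is the total subject database size n in the
    Karlin-Altschul e-value K*m*n*2^(-bits); it defaults to len(seq_b).
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    alphabet = set(seq_a) | set(seq_b)
    if not alphabet <= set("ACGTN"):
        raise ValueError(f"unexpected characters in sequences: {sorted(alphabet - set('ACGTN'))}")
    scoring = scoring or NucleotideScoring()
    aligner = scoring.aligner()
    raw = aligner.score(seq_a, seq_b)
    lam = scoring.ungapped_lambda()
    bits = (lam * raw - math.log(scoring.K)) / math.log(2)
    n = database_length if database_length is not None else len(seq_b)
    e_value = scoring.K * len(seq_a) * n * math.pow(2.0, -bits)
    # identity over a global edit alignment: cheap, adequate for reporting
    res = edlib.align(seq_a, seq_b, mode="NW", task="distance")
    align_len = max(len(seq_a), len(seq_b))
    identity = 100.0 * (1 - res["editDistance"] / align_len)
    return HomologyHit(
        query=query_id,
        subject=subject_id,
        identity=max(identity, 0.0),
        alignment_length=align_len,
        score=bits,
        e_value=e_value,
    )


def extract_gene_sequences(genome, annotations: AnnotationSet) -> dict[str, str]:
    """Strand-aware gene (transcript-orientation) sequences from a genome."""
    from .core import reverse_complement

    out: dict[str, str] = {}
    for g in annotations.genes:
        seq = genome[g.chrom][g.start : g.end]
        out[g.id] = reverse_complement(seq) if g.strand == "-" else seq
    return out


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _edlib_local_score(sa: str, sb: str, scoring: "NucleotideScoring") -> tuple[float, float, int]:
    """Fast local-alignment surrogate: best-scoring contiguous segment
    (Kadane) of the global edit alignment under the configured scoring.
    Returns (raw score, identity percent, alignment length). A lower bound
    on the true Smith-Waterman score, tight for high-identity pairs."""
    res = edlib.align(sa, sb, mode="NW", task="path")
    best = cur = 0.0
    matches = columns = 0
    for n_str, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        columns += n
        if op == "=":
            matches += n
            seg = n * scoring.match
        elif op in "XM":
            seg = n * scoring.mismatch
        else:  # I/D gap of length n
            seg = -(scoring.gap_open + scoring.gap_extend * n)
        cur = max(cur + seg, seg, 0.0)
        best = max(best, cur)
    identity = 100.0 * matches / columns if columns else 0.0
    return best, identity, columns


def _score_pair(sa: str, sb: str, scoring: "NucleotideScoring",
                prefilter_identity: float) -> tuple[float, float, int] | None:
    """Best of forward and reverse-complement orientation, with an
    edit-distance prefilter; None when neither orientation passes."""
    from .core import reverse_complement

    k = int(max(len(sa), len(sb)) * (1 - prefilter_identity))
    best = None
    for sb_o in (sb, reverse_complement(sb)):
        if edlib.align(sa, sb_o, mode="NW", task="distance", k=k)["editDistance"] == -1:
            continue
        cand = _edlib_local_score(sa, sb_o, scoring)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


_SEED_K = 11
_SEED_STRIDE = 8
_SEED_MIN_SHARED = 3


def _seed_sets(seq: str) -> tuple[frozenset, frozenset]:
    """Strided k-mer fingerprints of a sequence and its reverse complement;
    homologous pairs (either orientation) share many seeds, random pairs
    essentially none."""
    from .core import reverse_complement

    fwd = frozenset(seq[i : i + _SEED_K] for i in range(0, len(seq) - _SEED_K + 1, _SEED_STRIDE))
    rc = reverse_complement(seq)
    rev = frozenset(rc[i : i + _SEED_K] for i in range(0, len(rc) - _SEED_K + 1, _SEED_STRIDE))
    return fwd, rev


def _seeds_shared(sets_a: tuple[frozenset, frozenset], sets_b: tuple[frozenset, frozenset]) -> bool:
    fa, _ra = sets_a
    fb, rb = sets_b
    return (len(fa & fb) >= _SEED_MIN_SHARED) or (len(fa & rb) >= _SEED_MIN_SHARED)


def _hit_from_score(raw: float, identity: float, align_len: int, scoring: "NucleotideScoring",
                    m: int, db_len: int, qid: str, sid: str) -> HomologyHit:
    lam = scoring.ungapped_lambda()
    bits = (lam * raw - math.log(scoring.K)) / math.log(2)
    e_value = scoring.K * m * db_len * math.pow(2.0, -bits)
    return HomologyHit(query=qid, subject=sid, identity=identity,
                       alignment_length=align_len, score=bits, e_value=e_value)


def all_vs_all_hits(
    genes: list[GeneModel],
    sequences: dict[str, str],
    scoring: NucleotideScoring | None = None,
    e_value_max: float = 1e-5,
    prefilter_identity: float = 0.5,
    same_chrom_only: bool = False,
) -> list[HomologyHit]:
    """All-vs-all gene homology with an edit-distance prefilter.

    Pairs whose global edit identity falls below ``prefilter_identity`` in
    both orientations are skipped; surviving pairs are scored with the fast
    segment scorer, which matches Smith-Waterman on high-identity pairs
    (random pairs sit far below the prefilter bound either way).
    """
    scoring = scoring or NucleotideScoring()
    db_len = sum(len(s) for s in sequences.values())
    seeds = {g.id: _seed_sets(sequences[g.id]) for g in genes}
    hits: list[HomologyHit] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            if same_chrom_only and a.chrom != b.chrom:
                continue
            if not _seeds_shared(seeds[a.id], seeds[b.id]):
                continue
            scored = _score_pair(sequences[a.id], sequences[b.id], scoring, prefilter_identity)
            if scored is None:
                continue
            hit = _hit_from_score(*scored, scoring, len(sequences[a.id]), db_len, a.id, b.id)
            if hit.e_value <= e_value_max:
                hits.append(hit)
    return hits


def cross_genome_hits(
    genes_a: list[GeneModel],
    sequences_a: dict[str, str],
    genes_b: list[GeneModel],
    sequences_b: dict[str, str],
    scoring: NucleotideScoring | None = None,
    e_value_max: float = 1e-5,
    prefilter_identity: float = 0.5,
) -> list[HomologyHit]:
    """Gene homology across two genomes (query in A, subject in B)."""
    scoring = scoring or NucleotideScoring()
    db_len = sum(len(s) for s in sequences_b.values())
    seeds_a = {g.id: _seed_sets(sequences_a[g.id]) for g in genes_a}
    seeds_b = {g.id: _seed_sets(sequences_b[g.id]) for g in genes_b}
    hits: list[HomologyHit] = []
    for a in genes_a:
        sa = sequences_a[a.id]
        for b in genes_b:
            if not _seeds_shared(seeds_a[a.id], seeds_b[b.id]):
                continue
            scored = _score_pair(sa, sequences_b[b.id], scoring, prefilter_identity)
            if scored is None:
                continue
            hit = _hit_from_score(*scored, scoring, len(sa), db_len, a.id, b.id)
            if hit.e_value <= e_value_max:
                hits.append(hit)
    return hits


def hits_from_dataframe(df: pd.DataFrame) -> list[HomologyHit]:
    """Convert a 12-column outfmt-6 style table to HomologyHit records."""
    return [
        HomologyHit(
            query=str(r.qseqid), subject=str(r.sseqid), identity=float(r.pident),
            alignment_length=int(r.length), score=float(r.bitscore), e_value=float(r.evalue),
        )
        for r in df.itertuples()
    ]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def call_tandem_arrays(
    annotations: AnnotationSet,
    hits: list[HomologyHit],
    e_value_max: float = 1e-5,
    max_gene_distance: int = 10,
) -> list[TandemArray]:
    """Single-linkage tandem arrays from qualifying same-chromosome hits.

    A pair qualifies when e-value <= ``e_value_max`` and the absolute
    difference of annotation ranks is <= ``max_gene_distance``; arrays are
    the connected components of size >= 2, members ordered by rank.
    """
    by_id = annotations.by_id()
    uf = _UnionFind()
    for h in hits:
        if h.query == h.subject:
            continue  # self-hits dropped; duplicates are harmless to a union
        if h.query not in by_id or h.subject not in by_id:
            raise KeyError(f"hit references unknown gene: {h.query} / {h.subject}")
        a, b = by_id[h.query], by_id[h.subject]
        if a.chrom != b.chrom:
            continue
        if h.e_value > e_value_max:
            continue
        if abs(a.rank - b.rank) > max_gene_distance:
            continue
        uf.union(a.id, b.id)

    clusters: dict[str, list[GeneModel]] = {}
    for gid in uf.parent:
        clusters.setdefault(uf.find(gid), []).append(by_id[gid])
    arrays = []
    for members in clusters.values():
        if len(members) >= 2:
            ordered = sorted(members, key=lambda g: g.rank)
            arrays.append(TandemArray(chrom=ordered[0].chrom, members=[g.id for g in ordered]))
    arrays.sort(key=lambda t: (t.chrom, t.members[0]))
    return arrays


@dataclass
class AssemblyComparison:
    """Old-vs-new tandem array comparison (V1-vs-V3 style)."""

    matched: list[dict] = field(default_factory=list)  # old_size, new_size, delta per matched array
    novel_new_arrays: int = 0
    total_new_arrays: int = 0
    shared_genes: int = 0
    old_only_genes: int = 0
    new_only_genes: int = 0

    @property
    def fraction_novel_arrays(self) -> float:
        return self.novel_new_arrays / self.total_new_arrays if self.total_new_arrays else 0.0


def compare_assemblies(
    arrays_old: list[TandemArray],
    arrays_new: list[TandemArray],
    gene_map: dict[str, str],
) -> AssemblyComparison:
    """Match arrays across assemblies through an old->new gene id map.

    Each new array is matched to the old array sharing the most mapped
    members (ties broken by chromosome and leftmost member); new arrays with
    no mapped member in any old array are counted novel. Gene-level Venn
    counts use the mapping over array members.
    """
    comp = AssemblyComparison(total_new_arrays=len(arrays_new))
    old_by_gene: dict[str, int] = {}
    for idx, arr in enumerate(arrays_old):
        for gid in arr.members:
            old_by_gene[gid] = idx

    old_members_all = {g for arr in arrays_old for g in arr.members}
    new_members_all = {g for arr in arrays_new for g in arr.members}
    image_of_old = {gene_map[g] for g in old_members_all if g in gene_map}
    comp.shared_genes = sum(1 for g in old_members_all if gene_map.get(g) in new_members_all)
    comp.old_only_genes = len(old_members_all) - comp.shared_genes
    comp.new_only_genes = sum(1 for g in new_members_all if g not in image_of_old)

    new_ids_by_old_gene: dict[str, str] = gene_map
    for new_arr in arrays_new:
        # votes: old array index -> number of shared (mapped) members
        votes: dict[int, int] = {}
        for old_gid, new_gid in new_ids_by_old_gene.items():
            if new_gid in new_arr.members and old_gid in old_by_gene:
                votes[old_by_gene[old_gid]] = votes.get(old_by_gene[old_gid], 0) + 1
        if not votes:
            comp.novel_new_arrays += 1
            continue
        best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        old_arr = arrays_old[best]
        comp.matched.append(
            {
                "chrom": new_arr.chrom,
                "old_size": old_arr.size,
                "new_size": new_arr.size,
                "delta": new_arr.size - old_arr.size,
            }
        )
    return comp


def size_class_gain(comparison: AssemblyComparison, class_min: int, class_max: int) -> float | None:
    """Mean percent copy gain, 100*(new-old)/old, over matched arrays whose
    NEW size falls in [class_min, class_max]. None when the class is empty."""
    gains = [
        100.0 * (m["new_size"] - m["old_size"]) / m["old_size"]
        for m in comparison.matched
        if class_min <= m["new_size"] <= class_max and m["old_size"] > 0
    ]
    if not gains:
        return None
    return float(np.mean(gains))
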