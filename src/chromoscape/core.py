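"""Core containers shared across the toolkit.

Coordinates are 0-based half-open everywhere in memory. GFF3 output is
written 1-based inclusive and BED output 0-based half-open, per the format
standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersect_len(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "Interval") -> float:
        inter = self.intersect_len(other)
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0

    def shift(self, delta: int) -> "Interval":
        return Interval(self.start + delta, self.end + delta)


class Genome:
    """Named chromosome sequences (uppercase strings)."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences: dict[str, str] = {name: s.upper() for name, s in sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def copy(self) -> "Genome":
        return Genome(dict(self.sequences))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.sequences == other.sequences


@dataclass(frozen=True)
class GeneModel:
    """A gene with its ordered position on a chromosome.

    ``rank`` is the 0-based index of the gene on its chromosome when genes
    are sorted by start coordinate; ranks are consecutive and unique per
    chromosome. ``family_id`` carries simulator truth (shared by planted
    tandem-array members) or any external family annotation.
    """

    id: str
    chrom: str
    interval: Interval
    strand: str = "+"
    rank: int = -1
    family_id: str | None = None

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class AnnotationSet:
    """Gene models plus repeat (LTR) intervals for one genome."""

    def __init__(self, genes: Iterable[GeneModel] = (), ltr_intervals: Iterable[tuple[str, Interval]] = ()):
        self.genes: list[GeneModel] = list(genes)
        self.ltr_intervals: list[tuple[str, Interval]] = list(ltr_intervals)
        self._assign_ranks()

    def _assign_ranks(self) -> None:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        ranked: dict[str, GeneModel] = {}
        for chrom, genes in by_chrom.items():
            for rank, g in enumerate(sorted(genes, key=lambda g: (g.start, g.id))):
                ranked[g.id] = replace(g, rank=rank)
        self.genes = [ranked[g.id] for g in self.genes]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted((g for g in self.genes if g.chrom == chrom), key=lambda g: g.rank)

    def by_id(self) -> dict[str, GeneModel]:
        return {g.id: g for g in self.genes}

    def families(self) -> dict[str, list[GeneModel]]:
        fams: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.family_id is not None:
                fams.setdefault(g.family_id, []).append(g)
        return fams

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(list(self.genes), list(self.ltr_intervals))


@dataclass(frozen=True)
class TelomereCall:
    chrom: str
    end_label: str  # "left" | "right"
    interval: Interval
    copy_number: int
    motif: str


@dataclass(frozen=True)
class RepeatArray:
    chrom: str
    interval: Interval
    monomer_length: int
    copy_number: int
    mean_identity: float  # percent, 0..100


@dataclass
class CentromereCall:
    chrom: str
    interval: Interval | None
    evidence: frozenset[str]  # subset of {"repeat_array", "ltr_density", "hic_depression"}
    status: str  # "called" | "no_call"

    @property
    def size(self) -> int:
        return len(self.interval) if self.interval is not None else 0


@dataclass
class DensityTrack:
    """Sliding-window coverage fractions along one chromosome."""

    chrom: str
    window: int
    step: int
    values: "list[float]"

    def bin_start(self, i: int) -> int:
        return i * self.step


@dataclass
class ContactMatrix:
    """Binned symmetric intra-chromosomal contact counts."""

    chrom: str
    bin_size: int
    counts: "object"  # numpy (n_bins, n_bins) int array


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(Interval(iv.start, iv.end))
    return merged
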