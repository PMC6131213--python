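"""Synthetic genomes with planted, ledgered features.

The simulator emulates the landscape of a small repeat-rich plant genome:
terminal telomere tracks, a single centromeric satellite array of ~317-bp
monomers per chromosome (one chromosome optionally left acentric, with a
few stray monomers), LTR-dense pericentromeric fields, ordered gene models
including tandem gene arrays, a "degraded" derivative with collapsed arrays
and inversions, a diverged syntenic second species, distance-decay Hi-C
contacts with centromeric depression, and multi-tissue count matrices with
planted tissue-specific genes. Every planted feature is recorded in a
TruthSet so downstream callers can be scored against ground truth.

Background sequence is i.i.d. uniform over ACGT — the simplest null for
homology-based detection. All randomness flows from a single seed;
identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AnnotationSet, GeneModel, Genome, Interval, ContactMatrix, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at the given rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    # shift each hit base by 1..3 within ACGT so it always changes
    idx = np.searchsorted(_BASES, arr[hit])
    arr[hit] = _BASES[(idx + rng.integers(1, 4, size=int(hit.sum()))) % 4]
    return arr.tobytes().decode()


@dataclass
class SimulationConfig:
    """Knobs of the planted-genome generator.

    Lengths are base pairs; fractions are in [0, 1]. ``tandem_array_spec``
    lists planted tandem gene arrays as (copy number, per-member sequence
    divergence); arrays are distributed round-robin over chromosomes.
    ``telomere_plan`` maps a 0-based chromosome index to the ends that get a
    telomere track ("left"/"right"); None means both ends everywhere.
    ``acentric_chrom`` marks one chromosome that receives no centromeric
    array, only a handful of stray monomers.
    """

    n_chromosomes: int = 7
    chrom_length: int = 1_000_000
    telomere_motif: str = "TTTAGGG"
    telomere_copies: int = 40
    centromere_monomer_length: int = 317
    centromere_copy_range: tuple[int, int] = (110, 320)
    monomer_divergence: float = 0.11
    ltr_field_density: float = 0.9
    n_genes_per_chrom: int = 60
    tandem_array_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(26, 0.05), (12, 0.05), (8, 0.05), (5, 0.05), (3, 0.05), (2, 0.05)]
    )
    seed: int = 0
    gene_length: int = 2_000
    intergenic_gap: tuple[int, int] = (500, 3_000)
    pericentromere_length: int = 100_000
    ltr_element_length: int = 5_000
    telomere_plan: dict[int, tuple[str, ...]] | None = None
    acentric_chrom: int | None = None
    stray_monomers: int = 4  # planted on the acentric chromosome

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "telomere_copies",
                     "centromere_monomer_length", "n_genes_per_chrom", "gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("monomer_divergence", "ltr_field_density"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.centromere_copy_range
        if lo < 1 or hi < lo:
            raise ValueError("centromere_copy_range must satisfy 1 <= min <= max")
        for size, div in self.tandem_array_spec:
            if size < 2 or not 0 <= div <= 1:
                raise ValueError("tandem_array_spec entries must be (size >= 2, divergence in [0,1])")

    def chrom_name(self, i: int) -> str:
        return f"chr{i + 1:02d}"


def raspberry_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset mirroring the study genome's layout at desk scale.

    Seven chromosomes; telomere tracks at both ends of chromosomes 2, 3, 5
    and 7 and one end of 1 and 4 (ten tracks total); chromosome 6 acentric
    with four stray centromeric monomers; 317-bp monomers at ~11%
    divergence.
    """
    plan = {0: ("right",), 1: ("left", "right"), 2: ("left", "right"),
            3: ("left",), 4: ("left", "right"), 5: (), 6: ("left", "right")}
    cfg = dict(telomere_plan=plan, acentric_chrom=5, seed=seed)
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@dataclass
class TruthSet:
    """Ledger of every planted feature; the acceptance surface for recovery tests."""

    telomeres: list[tuple[str, str, Interval]] = field(default_factory=list)
    centromeres: list[tuple[str, Interval, int]] = field(default_factory=list)
    ltr_intervals: list[tuple[str, Interval]] = field(default_factory=list)
    tandem_arrays: list[tuple[str, str, list[str]]] = field(default_factory=list)  # (family, chrom, gene ids)
    centromere_arrays: list[tuple[str, Interval, int]] = field(default_factory=list)  # satellite array proper
    inversions: list[tuple[str, Interval]] = field(default_factory=list)
    collapsed_arrays: list[tuple[str, int, int]] = field(default_factory=list)  # (family, orig, kept)
    specific_genes: dict[str, str] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    centromere_monomer: str = ""
    orthology: dict[str, str] = field(default_factory=dict)

    def centromere_on(self, chrom: str) -> Interval | None:
        for c, iv, _n in self.centromeres:
            if c == chrom:
                return iv
        return None


class _ChromBuilder:
    """Mutable chromosome under construction: background plus replacements."""

    def __init__(self, rng: np.random.Generator, length: int):
        self.seq = bytearray(_random_seq(rng, length).encode())

    def plant(self, start: int, payload: str) -> Interval:
        if start < 0 or start + len(payload) > len(self.seq):
            raise ValueError("planted feature exceeds chromosome bounds")
        self.seq[start : start + len(payload)] = payload.encode()
        return Interval(start, start + len(payload))

    def text(self) -> str:
        return self.seq.decode()


def _build_array(monomer: str, copies: int, divergence: float, rng: np.random.Generator) -> str:
    return "".join(_mutate(monomer, divergence, rng) for _ in range(copies))


def generate_genome(config: SimulationConfig) -> tuple[Genome, AnnotationSet, TruthSet]:
    """Generate a genome, annotations (genes + LTR intervals) and its TruthSet."""
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    mono_len = config.centromere_monomer_length
    tel_len = len(config.telomere_motif) * config.telomere_copies
    max_copies = config.centromere_copy_range[1]
    needed = 2 * tel_len + max_copies * mono_len + 2 * config.pericentromere_length + 20_000
    if needed > L:
        raise ValueError(
            f"chrom_length {L} too small for requested features (need >= {needed})"
        )

    monomer = _random_seq(rng, mono_len)
    ltr_consensus = _random_seq(rng, config.ltr_element_length)
    truth = TruthSet(centromere_monomer=monomer)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    ltrs: list[tuple[str, Interval]] = []

    # round-robin assignment of planted tandem arrays to chromosomes
    array_plan: dict[int, list[tuple[str, int, float]]] = {i: [] for i in range(config.n_chromosomes)}
    for k, (size, div) in enumerate(config.tandem_array_spec):
        array_plan[k % config.n_chromosomes].append((f"fam{k + 1:02d}", size, div))

    for ci in range(config.n_chromosomes):
        chrom = config.chrom_name(ci)
        builder = _ChromBuilder(rng, L)
        truth.chrom_lengths[chrom] = L

        ends = ("left", "right") if config.telomere_plan is None else config.telomere_plan.get(ci, ())
        if "left" in ends:
            iv = builder.plant(0, config.telomere_motif * config.telomere_copies)
            truth.telomeres.append((chrom, "left", iv))
        if "right" in ends:
            track = reverse_complement(config.telomere_motif) * config.telomere_copies
            iv = builder.plant(L - len(track), track)
            truth.telomeres.append((chrom, "right", iv))

        # centromere near the middle, jittered
        if ci == config.acentric_chrom:
            # stray monomers only, scattered over the middle half
            for pos in sorted(rng.integers(L // 4, 3 * L // 4, size=config.stray_monomers)):
                builder.plant(int(pos), _mutate(monomer, config.monomer_divergence, rng))
            cen_iv = None
            peri = []
        else:
            copies = int(rng.integers(config.centromere_copy_range[0], config.centromere_copy_range[1] + 1))
            arr = _build_array(monomer, copies, config.monomer_divergence, rng)
            center = int(L * rng.uniform(0.45, 0.55))
            cen_iv = builder.plant(center - len(arr) // 2, arr)
            truth.centromere_arrays.append((chrom, cen_iv, copies))
            peri = [
                Interval(cen_iv.start - config.pericentromere_length, cen_iv.start),
                Interval(cen_iv.end, cen_iv.end + config.pericentromere_length),
            ]
            # the planted centromeric domain: satellite array plus both
            # LTR-dense pericentromeric fields
            truth.centromeres.append((chrom, Interval(peri[0].start, peri[1].end), copies))
            # LTR elements tile each pericentromeric field at the target density
            for field_iv in peri:
                pos = field_iv.start
                while pos + config.ltr_element_length <= field_iv.end:
                    if rng.random() < config.ltr_field_density:
                        elem = _mutate(ltr_consensus, 0.05, rng)
                        iv = builder.plant(pos, elem)
                        ltrs.append((chrom, iv))
                        truth.ltr_intervals.append((chrom, iv))
                        pos += config.ltr_element_length
                    else:
                        pos += config.ltr_element_length // 2

        # gene-permissive arms: outside telomeres (+margin), centromere and pericentromere
        margin = tel_len + 2_000
        if cen_iv is not None:
            arms = [Interval(margin, peri[0].start - 1_000), Interval(peri[1].end + 1_000, L - margin)]
        else:
            arms = [Interval(margin, L - margin)]

        chrom_genes = _place_genes(
            builder, rng, chrom, arms, config, array_plan[ci], truth
        )
        genes.extend(chrom_genes)
        sequences[chrom] = builder.text()

    annotations = AnnotationSet(genes, ltrs)
    return Genome(sequences), annotations, truth


def _place_genes(builder, rng, chrom, arms, config, arrays, truth) -> list[GeneModel]:
    """Lay out genes left to right across the arms; plant tandem arrays as
    runs of consecutive gene slots sharing a mutated family sequence."""
    glen = config.gene_length
    lo_gap, hi_gap = config.intergenic_gap
    # build the per-slot payload plan: singletons + arrays at random ranks
    n_single = config.n_genes_per_chrom - sum(size for _f, size, _d in arrays)
    if n_single < 0:
        raise ValueError(f"n_genes_per_chrom too small for arrays on {chrom}")
    slots: list[tuple[str | None, str]] = [(None, "") for _ in range(n_single)]  # (family, seq)
    for fam, size, div in arrays:
        family_seq = _random_seq(rng, glen)
        members = [(fam, _mutate(family_seq, div, rng)) for _ in range(size)]
        at = int(rng.integers(0, len(slots) + 1))
        slots = slots[:at] + members + slots[at:]

    genes: list[GeneModel] = []
    arm_idx = 0
    pos = arms[0].start
    counter = 0
    fam_members: dict[str, list[str]] = {}
    for fam, seq in slots:
        pos += int(rng.integers(lo_gap, hi_gap))
        while arm_idx < len(arms) and pos + glen > arms[arm_idx].end:
            arm_idx += 1
            if arm_idx < len(arms):
                pos = arms[arm_idx].start + int(rng.integers(lo_gap, hi_gap))
        if arm_idx >= len(arms):
            raise ValueError(f"not enough gene-permissive space on {chrom}")
        if fam is None:
            seq = _random_seq(rng, glen)
        iv = builder.plant(pos, seq)
        counter += 1
        gid = f"{chrom}.g{counter:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(id=gid, chrom=chrom, interval=iv, strand=strand, family_id=fam))
        if fam is not None:
            fam_members.setdefault(fam, []).append(gid)
        pos = iv.end
    for fam, ids in fam_members.items():
        truth.tandem_arrays.append((fam, chrom, ids))
    return genes


# ---------------------------------------------------------------------------
# degraded ("V1-like") derivative


def _remap_after_excisions(pos: int, excisions: list[Interval]) -> int:
    """Map an old coordinate to the post-excision coordinate system."""
    shift = 0
    for ex in excisions:
        if pos >= ex.end:
            shift += len(ex)
        elif pos > ex.start:
            return ex.start - shift  # inside an excised region: clamp to junction
    return pos - shift


def degrade_assembly(
    genome: Genome,
    annotations: AnnotationSet,
    truth: TruthSet,
    collapse_fraction: float = 0.5,
    collapse_keep: int = 1,
    inversion_count: int = 0,
    drop_pericentromere: bool = False,
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[Genome, AnnotationSet, TruthSet]:
    """Derive a short-read-like assembly: tandem arrays collapsed to
    ``collapse_keep`` members (sequence excised, coordinates shifted),
    segments inverted, and optionally the pericentromeric region replaced
    by a gap of N bases."""
    rng = np.random.default_rng(seed)
    if not 0 <= collapse_fraction <= 1:
        raise ValueError("collapse_fraction must be in [0, 1]")
    if collapse_fraction == 0 and inversion_count == 0 and not drop_pericentromere:
        return genome.copy(), annotations.copy(), _copy_truth(truth)

    gene_by_id = annotations.by_id()
    eligible = [t for t in truth.tandem_arrays if len(t[2]) > collapse_keep]
    n_collapse = int(round(collapse_fraction * len(eligible)))
    chosen_idx = sorted(rng.choice(len(eligible), size=n_collapse, replace=False)) if n_collapse else []
    excisions: dict[str, list[Interval]] = {c: [] for c in genome}
    removed_genes: set[str] = set()
    collapsed: list[tuple[str, int, int]] = []
    for i in chosen_idx:
        fam, chrom, ids = eligible[i]
        members = sorted((gene_by_id[g] for g in ids), key=lambda g: g.start)
        cut = Interval(members[collapse_keep].start, members[-1].end)
        excisions[chrom].append(cut)
        removed_genes.update(g.id for g in members[collapse_keep:])
        collapsed.append((fam, len(ids), collapse_keep))

    new_seqs: dict[str, str] = {}
    for chrom, seq in genome.sequences.items():
        exs = sorted(excisions[chrom], key=lambda iv: iv.start)
        if drop_pericentromere:
            seq = _gap_pericentromere(seq, chrom, truth)
        parts, last = [], 0
        for ex in exs:
            parts.append(seq[last : ex.start])
            last = ex.end
        parts.append(seq[last:])
        new_seqs[chrom] = "".join(parts)

    def remap_iv(chrom: str, iv: Interval) -> Interval:
        exs = sorted(excisions[chrom], key=lambda e: e.start)
        return Interval(_remap_after_excisions(iv.start, exs), _remap_after_excisions(iv.end, exs))

    new_genes = [
        replace(g, interval=remap_iv(g.chrom, g.interval), rank=-1)
        for g in annotations.genes
        if g.id not in removed_genes
    ]
    new_ltrs = [(c, remap_iv(c, iv)) for c, iv in annotations.ltr_intervals if not drop_pericentromere]

    new_truth = _copy_truth(truth)
    new_truth.collapsed_arrays = collapsed
    new_truth.chrom_lengths = {c: len(s) for c, s in new_seqs.items()}
    new_truth.telomeres = [(c, e, remap_iv(c, iv)) for c, e, iv in truth.telomeres]
    if drop_pericentromere:
        new_truth.centromeres = []
        new_truth.centromere_arrays = []
        new_truth.ltr_intervals = []
    else:
        new_truth.centromeres = [(c, remap_iv(c, iv), n) for c, iv, n in truth.centromeres]
        new_truth.centromere_arrays = [(c, remap_iv(c, iv), n) for c, iv, n in truth.centromere_arrays]
        new_truth.ltr_intervals = [(c, remap_iv(c, iv)) for c, iv in truth.ltr_intervals]
    kept_arrays = []
    for fam, chrom, ids in truth.tandem_arrays:
        kept = [g for g in ids if g not in removed_genes]
        if kept:
            kept_arrays.append((fam, chrom, kept))
    new_truth.tandem_arrays = kept_arrays

    degraded = Genome(new_seqs)
    degraded_ann = AnnotationSet(new_genes, new_ltrs)

    if inversion_count:
        junctions = {
            c: [_remap_after_excisions(ex.start, sorted(excisions[c], key=lambda e: e.start))
                for ex in excisions[c]]
            for c in genome
        }
        degraded, degraded_ann, inv_ivs = _apply_inversions(
            degraded, degraded_ann, inversion_count, rng, max_retries,
            forbidden_points=junctions, truth=new_truth,
        )
        new_truth.inversions = inv_ivs
    return degraded, degraded_ann, new_truth


def _gap_pericentromere(seq: str, chrom: str, truth: TruthSet) -> str:
    cen = truth.centromere_on(chrom)
    if cen is None:
        return seq
    fields = [iv for c, iv in truth.ltr_intervals if c == chrom]
    lo = min([iv.start for iv in fields] + [cen.start])
    hi = max([iv.end for iv in fields] + [cen.end])
    return seq[:lo] + "N" * (hi - lo) + seq[hi:]


def _apply_inversions(genome, annotations, count, rng, max_retries, forbidden_points, truth):
    """Invert ``count`` gene-bounded segments, flipping strands and remapping
    coordinates; segments must avoid collapse junctions, planted telomere and
    centromere tracks, and one another."""
    chroms = [c for c in genome if len(annotations.genes_on(c)) >= 8]
    chosen: list[tuple[str, Interval]] = []
    attempts = 0
    while len(chosen) < count:
        attempts += 1
        if attempts > max_retries * max(count, 1):
            raise RuntimeError("could not place the requested inversions")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        cg = annotations.genes_on(chrom)
        span = int(rng.integers(5, min(15, len(cg) - 1)))
        first = int(rng.integers(0, len(cg) - span))
        lo = max(0, cg[first].start - 200)
        hi = min(len(genome[chrom]), cg[first + span - 1].end + 200)
        iv = Interval(lo, hi)
        if any(lo < p < hi for p in forbidden_points.get(chrom, [])):
            continue
        if any(c == chrom and iv.overlaps(other) for c, other in chosen):
            continue
        blocked = [t[2] for t in truth.telomeres if t[0] == chrom]
        blocked += [t[1] for t in truth.centromeres if t[0] == chrom]
        if any(iv.overlaps(b) for b in blocked):
            continue
        # avoid bisecting genes outside the chosen run
        if any(g.interval.overlaps(iv) and not (lo <= g.start and g.end <= hi) for g in cg):
            continue
        chosen.append((chrom, iv))

    seqs = dict(genome.sequences)
    genes = list(annotations.genes)
    for chrom, iv in chosen:
        s = seqs[chrom]
        seqs[chrom] = s[: iv.start] + reverse_complement(s[iv.start : iv.end]) + s[iv.end :]
        flipped = []
        for g in genes:
            if g.chrom == chrom and iv.start <= g.start and g.end <= iv.end:
                new_start = iv.start + (iv.end - g.end)
                flipped.append(
                    replace(g, interval=Interval(new_start, new_start + len(g.interval)),
                            strand="-" if g.strand == "+" else "+", rank=-1)
                )
            else:
                flipped.append(g)
        genes = flipped
    new_ltrs = list(annotations.ltr_intervals)  # LTR fields never overlap chosen segments
    return Genome(seqs), AnnotationSet(genes, new_ltrs), chosen


def _copy_truth(truth: TruthSet) -> TruthSet:
    return TruthSet(
        telomeres=list(truth.telomeres),
        centromeres=list(truth.centromeres),
        centromere_arrays=list(truth.centromere_arrays),
        ltr_intervals=list(truth.ltr_intervals),
        tandem_arrays=[(f, c, list(ids)) for f, c, ids in truth.tandem_arrays],
        inversions=list(truth.inversions),
        collapsed_arrays=list(truth.collapsed_arrays),
        specific_genes=dict(truth.specific_genes),
        chrom_lengths=dict(truth.chrom_lengths),
        centromere_monomer=truth.centromere_monomer,
        orthology=dict(truth.orthology),
    )


# ---------------------------------------------------------------------------
# diverged ortholog ("second species") genome


def generate_ortholog_genome(
    genome: Genome,
    annotations: AnnotationSet,
    truth: TruthSet,
    substitution_rate: float = 0.1,
    inversion_count: int = 0,
    lineage_array_spec: dict[str, int] | None = None,
    seed: int = 0,
    chrom_prefix: str = "ort",
) -> tuple[Genome, AnnotationSet, TruthSet]:
    """Second species: mutated gene sequences, preserved gene order except
    planted order-reversing inversions, and per-family tandem array
    expansions/contractions given as {family_id: new_size}. The orthology
    map (gene id in A -> gene id in B) is recorded in the returned TruthSet.
    """
    rng = np.random.default_rng(seed)
    lineage_array_spec = lineage_array_spec or {}
    family_seqs: dict[str, str] = {}
    new_truth = TruthSet(centromere_monomer="")
    sequences: dict[str, str] = {}
    out_genes: list[GeneModel] = []

    for ci, chrom in enumerate(genome.names):
        new_chrom = f"{chrom_prefix}{ci + 1:02d}"
        src = annotations.genes_on(chrom)
        # items: (source gene or None for a new lineage copy, family)
        items: list[tuple[GeneModel | None, str | None]] = []
        fam_seen: dict[str, int] = {}
        for g in src:
            if g.family_id is None:
                items.append((g, None))
                continue
            size_now = sum(1 for s in src if s.family_id == g.family_id)
            target = lineage_array_spec.get(g.family_id, size_now)
            k = fam_seen.get(g.family_id, 0)
            fam_seen[g.family_id] = k + 1
            if k < target:
                items.append((g, g.family_id))
            if k == size_now - 1 and target > size_now:
                items.extend((None, g.family_id) for _ in range(target - size_now))

        # planted inversions reverse arm-sized runs of consecutive genes
        # (large relative to chaining rank gaps, as major inversions are)
        inv_runs: list[tuple[int, int]] = []
        per_chrom = 0
        # distribute inversions round-robin from the last chromosome down —
        # the early chromosomes carry the largest planted arrays, whose
        # near-identical members would make anchor order inherently ambiguous
        for j in range(inversion_count):
            if len(genome.names) - 1 - (j % len(genome.names)) == ci:
                per_chrom += 1
        attempts = 0
        while len(inv_runs) < per_chrom:
            attempts += 1
            if attempts > 200:
                raise RuntimeError("could not place the requested inversions")
            # arm-sized: over half the genes, so the inverted run both
            # exceeds default chaining rank gaps (no collinear chain can
            # step across it) and outscores any chain bridging its flanks
            lo = max(27, int(0.52 * len(items)))
            hi = max(lo + 1, int(0.62 * len(items)))
            span = int(rng.integers(lo, hi + 1))
            if span >= len(items):
                raise RuntimeError("too few genes for an arm-sized inversion")
            first = int(rng.integers(0, len(items) - span))
            if any(first < e and s < first + span for s, e in inv_runs):
                continue
            inv_runs.append((first, first + span))
        order = list(range(len(items)))
        flip = [False] * len(items)
        for s, e in sorted(inv_runs):
            order[s:e] = order[s:e][::-1]
            for k in range(s, e):
                flip[k] = True

        # lay out on fresh background
        builder_len = int(len(genome[chrom]))
        builder = _ChromBuilder(rng, builder_len)
        pos = 5_000
        counter = 0
        fam_members: dict[str, list[str]] = {}
        inv_gene_spans: dict[int, list[Interval]] = {}
        for slot, oi in enumerate(order):
            src_gene, fam = items[oi]
            if fam is not None and fam not in family_seqs:
                base = next(g for g in src if g.family_id == fam)
                family_seqs[fam] = genome[chrom][base.start : base.end]
            if src_gene is not None:
                seq = genome[chrom][src_gene.start : src_gene.end]
            else:
                seq = family_seqs[fam]
            seq = _mutate(seq, substitution_rate, rng)
            strand = src_gene.strand if src_gene is not None else "+"
            if flip[slot]:
                seq = reverse_complement(seq)
                strand = "-" if strand == "+" else "+"
            pos += int(rng.integers(500, 3_000))
            if pos + len(seq) > builder_len - 5_000:
                raise ValueError("ortholog layout exceeded chromosome length")
            iv = builder.plant(pos, seq)
            counter += 1
            gid = f"{new_chrom}.g{counter:03d}"
            out_genes.append(GeneModel(id=gid, chrom=new_chrom, interval=iv, strand=strand, family_id=fam))
            if src_gene is not None:
                new_truth.orthology[src_gene.id] = gid
            if fam is not None:
                fam_members.setdefault(fam, []).append(gid)
            for ri, (s, e) in enumerate(inv_runs):
                if s <= slot < e:
                    inv_gene_spans.setdefault(ri, []).append(iv)
            pos = iv.end
        for ri, ivs in inv_gene_spans.items():
            new_truth.inversions.append(
                (new_chrom, Interval(min(v.start for v in ivs), max(v.end for v in ivs)))
            )
        for fam, ids in fam_members.items():
            if len(ids) >= 2:
                new_truth.tandem_arrays.append((fam, new_chrom, ids))
        sequences[new_chrom] = builder.text()
        new_truth.chrom_lengths[new_chrom] = builder_len

    return Genome(sequences), AnnotationSet(out_genes), new_truth


# ---------------------------------------------------------------------------
# Hi-C contacts


def generate_contact_matrix(
    truth: TruthSet,
    bin_size: int = 25_000,
    decay_exponent: float = 1.0,
    depression_factor: float = 0.3,
    noise_dispersion: float = 0.0,
    seed: int = 0,
    scale: float = 500.0,
) -> dict[str, ContactMatrix]:
    """Per-chromosome binned contacts with power-law distance decay and a
    multiplicative depression for bin pairs touching a planted centromere.

    Expected count for bins i, j is ``scale * (1 + d)^(-decay_exponent)``
    with d the bin-center distance in bp, times ``depression_factor`` when
    either bin overlaps the centromere. ``noise_dispersion`` > 0 switches on
    gamma-Poisson (negative binomial) noise with that inverse-size value.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, ContactMatrix] = {}
    for chrom, L in truth.chrom_lengths.items():
        if bin_size >= L:
            raise ValueError(f"bin_size {bin_size} >= chromosome length {L}")
        n = math.ceil(L / bin_size)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))  # bin-distance
        mu = scale * np.power(1.0 + d, -decay_exponent)
        cen = truth.centromere_on(chrom)
        if cen is not None and depression_factor != 1.0:
            starts = np.arange(n) * bin_size
            in_cen = (starts < cen.end) & (starts + bin_size > cen.start)
            mask = np.logical_or.outer(in_cen, in_cen)
            mu = np.where(mask, mu * depression_factor, mu)
        if noise_dispersion > 0:
            shape = 1.0 / noise_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
        else:
            counts = np.rint(mu).astype(np.int64)
        counts = np.triu(counts)
        counts = counts + np.triu(counts, 1).T
        out[chrom] = ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts.astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# expression counts


def generate_expression_counts(
    annotations: AnnotationSet,
    n_tissues: int = 10,
    specific_fraction: float = 0.1,
    library_size: int = 20_000_000,
    seed: int = 0,
    detectable_fraction: float = 0.65,
    dispersion: float = 0.05,
    truth: TruthSet | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x tissue count matrix with planted tissue-specific genes.

    A ``specific_fraction`` of genes is planted to exceed FPKM 1 in exactly
    one tissue and stay below 1 elsewhere; of the rest, ``detectable_fraction``
    are broadly expressed above FPKM 1 and the remainder near-silent. Counts
    are negative binomial around the FPKM-implied means. Updates
    ``truth.specific_genes`` when a TruthSet is passed.
    """
    if specific_fraction > 0 and n_tissues < 2:
        raise ValueError("tissue-specific planting needs at least 2 tissues")
    rng = np.random.default_rng(seed)
    genes = [g.id for g in annotations.genes]
    lengths = pd.Series({g.id: len(g.interval) for g in annotations.genes}, name="length")
    n = len(genes)
    n_specific = int(round(specific_fraction * n))
    order = rng.permutation(n)
    specific = [genes[i] for i in order[:n_specific]]
    rest = [genes[i] for i in order[n_specific:]]
    n_detect = int(round(detectable_fraction * len(rest)))
    broad, silent = rest[:n_detect], rest[n_detect:]

    tissues = [f"tissue{t + 1:02d}" for t in range(n_tissues)]
    target = pd.DataFrame(0.0, index=genes, columns=tissues)
    spec_map: dict[str, str] = {}
    for gid in specific:
        t = tissues[int(rng.integers(0, n_tissues))]
        target.loc[gid, :] = 0.05
        target.loc[gid, t] = rng.uniform(5, 50)
        spec_map[gid] = t
    for gid in broad:
        base = rng.uniform(3, 100)
        target.loc[gid, :] = base * rng.uniform(0.7, 1.3, size=n_tissues)
    for gid in silent:
        target.loc[gid, :] = 0.02

    len_kb = lengths.loc[genes] / 1_000.0
    lib_m = library_size / 1e6
    mu = target.mul(len_kb, axis=0) * lib_m
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu.to_numpy() / shape)
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=tissues)
    if truth is not None:
        truth.specific_genes = spec_map
    return counts, lengths
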