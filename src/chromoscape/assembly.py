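"""Assembly summary statistics and terminal telomere detection.

N50-style statistics follow the standard convention: nX is the length L of
the sequence that carries the cumulative sum across the fraction-X boundary
when sequences are walked longest-first.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .core import Genome, Interval, TelomereCall, reverse_complement

#: Plant consensus telomeric repeat (Arabidopsis-type).
PLANT_TELOMERE_MOTIF = "TTTAGGG"


@dataclass
class AssemblySummary:
    total_size: int
    n_sequences: int
    nX_values: dict[int, int]  # percent (10..90) -> length
    gap_count: int
    gap_bases: int


def nX(lengths: list[int], fraction: float) -> int:
    """Length L such that sequences of length >= L hold >= fraction of all bases.

    ``fraction=0.5`` gives the N50. Raises on empty input, non-positive
    lengths, or a fraction outside (0, 1).
    """
    if not lengths:
        raise ValueError("nX of an empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("sequence lengths must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    target = fraction * sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= target:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_summary(genome: Genome) -> AssemblySummary:
    """Totals, N10..N90, and gap (N-run) statistics for an assembly."""
    if len(genome) == 0:
        raise ValueError("empty genome")
    lengths = list(genome.lengths.values())
    gap_count = 0
    gap_bases = 0
    for seq in genome.sequences.values():
        for m in re.finditer(r"N+", seq):
            gap_count += 1
            gap_bases += m.end() - m.start()
    return AssemblySummary(
        total_size=sum(lengths),
        n_sequences=len(lengths),
        nX_values={x: nX(lengths, x / 100) for x in range(10, 100, 10)},
        gap_count=gap_count,
        gap_bases=gap_bases,
    )


def busco_percent(found: int, total: int) -> int:
    """Completeness as an integer percent, e.g. 1,352 of 1,440 -> 94."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= found <= total:
        raise ValueError("found must be within [0, total]")
    return round(100 * found / total)


def _motif_runs(seq: str, motif: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Maximal tandem runs of ``motif`` in ``seq`` as (start, n_copies).

    A run is a chain of consecutive motif-length frames, each within
    ``max_mismatch`` Hamming distance of the motif.
    """
    m = len(motif)
    n = len(seq)
    ok = [
        sum(a != b for a, b in zip(seq[i : i + m], motif)) <= max_mismatch
        for i in range(n - m + 1)
    ]
    runs: list[tuple[int, int]] = []
    # runs can start at any phase; chain greedily and skip past each run
    i = 0
    while i < len(ok):
        if ok[i]:
            start = i
            copies = 0
            while i < len(ok) and ok[i]:
                copies += 1
                i += m
            runs.append((start, copies))
        else:
            i += 1
    return runs


def detect_telomeres(
    genome: Genome,
    motif: str = PLANT_TELOMERE_MOTIF,
    min_copies: int = 10,
    terminal_window: int = 10_000,
    max_divergence: float = 0.1,
) -> list[TelomereCall]:
    """Longest terminal tandem motif run at each chromosome end.

    Both the motif and its reverse complement are searched at both ends
    (telomeres read off either strand depending on orientation); at most
    one call per end is reported, the one with the most copies.
    """
    if len(motif) < 5:
        raise ValueError("motif length must be >= 5")
    max_mm = int(max_divergence * len(motif))
    calls: list[TelomereCall] = []
    for chrom, seq in genome.sequences.items():
        window = terminal_window
        if window > len(seq):
            warnings.warn(f"terminal window clipped to chromosome length on {chrom}")
            window = len(seq)
        for end_label in ("left", "right"):
            offset = 0 if end_label == "left" else len(seq) - window
            segment = seq[offset : offset + window]
            best: TelomereCall | None = None
            for m in (motif, reverse_complement(motif)):
                for start, copies in _motif_runs(segment, m, max_mm):
                    if copies < min_copies:
                        continue
                    iv = Interval(offset + start, offset + start + copies * len(m))
                    if best is None or copies > best.copy_number:
                        best = TelomereCall(chrom, end_label, iv, copies, motif)
            if best is not None:
                calls.append(best)
    return calls
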