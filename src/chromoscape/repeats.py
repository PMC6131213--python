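"""Tandem repeat landscape: satellite monomer discovery, centromeric array
scanning with identity scoring, and sliding-window density tracks.

Monomer discovery uses a k-mer recurrence-distance histogram: the distances
between successive occurrences of each k-mer vote for candidate periods, and
a consensus monomer is read off a period-phased stack of frames. Array
scanning locates approximate monomer matches with banded edit-distance
alignment (edlib) and phases each candidate region into consecutive
monomer-length elements anchored at the best first match.
"""

from __future__ import annotations

import re
from collections import Counter

import edlib
import numpy as np
import pandas as pd

from .core import (
    DensityTrack,
    Genome,
    Interval,
    RepeatArray,
    TelomereCall,
    merge_intervals,
    reverse_complement,
)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns, in [0, 1]."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches / columns


def mean_element_identity(elements: list[str], monomer: str) -> float:
    """Mean element-vs-consensus global-alignment identity, as a percent."""
    if not elements:
        raise ValueError("no elements")
    return 100.0 * float(np.mean([alignment_identity(e, monomer) for e in elements]))


def pairwise_mean_identity(elements: list[str]) -> float:
    """All-pairs mean identity (percent); the alternative reading of
    'element homology', quadratic cost — use on small arrays."""
    if len(elements) < 2:
        raise ValueError("need >= 2 elements")
    vals = [
        alignment_identity(elements[i], elements[j])
        for i in range(len(elements))
        for j in range(i + 1, len(elements))
    ]
    return 100.0 * float(np.mean(vals))


def find_tandem_monomer(
    sequence: str,
    min_period: int = 50,
    max_period: int = 2_000,
    k: int = 13,
    min_support: int = 10,
) -> list[tuple[str, int, int]]:
    """Dominant tandem periodicities of a sequence.

    Returns (consensus monomer, period, support) tuples ranked by support.
    Support is the number of k-mer recurrences voting for the period; random
    sequence of desk scale yields essentially no votes, so ``min_support``
    acts as the null cutoff.
    """
    if max_period < min_period or min_period < 10:
        raise ValueError("require max_period >= min_period >= 10")
    n = len(sequence)
    if n < 3 * min_period:
        return []
    last: dict[str, int] = {}
    votes: Counter[int] = Counter()
    vote_pos: dict[int, list[int]] = {}
    for i in range(n - k + 1):
        kmer = sequence[i : i + k]
        prev = last.get(kmer)
        if prev is not None:
            d = i - prev
            if min_period <= d <= max_period:
                votes[d] += 1
                vote_pos.setdefault(d, []).append(prev)
        last[kmer] = i

    results: list[tuple[str, int, int]] = []
    taken: list[int] = []
    for period, support in votes.most_common():
        if support < min_support:
            break
        if any(abs(period - t) <= 2 for t in taken):
            continue
        taken.append(period)
        # phase only across the span where the periodicity actually voted
        span_lo = min(vote_pos[period])
        span_hi = min(n, max(vote_pos[period]) + 2 * period)
        consensus = _phased_consensus(sequence[span_lo:span_hi], 0, period)
        results.append((consensus, period, support))
    return results


def _phased_consensus(sequence: str, anchor: int, period: int) -> str:
    frames = []
    pos = anchor
    while pos + period <= len(sequence):
        frames.append(sequence[pos : pos + period])
        pos += period
    pos = anchor - period
    while pos >= 0:
        frames.insert(0, sequence[pos : pos + period])
        pos -= period
    if not frames:
        return sequence[anchor : anchor + period]
    stack = np.frombuffer("".join(frames).encode(), dtype=np.uint8).reshape(len(frames), period)
    consensus = np.empty(period, dtype=np.uint8)
    for col in range(period):
        vals, counts = np.unique(stack[:, col], return_counts=True)
        consensus[col] = vals[np.argmax(counts)]
    return consensus.tobytes().decode()


def _anchor_scan(seq: str, monomer: str, min_identity: float) -> list[Interval]:
    """Coarse scan: stride-L windows, banded infix alignment of the monomer."""
    L = len(monomer)
    max_edits = int(L * (1 - min_identity / 100.0)) + 2
    hits: list[Interval] = []
    for p in range(0, max(1, len(seq) - L + 1), L):
        window = seq[p : p + 2 * L]
        if len(window) < L // 2:
            break
        res = edlib.align(monomer, window, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] == -1:
            continue
        s, e = res["locations"][0]
        hits.append(Interval(p + s, p + e + 1))
    return hits


def scan_repeat_arrays(
    genome: Genome,
    monomer: str,
    min_copies: int = 5,
    min_identity: float = 70.0,
    max_gap: int | None = None,
) -> list[RepeatArray]:
    """Find tandem arrays of ``monomer`` (either strand) genome-wide.

    Approximate matches with alignment identity >= ``min_identity`` are
    merged into candidate regions when separated by <= ``max_gap``; each
    region is phased into consecutive monomer-length elements anchored at
    its best first match, and reported when it holds >= ``min_copies``.
    """
    if not monomer:
        raise ValueError("empty monomer")
    L = len(monomer)
    if max_gap is None:
        max_gap = 2 * L
    out: list[RepeatArray] = []
    for chrom, seq in genome.sequences.items():
        anchors: list[Interval] = []
        for m in (monomer, reverse_complement(monomer)):
            anchors.extend(_anchor_scan(seq, m, min_identity))
        if not anchors:
            continue
        regions: list[Interval] = []
        for iv in sorted(anchors, key=lambda v: v.start):
            if regions and iv.start - regions[-1].end <= max_gap:
                if iv.end > regions[-1].end:
                    regions[-1] = Interval(regions[-1].start, iv.end)
            else:
                regions.append(iv)
        claimed: list[Interval] = []
        for region in regions:
            arr = _phase_region(seq, region, monomer, min_identity, max_gap)
            if arr is None or arr[1] < min_copies:
                continue
            iv, copies, identity = arr
            if any(iv.overlaps(c) for c in claimed):
                continue
            claimed.append(iv)
            out.append(RepeatArray(chrom, iv, L, copies, identity))
    return out


def _phase_region(seq: str, region: Interval, monomer: str, min_identity: float, max_gap: int):
    """Phase a candidate region into monomer-length frames; returns
    (interval, copy_number, mean_identity_percent) or None."""
    L = len(monomer)
    rc = reverse_complement(monomer)
    lo = max(0, region.start - 2 * L)
    hi = min(len(seq), region.start + 2 * L)
    best = None
    for m in (monomer, rc):
        res = edlib.align(m, seq[lo:hi], mode="HW", task="locations")
        if res["editDistance"] != -1 and (best is None or res["editDistance"] < best[0]):
            best = (res["editDistance"], lo + res["locations"][0][0], m)
    if best is None:
        return None
    _, anchor, mono = best
    thr = min_identity / 100.0
    allowed_skip = max_gap // L

    def frame_identity(pos: int) -> float:
        frame = seq[pos : pos + L]
        if len(frame) < L:
            return 0.0
        return alignment_identity(frame, mono)

    idents: list[tuple[int, float]] = []
    pos = anchor
    skips = 0
    while pos + L <= len(seq):
        ident = frame_identity(pos)
        if ident >= thr:
            idents.append((pos, ident))
            skips = 0
        else:
            skips += 1
            if skips > allowed_skip or not idents:
                break
        pos += L
    pos = anchor - L
    skips = 0
    while pos >= 0:
        ident = frame_identity(pos)
        if ident >= thr:
            idents.insert(0, (pos, ident))
            skips = 0
        else:
            skips += 1
            if skips > allowed_skip:
                break
        pos -= L
    if not idents:
        return None
    start = idents[0][0]
    end = idents[-1][0] + L
    mean_ident = 100.0 * float(np.mean([v for _p, v in idents]))
    return Interval(start, end), len(idents), mean_ident


def windowed_density(
    intervals: list[Interval],
    chrom_length: int,
    window: int = 50_000,
    step: int = 25_000,
    chrom: str = "",
) -> DensityTrack:
    """Fraction of bases covered by the interval union, in sliding windows
    starting at multiples of ``step``; the last window is truncated at the
    chromosome end."""
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    for iv in intervals:
        if iv.start < 0 or iv.end > chrom_length:
            raise ValueError(f"interval {iv} outside [0, {chrom_length})")
    merged = merge_intervals(intervals)
    starts = np.array([iv.start for iv in merged], dtype=np.int64)
    ends = np.array([iv.end for iv in merged], dtype=np.int64)
    values: list[float] = []
    for w_start in range(0, chrom_length, step):
        w_end = min(w_start + window, chrom_length)
        if len(starts):
            cov = np.clip(np.minimum(ends, w_end) - np.maximum(starts, w_start), 0, None).sum()
        else:
            cov = 0
        values.append(float(cov) / (w_end - w_start))
    return DensityTrack(chrom=chrom, window=window, step=step, values=values)


def landscape_table(
    genome: Genome,
    gene_intervals: list[tuple[str, Interval]],
    ltr_intervals: list[tuple[str, Interval]],
    arrays: list[RepeatArray],
    telomeres: list[TelomereCall],
    window: int = 50_000,
    step: int = 25_000,
) -> pd.DataFrame:
    """Joined per-bin landscape: LTR, gene and centromeric-repeat density
    plus telomere call positions, one row per (chrom, bin)."""
    known = set(genome.names)
    seen = (
        {c for c, _ in gene_intervals}
        | {c for c, _ in ltr_intervals}
        | {a.chrom for a in arrays}
        | {t.chrom for t in telomeres}
    )
    offenders = sorted(seen - known)
    if offenders:
        raise ValueError(f"unknown chromosomes in annotation tracks: {offenders}")
    rows = []
    for chrom, L in genome.lengths.items():
        tracks = {
            "gene_density": windowed_density([iv for c, iv in gene_intervals if c == chrom], L, window, step, chrom),
            "ltr_density": windowed_density([iv for c, iv in ltr_intervals if c == chrom], L, window, step, chrom),
            "cent_density": windowed_density([a.interval for a in arrays if a.chrom == chrom], L, window, step, chrom),
        }
        tel_pos = {t.end_label: (t.interval.start + t.interval.end) // 2 for t in telomeres if t.chrom == chrom}
        n_bins = len(tracks["gene_density"].values)
        for b in range(n_bins):
            b_start = b * step
            b_end = min(b_start + window, L)
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b_start,
                    "gene_density": tracks["gene_density"].values[b],
                    "ltr_density": tracks["ltr_density"].values[b],
                    "cent_density": tracks["cent_density"].values[b],
                    "telomere": any(b_start <= p < b_end for p in tel_pos.values()),
                }
            )
    return pd.DataFrame(rows)
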