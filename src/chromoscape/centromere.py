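"""Centromere calling from three evidence tracks.

A centromere call integrates (1) centromere-specific tandem repeat arrays,
(2) high LTR retrotransposon density (>85% by default) at the borders, and
(3) depressed intra-chromosomal Hi-C interaction. The seed of a call is the
union of repeat arrays overlapping the Hi-C depression minimum; borders are
extended outward while windowed LTR density stays above the threshold
(tolerating one sub-threshold window) or further arrays occur. A chromosome
with neither array support nor a depression region yields ``no_call``.
When Hi-C and repeat evidence disagree on location, the repeat arrays win.
"""

from __future__ import annotations

import numpy as np

from .core import CentromereCall, ContactMatrix, DensityTrack, Interval, RepeatArray, merge_intervals


def contact_depression_track(matrix: ContactMatrix, smooth_bins: int = 3) -> np.ndarray:
    """Relative intra-chromosomal interaction per bin (1 = chromosome-typical).

    Row sums excluding the diagonal, smoothed by a running mean over
    ``smooth_bins`` bins, divided by the chromosome median. Scale-invariant:
    multiplying the matrix by a positive constant leaves the track unchanged.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    n = counts.shape[0]
    if n < 5:
        raise ValueError("need at least 5 bins")
    if not counts.any():
        raise ValueError("all-zero contact matrix")
    row = counts.sum(axis=1) - np.diag(counts)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        padded = np.pad(row, pad, mode="edge")
        row = np.convolve(padded, kernel, mode="valid")[:n]
    med = np.median(row)
    if med == 0:
        raise ValueError("median interaction is zero")
    return row / med


def _depression_region(depression: np.ndarray, bin_size: int, threshold: float) -> Interval | None:
    """Contiguous sub-threshold run containing the global minimum, in bp."""
    below = depression < threshold
    if not below.any():
        return None
    i = int(np.argmin(depression))
    if not below[i]:
        return None
    lo = i
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = i
    while hi + 1 < len(below) and below[hi + 1]:
        hi += 1
    return Interval(lo * bin_size, (hi + 1) * bin_size)


def _extend_by_ltr(interval: Interval, ltr_track: DensityTrack, chrom_length: int,
                   threshold: float, gap_tolerance: int = 1) -> tuple[Interval, bool]:
    """Extend outward while windowed LTR density exceeds the threshold,
    allowing ``gap_tolerance`` sub-threshold windows. Returns the extended
    interval and whether any extension happened."""
    step = ltr_track.step
    window = ltr_track.window
    values = ltr_track.values
    n = len(values)
    extended = False

    # only windows lying fully outside the current interval are judged, so
    # the (LTR-free) satellite array itself never dilutes a border window
    s = interval.start
    i = (s - window) // step
    gaps = 0
    while i >= 0:
        if values[i] > threshold:
            s = i * step
            extended = True
            gaps = 0
        else:
            gaps += 1
            if gaps > gap_tolerance:
                break
        i -= 1

    e = interval.end
    i = (e + step - 1) // step
    gaps = 0
    while i < n:
        if values[i] > threshold:
            e = min(i * step + window, chrom_length)
            extended = True
            gaps = 0
        else:
            gaps += 1
            if gaps > gap_tolerance:
                break
        i += 1
    return Interval(max(s, 0), min(e, chrom_length)), extended


def call_centromere(
    chrom: str,
    arrays: list[RepeatArray],
    ltr_track: DensityTrack | None,
    depression: np.ndarray | None = None,
    depression_bin_size: int | None = None,
    ltr_threshold: float = 0.85,
    depression_threshold: float = 0.6,
    chrom_length: int | None = None,
) -> CentromereCall:
    """Integrate the three evidence tracks into one per-chromosome call."""
    arrays = [a for a in arrays if a.chrom == chrom]
    if chrom_length is None:
        if ltr_track is not None:
            chrom_length = len(ltr_track.values) * ltr_track.step
        elif depression is not None and depression_bin_size is not None:
            chrom_length = len(depression) * depression_bin_size
        else:
            raise ValueError("chrom_length required when no track is supplied")
    if depression is not None and depression_bin_size is None:
        raise ValueError("depression supplied without depression_bin_size")

    dep_region = (
        _depression_region(depression, depression_bin_size, depression_threshold)
        if depression is not None
        else None
    )

    evidence: set[str] = set()
    if arrays:
        overlapping = [a for a in arrays if dep_region is not None and a.interval.overlaps(dep_region)]
        if overlapping:
            seeds = [a.interval for a in overlapping]
        else:
            # repeat evidence wins on disagreement: seed at the largest array
            seeds = [max(arrays, key=lambda a: a.copy_number).interval]
        merged = merge_intervals(seeds)
        seed = Interval(merged[0].start, merged[-1].end)
        evidence.add("repeat_array")
        if dep_region is not None and seed.overlaps(dep_region):
            evidence.add("hic_depression")
    elif dep_region is not None:
        seed = dep_region
        evidence.add("hic_depression")
    else:
        return CentromereCall(chrom=chrom, interval=None, evidence=frozenset(), status="no_call")

    interval = seed
    if ltr_track is not None:
        interval, extended = _extend_by_ltr(seed, ltr_track, chrom_length, ltr_threshold)
        if extended:
            evidence.add("ltr_density")
        # absorb further arrays reachable from the extended borders
        changed = True
        while changed:
            changed = False
            for a in arrays:
                if a.interval.overlaps(interval) and not (
                    interval.start <= a.interval.start and a.interval.end <= interval.end
                ):
                    interval = Interval(
                        min(interval.start, a.interval.start), max(interval.end, a.interval.end)
                    )
                    changed = True
            if changed:
                interval, ext2 = _extend_by_ltr(interval, ltr_track, chrom_length, ltr_threshold)
                changed = changed or ext2

    status = "called" if ("repeat_array" in evidence or
                          {"ltr_density", "hic_depression"} <= evidence) else "no_call"
    if status == "no_call":
        return CentromereCall(chrom=chrom, interval=None, evidence=frozenset(evidence), status="no_call")
    return CentromereCall(chrom=chrom, interval=interval, evidence=frozenset(evidence), status="called")


def centromere_summary(calls: list[CentromereCall]) -> dict:
    """Mean/min/max size over called chromosomes; no-calls listed separately."""
    if not calls:
        raise ValueError("no calls")
    called = [c for c in calls if c.status == "called"]
    summary = {
        "n_called": len(called),
        "n_no_call": len(calls) - len(called),
        "no_call_chroms": [c.chrom for c in calls if c.status != "called"],
    }
    if called:
        sizes = [c.size for c in called]
        summary.update(
            mean_size=float(np.mean(sizes)),
            min_size=int(min(sizes)),
            max_size=int(max(sizes)),
        )
    return summary
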