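"""Fragment-depth coverage tracks and scaled fractional-count normalization.

A :class:`CoverageTrack` is a run-length-encoded, per-chromosome map of
sorted, disjoint ``[start, end) -> value`` intervals; everything not covered
by an explicit interval has value zero.  This mirrors bedGraph semantics.

The fractional-count normalization rescales per-bp depth by
``genome_size / total_covered_bp`` so that uniformly distributed coverage
has value 1 at every base pair.  The normalizing denominator is the summed
per-bp depth (total fragment base pairs), not the fragment count: only this
reading gives the value-1-everywhere property for finite-length fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core_io import FragmentSet, GenomeSpec

__all__ = ["CoverageTrack", "fragment_depth", "fractional_count_track", "scale_track"]

ChromRuns = tuple[np.ndarray, np.ndarray, np.ndarray]  # starts, ends, values


@dataclass
class CoverageTrack:
    """Sorted disjoint value-bearing intervals over a genome; implicit zeros."""

    genome: str
    data: dict[str, ChromRuns] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, ChromRuns] = {}
        for chrom, (starts, ends, values) in self.data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged run arrays")
            if np.any(starts >= ends):
                raise ValueError(f"{chrom}: empty or inverted run")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping or unsorted runs")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{chrom}: non-finite values")
            keep = values != 0.0
            if not keep.any():
                continue
            starts, ends, values = starts[keep], ends[keep], values[keep]
            # canonical form: coalesce book-ended runs of equal value
            new_run = np.ones(len(starts), dtype=bool)
            new_run[1:] = (starts[1:] != ends[:-1]) | (values[1:] != values[:-1])
            idx = np.flatnonzero(new_run)
            run_ends = np.append(idx[1:], len(starts)) - 1
            clean[chrom] = (starts[idx], ends[run_ends], values[idx])
        self.data = clean

    def iter_intervals(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def total_signal(self) -> float:
        """Sum over all base pairs of the track value (bp-weighted sum)."""
        total = 0.0
        for starts, ends, values in self.data.values():
            total += float(np.sum((ends - starts) * values))
        return total

    def value_at(self, chrom: str, pos: int) -> float:
        """Track value at a single base pair (0 where uncovered)."""
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def window_sum(self, chrom: str, lo: int, hi: int) -> float:
        """Sum of per-bp values over [lo, hi); implicit zeros contribute 0."""
        if chrom not in self.data or hi <= lo:
            return 0.0
        starts, ends, values = self.data[chrom]
        first = int(np.searchsorted(ends, lo, side="right"))
        last = int(np.searchsorted(starts, hi, side="left"))
        if first >= last:
            return 0.0
        s = np.maximum(starts[first:last], lo)
        e = np.minimum(ends[first:last], hi)
        return float(np.sum((e - s) * values[first:last]))

    def to_array(self, chrom: str, length: int) -> np.ndarray:
        """Materialize one chromosome as a dense per-bp array (tests/oracles)."""
        arr = np.zeros(length, dtype=float)
        if chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                arr[s:e] += v
        return arr


def fragment_depth(fs: FragmentSet, genome: GenomeSpec) -> CoverageTrack:
    """Per-bp fragment depth as a run-length-encoded track.

    The value at base x is the number of fragments whose interval contains x.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for frag in fs:
        iv = frag.interval
        if iv.chrom not in genome:
            raise ValueError(f"fragment on unknown chromosome {iv.chrom!r}")
        if iv.end > genome.chrom_sizes[iv.chrom]:
            raise ValueError(f"fragment {iv} outside chromosome bounds")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    data: dict[str, ChromRuns] = {}
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        # breakpoint sweep: +1 at starts, -1 at ends, cumulative sum per run
        edges = np.concatenate([arr[:, 0], arr[:, 1]])
        deltas = np.concatenate(
            [np.ones(len(arr), dtype=np.int64), -np.ones(len(arr), dtype=np.int64)]
        )
        order = np.argsort(edges, kind="stable")
        edges, deltas = edges[order], deltas[order]
        uniq, idx = np.unique(edges, return_index=True)
        summed = np.add.reduceat(deltas, idx)
        depth = np.cumsum(summed)[:-1]
        starts, ends = uniq[:-1], uniq[1:]
        data[chrom] = (starts, ends, depth.astype(float))
    return CoverageTrack(genome=genome.name, data=data)


def fractional_count_track(depth: CoverageTrack, genome: GenomeSpec) -> CoverageTrack:
    """Scaled fractional-count normalization of a depth track.

    value(x) = depth(x) * genome.total_size / sum_y depth(y), so the
    base-pair-weighted mean over the genome is exactly 1 and uniform unit
    depth maps to 1 everywhere.
    """
    total = depth.total_signal()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero depth track")
    return scale_track(depth, genome.total_size / total)


def scale_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Multiply every value by *factor*; interval structure unchanged."""
    if not (factor > 0 and math.isfinite(factor)):
        raise ValueError(f"scale factor must be positive and finite, got {factor}")
    data = {
        chrom: (starts.copy(), ends.copy(), values * factor)
        for chrom, (starts, ends, values) in track.data.items()
    }
    return CoverageTrack(genome=track.genome, data=data)
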