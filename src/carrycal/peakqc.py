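"""Peak-summit scoring, IgG outlier filtering, correlation matrices, FRiP.

The reproducibility pipeline for a sample series:

1. score every peak in every sample as the mean coverage over the window
   ``[summit - flank, summit + flank]`` (inclusive, 2*flank + 1 bp, default
   flank 150, truncated at chromosome ends, uncovered bases counting as 0);
2. drop peaks whose IgG-control score exceeds the 99th percentile of all
   IgG scores (linear-interpolation percentile, strictly-greater removal) —
   these are non-specific accessibility artifacts;
3. assemble the peaks x samples score matrix and compute pairwise Pearson
   correlations over peak vectors, reported as R^2;
4. summarize signal-to-noise as FRiP (fraction of fragments overlapping any
   peak by >= 1 bp), optionally over a down-sampling series to compare
   samples at matched depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import FragmentSet, GenomeSpec, PeakRecord, merge_intervals, sample_fragments
from .coverage import CoverageTrack

__all__ = [
    "ScoreMatrix",
    "QCConfig",
    "peak_summit_scores",
    "igg_peak_filter",
    "build_score_matrix",
    "correlation_matrix",
    "frip",
    "frip_series",
]

DEFAULT_DEPTHS = (5_000_000, 2_500_000, 1_250_000, 625_000, 312_500)


@dataclass(frozen=True)
class QCConfig:
    """Tunable QC parameters: summit flank (bp), IgG removal percentile,
    down-sampling depth series, and the seed driving subsampling."""

    flank: int = 150
    igg_percentile: float = 99.0
    downsample_depths: tuple[int, ...] = DEFAULT_DEPTHS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if not 0 < self.igg_percentile < 100:
            raise ValueError("igg_percentile must be in (0, 100)")
        depths = tuple(self.downsample_depths)
        if any(b >= a for a, b in zip(depths, depths[1:])):
            raise ValueError("downsample_depths must be strictly decreasing")


@dataclass
class ScoreMatrix:
    """Peaks x samples matrix of mean summit-window scores (NaN = missing)."""

    peaks: list[PeakRecord]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peaks), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} != ({len(self.peaks)}, {len(self.samples)})"
            )

    def to_frame(self) -> pd.DataFrame:
        index = [
            f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
            for p in self.peaks
        ]
        return pd.DataFrame(self.values, index=index, columns=self.samples)


def peak_summit_scores(
    track: CoverageTrack,
    peaks: Sequence[PeakRecord],
    flank: int = 150,
    genome: GenomeSpec | None = None,
) -> np.ndarray:
    """Mean track value over [summit - flank, summit + flank] per peak.

    The window is inclusive on both sides (2*flank + 1 bp) and truncated at
    chromosome ends when a genome is supplied; uncovered base pairs count
    as zero in the mean.
    """
    scores = np.empty(len(peaks), dtype=float)
    for i, peak in enumerate(peaks):
        chrom, summit = peak.interval.chrom, peak.summit
        if genome is not None:
            if chrom not in genome:
                raise ValueError(f"peak {i}: unknown chromosome {chrom!r}")
            chrom_len = genome.chrom_sizes[chrom]
            if not 0 <= summit < chrom_len:
                raise ValueError(
                    f"peak {i} ({chrom}:{summit}): summit outside chromosome"
                )
            lo = max(0, summit - flank)
            hi = min(chrom_len, summit + flank + 1)
        else:
            lo = max(0, summit - flank)
            hi = summit + flank + 1
        scores[i] = track.window_sum(chrom, lo, hi) / (hi - lo)
    return scores


def igg_peak_filter(scores_igg: np.ndarray, percentile: float = 99.0) -> np.ndarray:
    """Indices of peaks whose IgG score does not exceed the given percentile.

    The percentile is computed by linear interpolation between order
    statistics; peaks with scores *strictly greater* than the threshold are
    removed.  With all-equal scores nothing is removed.
    """
    scores_igg = np.asarray(scores_igg, dtype=float)
    if scores_igg.size == 0:
        raise ValueError("empty IgG score list")
    threshold = np.percentile(scores_igg, percentile, method="linear")
    return np.flatnonzero(scores_igg <= threshold)


def build_score_matrix(
    tracks: dict[str, CoverageTrack],
    peaks: Sequence[PeakRecord],
    flank: int = 150,
    genome: GenomeSpec | None = None,
) -> ScoreMatrix:
    """Peaks x samples matrix of summit-window means, one column per track."""
    genomes = {t.genome for t in tracks.values() if t.genome}
    if len(genomes) > 1:
        raise ValueError(f"tracks on different genomes: {sorted(genomes)}")
    samples = list(tracks)
    values = np.column_stack(
        [peak_summit_scores(tracks[s], peaks, flank, genome) for s in samples]
    ) if samples else np.empty((len(peaks), 0))
    return ScoreMatrix(peaks=list(peaks), samples=samples, values=values)


def correlation_matrix(
    m: ScoreMatrix, use_complete_rows: bool = True, squared: bool = True
) -> pd.DataFrame:
    """Pairwise Pearson correlation of sample score vectors, as R^2.

    Mirrors complete-observation handling: any peak row containing a missing
    entry for any sample is dropped before *all* pairwise correlations.
    Zero-variance columns give NaN off-diagonal entries with a warning.
    """
    values = m.values
    if use_complete_rows:
        values = values[~np.isnan(values).any(axis=1)]
    if values.shape[0] < 2:
        raise ValueError("need >= 2 complete peak rows for correlations")
    n = len(m.samples)
    out = np.ones((n, n), dtype=float)
    sd = values.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    for j in degenerate:
        warnings.warn(f"sample {m.samples[j]!r}: zero variance over peaks")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    out[:] = corr
    for j in degenerate:
        out[j, :] = np.nan
        out[:, j] = np.nan
        out[j, j] = np.nan
    if squared:
        out = out**2
    return pd.DataFrame(out, index=m.samples, columns=m.samples)


def frip(fs: FragmentSet, peaks: Sequence[PeakRecord]) -> float:
    """Fraction of fragments overlapping >= 1 peak by >= 1 bp.

    Fragments (pairs), not reads, are the unit.  Invariant to peak order and
    to merging of overlapping peaks.
    """
    if len(fs) == 0:
        raise ValueError("empty fragment set")
    merged = merge_intervals([p.interval for p in peaks])
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in merged}:
        rs = [r for r in merged if r.chrom == chrom]
        by_chrom[chrom] = (
            np.array([r.start for r in rs], dtype=np.int64),
            np.array([r.end for r in rs], dtype=np.int64),
        )
    hits = 0
    for frag in fs:
        iv = frag.interval
        if iv.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[iv.chrom]
        i = int(np.searchsorted(ends, iv.start, side="right"))
        if i < len(starts) and starts[i] < iv.end:
            hits += 1
    return hits / len(fs)


def frip_series(
    fs: FragmentSet,
    peaks: Sequence[PeakRecord],
    depths: Sequence[int] = DEFAULT_DEPTHS,
    seed: int = 0,
    nested: bool = False,
) -> pd.Series:
    """FRiP at each down-sampling depth.

    By default each depth is an independent seeded draw from the full set
    (``nested=True`` instead subsamples each depth from the previous one).
    Depths exceeding the available fragment count are skipped with a warning.
    """
    out: dict[int, float] = {}
    current = fs
    for k, depth in enumerate(depths):
        source = current if nested else fs
        if depth > len(source):
            warnings.warn(
                f"depth {depth} exceeds available {len(source)} fragments; skipped"
            )
            continue
        sub = sample_fragments(source, depth, seed=seed + k)
        out[depth] = frip(sub, peaks)
        if nested:
            current = sub
    return pd.Series(out, name="frip")
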