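"""Domain types, standard-format I/O, and interval algebra.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Overlap means at least one shared base pair.  Strand is
ignored throughout; CUT&RUN fragment processing is strand-agnostic.

Formats handled here are plain tab-delimited text: two-column chrom.sizes,
BED3+ fragment files, 4-column bedGraph, and 10-column narrowPeak (summit =
start + column-10 offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeSpec",
    "GenomicInterval",
    "FragmentRecord",
    "FragmentSet",
    "PeakRecord",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_narrowpeak",
    "read_summit_bed",
    "merge_intervals",
    "overlaps",
    "sample_fragments",
    "pool_fragments",
    "format_value",
]


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class GenomeSpec:
    """A named genome: ordered chromosome-name -> length (bp) map."""

    name: str
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError(f"genome {self.name!r}: no chromosomes")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(
                    f"genome {self.name!r}: chromosome {chrom!r} has "
                    f"non-positive length {size}"
                )

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class FragmentRecord:
    """One sequenced fragment (a properly paired read pair collapsed to its
    genomic span)."""

    interval: GenomicInterval
    name: str | None = field(default=None, compare=False)


@dataclass
class FragmentSet:
    """Sorted collection of fragments from one sample mapped to one genome.

    Duplicates are kept: the collection is a multiset, and each mapped pair
    counts once.
    """

    sample_id: str
    genome: str
    fragments: list[FragmentRecord]

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def intervals(self) -> list[GenomicInterval]:
        return [f.interval for f in self.fragments]


@dataclass(frozen=True)
class PeakRecord:
    """A called peak with a single-bp summit (absolute coordinate)."""

    interval: GenomicInterval
    summit: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak {self.interval}"
            )


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeSpec:
    """Read a two-column chrom.sizes file into a :class:`GenomeSpec`."""
    path = Path(path)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            chrom = parts[0]
            try:
                size = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length {parts[1]!r}"
                ) from None
            if chrom in sizes:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            if size <= 0:
                raise FormatError(
                    f"{path}:{lineno}: non-positive length {size} for {chrom!r}"
                )
            sizes[chrom] = size
    if not sizes:
        raise FormatError(f"{path}: no chromosomes")
    return GenomeSpec(name=name or path.stem, chrom_sizes=sizes)


def write_chrom_sizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# BED fragments


def read_fragments_bed(
    path: str | Path,
    genome: GenomeSpec | None = None,
    sample_id: str | None = None,
) -> FragmentSet:
    """Read a BED3+ fragment file.

    When *genome* is given, records on unknown chromosomes or out of bounds
    raise :class:`FormatError`.
    """
    path = Path(path)
    frags: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"[{start}, {end})"
                )
            if genome is not None:
                if chrom not in genome:
                    raise FormatError(
                        f"{path}:{lineno}: unknown chromosome {chrom!r}"
                    )
                if end > genome.chrom_sizes[chrom] or start < 0:
                    raise FormatError(
                        f"{path}:{lineno}: interval [{start}, {end}) outside "
                        f"{chrom} (length {genome.chrom_sizes[chrom]})"
                    )
            name = parts[3] if len(parts) > 3 else None
            frags.append(FragmentRecord(GenomicInterval(chrom, start, end), name))
    return FragmentSet(
        sample_id=sample_id or path.stem,
        genome=genome.name if genome is not None else "",
        fragments=frags,
    )


def write_fragments_bed(fs: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for frag in fs:
            iv = frag.interval
            if frag.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{frag.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# bedGraph

def format_value(v: float) -> str:
    """bedGraph value formatting: 5 significant digits, integers without
    a trailing ``.0``."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return f"{v:.5g}"


def write_bedgraph(track, path: str | Path) -> None:
    """Write a coverage track as 4-column bedGraph.

    Zero-valued intervals are omitted; intervals must be sorted and disjoint
    (enforced by the track container).
    """
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_intervals():
            if value == 0:
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{format_value(value)}\n")


def read_bedgraph(path: str | Path, genome_name: str = ""):
    """Read a 4-column bedGraph into a CoverageTrack."""
    from .coverage import CoverageTrack

    path = Path(path)
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: empty interval")
            raw.setdefault(parts[0], []).append((start, end, value))
    data = {}
    for chrom, rows in raw.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        data[chrom] = (starts, ends, values)
    return CoverageTrack(genome=genome_name or path.stem, data=data)


# ---------------------------------------------------------------------------
# peaks


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read a 10-column narrowPeak file; summit = start + column-10 offset."""
    path = Path(path)
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns"
                )
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            offset = int(parts[9])
            if offset < 0:
                # MACS2 writes -1 when no summit was determined; use midpoint
                summit = (start + end) // 2
            else:
                summit = start + offset
            peaks.append(
                PeakRecord(
                    GenomicInterval(chrom, start, end),
                    summit=summit,
                    score=float(parts[6]) if parts[6] != "." else None,
                    name=parts[3] if parts[3] != "." else None,
                )
            )
    return peaks


def read_summit_bed(path: str | Path) -> list[PeakRecord]:
    """Read peaks from BED with a 4th/5th column summit position (absolute).

    Falls back to the interval midpoint when no summit column is present.
    """
    path = Path(path)
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            summit = (start + end) // 2
            name = None
            if len(parts) >= 4:
                try:
                    summit = int(parts[3])
                except ValueError:
                    name = parts[3]
                    if len(parts) >= 5:
                        summit = int(parts[4])
            peaks.append(
                PeakRecord(GenomicInterval(chrom, start, end), summit, name=name)
            )
    return peaks


def write_peaks_bed(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.summit}\n")


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Collapse overlapping and book-ended intervals into a sorted, disjoint,
    non-adjacent set (bedtools-merge semantics)."""
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >=1 bp."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def sample_fragments(fs: FragmentSet, n: int, seed: int) -> FragmentSet:
    """Uniform sample of *n* fragments without replacement, deterministic
    given *seed* (NumPy PCG64 permutation over the sorted index)."""
    if n > len(fs):
        raise ValueError(
            f"cannot sample {n} fragments from a set of {len(fs)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fs), size=n, replace=False)
    picked = [fs.fragments[i] for i in np.sort(idx)]
    return FragmentSet(sample_id=fs.sample_id, genome=fs.genome, fragments=picked)


def pool_fragments(sets: Sequence[FragmentSet], sample_id: str = "pooled") -> FragmentSet:
    """Multiset union of fragment sets on the same genome (duplicates kept)."""
    if not sets:
        raise ValueError("cannot pool zero fragment sets")
    genomes = {fs.genome for fs in sets}
    if len(genomes) > 1:
        raise ValueError(f"genome mismatch across pooled sets: {sorted(genomes)}")
    frags: list[FragmentRecord] = []
    for fs in sets:
        frags.extend(fs.fragments)
    return FragmentSet(sample_id=sample_id, genome=sets[0].genome, fragments=frags)
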