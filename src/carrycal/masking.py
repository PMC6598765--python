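"""(TA)n low-complexity region detection and fragment exclusion.

Some CUT&RUN libraries contain contaminating reads of undetermined origin
consisting of alternating T/A sequence.  To avoid cross-mapping artifacts,
fragments overlapping any genomic (TA)n run are removed before peak scoring.

Detection here is an exact scanner for maximal alternating T/A runs (either
phase, starting with T or A) of at least ``min_run_length`` base pairs —
deterministic and conservative, with no alignment heuristics.  The scan is
case-insensitive; N and any non-T/A base terminate a run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .core_io import (
    FragmentRecord,
    FragmentSet,
    GenomicInterval,
    merge_intervals,
)

__all__ = ["MaskRegions", "scan_ta_repeats", "exclude_fragments", "read_mask_bed",
           "write_mask_bed", "read_fasta"]

# maximal strictly alternating T/A run, either phase
_ALT_RUN = re.compile(r"(?:TA)+T?|(?:AT)+A?")


@dataclass
class MaskRegions:
    """Merged, sorted (TA)n regions for one genome."""

    genome: str
    regions: list[GenomicInterval]
    min_run_length: int

    def __post_init__(self) -> None:
        self.regions = merge_intervals(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def scan_ta_repeats(
    sequences: Mapping[str, str],
    min_run_length: int = 25,
    genome_name: str = "",
) -> MaskRegions:
    """Find all maximal alternating-T/A runs of length >= *min_run_length*.

    Parameters
    ----------
    sequences
        chromosome name -> DNA string over {A, C, G, T, N}, any case.
    min_run_length
        Minimum run length in bp; the default 25 matches a 25-mer
        (TA)12T query sequence.
    """
    if min_run_length < 2:
        raise ValueError(f"min_run_length must be >= 2, got {min_run_length}")
    regions: list[GenomicInterval] = []
    for chrom, seq in sequences.items():
        s = seq.upper()
        for m in _ALT_RUN.finditer(s):
            if m.end() - m.start() >= min_run_length:
                regions.append(GenomicInterval(chrom, m.start(), m.end()))
    return MaskRegions(genome=genome_name, regions=regions,
                       min_run_length=min_run_length)


def exclude_fragments(fs: FragmentSet, mask: MaskRegions) -> FragmentSet:
    """Keep exactly the fragments with zero bp overlap with every mask region.

    Half-open adjacency (fragment end == region start) is not overlap.
    """
    if mask.genome and fs.genome and mask.genome != fs.genome:
        raise ValueError(
            f"genome mismatch: fragments on {fs.genome!r}, mask on {mask.genome!r}"
        )
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in mask.regions}:
        rs = [r for r in mask.regions if r.chrom == chrom]
        by_chrom[chrom] = (
            np.array([r.start for r in rs], dtype=np.int64),
            np.array([r.end for r in rs], dtype=np.int64),
        )
    kept: list[FragmentRecord] = []
    for frag in fs:
        iv = frag.interval
        if iv.chrom not in by_chrom:
            kept.append(frag)
            continue
        starts, ends = by_chrom[iv.chrom]
        # mask regions are disjoint+sorted: overlap iff the first region with
        # end > frag.start also starts before frag.end
        i = int(np.searchsorted(ends, iv.start, side="right"))
        if i >= len(starts) or starts[i] >= iv.end:
            kept.append(frag)
    return FragmentSet(sample_id=fs.sample_id, genome=fs.genome, fragments=kept)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into name -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_mask_bed(mask: MaskRegions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in mask.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_mask_bed(
    path: str | Path, min_run_length: int = 25, genome_name: str = ""
) -> MaskRegions:
    regions: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            regions.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return MaskRegions(genome=genome_name, regions=regions,
                       min_run_length=min_run_length)
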