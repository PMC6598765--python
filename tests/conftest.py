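import numpy as np
import pytest

from carrycal.core_io import (
    FragmentRecord,
    FragmentSet,
    GenomeSpec,
    GenomicInterval,
)


@pytest.fixture
def toy_genome():
    return GenomeSpec("toy", {"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def tiny_genome():
    return GenomeSpec("tiny", {"chr1": 10})


def random_fragment_set(
    rng: np.random.Generator,
    genome: GenomeSpec,
    n: int,
    max_len: int = 200,
    sample_id: str = "s",
) -> FragmentSet:
    """Uniform random fragments within genome bounds (test helper)."""
    chroms = list(genome.chrom_sizes)
    frags = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        size = genome.chrom_sizes[chrom]
        length = int(rng.integers(1, min(max_len, size) + 1))
        start = int(rng.integers(0, size - length + 1))
        frags.append(FragmentRecord(GenomicInterval(chrom, start, start + length)))
    return FragmentSet(sample_id=sample_id, genome=genome.name, fragments=frags)


def random_intervals(rng, chrom="chr1", n=20, span=1000, max_len=100):
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, span - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


# ---------------------------------------------------------------------------
# independent brute-force oracles


def occupancy_oracle(intervals, span: int) -> np.ndarray:
    """Per-bp boolean union of intervals on a single chromosome."""
    occ = np.zeros(span, dtype=bool)
    for iv in intervals:
        occ[iv.start : iv.end] = True
    return occ


def depth_oracle(fs: FragmentSet, genome: GenomeSpec) -> dict[str, np.ndarray]:
    """Per-bp depth by direct array accumulation."""
    arrays = {c: np.zeros(s, dtype=float) for c, s in genome.chrom_sizes.items()}
    for frag in fs:
        iv = frag.interval
        arrays[iv.chrom][iv.start : iv.end] += 1
    return arrays


def overlap_oracle_perbp(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Shared-base-pair check by literal per-bp enumeration (small spans)."""
    if a.chrom != b.chrom:
        return False
    return any(
        a.start <= x < a.end and b.start <= x < b.end
        for x in range(min(a.start, b.start), max(a.end, b.end))
    )


def overlap_oracle(a: GenomicInterval, b: GenomicInterval) -> bool:
    """All-pairs brute-force overlap test (direct comparison, no index
    structures); itself validated against the per-bp enumeration."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def pearson_oracle(x, y) -> float:
    """Pearson r from the covariance definition, no library call."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    return cov / np.sqrt(((x - mx) ** 2).mean() * ((y - my) ** 2).mean())


def maximal_ta_runs_oracle(seq: str, min_len: int):
    """Brute-force scan for maximal alternating T/A runs (no regex)."""
    s = seq.upper()
    runs = []
    i = 0
    n = len(s)
    while i < n:
        if s[i] not in "TA":
            i += 1
            continue
        j = i + 1
        while j < n and s[j] in "TA" and s[j] != s[j - 1]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs
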