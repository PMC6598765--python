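"""Synthetic multi-species CUT&RUN fragment datasets.

Generates fully specified three-genome experiments — a primary toy genome
with peak-enriched fragments over uniform background, a spike-in genome, and
a carry-over genome — so every pipeline stage (masking, calibration,
coverage, peak QC) is testable without any external downloads.

Model
-----
Each sample ``i`` has a *technical depth factor* ``d_i`` standing for its
sequencing/recovery depth.  A constant amount of spike-in DNA is added per
sample and a constant amount of carry-over DNA rides in on the
antibody-bound beads, so the *sequenced* calibration counts scale with
``d_i`` while the underlying amounts stay constant:

* primary fragments:  ``N_i ~ Poisson(primary_depth_i * d_i * yield_i)``
* spike-in fragments: ``S_i ~ Poisson(spike_rate * d_i)``
* carry-over:         ``C_i ~ Poisson(carryover_rate * d_i)``

``yield_i`` is an optional *biological* multiplier (digestion time-course
yield) that scales the primary genome only.  Because ``d_i`` is shared,
spike-in and carry-over counts are strongly concordant across a series, and
dividing primary signal by either calibration count cancels ``d_i`` — which
is exactly what makes the carry-over a valid calibrant.

A primary fragment is, independently: with probability ``contamination_rate``
a premature-release artifact fragment (the standard-protocol background);
otherwise with probability ``background_rate`` uniform background; otherwise
peak-derived, with the peak chosen proportionally to
``enrichment x length`` and the fragment midpoint uniform within the peak.
Premature release digests accessible DNA, which includes the marked peak
regions themselves, and its per-site intensity varies stochastically between
samples because release timing is uncontrolled: artifact fragments are
therefore drawn half uniformly over the genome and half from the peak
regions under per-sample Dirichlet-random site weights, which is what
degrades between-sample peak-vector reproducibility under the standard
protocol.  Fragment lengths are truncated-normal (nucleosomal scale, default
mean 150 / sd 30 bp).

Everything is reproducible from ``(seed, sample_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    FragmentRecord,
    FragmentSet,
    GenomeSpec,
    GenomicInterval,
    PeakRecord,
    write_chrom_sizes,
    write_fragments_bed,
    write_peaks_bed,
)
from .calibration import SpeciesCountTable, tally_species

__all__ = [
    "SimConfig",
    "SimResult",
    "default_genomes",
    "random_sequences",
    "make_peaks",
    "simulate_sample",
    "simulate_series",
]


def default_genomes(
    primary_size: int = 1_000_000,
    spikein_size: int = 100_000,
    carryover_size: int = 100_000,
) -> tuple[GenomeSpec, GenomeSpec, GenomeSpec]:
    """Toy primary / spike-in / carry-over genomes (single chromosome each)."""
    return (
        GenomeSpec("toy_primary", {"chrP": primary_size}),
        GenomeSpec("toy_spikein", {"chrS": spikein_size}),
        GenomeSpec("toy_carryover", {"chrC": carryover_size}),
    )


def random_sequences(
    genome: GenomeSpec,
    seed: int,
    ta_runs: Sequence[tuple[str, int, int]] = (),
) -> dict[str, str]:
    """Seeded random DNA for a genome, optionally with implanted alternating
    T/A runs given as (chrom, start, run_length) so the masking scanner can
    be exercised end to end."""
    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom, size in genome.chrom_sizes.items():
        seqs[chrom] = bases[rng.integers(0, 4, size=size)].copy()
    for chrom, start, run_length in ta_runs:
        run = np.frombuffer(b"TA" * (run_length // 2 + 1), dtype="S1")[:run_length]
        seqs[chrom][start : start + run_length] = run
        # break up accidental extension of the implanted run
        if start > 0:
            seqs[chrom][start - 1] = b"C"
        if start + run_length < len(seqs[chrom]):
            seqs[chrom][start + run_length] = b"C"
    return {chrom: arr.tobytes().decode() for chrom, arr in seqs.items()}


def make_peaks(
    genome: GenomeSpec,
    n_peaks: int,
    seed: int,
    width: int = 1000,
    enrichment_mean: float = 20.0,
    enrichment_spread: float = 0.6,
) -> list[tuple[GenomicInterval, float]]:
    """Non-overlapping peak intervals with lognormal enrichment folds.

    Peaks are laid out on an evenly spaced grid with seeded jitter so they
    never overlap; folds are lognormal around ``enrichment_mean`` with
    log-scale sd ``enrichment_spread`` (heterogeneous peak strengths make
    peak-vector correlations informative).
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(genome.chrom_sizes))
    size = genome.chrom_sizes[chrom]
    if n_peaks * 2 * width > size:
        raise ValueError("genome too small for requested peaks")
    slot = size // n_peaks
    starts = np.arange(n_peaks) * slot + rng.integers(0, slot - width, size=n_peaks)
    folds = enrichment_mean * rng.lognormal(
        mean=-0.5 * enrichment_spread**2, sigma=enrichment_spread, size=n_peaks
    )
    folds = np.maximum(folds, 1.0)
    return [
        (GenomicInterval(chrom, int(s), int(s) + width), float(f))
        for s, f in zip(starts, folds)
    ]


@dataclass
class SimConfig:
    """Full specification of a synthetic multi-sample experiment."""

    seed: int = 0
    genomes: tuple[GenomeSpec, GenomeSpec, GenomeSpec] = field(
        default_factory=default_genomes
    )
    n_samples: int = 8
    primary_depth: float | Sequence[float] = 5_000.0
    depth_factors: Sequence[float] | None = None
    spike_rate: float | Sequence[float] = 1_000.0
    carryover_rate: float = 3_000.0
    peaks: list[tuple[GenomicInterval, float]] | None = None
    n_peaks: int = 30
    background_rate: float = 0.2
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 30.0
    contamination_rate: float = 0.0
    timecourse_yields: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must be in [0, 1]")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        if self.carryover_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.timecourse_yields is not None:
            self.n_samples = len(self.timecourse_yields)
        if self.peaks is None:
            self.peaks = make_peaks(self.genomes[0], self.n_peaks, seed=self.seed + 977)
        if any(f < 1 for _, f in self.peaks):
            raise ValueError("peak enrichment folds must be >= 1")

    # -- per-sample resolved parameters ------------------------------------

    def _per_sample(self, value, i: int) -> float:
        if np.isscalar(value):
            return float(value)
        return float(value[i])

    def sample_params(self, i: int) -> dict[str, float]:
        d = 1.0 if self.depth_factors is None else float(self.depth_factors[i])
        y = 1.0 if self.timecourse_yields is None else float(self.timecourse_yields[i])
        return {
            "depth_factor": d,
            "yield": y,
            "lambda_primary": self._per_sample(self.primary_depth, i) * d * y,
            "lambda_spikein": self._per_sample(self.spike_rate, i) * d,
            "lambda_carryover": self.carryover_rate * d,
        }

    # -- canonical scenarios ------------------------------------------------

    @classmethod
    def depth_series(
        cls, seed: int = 0, n_samples: int = 20, depth_range: float = 100.0, **kw
    ) -> "SimConfig":
        """Calibration-series scenario: constant biology, technical depth
        varying ``depth_range``-fold (default 100x) across samples, constant
        spike-in and carry-over amounts."""
        factors = np.geomspace(1.0, depth_range, n_samples) / np.sqrt(depth_range)
        return cls(seed=seed, n_samples=n_samples, depth_factors=factors, **kw)

    @classmethod
    def timecourse(
        cls,
        seed: int = 0,
        yields: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0),
        contamination_rate: float = 0.0,
        primary_depth: float = 1_000.0,
        **kw,
    ) -> "SimConfig":
        """Digestion time-course scenario: yield increasing with digestion
        time; ``contamination_rate`` > 0 models the standard protocol's
        premature-release background, 0 the high-calcium/low-salt protocol."""
        return cls(
            seed=seed,
            timecourse_yields=tuple(yields),
            contamination_rate=contamination_rate,
            primary_depth=primary_depth,
            **kw,
        )

    def truth_peaks(self) -> list[PeakRecord]:
        """PeakRecords at the true enriched intervals (summit = center)."""
        return [
            PeakRecord(iv, summit=(iv.start + iv.end) // 2, score=fold)
            for iv, fold in self.peaks
        ]


@dataclass
class SimResult:
    """Simulated series: per-sample fragment sets, count table, truth table."""

    config: SimConfig
    primary: list[FragmentSet]
    spikein: list[FragmentSet]
    carryover: list[FragmentSet]
    counts: SpeciesCountTable
    truth: pd.DataFrame


def _draw_fragments(
    rng: np.random.Generator,
    n: int,
    genome: GenomeSpec,
    cfg: SimConfig,
    peaks: list[tuple[GenomicInterval, float]] | None,
    background_rate: float,
    contamination_rate: float,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Midpoint-model fragment draw; returns (starts, ends, category tally)."""
    chrom = next(iter(genome.chrom_sizes))
    size = genome.chrom_sizes[chrom]
    lengths = rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, size=n)
    lengths = np.clip(np.round(lengths), 20, None).astype(np.int64)
    lengths = np.minimum(lengths, size)

    mids = np.empty(n, dtype=np.int64)
    tally = {"peak": 0, "background": 0, "contamination": 0}
    if peaks:
        u = rng.random(n)
        contam = u < contamination_rate
        bg = (~contam) & (u < contamination_rate + (1 - contamination_rate) * background_rate)
        signal = ~(contam | bg)
        mids[bg] = rng.integers(0, size, size=int(bg.sum()))
        n_contam = int(contam.sum())
        if n_contam:
            # premature-release artifact: half uniform, half at accessible
            # (peak) sites with per-sample random intensities
            uniform_half = rng.random(n_contam) < 0.5
            c_mids = np.empty(n_contam, dtype=np.int64)
            c_mids[uniform_half] = rng.integers(0, size, size=int(uniform_half.sum()))
            n_acc = int((~uniform_half).sum())
            if n_acc:
                site_w = rng.dirichlet(np.ones(len(peaks)))
                which_c = rng.choice(len(peaks), size=n_acc, p=site_w)
                offs_c = rng.random(n_acc)
                starts_c = np.array([peaks[k][0].start for k in which_c])
                widths_c = np.array([len(peaks[k][0]) for k in which_c])
                c_mids[~uniform_half] = starts_c + (offs_c * widths_c).astype(np.int64)
            mids[contam] = c_mids
        n_sig = int(np.sum(signal))
        if n_sig:
            weights = np.array([f * len(iv) for iv, f in peaks])
            weights = weights / weights.sum()
            which = rng.choice(len(peaks), size=n_sig, p=weights)
            offs = rng.random(n_sig)
            starts_p = np.array([peaks[k][0].start for k in which])
            widths_p = np.array([len(peaks[k][0]) for k in which])
            mids[signal] = starts_p + (offs * widths_p).astype(np.int64)
        tally = {
            "peak": n_sig,
            "background": int(bg.sum()),
            "contamination": int(contam.sum()),
        }
    else:
        mids[:] = rng.integers(0, size, size=n)
        tally["background"] = n
    starts = np.clip(mids - lengths // 2, 0, None)
    ends = np.minimum(starts + lengths, size)
    starts = np.minimum(starts, ends - 1)
    return starts, ends, tally


def _to_fragment_set(
    sample_id: str, genome: GenomeSpec, starts: np.ndarray, ends: np.ndarray
) -> FragmentSet:
    chrom = next(iter(genome.chrom_sizes))
    frags = [
        FragmentRecord(GenomicInterval(chrom, int(s), int(e)))
        for s, e in zip(starts, ends)
    ]
    return FragmentSet(sample_id=sample_id, genome=genome.name, fragments=frags)


def simulate_sample(
    cfg: SimConfig, sample_index: int
) -> tuple[FragmentSet, FragmentSet, FragmentSet, dict]:
    """Simulate one sample; fully reproducible from (cfg.seed, sample_index).

    Returns the three per-genome fragment sets (primary, spike-in,
    carry-over) and a truth record with every latent value.
    """
    for g in cfg.genomes:
        if g.total_size <= 0:
            raise ValueError(f"zero-size genome {g.name!r}")
    rng = np.random.default_rng([cfg.seed, sample_index])
    params = cfg.sample_params(sample_index)
    sid = f"s{sample_index:02d}"

    n_primary = rng.poisson(params["lambda_primary"])
    n_spike = rng.poisson(params["lambda_spikein"])
    n_carry = rng.poisson(params["lambda_carryover"])

    g_pri, g_spk, g_car = cfg.genomes
    ps, pe, tally = _draw_fragments(
        rng, n_primary, g_pri, cfg, cfg.peaks, cfg.background_rate,
        cfg.contamination_rate,
    )
    ss, se, _ = _draw_fragments(rng, n_spike, g_spk, cfg, None, 1.0, 0.0)
    cs, ce, _ = _draw_fragments(rng, n_carry, g_car, cfg, None, 1.0, 0.0)

    truth = {
        "sample_id": sid,
        **params,
        "n_primary": int(n_primary),
        "n_spikein": int(n_spike),
        "n_carryover": int(n_carry),
        "n_peak_fragments": tally["peak"],
        "n_background_fragments": tally["background"],
        "n_contamination_fragments": tally["contamination"],
        "true_in_peak_fraction": (
            tally["peak"] / n_primary if n_primary else float("nan")
        ),
    }
    return (
        _to_fragment_set(sid, g_pri, ps, pe),
        _to_fragment_set(sid, g_spk, ss, se),
        _to_fragment_set(sid, g_car, cs, ce),
        truth,
    )


def simulate_series(cfg: SimConfig) -> SimResult:
    """Simulate all samples of a series and tabulate counts and truth."""
    primary, spikein, carryover, rows, truths = [], [], [], [], []
    for i in range(cfg.n_samples):
        p, s, c, truth = simulate_sample(cfg, i)
        primary.append(p)
        spikein.append(s)
        carryover.append(c)
        rows.append(tally_species(p, s, c))
        truths.append(truth)
    return SimResult(
        config=cfg,
        primary=primary,
        spikein=spikein,
        carryover=carryover,
        counts=SpeciesCountTable.from_rows(rows),
        truth=pd.DataFrame(truths),
    )


def write_series(result: SimResult, outdir: str | Path) -> None:
    """Emit a series as plain-text files: per-sample BEDs, chrom.sizes for
    each genome, true peaks, counts TSV and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for genome, label in zip(cfg.genomes, ("primary", "spikein", "carryover")):
        write_chrom_sizes(genome, outdir / f"{label}.chrom.sizes")
    for sets, label in (
        (result.primary, "primary"),
        (result.spikein, "spikein"),
        (result.carryover, "carryover"),
    ):
        for fs in sets:
            write_fragments_bed(fs, outdir / f"{fs.sample_id}.{label}.bed")
    write_peaks_bed(cfg.truth_peaks(), outdir / "true_peaks.bed")
    result.counts.write_tsv(outdir / "counts.tsv")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
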