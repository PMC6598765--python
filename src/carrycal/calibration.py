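"""Species tallies, spike-in / carry-over calibration, and concordance.

CUT&RUN samples carry fragments from three genomes: the primary genome under
study, an optional heterologous spike-in (e.g. *S. cerevisiae* MNase-digest
DNA added in constant amount per sample), and *E. coli* DNA carried over from
purification of the pA/MNase or pAG/MNase fusion protein.  Because the
carry-over is affixed to a constant number of antibody-coated beads per
sample, its fragment count is constant in expectation across a series and
can substitute for a deliberate spike-in — samples can be recalibrated
post hoc simply by counting fragments mapping to the *E. coli* genome.

Calibration divides per-sample signal by the calibration-genome fragment
count: ``factor = multiplier / calib_count``.  The multiplier (default
10,000) is a dimensionless display scale; relative comparisons between
samples are unaffected by its value.

Concordance between spike-in and carry-over counts across a series is
summarized by Pearson's r on the raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import FragmentSet

__all__ = [
    "SpeciesCountTable",
    "CalibrationConfig",
    "ScaleFactors",
    "tally_species",
    "scale_factor",
    "compute_scale_factors",
    "calibrated_count",
    "spike_carryover_correlation",
    "load_reference_counts",
]

COUNT_COLUMNS = ("primary_count", "spikein_count", "carryover_count")


@dataclass
class SpeciesCountTable:
    """Per-sample fragment tallies for primary, spike-in, and carry-over
    genomes, plus free-form condition labels (protocol, ab_first, ...)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", *COUNT_COLUMNS) if c not in self.df]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        for c in COUNT_COLUMNS:
            col = self.df[c]
            if (col < 0).any():
                raise ValueError(f"negative counts in {c}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "SpeciesCountTable":
        return cls(pd.DataFrame(rows))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SpeciesCountTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class CalibrationConfig:
    """Which genome calibrates (spike-in or carry-over) and the display
    multiplier."""

    mode: str = "carryover"
    multiplier: float = 10_000.0

    def __post_init__(self) -> None:
        if self.mode not in ("spikein", "carryover"):
            raise ValueError(f"mode must be 'spikein' or 'carryover', got {self.mode!r}")
        if not self.multiplier > 0:
            raise ValueError("multiplier must be positive")

    @property
    def count_column(self) -> str:
        return f"{self.mode}_count"


@dataclass
class ScaleFactors:
    """Per-sample calibration factors (all positive and finite)."""

    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, f in self.factors.items():
            if not (f > 0 and np.isfinite(f)):
                raise ValueError(f"invalid factor {f} for sample {sid!r}")

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.factors), "factor": list(self.factors.values())}
        ).to_csv(path, sep="\t", index=False)


def tally_species(
    primary: FragmentSet, spikein: FragmentSet, carryover: FragmentSet,
    sample_id: str | None = None, **conditions,
) -> dict:
    """One count-table row from the three per-genome fragment sets of a
    sample (fragments, not reads: each mapped pair counts once)."""
    return {
        "sample_id": sample_id or primary.sample_id,
        **conditions,
        "primary_count": len(primary),
        "spikein_count": len(spikein),
        "carryover_count": len(carryover),
    }


def scale_factor(calib_count: int, config: CalibrationConfig = CalibrationConfig()) -> float:
    """multiplier / calib_count; undefined for zero calibration fragments.

    A zero spike-in count is the no-spike scenario: such a sample cannot be
    calibrated in spike-in mode, but usually still can via carry-over.
    """
    if calib_count <= 0:
        raise ValueError(
            "cannot calibrate: zero calibration-genome fragments"
        )
    return config.multiplier / calib_count


def compute_scale_factors(
    table: SpeciesCountTable, config: CalibrationConfig = CalibrationConfig()
) -> ScaleFactors:
    """Scale factor for every sample in a count table."""
    factors: dict[str, float] = {}
    for _, row in table.df.iterrows():
        count = int(row[config.count_column])
        if count <= 0:
            raise ValueError(
                f"cannot calibrate sample {row['sample_id']!r}: zero "
                f"{config.mode} fragments"
            )
        factors[row["sample_id"]] = config.multiplier / count
    return ScaleFactors(factors)


def calibrated_count(raw: float, factor: float) -> float:
    """Apply a calibration factor to a raw count."""
    if not factor > 0:
        raise ValueError("factor must be positive")
    return raw * factor


def spike_carryover_correlation(
    table: SpeciesCountTable, group_by: str | None = None
) -> pd.Series:
    """Pearson r between spike-in and carry-over counts, per condition group.

    Computed on raw counts; groups with fewer than 3 samples or zero variance
    in either count vector yield NaN with a warning.  Full precision is
    retained; round only for display.
    """
    df = table.df
    groups = df.groupby(group_by, sort=False) if group_by else [("all", df)]
    out: dict[str, float] = {}
    for key, g in groups:
        sc = g["spikein_count"].to_numpy(dtype=float)
        ec = g["carryover_count"].to_numpy(dtype=float)
        if len(g) < 3 or np.std(sc) == 0 or np.std(ec) == 0:
            warnings.warn(
                f"group {key!r}: correlation undefined "
                f"(n={len(g)}, needs >=3 samples and nonzero variance)"
            )
            out[key] = float("nan")
            continue
        out[key] = float(np.corrcoef(sc, ec)[0, 1])
    return pd.Series(out, name="corr_sc_ec")


def load_reference_counts() -> SpeciesCountTable:
    """The packaged H3K27me3 bead-batch comparison count table: 16 samples,
    4 protocol groups (pA/pAG x lo-hi/std), with human, yeast spike-in and
    *E. coli* carry-over fragment counts."""
    with resources.files("carrycal").joinpath("data/table1.tsv").open() as fh:
        return SpeciesCountTable(pd.read_csv(fh, sep="\t"))
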