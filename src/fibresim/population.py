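"""Fibre populations: synthetic generation, CSV I/O and length-class binning.

A fibre population is just a list of fibre lengths in µm, as produced by
automated image analysis of a pulp sample.  The synthetic generator
emulates the starting material of a hydrolysis experiment: flax fibres
cut into 3-7 mm segments, plus a log-normal "fines" fraction of short
fragments that cutting and handling inevitably produce.

Length distributions are reported as *length-weighted shares* per length
class — the fraction of total fibre length, not of fibre count, falling
in each class.  The conventional classes are 3-7 mm (intact), 0.5-3 mm,
and two sub-0.5 mm classes split at 0.25 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FibrePopulation",
    "SyntheticPopulationConfig",
    "LengthDistribution",
    "DEFAULT_BIN_EDGES_MM",
    "generate_initial_population",
    "read_lengths",
    "write_lengths",
    "bin_length_weighted",
]

#: Default length-class edges in mm: two sub-0.5 mm classes split at
#: 0.25 mm, the 0.5-3 mm class, and the 3-7 mm class of intact segments.
DEFAULT_BIN_EDGES_MM = (0.0, 0.25, 0.5, 3.0, 7.0)

MM_PER_UM = 1e-3


@dataclass
class FibrePopulation:
    """A set of fibre lengths, stored internally in µm."""

    lengths: np.ndarray
    label: str = ""

    #: unit marker; lengths are always converted to µm on construction
    unit: str = field(default="um")

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        if arr.ndim != 1:
            raise ValueError("lengths must be one-dimensional")
        if arr.size and (np.any(~np.isfinite(arr)) or np.any(arr <= 0)):
            raise ValueError("all fibre lengths must be positive and finite")
        if self.unit != "um":
            raise ValueError("FibrePopulation stores lengths in µm; convert before constructing")
        self.lengths = arr

    def __len__(self) -> int:
        return self.lengths.size

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def mean_length(self) -> float:
        return float(self.lengths.mean()) if self.lengths.size else float("nan")


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Parameters of the synthetic initial population.

    ``intact_fraction`` of the fibres are segments drawn uniformly on
    ``intact_range`` (µm); the remainder are fines drawn log-normally
    with the given median (µm) and log-standard-deviation, truncated to
    the cap at the top of the intact range.
    """

    n_fibres: int = 10_000
    intact_fraction: float = 0.8
    intact_range: tuple[float, float] = (3000.0, 7000.0)
    fines_log_median: float = 500.0
    fines_log_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.intact_range
        if not (0 < lo < hi):
            raise ValueError(f"intact_range must satisfy 0 < min < max, got {self.intact_range}")
        if not (0.0 <= self.intact_fraction <= 1.0):
            raise ValueError("intact_fraction must lie in [0, 1]")
        if self.n_fibres < 0:
            raise ValueError("n_fibres must be >= 0")
        if self.fines_log_median <= 0 or self.fines_log_sigma <= 0:
            raise ValueError("fines parameters must be positive")


def generate_initial_population(cfg: SyntheticPopulationConfig) -> FibrePopulation:
    """Draw a synthetic pre-hydrolysis fibre population.

    The number of intact segments is binomial(n, intact_fraction); intact
    lengths are uniform on the intact range, fines log-normal (median
    ``fines_log_median``, log-sd ``fines_log_sigma``) resampled until
    below the top of the intact range.  Same config and seed gives an
    identical population.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.n_fibres)
    if n == 0:
        return FibrePopulation(np.empty(0), label="synthetic")
    lo, hi = cfg.intact_range
    n_intact = int(rng.binomial(n, cfg.intact_fraction))
    intact = rng.uniform(lo, hi, size=n_intact)
    n_fines = n - n_intact
    fines = rng.lognormal(np.log(cfg.fines_log_median), cfg.fines_log_sigma, size=n_fines)
    # truncate the upper tail: a "fine" longer than an intact segment is unphysical
    while np.any(fines > hi):
        bad = fines > hi
        fines[bad] = rng.lognormal(np.log(cfg.fines_log_median), cfg.fines_log_sigma, size=int(bad.sum()))
    lengths = rng.permutation(np.concatenate([intact, fines]))
    return FibrePopulation(lengths, label="synthetic")


class LengthTableFormatError(ValueError):
    """A fibre-length CSV violates the expected format."""


_UNIT_FACTORS = {"length_um": 1.0, "length_mm": 1000.0}


def read_lengths(path) -> FibrePopulation:
    """Read a one-column fibre-length CSV.

    The single header must be ``length_um`` or ``length_mm`` (declaring
    the unit of every row); rows must be positive numbers.  mm values
    are converted to µm.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] != 1 or df.columns[0] not in _UNIT_FACTORS:
        raise LengthTableFormatError(
            f"{path}: expected a single column named 'length_um' or 'length_mm', "
            f"got columns {list(df.columns)}"
        )
    col = df.columns[0]
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.index[values.isna()]
    if len(bad):
        raise LengthTableFormatError(
            f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in data row {bad[0] + 1}"
        )
    nonpos = values.index[values <= 0]
    if len(nonpos):
        raise LengthTableFormatError(
            f"{path}: non-positive length {values.iloc[nonpos[0]]} in data row {nonpos[0] + 1}"
        )
    lengths = values.to_numpy(dtype=float) * _UNIT_FACTORS[col]
    return FibrePopulation(lengths, label=path.stem)


def write_lengths(population: FibrePopulation, path, unit: str = "length_um") -> None:
    """Write a population to a one-column CSV in µm (or mm)."""
    if unit not in _UNIT_FACTORS:
        raise LengthTableFormatError(f"unknown unit header {unit!r}")
    values = population.lengths / _UNIT_FACTORS[unit]
    pd.DataFrame({unit: values}).to_csv(path, index=False)


@dataclass
class LengthDistribution:
    """Length-weighted shares of fibre length per length class.

    ``shares[i]`` is the fraction of total fibre length in
    ``[bin_edges_mm[i], bin_edges_mm[i+1])``; the last bin is closed on
    the right.  Lengths above the top edge are folded into the last bin
    and flagged via ``overflow``; an empty input yields all-zero shares
    and ``empty=True``.
    """

    bin_edges_mm: np.ndarray
    shares: np.ndarray
    overflow: bool = False
    empty: bool = False

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_mm, dtype=float)
        shares = np.asarray(self.shares, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be ascending with at least two entries")
        if shares.size != edges.size - 1:
            raise ValueError("need exactly one share per bin")
        if np.any(shares < -1e-12):
            raise ValueError("shares must be non-negative")
        if not self.empty and abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("shares of a non-empty population must sum to 1")
        self.bin_edges_mm = edges
        self.shares = shares

    def same_edges(self, other: "LengthDistribution") -> bool:
        return (
            self.bin_edges_mm.size == other.bin_edges_mm.size
            and bool(np.allclose(self.bin_edges_mm, other.bin_edges_mm))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower_mm": self.bin_edges_mm[:-1],
                "bin_upper_mm": self.bin_edges_mm[1:],
                "share": self.shares,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges_mm": self.bin_edges_mm.tolist(),
                "shares": self.shares.tolist(),
                "overflow": self.overflow,
                "empty": self.empty,
            }
        )


def bin_length_weighted(
    lengths_um,
    bin_edges_mm=DEFAULT_BIN_EDGES_MM,
    *,
    number_weighted: bool = False,
) -> LengthDistribution:
    """Bin fibre lengths (µm) into length classes (edges in mm).

    Bins are half-open ``[a, b)`` with the last bin closed on the right;
    lengths above the top edge fall into the last bin (flagged).  Shares
    are length-weighted by default — the statistic in which a single
    intact fibre counts as much as dozens of fines — or per-fibre counts
    with ``number_weighted=True``.
    """
    edges = np.asarray(bin_edges_mm, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be ascending with at least two entries")
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size == 0:
        return LengthDistribution(edges, np.zeros(edges.size - 1), empty=True)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("all fibre lengths must be positive and finite")

    mm = lengths * MM_PER_UM
    if np.any(mm < edges[0]):
        raise ValueError(f"lengths below the lowest bin edge {edges[0]} mm")
    nbins = edges.size - 1
    idx = np.searchsorted(edges, mm, side="right") - 1
    overflow = bool(np.any(mm > edges[-1]))
    idx = np.minimum(idx, nbins - 1)  # closed last bin + overflow fold-in

    weights = np.ones_like(mm) if number_weighted else lengths
    totals = np.bincount(idx, weights=weights, minlength=nbins)
    shares = totals / weights.sum()
    return LengthDistribution(edges, shares, overflow=overflow)
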