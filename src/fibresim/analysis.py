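"""Comparing binned length distributions: distance, stagnation, calibration.

The attrition model's output is a sequence of length-weighted length
distributions, one per mixing step.  This module quantifies two things
the raw figures only show visually:

* **stagnation** — the point at which the distribution stops changing
  from step to step, measured by total-variation distance between
  consecutive distributions staying below a tolerance;
* **schedule fit** — a direct grid search recovering the weakening
  schedule (initial ``M_u/P``, per-step decay, floor) that best
  reproduces an observed distribution series.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .population import DEFAULT_BIN_EDGES_MM, LengthDistribution, bin_length_weighted
from .simulator import SimConfig, Trajectory, WeakeningSchedule, run_attrition

__all__ = [
    "DistributionSeries",
    "CalibrationResult",
    "distribution_distance",
    "detect_stagnation",
    "calibrate_schedule",
    "series_from_trajectory",
]


@dataclass
class DistributionSeries:
    """Ordered (label, distribution) pairs sharing one set of bin edges."""

    labels: list
    distributions: list[LengthDistribution]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.distributions):
            raise ValueError("need one label per distribution")
        if len(self.labels) > 1:
            if any(np.asarray(self.labels[1:]) <= np.asarray(self.labels[:-1])):
                raise ValueError("labels must be strictly increasing")
            first = self.distributions[0]
            for d in self.distributions[1:]:
                if not first.same_edges(d):
                    raise ValueError("all distributions in a series must share bin edges")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def bin_edges_mm(self) -> np.ndarray:
        return self.distributions[0].bin_edges_mm

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, d in zip(self.labels, self.distributions):
            f = d.to_frame()
            f.insert(0, "label", label)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DistributionSeries":
        df = pd.read_csv(path)
        required = {"label", "bin_lower_mm", "bin_upper_mm", "share"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        labels, dists = [], []
        for label, grp in df.groupby("label", sort=True):
            grp = grp.sort_values("bin_lower_mm")
            edges = np.append(grp["bin_lower_mm"].to_numpy(), grp["bin_upper_mm"].iloc[-1])
            dists.append(LengthDistribution(edges, grp["share"].to_numpy()))
            labels.append(label)
        return cls(labels, dists)


def series_from_trajectory(
    traj: Trajectory,
    bin_edges_mm=DEFAULT_BIN_EDGES_MM,
    include_initial: bool = True,
) -> DistributionSeries:
    """Bin every step of a trajectory (active plus retired fibres).

    Retired fibres stay part of the material, so they are included in
    every step's distribution.  With ``include_initial`` the series
    starts with the step-0 snapshot of the initial population.
    """
    labels: list[int] = []
    dists: list[LengthDistribution] = []
    if include_initial:
        labels.append(0)
        dists.append(bin_length_weighted(traj.initial_lengths, bin_edges_mm))
    for rec in traj.steps:
        labels.append(rec.step_index)
        dists.append(bin_length_weighted(traj.all_lengths_after(rec.step_index), bin_edges_mm))
    return DistributionSeries(labels, dists)


def distribution_distance(d1: LengthDistribution, d2: LengthDistribution) -> float:
    """Total-variation distance between two binned distributions.

    ``0.5 * sum(|share1_i - share2_i|)``: the fraction of total length
    that would have to move between classes to turn one distribution
    into the other.  Bounded in [0, 1]; requires identical bin edges.
    """
    if not d1.same_edges(d2):
        raise ValueError("distributions must share identical bin edges")
    return float(0.5 * np.abs(d1.shares - d2.shares).sum())


def detect_stagnation(series: DistributionSeries, tol: float = 0.01, patience: int = 2):
    """First label from which the series stays put for ``patience`` steps.

    Returns the first label ``s`` such that the total-variation distance
    between every pair of consecutive entries from ``s`` through
    ``s + patience`` is below ``tol``; ``None`` if the series never
    settles.  ``patience >= 1`` guards against one-step coincidences.
    """
    if len(series) < 2:
        raise ValueError("need at least two entries to detect stagnation")
    if not tol > 0:
        raise ValueError("tol must be positive")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    dists = [
        distribution_distance(a, b)
        for a, b in zip(series.distributions[:-1], series.distributions[1:])
    ]
    for i in range(len(dists) - patience + 1):
        if all(d < tol for d in dists[i : i + patience]):
            return series.labels[i]
    return None


@dataclass
class CalibrationResult:
    """Outcome of a grid search over weakening schedules."""

    best_schedule: WeakeningSchedule
    best_objective: float
    grid: list[dict] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.grid:
            lowest = min(pt["objective"] for pt in self.grid)
            if self.best_objective > lowest + 1e-12:
                raise ValueError("best objective must be the minimum over the grid")

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "best": {
                    "initial_mu_over_p": self.best_schedule.initial_mu_over_p,
                    "decay_factor": self.best_schedule.decay_factor,
                    "floor_mu_over_p": self.best_schedule.floor_mu_over_p,
                },
                "best_objective": self.best_objective,
                "grid": self.grid,
                "seeds": self.seeds,
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _series_objective(observed: DistributionSeries, simulated: DistributionSeries) -> float:
    """Mean TV distance, aligning simulated entries to observed by index.

    Excess simulated entries are ignored; missing ones are padded with
    the terminal simulated distribution.
    """
    last = len(simulated) - 1
    dists = [
        distribution_distance(obs, simulated.distributions[min(i, last)])
        for i, obs in enumerate(observed.distributions)
    ]
    return float(np.mean(dists))


def calibrate_schedule(
    observed: DistributionSeries,
    initial_lengths,
    *,
    initial_grid,
    decay_grid,
    floor_grid,
    sim_config: SimConfig | None = None,
    replicates: int = 3,
) -> CalibrationResult:
    """Direct grid search for the weakening schedule behind an observed series.

    Every grid point is simulated with ``replicates`` independent seeds
    (derived deterministically from ``sim_config.seed``); each run is
    binned at the observed bin edges, aligned to the observed labels by
    index, and scored by mean total-variation distance.  Returns the
    argmin plus the full objective surface.
    """
    if not (len(initial_grid) and len(decay_grid) and len(floor_grid)):
        raise ValueError("all three parameter grids must be non-empty")
    if len(observed) == 0:
        raise ValueError("observed series must be non-empty")
    sim_config = sim_config or SimConfig()
    # step 0 of a simulated series is the initial snapshot, which carries no
    # information about the schedule; include it iff the observed series does
    include_initial = observed.labels[0] == 0
    seeds = [int(s) for s in np.random.SeedSequence(sim_config.seed).generate_state(replicates)]

    grid_rows: list[dict] = []
    best: tuple[float, WeakeningSchedule] | None = None
    for ini, dec, flo in itertools.product(initial_grid, decay_grid, floor_grid):
        try:
            schedule = WeakeningSchedule(ini, dec, flo)
        except ValueError:
            continue  # e.g. floor above initial: not a valid schedule
        objs = []
        for seed in seeds:
            cfg = SimConfig(sim_config.min_active_to_continue, sim_config.max_steps, seed)
            traj = run_attrition(initial_lengths, schedule, cfg)
            sim_series = series_from_trajectory(
                traj, observed.bin_edges_mm, include_initial=include_initial
            )
            objs.append(_series_objective(observed, sim_series))
        objective = float(np.mean(objs))
        grid_rows.append(
            {
                "initial_mu_over_p": float(ini),
                "decay_factor": float(dec),
                "floor_mu_over_p": float(flo),
                "objective": objective,
            }
        )
        if best is None or objective < best[0]:
            best = (objective, schedule)
    if best is None:
        raise ValueError("no valid schedule in the grid")
    return CalibrationResult(best[1], best[0], grid=grid_rows, seeds=seeds)
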