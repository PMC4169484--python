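"""Step-wise stochastic fibre-attrition simulation.

Free-fall mixing is modelled as a sequence of discrete impact steps.  In
each step every active fibre meets one of three fates:

* **retired** — its breakability ratio ``4*(M_u/P)/L`` exceeds 1: the
  fibre is too short to break at the current strength and is permanently
  excluded from the breakage loop (it remains part of the material and
  of every reported length distribution);
* **broken** — a candidate break point ``p = u * L`` (``u`` uniform on
  [0, 1)) falls inside the probable failure region: the fibre is cut
  into fragments ``p`` and ``L - p``, both forwarded to the next step;
* **passed** — the candidate point falls outside the PFR: the fibre is
  forwarded unchanged.

Enzymatic weakening is encoded by a :class:`WeakeningSchedule`: ``M_u/P``
starts at 400 µm and decays by 25% per step down to a floor of 40 µm.
The run stops when fewer than a configured number of fibres (default
100) are forwarded to the next step.

Because the break point is uniform over the whole fibre, the per-step
break probability of a breakable fibre equals the relative PFR extent
``sqrt(1 - 4*(M_u/P)/L)``, and every fragment is at least ``M_u/P`` long
(the PFR boundary is at least ``M_u/P`` from either fibre end).

The *random segmentation* null model splits every fibre at a uniform
point in every step, with no exclusion rule: counts double and the mean
length halves exactly each step, and fibre lengths shrink without bound.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mechanics import pfr_relative_extent

__all__ = [
    "WeakeningSchedule",
    "SimConfig",
    "EventCounts",
    "StepRecord",
    "Trajectory",
    "mu_over_p_at_step",
    "attrition_step",
    "run_attrition",
    "random_segmentation_step",
    "run_random_segmentation",
    "load_config",
]

logger = logging.getLogger(__name__)

#: cap on the total numbers a null-model trajectory may store (~1.6 GB)
_NULL_MODEL_MAX_ELEMENTS = 2e8


@dataclass(frozen=True)
class WeakeningSchedule:
    """Per-step strength schedule: geometric decay of ``M_u/P`` to a floor.

    Defaults: start at 400 µm, lose 25% per step, floor at 40 µm.  The
    floor is a clamp: once the geometric sequence falls below it the
    strength is held at the floor for all later steps.
    """

    initial_mu_over_p: float = 400.0
    decay_factor: float = 0.75
    floor_mu_over_p: float = 40.0

    def __post_init__(self) -> None:
        if not (0.0 < self.decay_factor < 1.0):
            raise ValueError("decay_factor must lie strictly between 0 and 1")
        if not (0.0 < self.floor_mu_over_p <= self.initial_mu_over_p):
            raise ValueError("need 0 < floor_mu_over_p <= initial_mu_over_p")

    def mu_over_p_at(self, step_index: int) -> float:
        return mu_over_p_at_step(self, step_index)


@dataclass(frozen=True)
class SimConfig:
    """Run-control parameters of the attrition simulation."""

    min_active_to_continue: int = 100
    max_steps: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_active_to_continue < 1:
            raise ValueError("min_active_to_continue must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def mu_over_p_at_step(schedule: WeakeningSchedule, step_index: int) -> float:
    """``M_u/P`` in force at a given 1-based step: ``max(floor, initial*decay^(k-1))``."""
    if step_index < 1:
        raise ValueError(f"step_index must be >= 1, got {step_index}")
    value = schedule.initial_mu_over_p * schedule.decay_factor ** (step_index - 1)
    return max(schedule.floor_mu_over_p, value)


@dataclass(frozen=True)
class EventCounts:
    """Per-step tally; broken + passed + retired = fibres entering the step."""

    broken: int = 0
    passed: int = 0
    retired: int = 0

    @property
    def entering(self) -> int:
        return self.broken + self.passed + self.retired


def attrition_step(active_lengths, mu_over_p: float, rng: np.random.Generator):
    """Apply one impact step to all active fibres.

    One uniform variate is drawn per entering fibre, in input order, from
    ``rng``.  Returns ``(forwarded, newly_retired, counts)``; forwarded
    fibres preserve input order, with a broken fibre replaced in place by
    its two fragments (left fragment first).  Total length is conserved
    exactly: the two fragments are ``p`` and ``length - p``.
    """
    lengths = np.asarray(active_lengths, dtype=float)
    if lengths.size and (np.any(~np.isfinite(lengths)) or np.any(lengths <= 0)):
        raise ValueError("all active lengths must be positive and finite")
    if not (np.isfinite(mu_over_p) and mu_over_p >= 0):
        raise ValueError("mu_over_p must be finite and >= 0")
    if lengths.size == 0:
        return lengths.copy(), lengths.copy(), EventCounts()

    u = rng.random(lengths.size)
    breakable = 4.0 * mu_over_p <= lengths
    extent = pfr_relative_extent(lengths, mu_over_p)  # 0 beyond the threshold
    p = u * lengths
    lower = 0.5 * lengths * (1.0 - extent)
    upper = 0.5 * lengths * (1.0 + extent)
    # PFR membership on the closed interval; zero-extent fibres can only
    # "break" at exactly the midpoint, a probability-zero event
    broken = breakable & (extent > 0.0) & (p >= lower) & (p <= upper)
    passed = breakable & ~broken

    # forwarded list keeps input order: passed fibres contribute one
    # entry, broken fibres two (left fragment first)
    contrib = np.where(broken, 2, np.where(passed, 1, 0))
    starts = np.concatenate([[0], np.cumsum(contrib)[:-1]])
    forwarded = np.empty(int(contrib.sum()), dtype=float)
    forwarded[starts[passed]] = lengths[passed]
    forwarded[starts[broken]] = p[broken]
    forwarded[starts[broken] + 1] = lengths[broken] - p[broken]

    newly_retired = lengths[~breakable]
    counts = EventCounts(
        broken=int(broken.sum()), passed=int(passed.sum()), retired=int(newly_retired.size)
    )
    return forwarded, newly_retired, counts


@dataclass
class StepRecord:
    """Snapshot after one simulation step.

    ``active_lengths`` are the fibres forwarded to the next step;
    ``newly_retired_lengths`` were excluded during this step.  The
    cumulative retired pool up to this step is the first
    ``total_retired`` entries of the trajectory's retired pool.
    """

    step_index: int
    mu_over_p: float | None
    active_lengths: np.ndarray
    newly_retired_lengths: np.ndarray
    total_retired: int
    counts: EventCounts


@dataclass
class Trajectory:
    """Full record of a simulation run."""

    initial_lengths: np.ndarray
    steps: list[StepRecord]
    stop_reason: str
    schedule: WeakeningSchedule | None = None
    config: SimConfig | None = None
    retired_pool: np.ndarray = field(default_factory=lambda: np.empty(0))
    kind: str = "attrition"

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def final_active_lengths(self) -> np.ndarray:
        return self.steps[-1].active_lengths if self.steps else self.initial_lengths

    def retired_lengths_after(self, step_index: int) -> np.ndarray:
        """Cumulative retired pool after the given 1-based step."""
        rec = self.steps[step_index - 1]
        return self.retired_pool[: rec.total_retired]

    def all_lengths_after(self, step_index: int) -> np.ndarray:
        """Every fibre in the material after a step: active plus retired."""
        rec = self.steps[step_index - 1]
        return np.concatenate([rec.active_lengths, self.retired_lengths_after(step_index)])

    def to_dict(self, include_lengths: bool = True) -> dict:
        d = {
            "kind": self.kind,
            "stop_reason": self.stop_reason,
            "schedule": None
            if self.schedule is None
            else {
                "initial_mu_over_p": self.schedule.initial_mu_over_p,
                "decay_factor": self.schedule.decay_factor,
                "floor_mu_over_p": self.schedule.floor_mu_over_p,
            },
            "config": None
            if self.config is None
            else {
                "min_active_to_continue": self.config.min_active_to_continue,
                "max_steps": self.config.max_steps,
                "seed": self.config.seed,
            },
            "n_initial": int(self.initial_lengths.size),
            "steps": [
                {
                    "step": rec.step_index,
                    "mu_over_p": rec.mu_over_p,
                    "broken": rec.counts.broken,
                    "passed": rec.counts.passed,
                    "retired": rec.counts.retired,
                    "n_active": int(rec.active_lengths.size),
                    "n_retired_total": rec.total_retired,
                }
                for rec in self.steps
            ],
        }
        if include_lengths:
            d["initial_lengths"] = self.initial_lengths.tolist()
            for entry, rec in zip(d["steps"], self.steps):
                entry["active_lengths"] = rec.active_lengths.tolist()
                entry["newly_retired_lengths"] = rec.newly_retired_lengths.tolist()
        return d

    def to_json(self, path=None, include_lengths: bool = True) -> str:
        text = json.dumps(self.to_dict(include_lengths=include_lengths))
        if path is not None:
            Path(path).write_text(text)
        return text


def run_attrition(
    initial_lengths,
    schedule: WeakeningSchedule | None = None,
    config: SimConfig | None = None,
) -> Trajectory:
    """Run the mechanical attrition simulation to its stop rule.

    Before each step the stop rule is checked: the run ends when fewer
    than ``config.min_active_to_continue`` fibres would enter the step,
    or after ``config.max_steps`` steps.  Total fibre length (active plus
    retired) is conserved throughout.
    """
    schedule = schedule or WeakeningSchedule()
    config = config or SimConfig()
    initial = np.asarray(initial_lengths, dtype=float)
    if initial.size == 0:
        raise ValueError("initial population must be non-empty")
    if np.any(~np.isfinite(initial)) or np.any(initial <= 0):
        raise ValueError("all initial lengths must be positive and finite")

    rng = np.random.default_rng(config.seed)
    active = initial.copy()
    retired_chunks: list[np.ndarray] = []
    total_retired = 0
    steps: list[StepRecord] = []
    stop_reason = "max_steps"
    for k in range(1, config.max_steps + 1):
        if active.size < config.min_active_to_continue:
            stop_reason = "stop_rule"
            break
        mu = mu_over_p_at_step(schedule, k)
        forwarded, newly_retired, counts = attrition_step(active, mu, rng)
        retired_chunks.append(newly_retired)
        total_retired += newly_retired.size
        steps.append(
            StepRecord(
                step_index=k,
                mu_over_p=mu,
                active_lengths=forwarded,
                newly_retired_lengths=newly_retired,
                total_retired=total_retired,
                counts=counts,
            )
        )
        logger.info(
            "step %d: mu_over_p=%.3f active=%d retired_total=%d broken=%d",
            k, mu, forwarded.size, total_retired, counts.broken,
        )
        active = forwarded
    else:
        if active.size < config.min_active_to_continue:
            stop_reason = "stop_rule"

    retired_pool = np.concatenate(retired_chunks) if retired_chunks else np.empty(0)
    return Trajectory(
        initial_lengths=initial,
        steps=steps,
        stop_reason=stop_reason,
        schedule=schedule,
        config=config,
        retired_pool=retired_pool,
        kind="attrition",
    )


def random_segmentation_step(lengths, rng: np.random.Generator) -> np.ndarray:
    """Split every fibre at a uniform random point; count doubles exactly.

    One uniform variate per fibre, in input order; the output interleaves
    left and right fragments so input order is preserved.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or np.any(arr <= 0)):
        raise ValueError("all lengths must be positive and finite")
    if arr.size == 0:
        return arr.copy()
    u = rng.random(arr.size)
    p = u * arr
    out = np.empty(2 * arr.size, dtype=float)
    out[0::2] = p
    out[1::2] = arr - p
    return out


def run_random_segmentation(initial_lengths, n_steps: int, seed: int = 0) -> Trajectory:
    """Run the random-segmentation null model for a fixed number of steps.

    No exclusion and no stop rule: after ``k`` steps the count is exactly
    ``2**k`` times the initial count and the mean length is the initial
    mean over ``2**k``.  Memory therefore grows geometrically; keep
    ``n_initial * 2**n_steps`` within reason.
    """
    initial = np.asarray(initial_lengths, dtype=float)
    if initial.size == 0:
        raise ValueError("initial population must be non-empty")
    if np.any(~np.isfinite(initial)) or np.any(initial <= 0):
        raise ValueError("all initial lengths must be positive and finite")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    # the count doubles every step and every step is recorded, so the
    # trajectory holds ~n_initial * 2**(n_steps+1) numbers; refuse runs
    # that could not be held in memory
    if n_steps > 60 or initial.size * 2.0 ** (n_steps + 1) > _NULL_MODEL_MAX_ELEMENTS:
        raise ValueError(
            f"random segmentation for {n_steps} steps from {initial.size} fibres "
            f"would store ~{initial.size * 2.0 ** (n_steps + 1):.2g} lengths; "
            "reduce n_steps or the population size"
        )

    rng = np.random.default_rng(seed)
    lengths = initial.copy()
    steps: list[StepRecord] = []
    for k in range(1, n_steps + 1):
        lengths = random_segmentation_step(lengths, rng)
        steps.append(
            StepRecord(
                step_index=k,
                mu_over_p=None,
                active_lengths=lengths,
                newly_retired_lengths=np.empty(0),
                total_retired=0,
                counts=EventCounts(broken=lengths.size // 2),
            )
        )
        logger.info("null step %d: n=%d mean=%.3f", k, lengths.size, lengths.mean())
    return Trajectory(
        initial_lengths=initial,
        steps=steps,
        stop_reason="n_steps",
        schedule=None,
        config=None,
        kind="random_segmentation",
    )


def load_config(path) -> tuple[WeakeningSchedule, SimConfig]:
    """Read a YAML/JSON mapping with WeakeningSchedule and SimConfig fields."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    sched_keys = {"initial_mu_over_p", "decay_factor", "floor_mu_over_p"}
    conf_keys = {"min_active_to_continue", "max_steps", "seed"}
    unknown = set(data) - sched_keys - conf_keys
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    schedule = WeakeningSchedule(**{k: v for k, v in data.items() if k in sched_keys})
    config = SimConfig(**{k: v for k, v in data.items() if k in conf_keys})
    return schedule, config
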