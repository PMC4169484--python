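"""Beam-theory mechanics of a single fibre under impact loading.

A stiff, elongated plant fibre tumbling in a free-fall mixer is idealised
as a simply supported beam of length ``L`` struck by a transverse force
``P`` at a random position.  Three-point bending with supports at the
fibre ends is the worst-case loading: sweeping the load point along the
fibre, the largest bending moment attainable at relative position
``x/L`` is the parabolic *moment envelope*

    M_max(x) = P * L * (x/L) * (1 - x/L)

with peak ``P*L/4`` under a central load.  The fibre can only break where
this envelope reaches the failure moment ``M_u`` of the wall.  That
central portion of the fibre is the *probable failure region* (PFR); its
relative extent is

    e = sqrt(1 - 4*(M_u/P)/L)      for L > 4*M_u/P, else 0.

Only the ratio ``M_u/P`` ever enters the model.  It has units of length
and is carried in micrometres throughout, the same unit as fibre lengths:
with the conventional schedule (``M_u/P`` falling from 400 to 40) the
minimum breakable length runs from 1.6 mm down to 0.16 mm, consistent
with fibres initially cut to 3-7 mm and the later stabilisation of the
sub-0.5 mm length classes.

All functions are pure, accept scalars or numpy arrays (broadcasting),
and validate their physical domain.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MechanicalState",
    "Fibre",
    "FibreStatus",
    "moment_envelope_per_unit_force",
    "breakability_ratio",
    "is_breakable",
    "pfr_relative_extent",
    "pfr_bounds",
]


@dataclass(frozen=True)
class MechanicalState:
    """The single mechanical parameter of the model.

    Parameters
    ----------
    mu_over_p
        Ratio of failure moment ``M_u`` to characteristic impact force
        ``P``; has units of length (µm).  Must be finite and >= 0.
    """

    mu_over_p: float

    def __post_init__(self) -> None:
        v = float(self.mu_over_p)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"mu_over_p must be finite and >= 0, got {self.mu_over_p!r}")


class FibreStatus(enum.Enum):
    """Breakage eligibility of a fibre."""

    ACTIVE = "active"
    RETIRED = "retired"


@dataclass(frozen=True)
class Fibre:
    """A single fibre: a length in µm and its simulation status.

    Retired fibres are permanently excluded from the breakage loop (they
    are too short to break at the strength in force when they were
    retired); their length never changes again.
    """

    length: float
    status: FibreStatus = FibreStatus.ACTIVE

    def __post_init__(self) -> None:
        if not (self.length > 0 and np.isfinite(self.length)):
            raise ValueError(f"fibre length must be positive and finite, got {self.length!r}")


def _validate_length(length) -> np.ndarray:
    arr = np.asarray(length, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("fibre length must be positive and finite")
    return arr


def _validate_mu(mu_over_p) -> np.ndarray:
    arr = np.asarray(mu_over_p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("mu_over_p must be finite and >= 0")
    return arr


def moment_envelope_per_unit_force(rel_pos, length):
    """Largest attainable bending moment per unit force, ``L*x'*(1-x')``.

    Parameters
    ----------
    rel_pos
        Relative position ``x/L`` along the fibre, in [0, 1].
    length
        Fibre length in µm (> 0).

    Returns
    -------
    Moment per unit force, in µm.  Zero at the supports, maximal
    (``length/4``) at mid-span, symmetric about ``rel_pos = 0.5``.
    """
    x = np.asarray(rel_pos, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x < 0) or np.any(x > 1):
        raise ValueError("rel_pos must lie in [0, 1]")
    L = _validate_length(length)
    out = L * x * (1.0 - x)
    return out if out.ndim else float(out)


def breakability_ratio(length, mu_over_p):
    """Ratio of failure moment to the peak moment under a central load.

    Equals ``4 * mu_over_p / length``; a fibre with ratio > 1 cannot be
    broken by any loading position.
    """
    L = _validate_length(length)
    mu = _validate_mu(mu_over_p)
    out = 4.0 * mu / L
    return out if out.ndim else float(out)


def is_breakable(length, mu_over_p):
    """Whether the fibre is long enough to break at all.

    True iff ``breakability_ratio <= 1`` (i.e. ``length >= 4*mu_over_p``).
    A fibre exactly at the threshold is formally breakable but its PFR has
    zero extent, so its break probability is zero.
    """
    r = breakability_ratio(length, mu_over_p)
    out = np.asarray(r) <= 1.0
    return out if out.ndim else bool(out)


def pfr_relative_extent(length, mu_over_p):
    """Relative extent of the probable failure region, ``sqrt(1 - 4*mu/L)``.

    The PFR is the central fraction of the fibre where the moment
    envelope reaches the failure moment; a break point drawn uniformly
    along the fibre falls inside it with exactly this probability.
    Returns 0 for fibres at or below the breakable-length threshold
    ``4*mu_over_p``, and 1 for a fibre of zero strength.
    """
    r = breakability_ratio(length, mu_over_p)
    # clamp at the threshold so roundoff never yields sqrt of a negative
    out = np.sqrt(np.maximum(0.0, 1.0 - np.asarray(r)))
    return out if out.ndim else float(out)


def pfr_bounds(length, mu_over_p):
    """Absolute PFR interval ``(lower, upper)`` in µm, symmetric about mid-span.

    ``lower = L*(1-e)/2`` and ``upper = L*(1+e)/2`` with ``e`` the relative
    extent; the interval degenerates to the midpoint when the extent is
    zero and spans the whole fibre when the strength is zero.
    """
    L = _validate_length(length)
    e = np.asarray(pfr_relative_extent(length, mu_over_p))
    half = 0.5 * L * e
    lower = 0.5 * L - half
    upper = 0.5 * L + half
    if np.ndim(lower):
        return lower, upper
    return float(lower), float(upper)
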