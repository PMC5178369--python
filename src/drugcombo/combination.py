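"""Combination-index and isobologram analysis of two-drug treatments.

The combination index (CI) of Chou for a dose pair (D1, D2) producing an
observed combined effect is

    CI = D1/Dx1 + D2/Dx2 + alpha * (D1*D2) / (Dx1*Dx2),

where Dx1 and Dx2 are the single-agent doses producing the same effect as
the combination (read off each agent's median-effect fit) and alpha encodes
the assumed mode of action: alpha=0 for drugs sharing a mechanism
(mutually exclusive), alpha=1 for independent mechanisms (mutually
nonexclusive).  CI = 1 is additivity, CI < 1 synergism, CI > 1 antagonism.

The isobologram is the geometric counterpart at a fixed effect level
(here 50%): normalizing each dose by its agent's IC50, the line
x + y = 1 joining the single-agent IC50s is the additivity isobole;
points below it indicate synergy, points above antagonism.  For
IC50-equieffective points the coordinate sum equals CI at alpha=0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .dose_response import MedianEffectFit, dose_for_effect, fraction_affected

__all__ = [
    "INTERACTION_CALLS",
    "EffectRangeError",
    "CombinationRecord",
    "IsobologramPoint",
    "combination_index",
    "derive_equieffective_doses",
    "classify_interaction",
    "round_half_up",
    "theoretical_isobologram",
    "place_on_isobologram",
    "build_record",
]

INTERACTION_CALLS = ("synergistic", "additive", "antagonistic")


class EffectRangeError(ValueError):
    """Combined effect of exactly 0% or 100%: equieffective doses undefined."""


@dataclass(frozen=True)
class CombinationRecord:
    """One scored combination row (the shape of a CI summary table)."""

    d1: float
    d2: float
    dx1: float
    dx2: float
    control_growth_pct: float | None
    alpha: int
    ci: float
    call: str

    def __post_init__(self) -> None:
        if self.call not in INTERACTION_CALLS:
            raise ValueError(f"unknown interaction call {self.call!r}")


@dataclass(frozen=True)
class IsobologramPoint:
    """A combination placed in normalized isobologram coordinates."""

    x: float  # D1 / IC50_1
    y: float  # D2 / IC50_2
    position: str  # below_line | on_line | above_line


def combination_index(d1, d2, dx1, dx2, alpha: int = 1):
    """Chou combination index for a dose pair and its equieffective doses.

    Parameters
    ----------
    d1, d2 :
        Doses of each drug in the combination (same units as dx1/dx2).
    dx1, dx2 :
        Single-agent doses giving the same response as the combination;
        must be positive.
    alpha :
        0 (shared mechanism) or 1 (independent mechanisms, the default).

    Notes
    -----
    CI is unit-invariant under simultaneous rescaling of (d1, dx1) or
    (d2, dx2).  Vectorized over array inputs.
    """
    if alpha not in (0, 1):
        raise ValueError(f"alpha must be 0 or 1, got {alpha!r}")
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    dx1_a = np.asarray(dx1, dtype=float)
    dx2_a = np.asarray(dx2, dtype=float)
    if np.any(dx1_a <= 0):
        raise ValueError(f"equieffective dose Dx1 must be positive, got {dx1}")
    if np.any(dx2_a <= 0):
        raise ValueError(f"equieffective dose Dx2 must be positive, got {dx2}")
    ci = d1 / dx1_a + d2 / dx2_a + alpha * (d1 * d2) / (dx1_a * dx2_a)
    return ci if ci.ndim else float(ci)


def derive_equieffective_doses(
    d1: float,
    d2: float,
    control_growth_pct: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
) -> tuple[float, float]:
    """Single-agent doses matching the combination's observed effect.

    The observed percent-of-control growth is converted to a fraction
    affected, and each agent's median-effect fit is inverted at that
    effect level.  A combined effect of exactly 0% or 100% has no finite
    equieffective dose and raises :class:`EffectRangeError`.
    """
    fa = fraction_affected(control_growth_pct)
    if not 0.0 < fa < 1.0:
        raise EffectRangeError(
            f"combined effect fa={fa} for (D1={d1}, D2={d2}) is outside (0,1); "
            "CI undefined"
        )
    return dose_for_effect(fit1, fa), dose_for_effect(fit2, fa)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_interaction(
    ci: float, *, decimals: int = 1, tol: float | None = None
) -> str:
    """Label a combination index as synergistic / additive / antagonistic.

    By default the CI is rounded half-up to one decimal (the precision CI
    tables are printed at) and compared with 1.0, so 0.96..1.04 counts as
    additive.  Pass ``tol`` for an explicit band |CI - 1| <= tol instead
    (``tol=0`` gives the exact rule).
    """
    if not ci > 0:
        raise ValueError(f"combination index must be positive, got {ci}")
    if tol is not None:
        if tol < 0:
            raise ValueError("tol must be non-negative")
        if abs(ci - 1.0) <= tol:
            return "additive"
        return "synergistic" if ci < 1.0 else "antagonistic"
    rounded = round_half_up(ci, decimals)
    if rounded == 1.0:
        return "additive"
    return "synergistic" if rounded < 1.0 else "antagonistic"


def theoretical_isobologram(
    ic50_1: float, ic50_2: float, n_points: int = 11
) -> np.ndarray:
    """Dose pairs on the additivity isobole D1/IC50_1 + D2/IC50_2 = 1.

    Returns an (n_points, 2) array evenly spaced in D1 from 0 to IC50_1;
    the endpoints are (IC50_1, 0) and (0, IC50_2).  This is the line used
    to pick candidate combination doses expected to be additive.
    """
    if not (ic50_1 > 0 and ic50_2 > 0):
        raise ValueError("both IC50 values must be positive")
    if n_points < 2:
        raise ValueError("need at least the two endpoint doses")
    d1 = np.linspace(0.0, ic50_1, n_points)
    d2 = ic50_2 * (1.0 - d1 / ic50_1)
    return np.column_stack([d1, d2])


def place_on_isobologram(
    d1: float,
    d2: float,
    ic50_1: float,
    ic50_2: float,
    tol: float = 0.05,
) -> IsobologramPoint:
    """Locate a dose pair relative to the 50%-effect additivity line.

    Coordinates are the doses normalized by each agent's IC50; the pair is
    below the line (synergy side) when x + y < 1 - tol, above it
    (antagonism side) when x + y > 1 + tol, and on it otherwise.  The
    default tolerance 0.05 matches the one-decimal granularity of the CI
    classification.
    """
    if not (ic50_1 > 0 and ic50_2 > 0):
        raise ValueError("both IC50 values must be positive")
    x = d1 / ic50_1
    y = d2 / ic50_2
    s = x + y
    if s < 1.0 - tol:
        position = "below_line"
    elif s > 1.0 + tol:
        position = "above_line"
    else:
        position = "on_line"
    return IsobologramPoint(x=x, y=y, position=position)


def build_record(
    d1: float,
    d2: float,
    *,
    control_growth_pct: float | None = None,
    dx1: float | None = None,
    dx2: float | None = None,
    fit1: MedianEffectFit | None = None,
    fit2: MedianEffectFit | None = None,
    alpha: int = 1,
    decimals: int = 1,
    tol: float | None = None,
) -> CombinationRecord:
    """Score one combination row, in either of two modes.

    Replication mode: pass ``dx1``/``dx2`` directly (e.g. transcribed from
    a published CI table).  Pipeline mode: pass the two median-effect fits
    and the observed ``control_growth_pct``; the equieffective doses are
    derived from the fits.  Both modes share the same CI evaluation and
    classification.
    """
    if dx1 is None or dx2 is None:
        if fit1 is None or fit2 is None or control_growth_pct is None:
            raise ValueError(
                "either (dx1, dx2) or (fit1, fit2, control_growth_pct) required"
            )
        dx1, dx2 = derive_equieffective_doses(
            d1, d2, control_growth_pct, fit1, fit2
        )
    ci = combination_index(d1, d2, dx1, dx2, alpha=alpha)
    call = classify_interaction(ci, decimals=decimals, tol=tol)
    return CombinationRecord(
        d1=d1,
        d2=d2,
        dx1=float(dx1),
        dx2=float(dx2),
        control_growth_pct=control_growth_pct,
        alpha=alpha,
        ci=float(ci),
        call=call,
    )
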