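"""Xenograft tumor-growth endpoints from caliper measurements.

Tumor volume from a two-dimensional caliper reading uses the ellipsoid
approximation

    V = (pi/6) * width**2 * length        [mm^3],

with width the smaller of the two dimensions.  Growth speed is summarized
as the cell doubling time

    CDT = days_of_treatment / log2(V_final / V_initial)   [days],

the treatment duration divided by the number of volume doublings over it;
for exponential growth V(t) = V0*exp(r*t) this equals ln2/r regardless of
the window.  A shrinking tumor gives a negative CDT, reported as-is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CDTUndefinedError",
    "TumorSeries",
    "GrowthSummary",
    "tumor_volume",
    "cell_doubling_time",
    "summarize_groups",
]

GROUPS = ("control", "CDDP", "alphaM", "CDDP_alphaM")


class CDTUndefinedError(ValueError):
    """Final volume equals initial volume: zero doublings, CDT undefined."""


def tumor_volume(width, length):
    """Ellipsoid caliper volume V = (pi/6) * width^2 * length, in mm^3.

    By convention width is the smaller dimension; swapped inputs are
    auto-corrected with a warning since the formula is asymmetric.
    Vectorized over arrays.  For width == length == d this is the sphere
    volume (pi/6) d^3.
    """
    w = np.asarray(width, dtype=float)
    l = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("caliper dimensions must be positive")
    if np.any(w > l):
        warnings.warn(
            "width larger than length; dimensions swapped (width is the "
            "smaller caliper reading)",
            stacklevel=2,
        )
        w, l = np.minimum(w, l), np.maximum(w, l)
    v = (math.pi / 6.0) * w**2 * l
    return v if v.ndim else float(v)


def cell_doubling_time(
    days_of_treatment: float, v_initial: float, v_final: float
) -> float:
    """Days per volume doubling over a treatment window.

    CDT = days / log2(v_final / v_initial).  Negative when the tumor
    shrank over the window (fewer than zero doublings); the sign carries
    the shrinkage information.  Unit-free in volume (only the ratio
    enters).

    Raises
    ------
    CDTUndefinedError
        If the volume did not change at all (division by zero doublings).
    """
    if not (v_initial > 0 and v_final > 0):
        raise ValueError("tumor volumes must be positive")
    if not days_of_treatment > 0:
        raise ValueError("days of treatment must be positive")
    doublings = math.log2(v_final / v_initial)
    if doublings == 0.0:
        raise CDTUndefinedError(
            "final volume equals initial volume; doubling time undefined"
        )
    return days_of_treatment / doublings


@dataclass(frozen=True)
class TumorSeries:
    """Longitudinal caliper record for one animal.

    Days must be non-decreasing; widths/lengths are matched mm readings.
    Volumes are always derived from the calipers, never stored.
    """

    animal_id: str
    group: str
    days: np.ndarray
    widths: np.ndarray
    lengths: np.ndarray
    body_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        widths = np.asarray(self.widths, dtype=float)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "lengths", lengths)
        if self.body_weights is not None:
            object.__setattr__(
                self, "body_weights", np.asarray(self.body_weights, dtype=float)
            )
        if not (days.shape == widths.shape == lengths.shape) or days.ndim != 1:
            raise ValueError(
                f"animal {self.animal_id!r}: days/widths/lengths must be "
                "matched 1-d arrays"
            )
        if days.size == 0:
            raise ValueError(f"animal {self.animal_id!r}: empty series")
        if np.any(np.diff(days) < 0):
            raise ValueError(
                f"animal {self.animal_id!r}: measurement days must be "
                "non-decreasing"
            )

    @property
    def volumes(self) -> np.ndarray:
        """Caliper volumes (mm^3) derived measurement-by-measurement."""
        return np.asarray(tumor_volume(self.widths, self.lengths))

    def volume_at(self, day: float, *, side: str) -> tuple[float, float]:
        """Volume at the measurement nearest ``day`` from one side.

        ``side="initial"`` takes the first measurement on or after ``day``;
        ``side="final"`` the last measurement on or before ``day``.
        Returns (actual measurement day, volume).
        """
        if side == "initial":
            idx = np.flatnonzero(self.days >= day)
            if idx.size == 0:
                raise ValueError(
                    f"animal {self.animal_id!r}: no measurement on/after day {day}"
                )
            i = int(idx[0])
        elif side == "final":
            idx = np.flatnonzero(self.days <= day)
            if idx.size == 0:
                raise ValueError(
                    f"animal {self.animal_id!r}: no measurement on/before day {day}"
                )
            i = int(idx[-1])
        else:
            raise ValueError("side must be 'initial' or 'final'")
        return float(self.days[i]), float(self.volumes[i])


@dataclass(frozen=True)
class GrowthSummary:
    """Per-group growth response: mean +/- SD of volumes and CDT."""

    group: str
    n: int
    initial_volume_mean: float
    initial_volume_sd: float
    final_volume_mean: float
    final_volume_sd: float
    cdt_mean: float
    cdt_sd: float
    n_shrinking: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group summary needs at least one animal")


def summarize_groups(
    series: list[TumorSeries],
    treatment_window: tuple[float, float] | None = None,
) -> list[GrowthSummary]:
    """Group-level growth response over a treatment window.

    For each animal the initial volume is taken at the first measurement
    on/after ``day_start`` and the final volume at the last measurement
    on/before ``day_end``; the per-animal CDT uses the actual span between
    those two measurement days.  The default window runs from each
    animal's first to last measurement.  SDs are population SDs over
    animals (ddof=0) so a duplicated animal yields SD 0.  Output order
    follows the canonical group order, then first appearance.
    """
    if not series:
        raise ValueError("no tumor series supplied")
    rows = []
    for s in series:
        start = treatment_window[0] if treatment_window else float(s.days[0])
        end = treatment_window[1] if treatment_window else float(s.days[-1])
        d0, v0 = s.volume_at(start, side="initial")
        d1, v1 = s.volume_at(end, side="final")
        if d1 <= d0:
            raise ValueError(
                f"animal {s.animal_id!r}: window [{start}, {end}] does not "
                "span two distinct measurements"
            )
        rows.append(
            {
                "group": s.group,
                "animal_id": s.animal_id,
                "initial": v0,
                "final": v1,
                "cdt": cell_doubling_time(d1 - d0, v0, v1),
            }
        )
    df = pd.DataFrame(rows)
    order = {g: i for i, g in enumerate(GROUPS)}
    groups = sorted(df["group"].unique(), key=lambda g: (order.get(g, len(order)), g))
    out = []
    for g in groups:
        # fixed within-group order makes the summary invariant to the
        # order animals were supplied in, down to the last bit
        sub = df[df["group"] == g].sort_values("animal_id", kind="stable")
        out.append(
            GrowthSummary(
                group=g,
                n=len(sub),
                initial_volume_mean=float(sub["initial"].mean()),
                initial_volume_sd=float(sub["initial"].std(ddof=0)),
                final_volume_mean=float(sub["final"].mean()),
                final_volume_sd=float(sub["final"].std(ddof=0)),
                cdt_mean=float(sub["cdt"].mean()),
                cdt_sd=float(sub["cdt"].std(ddof=0)),
                n_shrinking=int((sub["cdt"] < 0).sum()),
            )
        )
    return out
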