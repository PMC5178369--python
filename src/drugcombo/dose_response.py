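"""Median-effect dose-response modelling for single-agent cytotoxicity data.

The central model is Chou's median-effect equation

    fa / fu = (D / Dm)**m,        fu = 1 - fa,

which links the dose ``D`` of an inhibitor to the fraction of cells affected
``fa``.  ``Dm`` is the median-effect dose (the dose producing a 50% effect,
i.e. the IC50) and ``m`` is the sigmoidicity (Hill-type shape) coefficient.
Taking logarithms linearizes the model,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

so a least-squares line through (log10 D, log10 fa/fu) yields both
parameters.  This is the classical median-effect plot used throughout
combination-index analysis: the same fitted curve supplies the IC50 of each
single agent and the equieffective doses Dx needed to score combinations.

Viability input is the percent-of-control readout of an MTT plate (optical
density of treated wells over the mean control optical density, times 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "VALID_SCHEMES",
    "FitError",
    "ViabilityTable",
    "MedianEffectFit",
    "normalize_viability",
    "fraction_affected",
    "fit_median_effect",
    "effect_at_dose",
    "dose_for_effect",
]

VALID_SCHEMES = ("single", "coincubation", "preincubation")


class FitError(ValueError):
    """Raised when a median-effect fit cannot be performed."""


@dataclass(frozen=True)
class ViabilityTable:
    """Long-format single-agent viability data.

    Each entry of ``doses``/``viability_pct`` is one well; replicate wells
    simply repeat their dose.  Dose 0 (the control) is allowed and is by
    definition 100% viability, but control wells need not be present since
    the data are already normalized to control.

    Parameters
    ----------
    agent :
        Drug label, e.g. ``"CDDP"`` or ``"alphaM"``.
    scheme :
        Exposure scheme: ``"single"``, ``"coincubation"`` or
        ``"preincubation"``.
    doses :
        Concentrations in µM, non-negative.
    viability_pct :
        Percent-of-control viability matched to ``doses``.  Values above
        100% are legal (plates overshoot control) and handled downstream.
    replicate :
        Optional replicate index per well.
    """

    agent: str
    scheme: str
    doses: np.ndarray
    viability_pct: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        via = np.asarray(self.viability_pct, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability_pct", via)
        if self.replicate is not None:
            object.__setattr__(self, "replicate", np.asarray(self.replicate))
        if self.scheme not in VALID_SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme!r}; expected one of {VALID_SCHEMES}"
            )
        if doses.shape != via.shape or doses.ndim != 1:
            raise ValueError("doses and viability_pct must be matched 1-d arrays")
        if doses.size == 0:
            raise ValueError(f"empty viability table for agent {self.agent!r}")
        if np.any(doses < 0):
            raise ValueError(f"negative dose in table for agent {self.agent!r}")
        if np.any(via < 0):
            raise ValueError(f"negative viability in table for agent {self.agent!r}")

    def mean_per_dose(self) -> "ViabilityTable":
        """Collapse replicate wells to their per-dose mean viability."""
        uniq = np.unique(self.doses)
        means = np.array(
            [self.viability_pct[self.doses == d].mean() for d in uniq]
        )
        return replace(self, doses=uniq, viability_pct=means, replicate=None)


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect model for one agent.

    ``dm`` is the median-effect dose in µM (equal to the IC50), ``m`` the
    sigmoidicity coefficient, ``r2`` the coefficient of determination of
    the linearized fit and ``n_points`` the number of wells with
    0 < fa < 1 that entered the regression.  ``non_inhibitor`` flags a fit
    whose slope came out non-positive (effect decreasing with dose).
    """

    dm: float
    m: float
    r2: float = float("nan")
    n_points: int = 0
    agent: str = ""
    scheme: str = "single"
    non_inhibitor: bool = False

    def __post_init__(self) -> None:
        if not self.non_inhibitor and not self.dm > 0:
            raise ValueError(f"Dm must be positive, got {self.dm}")

    def effect_at_dose(self, dose):
        return effect_at_dose(self, dose)

    def dose_for_effect(self, fa):
        return dose_for_effect(self, fa)

    @property
    def ic50(self) -> float:
        """Alias: in the median-effect model the IC50 is Dm."""
        return self.dm


def normalize_viability(od_treated, od_control: float) -> np.ndarray:
    """Convert raw MTT optical densities to percent-of-control viability.

    ``viability = 100 * OD_treated / mean(OD_control)``.  Values above 100%
    are returned as-is.

    Raises
    ------
    ValueError
        If the control signal is zero or negative (a blank or failed
        control well) or any treated OD is negative.
    """
    od_treated = np.asarray(od_treated, dtype=float)
    if not od_control > 0:
        raise ValueError(
            f"control optical density must be positive, got {od_control!r}"
        )
    if np.any(od_treated < 0):
        bad = np.flatnonzero(od_treated < 0)
        raise ValueError(f"negative treated optical density at wells {bad.tolist()}")
    return 100.0 * od_treated / od_control


def fraction_affected(viability_pct) -> np.ndarray | float:
    """Map percent-of-control viability to the fraction affected fa.

    ``fa = 1 - viability/100``, clamped to [0, 1].  Viability above 100%
    (well brighter than control) clamps to fa = 0 with a warning rather
    than erroring: real plates overshoot control.
    """
    via = np.asarray(viability_pct, dtype=float)
    if np.any(via < 0):
        raise ValueError("viability percent must be non-negative")
    if np.any(via > 100):
        warnings.warn(
            "viability above 100% of control clamped to fa=0", stacklevel=2
        )
    fa = np.clip(1.0 - via / 100.0, 0.0, 1.0)
    return fa if fa.ndim else float(fa)


def fit_median_effect(
    table: ViabilityTable, *, per_replicate: bool = False
) -> MedianEffectFit:
    """Fit the median-effect model by its log-linearization.

    Least squares on (log10 D, log10(fa/fu)) over all points with a
    positive dose and 0 < fa < 1; points at fa ∈ {0, 1} carry no
    information on the log-odds scale and are excluded.  Slope gives
    ``m``; ``Dm`` is recovered from the intercept ``-m*log10(Dm)``.

    By default replicate wells are averaged to one viability value per
    dose before the transform, the usual median-effect workflow: the mean
    effect per dose enters the plot.  Averaging first also keeps the
    out-of-range exclusion from acting on individual noisy wells, which
    would retain a biased subset at the extreme doses.  Set
    ``per_replicate=True`` to regress on every well instead.

    Raises
    ------
    FitError
        Fewer than two usable points, or an exactly flat median-effect
        plot (fa identical at every dose), for which Dm is undefined.
    """
    if not per_replicate:
        table = table.mean_per_dose()
    fa = np.asarray(fraction_affected(table.viability_pct))
    usable = (table.doses > 0) & (fa > 0) & (fa < 1)
    n = int(usable.sum())
    if n < 2:
        raise FitError(
            f"median-effect fit for {table.agent!r} needs >=2 wells with "
            f"0 < fa < 1, got {n}"
        )
    x = np.log10(table.doses[usable])
    y = np.log10(fa[usable] / (1.0 - fa[usable]))
    if np.ptp(x) == 0:
        raise FitError(
            f"all usable wells for {table.agent!r} share one dose; slope undefined"
        )
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope == 0:
        raise FitError(
            f"degenerate median-effect plot for {table.agent!r}: identical "
            "effect at every dose, Dm undefined"
        )
    non_inhibitor = slope < 0
    if non_inhibitor:
        warnings.warn(
            f"negative median-effect slope for {table.agent!r}: effect "
            "decreases with dose (non-inhibitor behavior)",
            stacklevel=2,
        )
    dm = 10.0 ** (-intercept / slope)
    r2 = float(res.rvalue) ** 2
    return MedianEffectFit(
        dm=dm,
        m=slope,
        r2=r2,
        n_points=n,
        agent=table.agent,
        scheme=table.scheme,
        non_inhibitor=non_inhibitor,
    )


def effect_at_dose(fit: MedianEffectFit, dose):
    """Fraction affected at a dose: fa = (D/Dm)^m / (1 + (D/Dm)^m).

    fa(0) = 0 and fa(Dm) = 0.5 by construction; strictly increasing in D
    for m > 0. Accepts scalars or arrays.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = (d / fit.dm) ** fit.m
    fa = np.where(np.isinf(ratio), 1.0, ratio / (1.0 + ratio))
    fa = np.where(d == 0, 0.0, fa)
    return fa if fa.ndim else float(fa)


def dose_for_effect(fit: MedianEffectFit, fa):
    """Dose producing a target fraction affected: Dx = Dm*(fa/fu)^(1/m).

    The algebraic inverse of :func:`effect_at_dose`; fa = 0.5 returns Dm
    exactly.  Only effects strictly inside (0, 1) have a finite dose.
    """
    fa_arr = np.asarray(fa, dtype=float)
    if np.any((fa_arr <= 0) | (fa_arr >= 1)):
        raise ValueError(f"target effect must lie strictly in (0, 1), got {fa}")
    dx = fit.dm * (fa_arr / (1.0 - fa_arr)) ** (1.0 / fit.m)
    return dx if dx.ndim else float(dx)
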