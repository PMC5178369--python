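"""Synthetic MTT viability plates and xenograft growth trajectories.

The generators emulate the two experiments the analysis pipeline consumes:

* **In vitro.** Single-agent plates draw percent-of-control viability from
  a median-effect (Hill-type) curve plus Gaussian well noise. Combination
  plates are built on a Loewe-additivity null: for a dose pair (D1, D2) the
  additive combined effect F solves D1/Dx1(F) + D2/Dx2(F) = 1, where
  Dx_i(F) is each agent's dose-for-effect curve.  A per-scheme deviation
  factor beta then scales the fraction affected (beta < 1 protective/
  antagonistic, beta = 1 additive, beta > 1 synergistic) before noise,
  which is the single knob steering downstream CI calls.

* **In vivo.** Each animal grows exponentially, V(t) = V0*exp(r*t)*(1+eps),
  from a truncated-normal starting volume.  Caliper width/length are
  back-derived from the volume at a fixed length:width aspect ratio so the
  ellipsoid volume formula recovers V exactly.

All draws flow through numpy Generators seeded from ``SynthConfig.seed``
plus a fixed per-stream label, so a fixed seed reproduces every output
bit-for-bit while the streams stay independent of one another.

Defaults mirror the cisplatin (CDDP) + alpha-mangostin study conditions:
IC50 29.7 uM for CDDP and 19.1 uM for alpha-M, triplicate wells, 5% well
noise, coincubation protective (beta 0.7) and preincubation synergistic
(beta 1.3), and four xenograft arms whose exponential rates are set from
doubling times of 3.9 / 4.7 / 4.9 / 8.5 days with starting volumes around
150-190 mm^3.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import MedianEffectFit, ViabilityTable, effect_at_dose
from .invivo import TumorSeries

__all__ = [
    "AgentParams",
    "GroupParams",
    "SynthConfig",
    "loewe_additive_effect",
    "gen_single_agent_plate",
    "gen_combination_plate",
    "gen_tumor_cohort",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth median-effect curve of one agent: (Dm uM, m)."""

    dm: float
    m: float

    def __post_init__(self) -> None:
        if not (self.dm > 0 and self.m > 0):
            raise ValueError("Dm and m must be positive")

    def as_fit(self, agent: str = "", scheme: str = "single") -> MedianEffectFit:
        return MedianEffectFit(dm=self.dm, m=self.m, agent=agent, scheme=scheme)


@dataclass(frozen=True)
class GroupParams:
    """Ground truth for one xenograft arm.

    ``rate_per_day`` is the exponential growth rate r (CDT = ln2/r);
    ``v0_mean``/``v0_sd`` parameterize the truncated-normal starting
    volume in mm^3.
    """

    rate_per_day: float
    v0_mean: float
    v0_sd: float

    def __post_init__(self) -> None:
        if not self.v0_mean > 0 or self.v0_sd < 0:
            raise ValueError("starting volume mean must be positive, SD >= 0")


def _default_agents() -> dict[str, AgentParams]:
    return {
        "CDDP": AgentParams(dm=29.7, m=2.0),
        "alphaM": AgentParams(dm=19.1, m=2.0),
    }


def _default_doses() -> dict[str, tuple[float, ...]]:
    # dose 0 is the in-plate control well row; 6 positive doses per agent,
    # a twofold dilution series from each agent's top tested concentration
    return {
        "CDDP": (0.0, 3.75, 7.5, 15.0, 30.0, 60.0, 120.0),
        "alphaM": (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0),
    }


def _default_schemes() -> dict[str, float]:
    return {"single": 1.0, "coincubation": 0.7, "preincubation": 1.3}


def _default_combo_doses() -> tuple[tuple[float, float], ...]:
    # (CDDP, alpha-M) pairs picked from the theoretical additivity
    # isobole, as the emulated study design does: D1/IC50_1 + D2/IC50_2 = 1
    # at fractions 1/4, 1/2, 3/4 along the CDDP axis.  Near the 50% effect
    # level the combination index is least sensitive to well noise.
    return (
        (29.7 * 0.25, 19.1 * 0.75),
        (29.7 * 0.50, 19.1 * 0.50),
        (29.7 * 0.75, 19.1 * 0.25),
    )


def _default_invivo() -> dict[str, GroupParams]:
    return {
        "control": GroupParams(rate_per_day=LN2 / 3.9, v0_mean=168.0, v0_sd=59.0),
        "CDDP": GroupParams(rate_per_day=LN2 / 4.7, v0_mean=144.0, v0_sd=41.0),
        "alphaM": GroupParams(rate_per_day=LN2 / 4.9, v0_mean=143.0, v0_sd=36.0),
        "CDDP_alphaM": GroupParams(rate_per_day=LN2 / 8.5, v0_mean=192.0, v0_sd=93.0),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for the synthetic study.

    A fixed ``seed`` makes every generator deterministic; all other
    defaults encode the emulated study conditions (see module docstring).
    """

    seed: int = 0
    agents: dict[str, AgentParams] = field(default_factory=_default_agents)
    doses: dict[str, tuple[float, ...]] = field(default_factory=_default_doses)
    noise_sd_pct: float = 5.0
    scheme_interaction: dict[str, float] = field(default_factory=_default_schemes)
    n_replicates: int = 3
    combo_doses: tuple[tuple[float, float], ...] = field(
        default_factory=_default_combo_doses
    )
    combo_agents: tuple[str, str] = ("CDDP", "alphaM")
    invivo: dict[str, GroupParams] = field(default_factory=_default_invivo)
    invivo_days: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0)
    invivo_noise_sd: float = 0.05
    n_animals: int = 7
    aspect_ratio: float = 1.5

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_animals < 1:
            raise ValueError("n_replicates and n_animals must be >= 1")
        if self.noise_sd_pct < 0 or self.invivo_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be positive")
        for beta in self.scheme_interaction.values():
            if beta < 0:
                raise ValueError("scheme deviation factor beta must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator for a named stream."""
        label = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng([int(self.seed), label])


def loewe_additive_effect(
    d1: float, d2: float, fit1: MedianEffectFit, fit2: MedianEffectFit
) -> float:
    """Combined fraction affected of (d1, d2) under Loewe additivity.

    Solves for the effect F at which the pair sits exactly on the isobole:
    d1/Dx1(F) + d2/Dx2(F) = 1, with Dx_i(F) = Dm_i*(F/(1-F))^(1/m_i).
    The isobole sum is strictly decreasing in F (higher effect levels need
    higher doses), so the root is unique and bracketed by bisection.
    With one dose zero this reduces to the single agent's effect; with
    both doses zero the effect is 0.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be non-negative")
    if d1 == 0 and d2 == 0:
        return 0.0
    if d2 == 0:
        return effect_at_dose(fit1, d1)
    if d1 == 0:
        return effect_at_dose(fit2, d2)

    def isobole_excess(f: float) -> float:
        dx1 = fit1.dm * (f / (1.0 - f)) ** (1.0 / fit1.m)
        dx2 = fit2.dm * (f / (1.0 - f)) ** (1.0 / fit2.m)
        return d1 / dx1 + d2 / dx2 - 1.0

    eps = 1e-12
    return float(brentq(isobole_excess, eps, 1.0 - eps, xtol=1e-14, rtol=1e-14))


def gen_single_agent_plate(config: SynthConfig, agent: str) -> ViabilityTable:
    """Simulate one single-agent MTT plate (percent-of-control viability).

    Each well draws 100*(1 - fa(D)) plus Gaussian noise of SD
    ``noise_sd_pct``, clamped at 0; replicates are independent draws.
    """
    params = config.agents[agent]
    fit = params.as_fit(agent)
    doses = np.asarray(config.doses[agent], dtype=float)
    rng = config.rng(f"plate:{agent}")
    dose_col = np.repeat(doses, config.n_replicates)
    rep_col = np.tile(np.arange(config.n_replicates), doses.size)
    clean = 100.0 * (1.0 - np.asarray(effect_at_dose(fit, dose_col)))
    noisy = clean + rng.normal(0.0, config.noise_sd_pct, size=dose_col.size)
    return ViabilityTable(
        agent=agent,
        scheme="single",
        doses=dose_col,
        viability_pct=np.maximum(noisy, 0.0),
        replicate=rep_col,
    )


def gen_combination_plate(config: SynthConfig, scheme: str) -> pd.DataFrame:
    """Simulate combination wells for one exposure scheme.

    For every (D1, D2) pair the Loewe-additive effect F is computed from
    the ground-truth curves, scaled by the scheme's deviation factor beta
    (clamped back into [0, 1]), converted to percent-of-control growth,
    and degraded with well noise.  Returns a long DataFrame with columns
    ``d1_uM, d2_uM, scheme, replicate, control_growth_pct``.
    """
    if scheme not in config.scheme_interaction:
        raise ValueError(
            f"no deviation factor configured for scheme {scheme!r}"
        )
    beta = config.scheme_interaction[scheme]
    a1, a2 = config.combo_agents
    fit1 = config.agents[a1].as_fit(a1)
    fit2 = config.agents[a2].as_fit(a2)
    rng = config.rng(f"combo:{scheme}")
    rows = []
    for d1, d2 in config.combo_doses:
        f_add = loewe_additive_effect(d1, d2, fit1, fit2)
        fa_obs = min(max(beta * f_add, 0.0), 1.0)
        growth_clean = 100.0 * (1.0 - fa_obs)
        for rep in range(config.n_replicates):
            noisy = growth_clean + rng.normal(0.0, config.noise_sd_pct)
            rows.append(
                {
                    "d1_uM": d1,
                    "d2_uM": d2,
                    "scheme": scheme,
                    "replicate": rep,
                    "control_growth_pct": max(noisy, 0.0),
                }
            )
    return pd.DataFrame(rows)


def gen_tumor_cohort(config: SynthConfig) -> list[TumorSeries]:
    """Simulate the four-arm xenograft cohort.

    Per animal: starting volume V0 from a normal truncated at > 0, then
    V(t) = V0*exp(r*t)*(1 + eps_t) with eps_t ~ N(0, invivo_noise_sd)
    (truncated above -0.9 so volumes stay positive).  Calipers are
    back-derived at the fixed length = aspect_ratio * width, so
    (pi/6)*w^2*l reproduces V(t) exactly.
    """
    days = np.asarray(config.invivo_days, dtype=float)
    series = []
    for group, params in config.invivo.items():
        rng = config.rng(f"invivo:{group}")
        for i in range(config.n_animals):
            v0 = 0.0
            while v0 <= 0:
                v0 = rng.normal(params.v0_mean, params.v0_sd)
            eps = rng.normal(0.0, config.invivo_noise_sd, size=days.size)
            eps = np.maximum(eps, -0.9)
            volumes = v0 * np.exp(params.rate_per_day * days) * (1.0 + eps)
            # V = (pi/6) w^2 (a*w)  =>  w = (6V / (pi*a))^(1/3)
            widths = (6.0 * volumes / (np.pi * config.aspect_ratio)) ** (1.0 / 3.0)
            lengths = config.aspect_ratio * widths
            series.append(
                TumorSeries(
                    animal_id=f"{group}-{i + 1:02d}",
                    group=group,
                    days=days,
                    widths=widths,
                    lengths=lengths,
                )
            )
    return series
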