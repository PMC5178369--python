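"""CSV readers and writers for the three data dialects.

Formats (all plain CSV with a header row, doses in µM, lengths in mm):

* single-agent viability: ``agent,scheme,dose_uM,replicate,viability_pct``
* combination records:   ``d1_uM,d2_uM,control_growth_pct`` with optional
  ``scheme,replicate,dx1_uM,dx2_uM,ci_printed,interaction_printed``
  (the dx/printed columns enable replication of a published CI table)
* longitudinal calipers: ``animal_id,group,day,width_mm,length_mm``
  with optional ``body_weight_g``

Writers emit full-precision floats; every writer's output round-trips
through the corresponding reader without loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .dose_response import MedianEffectFit, ViabilityTable
from .invivo import GrowthSummary, TumorSeries
from .synthetic import AgentParams, GroupParams, SynthConfig

__all__ = [
    "read_viability_csv",
    "write_viability_csv",
    "read_combination_csv",
    "write_combination_csv",
    "read_tumor_csv",
    "write_tumor_csv",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
    "summaries_to_frame",
    "write_group_summary_csv",
    "load_synth_config",
]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line "
                f"{int(bad[0]) + 2}: {df.loc[bad[0], col]!r}"
            )
        if parsed.isna().any():
            line = int(parsed.index[parsed.isna()][0]) + 2
            raise ValueError(f"{path}: empty value in column {col!r} at line {line}")
        df[col] = parsed
    return df


def read_viability_csv(path) -> list[ViabilityTable]:
    """Read single-agent viability wells, one table per (agent, scheme)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["agent", "scheme", "dose_uM", "viability_pct"], path)
    df = _check_numeric(df, ["dose_uM", "viability_pct"], path)
    tables = []
    for (agent, scheme), sub in df.groupby(["agent", "scheme"], sort=True):
        rep = sub["replicate"].to_numpy() if "replicate" in sub.columns else None
        tables.append(
            ViabilityTable(
                agent=str(agent),
                scheme=str(scheme),
                doses=sub["dose_uM"].to_numpy(),
                viability_pct=sub["viability_pct"].to_numpy(),
                replicate=rep,
            )
        )
    return tables


def write_viability_csv(tables: list[ViabilityTable], path) -> None:
    frames = []
    for t in tables:
        frames.append(
            pd.DataFrame(
                {
                    "agent": t.agent,
                    "scheme": t.scheme,
                    "dose_uM": t.doses,
                    "replicate": t.replicate
                    if t.replicate is not None
                    else np.zeros(t.doses.size, dtype=int),
                    "viability_pct": t.viability_pct,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_combination_csv(path) -> pd.DataFrame:
    """Read combination records; tolerates an empty (header-only) file."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["d1_uM", "d2_uM", "control_growth_pct"], path)
    numeric = ["d1_uM", "d2_uM", "control_growth_pct"]
    for opt in ("dx1_uM", "dx2_uM", "ci_printed"):
        if opt in df.columns:
            numeric.append(opt)
    if len(df):
        df = _check_numeric(df, numeric, path)
    return df


def write_combination_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_tumor_csv(path) -> list[TumorSeries]:
    """Read long-format caliper measurements into per-animal series.

    Rows are sorted by day within each animal; the group label must be
    constant per animal.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["animal_id", "group", "day", "width_mm", "length_mm"], path)
    numeric = ["day", "width_mm", "length_mm"]
    if "body_weight_g" in df.columns:
        numeric.append("body_weight_g")
    df = _check_numeric(df, numeric, path)
    series = []
    for animal, sub in df.groupby("animal_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) > 1:
            raise ValueError(
                f"{path}: animal {animal!r} appears in several groups: "
                f"{sorted(map(str, groups))}"
            )
        sub = sub.sort_values("day", kind="stable")
        series.append(
            TumorSeries(
                animal_id=str(animal),
                group=str(groups[0]),
                days=sub["day"].to_numpy(),
                widths=sub["width_mm"].to_numpy(),
                lengths=sub["length_mm"].to_numpy(),
                body_weights=sub["body_weight_g"].to_numpy()
                if "body_weight_g" in sub.columns
                else None,
            )
        )
    return series


def write_tumor_csv(series: list[TumorSeries], path) -> None:
    frames = []
    for s in series:
        frame = pd.DataFrame(
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "day": s.days,
                "width_mm": s.widths,
                "length_mm": s.lengths,
            }
        )
        if s.body_weights is not None:
            frame["body_weight_g"] = s.body_weights
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fits_to_frame(fits: list[MedianEffectFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "agent": f.agent,
                "scheme": f.scheme,
                "Dm_uM": f.dm,
                "m": f.m,
                "r2": f.r2,
                "n_points": f.n_points,
                "non_inhibitor": f.non_inhibitor,
            }
            for f in fits
        ]
    )


def write_fits_csv(fits: list[MedianEffectFit], path) -> None:
    fits_to_frame(fits).to_csv(path, index=False)


def read_fits_csv(path) -> list[MedianEffectFit]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["agent", "scheme", "Dm_uM", "m"], path)
    return [
        MedianEffectFit(
            dm=float(row["Dm_uM"]),
            m=float(row["m"]),
            r2=float(row.get("r2", float("nan"))),
            n_points=int(row.get("n_points", 0)),
            agent=str(row["agent"]),
            scheme=str(row["scheme"]),
            non_inhibitor=bool(row.get("non_inhibitor", False)),
        )
        for _, row in df.iterrows()
    ]


def summaries_to_frame(summaries: list[GrowthSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": s.group,
                "n": s.n,
                "initial_volume_mean_mm3": s.initial_volume_mean,
                "initial_volume_sd_mm3": s.initial_volume_sd,
                "final_volume_mean_mm3": s.final_volume_mean,
                "final_volume_sd_mm3": s.final_volume_sd,
                "cdt_mean_days": s.cdt_mean,
                "cdt_sd_days": s.cdt_sd,
                "n_shrinking": s.n_shrinking,
            }
            for s in summaries
        ]
    )


def write_group_summary_csv(summaries: list[GrowthSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def load_synth_config(path) -> SynthConfig:
    """Build a :class:`SynthConfig` from a YAML/JSON mapping.

    Any omitted key keeps its default; ``agents`` maps agent name to
    ``{dm, m}`` and ``invivo`` maps group name to
    ``{rate_per_day, v0_mean, v0_sd}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "seed",
        "noise_sd_pct",
        "scheme_interaction",
        "n_replicates",
        "invivo_noise_sd",
        "n_animals",
        "aspect_ratio",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "agents" in raw:
        kwargs["agents"] = {
            name: AgentParams(**spec) for name, spec in raw["agents"].items()
        }
    if "doses" in raw:
        kwargs["doses"] = {k: tuple(v) for k, v in raw["doses"].items()}
    if "combo_doses" in raw:
        kwargs["combo_doses"] = tuple(tuple(p) for p in raw["combo_doses"])
    if "combo_agents" in raw:
        kwargs["combo_agents"] = tuple(raw["combo_agents"])
    if "invivo" in raw:
        kwargs["invivo"] = {
            name: GroupParams(**spec) for name, spec in raw["invivo"].items()
        }
    if "invivo_days" in raw:
        kwargs["invivo_days"] = tuple(raw["invivo_days"])
    return SynthConfig(**kwargs)
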