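"""End-to-end orchestration: fit -> combine -> classify -> report.

Two entry points mirror the two experiments.  :func:`run_invitro` fits the
median-effect model to each single-agent table, scores every combination
record with the combination index, classifies the interaction, and writes
a CI summary table plus isobologram coordinates.  :func:`run_invivo`
derives caliper volumes and the per-group growth summary (initial/final
volume and cell doubling time).

Reports carry full-precision values plus a ``ci_1dp`` column rounded the
way CI tables are printed (one decimal) for direct comparison.  Given the
same inputs the outputs are byte-identical across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dcio
from .combination import (
    EffectRangeError,
    classify_interaction,
    combination_index,
    derive_equieffective_doses,
    place_on_isobologram,
    round_half_up,
)
from .dose_response import FitError, MedianEffectFit, fit_median_effect
from .invivo import summarize_groups

__all__ = ["run_invitro", "run_invivo", "score_combination_frame"]

log = logging.getLogger(__name__)


def _fit_tables(tables) -> list[MedianEffectFit]:
    fits = []
    for table in tables:
        try:
            fits.append(fit_median_effect(table))
        except FitError as exc:
            log.warning("skipping unfittable table %s/%s: %s",
                        table.agent, table.scheme, exc)
    if not fits:
        raise FitError("no single-agent table could be fitted")
    return fits


def _fit_lookup(fits: list[MedianEffectFit]) -> dict[str, MedianEffectFit]:
    # prefer the single-agent scheme when an agent was fitted under several
    lookup: dict[str, MedianEffectFit] = {}
    for f in fits:
        if f.agent not in lookup or f.scheme == "single":
            lookup[f.agent] = f
    return lookup


def score_combination_frame(
    combos: pd.DataFrame,
    fit1: MedianEffectFit | None,
    fit2: MedianEffectFit | None,
    *,
    alpha: int = 1,
    decimals: int = 1,
    tol: float | None = None,
    average_replicates: bool = True,
) -> pd.DataFrame:
    """Score combination records into a CI summary table.

    Equieffective doses come from ``dx1_uM``/``dx2_uM`` columns when
    present (replication mode), otherwise from the two median-effect fits
    and the observed control growth (pipeline mode).  Replicate wells of
    one (scheme, D1, D2) cell are averaged to a single record first, as CI
    tables report mean control growth.  Records whose combined effect is
    exactly 0% or 100% are flagged and left unscored; when a published CI
    (``ci_printed``) disagrees with the computed one at the printed
    precision the row is flagged ``printed_ci_mismatch``.
    """
    df = combos.copy()
    if df.empty:
        return pd.DataFrame(
            columns=[
                "scheme", "d1_uM", "d2_uM", "dx1_uM", "dx2_uM",
                "control_growth_pct", "alpha", "ci", "ci_1dp",
                "interaction", "flags",
            ]
        )
    if "scheme" not in df.columns:
        df["scheme"] = "single"
    replication = "dx1_uM" in df.columns and "dx2_uM" in df.columns
    if average_replicates and not replication and "replicate" in df.columns:
        df = (
            df.groupby(["scheme", "d1_uM", "d2_uM"], as_index=False, sort=True)
            .agg(control_growth_pct=("control_growth_pct", "mean"))
        )
    rows = []
    for idx, rec in df.iterrows():
        flags: list[str] = []
        d1, d2 = float(rec["d1_uM"]), float(rec["d2_uM"])
        growth = float(rec["control_growth_pct"])
        if replication:
            dx1, dx2 = float(rec["dx1_uM"]), float(rec["dx2_uM"])
        else:
            if fit1 is None or fit2 is None:
                raise ValueError(
                    "combination records lack dx columns and no fitted "
                    "single-agent models are available"
                )
            try:
                dx1, dx2 = derive_equieffective_doses(d1, d2, growth, fit1, fit2)
            except EffectRangeError as exc:
                log.warning("record %s excluded: %s", idx, exc)
                rows.append(
                    {
                        "scheme": rec["scheme"], "d1_uM": d1, "d2_uM": d2,
                        "dx1_uM": np.nan, "dx2_uM": np.nan,
                        "control_growth_pct": growth, "alpha": alpha,
                        "ci": np.nan, "ci_1dp": np.nan, "interaction": "",
                        "flags": "effect_out_of_range",
                    }
                )
                continue
        ci = combination_index(d1, d2, dx1, dx2, alpha=alpha)
        call = classify_interaction(ci, decimals=decimals, tol=tol)
        ci_1dp = round_half_up(ci, decimals)
        if "ci_printed" in rec.index and pd.notna(rec.get("ci_printed")):
            if ci_1dp != float(rec["ci_printed"]):
                flags.append("printed_ci_mismatch")
                log.warning(
                    "record %s: computed CI %.3f (prints as %.1f) differs "
                    "from published %.1f",
                    idx, ci, ci_1dp, float(rec["ci_printed"]),
                )
        rows.append(
            {
                "scheme": rec["scheme"], "d1_uM": d1, "d2_uM": d2,
                "dx1_uM": dx1, "dx2_uM": dx2,
                "control_growth_pct": growth, "alpha": alpha,
                "ci": float(ci), "ci_1dp": ci_1dp, "interaction": call,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def run_invitro(
    single_csv,
    combo_csv,
    out_dir,
    *,
    alpha: int = 1,
    decimals: int = 1,
    tol: float | None = None,
    agent_pair: tuple[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full in vitro analysis: fits, CI table, isobologram coordinates.

    ``agent_pair`` names (drug 1, drug 2) of the combination; by default
    the first two fitted agents in file order.  Writes ``fits.csv``,
    ``ci_table.csv`` and ``isobologram.csv`` under ``out_dir`` and returns
    the three frames.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = dcio.read_viability_csv(single_csv)
    fits = _fit_tables(tables)
    lookup = _fit_lookup(fits)
    if agent_pair is None:
        agent_pair = tuple(lookup)[:2]  # type: ignore[assignment]
    fit1 = lookup.get(agent_pair[0]) if agent_pair else None
    fit2 = lookup.get(agent_pair[1]) if len(agent_pair) > 1 else None

    combos = dcio.read_combination_csv(combo_csv)
    if combos.empty:
        log.warning("%s: no combination records; CI table will be empty",
                    combo_csv)
    ci_table = score_combination_frame(
        combos, fit1, fit2, alpha=alpha, decimals=decimals, tol=tol
    )

    iso_rows = []
    if fit1 is not None and fit2 is not None:
        for _, rec in ci_table.iterrows():
            if not np.isfinite(rec.get("ci", np.nan)):
                continue
            pt = place_on_isobologram(
                rec["d1_uM"], rec["d2_uM"], fit1.dm, fit2.dm
            )
            iso_rows.append(
                {
                    "scheme": rec["scheme"],
                    "d1_uM": rec["d1_uM"],
                    "d2_uM": rec["d2_uM"],
                    "x": pt.x,
                    "y": pt.y,
                    "position": pt.position,
                }
            )
    isobologram = pd.DataFrame(
        iso_rows, columns=["scheme", "d1_uM", "d2_uM", "x", "y", "position"]
    )

    fits_frame = dcio.fits_to_frame(fits)
    dcio.write_fits_csv(fits, out / "fits.csv")
    ci_table.to_csv(out / "ci_table.csv", index=False)
    isobologram.to_csv(out / "isobologram.csv", index=False)
    return {"fits": fits_frame, "ci_table": ci_table, "isobologram": isobologram}


def run_invivo(
    tumor_csv,
    out_dir,
    *,
    window: tuple[float, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full in vivo analysis: volume trajectories and group summary.

    Animals with fewer than two measurements cannot contribute a doubling
    time and are excluded with a warning.  Writes ``volumes.csv`` and
    ``group_summary.csv`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = dcio.read_tumor_csv(tumor_csv)
    usable = []
    for s in series:
        if s.days.size < 2:
            log.warning("animal %s excluded: fewer than two measurements",
                        s.animal_id)
            continue
        usable.append(s)
    if not usable:
        raise ValueError(f"{tumor_csv}: no animal has two or more measurements")

    vol_frames = []
    for s in usable:
        vol_frames.append(
            pd.DataFrame(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "day": s.days,
                    "width_mm": s.widths,
                    "length_mm": s.lengths,
                    "volume_mm3": s.volumes,
                }
            )
        )
    volumes = pd.concat(vol_frames, ignore_index=True)
    summaries = summarize_groups(usable, treatment_window=window)
    summary_frame = dcio.summaries_to_frame(summaries)

    volumes.to_csv(out / "volumes.csv", index=False)
    dcio.write_group_summary_csv(summaries, out / "group_summary.csv")
    return {"volumes": volumes, "group_summary": summary_frame}
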