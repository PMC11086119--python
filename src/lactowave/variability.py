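"""Staged dispersion analysis of longitudinal dielectric fits.

Cows with a successful artificial insemination (AI) are partitioned into
three reproductive stages — pre-insemination ("stage1"), the first fifteen
days of pregnancy ("stage2"), and established pregnancy from day 16 on
("stage3") — while cows whose AI failed are split into "before" and
"after" at the (first failed) insemination day.  Day counting starts at 1
the day after insemination; for a failed AI the insemination day itself
belongs to "after".

The headline statistic is the percent drop in the sample SD of a fitted
parameter between a reference stage and a comparison stage, by default
stage1 vs stage3 for pregnant cows and before vs after for the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DomainError

__all__ = [
    "StageSummary",
    "LabelingError",
    "PREGNANT_STAGES",
    "NONPREGNANT_STAGES",
    "DEFAULT_PAIRINGS",
    "assign_stage",
    "assign_stages",
    "stage_dispersion",
    "percent_drop",
    "drop_report",
]

PREGNANT_STAGES = ("stage1", "stage2", "stage3")
NONPREGNANT_STAGES = ("before", "after")
_ORDER = PREGNANT_STAGES + NONPREGNANT_STAGES

#: Default reference/comparison stage pairs of the drop statistic.
DEFAULT_PAIRINGS = {
    "pregnant": ("stage1", "stage3"),
    "nonpregnant": ("before", "after"),
}


class LabelingError(ValueError):
    """A record cannot be assigned a reproductive stage."""


@dataclass
class StageSummary:
    """Per-stage dispersion of one fitted parameter."""

    stage: str
    parameter: str
    n_points: int
    mean: float
    sd: float | None  # None when n_points < 2 (SD undefined, not zero)


def _dsi(record: Mapping) -> float:
    dsi = record.get("days_since_insemination")
    if dsi is not None and not (isinstance(dsi, float) and math.isnan(dsi)):
        return float(dsi)
    day = record.get("day")
    ai = record.get("insemination_day")
    if ai is None or (isinstance(ai, float) and math.isnan(ai)):
        return float("nan")
    return float(day) - float(ai)


def assign_stage(record: Mapping) -> str:
    """Reproductive-stage label of one cohort record.

    Pregnant-outcome cows map to stage1/stage2/stage3 by days since the
    successful insemination (stage2 spans days 1–15 inclusive); cows with a
    failed AI map to before/after, the AI day itself counting as after.
    A record with no insemination day resolves to stage1/"before" only if
    that is unambiguous; a pregnant record without one is an error.
    """
    pregnant = bool(record["pregnant_outcome"])
    dsi = _dsi(record)
    if math.isnan(dsi):
        if pregnant:
            raise LabelingError(
                "pregnant-outcome record lacks an insemination day / "
                "days_since_insemination"
            )
        return "before"
    if pregnant:
        if dsi <= 0:
            return "stage1"
        return "stage2" if dsi <= 15 else "stage3"
    return "before" if dsi < 0 else "after"


def assign_stages(table: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`assign_stage` over a cohort table."""
    return pd.Series(
        [assign_stage(row) for row in table.to_dict("records")],
        index=table.index, name="stage",
    )


def stage_dispersion(
    table: pd.DataFrame,
    parameters: Sequence[str] = ("delta_eps", "tau", "alpha", "sigma_dc"),
    stage_column: str | None = None,
) -> list[StageSummary]:
    """Sample SD (and mean) of fitted parameters per reproductive stage.

    Stages are taken from ``stage_column`` if given, otherwise derived with
    :func:`assign_stage`.  A stage with fewer than two points gets
    ``sd=None`` rather than a misleading zero.  Summaries come back in
    canonical stage order.
    """
    stages = table[stage_column] if stage_column else assign_stages(table)
    out: list[StageSummary] = []
    present = [s for s in _ORDER if (stages == s).any()]
    for stage in present:
        sel = table.loc[stages == stage]
        for p in parameters:
            vals = sel[p].to_numpy(dtype=float)
            n = vals.size
            out.append(StageSummary(
                stage=stage, parameter=p, n_points=n,
                mean=float(vals.mean()) if n else float("nan"),
                sd=float(vals.std(ddof=1)) if n >= 2 else None,
            ))
    return out


def percent_drop(sd_reference: float, sd_comparison: float) -> float:
    """Percent reduction in SD from a reference stage to a comparison stage.

    ``100 * (sd_ref - sd_cmp) / sd_ref``; negative when variability rose.
    """
    if not (math.isfinite(sd_reference) and sd_reference > 0):
        raise DomainError(
            f"percent drop undefined for reference SD {sd_reference!r}"
        )
    return 100.0 * (sd_reference - sd_comparison) / sd_reference


def drop_report(
    table: pd.DataFrame,
    parameters: Sequence[str] = ("delta_eps", "tau", "alpha", "sigma_dc"),
    pairing: tuple[str, str] | None = None,
    stage_column: str | None = None,
) -> dict:
    """Drop statistics for every parameter over one stage pairing.

    The pairing defaults to stage1-vs-stage3 when pregnant stages are
    present in the table, else before-vs-after.
    """
    summaries = stage_dispersion(table, parameters, stage_column)
    stages_present = {s.stage for s in summaries}
    if pairing is None:
        pairing = (DEFAULT_PAIRINGS["pregnant"]
                   if stages_present & set(PREGNANT_STAGES)
                   else DEFAULT_PAIRINGS["nonpregnant"])
    ref_stage, cmp_stage = pairing
    by_key = {(s.stage, s.parameter): s for s in summaries}
    report: dict = {"pairing": list(pairing), "drops_pct": {}, "stage_sd": {}}
    for p in parameters:
        ref = by_key.get((ref_stage, p))
        cmp_ = by_key.get((cmp_stage, p))
        report["stage_sd"][p] = {
            s.stage: s.sd for s in summaries if s.parameter == p
        }
        if ref is None or cmp_ is None or ref.sd is None or cmp_.sd is None:
            report["drops_pct"][p] = None
        else:
            report["drops_pct"][p] = percent_drop(ref.sd, cmp_.sd)
    return report
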