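"""Dose-response growth/viability summaries, toxicity calls, optimal
dose selection, and growth-curve endpoint comparisons.

Per dose, percent growth is the treated mean cell count relative to
the vehicle mean; percent inhibition is its complement; percent
viability is the dead-negative fraction of all cells. A dose is toxic
when its per-well dead fraction is significantly *greater* than the
vehicle's (one-sided test) — the screen's goal being proliferation
delay without overt cell death. The optimal dose is the greatest
inhibition among significant, non-toxic doses.

Wherever a two-sample t-test is called for, Welch's unequal-variance
form is the default (count data rarely share variances across doses);
``equal_var=True`` restores the pooled-variance Student form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseSummary",
    "GrowthCurve",
    "summarize_dose",
    "summarize_plate",
    "optimal_dose",
    "compare_growth_curves",
]


@dataclass(frozen=True)
class DoseSummary:
    """Per-dose quantification of one compound."""

    compound: str
    dose: float
    percent_growth: float
    percent_inhibition: float
    percent_viability: float
    growth_p: float
    death_p: float
    toxic: bool
    n_treated: int
    n_vehicle: int


def _safe_p(p: float) -> float:
    # identical degenerate samples give nan; treat as "no evidence"
    return 1.0 if (p is None or math.isnan(p)) else float(p)


def summarize_dose(
    treated: pd.DataFrame,
    vehicle: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
    compound: str = "",
    dose: float = float("nan"),
) -> DoseSummary:
    """Summarize one treatment group against the vehicle controls.

    ``treated`` and ``vehicle`` need columns ``total`` and ``dead``
    with at least 2 replicate wells each. Raises on fewer replicates
    or a zero vehicle mean.
    """
    for name, df in (("treated", treated), ("vehicle", vehicle)):
        if len(df) < 2:
            raise ValueError(f"{name} group needs >= 2 replicate wells")
        if (df["dead"] > df["total"]).any() or (df["dead"] < 0).any():
            raise ValueError(f"{name} group has dead counts outside [0, total]")
    t_tot = treated["total"].to_numpy(float)
    v_tot = vehicle["total"].to_numpy(float)
    if v_tot.mean() <= 0:
        raise ValueError("vehicle mean cell count is zero")

    percent_growth = 100.0 * t_tot.mean() / v_tot.mean()
    live = (treated["total"] - treated["dead"]).to_numpy(float)
    viability = 100.0 * live.mean() / t_tot.mean() if t_tot.mean() > 0 else 100.0

    growth_p = _safe_p(stats.ttest_ind(t_tot, v_tot, equal_var=equal_var).pvalue)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_frac = np.where(t_tot > 0, treated["dead"].to_numpy(float) / t_tot, 0.0)
        v_frac = np.where(v_tot > 0, vehicle["dead"].to_numpy(float) / v_tot, 0.0)
    death_p = _safe_p(
        stats.ttest_ind(t_frac, v_frac, equal_var=equal_var,
                        alternative="greater").pvalue)

    return DoseSummary(
        compound=compound, dose=dose,
        percent_growth=percent_growth,
        percent_inhibition=100.0 - percent_growth,
        percent_viability=viability,
        growth_p=growth_p, death_p=death_p,
        toxic=death_p < alpha,
        n_treated=len(treated), n_vehicle=len(vehicle),
    )


def summarize_plate(
    plate: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
    vehicle_dose: float = 0.0,
) -> list[DoseSummary]:
    """Summarize every (compound, dose) group of a long-format plate.

    Vehicle wells are the rows at ``vehicle_dose`` (shared across
    compounds if labelled with each compound, or labelled "vehicle").
    """
    summaries: list[DoseSummary] = []
    for compound, group in plate.groupby("compound", sort=True):
        vehicle = group[group["dose"] == vehicle_dose]
        if vehicle.empty:
            vehicle = plate[(plate["dose"] == vehicle_dose)]
        if vehicle.empty:
            raise ValueError(f"no vehicle wells (dose={vehicle_dose}) for {compound}")
        for dose, wells in group[group["dose"] != vehicle_dose].groupby("dose"):
            summaries.append(summarize_dose(
                wells, vehicle, alpha=alpha, equal_var=equal_var,
                compound=str(compound), dose=float(dose),
            ))
    return summaries


def optimal_dose(
    summaries: Sequence[DoseSummary],
    alpha: float = 0.05,
) -> float | None:
    """Greatest inhibition among significant, non-toxic doses.

    A dose qualifies when it is not toxic and its growth reduction is
    significant (growth_p < alpha). Ties favour the lower dose. When
    nothing qualifies, returns None with a warning — an optimal dose is
    never a toxic one.
    """
    qualifying = [s for s in summaries if not s.toxic and s.growth_p < alpha]
    if not qualifying:
        warnings.warn("no dose qualifies (all toxic or non-significant)",
                      stacklevel=2)
        return None
    best = max(qualifying, key=lambda s: (s.percent_inhibition, -s.dose))
    return best.dose


@dataclass(frozen=True)
class GrowthCurve:
    """Daily replicate counts for one culture condition."""

    condition: str
    counts: Mapping[int, Sequence[float]]  # day -> replicate counts

    def __post_init__(self) -> None:
        days = list(self.counts)
        if days != sorted(days):
            raise ValueError("days must be strictly increasing")
        for day, reps in self.counts.items():
            if any(c < 0 for c in reps):
                raise ValueError(f"negative count on day {day}")

    @property
    def final_day(self) -> int:
        return max(self.counts)


def compare_growth_curves(
    a: GrowthCurve,
    b: GrowthCurve,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> dict:
    """Two-sided endpoint t-test between two growth curves.

    The curves must share their final day and have >= 2 replicates
    each there. Returns means, p-value and a significance flag.
    """
    if a.final_day != b.final_day:
        raise ValueError(
            f"curves end on different days ({a.final_day} vs {b.final_day})")
    xa = np.asarray(a.counts[a.final_day], dtype=float)
    xb = np.asarray(b.counts[b.final_day], dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("endpoint comparison needs >= 2 replicates per curve")
    p = _safe_p(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
    return {
        "condition_a": a.condition, "condition_b": b.condition,
        "day": a.final_day,
        "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
        "p": p, "significant": p < alpha,
    }
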