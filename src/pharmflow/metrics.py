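"""Outcome metrics and scenario comparison tables.

A facility-day counts as a stockout day when the sampled facility stock
is below a small threshold (1e-9 packages) on the daily grid.  Unmet
demand totals, stock summaries and per-link shipped totals support
side-by-side comparison of intervention scenarios; the mean stock level
doubles as an expiry-risk proxy (stock held far above need risks
expiring before use).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Trajectory
from .simulator import resample

__all__ = [
    "STOCKOUT_THRESHOLD",
    "daily",
    "first_rise_day",
    "stockout_days",
    "stockout_days_between_arrivals",
    "scenario_report",
]

#: Facility stock at or below this many packages counts as stocked out.
STOCKOUT_THRESHOLD = 1e-9


def daily(traj: Trajectory) -> Trajectory:
    """The trajectory on the one-day grid (identity if already daily)."""
    if traj.spacing == 1.0:
        return traj
    if traj.spacing > 1.0:
        raise ValueError(f"trajectory spacing {traj.spacing} is coarser than one day")
    return resample(traj, 1.0)


def first_rise_day(traj: Trajectory, comp: str, tol: float = 1e-9) -> float | None:
    """First sampled day on which a stock strictly increases, else None."""
    y = traj.stock(comp)
    rises = np.nonzero(np.diff(y) > tol)[0]
    if len(rises) == 0:
        return None
    return float(traj.t[rises[0] + 1])


def stockout_days(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    threshold: float = STOCKOUT_THRESHOLD,
) -> int:
    """Whole days in the window whose sampled facility stock is below threshold."""
    d = daily(traj)
    lo, hi = window if window is not None else (d.t[0], d.t[-1])
    if lo < d.t[0] - 1e-9 or hi > d.t[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] outside trajectory span [{d.t[0]}, {d.t[-1]}]")
    mask = (d.t >= lo - 1e-9) & (d.t <= hi + 1e-9)
    return int(np.sum(d.Y_H[mask] <= threshold))


def stockout_days_between_arrivals(
    traj: Trajectory, threshold: float = STOCKOUT_THRESHOLD
) -> list[int]:
    """Stockout-day counts per inter-arrival interval at the facility.

    Intervals run between consecutive shipment arrivals on the W->H
    link (plus the leading and trailing partial intervals).  The
    between-shipments stockout period of a run is the max (or mean)
    over these counts.
    """
    d = daily(traj)
    arrivals = sorted(
        s.arrival_day for s in d.shipments if s.link == "WH" and s.arrival_day <= d.t[-1]
    )
    edges = [d.t[0]] + arrivals + [d.t[-1]]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo < 1.0:
            continue
        # half-open [lo, hi) so a day is never counted in two intervals
        mask = (d.t >= lo - 1e-9) & (d.t < hi - 1e-9)
        out.append(int(np.sum(d.Y_H[mask] <= threshold)))
    return out


def scenario_report(trajectories: dict[str, Trajectory]) -> pd.DataFrame:
    """One summary row per labeled scenario.

    Columns: stockout days, total unmet demand, min/mean/max facility
    stock, total shipped per link, and the mean total stock held (an
    expiry proxy).  All trajectories must share a horizon.
    """
    if not trajectories:
        raise ValueError("no trajectories to report on")
    horizons = {round(float(tr.t[-1]), 9) for tr in trajectories.values()}
    if len(horizons) > 1:
        raise ValueError(f"trajectories have mismatched horizons: {sorted(horizons)}")
    rows = []
    for label, tr in trajectories.items():
        between = stockout_days_between_arrivals(tr)
        rows.append(
            {
                "scenario": label,
                "stockout_days": stockout_days(tr),
                "max_stockout_between_shipments": max(between) if between else 0,
                "unmet_demand_pkgs": tr.total_unmet(),
                "min_Y_H": float(np.min(tr.Y_H)),
                "mean_Y_H": float(np.mean(tr.Y_H)),
                "max_Y_H": float(np.max(tr.Y_H)),
                "shipped_MP_pkgs": float(np.sum(tr.F_MP) * tr.spacing),
                "shipped_PW_pkgs": float(np.sum(tr.F_PW) * tr.spacing),
                "shipped_WH_pkgs": float(np.sum(tr.F_WH) * tr.spacing),
                "mean_total_stock": float(np.mean(tr.Y_P + tr.Y_W + tr.Y_H)),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
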