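"""Stock-and-flow integrator for the supply chain.

The tracked stocks obey a delayed flow balance:

    dY_P/dt = F_MP(t - tau_MP) - F_PW(t)
    dY_W/dt = F_PW(t - tau_PW) - F_WH(t)
    dY_H/dt = F_WH(t - tau_WH) - D(t)

where each F is the dispatch-side shipment flow on a link and D the
patient demand rate.  The delayed inflow terms are not state dependent,
so integration is ordinary quadrature on a fixed grid (first order,
default dt = 0.05 day) rather than a true delay-differential solve.
Gaussian pulse masses are assigned to steps by exact cell integrals
(erf differences), so a pulse's area is preserved however narrow B is
relative to dt; demand is withdrawn at the left-edge rate.

Conservation is structural: every step's actual outflow on a link is
buffered and delivered to the receiver exactly tau later, so whatever
leaves a sender arrives downstream (or is still in transit at the
horizon) to within float round-off, including when dispatches are
clipped against an empty sender.

Step semantics, in order, within each step (t_prev, t_now]:

1. controller decisions due by t_now are taken (using stocks at t_prev);
2. arrivals are credited (so a same-instant arrival prevents a spurious
   one-step stockout);
3. dispatches leave the senders — discrete events first, then Gaussian
   flow — floored at the available stock for P and W (M is unbounded);
4. demand is withdrawn from the facility stock, dispensing
   min(demand, stock) and logging the shortfall as unmet (lost, not
   backlogged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .demand import DemandModel, demand_rate, mean_demand_over_window
from .model import LINK_NAMES, LinkParams, ScenarioConfig, ShipmentRecord, Trajectory, validate_scenario
from .shipments import ShipmentPlan, pulse_train

__all__ = [
    "integrate",
    "resample",
    "mass_balance",
    "SteadyStateCheck",
    "check_steady_state_condition",
    "SenderStockError",
]

_CLIP_TOL = 1e-9


class SenderStockError(RuntimeError):
    """Raised in strict mode when a dispatch exceeds the sender's stock."""


def _event_step(day: float, dt: float, nsteps: int) -> int | None:
    """Step index k such that day falls in (t_{k-1}, t_k]; None if past horizon."""
    k = int(math.ceil(day / dt - 1e-9))
    if k < 1:
        k = 1
    return k if k <= nsteps else None


def integrate(cfg: ScenarioConfig, plans: dict[str, ShipmentPlan] | None = None, controller=None) -> Trajectory:
    """Run one simulation and return the sampled Trajectory.

    Parameters
    ----------
    cfg : ScenarioConfig
        Must pass :func:`validate_scenario`.
    plans : dict link-name -> ShipmentPlan, optional
        Open-loop dispatch plans.  Links without a plan (and without a
        controller) default to the link's periodic pulse train.
    controller : optional
        A feedback-controller hook driving its enabled links (see
        :mod:`pharmflow.controller`); those links ignore ``plans``.

    Raises
    ------
    ValueError
        If the scenario is invalid; controller exceptions propagate with
        the decision day attached.
    """
    violations = validate_scenario(cfg)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))

    dt = cfg.dt
    nsteps = int(round(cfg.horizon / dt))
    t = np.arange(nsteps + 1) * dt

    controlled = set()
    if controller is not None:
        controlled = set(controller.enabled_links())

    links = {name: cfg.link(name) for name in LINK_NAMES}
    tau_steps = {}
    for name, lk in links.items():
        ts = int(round(lk.tau / dt))
        if abs(lk.tau - ts * dt) > 1e-9:
            raise ValueError(f"tau_{name}={lk.tau} is not a multiple of dt={dt}")
        tau_steps[name] = ts

    # Per-link dispatch bookkeeping: precomputed Gaussian step amounts,
    # discrete events keyed by step, actual outflow buffer.
    gauss_amt = {name: np.zeros(nsteps + 1) for name in LINK_NAMES}
    events: dict[str, dict[int, list]] = {name: {} for name in LINK_NAMES}
    out_buf = {name: np.zeros(nsteps + 1) for name in LINK_NAMES}
    records: list[ShipmentRecord] = []
    clip_events: list[tuple[str, float, float]] = []

    def add_gaussian(name: str, ship, from_step: int = 1) -> None:
        # Exact per-step masses via erf differences: the pulse area is
        # preserved to the truncation tail however narrow B is vs dt.
        lo = max(from_step, _event_step(ship.dispatch_day - cfg.truncation_k * ship.B, dt, nsteps) or 1)
        hi_day = ship.dispatch_day + cfg.truncation_k * ship.B
        hi = min(nsteps, int(math.floor(hi_day / dt + 1e-9)) + 1)
        if lo > nsteps:
            return
        edges = np.arange(lo - 1, hi + 1) * dt
        cdf = erf((edges - ship.dispatch_day) / ship.B)
        gauss_amt[name][lo : hi + 1] += 0.5 * ship.size * np.diff(cdf)

    def add_shipment(name: str, ship, from_step: int = 1) -> ShipmentRecord:
        rec = ShipmentRecord(
            link=name,
            dispatch_day=ship.dispatch_day,
            arrival_day=ship.dispatch_day + links[name].tau,
            size=ship.size,
        )
        records.append(rec)
        if ship.B > 0:
            add_gaussian(name, ship, from_step)
        else:
            k = _event_step(ship.dispatch_day, dt, nsteps)
            if k is not None:
                events[name].setdefault(k, []).append([rec, ship.size])
        return rec

    for name, lk in links.items():
        if name in controlled:
            continue
        plan = plans.get(name) if plans else None
        if plan is None:
            plan = pulse_train(lk, cfg.horizon, truncation_k=cfg.truncation_k)
        for ship in plan.shipments:
            add_shipment(name, ship)

    stocks = {c: float(cfg.initial_stocks[c]) for c in ("P", "W", "H")}
    Y = {c: np.empty(nsteps + 1) for c in ("P", "W", "H")}
    for c in ("P", "W", "H"):
        Y[c][0] = stocks[c]
    D_arr = np.zeros(nsteps + 1)
    unmet = np.zeros(nsteps + 1)

    sender_of = {"MP": None, "PW": "P", "WH": "W"}
    dest_of = {"MP": "P", "PW": "W", "WH": "H"}

    for k in range(1, nsteps + 1):
        t_prev = t[k - 1]
        t_now = t[k]

        # 1. controller decisions due by t_now, using stocks at t_prev
        if controller is not None:
            for order in controller.poll(t_now, stocks):
                rec = add_shipment(order.link, order.shipment, from_step=k)
                order.record = rec
            controller.prune_arrivals(t_now)

        # 2. arrivals (credited before withdrawals)
        for name in LINK_NAMES:
            ka = k - tau_steps[name]
            if ka >= 1:
                stocks[dest_of[name]] += out_buf[name][ka]

        # 3. dispatches, senders floored at zero (discrete first)
        for name in LINK_NAMES:
            sender = sender_of[name]
            avail = math.inf if sender is None else stocks[sender]
            moved = 0.0
            for ev in events[name].get(k, ()):
                rec, size = ev
                actual = min(size, max(avail - moved, 0.0))
                if actual < size - _CLIP_TOL:
                    rec.clipped = True
                    clip_events.append((name, t_now, size - actual))
                    if cfg.strict_clipping:
                        raise SenderStockError(
                            f"link {name}: dispatch of {size} pkgs on day {rec.dispatch_day} "
                            f"exceeds sender stock {avail - moved:.6g}"
                        )
                    if controller is not None and name in controlled:
                        controller.note_dispatch(name, rec.dispatch_day, size, actual)
                        rec.size = actual
                moved += actual
            g = gauss_amt[name][k]
            if g > 0.0:
                actual = min(g, max(avail - moved, 0.0))
                if actual < g - _CLIP_TOL:
                    clip_events.append((name, t_now, g - actual))
                    if cfg.strict_clipping:
                        raise SenderStockError(
                            f"link {name}: flow of {g / dt:.6g} pkgs/day on day {t_prev:.6g} "
                            f"exceeds sender stock"
                        )
                moved += actual
            if sender is not None:
                stocks[sender] -= moved
                if stocks[sender] < 0.0:  # float guard
                    stocks[sender] = 0.0
            out_buf[name][k] = moved

        # 4. demand withdrawal at the facility
        want = demand_rate(cfg.demand, t_prev) * dt
        dispensed = min(want, stocks["H"])
        stocks["H"] -= dispensed
        D_arr[k] = want / dt
        unmet[k] = (want - dispensed) / dt

        for c in ("P", "W", "H"):
            Y[c][k] = stocks[c]

    in_transit = {}
    for name in LINK_NAMES:
        ts = tau_steps[name]
        delivered = out_buf[name][1 : nsteps + 1 - ts].sum() if ts > 0 else out_buf[name].sum()
        in_transit[name] = float(out_buf[name].sum() - delivered)

    traj = Trajectory(
        t=t,
        Y_P=Y["P"],
        Y_W=Y["W"],
        Y_H=Y["H"],
        F_MP=out_buf["MP"] / dt,
        F_PW=out_buf["PW"] / dt,
        F_WH=out_buf["WH"] / dt,
        D=D_arr,
        unmet=unmet,
        shipments=sorted(records, key=lambda r: (r.dispatch_day, r.link)),
        in_transit_end=in_transit,
        clip_events=clip_events,
        dt=dt,
    )
    traj.F_MP[0] = traj.F_PW[0] = traj.F_WH[0] = 0.0
    if cfg.sample_every > dt:
        traj = resample(traj, cfg.sample_every)
    return traj


def resample(traj: Trajectory, every: float) -> Trajectory:
    """Resample onto a coarser grid of spacing ``every`` days.

    Stocks (and demand snapshots at index 0) are point samples; flow
    series are window averages, so their integrals over the covered
    span match the fine grid exactly.  ``every`` must be a whole
    multiple of the trajectory's spacing; a trailing partial window is
    dropped.
    """
    sp = traj.spacing
    if every < sp - 1e-12:
        raise ValueError(f"resample interval {every} is finer than the trajectory spacing {sp}")
    stride = int(round(every / sp))
    if abs(every - stride * sp) > 1e-9:
        raise ValueError(f"resample interval {every} is not a multiple of the spacing {sp}")
    if stride == 1:
        return traj
    m = (len(traj.t) - 1) // stride
    idx = np.arange(m + 1) * stride

    def avg(series: np.ndarray) -> np.ndarray:
        out = np.zeros(m + 1)
        out[1:] = series[1 : m * stride + 1].reshape(m, stride).mean(axis=1)
        return out

    return Trajectory(
        t=traj.t[idx].copy(),
        Y_P=traj.Y_P[idx].copy(),
        Y_W=traj.Y_W[idx].copy(),
        Y_H=traj.Y_H[idx].copy(),
        F_MP=avg(traj.F_MP),
        F_PW=avg(traj.F_PW),
        F_WH=avg(traj.F_WH),
        D=avg(traj.D),
        unmet=avg(traj.unmet),
        shipments=list(traj.shipments),
        in_transit_end=dict(traj.in_transit_end),
        clip_events=list(traj.clip_events),
        dt=every,
    )


def mass_balance(traj: Trajectory) -> float:
    """Conservation residual of a run, in packages.

    residual = |initial stock + total dispatched by manufacturers
                - final stock - in transit at horizon - total dispensed|

    The integrator moves packages between ledgers without creating or
    destroying them, so the residual is float round-off (contract:
    <= 1e-6 of the manufacturer total, and exactly 0 up to accumulation
    error for discrete shipments with zero demand).
    """
    sp = traj.spacing
    initial = float(traj.Y_P[0] + traj.Y_W[0] + traj.Y_H[0])
    final = float(traj.Y_P[-1] + traj.Y_W[-1] + traj.Y_H[-1])
    dispatched_m = float(np.sum(traj.F_MP) * sp)
    dispensed = traj.total_dispensed()
    in_transit = float(sum(traj.in_transit_end.values()))
    return abs(initial + dispatched_m - final - in_transit - dispensed)


@dataclass
class SteadyStateCheck:
    """Both sides of the no-depletion balance for a link."""

    supply_rate: float  # A*B*sqrt(pi)/n, packages/day
    mean_demand: float  # average demand over [tau, tau + n]
    rel_diff: float
    holds: bool


def check_steady_state_condition(
    link: LinkParams, demand: DemandModel, tol: float = 1e-6
) -> SteadyStateCheck:
    """Check A*B*sqrt(pi)/n == mean demand over one delivery cycle.

    When the condition holds (constant demand), the facility stock
    undergoes a periodic variation over a constant level: each period's
    deliveries exactly replace one period of demand.  A surplus on the
    left accumulates stock (expiry risk); a deficit depletes it
    (stockouts).
    """
    if link.n <= 0:
        raise ValueError(f"link periodicity n must be > 0, got {link.n}")
    lhs = link.A * link.B * math.sqrt(math.pi) / link.n
    rhs = mean_demand_over_window(demand, link.tau, link.n)
    denom = max(abs(lhs), abs(rhs))
    rel = 0.0 if denom == 0 else abs(lhs - rhs) / denom
    return SteadyStateCheck(supply_rate=lhs, mean_demand=rhs, rel_diff=rel, holds=rel <= tol)
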