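"""Digital drug-tracking controller (order-up-to forecasting loops).

A digital tracking system gives each tier visibility of its stock, so
shipment sizes can be decided adaptively instead of being fixed.  For a
link with periodicity ``n``, transport time ``tau`` and lead time ``d``,
a shipment scheduled to leave on day ``s`` is sized on day ``s - d``.
It must carry the receiver through to the arrival of the *next*
shipment, on day ``s + n + tau``; that span, [s - d, s + n + tau], is
the forecasting window.

The controller projects the receiver's stock to the window end assuming
the demand rate observed on the decision day stays constant, counts
pipeline (ordered-but-unarrived) shipments arriving inside the window,
and orders up to the desired level L:

    order = max(0, L - predicted stock at window end)

A zero order produces no dispatch.  The projected stock is signed: a
negative projection is the accumulated shortfall the order must also
cover, which is what keeps the post-arrival stock at L under constant
demand.  (Physical stocks never go negative — the simulator dispenses
at most what is on hand — but flooring the *projection* at zero would
systematically undersize orders whenever a window's depletion exceeds
the current stock, and the desired-level floor could then never be
held; ``forecast_stock`` exposes the floored variant for comparison.)

Upstream tiers use the same rule with their own L and d.  Their outflow
is bursty (downstream orders), so the decision-day patient demand rate
serves as the depletion-rate proxy: in sustained operation every tier's
average throughput equals patient demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .demand import demand_rate
from .model import LINK_NAMES, LinkParams, ScenarioConfig, Trajectory, validate_scenario
from .shipments import Shipment

__all__ = [
    "DecisionRecord",
    "PipelineEntry",
    "ControllerState",
    "Order",
    "decision_schedule",
    "forecast_stock",
    "order_size",
    "FeedbackController",
    "run_closed_loop",
]

_TOL = 1e-9


@dataclass
class DecisionRecord:
    """One sizing decision on one link."""

    link: str
    decision_day: float
    dispatch_day: float
    window_start: float
    window_end: float
    current_stock: float
    pipeline: float
    predicted: float
    ordered: float
    clipped: bool = False


@dataclass
class PipelineEntry:
    """A shipment ordered but not yet arrived (in transit or pending)."""

    link: str
    dispatch_day: float
    arrival_day: float
    size: float


@dataclass
class ControllerState:
    """Pipeline ledgers and the full decision log of a closed-loop run."""

    pipeline: dict[str, list[PipelineEntry]] = field(default_factory=dict)
    decisions: list[DecisionRecord] = field(default_factory=list)

    def decisions_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "link": r.link,
                    "decision_day": r.decision_day,
                    "dispatch_day": r.dispatch_day,
                    "window_end": r.window_end,
                    "predicted_stock": r.predicted,
                    "ordered_size": r.ordered,
                    "clipped_flag": r.clipped,
                }
                for r in self.decisions
            ],
            columns=[
                "link",
                "decision_day",
                "dispatch_day",
                "window_end",
                "predicted_stock",
                "ordered_size",
                "clipped_flag",
            ],
        )


@dataclass
class Order:
    """A controller order handed to the integrator."""

    link: str
    shipment: Shipment
    record: object = None


def decision_schedule(link: LinkParams, d: float, horizon: float) -> list[tuple[float, float, float, float]]:
    """(decision day, dispatch day, window start, window end) per scheduled dispatch.

    Dispatches fall at r0, r0 + n, ... <= horizon; the decision is taken
    ``d`` days earlier and the window runs to the next shipment's
    arrival, dispatch + n + tau.
    """
    if d < 0 or d > link.n:
        raise ValueError(f"lead time d={d} must satisfy 0 <= d <= n={link.n}")
    out = []
    s = link.r0
    while s <= horizon + _TOL:
        out.append((s - d, s, s - d, s + link.n + link.tau))
        s += link.n
    return out


def forecast_stock(
    stock: float,
    pipeline_arrivals,
    rate: float,
    window: tuple[float, float],
    clip_negative: bool = False,
) -> float:
    """Project a stock to the window end at a constant demand rate.

    ``pipeline_arrivals`` is an iterable of (arrival day, size); only
    arrivals inside the window count.  With ``clip_negative`` the
    projection is floored at zero (a physical stock reading); the
    default signed projection carries the shortfall so order-up-to
    sizing can cover it.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"window end {end} must exceed start {start}")
    incoming = sum(size for day, size in pipeline_arrivals if start - _TOL <= day <= end + _TOL)
    predicted = stock + incoming - rate * (end - start)
    if clip_negative and predicted < 0.0:
        return 0.0
    return predicted


def order_size(predicted: float, L: float) -> float:
    """Order-up-to rule: max(0, L - predicted); zero means no shipment."""
    if L < 0:
        raise ValueError(f"desired level L must be >= 0, got {L}")
    return max(0.0, L - predicted)


class FeedbackController:
    """Engine hook running the forecasting loop on every enabled link."""

    def __init__(self, cfg: ScenarioConfig):
        if cfg.controller is None:
            raise ValueError("scenario has no controller block")
        self.cfg = cfg
        self.ctrl = cfg.controller
        self.state = ControllerState(pipeline={name: [] for name in LINK_NAMES})
        self._queue: list[tuple[float, str, float, float]] = []
        for name in LINK_NAMES:
            if not self.ctrl.is_enabled(name):
                continue
            dest, sender = name[1], name[0]
            if dest not in self.ctrl.L or sender not in self.ctrl.d:
                raise ValueError(f"controller enabled on {name} but L_{dest} or d_{sender} missing")
            link = cfg.link(name)
            sched = decision_schedule(link, self.ctrl.d[sender], cfg.horizon)
            if not sched:
                raise ValueError(f"controller enabled on link {name} but its schedule is empty")
            for dec, disp, _, wend in sched:
                self._queue.append((dec, name, disp, wend))
        if not self._queue:
            raise ValueError("controller has no enabled link")
        self._queue.sort()
        self._cursor = 0

    def enabled_links(self):
        return {name for name in LINK_NAMES if self.ctrl.is_enabled(name)}

    def poll(self, t_now: float, stocks: dict[str, float]) -> list[Order]:
        """Take every decision due by ``t_now``; return the non-zero orders."""
        orders: list[Order] = []
        while self._cursor < len(self._queue) and self._queue[self._cursor][0] <= t_now + _TOL:
            dec_day, name, dispatch_day, window_end = self._queue[self._cursor]
            self._cursor += 1
            link = self.cfg.link(name)
            dest = name[1]
            stock = stocks[dest]
            try:
                rate = demand_rate(self.cfg.demand, max(dec_day, 0.0))
            except Exception as exc:
                raise type(exc)(f"decision day {dec_day} on link {name}: {exc}") from exc
            pipe = self.state.pipeline[name] if self.ctrl.count_pipeline else []
            pipeline_in = [(e.arrival_day, e.size) for e in pipe]
            window = (dec_day, window_end)
            predicted = forecast_stock(stock, pipeline_in, rate, window)
            ordered = order_size(predicted, self.ctrl.L[dest])
            rec = DecisionRecord(
                link=name,
                decision_day=dec_day,
                dispatch_day=dispatch_day,
                window_start=dec_day,
                window_end=window_end,
                current_stock=stock,
                pipeline=sum(s for _, s in pipeline_in),
                predicted=predicted,
                ordered=ordered,
            )
            self.state.decisions.append(rec)
            if ordered > _TOL:
                B = 0.0 if self.ctrl.discrete_dispatch else link.B
                entry = PipelineEntry(
                    link=name,
                    dispatch_day=dispatch_day,
                    arrival_day=dispatch_day + link.tau,
                    size=ordered,
                )
                self.state.pipeline[name].append(entry)
                orders.append(Order(link=name, shipment=Shipment(dispatch_day, ordered, B)))
        return orders

    def note_dispatch(self, link: str, dispatch_day: float, requested: float, actual: float) -> None:
        """Record sender-stock clipping of an ordered shipment."""
        for entry in self.state.pipeline[link]:
            if abs(entry.dispatch_day - dispatch_day) < _TOL and abs(entry.size - requested) < _TOL:
                entry.size = actual
                break
        for rec in reversed(self.state.decisions):
            if rec.link == link and abs(rec.dispatch_day - dispatch_day) < _TOL:
                rec.clipped = True
                break

    def prune_arrivals(self, t_now: float) -> None:
        """Drop pipeline entries exactly when their arrival day is reached."""
        for name, entries in self.state.pipeline.items():
            self.state.pipeline[name] = [e for e in entries if e.arrival_day > t_now + _TOL]


def run_closed_loop(cfg: ScenarioConfig) -> tuple[Trajectory, ControllerState]:
    """Simulate with the forecasting controller driving its enabled links.

    Non-enabled links keep their open-loop pulse trains.  Returns the
    trajectory and the controller state (pipeline ledger at the horizon
    plus the full decision log).
    """
    from .simulator import integrate

    violations = validate_scenario(cfg)
    if violations:
        raise ValueError("invalid scenario: " + "; ".join(violations))
    if cfg.controller is None:
        raise ValueError("run_closed_loop requires cfg.controller")
    fc = FeedbackController(cfg)
    traj = integrate(cfg, controller=fc)
    return traj, fc.state
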