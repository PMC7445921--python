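"""Built-in study scenarios.

These fixtures reproduce the qualitative behaviors of the illustrative
low-income-country supply chain: an open-loop baseline whose fixed
schedule causes recurrent facility stockouts, its four intervention
variants, a digital-tracking (closed-loop) run under constant demand,
and a closed-loop run against a three-season demand year.

Shared chain geometry: transport times tau_MP = 60, tau_PW = 15,
tau_WH = 3 days; manufacturer shipments every 180 days.  Demand runs at
4 packages/day in the constant-demand scenarios.  The baseline's
facility-bound shipments carry 40 packages every 14 days against a
56-package-per-cycle need, which is what makes its stockouts recur.
"""

from __future__ import annotations

from .demand import DemandModel
from .interventions import apply_intervention
from .model import ControllerParams, LinkParams, ScenarioConfig

__all__ = ["FIXTURE_NAMES", "baseline", "tracking", "seasonal", "interventions", "make_fixtures"]

FIXTURE_NAMES = ("baseline", "tracking", "seasonal", "interventions")


def baseline(horizon: float = 365.0, dt: float = 0.05) -> ScenarioConfig:
    """Open-loop chain with a fixed, undersized shipment schedule.

    All three tiers dispatch on day 120 (the manufacturers' shipment
    arriving day 180, the procurers' day 135), and the facility tier
    restocks every 14 days with shipments too small to cover demand, so
    stockouts recur between arrivals.
    """
    return ScenarioConfig(
        links=[
            # sizes via A*B*sqrt(pi): MP 720, PW 240, WH 40 pkgs
            LinkParams("M", "P", tau=60.0, n=180.0, A=81.2353, B=5.0, r0=120.0),
            LinkParams("P", "W", tau=15.0, n=60.0, A=45.1352, B=3.0, r0=120.0),
            LinkParams("W", "H", tau=3.0, n=14.0, A=11.2838, B=2.0, r0=8.0),
        ],
        demand=DemandModel.constant(4.0),
        initial_stocks={"P": 800.0, "W": 400.0, "H": 30.0},
        horizon=horizon,
        dt=dt,
    )


def tracking(
    horizon: float = 365.0,
    dt: float = 0.05,
    L_H: float = 10.0,
    demand_rate: float = 4.0,
) -> ScenarioConfig:
    """Closed-loop chain: the forecasting controller on every link.

    Constant demand; the facility link follows the worked-example
    pattern (n = 14, tau = 3, d = 2, first dispatch day 28).  Upstream
    stocks start ample so sender clipping never binds and the facility
    floor property can be observed cleanly.
    """
    return ScenarioConfig(
        links=[
            LinkParams("M", "P", tau=60.0, n=180.0, A=0.0, B=5.0, r0=40.0),
            LinkParams("P", "W", tau=15.0, n=28.0, A=0.0, B=3.0, r0=35.0),
            LinkParams("W", "H", tau=3.0, n=14.0, A=0.0, B=2.0, r0=28.0),
        ],
        demand=DemandModel.constant(demand_rate),
        initial_stocks={"P": 5000.0, "W": 2000.0, "H": 200.0},
        horizon=horizon,
        dt=dt,
        controller=ControllerParams(
            L={"P": 800.0, "W": 200.0, "H": L_H},
            d={"M": 10.0, "P": 5.0, "W": 2.0},
        ),
    )


def seasonal(horizon: float = 365.0, dt: float = 0.05) -> ScenarioConfig:
    """Closed loop against a three-season demand year.

    Low season at 2 pkgs/day until the high season starts on day 100
    (6 pkgs/day), easing to a moderate 4 pkgs/day from day 250.  The
    facility schedule is phased so a delivery lands exactly on day 100:
    the jump then sits inside exactly one forecasting window, producing
    the single below-target excursion that the next decision corrects.
    Warehouse and procurer stocks start high enough that their first
    controlled shipments are deferred well into the run.
    """
    return ScenarioConfig(
        links=[
            LinkParams("M", "P", tau=60.0, n=180.0, A=0.0, B=5.0, r0=30.0),
            LinkParams("P", "W", tau=15.0, n=60.0, A=0.0, B=3.0, r0=20.0),
            LinkParams("W", "H", tau=3.0, n=14.0, A=0.0, B=2.0, r0=13.0),
        ],
        demand=DemandModel.seasonal(
            [(0.0, 100.0, 2.0), (100.0, 250.0, 6.0), (250.0, horizon, 4.0)]
        ),
        initial_stocks={"P": 1500.0, "W": 600.0, "H": 60.0},
        horizon=horizon,
        dt=dt,
        controller=ControllerParams(
            L={"P": 500.0, "W": 150.0, "H": 10.0},
            d={"M": 10.0, "P": 5.0, "W": 2.0},
        ),
    )


def interventions(horizon: float = 365.0, dt: float = 0.05) -> dict[str, ScenarioConfig]:
    """The baseline plus one variant per intervention kind.

    Magnitudes are illustrative: prevention halves demand, roads halve
    transport times (with the 1.1 size accompaniment), workforce halves
    the shipment interval, vehicles double the pulse amplitudes.
    """
    base = baseline(horizon=horizon, dt=dt)
    return {
        "baseline": base,
        "prevention": apply_intervention(base, "prevention", factor=0.5),
        "roads": apply_intervention(base, "roads", tau_scale=0.5),
        "workforce": apply_intervention(base, "workforce", n_scale=0.5),
        "vehicles": apply_intervention(base, "vehicles", amplitude_scale=2.0),
    }


def make_fixtures(name: str, horizon: float = 365.0, dt: float = 0.05) -> dict[str, ScenarioConfig]:
    """Fixture scenarios by family name, as a {label: config} mapping."""
    if name == "baseline":
        return {"baseline": baseline(horizon, dt)}
    if name == "tracking":
        return {"tracking": tracking(horizon, dt)}
    if name == "seasonal":
        return {"seasonal": seasonal(horizon, dt)}
    if name == "interventions":
        return interventions(horizon, dt)
    raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
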