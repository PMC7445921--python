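"""Integrator: delay bookkeeping, conservation, periodicity, resampling."""

import math

import numpy as np
import pytest

from pharmflow import integrate, mass_balance, resample, scenarios
from pharmflow.demand import DemandModel
from pharmflow.metrics import first_rise_day
from pharmflow.model import LinkParams, ScenarioConfig
from pharmflow.shipments import Shipment, ShipmentPlan
from pharmflow.simulator import SenderStockError, check_steady_state_condition


def chain_cfg(
    demand=0.0,
    stocks=(0.0, 0.0, 0.0),
    horizon=250.0,
    dt=0.05,
    r0=(1000.0, 1000.0, 1000.0),
    wh=dict(tau=3.0, n=14.0, A=0.0, B=2.0),
    **kw,
):
    """A chain with idle schedules (r0 beyond horizon) unless overridden."""
    demand_model = demand if isinstance(demand, DemandModel) else DemandModel.constant(demand)
    return ScenarioConfig(
        links=[
            LinkParams("M", "P", tau=60.0, n=180.0, r0=r0[0]),
            LinkParams("P", "W", tau=15.0, n=60.0, r0=r0[1]),
            LinkParams("W", "H", r0=r0[2], **wh),
        ],
        demand=demand_model,
        initial_stocks={"P": stocks[0], "W": stocks[1], "H": stocks[2]},
        horizon=horizon,
        dt=dt,
        **kw,
    )


def test_no_flows_means_constant_stocks():
    traj = integrate(chain_cfg(stocks=(10.0, 20.0, 30.0)))
    for comp, val in zip("PWH", (10.0, 20.0, 30.0)):
        assert np.all(traj.stock(comp) == val)
    assert mass_balance(traj) == 0.0


@pytest.mark.parametrize(
    "link,comp,tau,rise_day",
    [("MP", "P", 60.0, 180.0), ("PW", "W", 15.0, 135.0)],
)
def test_transport_delay_sets_the_rise_day(link, comp, tau, rise_day):
    """A discrete shipment dispatched on day 120 lifts the receiver tau days later."""
    cfg = chain_cfg(stocks=(500.0, 500.0, 0.0))
    plans = {link: ShipmentPlan([Shipment(120.0, 100.0, 0.0)])}
    traj = integrate(cfg, plans=plans)
    assert first_rise_day(traj, comp) == rise_day
    rec = [s for s in traj.shipments if s.link == link][0]
    assert rec.arrival_day == rec.dispatch_day + tau


def test_shipment_log_arrivals_equal_dispatch_plus_tau(baseline_traj):
    taus = {"MP": 60.0, "PW": 15.0, "WH": 3.0}
    assert baseline_traj.shipments
    for rec in baseline_traj.shipments:
        assert rec.arrival_day == pytest.approx(rec.dispatch_day + taus[rec.link])


def test_stocks_never_negative_and_unmet_logged(baseline_traj):
    for comp in "PWH":
        assert np.all(baseline_traj.stock(comp) >= 0.0)
    # the baseline schedule undersupplies, so shortfall must be recorded
    assert baseline_traj.total_unmet() > 0.0


def test_mass_balance_on_fixture_runs(baseline_traj, tracking_run, seasonal_run):
    for traj in (baseline_traj, tracking_run[0], seasonal_run[0]):
        dispatched = float(np.sum(traj.F_MP) * traj.spacing)
        assert mass_balance(traj) <= max(1e-6 * dispatched, 1e-9)


def test_mass_balance_exact_for_discrete_run_with_zero_demand():
    cfg = chain_cfg(stocks=(1000.0, 0.0, 0.0))
    plans = {
        "MP": ShipmentPlan([Shipment(10.0, 200.0, 0.0)]),
        "PW": ShipmentPlan([Shipment(100.0, 300.0, 0.0)]),
        "WH": ShipmentPlan([Shipment(249.0, 150.0, 0.0)]),
    }
    traj = integrate(cfg, plans=plans)
    assert mass_balance(traj) <= 1e-9
    # the horizon catches the last shipment mid-transport (dispatch 249, tau 3)
    assert traj.in_transit_end == {"MP": 0.0, "PW": 0.0, "WH": 150.0}


def test_oversized_dispatch_is_clipped_and_logged():
    cfg = chain_cfg(stocks=(0.0, 80.0, 0.0))
    plans = {"WH": ShipmentPlan([Shipment(10.0, 200.0, 0.0)])}
    traj = integrate(cfg, plans=plans)
    rec = [s for s in traj.shipments if s.link == "WH"][0]
    assert rec.clipped
    assert traj.clip_events and traj.clip_events[0][0] == "WH"
    assert traj.Y_H[-1] == pytest.approx(80.0)  # receiver got what actually left
    assert mass_balance(traj) <= 1e-9


def test_strict_mode_raises_on_clipping():
    cfg = chain_cfg(stocks=(0.0, 80.0, 0.0), strict_clipping=True)
    plans = {"WH": ShipmentPlan([Shipment(10.0, 200.0, 0.0)])}
    with pytest.raises(SenderStockError, match="WH"):
        integrate(cfg, plans=plans)


# -- steady-state supply/demand balance ------------------------------


def balanced_wh_cfg(surplus=1.0, c=4.0, n=14.0, B=2.0, horizon=200.0):
    A = surplus * c * n / (B * math.sqrt(math.pi))
    return chain_cfg(
        demand=c,
        stocks=(0.0, 1e6, 100.0),
        horizon=horizon,
        r0=(1000.0, 1000.0, 10.0),
        wh=dict(tau=3.0, n=n, A=A, B=B),
    )


def test_steady_state_condition_check():
    cfg = balanced_wh_cfg()
    chk = check_steady_state_condition(cfg.link("WH"), cfg.demand)
    assert chk.holds and chk.supply_rate == pytest.approx(4.0, rel=1e-12)
    empty = check_steady_state_condition(
        LinkParams("W", "H", tau=3.0, n=14.0, A=0.0, B=2.0), DemandModel.constant(4.0)
    )
    assert not empty.holds and empty.supply_rate == 0.0


def test_balanced_supply_gives_periodic_facility_stock():
    """With A*B*sqrt(pi) = c*n, Y_H repeats every n days (within 1% of one shipment)."""
    cfg = balanced_wh_cfg()
    traj = integrate(cfg)
    period = int(round(cfg.link("WH").n / traj.spacing))
    after = traj.t >= 13.0 + 12.0  # first arrival plus one pulse support
    y = traj.Y_H[after]
    assert np.max(np.abs(y[period:] - y[:-period])) <= 0.01 * 56.0


def test_surplus_supply_accumulates_stock():
    """A 10% supply surplus makes period-over-period facility minima increase."""
    traj = integrate(balanced_wh_cfg(surplus=1.1))
    y = traj.Y_H[traj.t >= 25.0]
    per = int(round(14.0 / traj.spacing))
    minima = np.array([y[i * per : (i + 1) * per].min() for i in range(10)])
    assert np.all(np.diff(minima) > 0.0)


# -- resampling ------------------------------------------------------


def test_resample_identity_and_point_sampling():
    cfg = balanced_wh_cfg(horizon=60.0)
    fine = integrate(cfg)
    assert resample(fine, fine.spacing) is fine
    daily = resample(fine, 1.0)
    stride = int(round(1.0 / fine.spacing))
    assert np.array_equal(daily.Y_H, fine.Y_H[::stride][: len(daily.t)])
    with pytest.raises(ValueError):
        resample(daily, 0.5)


def test_resample_window_averages_preserve_flow_integrals():
    cfg = balanced_wh_cfg(horizon=60.0)
    fine = integrate(cfg)
    daily = resample(fine, 1.0)
    for name in ("F_WH", "D", "unmet"):
        fine_total = np.sum(getattr(fine, name)) * fine.spacing
        daily_total = np.sum(getattr(daily, name)) * daily.spacing
        assert daily_total == pytest.approx(fine_total, rel=1e-9, abs=1e-9)


# -- numerics --------------------------------------------------------


def test_step_halving_convergence():
    """Halving dt changes sampled stocks by a bound that itself halves
    (first-order contract; the dt truncation shows on time-varying demand)."""
    ramp = DemandModel.tabulated([0.0, 200.0], [0.0, 8.0])
    runs = {
        dt: integrate(chain_cfg(demand=ramp, stocks=(0.0, 0.0, 2000.0), horizon=200.0, dt=dt))
        for dt in (0.2, 0.1, 0.05)
    }
    d1 = np.max(np.abs(runs[0.2].Y_H - runs[0.1].Y_H))
    d2 = np.max(np.abs(runs[0.1].Y_H - runs[0.05].Y_H))
    assert d1 > 0.0
    assert d2 <= 0.6 * d1 + 1e-9


def test_gaussian_to_discrete_limit_is_monotone():
    """Narrowing B toward 0 converges to the discrete run, monotonically."""

    def run(B):
        cfg = chain_cfg(demand=2.0, stocks=(0.0, 1000.0, 60.0), horizon=120.0)
        plans = {"WH": ShipmentPlan([Shipment(20.5 + 14.0 * k, 40.0, B) for k in range(7)])}
        return integrate(cfg, plans=plans)

    ref = run(0.0)
    devs = []
    for B in (1.0, 0.5, 0.1, 0.05):
        tr = run(B)
        devs.append(float(np.max(np.abs(tr.Y_H - ref.Y_H) + np.abs(tr.Y_W - ref.Y_W))))
    assert all(a > b for a, b in zip(devs, devs[1:]))
    assert devs[-1] <= 0.01 * 40.0  # within 1% of one shipment size


def test_invalid_scenario_is_rejected():
    cfg = chain_cfg()
    cfg.dt = -1.0
    with pytest.raises(ValueError, match="dt"):
        integrate(cfg)
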