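# Methods

## Model

The supply chain is a three-compartment stock-and-flow system. Stocks
are tracked at procurers (`Y_P`), warehouses (`Y_W`) and health
facilities (`Y_H`), in packages; manufacturers are an unbounded source
and recipients a pure sink. Each link X→Y carries a shipment flow
`F_XY(t)` (packages/day) that leaves the sender at dispatch and reaches
the receiver a fixed transport time `τ_XY` later:

    dY_P/dt = F_MP(t − τ_MP) − F_PW(t)
    dY_W/dt = F_PW(t − τ_PW) − F_WH(t)
    dY_H/dt = F_WH(t − τ_WH) − D(t)

Assumptions: a single undifferentiated drug product; one aggregate
location per tier (no geographic structure); deterministic transport
(no loss or delay variability); demand withdrawn continuously as a
rate, not as discrete patient arrivals. Units are globally days,
packages, packages/day; `t = 0` is simulation start and all dispatch,
decision and first-peak times are absolute days.

Shipments are Gaussian pulses `F(t) = A·exp(−(t−r)²/B²)` with size
(area) `SS = A·B·√π`, repeated every `n` days from a first peak `r0`.
`B = 0` selects the discrete limit: an exact step transfer of `SS` at
dispatch, credited to the receiver at dispatch + τ. Per-shipment size
overrides (and all controller orders) rescale `A` at fixed `B`: pulse
duration is a property of the link's loading process, size a planning
decision.

## Numerical scheme

Because the delayed inflow terms are prescribed (not state-dependent),
integration is ordinary quadrature on a fixed grid, default
`dt = 0.05` day — first order in the state, not a delay-differential
solve. Within each step, in order:

1. controller decisions due in the step are taken, reading the stocks
   at the step start;
2. arrivals are credited (a same-instant arrival therefore prevents a
   spurious one-step stockout);
3. dispatches leave the senders — discrete events first, then Gaussian
   flow — floored at the available stock for P and W (the manufacturer
   is unbounded);
4. demand `D(t)·dt` is withdrawn at the facility, dispensing
   `min(demand, stock)`; the shortfall is logged as unmet demand.
   Unmet demand is *lost*, not backlogged; backlogging would be a
   straightforward extension but changes the recovery dynamics after
   stockouts.

Gaussian pulse mass is assigned to steps by exact cell integrals (erf
differences of the step edges), not by sampling the rate: the pulse
area is then preserved to the truncation tail however narrow `B` is
relative to `dt`, which is what makes the B→0 comparison against
discrete runs converge monotonically. Pulses are truncated at
`|t − r| > K·B` with `K = 6` (tail mass < 1e-15 of the size;
configurable via `truncation_k`), keeping shipments temporally local.
Overlapping pulses add — the balance is linear in contributions.

Conservation is structural: each step's *actual* outflow on a link is
buffered and delivered exactly `round(τ/dt)` steps later, so whatever
leaves a sender arrives downstream or is still in transit at the
horizon. The `mass_balance` residual (initial stock + manufacturer
dispatches − final stock − in-transit − dispensed) is therefore float
round-off (~1e-12) rather than a quadrature error budget. Transport
times must be multiples of `dt` (checked); with the default grid that
means multiples of 0.05 day.

A dispatch that exceeds the sender's stock is clipped to what is
available and logged — as a flagged shipment record for discrete
events, and as per-step suppressed flow for Gaussian pulses (whose
mass is spread over many steps, so clipping is necessarily
incremental). `strict_clipping` raises instead, for scenarios meant to
be feasibility-checked. Stocks are point samples on the output grid
(default `sample_every = 1` day); flow series are window averages, so
resampling preserves transported totals exactly. A stockout day is a
daily sample with `Y_H ≤ 1e-9` packages.

## Forecasting controller

For a link with periodicity `n`, transport time `τ` and lead time `d`,
the shipment leaving on day `s` is sized on day `s − d` to cover the
window `[s − d, s + n + τ]` — up to the *next* shipment's arrival. The
projection assumes the demand rate observed on the decision day holds
through the window (that is the information available at decision
time), adds pipeline shipments arriving inside the window, and orders
`max(0, L − projection)`; zero orders dispatch nothing.

Three design choices were genuinely open:

* **Signed projections.** The projection is not floored at zero: a
  negative value is the depletion shortfall the order must also cover.
  Flooring would systematically undersize orders whenever one window's
  depletion exceeds the current stock (with `L_H = 10`, demand 4/day
  and a 19-day window that is the *steady state*), and the desired
  floor could then never be held. `forecast_stock(...,
  clip_negative=True)` exposes the floored variant for comparison.
* **Pipeline accounting.** In-transit and ordered-but-undispatched
  shipments are counted in forecasts (`count_pipeline=True`); ignoring
  them double-orders whenever `τ + d` overlaps a prior shipment. The
  flag exists for fidelity experiments.
* **Upstream demand proxy.** Warehouses and procurers face bursty
  downstream orders rather than a smooth rate; their forecasts use the
  patient demand rate at the decision day as depletion proxy, since in
  sustained operation every tier's average throughput equals patient
  demand. Upstream desired levels are static configuration values.

Controlled shipments default to discrete transfers (`B = 0`);
`discrete_dispatch=False` uses the link's Gaussian width instead.
Orders on P→W and W→H are capped by sender stock at dispatch (clipped
and flagged); M→P is uncapped. Under constant demand the controller
rediscovers the balance condition: steady-cycle orders equal `c·n`,
the pre-arrival facility stock sits exactly at `L_H`, and the long-run
mean stays within `[L, L + c·(n + τ)]` — stocks near the target, so
little inventory is exposed to expiry.

## Scenarios and what they do (not) show

The built-in fixtures reproduce qualitative behaviors, not any
particular dataset: parameter values are illustrative. Chain geometry
is shared (`τ_MP = 60`, `τ_PW = 15`, `τ_WH = 3` days; manufacturer
shipments every 180 days).

* `baseline` — open loop; all tiers dispatch on day 120 (so the
  procurer rise on day 180 and warehouse rise on day 135 expose the
  transport delays), and the facility link ships 40 packages every 14
  days against a 56-package-per-cycle demand, producing recurrent
  stockouts.
* `interventions` — the baseline plus one variant per intervention:
  prevention halves demand, roads halve τ (with a 1.1 size multiplier,
  an illustrative stand-in for newly reachable facilities), workforce
  halves `n`, vehicles double `A`.
* `tracking` — closed loop under constant demand 4/day, facility link
  per the worked-example pattern (`n = 14`, `τ = 3`, `d = 2`, first
  dispatch day 28), `L_H = 10`; upstream stocks start ample so sender
  clipping never binds and the floor property is observed cleanly.
* `seasonal` — closed loop against a three-season year: 2/day until
  day 100, 6/day through the high season, 4/day from day 250. Season
  rates and the day-100/day-250 boundaries follow the narrated year;
  the facility schedule is phased so a delivery lands exactly on day
  100, putting the demand jump inside exactly one forecasting window —
  one below-target excursion, corrected at the next decision.

Passing tests on these fixtures demonstrate the model's internal
logic — delay bookkeeping, conservation, the balance condition, the
controller's guarantees — under deterministic, single-product,
aggregated conditions. They do not validate against real consumption
or logistics data: real demand is stochastic and spatially
heterogeneous, lead times vary, and multi-product interactions
(shared trucks, budgets) are absent. Default problem sizes (365-day
horizon, `dt = 0.05`) run in well under a second each.

## Key parameters

| symbol | meaning | units | typical fixture value |
|---|---|---|---|
| `τ_MP, τ_PW, τ_WH` | transport times | days | 60, 15, 3 |
| `n_MP, n_PW, n_WH` | shipment periodicities | days | 180, 28–60, 14 |
| `A` | pulse amplitude | pkgs/day | set via size = A·B·√π |
| `B` | pulse duration parameter | days | 2–5 (0 = discrete) |
| `r0` | first dispatch/peak day | days | scenario-specific |
| `D(t)` | demand rate | pkgs/day | 4 (constant); 2/6/4 (seasonal) |
| `L_P, L_W, L_H` | desired stock levels | pkgs | e.g. `L_H = 10` |
| `d_M, d_P, d_W` | decision lead times | days | 10, 5, 2 |
| `dt` | integration step | days | 0.05 |
| `truncation_k` | pulse truncation `K·B` | — | 6 |

## Known limitations

Lost (not backlogged) unmet demand; a single demand-rate snapshot as
the forecast model (no smoothing or trend estimation — deliberately,
to stay faithful to the constant-rate projection); static upstream
desired levels; no costs or cost-effectiveness layer; no stochastic
demand, lead times or shipment loss. The balance-condition check
compares per-cycle supply with mean demand over `[τ, τ + n]` and is
meaningful for demand that is near-periodic on the cycle length.
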