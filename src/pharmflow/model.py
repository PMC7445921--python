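"""Core domain types for the supply-chain model.

The chain has five tiers: manufacturers (M) -> procurers (P) ->
warehouses (W) -> health facilities (H) -> recipients (R).  Stocks are
tracked for P, W and H only; M is an unbounded source and R a pure
sink.  Each link carries Gaussian-pulse (or discrete) shipments with a
transport delay tau, and the facility stock is drained by patient
demand.

Units are fixed globally: time in days, stock in packages ("pkgs"),
flows in packages/day.  Time zero is simulation start and every dispatch
day, decision day and first-peak time r0 is an absolute day on that
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np
import pandas as pd
import yaml

from .demand import DemandModel

__all__ = [
    "Compartment",
    "LINK_NAMES",
    "LinkParams",
    "ControllerParams",
    "ScenarioConfig",
    "ShipmentRecord",
    "Trajectory",
    "validate_scenario",
]


class Compartment(str, Enum):
    """Supply-chain tiers. Stocks exist only for P, W, H."""

    M = "M"  # manufacturers (unbounded source)
    P = "P"  # procurers
    W = "W"  # warehouses
    H = "H"  # health facilities
    R = "R"  # recipients / patients (sink)


#: The only admissible links, in chain order.
LINK_NAMES = ("MP", "PW", "WH")

#: Compartments with tracked stock.
STOCKED = ("P", "W", "H")


@dataclass
class LinkParams:
    """Shipment parameters for one link of the chain.

    Attributes
    ----------
    source, dest : str
        Compartment labels; together they must form one of the chain
        links M->P, P->W, W->H.
    tau : float
        Transport time in days between dispatch and arrival.
    n : float
        Shipment periodicity in days.
    A : float
        Pulse amplitude, packages/day.
    B : float
        Pulse width parameter, days.  B = 0 selects the discrete
        (instantaneous) shipment limit.
    r0 : float
        Absolute day of the first pulse peak / dispatch.
    """

    source: str
    dest: str
    tau: float
    n: float
    A: float = 0.0
    B: float = 0.0
    r0: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.source}{self.dest}"

    def default_size(self) -> float:
        """Default per-shipment size A*B*sqrt(pi) (packages)."""
        return self.A * self.B * float(np.sqrt(np.pi))

    def violations(self, prefix: str = "") -> list[str]:
        p = prefix or f"links[{self.name}]"
        out = []
        if self.name not in LINK_NAMES:
            out.append(f"{p}.source/dest: {self.source}->{self.dest} is not one of M->P, P->W, W->H")
        if self.tau < 0:
            out.append(f"{p}.tau: must be >= 0, got {self.tau}")
        if self.n <= 0:
            out.append(f"{p}.n: must be > 0, got {self.n}")
        if self.A < 0:
            out.append(f"{p}.A: must be >= 0, got {self.A}")
        if self.B < 0:
            out.append(f"{p}.B: must be >= 0, got {self.B}")
        return out


@dataclass
class ControllerParams:
    """Digital-tracking (forecasting) controller settings.

    ``L`` maps each stocked compartment (P, W, H) to its desired stock
    level in packages; ``d`` maps each sending compartment (M, P, W) to
    the decision lead time in days — how many days before a scheduled
    dispatch its size is decided.  ``enabled`` switches the feedback
    loop per link (default: on wherever L and d are given).

    ``count_pipeline`` includes in-transit and already-ordered shipments
    in stock forecasts; ignoring them double-orders whenever tau + d
    overlaps a prior shipment, so it defaults to on but is exposed for
    fidelity experiments.  ``discrete_dispatch`` sends controlled
    shipments as instantaneous transfers (B = 0); switch it off to use
    the link's Gaussian width instead.
    """

    L: dict[str, float] = field(default_factory=dict)
    d: dict[str, float] = field(default_factory=dict)
    enabled: dict[str, bool] = field(default_factory=dict)
    count_pipeline: bool = True
    discrete_dispatch: bool = True

    def is_enabled(self, link_name: str) -> bool:
        if link_name in self.enabled:
            return bool(self.enabled[link_name])
        return link_name[1] in self.L and link_name[0] in self.d

    def violations(self, links: list[LinkParams] | None = None) -> list[str]:
        out = []
        for comp, val in self.L.items():
            if comp not in STOCKED:
                out.append(f"controller.L[{comp}]: desired levels exist only for P, W, H")
            elif val < 0:
                out.append(f"controller.L[{comp}]: must be >= 0, got {val}")
        for comp, val in self.d.items():
            if comp not in ("M", "P", "W"):
                out.append(f"controller.d[{comp}]: lead times exist only for senders M, P, W")
            elif val < 0:
                out.append(f"controller.d[{comp}]: must be >= 0, got {val}")
        if links:
            by_name = {lk.name: lk for lk in links}
            for name, lk in by_name.items():
                sender = name[0]
                if sender in self.d and self.d[sender] > lk.n:
                    out.append(
                        f"controller.d[{sender}]: lead time {self.d[sender]} exceeds the "
                        f"periodicity n_{name}={lk.n}; a shipment's size must be decided "
                        f"at most one period before it departs"
                    )
        return out


@dataclass
class ScenarioConfig:
    """Full parameterization of one simulation run.

    One drug product per scenario; multi-drug studies are independent
    runs.  ``sample_every`` is the output sampling interval (stocks are
    point samples, flows window averages on that grid).
    """

    links: list[LinkParams]
    demand: DemandModel
    initial_stocks: dict[str, float]
    horizon: float
    dt: float = 0.05
    sample_every: float = 1.0
    controller: ControllerParams | None = None
    truncation_k: float = 6.0
    strict_clipping: bool = False

    def link(self, name: str) -> LinkParams:
        for lk in self.links:
            if lk.name == name:
                return lk
        raise KeyError(f"no link {name!r} in scenario")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "links": [asdict(lk) for lk in self.links],
            "demand": self.demand.to_dict(),
            "initial_stocks": dict(self.initial_stocks),
            "horizon": self.horizon,
            "dt": self.dt,
            "sample_every": self.sample_every,
            "truncation_k": self.truncation_k,
            "strict_clipping": self.strict_clipping,
        }
        if self.controller is not None:
            d["controller"] = {
                "L": dict(self.controller.L),
                "d": dict(self.controller.d),
                "enabled": dict(self.controller.enabled),
                "count_pipeline": self.controller.count_pipeline,
                "discrete_dispatch": self.controller.discrete_dispatch,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        ctrl = None
        if d.get("controller") is not None:
            c = d["controller"]
            ctrl = ControllerParams(
                L={k: float(v) for k, v in c.get("L", {}).items()},
                d={k: float(v) for k, v in c.get("d", {}).items()},
                enabled={k: bool(v) for k, v in c.get("enabled", {}).items()},
                count_pipeline=bool(c.get("count_pipeline", True)),
                discrete_dispatch=bool(c.get("discrete_dispatch", True)),
            )
        return cls(
            links=[LinkParams(**lk) for lk in d["links"]],
            demand=DemandModel.from_dict(d["demand"]),
            initial_stocks={k: float(v) for k, v in d["initial_stocks"].items()},
            horizon=float(d["horizon"]),
            dt=float(d.get("dt", 0.05)),
            sample_every=float(d.get("sample_every", 1.0)),
            controller=ctrl,
            truncation_k=float(d.get("truncation_k", 6.0)),
            strict_clipping=bool(d.get("strict_clipping", False)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_scenario(cfg: ScenarioConfig) -> list[str]:
    """Check every scenario invariant; return human-readable violations.

    An empty list means the scenario is well formed.  Violations are
    returned, never raised, so a caller can report all of them at once.
    """
    out: list[str] = []
    names = [lk.name for lk in cfg.links]
    if sorted(names) != sorted(LINK_NAMES):
        out.append(f"links: expected exactly the chain links {LINK_NAMES}, got {tuple(names)}")
    for lk in cfg.links:
        out.extend(lk.violations())
    out.extend(cfg.demand.violations())
    for comp in STOCKED:
        if comp not in cfg.initial_stocks:
            out.append(f"initial_stocks[{comp}]: missing")
        elif cfg.initial_stocks[comp] < 0:
            out.append(f"initial_stocks[{comp}]: must be >= 0, got {cfg.initial_stocks[comp]}")
    if cfg.horizon <= 0:
        out.append(f"horizon: must be > 0, got {cfg.horizon}")
    if cfg.dt <= 0:
        out.append(f"dt: must be > 0, got {cfg.dt}")
    elif cfg.sample_every < cfg.dt:
        out.append(f"sample_every: must be >= dt={cfg.dt}, got {cfg.sample_every}")
    if cfg.truncation_k <= 0:
        out.append(f"truncation_k: must be > 0, got {cfg.truncation_k}")
    if cfg.controller is not None:
        out.extend(cfg.controller.violations(cfg.links))
    return out


@dataclass
class ShipmentRecord:
    """One logged shipment: arrival_day = dispatch_day + link tau."""

    link: str
    dispatch_day: float
    arrival_day: float
    size: float
    clipped: bool = False


@dataclass
class Trajectory:
    """Sampled simulation output.

    Stocks (``Y_P``, ``Y_W``, ``Y_H``) are point samples at ``t``;
    flow-rate series (``F_MP``, ``F_PW``, ``F_WH``, ``D``, ``unmet``)
    hold, at index i >= 1, the average rate over the window
    (t[i-1], t[i]] — so flow * spacing sums to the transported totals —
    with index 0 fixed at 0.  ``in_transit_end`` gives per-link packages
    dispatched but not yet arrived at the horizon; ``clip_events`` logs
    (link, day, packages) suppressed because a sender ran dry.
    """

    t: np.ndarray
    Y_P: np.ndarray
    Y_W: np.ndarray
    Y_H: np.ndarray
    F_MP: np.ndarray
    F_PW: np.ndarray
    F_WH: np.ndarray
    D: np.ndarray
    unmet: np.ndarray
    shipments: list[ShipmentRecord] = field(default_factory=list)
    in_transit_end: dict[str, float] = field(default_factory=dict)
    clip_events: list[tuple[str, float, float]] = field(default_factory=list)
    dt: float = 1.0

    def stock(self, comp: str) -> np.ndarray:
        return getattr(self, f"Y_{comp}")

    def flow(self, link: str) -> np.ndarray:
        return getattr(self, f"F_{link}")

    @property
    def spacing(self) -> float:
        """Grid spacing of the sampled series, days."""
        return self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "Y_P": self.Y_P,
                "Y_W": self.Y_W,
                "Y_H": self.Y_H,
                "F_MP": self.F_MP,
                "F_PW": self.F_PW,
                "F_WH": self.F_WH,
                "D": self.D,
                "unmet": self.unmet,
            }
        )

    def shipments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "link": s.link,
                    "dispatch_day": s.dispatch_day,
                    "arrival_day": s.arrival_day,
                    "size_pkgs": s.size,
                    "clipped": s.clipped,
                }
                for s in self.shipments
            ],
            columns=["link", "dispatch_day", "arrival_day", "size_pkgs", "clipped"],
        )

    def write_csv(self, series_path, shipments_path=None) -> None:
        self.to_frame().to_csv(series_path, index=False)
        if shipments_path is not None:
            self.shipments_frame().to_csv(shipments_path, index=False)

    def total_dispensed(self) -> float:
        """Packages actually handed to recipients over the run."""
        return float(np.sum(self.D - self.unmet) * self.spacing)

    def total_unmet(self) -> float:
        """Packages of demand that went unserved (lost, not backlogged)."""
        return float(np.sum(self.unmet) * self.spacing)
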