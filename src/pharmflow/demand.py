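"""Patient demand models.

Demand is the rate at which recipients withdraw drugs from health
facilities, in packages/day.  It enters the facility stock balance as a
continuous sink term.  Three forms are supported:

``constant``
    A single rate for the whole horizon.
``piecewise_seasonal``
    Contiguous seasons, each with its own rate (e.g. a low / high /
    moderate malaria year).  Right-continuous at season boundaries: the
    first day of a season already runs at the new rate.
``tabulated``
    Sampled (day, rate) pairs with linear interpolation, e.g. from a
    historical consumption record.

A dimensionless ``scale`` multiplies every form; interventions that
lower population need (immunization, prevention programs) act through
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DemandModel",
    "DemandDomainError",
    "demand_rate",
    "mean_demand_over_window",
]

_FORMS = ("constant", "piecewise_seasonal", "tabulated")


class DemandDomainError(ValueError):
    """Raised when a demand model is evaluated outside its domain."""


@dataclass
class DemandModel:
    """Time -> dispensing rate (packages/day).

    Parameters
    ----------
    form : {"constant", "piecewise_seasonal", "tabulated"}
    rate : float
        Rate for the constant form.
    segments : list of (start_day, end_day, rate)
        Seasons for the piecewise form; must be contiguous and
        non-overlapping.  The last segment's end day is inclusive.
    table : (N, 2) array-like
        (day, rate) samples for the tabulated form.
    scale : float
        Dimensionless multiplier applied to every form (default 1).
    """

    form: str = "constant"
    rate: float = 0.0
    segments: list[tuple[float, float, float]] = field(default_factory=list)
    table: np.ndarray | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown demand form {self.form!r}; expected one of {_FORMS}")
        if self.table is not None:
            self.table = np.asarray(self.table, dtype=float)

    # -- constructors -------------------------------------------------
    @classmethod
    def constant(cls, rate: float, scale: float = 1.0) -> "DemandModel":
        return cls(form="constant", rate=float(rate), scale=scale)

    @classmethod
    def seasonal(cls, segments, scale: float = 1.0) -> "DemandModel":
        segs = [(float(a), float(b), float(r)) for a, b, r in segments]
        return cls(form="piecewise_seasonal", segments=segs, scale=scale)

    @classmethod
    def tabulated(cls, days, rates, scale: float = 1.0) -> "DemandModel":
        table = np.column_stack([np.asarray(days, float), np.asarray(rates, float)])
        return cls(form="tabulated", table=table, scale=scale)

    @classmethod
    def from_csv(cls, path, scale: float = 1.0) -> "DemandModel":
        """Read a two-column CSV (day, rate_pkgs_per_day)."""
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(form="tabulated", table=table[:, :2], scale=scale)

    # -- evaluation ---------------------------------------------------
    def rate_at(self, t: float) -> float:
        return demand_rate(self, t)

    def mean_over(self, start: float, length: float) -> float:
        return mean_demand_over_window(self, start, length)

    def rescaled(self, factor: float) -> "DemandModel":
        """A copy with ``scale`` multiplied by ``factor`` (intervention hook)."""
        return DemandModel(
            form=self.form,
            rate=self.rate,
            segments=list(self.segments),
            table=None if self.table is None else self.table.copy(),
            scale=self.scale * factor,
        )

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.scale < 0:
            out.append(f"demand.scale: must be >= 0, got {self.scale}")
        if self.form == "constant":
            if self.rate < 0:
                out.append(f"demand.rate: must be >= 0, got {self.rate}")
        elif self.form == "piecewise_seasonal":
            if not self.segments:
                out.append("demand.segments: piecewise_seasonal requires segments")
            prev_end = None
            for i, (a, b, r) in enumerate(self.segments):
                if b <= a:
                    out.append(f"demand.segments[{i}]: end {b} must exceed start {a}")
                if r < 0:
                    out.append(f"demand.segments[{i}]: rate must be >= 0, got {r}")
                if prev_end is not None and abs(a - prev_end) > 1e-9:
                    out.append(
                        f"demand.segments[{i}]: starts at {a}, previous ends at "
                        f"{prev_end}; seasons must be contiguous"
                    )
                prev_end = b
        elif self.form == "tabulated":
            if self.table is None or len(self.table) < 2:
                out.append("demand.table: tabulated form needs at least two samples")
            else:
                days = self.table[:, 0]
                if np.any(np.diff(days) <= 0):
                    out.append("demand.table: days must be strictly increasing")
                if np.any(self.table[:, 1] < 0):
                    out.append("demand.table: rates must be >= 0")
        return out

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"form": self.form, "scale": self.scale}
        if self.form == "constant":
            d["rate"] = self.rate
        elif self.form == "piecewise_seasonal":
            d["segments"] = [list(s) for s in self.segments]
        else:
            d["table"] = self.table.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemandModel":
        form = d["form"]
        if form == "constant":
            return cls(form=form, rate=float(d["rate"]), scale=float(d.get("scale", 1.0)))
        if form == "piecewise_seasonal":
            segs = [tuple(map(float, s)) for s in d["segments"]]
            return cls(form=form, segments=segs, scale=float(d.get("scale", 1.0)))
        return cls(form=form, table=np.asarray(d["table"], float), scale=float(d.get("scale", 1.0)))


def _domain(model: DemandModel) -> tuple[float, float]:
    """Evaluable [lo, hi] of the model; constant demand is unbounded above."""
    if model.form == "piecewise_seasonal":
        return model.segments[0][0], model.segments[-1][1]
    if model.form == "tabulated":
        return float(model.table[0, 0]), float(model.table[-1, 0])
    return 0.0, np.inf


def demand_rate(model: DemandModel, t: float) -> float:
    """Dispensing rate at time ``t`` (packages/day).

    Piecewise-seasonal demand is right-continuous: at a season boundary
    the new season's rate applies.
    """
    lo, hi = _domain(model)
    if t < lo - 1e-12 or t > hi + 1e-12:
        raise DemandDomainError(f"t={t} outside demand domain [{lo}, {hi}]")
    if model.form == "constant":
        return model.scale * model.rate
    if model.form == "piecewise_seasonal":
        for a, b, r in model.segments:
            if a - 1e-12 <= t < b:
                return model.scale * r
        return model.scale * model.segments[-1][2]  # inclusive right end
    return model.scale * float(np.interp(t, model.table[:, 0], model.table[:, 1]))


def mean_demand_over_window(model: DemandModel, start: float, length: float) -> float:
    """Average rate (1/length) * integral of D over [start, start+length].

    Exact segment arithmetic for the constant and seasonal forms;
    trapezoid rule (exact for the piecewise-linear interpolant) for
    tabulated demand.
    """
    if length <= 0:
        raise ValueError(f"window length must be > 0, got {length}")
    end = start + length
    lo, hi = _domain(model)
    if start < lo - 1e-12 or end > hi + 1e-12:
        raise DemandDomainError(f"window [{start}, {end}] outside demand domain [{lo}, {hi}]")

    if model.form == "constant":
        return model.scale * model.rate
    if model.form == "piecewise_seasonal":
        total = 0.0
        for a, b, r in model.segments:
            overlap = min(b, end) - max(a, start)
            if overlap > 0:
                total += r * overlap
        return model.scale * total / length
    days = model.table[:, 0]
    knots = np.unique(np.concatenate([[start, end], days[(days > start) & (days < end)]]))
    vals = np.interp(knots, days, model.table[:, 1])
    return model.scale * float(np.trapezoid(vals, knots)) / length
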