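"""Shipment flow functions.

A shipment on a supply-chain link is modelled as a Gaussian pulse in the
flow rate,

    F(t) = A * exp(-(t - r)^2 / B^2),

where ``A`` (packages/day) is the peak loading rate, ``B`` (days) sets
the duration of loading/unloading, and ``r`` (days) is the peak time.
The shipment size is the area under the pulse, SS = A*B*sqrt(pi)
packages.  Scheduled shipments repeat every ``n`` days, giving a pulse
train.  The limit B -> 0 at fixed size is an instantaneous (discrete)
transfer, which the simulator applies as an exact step change.

Pulses are truncated at |t - r| > K*B (default K = 6, tail mass below
1e-15 of the size) so a shipment never leaks into unrelated periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRUNCATION_K",
    "Shipment",
    "ShipmentPlan",
    "pulse_value",
    "shipment_size",
    "amplitude_for_size",
    "pulse_train",
    "discrete_shipment",
]

TRUNCATION_K = 6.0

_SQRT_PI = math.sqrt(math.pi)


def pulse_value(A: float, B: float, r: float, t, truncation_k: float = TRUNCATION_K):
    """Gaussian pulse flow rate at time ``t`` (packages/day).

    Returns exactly 0 where |t - r| > truncation_k * B.  Accepts scalar
    or array ``t``.

    Raises
    ------
    ValueError
        If B <= 0; a zero-width pulse has no finite rate and must be
        handled as a discrete transfer instead.
    """
    if B <= 0:
        raise ValueError("B must be > 0 for a Gaussian pulse; use discrete_shipment for B = 0")
    if A < 0:
        raise ValueError(f"pulse amplitude A must be >= 0, got {A}")
    t = np.asarray(t, dtype=float)
    u = (t - r) / B
    out = np.where(np.abs(u) > truncation_k, 0.0, A * np.exp(-(u * u)))
    return float(out) if out.ndim == 0 else out


def shipment_size(A: float, B: float) -> float:
    """Area under one pulse: SS = A * B * sqrt(pi) (packages)."""
    if A < 0 or B < 0:
        raise ValueError(f"A and B must be >= 0, got A={A}, B={B}")
    return A * B * _SQRT_PI


def amplitude_for_size(size: float, B: float) -> float:
    """Amplitude giving a pulse of the requested size at fixed width B."""
    if B <= 0:
        raise ValueError("B must be > 0 to solve for an amplitude")
    return size / (B * _SQRT_PI)


@dataclass
class Shipment:
    """One shipment: ``size`` packages leaving at ``dispatch_day``.

    ``B`` = 0 denotes a discrete (instantaneous) transfer; B > 0 a
    Gaussian pulse centred on the dispatch day.
    """

    dispatch_day: float
    size: float
    B: float = 0.0

    @property
    def amplitude(self) -> float:
        return amplitude_for_size(self.size, self.B)

    def flow(self, t, truncation_k: float = TRUNCATION_K):
        """Flow rate contribution at ``t``; only defined for B > 0."""
        return pulse_value(self.amplitude, self.B, self.dispatch_day, t, truncation_k)


@dataclass
class ShipmentPlan:
    """The dispatch-side flow on one link: a list of shipments.

    The plan's flow at any time is the sum of its pulses (overlapping
    pulses add; the flow balance is linear in contributions).  Discrete
    shipments (B = 0) carry no rate and are applied by the simulator as
    step changes.
    """

    shipments: list[Shipment] = field(default_factory=list)
    truncation_k: float = TRUNCATION_K

    @property
    def dispatch_days(self) -> list[float]:
        return [s.dispatch_day for s in self.shipments]

    @property
    def total_size(self) -> float:
        return sum(s.size for s in self.shipments)

    def flow(self, t):
        """Continuous (Gaussian) flow rate at ``t``; discrete shipments excluded."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in self.shipments:
            if s.B > 0 and s.size > 0:
                out = out + s.flow(t, self.truncation_k)
        return float(out) if out.ndim == 0 else out


def pulse_train(
    link,
    horizon: float,
    sizes=None,
    truncation_k: float = TRUNCATION_K,
) -> ShipmentPlan:
    """Periodic shipment schedule for a link over [0, horizon].

    Dispatch peaks fall at r0, r0 + n, r0 + 2n, ... <= horizon.  Each
    shipment's size defaults to the link's A*B*sqrt(pi); ``sizes`` (a
    sequence indexed by shipment, or a {dispatch_day: size} mapping)
    overrides individual shipments.  Overrides rescale the amplitude at
    fixed width B, so pulse duration stays a link property while size is
    a planning decision.  Zero-size shipments are dropped.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    if link.n <= 0:
        raise ValueError(f"shipment periodicity n must be > 0, got {link.n}")
    default = shipment_size(link.A, link.B)
    days: list[float] = []
    day = link.r0
    while day <= horizon + 1e-9:
        days.append(day)
        day += link.n
    shipments = []
    for i, d in enumerate(days):
        size = default
        if sizes is not None:
            if isinstance(sizes, dict):
                size = sizes.get(d, default)
            elif i < len(sizes):
                size = sizes[i]
        if size > 0:
            shipments.append(Shipment(dispatch_day=d, size=float(size), B=link.B))
    return ShipmentPlan(shipments=shipments, truncation_k=truncation_k)


def discrete_shipment(size: float, dispatch_day: float) -> Shipment:
    """An instantaneous transfer of ``size`` packages at ``dispatch_day``.

    The sender loses the full size at the dispatch instant and the
    receiver gains it one transport time later; integrating the implied
    flow over any window containing the event yields exactly ``size``.
    """
    if size < 0:
        raise ValueError(f"shipment size must be >= 0, got {size}")
    return Shipment(dispatch_day=float(dispatch_day), size=float(size), B=0.0)
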