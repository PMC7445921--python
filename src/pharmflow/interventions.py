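"""Health-system intervention transforms.

System-wide investments map onto the model's parameters:

==============================  ================================
Intervention                    Model component
==============================  ================================
prevention (e.g. immunization)  demand D(t), scaled down
roads / railroads               transport times tau, reduced —
                                and shipment sizes increased, as
                                newly reachable facilities join
workforce expansion             shipment periodicity n, reduced
higher-capacity vehicles        pulse amplitude A, increased
==============================  ================================

Each transform returns a new ScenarioConfig and never mutates its
input, so scenarios compose and compare cleanly.  The roads size
increase has no canonical magnitude; the default multiplier of 1.1 is
illustrative and configurable.
"""

from __future__ import annotations

import copy

from .model import LINK_NAMES, ScenarioConfig, validate_scenario

__all__ = ["INTERVENTION_KINDS", "apply_intervention"]

INTERVENTION_KINDS = ("prevention", "roads", "workforce", "vehicles")


def apply_intervention(
    cfg: ScenarioConfig,
    kind: str,
    links=None,
    *,
    factor: float | None = None,
    tau_scale: float | None = None,
    size_scale: float = 1.1,
    n_scale: float | None = None,
    amplitude_scale: float | None = None,
) -> ScenarioConfig:
    """Return a new scenario with one intervention applied.

    Parameters
    ----------
    kind : {"prevention", "roads", "workforce", "vehicles"}
    links : iterable of link names, optional
        Links the transform touches (default: all).  Ignored by
        ``prevention``, which acts on demand only.
    factor : float
        Demand multiplier for ``prevention`` (< 1 lowers need).
    tau_scale : float
        Transport-time multiplier for ``roads`` (< 1 shortens).
    size_scale : float
        Shipment-size multiplier accompanying ``roads`` (default 1.1).
    n_scale : float
        Periodicity multiplier for ``workforce`` (< 1 means more
        frequent shipments).
    amplitude_scale : float
        Pulse-amplitude multiplier for ``vehicles`` (> 1 means bigger
        shipments).

    Raises
    ------
    ValueError
        Unknown kind, missing magnitude, or a transform that leaves the
        scenario invalid.
    """
    if kind not in INTERVENTION_KINDS:
        raise ValueError(f"unknown intervention kind {kind!r}; expected one of {INTERVENTION_KINDS}")
    sel = tuple(links) if links is not None else LINK_NAMES
    for name in sel:
        if name not in LINK_NAMES:
            raise ValueError(f"unknown link {name!r}")
    new = copy.deepcopy(cfg)

    if kind == "prevention":
        if factor is None or factor <= 0:
            raise ValueError("prevention requires factor > 0")
        new.demand = new.demand.rescaled(factor)
    elif kind == "roads":
        if tau_scale is None or tau_scale < 0:
            raise ValueError("roads requires tau_scale >= 0")
        if size_scale <= 0:
            raise ValueError("roads size_scale must be > 0")
        for lk in new.links:
            if lk.name in sel:
                lk.tau *= tau_scale
                lk.A *= size_scale
    elif kind == "workforce":
        if n_scale is None or n_scale <= 0:
            raise ValueError("workforce requires n_scale > 0")
        for lk in new.links:
            if lk.name in sel:
                lk.n *= n_scale
    else:  # vehicles
        if amplitude_scale is None or amplitude_scale <= 0:
            raise ValueError("vehicles requires amplitude_scale > 0")
        for lk in new.links:
            if lk.name in sel:
                lk.A *= amplitude_scale

    violations = validate_scenario(new)
    if violations:
        raise ValueError(f"intervention {kind} yields an invalid scenario: " + "; ".join(violations))
    return new
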