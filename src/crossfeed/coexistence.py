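"""Analytical coexistence conditions for producer/consumer chemostats.

At steady state a surviving strain grows exactly at the dilution rate D, and
each extracellular resource is balanced, which turns the chemostat ODEs into
a small fixed-point problem:

    mu_P(M1) = D                    (producer limited by the primary, conc M1)
    mu_C(M1, M2) = D                (consumer using primary <= c and secondary)
    D (M1_feed - M1) = J1P X_P + J1C X_C
    D M2 = J2P X_P - J2C X_C

The strain response curves mu(.) come from FBA with uptake bounded by the
Michaelis-Menten transport limit at the ambient concentration, and are
monotone in the limiting resource, so the resource concentrations are found
by bisection and the biomasses then follow from the (linear) balances.

Coexistence of metabolically distinct strains requires (i) the producer to
excrete the secondary at 0 < p <= p_max (beyond p_max it cannot reach mu = D
and washes out), and (ii) the consumer to *need* the secondary: if it can
reach mu = D on the primary alone (uptake cap c high enough), the producer -
which pays for the excretion - is competitively excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .carbon_niche import transport_limit
from .chemostat import ChemostatConfig, StrainSpec
from .fba_core import MediumSpec, MetabolicModel, VIABILITY_EPS, apply_medium

__all__ = [
    "CoexistenceVerdict",
    "consumer_persists_alone",
    "coexistence_possible",
    "steady_state_solve",
]

#: convergence tolerance of the concentration bisections (relative)
BISECT_TOL = 1e-10


@dataclass
class CoexistenceVerdict:
    """Steady-state outcome of a producer/consumer chemostat."""

    outcome: str                       # "both" | "P_only" | "C_only" | "neither"
    p: float
    c: float
    steady_biomass: dict[str, float] = field(default_factory=dict)
    steady_concentrations: dict[str, float] = field(default_factory=dict)
    fluxes: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def coexists(self) -> bool:
        return self.outcome == "both"


def _mu_max(
    model: MetabolicModel,
    base_medium: MediumSpec,
    uptake_bounds: Mapping[str, float],
    forced_export: Mapping[str, float] = {},
) -> float:
    """Maximal growth under per-exchange uptake bounds and export floors.

    Returns -inf for an infeasible LP (an obligate producer with no carbon).
    """
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        for rid, bound in uptake_bounds.items():
            cm.reactions.get_by_id(rid).lower_bound = -max(bound, 0.0)
        for rid, floor in forced_export.items():
            cm.reactions.get_by_id(rid).lower_bound = floor
        cm.objective = cm.reactions.get_by_id(model.biomass_id)
        cm.objective_direction = "max"
        mu = cm.slim_optimize(error_value=float("nan"))
    if math.isnan(mu):
        return -math.inf
    return float(mu)


def _uptake_at_growth(
    model: MetabolicModel,
    base_medium: MediumSpec,
    growth: float,
    minimize: str,
    uptake_bounds: Mapping[str, float],
    forced_export: Mapping[str, float] = {},
    read: tuple[str, ...] = (),
) -> dict[str, float] | None:
    """Exchange fluxes at mu = growth, minimizing uptake of ``minimize``.

    Returns {exchange id: net flux} for ``minimize`` + ``read`` (negative =
    uptake), or None if infeasible.
    """
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        for rid, bound in uptake_bounds.items():
            cm.reactions.get_by_id(rid).lower_bound = -max(bound, 0.0)
        for rid, floor in forced_export.items():
            cm.reactions.get_by_id(rid).lower_bound = floor
        bio = cm.reactions.get_by_id(model.biomass_id)
        bio.bounds = (growth, growth)
        cm.objective = cm.reactions.get_by_id(minimize)
        cm.objective_direction = "max"   # max of negative flux = min uptake
        value = cm.slim_optimize(error_value=float("nan"))
        if math.isnan(value):
            return None
        out = {minimize: float(value)}
        for rid in read:
            out[rid] = float(cm.reactions.get_by_id(rid).flux)
    return out


def _bisect_conc(f, lo: float, hi: float) -> float:
    """Smallest concentration where the monotone f(conc) >= 0."""
    flo, fhi = f(lo), f(hi)
    if flo >= 0:
        return lo
    if fhi < 0:
        raise ValueError("no root in bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= BISECT_TOL * max(hi, 1.0):
            break
    return hi


def consumer_persists_alone(
    consumer: StrainSpec,
    base_medium: MediumSpec,
    primary: str,
    D: float,
    feed_conc: float,
    vmax: float = 20.0,
    km: float = 0.05,
) -> bool:
    """Can the consumer reach mu >= D on the primary carbon source alone?

    The primary uptake is bounded by min(c, transport limit at the feed
    concentration); no secondary is available.  The boundary mu = D counts as
    persisting.
    """
    c = consumer.uptake_caps.get(primary, math.inf)
    bound = min(c, transport_limit(feed_conc, vmax, km))
    mu = _mu_max(consumer.model, base_medium, {primary: bound})
    return mu >= D


def coexistence_possible(
    producer: StrainSpec,
    consumer: StrainSpec,
    base_medium: MediumSpec,
    primary: str,
    secondary: str,
    p: float,
    D: float,
    feed_conc: float,
    vmax: float = 20.0,
    km: float = 0.05,
) -> str:
    """Qualitative outcome for production rate ``p`` and the consumer's cap.

    "both" requires (i) the producer to sustain mu = D while excreting at p
    (0 < p <= p_max), and (ii) the consumer to persist only with the
    secondary's help: not on the primary alone, but reaching mu >= D when
    the secondary is additionally available at the producer's steady state.
    """
    verdict = steady_state_solve(
        producer, consumer, base_medium, primary, secondary, p,
        D=D, feed_conc=feed_conc, vmax=vmax, km=km,
    )
    return verdict.outcome


def steady_state_solve(
    producer: StrainSpec,
    consumer: StrainSpec | None,
    base_medium: MediumSpec,
    primary: str,
    secondary: str,
    p: float,
    D: float = 0.2,
    feed_conc: float = 1.0,
    vmax: float = 20.0,
    km: float = 0.05,
    dt: float = 0.0,
) -> CoexistenceVerdict:
    """Direct steady-state solution of the producer/consumer chemostat.

    With the default ``dt`` = 0 the continuous-chemostat equilibrium is
    returned.  ``dt`` > 0 additionally applies the discrete-time pool floor
    of the Euler dFBA loop: a fully drawn-down resource settles at
    concentration feed*D*dt/(1+D*dt) (and a produced one at
    production*dt/(1+D*dt)) rather than at the transport-limited level,
    because at most M/dt of a pool can be consumed per step.  Pass the
    simulation's dt to compare against :func:`crossfeed.chemostat.simulate`.

    Returns a :class:`CoexistenceVerdict` with steady biomasses (gDW/l),
    concentrations (mM) and per-strain exchange fluxes.
    """
    c_cap = consumer.uptake_caps.get(primary, math.inf) if consumer else 0.0
    sec_cap = consumer.uptake_caps.get(secondary, math.inf) if consumer else 0.0
    forced = {secondary: p} if p > 0 else {}

    def mu_P(M1: float) -> float:
        return _mu_max(
            producer.model, base_medium,
            {primary: transport_limit(M1, vmax, km)}, forced,
        )

    # --- producer persistence and its resource level -----------------
    p_washout = mu_P(feed_conc) < D
    if p_washout and consumer is None:
        return CoexistenceVerdict("neither", p, c_cap)

    if not p_washout:
        M1 = _bisect_conc(lambda M: mu_P(M) - D, 0.0, feed_conc)
        if dt > 0:
            M1 = max(M1, feed_conc * D * dt / (1.0 + D * dt))
        flux = _uptake_at_growth(
            producer.model, base_medium, D, primary,
            {primary: transport_limit(M1, vmax, km)}, forced, read=(secondary,),
        )
        J1P = -flux[primary]          # uptake, positive
        J2P = flux[secondary]         # export, positive (>= p)
    else:
        M1 = feed_conc
        J1P = J2P = 0.0

    # --- consumer-only and invasion logic ----------------------------
    def mu_C(M1_amb: float, M2: float) -> float:
        if consumer is None:
            return -math.inf
        return _mu_max(
            consumer.model, base_medium,
            {
                primary: min(c_cap, transport_limit(M1_amb, vmax, km)),
                secondary: min(sec_cap, transport_limit(M2, vmax, km)),
            },
        )

    if consumer is not None and mu_C(M1 if not p_washout else feed_conc, 0.0) >= D:
        # consumer persists on the primary alone: producer excluded
        def mu_C_alone(M: float) -> float:
            return mu_C(M, 0.0)
        M1c = _bisect_conc(lambda M: mu_C_alone(M) - D, 0.0, feed_conc)
        if dt > 0:
            M1c = max(M1c, feed_conc * D * dt / (1.0 + D * dt))
        flux = _uptake_at_growth(
            consumer.model, base_medium, D, primary,
            {primary: min(c_cap, transport_limit(M1c, vmax, km))},
        )
        J1C = -flux[primary]
        X_C = D * (feed_conc - M1c) / J1C if J1C > 0 else 0.0
        return CoexistenceVerdict(
            "C_only", p, c_cap,
            steady_biomass={producer.name: 0.0, consumer.name: X_C},
            steady_concentrations={primary: M1c, secondary: 0.0},
            fluxes={consumer.name: {primary: -J1C, secondary: 0.0}},
        )

    if p_washout:
        return CoexistenceVerdict("neither", p, c_cap)

    # --- producer-only equilibrium ------------------------------------
    X_P_alone = D * (feed_conc - M1) / J1P if J1P > 0 else 0.0
    M2_alone = J2P * X_P_alone / D if D > 0 else 0.0

    if consumer is None or p <= 0:
        names = {producer.name: X_P_alone}
        if consumer is not None:
            names[consumer.name] = 0.0
        return CoexistenceVerdict(
            "P_only", p, c_cap,
            steady_biomass=names,
            steady_concentrations={primary: M1, secondary: M2_alone},
            fluxes={producer.name: {primary: -J1P, secondary: J2P}},
        )

    # can the consumer invade the producer-only steady state?
    if mu_C(M1, M2_alone) < D:
        return CoexistenceVerdict(
            "P_only", p, c_cap,
            steady_biomass={producer.name: X_P_alone, consumer.name: 0.0},
            steady_concentrations={primary: M1, secondary: M2_alone},
            fluxes={producer.name: {primary: -J1P, secondary: J2P}},
        )

    # --- interior (coexistence) fixed point ---------------------------
    M2 = _bisect_conc(lambda M: mu_C(M1, M) - D, 0.0, max(M2_alone, 1e-12))
    cflux = _uptake_at_growth(
        consumer.model, base_medium, D, secondary,
        {
            primary: min(c_cap, transport_limit(M1, vmax, km)),
            secondary: min(sec_cap, transport_limit(M2, vmax, km)),
        },
        read=(primary,),
    )
    J2C = -cflux[secondary]
    J1C = max(-cflux[primary], 0.0)

    # linear balances:  J1P X_P + J1C X_C = D (feed - M1)
    #                   J2P X_P - J2C X_C = D M2
    det = -J1P * J2C - J1C * J2P
    if abs(det) < 1e-30:
        return CoexistenceVerdict("P_only", p, c_cap,
                                  steady_biomass={producer.name: X_P_alone,
                                                  consumer.name: 0.0},
                                  steady_concentrations={primary: M1,
                                                         secondary: M2_alone})
    b1 = D * (feed_conc - M1)

    def solve_balances(M2_val: float) -> tuple[float, float]:
        b2 = D * M2_val
        xp = (b1 * (-J2C) - J1C * b2) / det
        xc = (J1P * b2 - J2P * b1) / det
        return xp, xc

    X_P, X_C = solve_balances(M2)
    if dt > 0 and J2C > 0 and X_P > 0:
        # pool floor of the secondary: the consumer can drain at most M2/dt
        # per step, so the concentration settles at production*dt/(1+D*dt)
        # when that exceeds the transport-limited level
        M2_floor = J2P * X_P * dt / (1.0 + D * dt)
        if M2_floor > M2:
            M2 = M2_floor
            X_P, X_C = solve_balances(M2)

    if X_C <= VIABILITY_EPS * 1e-3:
        return CoexistenceVerdict(
            "P_only", p, c_cap,
            steady_biomass={producer.name: X_P_alone, consumer.name: 0.0},
            steady_concentrations={primary: M1, secondary: M2_alone},
            fluxes={producer.name: {primary: -J1P, secondary: J2P}},
        )
    if X_P <= 0:
        return CoexistenceVerdict("C_only", p, c_cap,
                                  steady_biomass={producer.name: 0.0,
                                                  consumer.name: max(X_C, 0.0)},
                                  steady_concentrations={primary: M1,
                                                         secondary: M2})
    return CoexistenceVerdict(
        "both", p, c_cap,
        steady_biomass={producer.name: X_P, consumer.name: X_C},
        steady_concentrations={primary: M1, secondary: M2},
        fluxes={
            producer.name: {primary: -J1P, secondary: J2P},
            consumer.name: {primary: -J1C, secondary: -J2C},
        },
    )


def verdict_map(
    producer_factory,
    consumer_factory,
    base_medium: MediumSpec,
    primary: str,
    secondary: str,
    p_values,
    c_values,
    **kwargs,
) -> "list[CoexistenceVerdict]":
    """Verdicts over a (p, c) grid; factories build strains for given p, c.

    The outcomes partition the plane into the coexistence region (bounded
    above by p_max and on the right by the persistence-alone threshold) and
    the single-strain / washout regions.
    """
    out = []
    for p in p_values:
        for c in c_values:
            out.append(
                steady_state_solve(
                    producer_factory(p), consumer_factory(c),
                    base_medium, primary, secondary, p, **kwargs,
                )
            )
    return out
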