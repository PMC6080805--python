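"""Dynamic-FBA simulation of multi-strain chemostat communities.

The chemostat is a continuous culture: fresh medium flows in and culture
flows out at dilution rate D, so a surviving strain grows at mu = D in steady
state.  Strain biomasses X_s (gDW/l) and extracellular metabolite
concentrations M (mM) follow

    dX_s/dt = (mu_s - D) X_s
    dM/dt   = D (M0 - M) + sum_s J_{M,s} X_s

where J_{M,s} is the net exchange flux of metabolite M by strain s
(positive = excretion, mmol gDW-1 h-1).  The simulation iterates three steps
on a fixed Euler grid (default dt = 0.1 h):

1. per-strain, per-nutrient uptake bounds: the minimum of a Michaelis-Menten
   transport limit Vmax*M/(kM+M) and an availability limit M/(X dt), with the
   pool shared among competing strains by max-min fair water-filling over
   their demands (see :func:`_allocate`; consumption- and biomass-share
   schemes are available as options);
2. one independent FBA per strain, maximizing growth, yielding mu_s and all
   exchange fluxes;
3. the Euler update above, with concentrations clipped at zero.

Strain phenotypes are phenomenological: a producer is forced to excrete its
secondary carbon source at a rate p (a lower bound on the export exchange);
a consumer's uptake of the primary carbon source is capped at c (possibly 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import cobra

from .fba_core import MediumSpec, MetabolicModel, apply_medium

__all__ = [
    "StrainSpec",
    "ChemostatConfig",
    "ChemostatState",
    "Trajectory",
    "uptake_limit",
    "simulate",
]

logger = logging.getLogger(__name__)

#: biomass below this is treated as extinct (gDW/l)
EXTINCTION_THRESHOLD = 1e-9


@dataclass
class StrainSpec:
    """A strain: a metabolic model plus phenomenological flux constraints.

    ``forced_production`` maps export-exchange ids to a minimum excretion
    flux (the producer phenotype p); ``uptake_caps`` maps exchange ids to a
    maximum uptake rate (the consumer phenotype c; 0 forbids uptake).  A
    strain cannot both force export and cap import of the same metabolite.
    """

    name: str
    model: MetabolicModel
    forced_production: Mapping[str, float] = field(default_factory=dict)
    uptake_caps: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = set(self.forced_production) & set(self.uptake_caps)
        if clash:
            raise ValueError(f"forced export and capped import clash: {clash}")
        for rid, v in {**self.forced_production, **self.uptake_caps}.items():
            if v < 0:
                raise ValueError(f"negative rate for {rid}: {v}")


@dataclass
class ChemostatConfig:
    """Chemostat protocol parameters.

    Defaults mirror a glucose-limited chemostat: D = 0.2 h-1, 1 mM glucose
    feed, dt = 0.1 h, at most 1000 h, Vmax = 20 mmol gDW-1 h-1, kM = 0.05 mM,
    steady state declared when the std of every present strain's growth rate
    over 50 consecutive steps falls below 1e-5.
    """

    medium: MediumSpec                      # mineral (carbon-free) base
    feed: Mapping[str, float]               # exchange id -> mM in fresh medium
    D: float = 0.2
    dt: float = 0.1
    t_max: float = 1000.0
    vmax: float = 20.0
    km: float = 0.05
    init_biomass: Mapping[str, float] = field(default_factory=dict)
    introduce_at: Mapping[str, float] = field(default_factory=dict)
    steady_window: int = 50
    steady_tol: float = 1e-5
    track: tuple[str, ...] = ()             # export-only tracked exchanges (e.g. CO2)
    allocation: str = "fair"                # or "consumption" | "biomass"
    init_conc: "Mapping[str, float] | None" = None   # default: the fresh medium

    def __post_init__(self) -> None:
        if self.D <= 0 or self.dt <= 0:
            raise ValueError("D and dt must be positive")
        if self.steady_window < 2:
            raise ValueError("steady_window must be >= 2")
        if self.allocation not in ("fair", "consumption", "biomass"):
            raise ValueError(f"unknown allocation scheme {self.allocation!r}")


@dataclass
class ChemostatState:
    """Snapshot of the chemostat at one time point."""

    t: float
    biomass: dict[str, float]
    concentrations: dict[str, float]
    growth_rates: dict[str, float]
    net_fluxes: dict[str, dict[str, float]]   # strain -> exchange -> J


@dataclass
class Trajectory:
    """Time-ordered chemostat states plus steady-state bookkeeping."""

    states: list[ChemostatState]
    steady_state: bool

    @property
    def final(self) -> ChemostatState:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (t, variable, value) table of the whole trajectory."""
        rows = []
        for st in self.states:
            for s, x in st.biomass.items():
                rows.append((st.t, f"X[{s}]", x))
            for s, mu in st.growth_rates.items():
                rows.append((st.t, f"mu[{s}]", mu))
            for m, conc in st.concentrations.items():
                rows.append((st.t, f"M[{m}]", conc))
        return pd.DataFrame(rows, columns=["t", "variable", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def series(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """(t, value) arrays for one variable key, e.g. ``"X[P]"``."""
        df = self.to_frame()
        sel = df[df.variable == variable]
        return sel.t.to_numpy(), sel.value.to_numpy()


def uptake_limit(
    conc: float, strain_share: float, vmax: float, km: float, dt: float
) -> float:
    """Maximal uptake rate of a nutrient over one time step.

    ``min(vmax*conc/(km+conc), conc/(strain_share*dt))``: the first term is
    Michaelis-Menten transport capacity, the second caps total consumption
    over the step at what is actually present.  ``strain_share`` is the
    availability-weighted biomass competing for this strain's share of the
    pool; with a zero share only the transport limit applies.
    """
    if conc <= 0:
        return 0.0
    transport = vmax * conc / (km + conc)
    denom = strain_share * dt
    if denom <= 0:  # no competing biomass (or an underflowing share)
        return transport
    return min(transport, conc / denom)


class _RunningStrain:
    """Private per-strain runtime state (cobra model copy with medium set)."""

    def __init__(self, spec: StrainSpec, config: ChemostatConfig, dynamic: Sequence[str]):
        self.spec = spec
        self.cm: cobra.Model = spec.model.cmodel.copy()
        apply_medium(self.cm, config.medium.without_carbon())
        self.biomass_rxn = self.cm.reactions.get_by_id(spec.model.biomass_id)
        self.cm.objective = self.biomass_rxn
        self.dynamic = list(dynamic)
        self.exchanges = {rid: self.cm.reactions.get_by_id(rid) for rid in dynamic}
        for rid, p in spec.forced_production.items():
            self.exchanges[rid].lower_bound = p
        self.prev_uptake: dict[str, float] = {rid: 0.0 for rid in dynamic}

    def solve(self, bounds: Mapping[str, float]) -> tuple[float, dict[str, float]]:
        """One FBA with the given per-nutrient uptake bounds.

        Returns (mu, net exchange fluxes).  If the forced-export floor is
        infeasible under this step's uptake bounds (starvation), the floor
        is relaxed to the maximal achievable export - a cell cannot excrete
        substrate it never took up - which keeps the response continuous;
        growth is then typically zero and the strain washes out.  A still
        infeasible LP yields mu = 0 and zero fluxes.
        """
        for rid, rxn in self.exchanges.items():
            forced = self.spec.forced_production.get(rid)
            if forced is not None:
                rxn.lower_bound = forced
                continue  # export floor; no uptake of own product
            # never raise the lower bound above the upper bound (which may be
            # negative for a forced-consumption phenotype)
            rxn.lower_bound = min(-bounds.get(rid, 0.0), rxn.upper_bound)
        mu = self.cm.slim_optimize(error_value=float("nan"))
        if math.isnan(mu) and self.spec.forced_production:
            logger.debug(
                "strain %s cannot meet its export floor; relaxing", self.spec.name
            )
            saved_objective = self.cm.objective
            for rid, forced in self.spec.forced_production.items():
                rxn = self.exchanges[rid]
                rxn.lower_bound = 0.0
                self.cm.objective = rxn
                self.cm.objective_direction = "max"
                achievable = self.cm.slim_optimize(error_value=0.0)
                if math.isnan(achievable):
                    achievable = 0.0
                rxn.lower_bound = min(forced, max(achievable, 0.0) * (1 - 1e-9))
            self.cm.objective = saved_objective
            self.cm.objective_direction = "max"
            mu = self.cm.slim_optimize(error_value=float("nan"))
        if math.isnan(mu):
            logger.debug("FBA infeasible for strain %s", self.spec.name)
            return 0.0, {rid: 0.0 for rid in self.dynamic}
        fluxes = {rid: float(rxn.flux) for rid, rxn in self.exchanges.items()}
        return float(mu), fluxes


#: relative floor added to consumption weights so that a strain that has not
#: yet consumed a nutrient (e.g. a freshly introduced invader) still receives
#: a small share of it
ALLOCATION_FLOOR = 1e-3


def _allocate(
    config: ChemostatConfig,
    strains: list[_RunningStrain],
    present: dict[str, bool],
    X: dict[str, float],
    rid: str,
    conc: float,
) -> dict[str, float]:
    """Per-strain uptake bound (mmol gDW-1 h-1) of nutrient ``rid``.

    Strains that cannot take the nutrient up (cap 0, or it is their own
    forced export) are excluded.  The default ``"fair"`` scheme water-fills
    the pool rate M/dt over per-strain demands min(cap, transport limit)
    with biomass-proportional fair shares: a strain whose demand is below
    its fair share takes its full demand, and the remainder is split among
    the strains that can use it.  Its fixed point reproduces the continuous
    competitive equilibrium (capped consumers unrationed, the uncapped
    strain marginal).  ``"consumption"`` shares the pool by last step's
    realized consumption (with a small floor) and ``"biomass"`` by plain
    biomass shares; both then cap each strain at share*M/(X dt).
    """
    eligible = [
        rs for rs in strains
        if present[rs.spec.name]
        and X[rs.spec.name] > 0
        and rs.spec.uptake_caps.get(rid, 1.0) > 0
        and rid not in rs.spec.forced_production
    ]
    if not eligible:
        return {}
    transport = uptake_limit(conc, 0.0, config.vmax, config.km, config.dt)

    if config.allocation == "fair":
        demand = {
            rs.spec.name: min(rs.spec.uptake_caps.get(rid, math.inf), transport)
            for rs in eligible
        }
        pool = conc / config.dt                      # mM/h available this step
        alloc = {rs.spec.name: 0.0 for rs in eligible}
        active = {rs.spec.name: X[rs.spec.name] for rs in eligible}
        for _ in range(len(eligible)):
            if not active or pool <= 0:
                break
            total_x = sum(active.values())
            fair = {n: x / total_x * pool for n, x in active.items()}
            saturated = [
                n for n in active if fair[n] >= demand[n] * active[n] - 1e-300
            ]
            if not saturated:
                for n in active:
                    alloc[n] += fair[n]
                pool = 0.0
                break
            for n in saturated:
                take = demand[n] * active[n]
                alloc[n] = take
                pool -= take
                del active[n]
        return {n: alloc[n] / X[n] for n in alloc}

    if config.allocation == "consumption":
        floor = ALLOCATION_FLOOR * config.vmax
        weights = {
            rs.spec.name: (rs.prev_uptake[rid] + floor) * X[rs.spec.name]
            for rs in eligible
        }
    else:
        weights = {rs.spec.name: X[rs.spec.name] for rs in eligible}
    total = sum(weights.values())
    if total <= 0:
        weights = {rs.spec.name: X[rs.spec.name] for rs in eligible}
        total = sum(weights.values())
    out = {}
    for rs in eligible:
        n = rs.spec.name
        share = weights[n] / total
        strain_share = X[n] / share if share > 0 else 0.0
        limit = uptake_limit(conc, strain_share, config.vmax, config.km, config.dt)
        cap = rs.spec.uptake_caps.get(rid)
        if cap is not None:
            limit = min(limit, cap)
        out[n] = limit
    return out


def simulate(strains: Sequence[StrainSpec], config: ChemostatConfig) -> Trajectory:
    """Run the chemostat to steady state or ``t_max``.

    Strains are introduced at their ``introduce_at`` times (multiples of dt)
    with their initial biomass.  Steady state is declared once every present
    strain's growth rate has a standard deviation below ``steady_tol`` over
    the last ``steady_window`` steps (checked only after the last
    introduction).  Returns the full trajectory either way.
    """
    if not strains:
        raise ValueError("at least one strain required")
    names = [s.name for s in strains]
    if len(set(names)) != len(names):
        raise ValueError("strain names must be unique")
    for s in strains:
        t_in = config.introduce_at.get(s.name, 0.0)
        if abs(round(t_in / config.dt) * config.dt - t_in) > 1e-9:
            raise ValueError(f"introduce_at[{s.name}] not a multiple of dt")

    dynamic = list(dict.fromkeys(
        list(config.feed)
        + [rid for s in strains for rid in s.forced_production]
        + list(config.track)
    ))
    # track-only metabolites accumulate but are not offered for uptake
    consumable = set(dynamic) - (set(config.track) - set(config.feed))

    runners = [_RunningStrain(s, config, dynamic) for s in strains]
    X = {n: 0.0 for n in names}
    init_conc = config.init_conc or {}
    M = {
        rid: float(init_conc.get(rid, config.feed.get(rid, 0.0)))
        for rid in dynamic
    }
    introduced = {n: False for n in names}
    mu_hist: dict[str, list[float]] = {n: [] for n in names}
    last_intro = max((config.introduce_at.get(n, 0.0) for n in names), default=0.0)

    n_steps = int(round(config.t_max / config.dt))
    states: list[ChemostatState] = []
    steady = False
    t = 0.0
    for step in range(n_steps + 1):
        for rs in runners:
            n = rs.spec.name
            if not introduced[n] and t >= config.introduce_at.get(n, 0.0) - 1e-9:
                X[n] = float(config.init_biomass.get(n, 0.0))
                introduced[n] = True

        present = {n: introduced[n] and X[n] > EXTINCTION_THRESHOLD for n in names}

        # step 1: uptake bounds
        bounds_by_strain: dict[str, dict[str, float]] = {n: {} for n in names}
        for rid in dynamic:
            if rid not in consumable:
                continue
            limits = _allocate(config, runners, present, X, rid, M[rid])
            for rs in runners:
                n = rs.spec.name
                if present[n]:
                    bounds_by_strain[n][rid] = limits.get(n, 0.0)

        # step 2: one FBA per strain
        mus: dict[str, float] = {}
        fluxes: dict[str, dict[str, float]] = {}
        for rs in runners:
            n = rs.spec.name
            if not present[n]:
                mus[n] = 0.0
                fluxes[n] = {rid: 0.0 for rid in dynamic}
                continue
            mu, J = rs.solve(bounds_by_strain.get(n, {}))
            mus[n] = mu
            fluxes[n] = J
            rs.prev_uptake = {rid: max(-J[rid], 0.0) for rid in dynamic}

        states.append(ChemostatState(
            t=t,
            biomass={n: X[n] if introduced[n] else 0.0 for n in names},
            concentrations=dict(M),
            growth_rates=dict(mus),
            net_fluxes={n: dict(fluxes[n]) for n in names},
        ))

        # steady-state check on growth-rate history
        if t >= last_intro:
            for n in names:
                if present[n]:
                    mu_hist[n].append(mus[n])
                else:
                    mu_hist[n].append(0.0)
            window = config.steady_window
            if len(mu_hist[names[0]]) >= window:
                stds = [float(np.std(mu_hist[n][-window:])) for n in names]
                if all(sd < config.steady_tol for sd in stds):
                    steady = True
                    break

        if step == n_steps:
            break

        # step 3: Euler update
        for n in names:
            if introduced[n]:
                X[n] = max(X[n] + (mus[n] - config.D) * X[n] * config.dt, 0.0)
        for rid in dynamic:
            influx = config.D * (config.feed.get(rid, 0.0) - M[rid])
            produced = sum(fluxes[n][rid] * states[-1].biomass[n] for n in names)
            new_M = M[rid] + (influx + produced) * config.dt
            if new_M < 0:
                # an undershoot of order D*M*dt per step is inherent to the
                # availability limit (consumption of the whole pool plus
                # dilution outflow); only larger ones indicate a problem
                if new_M < -1e-3 * (abs(M[rid]) + config.dt):
                    logger.warning(
                        "concentration of %s clipped at 0 (Euler undershoot %.3g)",
                        rid, new_M,
                    )
                new_M = 0.0
            M[rid] = new_M
        t = round(t + config.dt, 10)

    return Trajectory(states=states, steady_state=steady)
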