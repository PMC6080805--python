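"""Small, analytically tractable fixtures for every pipeline stage.

Three generators cover the package's test surface without any downloads:

* :func:`make_toy_universe` - a random pan-reaction universe of transport
  and internal reactions over a handful of nutrients, where viability means
  producing an ATP-like currency metabolite.  Sub-networks are bit-vectors,
  and every verdict (viability, producibility) can be recomputed by an
  independent scipy ``linprog`` oracle on the raw stoichiometric matrix.
* :func:`make_monod_model` - a minimal one-substrate model whose dynamic-FBA
  chemostat has the textbook Monod closed form S* = kM*D/(mu_max - D),
  X* = Y*(S0 - S*).
* :func:`make_crossfeeding_fixture` - a six-metabolite producer/consumer
  system with hand-derivable steady states over the whole (p, c) plane.

Toy stoichiometric coefficients are drawn from {1, 2} so the LPs stay
non-degenerate and hand-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import cobra
import numpy as np
from scipy.optimize import linprog

from .carbon_niche import transport_limit
from .chemostat import ChemostatConfig, StrainSpec
from .fba_core import BIG_BOUND, MediumSpec, MetabolicModel, VIABILITY_EPS
from .netsampler import Universe

__all__ = [
    "ToyUniverseSpec",
    "make_toy_universe",
    "make_monod_model",
    "MonodReference",
    "make_crossfeeding_fixture",
    "CrossfeedingFixture",
    "chain_model",
    "linprog_fba",
    "oracle_is_viable",
    "oracle_can_produce",
    "oracle_blocked_reactions",
]


# ---------------------------------------------------------------------------
# independent LP oracle (scipy route, no cobra/GLPK involved)
# ---------------------------------------------------------------------------

def linprog_fba(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    objective_index: int,
    direction: str = "max",
) -> float | None:
    """Reference FBA by scipy linprog: optimize v[j] s.t. S v = 0, lb<=v<=ub.

    Returns the optimal objective flux, or None if infeasible.  Used as the
    independent oracle against the GLPK-backed implementation.
    """
    r = S.shape[1]
    c = np.zeros(r)
    c[objective_index] = -1.0 if direction == "max" else 1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    if not res.success:
        return None
    return float(res.x[objective_index])


def _masked_bounds(model: MetabolicModel, bits: np.ndarray | None,
                   medium: MediumSpec) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds()
    ids = model.reaction_ids
    exch = set(model.exchange_ids)
    for j, rid in enumerate(ids):
        if rid in exch:
            if rid in medium.unlimited:
                lb[j] = -BIG_BOUND
            elif rid in medium.carbon_sources:
                lb[j] = -medium.carbon_sources[rid]
            elif rid in medium.uptake_caps:
                lb[j] = -medium.uptake_caps[rid]
            else:
                lb[j] = 0.0
    if bits is not None:
        off = ~np.asarray(bits, dtype=bool)
        lb[off] = 0.0
        ub[off] = 0.0
    return lb, ub


def oracle_is_viable(model: MetabolicModel, medium: MediumSpec,
                     bits: np.ndarray | None = None,
                     eps: float = VIABILITY_EPS) -> bool:
    """Viability verdict recomputed from scratch with scipy linprog."""
    S = model.stoichiometric_matrix()
    lb, ub = _masked_bounds(model, bits, medium)
    j = model.reaction_ids.index(model.biomass_id)
    value = linprog_fba(S, lb, ub, j, "max")
    return value is not None and value > eps


def oracle_can_produce(model: MetabolicModel, medium: MediumSpec,
                       primary: str, secondary: str, uptake: float = 10.0,
                       bits: np.ndarray | None = None,
                       eps: float = VIABILITY_EPS) -> float:
    """Production verdict recomputed with scipy linprog (0 if not producible)."""
    S = model.stoichiometric_matrix()
    lb, ub = _masked_bounds(model, bits, medium.without_carbon())
    ids = list(model.reaction_ids)
    jp, js = ids.index(primary), ids.index(secondary)
    jb = ids.index(model.biomass_id)
    lb[jp] = ub[jp] = -uptake
    lb[jb] = max(lb[jb], eps)
    value = linprog_fba(S, lb, ub, js, "max")
    return max(value, 0.0) if value is not None else 0.0


def oracle_blocked_reactions(model: MetabolicModel,
                             open_boundary: set[str] | None = None,
                             eps: float = 1e-6) -> frozenset[str]:
    """Blocked set by brute force: two linprogs (max/min) per reaction."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    open_set = set(open_boundary if open_boundary is not None else model.boundary_ids)
    for j, rid in enumerate(model.reaction_ids):
        if rid in model.boundary_ids:
            if rid in open_set:
                lb[j], ub[j] = -BIG_BOUND, BIG_BOUND
            else:
                lb[j], ub[j] = 0.0, 0.0
    blocked = []
    for j, rid in enumerate(model.reaction_ids):
        vmax = linprog_fba(S, lb, ub, j, "max")
        vmin = linprog_fba(S, lb, ub, j, "min")
        hi = abs(vmax) if vmax is not None else 0.0
        lo = abs(vmin) if vmin is not None else 0.0
        if max(hi, lo) <= eps:
            blocked.append(rid)
    return frozenset(blocked)


# ---------------------------------------------------------------------------
# toy model construction helpers
# ---------------------------------------------------------------------------

def _met(mid: str, carbons: int) -> cobra.Metabolite:
    m = cobra.Metabolite(mid, compartment="c" if not mid.endswith("_e") else "e")
    m.formula = f"C{carbons}" if carbons else ""
    return m


def _reaction(rid: str, stoich: dict[cobra.Metabolite, float],
              lb: float = 0.0, ub: float = BIG_BOUND) -> cobra.Reaction:
    r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
    r.add_metabolites(stoich)
    return r


def chain_model(yield_per_unit: float = 0.1, uptake_cap: float = 10.0) -> tuple[MetabolicModel, MediumSpec]:
    """Linear chain A_e -> A -> B -> biomass with per-unit yield y.

    The biomass optimum under an uptake cap u is exactly y*u - the simplest
    hand-checkable LP in the package.
    """
    a_e, a, b = _met("A_e", 1), _met("A_c", 1), _met("B_c", 1)
    cm = cobra.Model("chain")
    cm.add_metabolites([a_e, a, b])
    inv_y = 1.0 / yield_per_unit
    cm.add_reactions([
        _reaction("EX_A_e", {a_e: -1}, lb=-uptake_cap),
        _reaction("T_A", {a_e: -1, a: 1}),
        _reaction("R_AB", {a: -1, b: 1}),
        _reaction("BIOMASS", {b: -inv_y}),
    ])
    model = MetabolicModel(cm, biomass_id="BIOMASS")
    medium = MediumSpec(carbon_sources={"EX_A_e": uptake_cap})
    return model, medium


# ---------------------------------------------------------------------------
# toy universe
# ---------------------------------------------------------------------------

@dataclass
class ToyUniverseSpec:
    """Recipe for a random toy pan-reaction universe.

    Viability means producing the currency metabolite (an ATP stand-in)
    through the biomass pseudo-reaction.  The generator retries until the
    universe is viable on its designated primary nutrient and admits at
    least one producible secondary.
    """

    n_internal_reactions: int = 10
    n_transport_reactions: int = 5
    n_metabolites: int = 8        # internal metabolites incl. currency
    seed: int = 0
    max_tries: int = 200


def make_toy_universe(spec: ToyUniverseSpec) -> Universe:
    """Random toy universe satisfying the spec's viability guarantees.

    The universe has one exchange + transport reaction per external
    nutrient, random internal conversions with coefficients in {1, 2}, and a
    biomass reaction consuming the currency metabolite.  The returned
    :class:`Universe` carries a viability medium whose sole carbon source is
    the first nutrient (uptake <= 10).
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_tries):
        universe = _build_toy(spec, rng)
        medium = universe.medium
        model = universe.model
        if not oracle_is_viable(model, medium):
            continue
        # require at least one other nutrient to be both growth-sustaining
        # (primary) and producible on the designated primary (secondary)
        primary = next(iter(medium.carbon_sources))
        ok = False
        for rid in model.exchange_ids:
            if rid == primary:
                continue
            alt = medium.without_carbon().with_carbon(rid, 10.0)
            if not oracle_is_viable(model, alt):
                continue
            if oracle_can_produce(model, medium, primary, rid) > VIABILITY_EPS:
                ok = True
                break
        if ok:
            return universe
    raise RuntimeError("could not generate a viable toy universe; adjust spec")


def _build_toy(spec: ToyUniverseSpec, rng: np.random.Generator) -> Universe:
    cm = cobra.Model("toy_universe")
    nutrients = [_met(f"N{i}_e", int(rng.integers(1, 4))) for i in range(spec.n_transport_reactions)]
    internal = [_met(f"M{i}_c", int(rng.integers(1, 4))) for i in range(spec.n_metabolites - 1)]
    currency = _met("ATP_c", 0)
    cm.add_metabolites(nutrients + internal + [currency])
    reactions = []
    for i, nut in enumerate(nutrients):
        reactions.append(_reaction(f"EX_N{i}_e", {nut: -1}, lb=0.0))
        # transport maps the nutrient onto a random internal metabolite
        target = internal[int(rng.integers(len(internal)))]
        reactions.append(_reaction(f"T{i}", {nut: -1, target: 1}, lb=-BIG_BOUND))
    pool = internal + [currency]
    for j in range(spec.n_internal_reactions):
        k_sub = int(rng.integers(1, 3))
        subs = rng.choice(len(internal), size=k_sub, replace=False)
        prods = [p for p in rng.choice(len(pool), size=2, replace=False)
                 if pool[p].id not in {internal[s].id for s in subs}]
        if not prods:
            prods = [len(pool) - 1]  # fall back to the currency
        stoich: dict[cobra.Metabolite, float] = {}
        for s in subs:
            stoich[internal[s]] = -float(rng.integers(1, 3))
        for pi in prods:
            stoich[pool[pi]] = float(rng.integers(1, 3))
        reversible = bool(rng.random() < 0.3)
        reactions.append(
            _reaction(f"R{j}", stoich, lb=-BIG_BOUND if reversible else 0.0)
        )
    reactions.append(_reaction("BIOMASS", {currency: -1}))
    cm.add_reactions(reactions)
    model = MetabolicModel(cm, biomass_id="BIOMASS")
    medium = MediumSpec(carbon_sources={"EX_N0_e": 10.0})
    return Universe(model=model, medium=medium)


def viable_subnetworks_of_size(universe: Universe, n_internal: int) -> list[frozenset[str]]:
    """All internal-reaction subsets of a given size that remain viable.

    Exhaustive enumeration with the linprog oracle; meant for small toy
    universes only (combinatorial in the universe size).
    """
    model = universe.model
    internal = [
        rid for rid in model.reaction_ids
        if rid not in universe.immutable and not rid.startswith("T")
    ]
    keep_always = [rid for rid in model.reaction_ids if rid not in internal]
    index = {rid: i for i, rid in enumerate(model.reaction_ids)}
    out = []
    for combo in combinations(internal, n_internal):
        bits = np.zeros(len(model.reaction_ids), dtype=bool)
        for rid in list(combo) + keep_always:
            bits[index[rid]] = True
        if oracle_is_viable(model, universe.medium, bits):
            out.append(frozenset(combo))
    return out


# ---------------------------------------------------------------------------
# Monod oracle model
# ---------------------------------------------------------------------------

@dataclass
class MonodReference:
    """Closed-form chemostat solution of the Monod toy model."""

    mu_max: float
    km: float
    yield_per_mmol: float   # Y, gDW/mmol

    def steady_state(self, D: float, feed: float) -> tuple[float, float]:
        """(S*, X*): washout (feed, 0) when D >= mu_max or S* > feed."""
        if D >= self.mu_max:
            return feed, 0.0
        s_star = self.km * D / (self.mu_max - D)
        if s_star >= feed:
            return feed, 0.0
        return s_star, self.yield_per_mmol * (feed - s_star)


def make_monod_model(
    mu_max: float = 0.5, km: float = 0.05, yield_per_mmol: float = 0.1
) -> tuple[MetabolicModel, MonodReference]:
    """One-substrate model whose dFBA chemostat follows Monod kinetics.

    FBA gives mu = min(mu_max, Y * uptake); with the transport limit set to
    Vmax = mu_max / Y the uptake bound is Vmax*S/(kM+S), hence
    mu = mu_max * S/(kM+S) below saturation - the Monod law.  Pair the model
    with :meth:`monod_config` to get matching chemostat parameters.
    """
    s_e, s_c = _met("S_e", 1), _met("S_c", 1)
    cm = cobra.Model("monod")
    cm.add_metabolites([s_e, s_c])
    cm.add_reactions([
        _reaction("EX_S_e", {s_e: -1}, lb=0.0),
        _reaction("T_S", {s_e: -1, s_c: 1}),
        _reaction("BIOMASS", {s_c: -1.0 / yield_per_mmol}, ub=mu_max),
    ])
    model = MetabolicModel(cm, biomass_id="BIOMASS")
    return model, MonodReference(mu_max, km, yield_per_mmol)


def monod_config(
    ref: MonodReference, D: float = 0.2, feed: float = 1.0,
    dt: float = 0.1, t_max: float = 400.0, init_biomass: float = 0.01,
) -> ChemostatConfig:
    """Chemostat configuration matching a Monod reference model."""
    return ChemostatConfig(
        medium=MediumSpec(),
        feed={"EX_S_e": feed},
        D=D, dt=dt, t_max=t_max,
        vmax=ref.mu_max / ref.yield_per_mmol, km=ref.km,
        init_biomass={"M": init_biomass},
    )


# ---------------------------------------------------------------------------
# cross-feeding fixture
# ---------------------------------------------------------------------------

@dataclass
class CrossfeedingFixture:
    """A producer/consumer toy system with closed-form steady states.

    The shared model grows on primary S via an efficient route
    (S -> 2 X, ten X per unit growth) or diverts S to the by-product
    (S -> 2 B); B is exportable and consumable (2 B -> X).  Yields:
    alpha_S = 0.2, alpha_B = 0.05 gDW/mmol; producing B costs growth
    (0.1 h-1 per unit flux at fixed uptake).
    """

    model: MetabolicModel
    medium: MediumSpec
    primary: str = "EX_S_e"
    secondary: str = "EX_B_e"
    D: float = 0.2
    feed: float = 1.0
    vmax: float = 20.0
    km: float = 0.05

    def producer(self, p: float) -> StrainSpec:
        return StrainSpec(
            "P", self.model.copy(),
            forced_production={self.secondary: p},
        )

    def consumer(self, c: float = 0.0) -> StrainSpec:
        return StrainSpec("C", self.model.copy(), uptake_caps={self.primary: c})

    def config(self, dt: float = 0.1, t_max: float = 1000.0,
               introduce_consumer_at: float = 50.0,
               init_p: float = 0.01, init_c: float = 0.001) -> ChemostatConfig:
        return ChemostatConfig(
            medium=self.medium,
            feed={self.primary: self.feed},
            D=self.D, dt=dt, t_max=t_max, vmax=self.vmax, km=self.km,
            init_biomass={"P": init_p, "C": init_c},
            introduce_at={"C": introduce_consumer_at},
        )

    # --- closed forms -------------------------------------------------
    def p_max(self, uptake_limit: float | None = None) -> float:
        """Max production at growth D: p_max = 2*u_limit - 10*D."""
        if uptake_limit is None:
            uptake_limit = transport_limit(self.feed, self.vmax, self.km)
        return 2.0 * uptake_limit - 10.0 * self.D

    def reference_steady_state(self, p: float, c: float = 0.0,
                               dt: float = 0.0) -> dict:
        """Hand-derived steady state for production p, consumer cap c.

        Returns {"outcome", "X_P", "X_C", "M1", "M2"}.  ``dt`` > 0 applies
        the discrete-time pool floors of the Euler loop.
        """
        D, vmax, km, S0 = self.D, self.vmax, self.km, self.feed
        u_P = (10.0 * D + p) / 2.0          # producer's required S uptake
        if u_P >= transport_limit(S0, vmax, km):
            return {"outcome": "neither" if c <= 0 else "C_only",
                    "X_P": 0.0, "X_C": 0.0, "M1": S0, "M2": 0.0}
        M1 = km * u_P / (vmax - u_P)
        if dt > 0:
            M1 = max(M1, S0 * D * dt / (1.0 + D * dt))
        g = min(c, vmax * M1 / (km + M1))   # consumer's S uptake at the fp
        if 2.0 * g >= 10.0 * D:
            # consumer persists on the primary alone: producer excluded
            return {"outcome": "C_only", "X_P": 0.0,
                    "X_C": D * (S0 - km * 5 * D / (vmax - 5 * D)) / (5 * D),
                    "M1": km * 5 * D / (vmax - 5 * D), "M2": 0.0}
        u_B = 20.0 * D - 4.0 * g            # consumer's B requirement
        X_P_alone = D * (S0 - M1) / u_P
        if p <= 0:
            return {"outcome": "P_only", "X_P": X_P_alone, "X_C": 0.0,
                    "M1": M1, "M2": 0.0}
        M2 = km * u_B / (vmax - u_B) if u_B < vmax else float("inf")
        M2_ceiling = p * X_P_alone / D
        if M2 >= M2_ceiling:
            return {"outcome": "P_only", "X_P": X_P_alone, "X_C": 0.0,
                    "M1": M1, "M2": M2_ceiling}
        # interior: S and B balances
        def solve(M2_val: float) -> tuple[float, float]:
            a11, a12, b1 = u_P, g, D * (S0 - M1)
            a21, a22, b2 = p, -u_B, D * M2_val
            det = a11 * a22 - a12 * a21
            xp = (b1 * a22 - a12 * b2) / det
            xc = (a11 * b2 - b1 * a21) / det
            return xp, xc
        X_P, X_C = solve(M2)
        if dt > 0:
            M2_floor = p * X_P * dt / (1.0 + D * dt)
            if M2_floor > M2:
                M2 = M2_floor
                X_P, X_C = solve(M2)
        return {"outcome": "both", "X_P": X_P, "X_C": X_C, "M1": M1, "M2": M2}


def make_crossfeeding_fixture(D: float = 0.2, feed: float = 1.0) -> CrossfeedingFixture:
    """Build the six-metabolite cross-feeding toy system."""
    s_e, s_c = _met("S_e", 2), _met("S_c", 2)
    b_e, b_c = _met("B_e", 1), _met("B_c", 1)
    x_c = _met("X_c", 2)
    cm = cobra.Model("crossfeed_toy")
    cm.add_metabolites([s_e, s_c, b_e, b_c, x_c])
    cm.add_reactions([
        _reaction("EX_S_e", {s_e: -1}, lb=0.0),
        _reaction("T_S", {s_e: -1, s_c: 1}),
        _reaction("EX_B_e", {b_e: -1}, lb=0.0),
        _reaction("T_B", {b_c: -1, b_e: 1}, lb=-BIG_BOUND),
        _reaction("R_EFF", {s_c: -1, x_c: 2}),
        _reaction("R_BYP", {s_c: -1, b_c: 2}),
        _reaction("R_CONS", {b_c: -2, x_c: 1}),
        _reaction("BIOMASS", {x_c: -10}),
    ])
    model = MetabolicModel(cm, biomass_id="BIOMASS")
    return CrossfeedingFixture(model=model, medium=MediumSpec(), D=D, feed=feed)
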