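"""Primary/secondary carbon-source enumeration and niche descriptors.

A *primary* carbon source is an exchanged, carbon-containing metabolite that
sustains growth as the sole carbon source of a minimal medium.  A *secondary*
carbon source (relative to some primary) is a primary-capable metabolite that
can additionally be excreted as a by-product while the cell grows on that
primary.  Each (primary, secondary) pair defines a potential cross-feeding
niche, quantified by

* ``p_max``   -- maximal export flux of the secondary compatible with growth
  at the chemostat dilution rate D (beyond it the producer washes out),
* ``alpha``   -- biomass yield of the secondary, the growth rate attainable
  per unit flux of it consumed (alpha = D / u*, with u* the minimal uptake
  sustaining growth at D),
* ``cost``    -- growth-rate loss per unit of secondary exported, used for
  ranking only.

Screen conventions (reconstructed from the published counts): the primary
screen allows uptake of the candidate at up to 10 mmol gDW-1 h-1; the
production screen fixes primary uptake at exactly 10 and requires a biomass
flux above 1e-5; the ``p_max`` screen bounds primary uptake by the
Michaelis-Menten transport limit at the feed concentration,
Vmax*M0/(kM+M0), and leaves CO2 uptake open (CO2 may be refixed, which
matters for highly oxidised products such as formate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .fba_core import (
    BIG_BOUND,
    VIABILITY_EPS,
    MediumSpec,
    MetabolicModel,
    apply_medium,
)

__all__ = [
    "CarbonSourceRecord",
    "NichePair",
    "carbon_candidates",
    "find_primary_sources",
    "can_produce",
    "enumerate_secondary",
    "max_production_rate",
    "biomass_yield",
    "production_cost",
    "enumerate_pairs",
    "transport_limit",
]

logger = logging.getLogger(__name__)

#: default uptake bound of the viability / production screens (mmol gDW-1 h-1)
SCREEN_UPTAKE = 10.0
#: Michaelis-Menten transport parameters shared with the chemostat module
TRANSPORT_VMAX = 20.0
TRANSPORT_KM = 0.05
#: glucose concentration of the reference fresh medium (mM)
FEED_CONC = 1.0
#: chemostat dilution rate (h-1)
DILUTION = 0.2


def transport_limit(conc: float, vmax: float = TRANSPORT_VMAX, km: float = TRANSPORT_KM) -> float:
    """Michaelis-Menten transport bound Vmax*M/(kM+M) at concentration M."""
    if conc <= 0:
        return 0.0
    return vmax * conc / (km + conc)


@dataclass
class CarbonSourceRecord:
    """A primary carbon source and its yield descriptors."""

    exchange_id: str
    metabolite_id: str
    carbon_atoms: int
    is_primary: bool = True
    alpha: float | None = None        # gDW mmol-1
    min_uptake: float | None = None   # u* at growth = D, mmol gDW-1 h-1


@dataclass
class NichePair:
    """A (primary, secondary) carbon-source pair and its descriptors."""

    primary: str
    secondary: str
    p_max: float
    alpha: float | None = None
    alpha_times_pmax: float | None = None
    cost: float | None = None
    coexistence_ok: bool | None = None


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def carbon_candidates(model: MetabolicModel, base_medium: MediumSpec) -> list[str]:
    """Exchange ids of carbon-containing metabolites not in the mineral set."""
    out = []
    for rid in model.exchange_ids:
        if rid in base_medium.unlimited or rid in base_medium.uptake_caps:
            continue
        met = model.exchanged_metabolite(rid)
        if model.carbon_count(met) >= 1:
            out.append(rid)
    return out


def find_primary_sources(
    model: MetabolicModel,
    base_medium: MediumSpec,
    uptake: float = SCREEN_UPTAKE,
    eps: float = VIABILITY_EPS,
    with_yield: bool = False,
    dilution: float = DILUTION,
) -> list[CarbonSourceRecord]:
    """All metabolites viable as sole carbon source under ``base_medium``.

    Each candidate exchange is opened for uptake at up to ``uptake`` while all
    other carbon uptake stays closed; it is kept iff the biomass optimum
    exceeds ``eps``.  With ``with_yield`` the record also carries the biomass
    yield at growth rate ``dilution``.
    """
    if base_medium.carbon_sources:
        raise ValueError("base medium must be carbon-free")
    records: list[CarbonSourceRecord] = []
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        cm.objective = cm.reactions.get_by_id(model.biomass_id)
        for rid in carbon_candidates(model, base_medium):
            rxn = cm.reactions.get_by_id(rid)
            lb = rxn.lower_bound
            rxn.lower_bound = -uptake
            value = cm.slim_optimize(error_value=0.0)
            rxn.lower_bound = lb
            if value > eps:
                records.append(
                    CarbonSourceRecord(
                        exchange_id=rid,
                        metabolite_id=model.exchanged_metabolite(rid),
                        carbon_atoms=model.carbon_count(
                            model.exchanged_metabolite(rid)
                        ),
                    )
                )
    if with_yield:
        for rec in records:
            rec.alpha, rec.min_uptake = biomass_yield(
                model, base_medium, rec.exchange_id, dilution
            )
    return records


def can_produce(
    model: MetabolicModel,
    base_medium: MediumSpec,
    primary: str,
    secondary: str,
    uptake: float = SCREEN_UPTAKE,
    eps: float = VIABILITY_EPS,
) -> float:
    """Maximal export of ``secondary`` while growing on ``primary``.

    Primary uptake is fixed at exactly ``uptake``, the biomass flux is
    required to exceed ``eps``, and the export of ``secondary`` is maximized.
    Returns the optimum (0 means not producible; an infeasible LP also
    returns 0 with a logged note).
    """
    if primary == secondary:
        raise ValueError("secondary must differ from primary")
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        prim = cm.reactions.get_by_id(primary)
        prim.bounds = (-uptake, -uptake)
        bio = cm.reactions.get_by_id(model.biomass_id)
        bio.lower_bound = eps
        cm.objective = cm.reactions.get_by_id(secondary)
        cm.objective_direction = "max"
        value = cm.slim_optimize(error_value=float("nan"))
    if value != value:  # NaN: infeasible
        logger.info("production LP infeasible for %s on %s", secondary, primary)
        return 0.0
    return max(float(value), 0.0)


def enumerate_secondary(
    model: MetabolicModel,
    base_medium: MediumSpec,
    primary: str,
    candidates: Sequence[str] | None = None,
    uptake: float = SCREEN_UPTAKE,
    eps: float = VIABILITY_EPS,
) -> list[str]:
    """All primary-capable metabolites producible as by-products on ``primary``.

    ``candidates`` defaults to the model's primary-source list (a secondary
    carbon source must itself sustain growth).  The output order follows the
    model's exchange ordering and is independent of the candidate order.
    """
    if candidates is None:
        candidates = [
            r.exchange_id for r in find_primary_sources(model, base_medium, uptake)
        ]
    wanted = set(candidates) - {primary}
    out = []
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        prim = cm.reactions.get_by_id(primary)
        prim.bounds = (-uptake, -uptake)
        bio = cm.reactions.get_by_id(model.biomass_id)
        bio.lower_bound = eps
        for rid in model.exchange_ids:
            if rid not in wanted:
                continue
            cm.objective = cm.reactions.get_by_id(rid)
            cm.objective_direction = "max"
            value = cm.slim_optimize(error_value=float("nan"))
            if value == value and value > eps:
                out.append(rid)
    return out


def max_production_rate(
    model: MetabolicModel,
    base_medium: MediumSpec,
    primary: str,
    secondary: str,
    dilution: float = DILUTION,
    uptake_limit: float | None = None,
    co2_open: bool = True,
    eps: float = VIABILITY_EPS,
) -> float:
    """Maximal export of ``secondary`` compatible with growth at ``dilution``.

    Primary uptake is bounded by ``uptake_limit`` (default: the transport
    limit at the reference feed concentration, Vmax*M0/(kM+M0) ~= 19.05);
    growth is fixed at the dilution rate.  Beyond this export rate a producer
    strain washes out of the chemostat.  Returns 0 if infeasible.
    """
    if uptake_limit is None:
        uptake_limit = transport_limit(FEED_CONC)
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        prim = cm.reactions.get_by_id(primary)
        prim.lower_bound = -uptake_limit
        if co2_open and "EX_co2_e" in {r.id for r in cm.exchanges}:
            cm.reactions.EX_co2_e.lower_bound = -BIG_BOUND
        bio = cm.reactions.get_by_id(model.biomass_id)
        bio.bounds = (dilution, dilution)
        cm.objective = cm.reactions.get_by_id(secondary)
        cm.objective_direction = "max"
        value = cm.slim_optimize(error_value=float("nan"))
    if value != value or value < eps:  # NaN: infeasible at growth = D
        return 0.0
    return float(value)


def biomass_yield(
    model: MetabolicModel,
    base_medium: MediumSpec,
    carbon_source: str,
    dilution: float = DILUTION,
) -> tuple[float, float]:
    """Biomass yield alpha of a carbon source and the uptake u* behind it.

    alpha = D / u* where u* is the minimal uptake of the carbon source (as
    sole carbon source) that sustains growth exactly at D.  Returns
    ``(alpha, u_star)``; ``(0, inf)`` if growth at D is infeasible.
    """
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        src = cm.reactions.get_by_id(carbon_source)
        src.lower_bound = -BIG_BOUND
        bio = cm.reactions.get_by_id(model.biomass_id)
        bio.bounds = (dilution, dilution)
        # maximizing the (negative) exchange flux minimizes uptake
        cm.objective = src
        cm.objective_direction = "max"
        value = cm.slim_optimize(error_value=float("nan"))
    if value != value:
        return 0.0, float("inf")
    u_star = max(-float(value), 0.0)
    if u_star <= 0:
        return 0.0, float("inf")
    return dilution / u_star, u_star


def production_cost(
    model: MetabolicModel,
    base_medium: MediumSpec,
    primary: str,
    secondary: str,
    uptake: float = SCREEN_UPTAKE,
    fraction: float = 0.01,
    p_max: float | None = None,
) -> float:
    """Growth-rate loss per unit of secondary exported, near zero export.

    Computed as a secant (mu0 - mu(p)) / p at p = ``fraction`` of the pair's
    maximal production under fixed primary uptake ``uptake``.  Reported for
    ranking; a positive cost means production diverts resources from growth.
    """
    cm = model.cmodel
    with cm:
        apply_medium(cm, base_medium)
        prim = cm.reactions.get_by_id(primary)
        prim.bounds = (-uptake, -uptake)
        bio = cm.reactions.get_by_id(model.biomass_id)
        cm.objective = bio
        mu0 = cm.slim_optimize(error_value=float("nan"))
        if mu0 != mu0 or mu0 <= 0:
            return float("nan")
        if p_max is None:
            sec = cm.reactions.get_by_id(secondary)
            with cm:
                bio.lower_bound = VIABILITY_EPS
                cm.objective = sec
                p_max = cm.slim_optimize(error_value=0.0)
        if not p_max or p_max <= 0:
            return float("nan")
        p = fraction * p_max
        sec = cm.reactions.get_by_id(secondary)
        sec.lower_bound = p
        cm.objective = bio
        mu_p = cm.slim_optimize(error_value=float("nan"))
    if mu_p != mu_p:
        return float("inf")
    return (float(mu0) - float(mu_p)) / p


def enumerate_pairs(
    model: MetabolicModel,
    base_medium: MediumSpec,
    dilution: float = DILUTION,
    primaries: Sequence[str] | None = None,
    uptake: float = SCREEN_UPTAKE,
    with_descriptors: bool = False,
    vmax: float = TRANSPORT_VMAX,
) -> tuple[list[NichePair], dict]:
    """Enumerate all (primary, secondary) cross-feeding pairs of a model.

    Loops every primary carbon source against every other primary-capable
    candidate, keeping pairs whose production screen succeeds.  With
    ``with_descriptors`` each pair also carries p_max, alpha, alpha*p_max and
    cost (slower: three extra LPs per pair).  The coexistence flag is the
    analytical condition for a consumer that cannot take up the primary
    (c = 0): the secondary's u* at D must be within the transport limit.

    Returns the pair list and a Table-1-style summary dict.  For a
    genome-scale model the full loop is an hour-scale batch.
    """
    if primaries is None:
        primaries = [
            r.exchange_id for r in find_primary_sources(model, base_medium, uptake)
        ]
    primaries = list(primaries)
    alpha_cache: dict[str, tuple[float, float]] = {}
    pairs: list[NichePair] = []
    for prim in primaries:
        for sec in enumerate_secondary(
            model, base_medium, prim, candidates=primaries, uptake=uptake
        ):
            pair = NichePair(primary=prim, secondary=sec, p_max=float("nan"))
            if with_descriptors:
                pair.p_max = max_production_rate(
                    model, base_medium, prim, sec, dilution
                )
                if sec not in alpha_cache:
                    alpha_cache[sec] = biomass_yield(model, base_medium, sec, dilution)
                pair.alpha, u_star = alpha_cache[sec]
                pair.alpha_times_pmax = pair.alpha * pair.p_max
                pair.cost = production_cost(model, base_medium, prim, sec, uptake)
                # consumer on the secondary alone persists iff u* <= Vmax
                pair.coexistence_ok = pair.p_max > 0 and u_star <= vmax
            pairs.append(pair)
    summary = {
        "primary_carbon_sources": len(primaries),
        "secondary_carbon_sources_total": len({p.secondary for p in pairs}),
        "pairs": len(pairs),
    }
    return pairs, summary


def pairs_to_frame(pairs: Iterable[NichePair]) -> pd.DataFrame:
    """Tidy table of niche pairs, ready for TSV export."""
    return pd.DataFrame([vars(p) for p in pairs])
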