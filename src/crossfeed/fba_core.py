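"""Constraint-based model handling shared by every pipeline stage.

This module wraps a genome-scale (or toy) stoichiometric model together with
the conventions used throughout the package:

* a *medium* is a set of freely available inorganic nutrients plus explicit
  carbon sources with bounded uptake rates;
* uptake is a negative flux through an exchange reaction internally, while all
  user-facing rates are positive magnitudes;
* growth (and production) fluxes below ``VIABILITY_EPS`` = 1e-5
  mmol gDW-1 h-1 are treated as zero.

The linear programming itself is delegated to cobrapy/optlang (GLPK).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import cobra
import numpy as np
from cobra.flux_analysis import find_blocked_reactions
from cobra.util.array import create_stoichiometric_matrix

__all__ = [
    "VIABILITY_EPS",
    "BIG_BOUND",
    "MediumSpec",
    "FluxSolution",
    "MetabolicModel",
    "load_model",
    "write_model",
    "solve_fba",
    "blocked_reactions",
    "is_viable",
    "ecoli_mineral_medium",
    "bsubtilis_mineral_medium",
    "scerevisiae_mineral_medium",
    "read_bitvector",
    "write_bitvector",
    "write_reaction_index",
]

#: growth/production fluxes below this are considered zero (mmol gDW-1 h-1)
VIABILITY_EPS = 1e-5

#: bound used for "unconstrained" exchange fluxes
BIG_BOUND = 1000.0

# Inorganic nutrients assumed freely available for E. coli minimal media:
# ammonium, calcium, chloride, cobalt, copper, iron (II and III), magnesium,
# manganese, molybdate, nickel, oxygen, phosphate, potassium, protons, sodium,
# sulphate, zinc.  Water is additionally exchanged freely in both directions.
ECOLI_MINERALS = (
    "nh4", "ca2", "cl", "cobalt2", "cu2", "fe2", "fe3", "mg2", "mn2",
    "mobd", "ni2", "o2", "pi", "k", "h", "na1", "so4", "zn2", "h2o",
)

# B. subtilis (iYO844): ammonium, calcium, carbon dioxide, iron, magnesium,
# oxygen, phosphate, potassium, protons, sodium, sulphate; ammonium, phosphate
# and sulphate are capped at 5 mmol gDW-1 h-1.
BSUBTILIS_MINERALS = (
    "ca2", "co2", "fe3", "mg2", "o2", "k", "h", "na1", "h2o",
)
BSUBTILIS_CAPS = {"EX_nh4_e": 5.0, "EX_pi_e": 5.0, "EX_so4_e": 5.0}

# S. cerevisiae (iMM904): ammonium, iron, oxygen, phosphate, potassium,
# protons, sodium, sulphate; oxygen capped at 2 mmol gDW-1 h-1.
SCEREVISIAE_MINERALS = (
    "nh4", "fe2", "pi", "k", "h", "na1", "so4", "h2o",
)
SCEREVISIAE_CAPS = {"EX_o2_e": 2.0}


@dataclass(frozen=True)
class MediumSpec:
    """Chemical environment for an FBA problem.

    Parameters
    ----------
    unlimited:
        Exchange-reaction ids opened for uptake without constraint
        (the mineral set of a minimal medium).
    carbon_sources:
        Exchange-reaction id -> maximal uptake rate (positive,
        mmol gDW-1 h-1).
    uptake_caps:
        Exchange-reaction id -> maximal uptake rate for nutrients that are
        available but rate-limited (e.g. ammonium <= 5 for iYO844).  Caps on
        ids also listed in ``unlimited`` are rejected.
    """

    unlimited: frozenset[str] = frozenset()
    carbon_sources: Mapping[str, float] = field(default_factory=dict)
    uptake_caps: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "unlimited", frozenset(self.unlimited))
        for rid, rate in {**self.carbon_sources, **self.uptake_caps}.items():
            if rate < 0:
                raise ValueError(f"negative uptake rate for {rid}: {rate}")
        if self.unlimited & set(self.uptake_caps):
            raise ValueError("unlimited and capped exchange sets overlap")

    def with_carbon(self, exchange_id: str, rate: float) -> "MediumSpec":
        """Return a copy with ``exchange_id`` as the sole carbon source."""
        return replace(self, carbon_sources={exchange_id: rate})

    def without_carbon(self) -> "MediumSpec":
        return replace(self, carbon_sources={})


@dataclass
class FluxSolution:
    """Outcome of one FBA optimization."""

    objective_value: float
    fluxes: "np.ndarray | None"
    status: str  # "optimal" | "infeasible"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class MetabolicModel:
    """A stoichiometric model plus the package's conventions.

    Wraps a :class:`cobra.Model`, identifying the (unique) biomass reaction
    and the exchange/boundary reactions, and caching per-metabolite carbon
    counts parsed from the chemical formulas.
    """

    def __init__(self, cobra_model: cobra.Model, biomass_id: str | None = None):
        self.cmodel = cobra_model
        self.biomass_id = biomass_id or _find_biomass(cobra_model)
        self.cmodel.objective = self.cmodel.reactions.get_by_id(self.biomass_id)
        # exchange reactions follow the boundary convention: a single
        # external metabolite, no products
        self.exchange_ids: tuple[str, ...] = tuple(
            r.id for r in cobra_model.exchanges
        )
        # the full boundary additionally includes demand/sink reactions
        self.boundary_ids: tuple[str, ...] = tuple(
            r.id for r in cobra_model.boundary
        )
        for rid in self.exchange_ids:
            rxn = cobra_model.reactions.get_by_id(rid)
            if len(rxn.metabolites) != 1:
                raise ValueError(
                    f"exchange reaction {rid} touches {len(rxn.metabolites)} metabolites"
                )
        self._carbon: dict[str, int] = {}
        for met in cobra_model.metabolites:
            try:
                self._carbon[met.id] = int(met.elements.get("C", 0))
            except Exception:
                self._carbon[met.id] = 0

    # -- introspection -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.cmodel.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.cmodel.metabolites)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.cmodel.reactions)

    def carbon_count(self, metabolite_id: str) -> int:
        return self._carbon.get(metabolite_id, 0)

    def exchanged_metabolite(self, exchange_id: str) -> str:
        rxn = self.cmodel.reactions.get_by_id(exchange_id)
        return next(iter(rxn.metabolites)).id

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape (metabolites, reactions), cobra ordering."""
        return create_stoichiometric_matrix(self.cmodel)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.cmodel.reactions])
        ub = np.array([r.upper_bound for r in self.cmodel.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.cmodel.copy(), biomass_id=self.biomass_id)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.cmodel.id or 'unnamed'}: "
            f"{self.n_reactions} reactions, {self.n_metabolites} metabolites, "
            f"{len(self.exchange_ids)} exchanges>"
        )


def _find_biomass(cmodel: cobra.Model) -> str:
    # prefer the current objective if it is a single reaction
    objective_ids = [
        v.name for v in cmodel.objective.variables if not v.name.endswith("_reverse")
        and "_reverse_" not in v.name
    ]
    candidates = [
        r.id for r in cmodel.reactions if "biomass" in r.id.lower()
    ]
    for rid in objective_ids:
        if rid in candidates:
            return rid
    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        raise ValueError("model has no biomass reaction")
    # several biomass-like reactions (e.g. core + wild-type): take the
    # objective one, else fail loudly
    raise ValueError(
        f"ambiguous biomass reaction, candidates: {sorted(candidates)}; "
        "pass biomass_id explicitly"
    )


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def load_model(
    path: str | Path,
    dialect: str | None = None,
    biomass_id: str | None = None,
) -> MetabolicModel:
    """Read an SBML (L3/FBC) or BiGG-style JSON model from ``path``.

    ``dialect`` is ``"sbml"`` or ``"bigg-json"``; inferred from the file
    suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = "bigg-json" if path.suffix == ".json" else "sbml"
    if dialect == "bigg-json":
        cmodel = cobra.io.load_json_model(str(path))
    elif dialect == "sbml":
        cmodel = cobra.io.read_sbml_model(str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return MetabolicModel(cmodel, biomass_id=biomass_id)


def load_bigg_model(name: str, biomass_id: str | None = None) -> MetabolicModel:
    """Load a model bundled with cobrapy by BiGG name (e.g. ``"iJO1366"``)."""
    return MetabolicModel(cobra.io.load_model(name), biomass_id=biomass_id)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as BiGG JSON (.json) or SBML (anything else)."""
    path = Path(path)
    if path.suffix == ".json":
        cobra.io.save_json_model(model.cmodel, str(path))
    else:
        cobra.io.write_sbml_model(model.cmodel, str(path))


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------

def _present(model: MetabolicModel, ids: Iterable[str]) -> frozenset[str]:
    have = set(model.reaction_ids)
    return frozenset(i for i in ids if i in have)


def ecoli_mineral_medium(model: MetabolicModel) -> MediumSpec:
    """Carbon-free mineral medium for E. coli-style models (iJO1366 ids)."""
    return MediumSpec(
        unlimited=_present(model, (f"EX_{m}_e" for m in ECOLI_MINERALS))
    )


def bsubtilis_mineral_medium(model: MetabolicModel) -> MediumSpec:
    return MediumSpec(
        unlimited=_present(model, (f"EX_{m}_e" for m in BSUBTILIS_MINERALS)),
        uptake_caps={
            k: v for k, v in BSUBTILIS_CAPS.items() if k in set(model.reaction_ids)
        },
    )


def scerevisiae_mineral_medium(model: MetabolicModel) -> MediumSpec:
    return MediumSpec(
        unlimited=_present(model, (f"EX_{m}_e" for m in SCEREVISIAE_MINERALS)),
        uptake_caps={
            k: v for k, v in SCEREVISIAE_CAPS.items() if k in set(model.reaction_ids)
        },
    )


def apply_medium(cmodel: cobra.Model, medium: MediumSpec) -> None:
    """Set exchange lower bounds from ``medium`` (in place).

    Uptake of anything not named by the medium is forbidden; export bounds
    are left untouched.
    """
    ids = {r.id for r in cmodel.exchanges}
    for rid in medium.unlimited | set(medium.carbon_sources) | set(medium.uptake_caps):
        if rid not in ids:
            raise KeyError(f"medium names unknown exchange reaction {rid}")
    for rxn in cmodel.exchanges:
        if rxn.id in medium.unlimited:
            lb = -BIG_BOUND
        elif rxn.id in medium.carbon_sources:
            lb = -float(medium.carbon_sources[rxn.id])
        elif rxn.id in medium.uptake_caps:
            lb = -float(medium.uptake_caps[rxn.id])
        else:
            lb = 0.0
        # respect a negative upper bound (forced-consumption phenotypes)
        rxn.lower_bound = min(lb, rxn.upper_bound)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def solve_fba(
    model: MetabolicModel,
    medium: MediumSpec,
    objective: str | None = None,
    direction: str = "max",
    return_fluxes: bool = False,
) -> FluxSolution:
    """Optimize ``objective`` (default: biomass) under ``medium``.

    Returns a :class:`FluxSolution`; an infeasible LP yields
    ``status="infeasible"`` rather than raising.  Only the objective value is
    contractual: the flux vector may be degenerate.
    """
    objective = objective or model.biomass_id
    cm = model.cmodel
    with cm:
        apply_medium(cm, medium)
        cm.objective = cm.reactions.get_by_id(objective)
        cm.objective_direction = direction
        if return_fluxes:
            try:
                sol = cm.optimize()
            except Exception:
                return FluxSolution(math.nan, None, "infeasible")
            if sol.status != "optimal":
                return FluxSolution(math.nan, None, "infeasible")
            return FluxSolution(
                float(sol.objective_value), sol.fluxes.to_numpy(), "optimal"
            )
        value = cm.slim_optimize(error_value=float("nan"))
        if math.isnan(value):
            return FluxSolution(math.nan, None, "infeasible")
        return FluxSolution(float(value), None, "optimal")


def is_viable(
    model: MetabolicModel, medium: MediumSpec, eps: float = VIABILITY_EPS
) -> bool:
    """True iff maximal biomass production under ``medium`` exceeds ``eps``."""
    sol = solve_fba(model, medium)
    return sol.optimal and sol.objective_value > eps


def blocked_reactions(
    model: MetabolicModel,
    open_boundary: Iterable[str] | None = None,
    zero_cutoff: float = 1e-6,
) -> frozenset[str]:
    """Unconditionally blocked reactions.

    A reaction is unconditionally blocked if it cannot carry a flux larger
    than ``zero_cutoff`` in either direction when every boundary reaction in
    ``open_boundary`` (default: all of them) is unbounded in both directions.
    Determined by flux-variability analysis with a zero objective.
    """
    open_set = set(open_boundary if open_boundary is not None else model.boundary_ids)
    unknown = open_set - set(model.boundary_ids)
    if unknown:
        raise KeyError(f"not boundary reactions: {sorted(unknown)}")
    cm = model.cmodel
    with cm:
        for rxn in cm.boundary:
            if rxn.id in open_set:
                rxn.bounds = (-BIG_BOUND, BIG_BOUND)
            else:
                rxn.bounds = (0.0, 0.0)
        blocked = find_blocked_reactions(
            cm, open_exchanges=False, zero_cutoff=zero_cutoff
        )
    return frozenset(blocked)


# ---------------------------------------------------------------------------
# presence/absence bit-vectors over a reaction universe
# ---------------------------------------------------------------------------

def write_bitvector(path: str | Path, bits: np.ndarray) -> None:
    """Write a network as one line of 0/1 characters in universe order."""
    bits = np.asarray(bits).astype(int)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bit-vector entries must be 0 or 1")
    Path(path).write_text("".join(map(str, bits.tolist())) + "\n")


def read_bitvector(path: str | Path, expected_length: int | None = None) -> np.ndarray:
    text = Path(path).read_text().strip()
    if set(text) - {"0", "1"}:
        raise ValueError(f"{path}: not a 0/1 bit-vector")
    bits = np.frombuffer(text.encode(), dtype=np.uint8) - ord("0")
    bits = bits.astype(bool)
    if expected_length is not None and bits.size != expected_length:
        raise ValueError(
            f"{path}: expected {expected_length} bits, found {bits.size}"
        )
    return bits


def write_reaction_index(path: str | Path, model: MetabolicModel) -> None:
    """Sidecar documenting the universe ordering of a bit-vector set."""
    lines = [f"{i}\t{rid}" for i, rid in enumerate(model.reaction_ids)]
    Path(path).write_text("\n".join(lines) + "\n")
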