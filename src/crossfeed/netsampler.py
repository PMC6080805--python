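"""MCMC sampling of random viable metabolic networks from a pan-reaction universe.

A metabolic network is represented as a presence/absence bit-vector over the
reaction universe (e.g. a pan-metabolic network).  Starting from a seed
network that is viable on a reference carbon source (glucose), the sampler
performs *reaction swaps*: delete one uniformly random present reaction, add
one uniformly random absent one, and accept the swap iff the network remains
viable.  Network size is conserved either way.  After a sufficiently long
burn-in of accepted swaps the reaction complement is effectively random
beyond what viability requires.

Exchange reactions (the permeable boundary) and a protected set of reactions
essential for growth on the reference carbon source are never swapped; only
viability verdicts - never quantitative fluxes - are reported for sampled
networks, since sampled reaction combinations may contain thermodynamically
spurious cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .carbon_niche import enumerate_secondary, find_primary_sources
from .fba_core import (
    VIABILITY_EPS,
    MediumSpec,
    MetabolicModel,
    apply_medium,
)

__all__ = [
    "Universe",
    "WalkConfig",
    "SampledNetwork",
    "essential_reactions",
    "seed_network",
    "run_walks",
    "sample_statistics",
    "subnetwork_model",
]


@dataclass
class Universe:
    """A pan-reaction universe: the sampling space for random networks.

    ``medium`` is the viability medium (reference carbon source plus
    minerals); ``protected`` are reactions never deleted (defaults to the
    single-deletion essential set on the viability medium, recomputed from
    the supplied universe).
    """

    model: MetabolicModel
    medium: MediumSpec
    protected: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = set(self.model.reaction_ids)
        missing = set(self.protected) - ids
        if missing:
            raise ValueError(f"protected reactions not in universe: {missing}")

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return self.model.reaction_ids

    @property
    def immutable(self) -> frozenset[str]:
        """Reactions never swapped: boundary, biomass, and the protected set."""
        return frozenset(self.model.boundary_ids) | {self.model.biomass_id} | self.protected


@dataclass
class WalkConfig:
    """Parameters of one batch of MCMC walks."""

    network_size: int
    burn_in: int = 5000          # accepted swaps per walk
    n_walks: int = 1
    seed: int = 0
    max_attempts: int | None = None   # safety cap on attempted swaps

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class SampledNetwork:
    """A sampled network: bit-vector over the universe ordering + provenance."""

    bits: np.ndarray
    walk_id: int
    seed: int
    accepted: int = 0
    rejected: int = 0

    @property
    def size(self) -> int:
        return int(self.bits.sum())

    def reaction_ids(self, universe: Universe) -> list[str]:
        ids = universe.reaction_ids
        return [ids[i] for i in np.flatnonzero(self.bits)]


class _Sampler:
    """Maintains the current network on the universe model by bound-masking.

    Absent reactions have their bounds forced to (0, 0); present reactions
    keep the universe bounds.  This avoids structural model edits, so a
    viability check is a single warm-started LP.
    """

    def __init__(self, universe: Universe):
        self.universe = universe
        cm = universe.model.cmodel
        self._rxns = list(cm.reactions)
        self._index = {r.id: i for i, r in enumerate(self._rxns)}
        self._pristine = [r.bounds for r in self._rxns]
        apply_medium(cm, universe.medium)
        # universe bounds with the viability medium applied
        self._orig_bounds = [r.bounds for r in self._rxns]
        cm.objective = cm.reactions.get_by_id(universe.model.biomass_id)
        self.immutable_idx = np.array(
            sorted(self._index[rid] for rid in universe.immutable), dtype=int
        )
        self.bits = np.ones(len(self._rxns), dtype=bool)

    def set_bits(self, bits: np.ndarray) -> None:
        for i in np.flatnonzero(self.bits != bits):
            self._apply(i, bool(bits[i]))
        self.bits = bits.copy()

    def _apply(self, i: int, present: bool) -> None:
        self._rxns[i].bounds = self._orig_bounds[i] if present else (0.0, 0.0)

    def viable(self) -> bool:
        cm = self.universe.model.cmodel
        mu = cm.slim_optimize(error_value=0.0)
        return mu > VIABILITY_EPS

    def restore(self) -> None:
        """Undo all masking and medium changes on the shared universe model."""
        for rxn, bounds in zip(self._rxns, self._pristine):
            rxn.bounds = bounds
        self.bits = np.ones(len(self._rxns), dtype=bool)


def essential_reactions(universe_model: MetabolicModel, medium: MediumSpec,
                        candidates: Sequence[str] | None = None) -> frozenset[str]:
    """Single-deletion essential reactions on ``medium``.

    A reaction is essential if closing it alone drops the biomass optimum
    below the viability threshold.  Boundary reactions and the biomass
    reaction are excluded from the candidate set.
    """
    cm = universe_model.cmodel
    skip = set(universe_model.boundary_ids) | {universe_model.biomass_id}
    if candidates is None:
        candidates = [r for r in universe_model.reaction_ids if r not in skip]
    out = []
    with cm:
        apply_medium(cm, medium)
        cm.objective = cm.reactions.get_by_id(universe_model.biomass_id)
        for rid in candidates:
            rxn = cm.reactions.get_by_id(rid)
            saved = rxn.bounds
            rxn.bounds = (0.0, 0.0)
            mu = cm.slim_optimize(error_value=0.0)
            rxn.bounds = saved
            if mu <= VIABILITY_EPS:
                out.append(rid)
    return frozenset(out)


def seed_network(universe: Universe, size: int, rng: np.random.Generator) -> SampledNetwork:
    """Viable seed network: the FBA-active core plus a random fill to ``size``.

    FBA is run on the full universe under the viability medium; every
    reaction with non-zero flux is included (which guarantees viability), the
    boundary/biomass/protected reactions are always included, and the
    remainder is drawn uniformly at random from the other universe reactions.
    """
    model = universe.model
    n = len(model.reaction_ids)
    if not 0 < size <= n:
        raise ValueError(f"size must be in 1..{n}")
    cm = model.cmodel
    with cm:
        apply_medium(cm, universe.medium)
        cm.objective = cm.reactions.get_by_id(model.biomass_id)
        sol = cm.optimize()
        if sol.status != "optimal" or sol.objective_value <= VIABILITY_EPS:
            raise ValueError("universe is not viable on its viability medium")
        active = {rid for rid, v in sol.fluxes.items() if abs(v) > 1e-9}
    core = active | set(universe.immutable)
    index = {rid: i for i, rid in enumerate(model.reaction_ids)}
    bits = np.zeros(n, dtype=bool)
    bits[[index[rid] for rid in core]] = True
    if bits.sum() > size:
        raise ValueError(
            f"active core ({int(bits.sum())} reactions) exceeds requested size {size}"
        )
    fill = rng.choice(np.flatnonzero(~bits), size=size - int(bits.sum()), replace=False)
    bits[fill] = True
    return SampledNetwork(bits=bits, walk_id=-1, seed=-1)


def _swap_step(sampler: _Sampler, rng: np.random.Generator) -> bool:
    """One reaction swap on the sampler's current network; True if accepted."""
    bits = sampler.bits
    deletable = np.flatnonzero(bits)
    deletable = deletable[~np.isin(deletable, sampler.immutable_idx)]
    addable = np.flatnonzero(~bits)
    if deletable.size == 0 or addable.size == 0:
        return False
    out = int(rng.choice(deletable))
    inn = int(rng.choice(addable))
    sampler._apply(out, False)
    sampler._apply(inn, True)
    if sampler.viable():
        sampler.bits[out] = False
        sampler.bits[inn] = True
        return True
    sampler._apply(out, True)
    sampler._apply(inn, False)
    return False


def run_walks(universe: Universe, config: WalkConfig) -> list[SampledNetwork]:
    """Independent MCMC walks, each ending after ``burn_in`` accepted swaps.

    Each walk derives its RNG from (seed, walk id), so results are
    reproducible per walk and walks decorrelate.  The full-scale protocol
    (500 walks of 5000 accepted swaps at genome-scale network size) uses the
    same entry point with larger numbers.
    """
    out: list[SampledNetwork] = []
    sampler = _Sampler(universe)
    try:
        for walk in range(config.n_walks):
            rng = np.random.default_rng([config.seed, walk])
            net = seed_network(universe, config.network_size, rng)
            sampler.set_bits(net.bits)
            accepted = rejected = 0
            cap = config.max_attempts or max(1000, 200 * config.burn_in)
            attempts = 0
            while accepted < config.burn_in and attempts < cap:
                attempts += 1
                if _swap_step(sampler, rng):
                    accepted += 1
                else:
                    rejected += 1
            out.append(SampledNetwork(
                bits=sampler.bits.copy(), walk_id=walk, seed=config.seed,
                accepted=accepted, rejected=rejected,
            ))
    finally:
        sampler.restore()
    return out


def subnetwork_model(universe: Universe, bits: np.ndarray):
    """Context manager exposing the universe restricted to ``bits``.

    Usage::

        with subnetwork_model(universe, net.bits) as sub:
            find_primary_sources(sub, medium)
    """
    return _SubnetworkContext(universe, bits)


class _SubnetworkContext:
    def __init__(self, universe: Universe, bits: np.ndarray):
        self.universe = universe
        self.bits = np.asarray(bits, dtype=bool)

    def __enter__(self) -> MetabolicModel:
        cm = self.universe.model.cmodel
        self._saved = []
        for i, rid in enumerate(self.universe.reaction_ids):
            if not self.bits[i]:
                rxn = cm.reactions.get_by_id(rid)
                self._saved.append((rxn, rxn.bounds))
                rxn.bounds = (0.0, 0.0)
        return self.universe.model

    def __exit__(self, *exc) -> None:
        for rxn, bounds in self._saved:
            rxn.bounds = bounds


def sample_statistics(
    networks: Sequence[SampledNetwork],
    universe: Universe,
    primary_reference: str | None = None,
    uptake: float = 10.0,
) -> dict:
    """Niche statistics of a network sample.

    Per network: number of primary carbon sources (among the permeable
    candidates), number of secondary carbon sources producible on the
    reference primary (default: the first carbon source of the viability
    medium), and the number of (primary, secondary) pairs.  Pooled: union
    counts and the per-secondary production-fraction ranking (fraction of
    networks that produce each secondary on the reference primary, ranked
    in decreasing order).
    """
    medium = universe.medium.without_carbon()
    if primary_reference is None:
        primary_reference = next(iter(universe.medium.carbon_sources))
    per_network = []
    union_primaries: set[str] = set()
    union_secondaries: set[str] = set()
    union_pairs: set[tuple[str, str]] = set()
    produced_by: dict[str, int] = {}
    for net in networks:
        with subnetwork_model(universe, net.bits) as sub:
            primaries = [r.exchange_id for r in find_primary_sources(sub, medium, uptake)]
            secondaries = enumerate_secondary(
                sub, medium, primary_reference, candidates=primaries, uptake=uptake
            ) if primary_reference in primaries else []
            pairs = set()
            for prim in primaries:
                for sec in enumerate_secondary(
                    sub, medium, prim, candidates=primaries, uptake=uptake
                ):
                    pairs.add((prim, sec))
        union_primaries.update(primaries)
        union_secondaries.update(s for _, s in pairs)
        union_pairs.update(pairs)
        for sec in secondaries:
            produced_by[sec] = produced_by.get(sec, 0) + 1
        per_network.append({
            "walk_id": net.walk_id,
            "n_primaries": len(primaries),
            "n_secondaries_on_reference": len(secondaries),
            "n_pairs": len(pairs),
        })
    n = max(len(networks), 1)
    ranking = sorted(
        ((sec, cnt / n) for sec, cnt in produced_by.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return {
        "per_network": per_network,
        "union_primaries": sorted(union_primaries),
        "union_secondaries": sorted(union_secondaries),
        "union_pairs": sorted(union_pairs),
        "production_fraction_ranking": ranking,
    }
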