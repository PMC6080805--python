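"""MCMC reaction-swap sampling of viable networks on the toy universe."""

import numpy as np
import pytest

import crossfeed as cf
from crossfeed.netsampler import _Sampler, _swap_step, subnetwork_model
from crossfeed.synthetic_data import (
    oracle_can_produce,
    oracle_is_viable,
)


def test_essential_reactions_match_single_deletion_oracle(toy_universe):
    """Essentiality equals per-reaction deletion viability by linprog."""
    model, medium = toy_universe.model, toy_universe.medium
    ess = cf.essential_reactions(model, medium)
    index = {rid: i for i, rid in enumerate(model.reaction_ids)}
    skip = set(model.boundary_ids) | {model.biomass_id}
    for rid in model.reaction_ids:
        if rid in skip:
            continue
        bits = np.ones(model.n_reactions, dtype=bool)
        bits[index[rid]] = False
        assert (rid in ess) == (not oracle_is_viable(model, medium, bits))


def test_seed_network_contains_active_core_and_is_viable(protected_toy_universe):
    """Seeds include every FBA-active reaction, hit the size, and are viable."""
    uni = protected_toy_universe
    rng = np.random.default_rng(0)
    size = uni.model.n_reactions - 3
    net = cf.seed_network(uni, size, rng)
    assert net.size == size
    assert oracle_is_viable(uni.model, uni.medium, net.bits)
    index = {rid: i for i, rid in enumerate(uni.model.reaction_ids)}
    for rid in uni.immutable:
        assert net.bits[index[rid]]


def test_seed_network_full_size_is_the_universe(protected_toy_universe):
    uni = protected_toy_universe
    net = cf.seed_network(uni, uni.model.n_reactions, np.random.default_rng(1))
    assert net.bits.all()


def test_swap_acceptance_equals_viability_oracle(protected_toy_universe):
    """Each proposed swap is accepted iff the proposal is viable (linprog)."""
    uni = protected_toy_universe
    rng = np.random.default_rng(3)
    sampler = _Sampler(uni)
    try:
        net = cf.seed_network(uni, uni.model.n_reactions - 3, rng)
        sampler.set_bits(net.bits)
        immutable = set(sampler.immutable_idx.tolist())
        for _ in range(60):
            before = sampler.bits.copy()
            # snapshot the RNG so the proposal (out, in) can be replayed
            state = rng.bit_generator.state
            accepted = _swap_step(sampler, rng)
            replay = np.random.default_rng()
            replay.bit_generator.state = state
            deletable = np.flatnonzero(before)
            deletable = deletable[~np.isin(deletable, sampler.immutable_idx)]
            addable = np.flatnonzero(~before)
            out = int(replay.choice(deletable))
            inn = int(replay.choice(addable))
            proposal = before.copy()
            proposal[out] = False
            proposal[inn] = True
            assert accepted == oracle_is_viable(uni.model, uni.medium, proposal)
            after_expected = proposal if accepted else before
            assert (sampler.bits == after_expected).all()
            assert sampler.bits.sum() == before.sum()   # size conserved
    finally:
        sampler.restore()


def test_walks_are_reproducible_and_seed_sensitive(protected_toy_universe):
    uni = protected_toy_universe
    cfgA = cf.WalkConfig(network_size=uni.model.n_reactions - 3,
                         burn_in=30, n_walks=3, seed=11)
    a1 = cf.run_walks(uni, cfgA)
    a2 = cf.run_walks(uni, cfgA)
    for x, y in zip(a1, a2):
        assert (x.bits == y.bits).all()
    b = cf.run_walks(uni, cf.WalkConfig(
        network_size=uni.model.n_reactions - 3, burn_in=30, n_walks=3, seed=12))
    assert any((x.bits != y.bits).any() for x, y in zip(a1, b))


def test_zero_burnin_returns_seed_networks(protected_toy_universe):
    uni = protected_toy_universe
    size = uni.model.n_reactions - 3
    nets = cf.run_walks(uni, cf.WalkConfig(network_size=size, burn_in=0,
                                           n_walks=2, seed=5))
    for walk, net in enumerate(nets):
        expected = cf.seed_network(uni, size, np.random.default_rng([5, walk]))
        assert (net.bits == expected.bits).all()
        assert net.accepted == 0


def test_samples_are_viable_sized_and_share_immutable_core(protected_toy_universe):
    uni = protected_toy_universe
    size = uni.model.n_reactions - 3
    nets = cf.run_walks(uni, cf.WalkConfig(network_size=size, burn_in=40,
                                           n_walks=6, seed=2))
    index = {rid: i for i, rid in enumerate(uni.model.reaction_ids)}
    core = [index[rid] for rid in uni.immutable]
    for net in nets:
        assert net.size == size
        assert oracle_is_viable(uni.model, uni.medium, net.bits)
        assert net.bits[core].all()


def test_memory_of_the_seed_decays_with_burn_in(protected_toy_universe):
    """Jaccard similarity to the seed (over swappable reactions) decreases."""
    uni = protected_toy_universe
    size = uni.model.n_reactions - 3
    index = {rid: i for i, rid in enumerate(uni.model.reaction_ids)}
    swappable = np.array([
        i for rid, i in index.items() if rid not in uni.immutable
    ])

    def mean_jaccard(burn_in):
        sims = []
        for walk, net in enumerate(cf.run_walks(uni, cf.WalkConfig(
                network_size=size, burn_in=burn_in, n_walks=12, seed=21))):
            seed = cf.seed_network(uni, size, np.random.default_rng([21, walk]))
            a = net.bits[swappable]
            b = seed.bits[swappable]
            sims.append((a & b).sum() / max((a | b).sum(), 1))
        return float(np.mean(sims))

    assert mean_jaccard(40) < mean_jaccard(2)


def test_sample_statistics_match_bruteforce(protected_toy_universe):
    """Per-network niche counts equal direct oracle recomputation."""
    uni = protected_toy_universe
    size = uni.model.n_reactions - 2
    nets = cf.run_walks(uni, cf.WalkConfig(network_size=size, burn_in=20,
                                           n_walks=4, seed=9))
    stats = cf.sample_statistics(nets, uni)
    base = uni.medium.without_carbon()
    reference = next(iter(uni.medium.carbon_sources))
    for net, row in zip(nets, stats["per_network"]):
        prims = [
            rid for rid in cf.carbon_candidates(uni.model, base)
            if oracle_is_viable(uni.model, base.with_carbon(rid, 10.0), net.bits)
        ]
        pairs = {
            (p, s)
            for p in prims for s in prims if s != p
            and oracle_can_produce(uni.model, uni.medium, p, s, bits=net.bits) > 1e-5
        }
        assert row["n_primaries"] == len(prims)
        assert row["n_pairs"] == len(pairs)
        expected_sec = {s for (p, s) in pairs if p == reference}
        assert row["n_secondaries_on_reference"] == len(expected_sec)
    assert stats["production_fraction_ranking"] == sorted(
        stats["production_fraction_ranking"], key=lambda kv: (-kv[1], kv[0])
    )


def test_empty_sample_gives_empty_statistics(protected_toy_universe):
    stats = cf.sample_statistics([], protected_toy_universe)
    assert stats["per_network"] == []
    assert stats["union_pairs"] == []


def test_bitvector_files_roundtrip_with_index(tmp_path, protected_toy_universe):
    """Sampled networks serialize to the one-line 0/1 format plus a sidecar."""
    uni = protected_toy_universe
    nets = cf.run_walks(uni, cf.WalkConfig(
        network_size=uni.model.n_reactions - 3, burn_in=10, n_walks=2, seed=4))
    cf.write_reaction_index(tmp_path / "universe_index.tsv", uni.model)
    for net in nets:
        path = tmp_path / f"network_{net.walk_id}.txt"
        cf.write_bitvector(path, net.bits)
        assert (cf.read_bitvector(path, uni.model.n_reactions) == net.bits).all()
    index_lines = (tmp_path / "universe_index.tsv").read_text().splitlines()
    assert len(index_lines) == uni.model.n_reactions
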