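"""Model I/O, FBA, and blocked-reaction analysis against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crossfeed as cf
from crossfeed.fba_core import MediumSpec, apply_medium
from crossfeed.synthetic_data import (
    linprog_fba,
    oracle_blocked_reactions,
    oracle_is_viable,
)


@pytest.mark.parametrize("y,cap", [(0.1, 10.0), (0.25, 4.0), (0.5, 7.0)])
def test_chain_model_fba_optimum_is_yield_times_uptake(y, cap):
    """A -> B -> biomass chain: the LP optimum is exactly y * uptake cap."""
    model, medium = cf.chain_model(y, cap)
    sol = cf.solve_fba(model, medium)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(y * cap, rel=1e-9)


def test_no_carbon_means_no_growth(toy_universe):
    """With every carbon exchange closed the biomass optimum is zero."""
    empty = toy_universe.medium.without_carbon()
    sol = cf.solve_fba(toy_universe.model, empty)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    assert not cf.is_viable(toy_universe.model, empty)


def test_fba_objective_matches_scipy_linprog(toy_universe):
    """GLPK-backed FBA equals an independent scipy-linprog solve of the same LP."""
    model, medium = toy_universe.model, toy_universe.medium
    sol = cf.solve_fba(model, medium)
    cm = model.cmodel
    with cm:
        apply_medium(cm, medium)
        lb, ub = model.bounds()
    j = model.reaction_ids.index(model.biomass_id)
    expected = linprog_fba(model.stoichiometric_matrix(), lb, ub, j, "max")
    assert sol.objective_value == pytest.approx(expected, rel=1e-6, abs=1e-9)


def test_optimal_flux_vector_is_steady_state_and_within_bounds(toy_universe):
    """S.v = 0 (to 1e-6) and l <= v <= u hold for every optimal solution."""
    model, medium = toy_universe.model, toy_universe.medium
    sol = cf.solve_fba(model, medium, return_fluxes=True)
    assert sol.optimal
    S = model.stoichiometric_matrix()
    assert np.abs(S @ sol.fluxes).max() <= 1e-6
    cm = model.cmodel
    with cm:
        apply_medium(cm, medium)
        lb, ub = model.bounds()
    assert (sol.fluxes >= lb - 1e-9).all()
    assert (sol.fluxes <= ub + 1e-9).all()


def test_repeated_solves_are_deterministic(toy_universe):
    """The objective value of the same LP is reproducible to 1e-9 relative."""
    values = {
        cf.solve_fba(toy_universe.model, toy_universe.medium).objective_value
        for _ in range(5)
    }
    assert max(values) - min(values) <= 1e-9 * max(abs(v) for v in values)


def test_infeasible_lp_reports_status_not_exception():
    """An over-constrained model returns status='infeasible'."""
    model, medium = cf.chain_model(0.1, 10.0)
    model.cmodel.reactions.BIOMASS.lower_bound = 5.0  # needs uptake 50 > cap
    sol = cf.solve_fba(model, medium)
    assert not sol.optimal
    assert sol.status == "infeasible"


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_blocked_reactions_equal_two_lp_oracle(seed):
    """FVA-based blocked set equals the per-reaction max/min linprog oracle."""
    uni = cf.make_toy_universe(cf.ToyUniverseSpec(seed=seed))
    assert cf.blocked_reactions(uni.model) == oracle_blocked_reactions(uni.model)


def test_dead_end_metabolite_blocks_its_reaction():
    """A reaction feeding a dead-end metabolite cannot carry flux."""
    import cobra

    model, _ = cf.chain_model(0.1, 10.0)
    cm = model.cmodel
    dead = cobra.Metabolite("DEAD_c", compartment="c")
    rxn = cobra.Reaction("R_DEAD", lower_bound=0.0, upper_bound=1000.0)
    rxn.add_metabolites({cm.metabolites.B_c: -1, dead: 1})
    cm.add_reactions([rxn])
    model2 = cf.MetabolicModel(cm, biomass_id="BIOMASS")
    blocked = cf.blocked_reactions(model2)
    assert "R_DEAD" in blocked
    assert blocked == oracle_blocked_reactions(model2)


def test_opening_more_exchanges_never_increases_blocked_set(toy_universe):
    """Blocked reactions are monotone in the permitted boundary set."""
    model = toy_universe.model
    all_boundary = list(model.boundary_ids)
    partial = cf.blocked_reactions(model, open_boundary=all_boundary[:2])
    full = cf.blocked_reactions(model, open_boundary=all_boundary)
    assert full <= partial


def test_viability_matches_oracle_on_random_subnetworks(toy_universe):
    """GLPK and linprog agree on viability of random reaction subsets."""
    model, medium = toy_universe.model, toy_universe.medium
    rng = np.random.default_rng(7)
    n = model.n_reactions
    keep = [model.reaction_ids.index(r) for r in model.boundary_ids]
    keep.append(model.reaction_ids.index(model.biomass_id))
    from crossfeed.netsampler import subnetwork_model

    for _ in range(8):
        bits = rng.random(n) < 0.7
        bits[keep] = True
        with subnetwork_model(toy_universe, bits) as sub:
            ours = cf.is_viable(sub, medium)
        assert ours == oracle_is_viable(model, medium, bits)


def test_model_roundtrip_json_and_sbml(tmp_path, toy_universe):
    """Writing and re-loading a toy model preserves S, bounds, and ids."""
    model = toy_universe.model
    for name in ("toy.json", "toy.xml"):
        path = tmp_path / name
        cf.write_model(model, path)
        again = cf.load_model(path)
        assert sorted(again.reaction_ids) == sorted(model.reaction_ids)
        assert again.n_metabolites == model.n_metabolites
        if name.endswith(".json"):  # JSON preserves ordering exactly
            np.testing.assert_allclose(
                again.stoichiometric_matrix(), model.stoichiometric_matrix()
            )
            assert again.bounds()[0].tolist() == model.bounds()[0].tolist()


@settings(deadline=None, max_examples=25)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=200))
def test_bitvector_roundtrip(tmp_path_factory, bits):
    """Presence/absence vectors survive the one-line text format."""
    path = tmp_path_factory.mktemp("bits") / "net.txt"
    arr = np.array(bits, dtype=bool)
    cf.write_bitvector(path, arr)
    assert (cf.read_bitvector(path, len(bits)) == arr).all()


def test_medium_validation():
    with pytest.raises(ValueError):
        MediumSpec(carbon_sources={"EX_A_e": -1.0})
    with pytest.raises(ValueError):
        MediumSpec(unlimited={"EX_A_e"}, uptake_caps={"EX_A_e": 5.0})
    model, _ = cf.chain_model()
    with pytest.raises(KeyError):
        cf.solve_fba(model, MediumSpec(carbon_sources={"EX_missing_e": 1.0}))
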