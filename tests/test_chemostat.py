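"""Dynamic-FBA chemostat: uptake limits, mass balance, and steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crossfeed as cf
from crossfeed.chemostat import uptake_limit


class TestUptakeLimit:
    def test_saturation_reaches_vmax(self):
        assert uptake_limit(1e9, 0.0, 20.0, 0.05, 0.1) == pytest.approx(20.0)

    def test_half_saturation(self):
        """At M = kM the transport term is Vmax/2."""
        assert uptake_limit(0.05, 1e-9, 20.0, 0.05, 0.1) == pytest.approx(10.0)

    def test_availability_part_binds_when_scarce(self):
        """M=0.001, X=1, dt=0.1: availability 0.01 beats transport ~0.39."""
        assert uptake_limit(0.001, 1.0, 20.0, 0.05, 0.1) == pytest.approx(0.01)

    def test_zero_concentration_gives_zero(self):
        assert uptake_limit(0.0, 1.0, 20.0, 0.05, 0.1) == 0.0

    def test_zero_biomass_gives_transport_only(self):
        got = uptake_limit(1.0, 0.0, 20.0, 0.05, 0.1)
        assert got == pytest.approx(20.0 / 1.05)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(0, 100), st.floats(0, 10), st.floats(0.01, 50),
        st.floats(1e-4, 1), st.floats(1e-3, 1),
    )
    def test_bounded_and_monotone(self, conc, share, vmax, km, dt):
        """0 <= limit <= Vmax, and the limit never decreases with more nutrient."""
        lim = uptake_limit(conc, share, vmax, km, dt)
        assert 0 <= lim <= vmax + 1e-12
        assert uptake_limit(2 * conc, share, vmax, km, dt) >= lim - 1e-12


def test_concentrations_relax_to_feed_without_consumers(monod):
    """With no strain present, M(t) = M0 + (M(0)-M0) e^{-Dt} up to Euler error."""
    model, ref = monod
    cfg = cf.monod_config(ref, D=0.2, feed=1.0, dt=0.1, t_max=20.0)
    cfg.init_conc = {"EX_S_e": 0.2}
    cfg.introduce_at = {"M": 1000.0}  # never within the horizon
    traj = cf.simulate([cf.StrainSpec("M", model)], cfg)
    t, m = traj.series("M[EX_S_e]")
    expected = 1.0 + (0.2 - 1.0) * np.exp(-0.2 * t)
    assert np.abs(m - expected).max() < 0.01


def test_monod_steady_state_matches_closed_form(monod):
    """S* = kM D/(mu_max - D), X* = Y (S0 - S*) within 2% at dt = 0.1."""
    model, ref = monod
    s_star, x_star = ref.steady_state(D=0.2, feed=1.0)
    traj = cf.simulate([cf.StrainSpec("M", model)], cf.monod_config(ref, dt=0.1))
    fin = traj.final
    assert traj.steady_state
    assert fin.biomass["M"] == pytest.approx(x_star, rel=0.02)
    assert fin.concentrations["EX_S_e"] == pytest.approx(s_star, rel=0.02)


def test_monod_trajectory_converges_to_ode_reference(monod):
    """The Euler dFBA trajectory approaches the Monod ODE as dt shrinks."""
    from scipy.integrate import solve_ivp

    model, ref = monod
    D, S0 = 0.2, 1.0

    def ode(t, y):
        X, S = y
        mu = ref.mu_max * max(S, 0.0) / (ref.km + max(S, 0.0))
        return [(mu - D) * X, D * (S0 - S) - mu / ref.yield_per_mmol * X]

    horizon = 40.0
    sol = solve_ivp(ode, (0, horizon), [0.01, S0], rtol=1e-10, atol=1e-12,
                    dense_output=True)
    errs = []
    for dt in (0.1, 0.05):
        cfg = cf.monod_config(ref, dt=dt, t_max=horizon)
        cfg.steady_tol = 0.0  # integrate the full horizon
        traj = cf.simulate([cf.StrainSpec("M", model)], cfg)
        t, x = traj.series("X[M]")
        errs.append(np.abs(x - sol.sol(t)[0]).max())
    assert errs[0] < 0.05 * 0.0966  # within 5% of X* even at dt = 0.1
    assert errs[1] < 0.75 * errs[0]  # first-order convergence


def test_monod_washout_when_dilution_exceeds_mu_max(monod):
    """D >= mu_max: the closed form gives X* = 0 and the culture washes out."""
    model, ref = monod
    assert ref.steady_state(D=0.6, feed=1.0) == (1.0, 0.0)
    cfg = cf.monod_config(ref, D=0.6, t_max=60.0)
    traj = cf.simulate([cf.StrainSpec("M", model)], cfg)
    fin = traj.final
    # biomass follows the washout exponential at the feed-limited growth rate
    mu_feed = ref.mu_max * 1.0 / (ref.km + 1.0)
    assert fin.biomass["M"] < 1e-3
    assert fin.biomass["M"] == pytest.approx(
        0.01 * math.exp((mu_feed - 0.6) * fin.t), rel=0.2
    )


def test_per_step_mass_balance_identity(crossfeed_fixture):
    """Delta M equals [D(M0-M) + sum_s J X] dt exactly at every recorded step."""
    fx = crossfeed_fixture
    cfg = fx.config(dt=0.1, t_max=30.0)
    traj = cf.simulate([fx.producer(2.0), fx.consumer(0.0)], cfg)
    feed = {fx.primary: fx.feed, fx.secondary: 0.0}
    for before, after in zip(traj.states[:-1], traj.states[1:]):
        for rid in (fx.primary, fx.secondary):
            rhs = cfg.D * (feed[rid] - before.concentrations[rid])
            rhs += sum(
                before.net_fluxes[n][rid] * before.biomass[n]
                for n in before.biomass
            )
            predicted = before.concentrations[rid] + rhs * cfg.dt
            assert after.concentrations[rid] == pytest.approx(
                max(predicted, 0.0), abs=1e-12
            )


def test_consumption_never_exceeds_availability(crossfeed_fixture):
    """Total uptake of a nutrient over one step is at most the standing pool."""
    fx = crossfeed_fixture
    cfg = fx.config(dt=0.1, t_max=120.0)
    traj = cf.simulate([fx.producer(2.0), fx.consumer(0.5)], cfg)
    for st_ in traj.states:
        for rid in (fx.primary, fx.secondary):
            consumed = sum(
                max(-st_.net_fluxes[n][rid], 0.0) * st_.biomass[n]
                for n in st_.biomass
            ) * cfg.dt
            assert consumed <= st_.concentrations[rid] + 1e-9


def test_surviving_strains_grow_at_dilution_rate(crossfeed_fixture):
    """At steady state every surviving strain's mu equals D within 1e-4."""
    fx = crossfeed_fixture
    traj = cf.simulate([fx.producer(2.0), fx.consumer(0.0)], fx.config(dt=0.1))
    assert traj.steady_state
    for n, mu in traj.final.growth_rates.items():
        assert traj.final.biomass[n] > 1e-3
        assert mu == pytest.approx(fx.D, abs=1e-4)


@pytest.mark.parametrize("vmax,km", [(15.0, 0.05), (25.0, 0.05), (20.0, 0.02), (20.0, 0.1)])
def test_steady_state_insensitive_to_transport_parameters(crossfeed_fixture, vmax, km):
    """Vmax and kM shape the transient, not the steady state (<=1% relative)."""
    fx = crossfeed_fixture
    base = cf.simulate([fx.producer(5.0), fx.consumer(0.0)], fx.config(dt=0.1)).final
    cfg = fx.config(dt=0.1)
    cfg.vmax, cfg.km = vmax, km
    alt = cf.simulate([fx.producer(5.0), fx.consumer(0.0)], cfg).final
    for n in ("P", "C"):
        assert alt.biomass[n] == pytest.approx(base.biomass[n], rel=0.01)


def test_steady_state_insensitive_to_dt_halving(crossfeed_fixture):
    """Halving dt shifts steady biomasses only by the O(D*dt) pool floor.

    The producer is exact to ~1%; the consumer additionally feels the
    secondary-pool floor (concentration ~ production*dt), giving a combined
    shift of up to ~2% at dt = 0.1 -> 0.05, in line with the discrete
    equilibrium's O(D*dt) bias."""
    fx = crossfeed_fixture
    a = cf.simulate([fx.producer(5.0), fx.consumer(0.0)], fx.config(dt=0.1)).final
    b = cf.simulate([fx.producer(5.0), fx.consumer(0.0)], fx.config(dt=0.05)).final
    assert b.biomass["P"] == pytest.approx(a.biomass["P"], rel=0.01)
    assert b.biomass["C"] == pytest.approx(a.biomass["C"], rel=0.02)
    # and each dt matches its own predicted discrete equilibrium tightly
    for dt, fin in ((0.1, a), (0.05, b)):
        ref = fx.reference_steady_state(5.0, 0.0, dt=dt)
        assert fin.biomass["P"] == pytest.approx(ref["X_P"], rel=1e-3)
        assert fin.biomass["C"] == pytest.approx(ref["X_C"], rel=1e-3)


def test_steady_state_independent_of_initial_conditions(crossfeed_fixture):
    """Initial biomasses and the consumer's introduction time do not matter."""
    fx = crossfeed_fixture
    ref = cf.simulate([fx.producer(2.0), fx.consumer(0.0)], fx.config(dt=0.1)).final
    alt_cfg = fx.config(dt=0.1, introduce_consumer_at=20.0, init_p=0.002, init_c=0.02)
    alt = cf.simulate([fx.producer(2.0), fx.consumer(0.0)], alt_cfg).final
    for n in ("P", "C"):
        assert alt.biomass[n] == pytest.approx(ref.biomass[n], rel=0.005)


def test_forced_production_above_pmax_washes_producer_out(crossfeed_fixture):
    """A producer forced beyond p_max cannot reach mu = D and is diluted away."""
    fx = crossfeed_fixture
    p_over = fx.p_max() + 1.0
    traj = cf.simulate(
        [fx.producer(p_over), fx.consumer(0.0)], fx.config(dt=0.1, t_max=300.0)
    )
    assert traj.final.biomass["P"] < 1e-6
    assert traj.final.biomass["C"] < 1e-6  # nothing left to feed on


@pytest.mark.parametrize("c", [0.0, 0.25, 0.5])
def test_consumer_nutrient_blend_trades_off_along_growth_isocline(crossfeed_fixture, c):
    """Capping primary uptake and forcing secondary consumption are two
    parametrizations of the same steady state: at mu = D the consumer's
    glucose uptake g and by-product uptake u_B satisfy the stoichiometric
    trade-off 2g + u_B/2 = 10 D, so raising one lowers the other by the
    equivalent amount and only the blend matters."""
    fx = crossfeed_fixture
    fin = cf.simulate([fx.producer(2.0), fx.consumer(c)], fx.config(dt=0.1)).final
    g = -fin.net_fluxes["C"][fx.primary]
    u_b = -fin.net_fluxes["C"][fx.secondary]
    assert g == pytest.approx(c, abs=1e-6)          # the cap binds
    assert 2 * g + u_b / 2 == pytest.approx(10 * fx.D, rel=1e-3)


def test_trajectory_export_roundtrip(tmp_path, monod):
    """The tidy TSV writer stores every (t, variable, value) triple."""
    import pandas as pd

    model, ref = monod
    traj = cf.simulate([cf.StrainSpec("M", model)], cf.monod_config(ref, t_max=5.0))
    path = tmp_path / "traj.tsv"
    traj.write_tsv(path)
    df = pd.read_csv(path, sep="\t")
    assert set(df.columns) == {"t", "variable", "value"}
    assert len(df) == len(traj.to_frame())
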