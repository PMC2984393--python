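import numpy as np
import pytest
from scipy.integrate import solve_ivp

from labeldyn.labeling import LabelModel, isotopomer_flux
from labeldyn.network import ParameterSet, build_network, integrate_to_steady_state

from _oracles import condensation_toy_derivatives, pdh_toy_derivatives


class TestIsotopomerFlux:
    def test_direct_substitution(self):
        assert isotopomer_flux(1.0, 0.2, 2.0) == pytest.approx(0.1)

    def test_zero_isotopomer(self):
        assert isotopomer_flux(1.0, 0.0, 2.0) == 0.0

    def test_conservation_over_pool(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 8)
        total = x.sum()
        flux = sum(isotopomer_flux(0.7, xi, total) for xi in x)
        assert flux == pytest.approx(0.7)

    def test_empty_pool_with_flux_raises(self):
        with pytest.raises(ValueError):
            isotopomer_flux(1.0, 0.0, 0.0)


@pytest.fixture()
def pdh_toy_model(pdh_toy):
    p = ParameterSet({"v_v0": 1.0, "vmax_pdh": 3.0, "vmax_efflux": 2.5},
                     free=())
    state = integrate_to_steady_state(pdh_toy, p, c0=np.array([1.0, 1.0]))
    assert state.steady
    return LabelModel(pdh_toy, state)


class TestPdhToyDerivatives:
    """The worked decarboxylation example, row by row."""

    def test_matches_hand_coded_table_on_random_states(self, pdh_toy_model):
        m = pdh_toy_model
        c_pyr = m.totals["pyr"]
        c_accoa = m.totals["accoa"]
        v0 = 1.0
        rng = np.random.default_rng(3)
        for _ in range(10):
            x_pyr = rng.uniform(0.0, 1.0, 8)
            x_pyr *= c_pyr / x_pyr.sum()
            x_accoa = rng.uniform(0.0, 1.0, 4)
            x_accoa *= c_accoa / x_accoa.sum()
            x = np.concatenate([x_pyr, x_accoa])
            dx = m.rhs(0.0, x)
            d_pyr, d_accoa = pdh_toy_derivatives(x_pyr, x_accoa, v0,
                                                 c_pyr, c_accoa)
            assert np.allclose(dx[:8], d_pyr, atol=1e-12, rtol=0)
            assert np.allclose(dx[8:], d_accoa, atol=1e-12, rtol=0)

    def test_specific_rows(self, pdh_toy_model):
        """D_111 = v0 - u_111; D_11 = u_111 + u_011; D_01 = u_101 + u_001 - u_01."""
        m = pdh_toy_model
        c_pyr, c_accoa = m.totals["pyr"], m.totals["accoa"]
        rng = np.random.default_rng(4)
        x_pyr = rng.uniform(0.1, 1.0, 8)
        x_pyr *= c_pyr / x_pyr.sum()
        x_accoa = rng.uniform(0.1, 1.0, 4)
        x_accoa *= c_accoa / x_accoa.sum()
        dx = m.rhs(0.0, np.concatenate([x_pyr, x_accoa]))
        u = 1.0 * x_pyr / c_pyr
        u_acc = 1.0 * x_accoa / c_accoa
        assert dx[0b111] == pytest.approx(1.0 - u[0b111], abs=1e-12)
        assert dx[8 + 0b11] == pytest.approx(u[0b111] + u[0b011] - u_acc[0b11],
                                             abs=1e-12)
        assert dx[8 + 0b01] == pytest.approx(u[0b101] + u[0b001] - u_acc[0b01],
                                             abs=1e-12)

    def test_unlabelled_state_stays_unlabelled_without_labelled_input(
            self, pdh_toy_config):
        config = dict(pdh_toy_config)
        config["reactions"] = [dict(r) for r in config["reactions"]]
        config["reactions"][0]["labeling"] = "000"
        net = build_network(config)
        p = ParameterSet({"v_v0": 1.0, "vmax_pdh": 3.0, "vmax_efflux": 2.5},
                         free=())
        state = integrate_to_steady_state(net, p, c0=np.array([1.0, 1.0]))
        m = LabelModel(net, state)
        dx = m.rhs(0.0, m.initial_state())
        labelled = np.ones(m.n_states, dtype=bool)
        labelled[m.offsets["pyr"]] = False
        labelled[m.offsets["accoa"]] = False
        assert np.allclose(dx[labelled], 0.0, atol=1e-14)


class TestPdhToyDynamics:
    def test_washout_closed_form(self, pdh_toy_model):
        """Labelled pyruvate fraction follows 1 - exp(-v0 t / C_pyr)."""
        m = pdh_toy_model
        c_pyr = m.totals["pyr"]
        traj = m.simulate(6.0 * c_pyr, n_out=13, rtol=1e-10, atol=1e-13)
        for it, t in enumerate(traj.times):
            frac = traj.pool("pyr", it)[0b111] / c_pyr
            assert frac == pytest.approx(1.0 - np.exp(-t / c_pyr), abs=1e-6)

    def test_t_end_zero_returns_initial_state(self, pdh_toy_model):
        traj = pdh_toy_model.simulate(0.0)
        assert np.allclose(traj.states[0], pdh_toy_model.initial_state())

    def test_isotopic_steady_state_pushes_input_through_carbon_map(
            self, pdh_toy_model):
        """At isotopic steady state accoa m2 equals the pyr '11x' input share."""
        m = pdh_toy_model
        traj = m.simulate(400.0, n_out=5)
        accoa_mid = traj.mid("accoa")
        assert accoa_mid[2] == pytest.approx(1.0, abs=1e-4)

    def test_label_conservation_by_quadrature(self, pdh_toy_model):
        """d/dt(total 13C) = labelled input - labelled efflux - labelled CO2."""
        m = pdh_toy_model
        traj = m.simulate(5.0, n_out=201, rtol=1e-10, atol=1e-13)
        bits_pyr = np.array([bin(i).count("1") for i in range(8)])
        bits_acc = np.array([bin(i).count("1") for i in range(4)])
        label = (traj.states[:, :8] @ bits_pyr + traj.states[:, 8:] @ bits_acc)
        efflux = (traj.states[:, 8:] @ bits_acc) / m.totals["accoa"] * 1.0
        # decarboxylation releases carbon 1 of pyruvate (codes with bit 3 set)
        leading = np.array([1.0 if i & 0b100 else 0.0 for i in range(8)])
        co2 = (traj.states[:, :8] @ leading) / m.totals["pyr"] * 1.0
        influx = np.full_like(traj.times, 3.0 * 1.0)
        gained = np.trapezoid(influx - efflux - co2, traj.times)
        assert label[-1] - label[0] == pytest.approx(gained, rel=1e-3)


class TestCondensationToy:
    """1C + 1C -> 2C condensation against a fully hand-written ODE."""

    @pytest.fixture()
    def toy(self):
        config = {
            "metabolites": [{"name": "a", "carbons": 1},
                            {"name": "b", "carbons": 1},
                            {"name": "c", "carbons": 2}],
            "reactions": [
                {"name": "in_a", "kind": "const", "product": "a",
                 "labeling": "1", "map": {"a": "0"}},
                {"name": "in_b", "kind": "const", "product": "b",
                 "labeling": "0", "map": {"b": "0"}},
                {"name": "cond", "kind": "mm_bi", "substrates": ["a", "b"],
                 "product": "c", "km": {"a": 0.5, "b": 0.5},
                 "map": {"a": "x", "b": "y", "c": "xy"}},
                {"name": "out", "kind": "mm", "substrate": "c", "km": 0.5,
                 "map": {"c": "xy"}},
            ],
        }
        net = build_network(config)
        p = ParameterSet({"v_in_a": 0.4, "v_in_b": 0.4, "vmax_cond": 2.0,
                          "vmax_out": 1.5}, free=())
        state = integrate_to_steady_state(net, p, c0=np.ones(3))
        assert state.steady
        return net, state

    def test_derivatives_match_hand_ode(self, toy):
        net, state = toy
        m = LabelModel(net, state)
        u_cond = state.flux(net, "cond")
        u_out = state.flux(net, "out")
        rng = np.random.default_rng(5)
        for _ in range(10):
            x_a = rng.uniform(0.1, 1, 2)
            x_a *= m.totals["a"] / x_a.sum()
            x_b = rng.uniform(0.1, 1, 2)
            x_b *= m.totals["b"] / x_b.sum()
            x_c = rng.uniform(0.1, 1, 4)
            x_c *= m.totals["c"] / x_c.sum()
            dx = m.rhs(0.0, np.concatenate([x_a, x_b, x_c]))
            d_a, d_b, d_c = condensation_toy_derivatives(
                x_a, x_b, x_c, 0.4, 0.4, u_cond, u_out, label_a=1.0)
            assert np.allclose(dx, np.concatenate([d_a, d_b, d_c]),
                               atol=1e-12)

    def test_trajectory_matches_hand_ode(self, toy):
        net, state = toy
        m = LabelModel(net, state)
        u_cond = state.flux(net, "cond")
        u_out = state.flux(net, "out")
        x0 = m.initial_state()

        def hand_rhs(_t, x):
            d_a, d_b, d_c = condensation_toy_derivatives(
                x[:2], x[2:4], x[4:], 0.4, 0.4, u_cond, u_out, label_a=1.0)
            return np.concatenate([d_a, d_b, d_c])

        t_eval = np.linspace(0, 30, 7)
        ref = solve_ivp(hand_rhs, (0, 30), x0, t_eval=t_eval, method="BDF",
                        rtol=1e-10, atol=1e-12)
        traj = m.simulate(30.0, n_out=7, rtol=1e-10, atol=1e-12)
        assert np.allclose(traj.states.T, ref.y, atol=1e-7)


class TestFullModelConsistency:
    def test_sum_consistency_check(self, trajectory):
        """Per-pool isotopomer sums track the kinetic totals to 1e-4."""
        assert trajectory.accurate
        assert max(trajectory.sum_errors.values()) < 1e-4

    def test_emitted_mids_are_normalised(self, trajectory, label_model):
        for m in label_model.pools:
            mid = trajectory.mid(m.name)
            assert abs(mid.sum() - 1.0) < 1e-10

    def test_all_states_nonnegative(self, trajectory):
        assert trajectory.states.min() > -1e-10
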