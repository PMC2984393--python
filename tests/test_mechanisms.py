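import numpy as np
import pytest

from labeldyn.mechanisms import (decompose_aldolase, decompose_reversible,
                                 decompose_transaldolase,
                                 decompose_transketolase)

from _oracles import gillespie_aldolase, pingpong_event_rates


class TestDecomposeReversible:
    def test_definition(self):
        ex = decompose_reversible(2.0, 0.5)
        assert ex.forward["net"] == 2.0
        assert ex.reverse["net"] == 0.5
        assert ex.net("net") == pytest.approx(1.5)

    def test_equilibrium_still_exchanges(self):
        ex = decompose_reversible(1.0, 1.0)
        assert ex.net("net") == 0.0
        assert ex.forward["net"] == ex.reverse["net"] == 1.0

    def test_irreversible(self):
        assert decompose_reversible(1.0, 0.0).reverse["net"] == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            decompose_reversible(-1.0, 0.0)


ALD_CONC = {"fbp": 1.2, "g3p": 0.6, "dhap": 0.8}


class TestAldolase:
    def test_irreversible_limit(self):
        k = {"k1": 2.0, "km1": 0.0, "k2": 3.0, "km2": 0.0, "k3": 5.0,
             "km3": 0.0}
        ex = decompose_aldolase(k, ALD_CONC)
        assert ex.reverse["ald"] == 0.0
        assert ex.exchange["ald_fbp_g3p"] == 0.0
        assert ex.forward["ald"] > 0

    def test_half_exchange_zero_without_return_step(self):
        # km2 = 0: the complex can never re-form e-fbp from a pool g3p
        k = {"k1": 2.0, "km1": 1.0, "k2": 3.0, "km2": 0.0, "k3": 5.0,
             "km3": 1.0}
        assert decompose_aldolase(k, ALD_CONC).exchange["ald_fbp_g3p"] == 0.0

    def test_equilibrium_exchange(self):
        # constants/concentrations chosen so the QSSA net rate vanishes
        k = {"k1": 1.0, "km1": 1.0, "k2": 1.0, "km2": 1.0, "k3": 1.0,
             "km3": 1.0}
        c = {"fbp": 1.0, "g3p": 1.0, "dhap": 1.0}
        ex = decompose_aldolase(k, c)
        assert ex.net("ald") == pytest.approx(0.0, abs=1e-12)
        assert ex.forward["ald"] == pytest.approx(ex.reverse["ald"])
        assert ex.forward["ald"] > 0
        assert ex.exchange["ald_fbp_g3p"] > 0

    def test_net_flux_identity_random_draws(self):
        """u_f - u_r equals the elementary-step QSSA net rate."""
        rng = np.random.default_rng(7)
        from labeldyn.mechanisms import _aldolase_enzyme_state
        for _ in range(25):
            k = {n: float(rng.uniform(0.05, 8.0))
                 for n in ("k1", "km1", "k2", "km2", "k3", "km3")}
            c = {n: float(rng.uniform(0.05, 3.0))
                 for n in ("fbp", "g3p", "dhap")}
            e, c1, c2 = _aldolase_enzyme_state(k, c["fbp"], c["g3p"],
                                               c["dhap"], 1.0)
            net_qssa = k["k3"] * c2 - k["km3"] * e * c["dhap"]
            ex = decompose_aldolase(k, c)
            assert ex.net("ald") == pytest.approx(net_qssa, rel=1e-9, abs=1e-12)
            assert ex.forward["ald"] >= 0
            assert ex.reverse["ald"] >= 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_against_marked_molecule_simulation(self, seed):
        """Analytic u_f, u_r, u_e match a stochastic single-enzyme run."""
        rng = np.random.default_rng(seed)
        k = {n: float(rng.uniform(0.5, 4.0))
             for n in ("k1", "km1", "k2", "km2", "k3", "km3")}
        c = {n: float(rng.uniform(0.3, 2.0)) for n in ("fbp", "g3p", "dhap")}
        ex = decompose_aldolase(k, c)
        sim = gillespie_aldolase(k, c, n_sojourns=2_000_000, seed=seed)
        for key, ana in (("u_f", ex.forward["ald"]),
                         ("u_r", ex.reverse["ald"]),
                         ("u_e", ex.exchange["ald_fbp_g3p"])):
            assert sim[key] == pytest.approx(ana, rel=0.01), key


TK_CONC = {"x5p": 0.8, "r5p": 0.5, "f6p": 1.1, "g3p": 0.4, "s7p": 0.3,
           "e4p": 0.2}
TK_K = {"kx": 1.5, "kmx": 0.8, "kf": 0.6, "kmf": 1.2, "ks": 0.9, "kms": 0.7}


class TestTransketolase:
    def test_channel_nets_sum_to_cycle_nets(self):
        ex = decompose_transketolase(TK_K, TK_CONC)
        # net x5p consumption through its channel = tk1 net - tk2 net
        a_x = ex.forward["tk1"] + ex.reverse["tk2"] + ex.exchange["tk_x5p_g3p"]
        b_x = ex.reverse["tk1"] + ex.forward["tk2"] + ex.exchange["tk_x5p_g3p"]
        assert a_x - b_x == pytest.approx(ex.net("tk1") - ex.net("tk2"))

    def test_absent_channel_zeroes_its_cycles(self):
        c = dict(TK_CONC, x5p=0.0, g3p=0.0)
        ex = decompose_transketolase(TK_K, c)
        assert ex.forward["tk1"] == ex.reverse["tk1"] == 0.0
        assert ex.forward["tk2"] == ex.reverse["tk2"] == 0.0
        assert ex.exchange["tk_x5p_g3p"] == 0.0
        assert ex.forward["tk3"] > 0          # other cycle keeps running

    def test_detailed_balance_gives_zero_nets_positive_exchanges(self):
        k = {"kx": 1.0, "kmx": 2.0, "kf": 1.0, "kmf": 0.5, "ks": 2.0,
             "kms": 1.0}
        c = {"x5p": 1.0, "g3p": 0.5, "f6p": 0.5, "e4p": 1.0, "s7p": 0.5,
             "r5p": 1.0}
        ex = decompose_transketolase(k, c)
        for cyc in ("tk1", "tk2", "tk3"):
            assert ex.net(cyc) == pytest.approx(0.0, abs=1e-12)
        for val in ex.exchange.values():
            assert val > 0

    @pytest.mark.parametrize("seed", [11, 12])
    def test_against_marked_molecule_simulation(self, seed):
        rng = np.random.default_rng(seed)
        k = {n: float(rng.uniform(0.4, 3.0)) for n in TK_K}
        c = {n: float(rng.uniform(0.3, 2.0)) for n in TK_CONC}
        ex = decompose_transketolase(k, c)
        entries = np.array([k["kx"] * c["x5p"], k["kf"] * c["f6p"],
                            k["ks"] * c["s7p"]])
        exits = np.array([k["kmx"] * c["g3p"], k["kmf"] * c["e4p"],
                          k["kms"] * c["r5p"]])
        # the enzyme splits between its two states; propensities per state
        # are the same, so the sojourn chain uses raw channel propensities
        sim = pingpong_event_rates(entries, exits, 6_000_000, seed)
        expect = {("tk1", "f"): sim[0, 2], ("tk1", "r"): sim[2, 0],
                  ("tk2", "f"): sim[1, 0], ("tk2", "r"): sim[0, 1],
                  ("tk3", "f"): sim[1, 2], ("tk3", "r"): sim[2, 1]}
        for (cyc, d), measured in expect.items():
            ana = ex.forward[cyc] if d == "f" else ex.reverse[cyc]
            assert measured == pytest.approx(ana, rel=0.01), (cyc, d)
        assert sim[0, 0] == pytest.approx(ex.exchange["tk_x5p_g3p"], rel=0.01)
        assert sim[1, 1] == pytest.approx(ex.exchange["tk_f6p_e4p"], rel=0.01)
        assert sim[2, 2] == pytest.approx(ex.exchange["tk_s7p_r5p"], rel=0.01)


class TestTransaldolase:
    def test_irreversible_limit_kills_half_exchanges(self):
        k = {"kf": 1.0, "kmf": 0.0, "ks": 0.0, "kms": 1.0}
        c = {"f6p": 1.0, "g3p": 1.0, "s7p": 1.0, "e4p": 1.0}
        ex = decompose_transaldolase(k, c)
        assert ex.exchange["ta_f6p_g3p"] == 0.0
        assert ex.exchange["ta_s7p_e4p"] == 0.0
        assert ex.forward["ta"] > 0
        assert ex.reverse["ta"] == 0.0

    def test_symmetric_constants_give_equal_half_exchanges(self):
        k = {"kf": 1.3, "kmf": 0.9, "ks": 1.3, "kms": 0.9}
        c = {"f6p": 0.7, "g3p": 0.4, "s7p": 0.7, "e4p": 0.4}
        ex = decompose_transaldolase(k, c)
        assert ex.exchange["ta_f6p_g3p"] == pytest.approx(
            ex.exchange["ta_s7p_e4p"])

    @pytest.mark.parametrize("seed", [21, 22])
    def test_against_marked_molecule_simulation(self, seed):
        rng = np.random.default_rng(seed)
        k = {n: float(rng.uniform(0.4, 3.0)) for n in ("kf", "kmf", "ks", "kms")}
        c = {n: float(rng.uniform(0.3, 2.0)) for n in ("f6p", "g3p", "s7p", "e4p")}
        ex = decompose_transaldolase(k, c)
        entries = np.array([k["kf"] * c["f6p"], k["ks"] * c["s7p"]])
        exits = np.array([k["kmf"] * c["g3p"], k["kms"] * c["e4p"]])
        sim = pingpong_event_rates(entries, exits, 6_000_000, seed)
        assert sim[0, 1] == pytest.approx(ex.forward["ta"], rel=0.01)
        assert sim[1, 0] == pytest.approx(ex.reverse["ta"], rel=0.01)
        assert sim[0, 0] == pytest.approx(ex.exchange["ta_f6p_g3p"], rel=0.01)
        assert sim[1, 1] == pytest.approx(ex.exchange["ta_s7p_e4p"], rel=0.01)
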