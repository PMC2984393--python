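"""Brute-force oracles used only by the test suite.

The exchange-flux oracles simulate a *single enzyme molecule* of the explicit
elementary-step mechanism as a jump chain with clamped metabolite
concentrations, classify every completed sojourn (which molecule entered,
which left) and report event rates per unit time.  This measures the defined
quantities — whole-cycle transfers and half-molecule exchanges — directly
from trajectories of marked molecules, independently of any first-passage
algebra.
"""

from __future__ import annotations

import numpy as np


def gillespie_aldolase(k: dict[str, float], conc: dict[str, float],
                       n_sojourns: int, seed: int) -> dict[str, float]:
    """Event rates of the 3-step aldolase scheme for one enzyme molecule.

    Returns u_f (fbp -> dhap+g3p completions), u_r (reverse completions) and
    u_e (fbp binds, exchanges its g3p half, unbinds as fbp) per unit time,
    for enzyme total 1.
    """
    rng = np.random.default_rng(seed)
    a_bind_f = k["k1"] * conc["fbp"]     # e + fbp -> e-fbp
    a_bind_r = k["km3"] * conc["dhap"]   # e + dhap -> e-dhap
    a_fire2 = k["k2"]                    # e-fbp -> e-dhap + g3p
    a_unbind1 = k["km1"]                 # e-fbp -> e + fbp
    a_fire3 = k["k3"]                    # e-dhap -> e + dhap
    a_bind2 = k["km2"] * conc["g3p"]     # e-dhap + g3p -> e-fbp
    counts = {"u_f": 0, "u_r": 0, "u_e": 0}
    total_time = 0.0
    for _ in range(n_sojourns):
        # waiting in e (expected holding time keeps the clock unbiased)
        a_e = a_bind_f + a_bind_r
        total_time += 1.0 / a_e
        entered_fbp = rng.random() < a_bind_f / a_e
        state = 1 if entered_fbp else 2     # 1 = e-fbp, 2 = e-dhap
        fired2 = False
        while True:
            if state == 1:
                a_tot = a_fire2 + a_unbind1
                total_time += 1.0 / a_tot
                if rng.random() < a_fire2 / a_tot:
                    state = 2
                    fired2 = True
                else:                       # unbinds as fbp
                    if entered_fbp and fired2:
                        counts["u_e"] += 1
                    elif not entered_fbp:
                        counts["u_r"] += 1
                    break
            else:
                a_tot = a_fire3 + a_bind2
                total_time += 1.0 / a_tot
                if rng.random() < a_fire3 / a_tot:  # releases dhap
                    if entered_fbp:
                        counts["u_f"] += 1
                    break
                state = 1
    return {key: val / total_time for key, val in counts.items()}


def pingpong_event_rates(entries: np.ndarray, exits: np.ndarray,
                         n_sojourns: int, seed: int) -> np.ndarray:
    """Event-rate matrix u[i, j] of a two-state ping-pong enzyme.

    ``entries[i]``: propensity of e + donor_i -> adduct + product_i;
    ``exits[j]``: propensity of adduct + product_j -> e + donor_j.  Each
    sojourn draws an independent entry and exit channel; rates are counts
    over accumulated expected holding time (enzyme total 1).
    """
    rng = np.random.default_rng(seed)
    p_in = entries / entries.sum()
    p_out = exits / exits.sum()
    i_draw = rng.choice(len(entries), size=n_sojourns, p=p_in)
    j_draw = rng.choice(len(exits), size=n_sojourns, p=p_out)
    counts = np.zeros((len(entries), len(exits)))
    np.add.at(counts, (i_draw, j_draw), 1.0)
    total_time = n_sojourns * (1.0 / entries.sum() + 1.0 / exits.sum())
    return counts / total_time


def pdh_toy_derivatives(x_pyr: np.ndarray, x_accoa: np.ndarray, v0: float,
                        c_pyr: float, c_accoa: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Hand-coded derivative table of the pdh toy (input of '111' pyruvate).

    Every (reaction x isotopomer) transition written out explicitly:
    decarboxylation drops the leading bit; the efflux removes acetyl-CoA
    isotopomers in proportion to their share.
    """
    u = v0 * x_pyr / c_pyr                       # pdh rate per pyr isotopomer
    d_pyr = -u.copy()
    d_pyr[0b111] += v0                           # constant labelled input
    d_accoa = np.zeros(4)
    for code in range(8):
        d_accoa[code & 0b11] += u[code]          # remove first digit
    d_accoa -= v0 * x_accoa / c_accoa            # efflux
    return d_pyr, d_accoa


def condensation_toy_derivatives(x_a, x_b, x_c, v_in_a, v_in_b, u_cond, u_out,
                                 label_a: float):
    """Hand-coded ODE of a 1C+1C -> 2C condensation chain.

    in_a -> a (labelled with probability label_a), in_b -> b (unlabelled),
    a + b -> c (a supplies carbon 1), c -> out.
    """
    sa, sb, sc = x_a.sum(), x_b.sum(), x_c.sum()
    fa = x_a / sa
    fb = x_b / sb
    d_a = -u_cond * fa
    d_a[0] += v_in_a * (1 - label_a)
    d_a[1] += v_in_a * label_a
    d_b = -u_cond * fb
    d_b[0] += v_in_b
    d_c = -u_out * (x_c / sc)
    for i in range(2):
        for j in range(2):
            d_c[(i << 1) | j] += u_cond * fa[i] * fb[j]
    return d_a, d_b, d_c
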