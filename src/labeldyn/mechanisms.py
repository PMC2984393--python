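"""Decomposition of net enzyme rates into isotope-exchange fluxes.

A net reaction rate is not enough to propagate label: a reaction at
equilibrium moves no mass but still scrambles label between its substrate and
product pools.  Every reversible reaction is therefore decomposed into a
forward and a reverse whole-cycle flux (u_f, u_r, with u_f - u_r equal to the
kinetic net rate).  Enzymes that split or transfer parts of the carbon
skeleton additionally exchange *half-molecules*: aldolase can bind fbp,
release the g3p half, pick up a different g3p from the pool and re-form fbp
without ever completing the catalytic cycle.  Such half-exchange fluxes
(u_e) change no concentrations but redistribute label and must be evaluated
separately.

The decomposition is computed analytically from the quasi-steady-state
distribution of the enzyme intermediates of an explicit elementary-step
scheme, by first-passage (cycle-completion vs. return) probabilities:

* aldolase — three reversible elementary steps
  (1) e + fbp <-> e-fbp, (2) e-fbp <-> e-dhap + g3p, (3) e-dhap <-> e + dhap;
  u_e is the flux through steps 1-2 and back without entering step 3.
* transketolase — ping-pong with a covalent glycolaldehyde (2C) enzyme
  adduct shared by three donor/acceptor channels:
  e + x5p <-> e-C2 + g3p, e + f6p <-> e-C2 + e4p, e + s7p <-> e-C2 + r5p.
  Pairing entry channel i with exit channel j gives six directional cycle
  fluxes (i != j) and three half-exchanges (i == j: x5p<->g3p, f6p<->e4p,
  s7p<->r5p).
* transaldolase — same ping-pong pattern with a dihydroxyacetone (3C) adduct
  and two channels: e + f6p <-> e-C3 + g3p, e + s7p <-> e-C3 + e4p; one cycle
  (f6p + e4p <-> s7p + g3p) plus the half-exchanges f6p<->g3p and s7p<->e4p.

All fluxes are in mM/min; every directional flux is non-negative by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExchangeFluxSet",
    "decompose_reversible",
    "decompose_aldolase",
    "decompose_transketolase",
    "decompose_transaldolase",
]


@dataclass
class ExchangeFluxSet:
    """Directional cycle fluxes and half-molecule exchange fluxes (mM/min).

    ``forward[name]`` / ``reverse[name]`` hold the two whole-cycle directions
    of each catalytic cycle; ``exchange[name]`` holds the half-molecule
    exchanges, which move label but no mass.
    """

    forward: dict[str, float] = field(default_factory=dict)
    reverse: dict[str, float] = field(default_factory=dict)
    exchange: dict[str, float] = field(default_factory=dict)

    def net(self, name: str) -> float:
        return self.forward[name] - self.reverse[name]

    def __post_init__(self) -> None:
        for d in (self.forward, self.reverse, self.exchange):
            for key, val in d.items():
                if val < -1e-12:
                    raise ValueError(f"negative exchange flux {key}={val}")
                d[key] = max(val, 0.0)


def decompose_reversible(forward_rate: float, reverse_rate: float,
                         name: str = "net") -> ExchangeFluxSet:
    """Store the two directions of a skeleton-preserving reversible reaction.

    Both directions matter for label even when the net rate is zero.
    """
    if forward_rate < 0 or reverse_rate < 0:
        raise ValueError("directional rates must be non-negative")
    return ExchangeFluxSet(forward={name: forward_rate},
                           reverse={name: reverse_rate})


# ---------------------------------------------------------------------------
# aldolase: e + fbp <k1/km1> e-fbp <k2/km2(g3p)> e-dhap <k3/km3(dhap)> e + dhap
# ---------------------------------------------------------------------------

def _aldolase_enzyme_state(k: dict[str, float], fbp: float, g3p: float,
                           dhap: float, enzyme_total: float) -> np.ndarray:
    """Quasi-steady-state concentrations (e, e-fbp, e-dhap)."""
    k1, km1 = k["k1"], k["km1"]
    k2, km2 = k["k2"], k["km2"]
    k3, km3 = k["k3"], k["km3"]
    # d(e-fbp)/dt = 0, d(e-dhap)/dt = 0, conservation
    a = np.array([
        [k1 * fbp, -(km1 + k2), km2 * g3p],
        [km3 * dhap, k2, -(km2 * g3p + k3)],
        [1.0, 1.0, 1.0],
    ])
    b = np.array([0.0, 0.0, enzyme_total])
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular enzyme-species steady state") from err
    if np.any(sol < -1e-9 * enzyme_total):
        raise ValueError("singular enzyme-species steady state")
    return np.clip(sol, 0.0, None)


def decompose_aldolase(elementary_constants: dict[str, float],
                       concentrations: dict[str, float],
                       enzyme_total: float = 1.0) -> ExchangeFluxSet:
    """Aldolase (fbp <-> dhap + g3p) exchange fluxes.

    Parameters
    ----------
    elementary_constants:
        k1, km1, k2, km2, k3, km3 of the three elementary steps (km2 and km3
        are second-order: per mM of g3p / dhap respectively).
    concentrations:
        fbp, g3p, dhap pool concentrations in mM.

    Returns
    -------
    ExchangeFluxSet
        forward/reverse whole-cycle fluxes under ``"ald"`` and the
        half-molecule fbp<->g3p exchange under ``"ald_fbp_g3p"``.
    """
    k = elementary_constants
    for key, val in k.items():
        if val < 0:
            raise ValueError(f"negative elementary constant {key}")
    fbp = concentrations["fbp"]
    g3p = concentrations["g3p"]
    dhap = concentrations["dhap"]
    e, c1, c2 = _aldolase_enzyme_state(k, fbp, g3p, dhap, enzyme_total)

    bind_f = k["k1"] * e * fbp          # fbp binding flux
    bind_r = k["km3"] * e * dhap        # dhap binding flux
    # exit probabilities of the intermediate complexes
    den1 = k["k2"] + k["km1"]           # e-fbp: fire step 2 vs unbind fbp
    den2 = k["k3"] + k["km2"] * g3p     # e-dhap: fire step 3 vs rebind g3p
    if den1 <= 0 or den2 <= 0:
        return ExchangeFluxSet(forward={"ald": 0.0}, reverse={"ald": 0.0},
                               exchange={"ald_fbp_g3p": 0.0})
    q_f = k["k2"] / den1                # e-fbp -> e-dhap + g3p
    q_b = k["km1"] / den1               # e-fbp -> e + fbp
    r_f = k["k3"] / den2                # e-dhap -> e + dhap
    r_b = k["km2"] * g3p / den2         # e-dhap + g3p -> e-fbp
    # first-passage: complete forward from e-dhap / complete reverse from e-fbp
    denom = 1.0 - r_b * q_f
    a_fwd = r_f / denom if denom > 0 else 1.0
    b_rev = q_b / denom if denom > 0 else 1.0
    u_f = bind_f * q_f * a_fwd
    u_r = bind_r * r_b * b_rev
    u_e = bind_f * q_f * (1.0 - a_fwd)
    return ExchangeFluxSet(forward={"ald": u_f}, reverse={"ald": u_r},
                           exchange={"ald_fbp_g3p": u_e})


# ---------------------------------------------------------------------------
# ping-pong mechanisms (transketolase / transaldolase)
# ---------------------------------------------------------------------------

def _ping_pong_fluxes(channels: list[tuple[str, float, float, str, float, float]],
                      enzyme_total: float) -> tuple[dict, dict]:
    """Channel entry/exit fluxes of a two-state (e / e-adduct) mechanism.

    ``channels`` rows: (donor, k_fwd, donor_conc, acceptor_product, k_rev,
    product_conc).  Returns per-channel entry fluxes a_i (e + donor ->
    e-adduct + aldose) and exit fluxes b_i (reverse), evaluated at the
    quasi-steady-state enzyme split.
    """
    a_prop = sum(kf * s for _, kf, s, _, _, _ in channels)      # e -> e-adduct
    b_prop = sum(kr * p for _, _, _, _, kr, p in channels)      # e-adduct -> e
    if a_prop + b_prop <= 0:
        e = enzyme_total
        eg = 0.0
    else:
        eg = enzyme_total * a_prop / (a_prop + b_prop)
        e = enzyme_total - eg
    entry = {name: kf * e * s for name, kf, s, _, _, _ in channels}
    exit_ = {name: kr * eg * p for name, _, _, _, kr, p in channels}
    return entry, exit_


def _pair_cycle_fluxes(entry: dict[str, float], exit_: dict[str, float],
                       cycle_names: dict[tuple[str, str], str],
                       exchange_names: dict[str, str]) -> ExchangeFluxSet:
    total_exit = sum(exit_.values())
    fwd: dict[str, float] = {}
    rev: dict[str, float] = {}
    exch: dict[str, float] = {}
    for (i, j), name in cycle_names.items():
        if total_exit > 0:
            fwd[name] = entry[i] * exit_[j] / total_exit
            rev[name] = entry[j] * exit_[i] / total_exit
        else:
            fwd[name] = rev[name] = 0.0
    for i, name in exchange_names.items():
        exch[name] = entry[i] * exit_[i] / total_exit if total_exit > 0 else 0.0
    return ExchangeFluxSet(forward=fwd, reverse=rev, exchange=exch)


def decompose_transketolase(elementary_constants: dict[str, float],
                            concentrations: dict[str, float],
                            enzyme_total: float = 1.0) -> ExchangeFluxSet:
    """Transketolase exchange fluxes from the shared-adduct ping-pong scheme.

    Constants: kx/kmx (x5p <-> g3p channel), kf/kmf (f6p <-> e4p),
    ks/kms (s7p <-> r5p).  Concentrations: x5p, r5p, f6p, g3p, s7p, e4p.

    Cycle names: ``tk1`` x5p+r5p <-> s7p+g3p, ``tk2`` f6p+g3p <-> x5p+e4p,
    ``tk3`` f6p+r5p <-> s7p+e4p; half-exchanges ``tk_x5p_g3p``,
    ``tk_f6p_e4p``, ``tk_s7p_r5p``.
    """
    k = elementary_constants
    c = concentrations
    if any(v < 0 for v in k.values()):
        raise ValueError("negative elementary constant")
    channels = [
        ("X", k["kx"], c["x5p"], "g3p", k["kmx"], c["g3p"]),
        ("F", k["kf"], c["f6p"], "e4p", k["kmf"], c["e4p"]),
        ("S", k["ks"], c["s7p"], "r5p", k["kms"], c["r5p"]),
    ]
    entry, exit_ = _ping_pong_fluxes(channels, enzyme_total)
    cycle_names = {("X", "S"): "tk1", ("F", "X"): "tk2", ("F", "S"): "tk3"}
    exchange_names = {"X": "tk_x5p_g3p", "F": "tk_f6p_e4p", "S": "tk_s7p_r5p"}
    return _pair_cycle_fluxes(entry, exit_, cycle_names, exchange_names)


def decompose_transaldolase(elementary_constants: dict[str, float],
                            concentrations: dict[str, float],
                            enzyme_total: float = 1.0) -> ExchangeFluxSet:
    """Transaldolase (f6p + e4p <-> s7p + g3p) exchange fluxes.

    Constants: kf/kmf (f6p <-> g3p channel), ks/kms (s7p <-> e4p channel).
    Cycle name ``ta``; half-exchanges ``ta_f6p_g3p`` and ``ta_s7p_e4p``.
    """
    k = elementary_constants
    c = concentrations
    if any(v < 0 for v in k.values()):
        raise ValueError("negative elementary constant")
    channels = [
        ("F", k["kf"], c["f6p"], "g3p", k["kmf"], c["g3p"]),
        ("S", k["ks"], c["s7p"], "e4p", k["kms"], c["e4p"]),
    ]
    entry, exit_ = _ping_pong_fluxes(channels, enzyme_total)
    cycle_names = {("F", "S"): "ta"}
    exchange_names = {"F": "ta_f6p_g3p", "S": "ta_s7p_e4p"}
    return _pair_cycle_fluxes(entry, exit_, cycle_names, exchange_names)
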