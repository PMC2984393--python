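"""Automatic construction and solution of the isotopomer ODE system.

Once the kinetic model has reached metabolic steady state, every pool total
C_s and every decomposed flux u is a constant, and the 13C labelling state is
the vector of positional-isotopomer concentrations x = {x_si} over all pools
(2**n entries for an n-carbon metabolite).  Each label-moving event (a
directional whole-cycle flux, a half-molecule exchange, a constant input)
apportions its total rate over substrate isotopomers by mole fraction,

    u_i = u_t * x_i / C_t,

and routes every substrate pattern to its product pattern(s) through the
reaction's carbon map, implemented as bit arithmetic on the binary pattern
codes.  Bimolecular condensations pair the two substrate pools with rates
proportional to the product of mole fractions.  The resulting ODE system
(a few hundred states for the default network) is integrated with a stiff
BDF method; afterwards the per-pool isotopomer sums are compared with the
kinetic totals — a disagreement flags an inaccurate solution rather than
passing silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from . import patterns
from .mechanisms import ExchangeFluxSet
from .network import MetabolicState, ReactionNetwork, Reaction

__all__ = [
    "LabelModel",
    "LabelTrajectory",
    "isotopomer_flux",
    "assemble_derivatives",
    "simulate_label_dynamics",
]

#: relative tolerance of the isotopomer-sum vs kinetic-total consistency check
SUM_CHECK_RTOL = 1e-4


def isotopomer_flux(u_total: float, x_i: float, c_total: float) -> float:
    """Apportion a total rate to one isotopomer by its mole fraction."""
    if c_total <= 0:
        if u_total > 0:
            raise ValueError("positive flux through an empty pool")
        return 0.0
    if x_i < 0 or x_i > c_total * (1 + 1e-9):
        raise ValueError("isotopomer concentration outside [0, C_total]")
    return u_total * x_i / c_total


# role-letter carbon maps of the mechanism label events; substrate letter
# strings are concatenated left to right, '0' marks an unlabelled new carbon
_ALDOLASE_EVENTS = [
    # (flux kind, key, substrates, products)
    ("forward", "ald", [("fbp", "abcdef")], [("dhap", "abc"), ("g3p", "def")]),
    ("reverse", "ald", [("dhap", "abc"), ("g3p", "def")], [("fbp", "abcdef")]),
    ("exchange", "ald_fbp_g3p", [("fbp", "abcdef"), ("g3p", "xyz")],
     [("fbp", "abcxyz"), ("g3p", "def")]),
]

_TK_EVENTS = [
    ("forward", "tk1", [("x5p", "abcde"), ("r5p", "fghij")],
     [("s7p", "abfghij"), ("g3p", "cde")]),
    ("reverse", "tk1", [("s7p", "abcdefg"), ("g3p", "hij")],
     [("x5p", "abhij"), ("r5p", "cdefg")]),
    ("forward", "tk2", [("f6p", "abcdef"), ("g3p", "ghi")],
     [("x5p", "abghi"), ("e4p", "cdef")]),
    ("reverse", "tk2", [("x5p", "abcde"), ("e4p", "fghi")],
     [("f6p", "abfghi"), ("g3p", "cde")]),
    ("forward", "tk3", [("f6p", "abcdef"), ("r5p", "ghijk")],
     [("s7p", "abghijk"), ("e4p", "cdef")]),
    ("reverse", "tk3", [("s7p", "abcdefg"), ("e4p", "hijk")],
     [("f6p", "abhijk"), ("r5p", "cdefg")]),
    ("exchange", "tk_x5p_g3p", [("x5p", "abcde"), ("g3p", "fgh")],
     [("x5p", "abfgh"), ("g3p", "cde")]),
    ("exchange", "tk_f6p_e4p", [("f6p", "abcdef"), ("e4p", "ghij")],
     [("f6p", "abghij"), ("e4p", "cdef")]),
    ("exchange", "tk_s7p_r5p", [("s7p", "abcdefg"), ("r5p", "hijkl")],
     [("s7p", "abhijkl"), ("r5p", "cdefg")]),
]

_TA_EVENTS = [
    ("forward", "ta", [("f6p", "abcdef"), ("e4p", "ghij")],
     [("s7p", "abcghij"), ("g3p", "def")]),
    ("reverse", "ta", [("s7p", "abcdefg"), ("g3p", "hij")],
     [("f6p", "abchij"), ("e4p", "defg")]),
    ("exchange", "ta_f6p_g3p", [("f6p", "abcdef"), ("g3p", "ghi")],
     [("f6p", "abcghi"), ("g3p", "def")]),
    ("exchange", "ta_s7p_e4p", [("s7p", "abcdefg"), ("e4p", "hijk")],
     [("s7p", "abchijk"), ("e4p", "defg")]),
]

_MECHANISM_EVENTS = {
    "aldolase": _ALDOLASE_EVENTS,
    "transketolase": _TK_EVENTS,
    "transaldolase": _TA_EVENTS,
}


@dataclass
class _Event:
    """One compiled label-moving event."""

    rate: float
    kind: str                      # "src", "uni" or "bi"
    subs: list[tuple[str, np.ndarray | None]]  # (pool, fixed fractions or None)
    prod_idx: list[tuple[str, np.ndarray]]     # (pool, product code per substrate code)
    src_dist: tuple[str, np.ndarray] | None = None  # input pool distribution


def _product_codes(letters_by_sub: list[tuple[str, str]],
                   prod_letters: str) -> list[np.ndarray]:
    """Per-substrate contribution of each product code.

    Returns one array per substrate: contribution of that substrate's codes
    to the product code (bits land at the product positions of the letters
    the substrate supplies).  Summing the contributions over the substrate
    tuple gives the product code.
    """
    k = len(prod_letters)
    out = []
    for _, sub_letters in letters_by_sub:
        n = len(sub_letters)
        codes = np.arange(1 << n, dtype=np.int64)
        contrib = np.zeros_like(codes)
        for j, ch in enumerate(prod_letters):
            if ch == "0":
                continue
            pos = sub_letters.find(ch)
            if pos >= 0:
                bit = (codes >> (n - 1 - pos)) & 1
                contrib |= bit << (k - 1 - j)
        out.append(contrib)
    return out


class LabelModel:
    """Compiled isotopomer ODE system for one network at one steady state."""

    def __init__(self, network: ReactionNetwork, steady: MetabolicState):
        if not steady.steady:
            raise ValueError("label dynamics require a converged steady state")
        self.network = network
        self.steady = steady
        # dynamic pools: everything that is not clamped
        self.pools = [m for m in network.metabolites if m.role != "clamped"]
        self.sizes = {m.name: 1 << m.carbons for m in self.pools}
        self.offsets: dict[str, int] = {}
        off = 0
        for m in self.pools:
            self.offsets[m.name] = off
            off += self.sizes[m.name]
        self.n_states = off
        self.totals = {
            m.name: float(steady.concentrations[network.met_index[m.name]])
            for m in self.pools}
        self._clamped_dist = {
            m.name: self._distribution(m) for m in network.metabolites
            if m.role == "clamped"}
        self.accumulating = [m.name for m in self.pools
                             if network.met[m.name].role == "accumulating"]
        self.events = self._compile_events()
        def _feeds(ev: _Event, name: str) -> bool:
            if ev.kind == "src":
                return ev.src_dist[0] == name
            return any(pool == name for pool, _ in ev.prod_idx)

        self.influx = {name: sum(ev.rate for ev in self.events
                                 if _feeds(ev, name))
                       for name in self.accumulating}
        self._sparsity = None

    # -- construction ------------------------------------------------------

    def _distribution(self, met) -> np.ndarray:
        dist = np.zeros(1 << met.carbons)
        if met.labeling:
            for pattern, frac in met.labeling.items():
                dist[patterns.encode(pattern)] += frac
        else:
            dist[0] = 1.0
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError(f"labeling of {met.name} does not sum to 1")
        return dist

    def _compile_one(self, rate: float, subs: list[tuple[str, str]],
                     prods: list[tuple[str, str]]) -> _Event | None:
        """Compile an event from (pool, letters) substrate/product lists."""
        if rate <= 0:
            return None
        dyn_subs = [(pool, letters) for pool, letters in subs
                    if pool in self.offsets]
        fixed_subs = [(pool, letters) for pool, letters in subs
                      if pool not in self.offsets]
        if not subs:  # pure input
            pool, letters = prods[0]
            dist = np.zeros(self.sizes[pool])
            dist[0] = 1.0
            return _Event(rate, "src", [], [], (pool, dist))
        # per-product (positional, pools may repeat) substrate contributions
        contribs = [(p, _product_codes(subs, letters))
                    for p, letters in prods if p in self.offsets]
        if len(subs) == 1:
            pool, letters = subs[0]
            if fixed_subs:
                # substrate clamped: push its fixed distribution through the map
                dist_in = self._clamped_dist[pool]
                evs = []
                for p, (codes,) in contribs:
                    dist_out = np.bincount(codes, weights=dist_in,
                                           minlength=self.sizes[p])
                    evs.append(_Event(rate, "src", [], [], (p, dist_out)))
                return evs  # type: ignore[return-value]
            prod_idx = [(p, codes) for p, (codes,) in contribs]
            return _Event(rate, "uni", [(pool, None)], prod_idx)
        if len(subs) == 2:
            if fixed_subs:
                raise NotImplementedError(
                    "bimolecular events with clamped substrates")
            prod_idx = []
            for p, (pa, pb) in contribs:
                prod_idx.append((p, (pa[:, None] + pb[None, :]).ravel()))
            return _Event(rate, "bi", [(s, None) for s, _ in subs], prod_idx)
        raise ValueError("events with >2 substrates are not supported")

    def _add(self, out: list[_Event], ev) -> None:
        if ev is None:
            return
        if isinstance(ev, list):
            out.extend(ev)
        else:
            out.append(ev)

    def _compile_events(self) -> list[_Event]:
        events: list[_Event] = []
        done_mechs: set[str] = set()
        for j, rxn in enumerate(self.network.reactions):
            if rxn.mechanism is not None:
                if rxn.mechanism in done_mechs:
                    continue
                done_mechs.add(rxn.mechanism)
                info = self.network.mechanisms[rxn.mechanism]
                exch = self.steady.exchange[rxn.mechanism]
                pools = info["pools"]
                for flux_kind, key, subs, prods in _MECHANISM_EVENTS[info["kind"]]:
                    rate = getattr(exch, flux_kind)[key]
                    subs_p = [(pools[r], s) for r, s in subs]
                    prods_p = [(pools[r], s) for r, s in prods]
                    self._add(events, self._compile_one(rate, subs_p, prods_p))
                continue
            rate = float(self.steady.net_fluxes[j])
            if rate <= 0:
                continue
            if rxn.kind == "const":
                pool = rxn.products[0][0]
                dist_in = np.zeros(self.sizes[pool])
                if rxn.labeling:
                    dist_in[patterns.encode(rxn.labeling)] = 1.0
                else:
                    dist_in[0] = 1.0
                events.append(_Event(rate, "src", [], [], (pool, dist_in)))
                continue
            for weight, amap in (rxn.carbon_map or ((1.0, None),)):
                if amap is None:
                    raise ValueError(f"reaction {rxn.name} lacks a carbon map")
                subs = [(m, amap[m]) for m, _ in rxn.substrates]
                prods = [(m, amap[m]) for m, _ in rxn.products if m in amap]
                self._add(events, self._compile_one(rate * weight, subs, prods))
        return events

    # -- dynamics ----------------------------------------------------------

    def initial_state(self, labeled_fraction: dict[str, np.ndarray] | None = None
                      ) -> np.ndarray:
        """All pools unlabelled at their kinetic totals (accumulating start empty)."""
        x = np.zeros(self.n_states)
        for m in self.pools:
            if m.name in self.accumulating:
                continue
            off = self.offsets[m.name]
            if labeled_fraction and m.name in labeled_fraction:
                x[off:off + self.sizes[m.name]] = (
                    labeled_fraction[m.name] * self.totals[m.name])
            else:
                x[off] = self.totals[m.name]
        return x

    def _fraction(self, x: np.ndarray, pool: str) -> np.ndarray:
        """Mole-fraction vector of a pool.

        At metabolic steady state the pool sum equals the kinetic total, so
        dividing by the current sum is the same apportioning rule as dividing
        by C_t — but it keeps the conservation manifold neutrally stable
        instead of exponentially repelling under round-off drift.
        """
        blk = x[self.offsets[pool]:self.offsets[pool] + self.sizes[pool]]
        total = blk.sum()
        if total <= 0:
            return np.zeros_like(blk)
        return blk / total

    def rhs(self, _t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(x)
        off, sz = self.offsets, self.sizes
        for ev in self.events:
            if ev.kind == "src":
                pool, dist = ev.src_dist
                dx[off[pool]:off[pool] + sz[pool]] += ev.rate * dist
            elif ev.kind == "uni":
                pool = ev.subs[0][0]
                flux = ev.rate * self._fraction(x, pool)
                dx[off[pool]:off[pool] + sz[pool]] -= flux
                for p, idx in ev.prod_idx:
                    dx[off[p]:off[p] + sz[p]] += np.bincount(
                        idx, weights=flux, minlength=sz[p])
            else:  # bi
                pa, pb = ev.subs[0][0], ev.subs[1][0]
                fa = self._fraction(x, pa)
                fb = self._fraction(x, pb)
                dx[off[pa]:off[pa] + sz[pa]] -= ev.rate * fa
                dx[off[pb]:off[pb] + sz[pb]] -= ev.rate * fb
                w = ev.rate * np.outer(fa, fb).ravel()
                for p, idx in ev.prod_idx:
                    dx[off[p]:off[p] + sz[p]] += np.bincount(
                        idx, weights=w, minlength=sz[p])
        return dx

    def jac(self, _t: float, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` (dense).

        With f = x_pool / S_pool, d(u f_i)/dx_j = (u/S)(delta_ij - f_i), and
        for bimolecular production w_ij = u fa_i fb_j the derivative splits
        into a scatter part and a rank-one part per substrate pool.
        """
        n = self.n_states
        jac = np.zeros((n, n))
        off, sz = self.offsets, self.sizes
        for ev in self.events:
            if ev.kind == "src":
                continue
            if ev.kind == "uni":
                pool = ev.subs[0][0]
                o, m = off[pool], sz[pool]
                blk = x[o:o + m]
                s = blk.sum()
                if s <= 0:
                    continue
                f = blk / s
                us = ev.rate / s
                # consumption: -(u/S)(I - f 1^T) on the substrate block
                jac[o:o + m, o:o + m] -= us * np.eye(m)
                jac[o:o + m, o:o + m] += us * f[:, None]
                for p, idx in ev.prod_idx:
                    op = off[p]
                    np.add.at(jac, (idx + op, np.arange(m) + o), us)
                    prod = np.bincount(idx, weights=f, minlength=sz[p])
                    jac[op:op + sz[p], o:o + m] -= us * prod[:, None]
            else:
                pa, pb = ev.subs[0][0], ev.subs[1][0]
                oa, ma = off[pa], sz[pa]
                ob, mb = off[pb], sz[pb]
                sa = x[oa:oa + ma].sum()
                sb = x[ob:ob + mb].sum()
                if sa <= 0 or sb <= 0:
                    continue
                fa = x[oa:oa + ma] / sa
                fb = x[ob:ob + mb] / sb
                ua, ub = ev.rate / sa, ev.rate / sb
                jac[oa:oa + ma, oa:oa + ma] -= ua * np.eye(ma)
                jac[oa:oa + ma, oa:oa + ma] += ua * fa[:, None]
                jac[ob:ob + mb, ob:ob + mb] -= ub * np.eye(mb)
                jac[ob:ob + mb, ob:ob + mb] += ub * fb[:, None]
                cols_a = np.repeat(np.arange(ma) + oa, mb)
                cols_b = np.tile(np.arange(mb) + ob, ma)
                wa = ua * np.tile(fb, ma)          # d w_ij / d xa_i scatter part
                wb = ub * np.repeat(fa, mb)        # d w_ij / d xb_j scatter part
                for p, idx in ev.prod_idx:
                    op = off[p]
                    rows = idx + op
                    np.add.at(jac, (rows, cols_a), wa)
                    np.add.at(jac, (rows, cols_b), wb)
                    w = np.outer(fa, fb).ravel()
                    prod = np.bincount(idx, weights=w, minlength=sz[p])
                    jac[op:op + sz[p], oa:oa + ma] -= ua * prod[:, None]
                    jac[op:op + sz[p], ob:ob + mb] -= ub * prod[:, None]
        return jac

    def jac_sparsity(self) -> sparse.csr_matrix:
        if self._sparsity is not None:
            return self._sparsity
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []

        def link(r, c):
            rows.append(np.asarray(r, dtype=np.int64).ravel())
            cols.append(np.asarray(c, dtype=np.int64).ravel())

        off, sz = self.offsets, self.sizes
        # the current-sum normalisation couples every state of a substrate
        # pool into every derivative the event touches: link whole blocks
        for ev in self.events:
            if ev.kind == "src":
                continue
            sub_cols = np.concatenate([
                np.arange(sz[pool]) + off[pool] for pool, _ in ev.subs])
            touched = {pool for pool, _ in ev.subs}
            touched.update(pool for pool, _ in ev.prod_idx)
            target_rows = np.concatenate([
                np.arange(sz[pool]) + off[pool] for pool in touched])
            grid_r = np.repeat(target_rows, len(sub_cols))
            grid_c = np.tile(sub_cols, len(target_rows))
            link(grid_r, grid_c)
        data = np.ones(sum(len(r) for r in rows))
        mat = sparse.coo_matrix(
            (data, (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_states, self.n_states)).tocsr()
        mat.data[:] = 1.0
        self._sparsity = mat
        return mat

    def simulate(self, t_end: float, n_out: int = 25,
                 x0: np.ndarray | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> "LabelTrajectory":
        """Integrate the labelling transient from the unlabelled state."""
        if x0 is None:
            x0 = self.initial_state()
        if t_end == 0:
            return LabelTrajectory(self, np.array([0.0]),
                                   x0[None, :].copy(), True)
        t_eval = np.linspace(0.0, t_end, n_out)
        sol = solve_ivp(self.rhs, (0.0, t_end), x0, method="BDF",
                        t_eval=t_eval, rtol=rtol, atol=atol, jac=self.jac)
        if not sol.success:
            raise RuntimeError(f"isotopomer integration failed: {sol.message}")
        traj = LabelTrajectory(self, sol.t, sol.y.T.copy(), True)
        traj.accurate = traj.check_sums()
        return traj


@dataclass
class LabelTrajectory:
    """Isotopomer concentrations over time for every dynamic pool."""

    model: LabelModel
    times: np.ndarray
    states: np.ndarray              # (n_times, n_states)
    accurate: bool = True
    sum_errors: dict[str, float] = field(default_factory=dict)

    def pool(self, name: str, t_index: int = -1) -> np.ndarray:
        off = self.model.offsets[name]
        return self.states[t_index, off:off + self.model.sizes[name]]

    def mid(self, name: str, fragment_carbons: list[int] | None = None,
            t_index: int = -1) -> np.ndarray:
        met = self.model.network.met[name]
        return patterns.mass_distribution(
            self.pool(name, t_index), met.carbons, fragment_carbons)

    def check_sums(self, rtol: float = SUM_CHECK_RTOL) -> bool:
        """Consistency check: per-pool isotopomer sums vs kinetic totals."""
        ok = True
        for m in self.model.pools:
            name = m.name
            sums = self.states[:, self.model.offsets[name]:
                               self.model.offsets[name] + self.model.sizes[name]
                               ].sum(axis=1)
            if name in self.model.accumulating:
                expected = self.model.influx[name] * self.times
            else:
                expected = np.full_like(self.times, self.model.totals[name])
            scale = np.maximum(np.abs(expected), 1e-12)
            err = float(np.max(np.abs(sums - expected) / scale))
            self.sum_errors[name] = err
            if err > rtol:
                ok = False
        return ok


def assemble_derivatives(network: ReactionNetwork, x: np.ndarray,
                         steady: MetabolicState) -> np.ndarray:
    """Isotopomer time derivatives at state ``x`` (flat, pool-blocked)."""
    return LabelModel(network, steady).rhs(0.0, x)


def simulate_label_dynamics(network: ReactionNetwork, steady: MetabolicState,
                            t_end: float = 2880.0, n_out: int = 25,
                            **kwargs) -> LabelTrajectory:
    """Steady-state label transient over the incubation (default 48 h)."""
    return LabelModel(network, steady).simulate(t_end, n_out=n_out, **kwargs)
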