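"""Flux estimation: stochastic chi-square minimisation and confidence intervals.

Every objective evaluation runs the full forward pipeline — kinetic steady
state, isotope-exchange decomposition, isotopomer transient, observable MIDs
— and scores the result against the measured distributions.  The search
strategy mirrors the two-stage heuristic the method was designed around:

1. simulated annealing whose stochastic perturbations alternate with cyclic
   coordinate descent, archiving the parameter set and fluxes of every local
   minimum reached;
2. a genetic algorithm seeded with the archived minima (uniform crossover,
   log-scale mutation of randomly chosen parameters, chi-square-ranked
   selection).

Confidence intervals for fluxes are profile-threshold intervals: the spread
of each flux over all sampled parameter sets whose chi-square lies within
Delta of the minimum, Delta taken from the chi-square distribution at the
requested confidence level (3.84 at 95% for one parameter).

Parameters are searched in log space: fluxes and rate constants span many
orders of magnitude, and multiplicative perturbations keep them positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .calibrate import REF_CONC
from .labeling import LabelModel
from .measure import (MIDDataset, OBSERVABLES, optimal_dilution,
                      predict_observables, score_dataset)
from .network import (MetabolicState, ParameterSet, ReactionNetwork,
                      integrate_to_steady_state)

__all__ = [
    "PipelineObjective",
    "EvalRecord",
    "AnnealSchedule",
    "LocalMinimum",
    "FitResult",
    "anneal_descent",
    "genetic_refine",
    "confidence_intervals",
    "fit",
]

#: finite score assigned when the kinetic model fails to reach steady state,
#: keeping the stochastic search alive instead of raising
FAILURE_SCORE = 1e9


@dataclass
class EvalRecord:
    x: np.ndarray                   # log-parameter vector (free subset)
    chi2: float
    fluxes: np.ndarray | None       # net fluxes at steady state
    dilution: dict[str, float] = field(default_factory=dict)
    predicted: dict | None = None


class PipelineObjective:
    """Chi-square of the forward pipeline as a function of log-parameters.

    The hexokinase flux is pinned to the measured glucose uptake through the
    ``J_glc`` parameter; the lactate release flux is softly constrained to
    the measured value with a relative-error penalty.  The RNA-ribose
    dilution is profiled analytically (the observed MID is affine in it), so
    it never burdens the stochastic search.
    """

    def __init__(self, network: ReactionNetwork, base_params: ParameterSet,
                 datasets: Sequence[MIDDataset], t_end: float = 2880.0,
                 c0: dict[str, float] | None = None,
                 lactate_constraint: float | None = None,
                 constraint_rel_sd: float = 0.02,
                 rtol: float = 1e-6, atol: float = 1e-9,
                 keep_trace: bool = True):
        self.network = network
        self.base = base_params
        self.datasets = list(datasets)
        self.t_end = t_end
        self.c0 = dict(c0) if c0 is not None else dict(REF_CONC)
        if lactate_constraint is None:
            lactate_constraint = base_params.values.get("J_lac")
        self.lactate_constraint = lactate_constraint
        self.constraint_rel_sd = constraint_rel_sd
        self.rtol, self.atol = rtol, atol
        self.trace: list[EvalRecord] = [] if keep_trace else None
        self.n_eval = 0

    # -- parameter-vector mapping -----------------------------------------

    def to_vector(self, p: ParameterSet) -> np.ndarray:
        return np.log(p.vector())

    def to_params(self, x: np.ndarray) -> ParameterSet:
        vals = np.exp(np.asarray(x, dtype=float))
        lo, hi = np.array([self.base.bound(k) for k in self.base.free]).T
        return self.base.with_vector(np.clip(vals, lo, hi))

    def log_bounds(self) -> list[tuple[float, float]]:
        return [tuple(np.log(self.base.bound(k))) for k in self.base.free]

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, p: ParameterSet) -> EvalRecord:
        self.n_eval += 1
        x = self.to_vector(p)
        try:
            steady = integrate_to_steady_state(self.network, p, c0=self.c0)
            if not steady.steady:
                return self._record(EvalRecord(x, FAILURE_SCORE, None))
            model = LabelModel(self.network, steady)
            traj = model.simulate(self.t_end, n_out=5,
                                  rtol=self.rtol, atol=self.atol)
            if not traj.accurate:
                return self._record(EvalRecord(x, FAILURE_SCORE, None))
        except Exception:
            return self._record(EvalRecord(x, FAILURE_SCORE, None))
        chi2 = 0.0
        dilutions: dict[str, float] = {}
        predicted_all: dict[str, dict] = {}
        for ds in self.datasets:
            raw = predict_observables(traj, dilution=0.0)
            # profile the dilution of each diluted observable in closed form
            pred = dict(raw)
            for name, obs in OBSERVABLES.items():
                if obs.diluted and name in ds.fractions:
                    d = optimal_dilution(raw[name], ds.fractions[name],
                                         ds.sd[name])
                    pred[name] = raw[name] * (1 - d)
                    pred[name][0] += d
                    dilutions[f"{ds.condition}:{name}"] = d
            score = score_dataset(ds, pred)
            chi2 += score.chi2
            predicted_all[ds.condition] = pred
        if self.lactate_constraint:
            v_lac = steady.flux(self.network, "lac_out")
            sd = self.constraint_rel_sd * self.lactate_constraint
            chi2 += ((v_lac - self.lactate_constraint) / sd) ** 2
        return self._record(EvalRecord(x, float(chi2), steady.net_fluxes.copy(),
                                       dilutions, predicted_all))

    def _record(self, rec: EvalRecord) -> EvalRecord:
        if self.trace is not None:
            self.trace.append(rec)
        return rec

    def __call__(self, x: np.ndarray) -> float:
        return self.evaluate(self.to_params(x)).chi2

    def residuals(self, x: np.ndarray) -> np.ndarray:
        """Signed, sd-weighted residual vector (sum of squares = chi2)."""
        rec = self.evaluate(self.to_params(x))
        n_res = sum(len(f) for ds in self.datasets
                    for f in ds.fractions.values())
        n_res += 1 if self.lactate_constraint else 0
        if rec.fluxes is None:
            return np.full(n_res, np.sqrt(FAILURE_SCORE / n_res))
        res: list[float] = []
        for ds in self.datasets:
            pred = rec.predicted[ds.condition]
            for name, f_e in ds.fractions.items():
                res.extend((f_e - pred[name]) / ds.sd[name])
        if self.lactate_constraint:
            v_lac = None
            for j, rxn in enumerate(self.network.reactions):
                if rxn.name == "lac_out":
                    v_lac = rec.fluxes[j]
            sd = self.constraint_rel_sd * self.lactate_constraint
            res.append((v_lac - self.lactate_constraint) / sd)
        return np.asarray(res)


# ---------------------------------------------------------------------------
# simulated annealing with coordinate descent
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule and descent effort per local search."""

    t0: float = 10.0                # initial temperature (chi-square units)
    cooling: float = 0.95
    n_temps: int = 20
    per_temp: int = 50              # stochastic perturbations per temperature
    step: float = 0.7               # sd of log-space perturbations
    n_coords: int = 3               # coordinates perturbed per move
    descent_step: float = 0.4       # initial log-space line-search step
    descent_sweeps: int = 2
    descend_every: int = 10         # run descent on every k-th accepted move


@dataclass
class LocalMinimum:
    x: np.ndarray
    chi2: float


def _coordinate_descent(func: Callable[[np.ndarray], float], x: np.ndarray,
                        fx: float, bounds: list[tuple[float, float]],
                        step: float, sweeps: int,
                        order_rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Cyclic per-coordinate line search with step shrinking."""
    x = x.copy()
    h = step
    for _ in range(sweeps):
        order = order_rng.permutation(len(x))
        improved = False
        for i in order:
            for direction in (+1.0, -1.0):
                xt = x.copy()
                xt[i] = np.clip(x[i] + direction * h, *bounds[i])
                if xt[i] == x[i]:
                    continue
                ft = func(xt)
                if ft < fx:
                    x, fx = xt, ft
                    improved = True
                    # keep walking the profitable direction
                    while True:
                        xt = x.copy()
                        xt[i] = np.clip(x[i] + direction * h, *bounds[i])
                        if xt[i] == x[i]:
                            break
                        ft = func(xt)
                        if ft >= fx:
                            break
                        x, fx = xt, ft
                    break
        h *= 0.5
        if not improved and h < 1e-3:
            break
    return x, fx


def anneal_descent(func: Callable[[np.ndarray], float], x0: np.ndarray,
                   bounds: list[tuple[float, float]], seed: int,
                   schedule: AnnealSchedule = AnnealSchedule()
                   ) -> list[LocalMinimum]:
    """Simulated annealing alternated with coordinate descent.

    Returns the archive of local minima (parameter vector, chi-square),
    best first.  Fully reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    fx = func(x)
    archive: list[LocalMinimum] = []
    x, fx = _coordinate_descent(func, x, fx, bounds, schedule.descent_step,
                                schedule.descent_sweeps, rng)
    archive.append(LocalMinimum(x.copy(), fx))
    temp = schedule.t0
    accepted = 0
    for _ in range(schedule.n_temps):
        for _ in range(schedule.per_temp):
            k = min(schedule.n_coords, len(x))
            coords = rng.choice(len(x), size=k, replace=False)
            xt = x.copy()
            xt[coords] += schedule.step * rng.standard_normal(k)
            for i in coords:
                xt[i] = np.clip(xt[i], *bounds[i])
            ft = func(xt)
            if ft < fx or rng.random() < np.exp(-(ft - fx) / temp):
                x, fx = xt, ft
                accepted += 1
                if accepted % schedule.descend_every == 0:
                    x, fx = _coordinate_descent(
                        func, x, fx, bounds, schedule.descent_step,
                        schedule.descent_sweeps, rng)
                    archive.append(LocalMinimum(x.copy(), fx))
        temp *= schedule.cooling
    if not archive:
        raise RuntimeError("annealing accepted no move; empty archive")
    x, fx = _coordinate_descent(func, x, fx, bounds, schedule.descent_step,
                                schedule.descent_sweeps, rng)
    archive.append(LocalMinimum(x.copy(), fx))
    archive.sort(key=lambda m: m.chi2)
    return archive


# ---------------------------------------------------------------------------
# genetic refinement
# ---------------------------------------------------------------------------

def genetic_refine(func: Callable[[np.ndarray], float],
                   archive: Sequence[LocalMinimum],
                   bounds: list[tuple[float, float]], seed: int,
                   population: int = 20, generations: int = 50,
                   mutation_rate: float = 0.3, mutation_sd: float = 0.3
                   ) -> LocalMinimum:
    """Evolve the archived minima by crossover, mutation and selection.

    Elitist: the best individual is never lost, so the returned chi-square
    is never worse than the best archive entry.
    """
    if len(archive) < 2:
        raise ValueError("genetic refinement needs an archive of at least 2")
    rng = np.random.default_rng(seed)
    pool = sorted(archive, key=lambda m: m.chi2)[:population]
    pop = [m.x.copy() for m in pool]
    fit_ = [m.chi2 for m in pool]
    while len(pop) < population:
        base = pop[rng.integers(len(pool))].copy()
        i = rng.integers(len(base))
        base[i] = np.clip(base[i] + mutation_sd * rng.standard_normal(),
                          *bounds[i])
        pop.append(base)
        fit_.append(func(base))
    for _ in range(generations):
        if np.allclose(pop, pop[0]):
            break  # degenerate population: nothing left to recombine
        order = np.argsort(fit_)
        parents = [pop[i] for i in order[:max(2, population // 2)]]
        children: list[np.ndarray] = []
        while len(children) < population // 2:
            a, b = rng.choice(len(parents), size=2, replace=False)
            mask = rng.random(len(parents[0])) < 0.5
            child = np.where(mask, parents[a], parents[b])
            mut = rng.random(len(child)) < mutation_rate
            child = child + mut * mutation_sd * rng.standard_normal(len(child))
            for i in range(len(child)):
                child[i] = np.clip(child[i], *bounds[i])
            children.append(child)
        child_fit = [func(c) for c in children]
        pop.extend(children)
        fit_.extend(child_fit)
        order = np.argsort(fit_)[:population]
        pop = [pop[i] for i in order]
        fit_ = [fit_[i] for i in order]
    best = int(np.argmin(fit_))
    return LocalMinimum(pop[best].copy(), float(fit_[best]))


# ---------------------------------------------------------------------------
# confidence intervals and the full fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: ParameterSet
    fluxes: np.ndarray
    chi2: float
    dilution: dict[str, float]
    archive: list[LocalMinimum]
    seed: int
    flux_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.archive:
            if self.chi2 > m.chi2 + 1e-12:
                raise ValueError("best chi2 exceeds an archived minimum")

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "seed": self.seed,
            "parameters": {k: self.params.values[k] for k in self.params.free},
            "dilution": self.dilution,
            "fluxes": dict(zip(self.flux_names, map(float, self.fluxes))),
            "archive_chi2": [m.chi2 for m in self.archive],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def confidence_intervals(objective: PipelineObjective, result: FitResult,
                         confidence_level: float = 0.95,
                         min_samples: int = 10, max_extra: int = 60,
                         seed: int = 0) -> dict[str, tuple[float, float]]:
    """Per-flux intervals from all sampled sets within the chi-square threshold.

    Delta is the one-parameter profile threshold at the requested level
    (chi2.ppf(level, 1); 3.84 at 95%).  If too few of the already-sampled
    sets fall below the threshold, extra points are sampled around the best
    fit with shrinking spread (a widened sampling pass).
    """
    if confidence_level <= 0:
        return {name: (float(v), float(v)) for name, v in
                zip(result.flux_names, result.fluxes)}
    delta = float(stats.chi2.ppf(confidence_level, df=1))
    threshold = result.chi2 + delta
    rng = np.random.default_rng(seed)

    def within() -> list[EvalRecord]:
        return [r for r in objective.trace
                if r.fluxes is not None and r.chi2 <= threshold]

    extra = 0
    x_best = objective.to_vector(result.params)
    bounds = objective.log_bounds()
    n = len(x_best)
    # per-coordinate profile scan: walk each free parameter outward until
    # the chi-square threshold is crossed (then bisect the crossing), so
    # flat (weakly identified) directions contribute their full extent and
    # stiff directions still get a resolved, non-degenerate endpoint
    for i in range(n):
        for direction in (+1.0, -1.0):
            last_in, first_out = 0.0, None
            for step in (0.08, 0.2, 0.5, 1.0, 2.0):
                xt = x_best.copy()
                xt[i] = np.clip(x_best[i] + direction * step, *bounds[i])
                if objective(xt) > threshold:
                    first_out = step
                    break
                last_in = step
            if first_out is not None:
                for _ in range(2):      # refine the threshold crossing
                    mid = 0.5 * (last_in + first_out)
                    xt = x_best.copy()
                    xt[i] = np.clip(x_best[i] + direction * mid, *bounds[i])
                    if objective(xt) > threshold:
                        first_out = mid
                    else:
                        last_in = mid
    inside = within()
    while len(inside) < min_samples and extra < max_extra:
        # move small random coordinate subsets with mixed spread: wide
        # single-coordinate draws probe how far flat (weakly identified)
        # directions extend without leaving the threshold set through the
        # stiff ones
        sigma = rng.uniform(0.1, 1.2)
        k = int(rng.integers(1, min(3, n) + 1))
        coords = rng.choice(n, size=k, replace=False)
        xt = x_best.copy()
        xt[coords] += sigma * rng.standard_normal(k)
        for i in coords:
            xt[i] = np.clip(xt[i], *bounds[i])
        objective(xt)
        extra += 1
        inside = within()
    fluxes = np.array([r.fluxes for r in inside])
    out: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(result.flux_names):
        col = fluxes[:, j]
        lo, hi = float(col.min()), float(col.max())
        # the interval must contain the point estimate
        lo = min(lo, float(result.fluxes[j]))
        hi = max(hi, float(result.fluxes[j]))
        out[name] = (lo, hi)
    return out


def polish_least_squares(objective: PipelineObjective, x0: np.ndarray,
                         max_iter: int = 40,
                         diff_step: float = 2e-3) -> LocalMinimum:
    """Deterministic local refinement of a candidate by damped least squares.

    Operates on the same sd-weighted residual vector the chi-square sums,
    with finite-difference sensitivities in log-parameter space.  Used as
    the final polish after the stochastic stages; it cannot leave the
    basin the stochastic search delivered it to.
    """
    from scipy.optimize import least_squares

    sol = least_squares(objective.residuals, np.asarray(x0, dtype=float),
                        method="trf", max_nfev=max_iter, x_scale=0.3,
                        diff_step=diff_step, xtol=3e-16, ftol=1e-12,
                        gtol=1e-14)
    return LocalMinimum(sol.x.copy(), float(2 * sol.cost))


def fit(network: ReactionNetwork, base_params: ParameterSet,
        datasets: Sequence[MIDDataset], seed: int,
        schedule: AnnealSchedule = AnnealSchedule(),
        population: int = 20, generations: int = 50,
        polish_iter: int = 0,
        objective: PipelineObjective | None = None) -> tuple[FitResult,
                                                             PipelineObjective]:
    """Full two-stage fit; returns the result and the (trace-bearing) objective."""
    obj = objective or PipelineObjective(network, base_params, datasets)
    x0 = obj.to_vector(base_params)
    bounds = obj.log_bounds()
    archive = anneal_descent(obj, x0, bounds, seed, schedule)
    if len(archive) >= 2 and population >= 2 and generations > 0:
        best = genetic_refine(obj, archive, bounds, seed + 1,
                              population=population, generations=generations)
    else:
        best = archive[0]
    if polish_iter > 0:
        polished = polish_least_squares(obj, best.x, max_iter=polish_iter)
        if polished.chi2 < best.chi2:
            best = polished
    rec = obj.evaluate(obj.to_params(best.x))
    result = FitResult(
        params=obj.to_params(best.x), fluxes=rec.fluxes, chi2=rec.chi2,
        dilution=rec.dilution, archive=archive, seed=seed,
        flux_names=[r.name for r in network.reactions])
    return result, obj
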