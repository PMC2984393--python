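import numpy as np
import pytest

from labeldyn.fitting import (AnnealSchedule, EvalRecord, FitResult,
                              LocalMinimum, anneal_descent,
                              confidence_intervals, genetic_refine)
from labeldyn.network import ParameterSet

BOUNDS2 = [(-5.0, 5.0)] * 2
FAST = AnnealSchedule(t0=2.0, n_temps=4, per_temp=8, step=0.8,
                      descent_step=0.5, descent_sweeps=14, descend_every=3)


def quadratic(x):
    return float((x[0] - 1.2) ** 2 + 2.0 * (x[1] + 0.4) ** 2)


def two_well(x):
    # wells near x = -1 (depth 0) and x = +1 (depth 0.5)
    return float((x[0] ** 2 - 1.0) ** 2 + 0.25 * (x[0] + 1.0) + 0.25)


def rosenbrock(x):
    return float((1 - x[0]) ** 2 + 100.0 * (x[1] - x[0] ** 2) ** 2)


class TestAnnealDescent:
    def test_converges_on_convex_quadratic(self):
        archive = anneal_descent(quadratic, np.zeros(2), BOUNDS2, seed=0,
                                 schedule=FAST)
        assert archive[0].chi2 < 1e-6

    def test_reproducible_archive(self):
        a1 = anneal_descent(quadratic, np.zeros(2), BOUNDS2, seed=3,
                            schedule=FAST)
        a2 = anneal_descent(quadratic, np.zeros(2), BOUNDS2, seed=3,
                            schedule=FAST)
        assert len(a1) == len(a2)
        for m1, m2 in zip(a1, a2):
            assert m1.chi2 == m2.chi2
            assert np.array_equal(m1.x, m2.x)

    def test_two_well_archive_visits_both_wells(self):
        # brute-force scan of the test function locates the two wells
        grid = np.linspace(-5, 5, 20001)
        vals = np.array([two_well([g]) for g in grid])
        left_well = grid[np.argmin(np.where(grid < 0, vals, np.inf))]
        right_well = grid[np.argmin(np.where(grid > 0, vals, np.inf))]
        schedule = AnnealSchedule(t0=2.0, n_temps=6, per_temp=25, step=1.2,
                                  n_coords=1, descent_step=0.4,
                                  descent_sweeps=3, descend_every=2)
        archive = anneal_descent(two_well, np.array([0.2]), [(-5.0, 5.0)],
                                 seed=1, schedule=schedule)
        xs = np.array([m.x[0] for m in archive])
        assert np.any(np.abs(xs - left_well) < 0.05)
        assert np.any(np.abs(xs - right_well) < 0.05)


class TestGeneticRefine:
    def test_keeps_global_optimum_from_archive(self):
        archive = [LocalMinimum(np.array([1.2, -0.4]), 0.0),
                   LocalMinimum(np.array([0.0, 0.0]), quadratic([0, 0]))]
        best = genetic_refine(quadratic, archive, BOUNDS2, seed=0,
                              population=6, generations=5)
        assert best.chi2 == 0.0

    def test_improves_rosenbrock_over_poor_archive(self):
        rng = np.random.default_rng(0)
        archive = [LocalMinimum(rng.uniform(-2, 2, 2), None) for _ in range(6)]
        for m in archive:
            m.chi2 = rosenbrock(m.x)
        start_best = min(m.chi2 for m in archive)
        best = genetic_refine(rosenbrock, archive, BOUNDS2, seed=2,
                              population=10, generations=30)
        assert best.chi2 < start_best
        assert best.chi2 < 0.5 * start_best

    def test_reproducible_winner(self):
        archive = [LocalMinimum(np.array([0.0, 0.0]), quadratic([0, 0])),
                   LocalMinimum(np.array([2.0, 2.0]), quadratic([2, 2]))]
        b1 = genetic_refine(quadratic, archive, BOUNDS2, seed=5,
                            population=6, generations=10)
        b2 = genetic_refine(quadratic, archive, BOUNDS2, seed=5,
                            population=6, generations=10)
        assert b1.chi2 == b2.chi2 and np.array_equal(b1.x, b2.x)

    def test_monotone_best_across_generations(self):
        archive = [LocalMinimum(np.array([-1.0, 3.0]), rosenbrock([-1, 3])),
                   LocalMinimum(np.array([2.0, -2.0]), rosenbrock([2, -2]))]
        prev = np.inf
        for gen in (1, 3, 6, 10):
            best = genetic_refine(rosenbrock, archive, BOUNDS2, seed=7,
                                  population=8, generations=gen)
            assert best.chi2 <= prev + 1e-12
            prev = best.chi2

    def test_needs_archive_of_two(self):
        with pytest.raises(ValueError):
            genetic_refine(quadratic, [LocalMinimum(np.zeros(2), 0.0)],
                           BOUNDS2, seed=0)


class _DuckObjective:
    """Pipeline-objective stand-in whose 'fluxes' are the parameters.

    Synthetic (test-only): lets the confidence-interval logic be exercised
    against analytically transparent objectives.
    """

    def __init__(self, fun, free=("a", "b")):
        self.fun = fun
        self.free = free
        self.base = ParameterSet({k: 1.0 for k in free}, tuple(free),
                                 default_bounds=(1e-3, 1e3))
        self.trace = []

    def to_vector(self, p):
        return np.log(p.vector())

    def to_params(self, x):
        return self.base.with_vector(np.clip(np.exp(x), 1e-3, 1e3))

    def log_bounds(self):
        return [tuple(np.log(self.base.bound(k))) for k in self.free]

    def __call__(self, x):
        fluxes = np.exp(np.asarray(x))
        chi2 = float(self.fun(fluxes))
        self.trace.append(EvalRecord(np.asarray(x), chi2, fluxes))
        return chi2


def _result_for(obj, x_best):
    chi2 = obj(x_best)
    rec = obj.trace[-1]
    return FitResult(params=obj.to_params(x_best), fluxes=rec.fluxes,
                     chi2=chi2, dilution={}, archive=[LocalMinimum(
                         np.asarray(x_best), chi2)], seed=0,
                     flux_names=list(obj.free))


class TestConfidenceIntervals:
    def test_zero_level_collapses_to_point(self):
        obj = _DuckObjective(lambda f: (f[0] - 1) ** 2 + (f[1] - 2) ** 2)
        res = _result_for(obj, np.log([1.0, 2.0]))
        ci = confidence_intervals(obj, res, confidence_level=0.0)
        for name, (lo, hi) in ci.items():
            assert lo == hi

    def test_identifiable_parameter_has_finite_interval(self):
        obj = _DuckObjective(lambda f: 200 * (f[0] - 1) ** 2 +
                             200 * (f[1] - 2) ** 2)
        res = _result_for(obj, np.log([1.0, 2.0]))
        ci = confidence_intervals(obj, res, 0.95, min_samples=30,
                                  max_extra=200, seed=1)
        lo, hi = ci["a"]
        assert lo <= 1.0 <= hi
        assert hi - lo < 1.0

    def test_non_identifiable_pair_has_wide_intervals(self):
        """Only the product f_a * f_b is constrained: a redundant cycle."""
        obj = _DuckObjective(lambda f: 500 * (f[0] * f[1] - 1.0) ** 2)
        res = _result_for(obj, np.log([1.0, 1.0]))
        ci = confidence_intervals(obj, res, 0.95, min_samples=40,
                                  max_extra=300, seed=2)
        width_a = ci["a"][1] - ci["a"][0]
        # compare with an identifiable objective of similar curvature
        obj2 = _DuckObjective(lambda f: 500 * (f[0] - 1.0) ** 2 +
                              500 * (f[1] - 1.0) ** 2)
        res2 = _result_for(obj2, np.log([1.0, 1.0]))
        ci2 = confidence_intervals(obj2, res2, 0.95, min_samples=40,
                                   max_extra=300, seed=2)
        width_a2 = ci2["a"][1] - ci2["a"][0]
        assert width_a > 2.0 * width_a2

    def test_interval_contains_best_fit(self):
        obj = _DuckObjective(lambda f: (f[0] - 1) ** 2)
        res = _result_for(obj, np.log([1.0, 1.0]))
        ci = confidence_intervals(obj, res, 0.95, min_samples=10,
                                  max_extra=50, seed=0)
        for name, (lo, hi) in ci.items():
            v = res.fluxes[list(obj.free).index(name)]
            assert lo <= v <= hi


def test_fit_result_rejects_inconsistent_archive():
    p = ParameterSet({"a": 1.0}, ("a",))
    with pytest.raises(ValueError):
        FitResult(params=p, fluxes=np.array([1.0]), chi2=2.0, dilution={},
                  archive=[LocalMinimum(np.zeros(1), 1.0)], seed=0,
                  flux_names=["a"])
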