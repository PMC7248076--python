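"""Parameter estimation: log-deviation fitness and a (1+3)-evolution
strategy.

The fitness of a candidate parameter set against an observed time course is
the integrated absolute log-deviation

    integral_{t0}^{t1} | log f_model(t) - log f_data(t) | dt,

with the data represented by the piecewise-linear interpolant of the
observations and the integral evaluated by trapezoidal quadrature on the
union of the model and data grids.  Fitness values of several datasets are
added.  Minimisation uses an elitist (1+3)-evolution strategy: one possibly
immortal parent produces three children per generation by per-coordinate
log-normal mutation; the parent is replaced only by a strictly fitter
child, and the mutation step self-adapts (up on success, down on failure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .engine import DEFAULT_GRID, SimulationError, Trajectory, simulate
from .interventions import Scenario
from .parameters import ParameterError, ParameterSet


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Observed (or synthetic) time course of one observable.

    Times are days from scenario start and must be strictly increasing;
    values must be positive because the fitness works on log-scale.
    """

    observable: str
    times: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise CalibrationError(
                f"dataset {self.observable!r}: need at least two time points")
        if self.times.size != self.values.size:
            raise CalibrationError(
                f"dataset {self.observable!r}: times and values differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise CalibrationError(
                f"dataset {self.observable!r}: times must be strictly increasing")
        if np.any(self.values <= 0):
            t_bad = float(self.times[np.argmax(self.values <= 0)])
            raise CalibrationError(
                f"dataset {self.observable!r}: nonpositive value at t={t_bad:g}")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def fitness(model: "Trajectory | tuple[np.ndarray, np.ndarray]",
            dataset: "TimeSeriesDataset | Sequence[TimeSeriesDataset]") -> float:
    """Integrated absolute log-deviation between model and data.

    ``model`` is either a :class:`~ferropoiesis.engine.Trajectory` (the
    observable named by each dataset is extracted) or a ``(times, values)``
    pair.  A sequence of datasets yields the sum of the individual fitness
    values.
    """
    datasets = [dataset] if isinstance(dataset, TimeSeriesDataset) else list(dataset)
    total = 0.0
    for ds in datasets:
        if isinstance(model, Trajectory):
            t_m, y_m = model.times, model.series(ds.observable)
        else:
            t_m, y_m = np.asarray(model[0], float), np.asarray(model[1], float)
        total += _log_deviation(t_m, y_m, ds)
    return total


def _log_deviation(t_model: np.ndarray, y_model: np.ndarray,
                   ds: TimeSeriesDataset) -> float:
    t0, t1 = ds.span
    if t_model[0] > t0 + 1e-9 or t_model[-1] < t1 - 1e-9:
        raise CalibrationError(
            f"model trajectory does not cover the data span [{t0:g}, {t1:g}] "
            f"of {ds.observable!r}")
    inside = t_model[(t_model >= t0) & (t_model <= t1)]
    grid = np.union1d(inside, ds.times)
    m = np.interp(grid, t_model, y_model)
    d = np.interp(grid, ds.times, ds.values)
    if np.any(m <= 0):
        t_bad = float(grid[np.argmax(m <= 0)])
        raise CalibrationError(
            f"model value for {ds.observable!r} is nonpositive at t={t_bad:g}; "
            "log-deviation fitness undefined")
    return float(np.trapezoid(np.abs(np.log(m) - np.log(d)), grid))


@dataclass(frozen=True)
class FitSpec:
    """Specification of one calibration run.

    ``parameters`` maps dotted parameter paths (e.g. ``"iron.k_S"``) to
    positive, finite ``(lower, upper)`` bounds; mutation acts on log-scale
    so bounds are respected naturally.  ``start`` defaults to the geometric
    midpoint of the bounds.  ``ftol_rel`` stops early once the parent
    fitness falls below that fraction of the initial fitness.
    """

    parameters: dict[str, tuple[float, float]]
    start: dict[str, float] | None = None
    generations: int = 300
    initial_step: float = 0.3
    step_up: float = 1.3
    step_down: float = 1.3 ** -0.25
    ftol_rel: float | None = None
    seed: int = 0
    max_failed_generations: int = 20

    def __post_init__(self):
        if not self.parameters:
            raise CalibrationError("FitSpec needs at least one free parameter")
        for name, (lo, hi) in self.parameters.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
                raise CalibrationError(
                    f"bounds for {name!r} must be finite with 0 < lower < upper")
        if self.start is not None:
            for name, v in self.start.items():
                if name not in self.parameters:
                    raise CalibrationError(f"start value for unknown parameter {name!r}")
                lo, hi = self.parameters[name]
                if not lo <= v <= hi:
                    raise CalibrationError(f"start value for {name!r} outside bounds")
        if self.generations < 1:
            raise CalibrationError("generations must be >= 1")
        if self.initial_step < 0:
            raise CalibrationError("initial_step must be >= 0")


@dataclass
class ESResult:
    best: dict[str, float]
    best_fitness: float
    trace: np.ndarray
    evaluations: int
    converged: bool


def es_optimize(fit_spec: FitSpec,
                objective: Callable[[Mapping[str, float]], float]) -> ESResult:
    """Minimise ``objective`` with a (1+3)-evolution strategy.

    ``objective`` maps a parameter dict to a non-negative fitness; raising
    :class:`SimulationError` or :class:`CalibrationError` marks a child as
    unviable.  Runs are bit-reproducible for a fixed ``fit_spec.seed``.
    """
    rng = np.random.default_rng(fit_spec.seed)
    names = list(fit_spec.parameters)
    lo = np.log([fit_spec.parameters[n][0] for n in names])
    hi = np.log([fit_spec.parameters[n][1] for n in names])
    if fit_spec.start is None:
        z = 0.5 * (lo + hi)
    else:
        start = {**{n: math.exp(0.5 * (l + h)) for n, l, h in zip(names, lo, hi)},
                 **fit_spec.start}
        z = np.log([start[n] for n in names])
    steps = np.full(len(names), fit_spec.initial_step)

    def evaluate(zz: np.ndarray) -> float:
        try:
            return float(objective(dict(zip(names, np.exp(zz)))))
        except (SimulationError, CalibrationError, ParameterError):
            # inadmissible or unintegrable candidate: unviable child
            return math.inf

    f_parent = evaluate(z)
    if not math.isfinite(f_parent):
        raise CalibrationError("objective failed at the starting point")
    f_initial = f_parent
    trace = [f_parent]
    evaluations = 1
    converged = False
    failed_streak = 0
    for _ in range(fit_spec.generations):
        children = z + steps * rng.standard_normal((3, len(names)))
        np.clip(children, lo, hi, out=children)
        f_children = np.array([evaluate(c) for c in children])
        evaluations += 3
        if not np.any(np.isfinite(f_children)):
            failed_streak += 1
            if failed_streak >= fit_spec.max_failed_generations:
                raise CalibrationError(
                    f"all children failed for {failed_streak} consecutive "
                    "generations; check bounds and scenario")
        else:
            failed_streak = 0
        best = int(np.argmin(f_children))
        if f_children[best] < f_parent:  # strict: elitist, possibly immortal parent
            f_parent = float(f_children[best])
            z = children[best]
            steps = steps * fit_spec.step_up
        else:
            steps = steps * fit_spec.step_down
        trace.append(f_parent)
        if fit_spec.ftol_rel is not None and f_parent <= fit_spec.ftol_rel * f_initial:
            converged = True
            break
    return ESResult(best={n: float(v) for n, v in zip(names, np.exp(z))},
                    best_fitness=f_parent,
                    trace=np.asarray(trace), evaluations=evaluations,
                    converged=converged)


def make_objective(base_params: ParameterSet, scenario: Scenario,
                   datasets: Sequence[TimeSeriesDataset],
                   grid: float = 0.25, rtol: float = 1e-6,
                   atol: float = 1e-9) -> Callable[[Mapping[str, float]], float]:
    """Objective for :func:`es_optimize`: simulate the scenario with the
    candidate parameters installed and sum the dataset fitness values."""
    datasets = list(datasets)

    def objective(values: Mapping[str, float]) -> float:
        params = base_params.with_updates(dict(values))
        traj = simulate(scenario, params, grid=grid, rtol=rtol, atol=atol)
        return fitness(traj, datasets)

    return objective


def fit(base_params: ParameterSet, scenario: Scenario,
        datasets: Sequence[TimeSeriesDataset], fit_spec: FitSpec,
        grid: float = 0.25, rtol: float = 1e-6, atol: float = 1e-9,
        ) -> tuple[ParameterSet, ESResult]:
    """Calibrate the named free parameters against the datasets.

    Returns the parameter set with the best values installed (derived
    constants re-derived) together with the optimisation result.
    """
    objective = make_objective(base_params, scenario, datasets,
                               grid=grid, rtol=rtol, atol=atol)
    result = es_optimize(fit_spec, objective)
    return base_params.with_updates(result.best), result


def synthesize_dataset(params: ParameterSet, scenario: Scenario,
                       observables: Iterable[str],
                       sample_times: Sequence[float], noise_cv: float,
                       seed: int, grid: float = DEFAULT_GRID,
                       rtol: float = 1e-8) -> list[TimeSeriesDataset]:
    """Generate synthetic calibration targets from a simulated scenario.

    Observables are sampled at ``sample_times`` and perturbed by
    multiplicative, mean-preserving log-normal noise with coefficient of
    variation ``noise_cv``; reproducible under ``seed``.
    """
    if noise_cv < 0:
        raise CalibrationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    traj = simulate(scenario, params, grid=grid, rtol=rtol)
    sample_times = np.asarray(sample_times, dtype=float)
    out = []
    sigma = math.sqrt(math.log1p(noise_cv ** 2))
    for name in observables:
        clean = np.interp(sample_times, traj.times, traj.series(name))
        if noise_cv > 0:
            noise = np.exp(sigma * rng.standard_normal(sample_times.size)
                           - 0.5 * sigma ** 2)
            values = clean * noise
        else:
            values = clean
        out.append(TimeSeriesDataset(observable=name, times=sample_times,
                                     values=values,
                                     sd=noise_cv * clean if noise_cv > 0 else None))
    return out
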