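"""Sensor-placement optimization by generalized simulated annealing.

The array configuration is encoded as a flat parameter vector with box
bounds, which is what the annealer requires:

* per sensor, two surface coordinates ``(u, v)`` -- cumulative-area fraction
  along the helmet meridian and normalized azimuth over the admissible
  sector -- so every point of the box decodes to an admissible position;
* for a 3D shell volume, one radial coordinate ``t`` in [0, 1] mapping the
  inner to the outer surface;
* two orientation angles (polar, azimuth); the decoded orientation is always
  an exact unit vector.

The cost of a parameter vector is the worst-case noise amplification ``q`` of
the decoded array.  The search itself is delegated to
:func:`scipy.optimize.dual_annealing` (classical + fast simulated annealing
with a local search on accepted candidates); the parameterization, cost,
trajectory logging and checkpointing live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import dual_annealing

from .basis import MultipoleBasisSpec, basis_matrix
from .geometry import (
    HelmetShell3D,
    SamplingGrid,
    SamplingVolume,
    SensorArray,
)
from .noise import NoiseEvaluator

__all__ = [
    "ArrayParameterization",
    "OptimizerConfig",
    "TrajectoryPoint",
    "OptimizationTrajectory",
    "cost",
    "optimize",
    "orientation_diagnostics",
]


class ArrayParameterization:
    """Bijective (up to angle wraparound) map between arrays and box vectors."""

    def __init__(self, volume: SamplingVolume, n_sensors: int):
        if n_sensors < 1:
            raise ValueError("need at least one sensor")
        self.volume = volume
        self.n_sensors = n_sensors
        self.is_3d = isinstance(volume, HelmetShell3D)
        self.params_per_sensor = 5 if self.is_3d else 4

    @property
    def n_params(self) -> int:
        return self.n_sensors * self.params_per_sensor

    @property
    def bounds(self) -> np.ndarray:
        """(n_params, 2) box: position coords in [0, 1], polar angle in
        [0, pi], azimuth in [0, 2*pi]."""
        k = self.params_per_sensor
        lo = np.zeros(self.n_params)
        hi = np.ones(self.n_params)
        hi[k - 2 :: k] = np.pi  # orientation polar angle
        hi[k - 1 :: k] = 2 * np.pi  # orientation azimuth
        return np.stack([lo, hi], axis=1)

    def encode(self, array: SensorArray) -> np.ndarray:
        if len(array) != self.n_sensors:
            raise ValueError(
                f"array has {len(array)} sensors, parameterization expects "
                f"{self.n_sensors}"
            )
        ori = array.orientations
        theta = np.arccos(np.clip(ori[:, 2], -1.0, 1.0))
        phi = np.arctan2(ori[:, 1], ori[:, 0]) % (2 * np.pi)
        if self.is_3d:
            uvt = np.atleast_2d(self.volume.params_from_point(array.positions))
            cols = [uvt[:, 0], uvt[:, 1], uvt[:, 2], theta, phi]
        else:
            uv = np.atleast_2d(self.volume.params_from_point(array.positions))
            cols = [uv[:, 0], uv[:, 1], theta, phi]
        return np.stack(cols, axis=1).ravel()

    def decode(self, params: np.ndarray) -> SensorArray:
        x = np.asarray(params, dtype=float).reshape(
            self.n_sensors, self.params_per_sensor
        )
        # annealer proposals may sit exactly on (or marginally outside) the
        # box; clamp into the admissible set
        u = np.clip(x[:, 0], 0.0, 1.0)
        v = np.clip(x[:, 1], 0.0, 1.0)
        if self.is_3d:
            t = np.clip(x[:, 2], 0.0, 1.0)
            pos = self.volume.point_from_params(u, v, t)
        else:
            pos = self.volume.point_from_params(u, v)
        theta, phi = x[:, -2], x[:, -1]
        ori = np.stack(
            [
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ],
            axis=1,
        )
        return SensorArray(np.atleast_2d(pos), ori)


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for an annealing run.

    ``max_global_iterations`` and ``max_cost_evaluations`` default to the
    annealer's standard budget (1000 iterations, 1e7 evaluations); scale them
    down for quick runs.  ``local_search_steps`` caps each local-search
    polish (numerical gradients make unbounded local searches expensive).
    """

    basis: MultipoleBasisSpec = field(default_factory=MultipoleBasisSpec)
    max_global_iterations: int = 1000
    max_cost_evaluations: int = 10_000_000
    seed: int = 0
    grid_points: int | None = None
    checkpoint_every: int = 10_000
    local_search_steps: int | None = 20
    no_local_search: bool = False
    initial_temp: float = 5230.0

    def __post_init__(self) -> None:
        if self.max_global_iterations < 0 or self.max_cost_evaluations < 1:
            raise ValueError("iteration and evaluation limits must be positive")


@dataclass(frozen=True)
class TrajectoryPoint:
    iteration: int
    n_cost_evals: int
    best_q: float
    mean_amp: float


@dataclass
class OptimizationTrajectory:
    """Best-so-far history of an annealing run plus array snapshots."""

    points: list[TrajectoryPoint]
    snapshots: list[tuple[int, SensorArray]]
    initial: SensorArray
    final: SensorArray
    initial_q: float
    final_q: float
    seed: int
    n_cost_evals: int

    @property
    def best_q_sequence(self) -> np.ndarray:
        return np.array([p.best_q for p in self.points])


def cost(
    params: np.ndarray,
    parameterization: ArrayParameterization,
    evaluator: NoiseEvaluator,
) -> float:
    """Figure-of-merit ``q`` of the decoded parameter vector."""
    array = parameterization.decode(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transient rank deficiency mid-search
        return evaluator.amplification(
            basis_matrix(array, evaluator.spec)
        ).q


def optimize(
    initial: SensorArray,
    volume: SamplingVolume,
    config: OptimizerConfig,
    grid: SamplingGrid | None = None,
    progress: Callable[[TrajectoryPoint], None] | None = None,
) -> OptimizationTrajectory:
    """Minimize the figure-of-merit over sensor positions and orientations.

    Runs dual annealing from the encoded initial array; reproducible for a
    fixed ``config.seed``.  A zero-iteration budget returns a trajectory
    holding only the initial array.
    """
    spec = config.basis
    m = len(initial)
    if not np.all(volume.contains(initial.positions, tol=1e-6)):
        raise ValueError("initial array has sensors outside the sampling volume")
    if m < spec.n_components:
        warnings.warn(
            f"{m} sensors < {spec.n_components} basis components: the "
            "measurement matrix cannot reach full column rank",
            stacklevel=2,
        )
    param = ArrayParameterization(volume, m)
    if grid is None and config.grid_points is not None:
        from .geometry import sampling_grid

        grid = sampling_grid(volume, n_points=config.grid_points)
    evaluator = NoiseEvaluator(volume, spec, grid=grid)

    def q_and_mean(array: SensorArray) -> tuple[float, float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = evaluator.evaluate_array(array)
        return f.q, f.mean_amp

    q0, mean0 = q_and_mean(initial)
    state = {
        "n_evals": 0,
        "best_q": q0,
        "best_x": param.encode(initial),
        "iteration": 0,
    }
    points = [TrajectoryPoint(0, 0, q0, mean0)]
    snapshots: list[tuple[int, SensorArray]] = [(0, initial)]

    if config.max_global_iterations == 0:
        return OptimizationTrajectory(
            points, snapshots, initial, initial, q0, q0, config.seed, 0
        )

    def objective(x: np.ndarray) -> float:
        state["n_evals"] += 1
        array = param.decode(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # transient rank deficiency
            f = evaluator.evaluate_array(array)
        improved = f.q < state["best_q"]
        if improved:
            state["best_q"] = f.q
            state["best_x"] = x.copy()
            state["best_mean"] = f.mean_amp
        if improved or state["n_evals"] % config.checkpoint_every == 0:
            pt = TrajectoryPoint(
                state["iteration"],
                state["n_evals"],
                state["best_q"],
                state.get("best_mean", f.mean_amp),
            )
            points.append(pt)
            if progress is not None:
                progress(pt)
            if state["n_evals"] % config.checkpoint_every == 0:
                snapshots.append((state["n_evals"], param.decode(state["best_x"])))
        return f.q

    def on_iteration(x, f, context) -> None:
        state["iteration"] += 1

    minimizer_kwargs = None
    if config.local_search_steps is not None and not config.no_local_search:
        minimizer_kwargs = {
            "method": "L-BFGS-B",
            "options": {"maxiter": config.local_search_steps},
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dual_annealing(
            objective,
            bounds=param.bounds,
            x0=param.encode(initial),
            maxiter=config.max_global_iterations,
            maxfun=config.max_cost_evaluations,
            seed=config.seed,
            no_local_search=config.no_local_search,
            initial_temp=config.initial_temp,
            minimizer_kwargs=minimizer_kwargs,
            callback=on_iteration,
        )

    final = param.decode(state["best_x"])
    final_q, final_mean = q_and_mean(final)
    points.append(
        TrajectoryPoint(state["iteration"], state["n_evals"], final_q, final_mean)
    )
    snapshots.append((state["n_evals"], final))
    return OptimizationTrajectory(
        points=points,
        snapshots=snapshots,
        initial=initial,
        final=final,
        initial_q=q0,
        final_q=final_q,
        seed=config.seed,
        n_cost_evals=state["n_evals"],
    )


def orientation_diagnostics(
    array: SensorArray, bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of angles between sensor orientations and the outward
    spherical radial direction (origin at the helmet center).

    Returns ``(angles, counts)`` where ``angles`` are the per-sensor angles in
    [0, pi] and ``counts`` are histogram counts over ``bins`` equal bins
    (summing to the number of sensors).
    """
    pos = array.positions
    r = np.linalg.norm(pos, axis=1)
    if np.any(r == 0):
        raise ValueError("sensor at the origin has no radial direction")
    radial = pos / r[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", radial, array.orientations), -1.0, 1.0)
    angles = np.arccos(cosang)
    counts, _ = np.histogram(angles, bins=bins, range=(0.0, np.pi))
    return angles, counts
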