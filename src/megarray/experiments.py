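"""Experiment drivers: radial-array sweeps, optimization runs, array reports.

Each driver is a plain function taking explicit parameters (with defaults
matching the standard study configuration) and writing delimited-text outputs
into a directory, so runs are reproducible from the recorded configuration
and seed alone.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .anneal import (
    OptimizerConfig,
    OptimizationTrajectory,
    optimize,
    orientation_diagnostics,
)
from .basis import MultipoleBasisSpec, basis_matrix
from .capacity import (
    DEFAULT_N_DIPOLES,
    DEFAULT_NOISE_SD,
    DEFAULT_SOURCE_RADIUS,
    DEFAULT_TOTAL_RMS_MOMENT,
    array_capacity,
    sample_dipole_ensemble,
)
from .geometry import (
    HelmetShell3D,
    HelmetSurface,
    SensorArray,
    radial_array,
    sampling_grid,
)
from .io import write_config, write_noise_map, write_sensor_array, write_trajectory_log
from .noise import NoiseEvaluator, pseudoinverse

__all__ = ["run_radial_sweep", "run_optimization_experiment", "evaluate_array"]


def run_radial_sweep(
    sensor_counts=(120, 160, 200, 240, 280, 320),
    radii=(0.15, 0.2, 0.25),
    spec: MultipoleBasisSpec | None = None,
    grid_points: int | None = None,
    output_dir: Path | None = None,
) -> list[dict]:
    """Noise amplification of uniformly-spaced radial arrays over (N, R).

    Returns a list of ``{"n_sensors", "radius", "q", "mean_amp", "rank"}``
    records; optionally writes them as a TSV table.  Arrays with fewer
    sensors than basis components are evaluated with the minimum-norm
    pseudoinverse (their ``rank`` column shows the deficiency).
    """
    spec = spec or MultipoleBasisSpec()
    rows = []
    for R in radii:
        surface = HelmetSurface(radius=R)
        evaluator = NoiseEvaluator(
            surface, spec, grid=sampling_grid(surface, n_points=grid_points)
            if grid_points
            else None,
        )
        for N in sensor_counts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = evaluator.evaluate_array(radial_array(surface, N))
            rows.append(
                {
                    "n_sensors": N,
                    "radius": R,
                    "q": f.q,
                    "mean_amp": f.mean_amp,
                    "rank": f.rank,
                }
            )
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        lines = ["n_sensors\tradius\tq\tmean_amp\trank"]
        for row in rows:
            lines.append(
                f"{row['n_sensors']}\t{row['radius']:.6g}\t{row['q']:.9e}"
                f"\t{row['mean_amp']:.9e}\t{row['rank']}"
            )
        (output_dir / "radial_sweep.tsv").write_text("\n".join(lines) + "\n")
    return rows


def run_optimization_experiment(
    volume,
    n_sensors: int,
    config: OptimizerConfig,
    output_dir: Path,
    initial_radius_fraction: float = 1.0,
    capacity_seed: int | None = None,
) -> OptimizationTrajectory:
    """Optimize an array from a radial initialization and record everything.

    For a 3D shell, ``initial_radius_fraction`` places the initial radial
    array on the surface at that fractional depth (1.0 = outer surface).
    Writes the trajectory log, initial/final arrays, the final noise map and
    a summary (final q, capacities) into ``output_dir``.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, HelmetShell3D):
        init_surface = volume.surface(initial_radius_fraction)
    else:
        init_surface = volume
    initial = radial_array(init_surface, n_sensors)
    write_config(
        {
            "n_sensors": n_sensors,
            "volume": repr(volume),
            "initial_radius_fraction": initial_radius_fraction,
            **{
                k: (v if np.isscalar(v) or v is None else repr(v))
                for k, v in asdict(config).items()
            },
        },
        output_dir / "config.yaml",
    )
    trajectory = optimize(initial, volume, config)
    write_trajectory_log(trajectory, output_dir / "trajectory.tsv")
    write_sensor_array(initial, output_dir / "array_initial.tsv")
    write_sensor_array(trajectory.final, output_dir / "array_final.tsv")
    for n_evals, snapshot in trajectory.snapshots:
        write_sensor_array(snapshot, output_dir / f"array_evals{n_evals:08d}.tsv")
    seed = config.seed if capacity_seed is None else capacity_seed
    ensemble = sample_dipole_ensemble(seed=seed)
    cap_initial = array_capacity(initial, ensemble=ensemble)
    cap_final = array_capacity(trajectory.final, ensemble=ensemble)
    evaluator = NoiseEvaluator(volume, config.basis)
    final_field = evaluator.evaluate_array(trajectory.final)
    write_noise_map(
        final_field,
        output_dir / "noise_map_final.tsv",
        l_max_internal=config.basis.l_max_internal,
        l_max_external=config.basis.l_max_external,
        n_sensors=n_sensors,
    )
    write_config(
        {
            "initial_q": trajectory.initial_q,
            "final_q": trajectory.final_q,
            "initial_capacity_bits": cap_initial,
            "final_capacity_bits": cap_final,
            "n_cost_evals": trajectory.n_cost_evals,
            "seed": trajectory.seed,
        },
        output_dir / "summary.yaml",
    )
    return trajectory


def evaluate_array(
    array: SensorArray,
    volume,
    spec: MultipoleBasisSpec | None = None,
    n_dipoles: int = DEFAULT_N_DIPOLES,
    source_radius: float = DEFAULT_SOURCE_RADIUS,
    total_rms_moment: float = DEFAULT_TOTAL_RMS_MOMENT,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = 0,
    orientation_bins: int = 18,
) -> dict:
    """Single-document report for an existing array.

    Contains the figure-of-merit, mean amplification, measurement-matrix
    rank, channel capacity (seeded dipole ensemble) and the orientation
    histogram relative to the outward radial direction.
    """
    spec = spec or MultipoleBasisSpec()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        field = NoiseEvaluator(volume, spec).evaluate_array(array)
    _, rank = pseudoinverse(basis_matrix(array, spec))
    cap = array_capacity(
        array,
        n_dipoles=n_dipoles,
        source_radius=source_radius,
        total_rms_moment=total_rms_moment,
        noise_sd=noise_sd,
        seed=seed,
    )
    angles, counts = orientation_diagnostics(array, bins=orientation_bins)
    return {
        "n_sensors": len(array),
        "q": field.q,
        "mean_amp": field.mean_amp,
        "rank": rank,
        "rank_deficient": field.rank_deficient,
        "capacity_bits": cap,
        "orientation_angles_rad": angles.tolist(),
        "orientation_histogram": counts.tolist(),
    }
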