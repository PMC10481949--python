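"""Text-based file formats: sensor arrays, noise maps, trajectory logs, configs.

A sensor-array file is tab-separated text, one sensor per line, columns
``x y z ex ey ez`` (position in meters, unit orientation), with ``#`` comment
lines.  Orientations are re-normalized on read; rows whose orientation norm
deviates from 1 by more than 1e-3 are rejected.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TextIO, Union

import numpy as np
import yaml

from .geometry import SensorArray
from .noise import NoiseAmplificationField

__all__ = [
    "read_sensor_array",
    "write_sensor_array",
    "write_noise_map",
    "write_trajectory_log",
    "read_config",
    "write_config",
]

PathLike = Union[str, Path]


class SensorArrayParseError(ValueError):
    """Malformed sensor-array file; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_sensor_array(source: Union[PathLike, TextIO]) -> SensorArray:
    """Read a tab-separated sensor-array file."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    positions, orientations = [], []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 6:
            raise SensorArrayParseError(
                f"expected 6 columns (x y z ex ey ez), got {len(fields)}", i
            )
        try:
            vals = [float(v) for v in fields]
        except ValueError as err:
            raise SensorArrayParseError(str(err), i) from None
        e = np.array(vals[3:])
        norm = np.linalg.norm(e)
        if abs(norm - 1.0) > 1e-3:
            raise SensorArrayParseError(
                f"orientation norm {norm:.6f} deviates from 1 by more than 1e-3", i
            )
        positions.append(vals[:3])
        orientations.append(e / norm)
    if not positions:
        raise SensorArrayParseError("no sensors found", len(lines))
    return SensorArray(np.array(positions), np.array(orientations))


def write_sensor_array(array: SensorArray, dest: Union[PathLike, TextIO]) -> None:
    """Write a sensor array as tab-separated text."""
    buf = _io.StringIO()
    buf.write("# x\ty\tz\tex\tey\tez\n")
    for p, e in zip(array.positions, array.orientations):
        buf.write(
            "\t".join(f"{v:.12e}" for v in (*p, *e)) + "\n"
        )
    _write_text(dest, buf.getvalue())


def write_noise_map(
    field: NoiseAmplificationField,
    dest: Union[PathLike, TextIO],
    l_max_internal: int | None = None,
    l_max_external: int | None = None,
    n_sensors: int | None = None,
) -> None:
    """Export the per-grid-point noise-amplification map as delimited text."""
    buf = _io.StringIO()
    meta = {
        "l_max_internal": l_max_internal,
        "l_max_external": l_max_external,
        "n_sensors": n_sensors,
        "q": field.q,
        "mean_amp": field.mean_amp,
        "rank": field.rank,
    }
    for key, value in meta.items():
        if value is not None:
            buf.write(f"# {key}: {value}\n")
    buf.write("# x\ty\tz\tamp\n")
    for p, a in zip(field.grid.points, field.per_point_amp):
        buf.write(f"{p[0]:.9e}\t{p[1]:.9e}\t{p[2]:.9e}\t{a:.9e}\n")
    _write_text(dest, buf.getvalue())


def write_trajectory_log(trajectory, dest: Union[PathLike, TextIO]) -> None:
    """Write an optimization trajectory as delimited text."""
    buf = _io.StringIO()
    buf.write(f"# seed: {trajectory.seed}\n")
    buf.write("# iteration\tn_cost_evals\tbest_q\tmean_amp\n")
    for pt in trajectory.points:
        buf.write(
            f"{pt.iteration}\t{pt.n_cost_evals}\t{pt.best_q:.9e}\t{pt.mean_amp:.9e}\n"
        )
    _write_text(dest, buf.getvalue())


def read_config(source: Union[PathLike, TextIO]) -> dict:
    """Read a flat key/value configuration file (YAML subset)."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        data = yaml.safe_load(Path(source).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping of keys to values")
    return data


def write_config(config: dict, dest: Union[PathLike, TextIO]) -> None:
    _write_text(dest, yaml.safe_dump(config, sort_keys=True))


def _write_text(dest: Union[PathLike, TextIO], text: str) -> None:
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
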