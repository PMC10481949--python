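"""Helmet-shaped sampling volumes, quasi-uniform point sets and sensor arrays.

The admissible region for sensors (the *sampling volume*) is helmet-shaped:
a hemisphere of radius ``R`` over the top of the head (``z >= 0``) joined to a
cylindrical band of the same radius extending ``cylinder_height`` below the
equator, with an azimuthal sector of the band removed for the face opening.
The opening is centered on the +x azimuth.  A 2D volume is the helmet surface
itself (sensor radius fixed); the 3D volume is the shell swept between an
inner and an outer helmet surface.

Quasi-uniform point sets on the helmet are laid out with a generalized spiral:
the surface of revolution is parameterized by cumulative-area fraction along
the meridian, a single spiral is advanced in (area fraction, azimuth), and
candidates falling into the face opening are rejected, growing the candidate
count until the requested number survives.  The construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "Sensor",
    "SensorArray",
    "HelmetSurface",
    "HelmetShell3D",
    "SamplingGrid",
    "spiral_points",
    "radial_array",
    "sampling_grid",
]

_TOL = 1e-9  # boundary tolerance (m) for containment tests

# spiral azimuth advance constant (per Rakhmanov-Saff-Zhou style spirals)
_SPIRAL_C = 3.6


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return (np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi


@dataclass(frozen=True)
class Sensor:
    """A point magnetometer: position (m) and unit measurement orientation."""

    position: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        e = np.asarray(self.orientation, dtype=float).reshape(3)
        if abs(np.linalg.norm(e) - 1.0) > 1e-9:
            raise ValueError("sensor orientation must be a unit vector")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "orientation", e)


class SensorArray:
    """An ordered collection of point sensors (the array configuration).

    Parameters
    ----------
    positions : (m, 3) array
        Sensor positions in meters.
    orientations : (m, 3) array
        Unit measurement orientations (tolerance 1e-9 on the norm).
    """

    def __init__(self, positions, orientations):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        ori = np.atleast_2d(np.asarray(orientations, dtype=float))
        if pos.shape != ori.shape or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions and orientations must both be (m, 3), m >= 1")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("all orientations must be unit vectors (tol 1e-9)")
        self.positions = pos
        self.orientations = ori

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> Sensor:
        return Sensor(self.positions[i], self.orientations[i])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SensorArray)
            and self.positions.shape == other.positions.shape
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.orientations, other.orientations)
        )

    @classmethod
    def from_sensors(cls, sensors: Iterable[Sensor]) -> "SensorArray":
        sensors = list(sensors)
        return cls(
            np.array([s.position for s in sensors]),
            np.array([s.orientation for s in sensors]),
        )

    def subset(self, indices) -> "SensorArray":
        return SensorArray(self.positions[indices], self.orientations[indices])

    def concatenate(self, other: "SensorArray") -> "SensorArray":
        return SensorArray(
            np.vstack([self.positions, other.positions]),
            np.vstack([self.orientations, other.orientations]),
        )


@dataclass(frozen=True)
class HelmetSurface:
    """2D helmet sampling volume: hemisphere plus open cylindrical band.

    Attributes
    ----------
    radius : float
        Sphere/cylinder radius R in meters.
    cylinder_height : float
        Extent of the band below the equator (m).
    opening_angle : float
        Azimuthal width (rad) of the face opening in the band, centered on +x.
    """

    radius: float = 0.15
    cylinder_height: float = 0.15
    opening_angle: float = np.pi / 2

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.cylinder_height < 0:
            raise ValueError("radius must be > 0 and cylinder_height >= 0")
        if not 0 <= self.opening_angle <= 2 * np.pi:
            raise ValueError("opening_angle must lie in [0, 2*pi]")

    # -- areas ------------------------------------------------------------
    @property
    def hemisphere_area(self) -> float:
        return 2 * np.pi * self.radius**2

    @property
    def band_area(self) -> float:
        return (2 * np.pi - self.opening_angle) * self.radius * self.cylinder_height

    def surface_area(self) -> float:
        """Closed-form area of the admissible surface (m^2)."""
        return self.hemisphere_area + self.band_area

    # -- containment / normals -------------------------------------------
    def _in_opening(self, p: np.ndarray, tol: float = _TOL) -> np.ndarray:
        az = np.arctan2(p[..., 1], p[..., 0])
        half = self.opening_angle / 2
        ang_tol = tol / max(self.radius, tol)
        return np.abs(_wrap_angle(az)) < half - ang_tol

    def contains(self, p, tol: float = _TOL):
        """True where p lies on the surface (within ``tol`` meters)."""
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        r = np.linalg.norm(p, axis=1)
        rho = np.hypot(p[:, 0], p[:, 1])
        on_hemi = (p[:, 2] >= -tol) & (np.abs(r - self.radius) <= tol)
        on_band = (
            (np.abs(rho - self.radius) <= tol)
            & (p[:, 2] <= tol)
            & (p[:, 2] >= -self.cylinder_height - tol)
            & ~self._in_opening(p, tol)
        )
        out = on_hemi | on_band
        return bool(out[0]) if single else out

    def surface_normal(self, p) -> np.ndarray:
        """Outward unit normal at a surface point (tolerance 1e-6 m)."""
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if not np.all(self.contains(p, tol=1e-6)):
            raise ValueError("point is not on the helmet surface")
        out = np.empty_like(p)
        hemi = p[:, 2] >= 0
        out[hemi] = p[hemi] / np.linalg.norm(p[hemi], axis=1, keepdims=True)
        band = ~hemi
        rho = np.hypot(p[band, 0], p[band, 1])[:, None]
        out[band, :2] = p[band, :2] / rho
        out[band, 2] = 0.0
        return out[0] if single else out

    # -- cumulative-area parameterization ---------------------------------
    # u in [0, 1] is the area fraction along the admissible surface measured
    # from the apex; v in [0, 1] spans the admissible azimuth range at u.
    def point_from_params(self, u, v) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        single = u.ndim == 0
        u, v = np.atleast_1d(u), np.atleast_1d(v)
        if np.any((u < 0) | (u > 1) | (v < 0) | (v > 1)):
            raise ValueError("surface parameters must lie in [0, 1]")
        a = u * self.surface_area()
        pts = np.empty((u.size, 3))
        hemi = a <= self.hemisphere_area
        if np.any(hemi):
            cos_t = np.clip(1.0 - a[hemi] / self.hemisphere_area, 0.0, 1.0)
            sin_t = np.sqrt(1.0 - cos_t**2)
            phi = 2 * np.pi * v[hemi]
            pts[hemi, 0] = self.radius * sin_t * np.cos(phi)
            pts[hemi, 1] = self.radius * sin_t * np.sin(phi)
            pts[hemi, 2] = self.radius * cos_t
        band = ~hemi
        if np.any(band):
            width = 2 * np.pi - self.opening_angle
            depth = (a[band] - self.hemisphere_area) / (width * self.radius)
            phi = self.opening_angle / 2 + width * v[band]
            pts[band, 0] = self.radius * np.cos(phi)
            pts[band, 1] = self.radius * np.sin(phi)
            pts[band, 2] = -depth
        return pts[0] if single else pts

    def params_from_point(self, p) -> np.ndarray:
        """Inverse of :meth:`point_from_params` (requires surface points)."""
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if not np.all(self.contains(p, tol=1e-6)):
            raise ValueError("point is not on the helmet surface")
        out = np.empty((p.shape[0], 2))
        area = self.surface_area()
        hemi = p[:, 2] >= 0
        if np.any(hemi):
            r = np.linalg.norm(p[hemi], axis=1)
            cos_t = np.clip(p[hemi, 2] / r, 0.0, 1.0)
            a = self.hemisphere_area * (1.0 - cos_t)
            phi = np.arctan2(p[hemi, 1], p[hemi, 0]) % (2 * np.pi)
            out[hemi, 0] = a / area
            out[hemi, 1] = phi / (2 * np.pi)
        band = ~hemi
        if np.any(band):
            width = 2 * np.pi - self.opening_angle
            a = self.hemisphere_area + (-p[band, 2]) * width * self.radius
            phi = np.arctan2(p[band, 1], p[band, 0])
            # admissible azimuths run from opening/2 to 2*pi - opening/2
            rel = (phi - self.opening_angle / 2) % (2 * np.pi)
            out[band, 0] = a / area
            out[band, 1] = np.clip(rel / width, 0.0, 1.0)
        out[:, 0] = np.clip(out[:, 0], 0.0, 1.0)
        return out[0] if single else out


@dataclass(frozen=True)
class HelmetShell3D:
    """3D helmet sampling volume: shell between two helmet surfaces."""

    inner_radius: float = 0.15
    outer_radius: float = 0.25
    cylinder_height: float = 0.15
    opening_angle: float = np.pi / 2

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")

    def surface(self, t: float) -> HelmetSurface:
        """Constant-radius helmet surface at fractional depth t in [0, 1]."""
        if not 0 <= t <= 1:
            raise ValueError("t must lie in [0, 1]")
        radius = self.inner_radius + t * (self.outer_radius - self.inner_radius)
        return HelmetSurface(radius, self.cylinder_height, self.opening_angle)

    def contains(self, p, tol: float = _TOL):
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        r = np.linalg.norm(p, axis=1)
        rho = np.hypot(p[:, 0], p[:, 1])
        in_hemi = (
            (p[:, 2] >= -tol)
            & (r >= self.inner_radius - tol)
            & (r <= self.outer_radius + tol)
        )
        inner = self.surface(0.0)
        in_band = (
            (p[:, 2] <= tol)
            & (p[:, 2] >= -self.cylinder_height - tol)
            & (rho >= self.inner_radius - tol)
            & (rho <= self.outer_radius + tol)
            & ~inner._in_opening(p, tol)
        )
        out = in_hemi | in_band
        return bool(out[0]) if single else out

    def point_from_params(self, u, v, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any((t < 0) | (t > 1)):
            raise ValueError("radial parameter t must lie in [0, 1]")
        single = t.ndim == 0
        u, v, t = np.atleast_1d(u), np.atleast_1d(v), np.atleast_1d(t)
        pts = np.empty((t.size, 3))
        for i in range(t.size):
            pts[i] = self.surface(float(t[i])).point_from_params(u[i], v[i])
        return pts[0] if single else pts

    def params_from_point(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if not np.all(self.contains(p, tol=1e-6)):
            raise ValueError("point is not inside the 3D sampling volume")
        dr = self.outer_radius - self.inner_radius
        out = np.empty((p.shape[0], 3))
        for i, pi in enumerate(p):
            radial = np.linalg.norm(pi) if pi[2] >= 0 else np.hypot(pi[0], pi[1])
            t = np.clip((radial - self.inner_radius) / dr, 0.0, 1.0)
            surf = self.surface(float(t))
            # project onto the exact surface radius before inverting
            if pi[2] >= 0:
                q = pi / np.linalg.norm(pi) * surf.radius
            else:
                rho = np.hypot(pi[0], pi[1])
                q = np.array(
                    [pi[0] / rho * surf.radius, pi[1] / rho * surf.radius, pi[2]]
                )
            uv = surf.params_from_point(q)
            out[i] = (uv[0], uv[1], t)
        return out[0] if single else out


SamplingVolume = Union[HelmetSurface, HelmetShell3D]


@dataclass(frozen=True)
class SamplingGrid:
    """Discrete evaluation grid covering a sampling volume."""

    points: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def _spiral_candidates(surface: HelmetSurface, count: int) -> np.ndarray:
    """Spiral of `count` points over the FULL surface of revolution
    (opening not yet removed)."""
    area_full = surface.hemisphere_area + 2 * np.pi * surface.radius * surface.cylinder_height
    t = (np.arange(count) + 0.5) / count
    a = t * area_full
    hemi = a <= surface.hemisphere_area
    rho = np.empty(count)
    z = np.empty(count)
    cos_t = np.clip(1.0 - a[hemi] / surface.hemisphere_area, 0.0, 1.0)
    rho[hemi] = surface.radius * np.sqrt(1.0 - cos_t**2)
    z[hemi] = surface.radius * cos_t
    band = ~hemi
    rho[band] = surface.radius
    z[band] = -(a[band] - surface.hemisphere_area) / (2 * np.pi * surface.radius)
    # advance azimuth inversely to the local ring radius
    frac = np.maximum(rho / surface.radius, 1e-8)
    step = _SPIRAL_C / np.sqrt(count) / frac
    step[0] = 0.0
    step[step > np.pi] = 0.0  # near the apex the azimuth is arbitrary
    phi = np.cumsum(step)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def spiral_points(surface: HelmetSurface, count: int) -> np.ndarray:
    """Exactly ``count`` approximately area-uniform points on the surface.

    Deterministic: a generalized spiral is laid over the full surface of
    revolution and candidates inside the face opening are rejected; the
    candidate count is grown until at least ``count`` survive, then the
    trailing extras (bottom edge of the band) are dropped.
    """
    if count < 4:
        raise ValueError("count must be >= 4")
    area_full = surface.hemisphere_area + 2 * np.pi * surface.radius * surface.cylinder_height
    m = max(count, int(np.ceil(count * area_full / surface.surface_area())))
    for _ in range(10_000):
        cand = _spiral_candidates(surface, m)
        in_open = (cand[:, 2] < 0) & surface._in_opening(cand, tol=0.0)
        keep = cand[~in_open]
        if keep.shape[0] >= count:
            return keep[:count]
        m += 1
    raise RuntimeError("spiral candidate search failed to converge")


def radial_array(surface: HelmetSurface, count: int) -> SensorArray:
    """Uniformly-spaced radial reference array: spiral positions with
    orientations along the outward surface normal."""
    pts = spiral_points(surface, count)
    return SensorArray(pts, surface.surface_normal(pts))


def sampling_grid(
    volume: SamplingVolume,
    n_points: int | None = None,
    n_shells: int = 5,
) -> SamplingGrid:
    """Evaluation grid for the figure-of-merit.

    2D volume: ``n_points`` (default 1000) spiral points on the surface.
    3D volume: ``n_shells`` (default 5) concentric helmet surfaces with radii
    evenly spaced inner-to-outer inclusive, each carrying
    ``n_points / n_shells`` (default 500) spiral points, 2500 total.
    """
    if isinstance(volume, HelmetSurface):
        n = 1000 if n_points is None else n_points
        return SamplingGrid(
            spiral_points(volume, n), description=f"2D surface grid, {n} points"
        )
    if isinstance(volume, HelmetShell3D):
        n = 2500 if n_points is None else n_points
        per_shell = n // n_shells
        if per_shell * n_shells != n:
            raise ValueError("n_points must be divisible by n_shells")
        shells = [
            spiral_points(volume.surface(t), per_shell)
            for t in np.linspace(0.0, 1.0, n_shells)
        ]
        return SamplingGrid(
            np.vstack(shells),
            description=f"3D shell grid, {n_shells} shells x {per_shell} points",
        )
    raise TypeError(f"unsupported volume type: {type(volume).__name__}")
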