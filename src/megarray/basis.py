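"""Truncated vector-spherical-harmonics (VSH) model of a source-free magnetic field.

A magnetic field in a source-free shell around the head is the gradient of a
harmonic scalar potential and can be expanded in two families of multipole
components: *internal* components, whose potentials decay with radius and
represent fields generated inside the helmet (the brain), and *external*
components, whose potentials grow with radius and represent environmental
interference generated far outside.  This is the basis used by signal-space
separation (SSS).

Conventions (part of the public contract):

* Real orthonormal spherical harmonics ``Y_lm`` (Condon--Shortley phase folded
  into the real transform), with unit leading coefficients in the potentials:

  - internal potential:  ``V_lm(r) = Y_lm(theta, phi) / r**(l+1)``
  - external potential:  ``V_lm(r) = r**l * Y_lm(theta, phi)``

  and the component field is ``B = -grad(V)``.  Any fixed per-component
  rescaling of this convention leaves the noise-amplification figure-of-merit
  unchanged (diagonal rescalings commute with the internal/external selectors
  and invert through the pseudoinverse), so the choice is immaterial for array
  comparison; it is fixed here for reproducibility.

* Canonical component (column) ordering: all internal components first with
  degree ``l = 1..l_max_internal`` ascending and order ``m = -l..l`` ascending
  within each degree, then all external components likewise.

* Coordinates: right-handed Cartesian about the expansion origin, +z through
  the helmet apex, +x through the face opening; ``theta`` is the polar angle
  from +z and ``phi`` the azimuth from +x.  SI units throughout.

Evaluation uses the spherical-coordinate gradient; points closer than
``_AXIS_EPS`` (1e-12 m) to the polar axis are displaced off the axis by that
amount before evaluation, which keeps the ``1/sin(theta)`` terms finite while
perturbing the field by a negligible amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y_all

__all__ = [
    "BasisPart",
    "BasisComponent",
    "MultipoleBasisSpec",
    "component_count",
    "components",
    "internal_mask",
    "selector_matrix",
    "basis_field",
    "basis_field_matrix",
    "basis_row",
    "basis_matrix",
    "field_at",
]

#: Distance (m) below which a point is considered to lie on the polar axis
#: and is displaced off it before spherical-gradient evaluation.
_AXIS_EPS = 1e-12


class BasisPart(str, Enum):
    """Internal (brain-side) vs external (interference-side) expansion."""

    INTERNAL = "internal"
    EXTERNAL = "external"


@dataclass(frozen=True)
class BasisComponent:
    """One column of the multipole measurement matrix.

    Attributes
    ----------
    part : BasisPart
        Internal or external family.
    degree : int
        Spherical-harmonic degree ``l >= 1``.
    order : int
        Spherical-harmonic order ``m`` with ``-l <= m <= l``.
    column : int
        Position in the canonical column ordering.
    """

    part: BasisPart
    degree: int
    order: int
    column: int

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if abs(self.order) > self.degree:
            raise ValueError(
                f"order {self.order} out of range for degree {self.degree}"
            )


def component_count(l_max_internal: int, l_max_external: int) -> int:
    """Number of components in a truncated expansion.

    ``n = L_int*(L_int + 2) + L_ext*(L_ext + 2)`` -- each degree ``l``
    contributes ``2l + 1`` orders and the sums telescope.
    """
    if l_max_internal < 1 or l_max_external < 0:
        raise ValueError(
            "internal cutoff must be >= 1 and external cutoff >= 0, got "
            f"({l_max_internal}, {l_max_external})"
        )
    return l_max_internal * (l_max_internal + 2) + l_max_external * (l_max_external + 2)


@dataclass(frozen=True)
class MultipoleBasisSpec:
    """Cutoffs and origin of a truncated VSH expansion.

    Parameters
    ----------
    l_max_internal : int
        Highest degree of the internal (neuromagnetic) expansion; >= 1.
    l_max_external : int
        Highest degree of the external (interference) expansion; >= 0,
        where 0 means no external model.
    origin : array-like of 3 floats
        Expansion origin in meters (the helmet's sphere center).
    """

    l_max_internal: int = 10
    l_max_external: int = 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        component_count(self.l_max_internal, self.l_max_external)  # validates
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))
        if len(self.origin) != 3:
            raise ValueError("origin must be a 3-vector")

    @property
    def n_internal(self) -> int:
        return self.l_max_internal * (self.l_max_internal + 2)

    @property
    def n_external(self) -> int:
        return self.l_max_external * (self.l_max_external + 2)

    @property
    def n_components(self) -> int:
        return self.n_internal + self.n_external


def components(spec: MultipoleBasisSpec) -> list[BasisComponent]:
    """All components in canonical column order."""
    out: list[BasisComponent] = []
    col = 0
    for part, l_max in (
        (BasisPart.INTERNAL, spec.l_max_internal),
        (BasisPart.EXTERNAL, spec.l_max_external),
    ):
        for l in range(1, l_max + 1):
            for m in range(-l, l + 1):
                out.append(BasisComponent(part, l, m, col))
                col += 1
    return out


def internal_mask(spec: MultipoleBasisSpec) -> np.ndarray:
    """Boolean mask over columns that selects internal components."""
    mask = np.zeros(spec.n_components, dtype=bool)
    mask[: spec.n_internal] = True
    return mask


def selector_matrix(spec: MultipoleBasisSpec, part: BasisPart) -> np.ndarray:
    """Diagonal selector matrix (I_internal or I_external) as a dense array."""
    mask = internal_mask(spec)
    if part is BasisPart.EXTERNAL:
        mask = ~mask
    return np.diag(mask.astype(float))


def _spherical_frame(points: np.ndarray, origin: Sequence[float]) -> tuple:
    """Spherical coordinates and unit frame vectors of points about origin.

    Points on the polar axis are displaced by ``_AXIS_EPS`` along +x.
    Returns (r, theta, phi, rhat, that, phat) with frame vectors (N, 3).
    """
    d = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(origin, float)
    rho = np.hypot(d[:, 0], d[:, 1])
    on_axis = rho < _AXIS_EPS
    if np.any(on_axis):
        d = d.copy()
        d[on_axis, 0] += _AXIS_EPS
        rho = np.hypot(d[:, 0], d[:, 1])
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("basis fields are singular at the expansion origin")
    theta = np.arctan2(rho, d[:, 2])  # accurate for near-axis points
    phi = np.arctan2(d[:, 1], d[:, 0])
    rhat = d / r[:, None]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    that = np.stack([cos_t * cos_p, cos_t * sin_p, -sin_t], axis=1)
    phat = np.stack([-sin_p, cos_p, np.zeros_like(sin_p)], axis=1)
    return r, theta, phi, rhat, that, phat


@lru_cache(maxsize=32)
def _component_index_arrays(l_max_internal: int, l_max_external: int):
    """Per-column (is_internal, l, m) arrays in canonical order."""
    parts, ls, ms = [], [], []
    for internal, l_max in ((True, l_max_internal), (False, l_max_external)):
        for l in range(1, l_max + 1):
            for m in range(-l, l + 1):
                parts.append(internal)
                ls.append(l)
                ms.append(m)
    return (
        np.array(parts, dtype=bool),
        np.array(ls, dtype=int),
        np.array(ms, dtype=int),
    )


def basis_field_matrix(points: np.ndarray, spec: MultipoleBasisSpec) -> np.ndarray:
    """Evaluate every basis component's field at every point.

    Parameters
    ----------
    points : (N, 3) or (3,) array
        Evaluation points in meters.
    spec : MultipoleBasisSpec

    Returns
    -------
    (N, 3, n) array
        ``out[i, :, j]`` is the field (T per unit coefficient) of canonical
        component ``j`` at point ``i``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r, theta, phi, rhat, that, phat = _spherical_frame(pts, spec.origin)
    internal, ls, ms = _component_index_arrays(
        spec.l_max_internal, spec.l_max_external
    )
    l_top = max(spec.l_max_internal, spec.l_max_external)
    y_all, dy_all = sph_harm_y_all(l_top, l_top, theta, phi, diff_n=1)
    m_abs = np.abs(ms)
    yc = y_all[ls, m_abs]  # (n, N) complex harmonics of order |m|
    dtc = dy_all[ls, m_abs, :, 0]  # (n, N) complex d/dtheta
    # real harmonics: m > 0 -> sqrt(2)(-1)^m Re, m < 0 -> sqrt(2)(-1)^|m| Im
    sgn = np.where(ms == 0, 1.0, np.sqrt(2.0) * (-1.0) ** m_abs)[:, None]
    pos_m = (ms >= 0)[:, None]
    y = sgn * np.where(pos_m, yc.real, yc.imag)
    dy_dt = sgn * np.where(pos_m, dtc.real, dtc.imag)
    # (1/sin)dY/dphi from dY/dphi = i m Y of the complex harmonic
    yos = yc / np.sin(theta)
    dy_dp = sgn * np.where(pos_m, -m_abs[:, None] * yos.imag, m_abs[:, None] * yos.real)
    # radial prefactors and B = -grad(potential), spherical components
    lcol = ls[:, None].astype(float)
    rad = np.where(
        internal[:, None], r[None, :] ** (-(lcol + 2)), r[None, :] ** (lcol - 1)
    )
    br = np.where(internal[:, None], (lcol + 1) * rad * y, -lcol * rad * y)
    bt = -rad * dy_dt
    bp = -rad * dy_dp
    return (
        br.T[:, None, :] * rhat[:, :, None]
        + bt.T[:, None, :] * that[:, :, None]
        + bp.T[:, None, :] * phat[:, :, None]
    )


def basis_field(
    component: BasisComponent,
    r: np.ndarray,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Field of a single basis component at point(s) ``r``.

    Returns a (3,) vector for a single point or (N, 3) for a stack.
    """
    single = np.asarray(r).ndim == 1
    l = component.degree
    spec = MultipoleBasisSpec(
        l_max_internal=l,
        l_max_external=l if component.part is BasisPart.EXTERNAL else 0,
        origin=tuple(origin),
    )
    fm = basis_field_matrix(np.atleast_2d(r), spec)
    offset = 0 if component.part is BasisPart.INTERNAL else spec.n_internal
    col = offset + (l * l - 1) + (component.order + l)
    b = fm[:, :, col]
    return b[0] if single else b


def basis_row(r: np.ndarray, e: np.ndarray, spec: MultipoleBasisSpec) -> np.ndarray:
    """Measurement row ``s_(r,e)``: each basis field projected on orientation e.

    ``e`` must be a unit vector (tolerance 1e-9).
    """
    e = np.asarray(e, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-9:
        raise ValueError("sensor orientation must be a unit vector")
    fm = basis_field_matrix(np.atleast_2d(r), spec)
    return e @ fm[0]


def basis_matrix(array, spec: MultipoleBasisSpec) -> np.ndarray:
    """Measurement matrix S for a sensor array: row i = s_(r_i, e_i).

    ``array`` is anything with ``positions`` (m, 3) and ``orientations``
    (m, 3) attributes, e.g. :class:`megarray.geometry.SensorArray`.
    """
    pos = np.atleast_2d(np.asarray(array.positions, dtype=float))
    ori = np.atleast_2d(np.asarray(array.orientations, dtype=float))
    if pos.shape[0] == 0:
        raise ValueError("sensor array must contain at least one sensor")
    norms = np.linalg.norm(ori, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise ValueError("all sensor orientations must be unit vectors")
    fm = basis_field_matrix(pos, spec)
    # row i = e_i . B_j(r_i) over components j
    return np.einsum("ik,ikj->ij", ori, fm)


def field_at(
    coefficients: np.ndarray, r: np.ndarray, spec: MultipoleBasisSpec
) -> np.ndarray:
    """Model field ``B(r)`` for a coefficient vector in canonical order."""
    x = np.asarray(coefficients, dtype=float)
    if x.shape != (spec.n_components,):
        raise ValueError(
            f"coefficient vector must have length {spec.n_components}, "
            f"got shape {x.shape}"
        )
    single = np.asarray(r).ndim == 1
    fm = basis_field_matrix(np.atleast_2d(r), spec)
    b = fm @ x
    return b[0] if single else b
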