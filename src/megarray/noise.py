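"""Interpolation-noise figure-of-merit for sensor arrays.

Given a sensor array with measurement matrix ``S`` (one row per sensor in the
truncated multipole basis), measured fields can be interpolated to any virtual
sensor ``(r, e)`` in the sampling volume by least squares:
``phi(r, e) = s_(r,e) @ pinv(S) @ phi``.  Restricting the interpolation to the
internal (brain-side) components with the diagonal selector ``I_int`` yields
the estimated *neuronal* field component and rejects external interference.

With i.i.d. sensor noise of standard deviation ``sigma``, the noise of that
estimate is Gaussian with standard deviation
``||s_(r,e) @ I_int @ pinv(S)|| * sigma``.  The ratio to ``sigma`` is the
*noise amplification* at ``(r, e)``; its maximum over the sampling volume and
all orientations is the scalar figure-of-merit ``q`` of the array.  The
orientation maximum has a closed form: it is the largest singular value of the
3 x m matrix obtained by stacking the three Cartesian components of the
interpolation row at ``r``.

``q`` is invariant to ``sigma`` and to any per-component rescaling of the
basis (for full-column-rank ``S``), so it compares arrays, not conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import MultipoleBasisSpec, basis_field_matrix, basis_row
from .geometry import SamplingGrid, SamplingVolume, SensorArray, sampling_grid

__all__ = [
    "NoiseAmplificationField",
    "pseudoinverse",
    "interpolation_operator",
    "virtual_sensor",
    "noise_amp_at",
    "max_noise_amp_at_point",
    "NoiseEvaluator",
    "figure_of_merit",
]


def _max_eig_sym3(M: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of a stack of symmetric 3x3 matrices.

    Closed-form trigonometric solution of the characteristic cubic; much
    faster than batched LAPACK for the thousands of tiny Gram matrices the
    grid evaluation produces.
    """
    a, b, c = M[:, 0, 0], M[:, 1, 1], M[:, 2, 2]
    d, e, f = M[:, 0, 1], M[:, 1, 2], M[:, 0, 2]
    q = (a + b + c) / 3.0
    da, db, dc = a - q, b - q, c - q
    p2 = (da * da + db * db + dc * dc + 2.0 * (d * d + e * e + f * f)) / 6.0
    p = np.sqrt(np.maximum(p2, 0.0))
    # det of (M - q I) / p, guarded against p == 0 (isotropic case)
    safe_p = np.where(p > 0.0, p, 1.0)
    r = (
        da * (db * dc - e * e) - d * (d * dc - e * f) + f * (d * e - db * f)
    ) / (2.0 * safe_p**3)
    phi = np.arccos(np.clip(r, -1.0, 1.0)) / 3.0
    return np.where(p > 0.0, q + 2.0 * p * np.cos(phi), q)


@dataclass(frozen=True)
class NoiseAmplificationField:
    """Worst-case noise amplification over a sampling grid.

    Attributes
    ----------
    grid : SamplingGrid
        Evaluation grid.
    per_point_amp : (N,) array
        Worst case over orientations of sigma_interp / sigma at each point.
    q : float
        Maximum of ``per_point_amp`` -- the array figure-of-merit.
    mean_amp : float
        Arithmetic mean of ``per_point_amp`` (worst-case-over-orientation
        averaged over grid points).
    rank : int
        Numerical rank of the measurement matrix.
    rank_deficient : bool
        True when rank < number of basis components (the minimum-norm
        pseudoinverse was used; q is then optimistic).
    """

    grid: SamplingGrid
    per_point_amp: np.ndarray
    q: float
    mean_amp: float
    rank: int
    rank_deficient: bool


def pseudoinverse(S: np.ndarray) -> tuple[np.ndarray, int]:
    """Moore-Penrose pseudoinverse by SVD, with the numerical rank.

    The columns are equilibrated to unit norm before the SVD and the scaling
    is inverted afterwards: ``pinv(B @ D) = inv(D) @ pinv(B)`` for diagonal
    ``D``, so this leaves the exact pseudoinverse unchanged for full-rank
    matrices while removing the enormous spread of column scales between low-
    and high-degree multipole components (which would otherwise masquerade as
    rank deficiency).  Singular values of the equilibrated matrix below
    ``max(m, n) * eps * s_max`` are treated as zero.
    """
    S = np.asarray(S, dtype=float)
    col_norms = np.linalg.norm(S, axis=0)
    if S.size == 0 or not np.any(col_norms > 0.0):
        raise np.linalg.LinAlgError("degenerate (all-zero) measurement matrix")
    scale = np.where(col_norms > 0.0, col_norms, 1.0)
    u, s, vt = np.linalg.svd(S / scale, full_matrices=False)
    cutoff = max(S.shape) * np.finfo(float).eps * s[0]
    rank = int(np.sum(s > cutoff))
    s_inv = np.zeros_like(s)
    s_inv[:rank] = 1.0 / s[:rank]
    return ((vt.T * s_inv) @ u.T) / scale[:, None], rank


def interpolation_operator(
    S: np.ndarray, spec: MultipoleBasisSpec
) -> tuple[np.ndarray, int]:
    """Internal-component interpolation operator ``I_int @ pinv(S)``.

    Returns the (n, m) operator (rows of external components are zero) and
    the numerical rank of ``S``.
    """
    pinv, rank = pseudoinverse(S)
    W = pinv.copy()
    W[spec.n_internal :, :] = 0.0
    return W, rank


def virtual_sensor(
    measurement: np.ndarray,
    r: np.ndarray,
    e: np.ndarray,
    S: np.ndarray,
    spec: MultipoleBasisSpec,
) -> float:
    """Estimated neuronal field component at a virtual sensor ``(r, e)``.

    ``s_(r,e) @ I_int @ pinv(S) @ measurement``; exact when the measurement is
    noiseless, S has full column rank and the field is within the model.
    """
    phi = np.asarray(measurement, dtype=float).ravel()
    if phi.shape[0] != np.asarray(S).shape[0]:
        raise ValueError("measurement length must equal the number of sensors")
    W, _ = interpolation_operator(S, spec)
    return float(basis_row(r, e, spec) @ W @ phi)


def noise_amp_at(
    r: np.ndarray, e: np.ndarray, S: np.ndarray, spec: MultipoleBasisSpec
) -> float:
    """Noise amplification sigma_interp / sigma at a specific ``(r, e)``."""
    W, _ = interpolation_operator(S, spec)
    return float(np.linalg.norm(basis_row(r, e, spec) @ W))


def max_noise_amp_at_point(
    r: np.ndarray, S: np.ndarray, spec: MultipoleBasisSpec
) -> float:
    """Worst-case noise amplification over all orientations at point ``r``.

    Computed exactly as the largest singular value of ``F(r) @ I_int @
    pinv(S)`` where the rows of the 3 x n matrix ``F(r)`` are the Cartesian
    components of the basis fields at ``r``.
    """
    W, _ = interpolation_operator(S, spec)
    F = basis_field_matrix(np.atleast_2d(r), spec)[0]  # (3, n)
    return float(np.linalg.svd(F @ W, compute_uv=False)[0])


class NoiseEvaluator:
    """Figure-of-merit evaluator with the grid basis fields precomputed.

    Evaluating ``q`` for many candidate arrays over a fixed grid (as the
    optimizer does) reuses the (N, 3, n) tensor of basis fields at the grid
    points, which dominates the per-evaluation cost otherwise.
    """

    def __init__(
        self,
        volume: SamplingVolume,
        spec: MultipoleBasisSpec,
        grid: SamplingGrid | None = None,
    ):
        self.volume = volume
        self.spec = spec
        self.grid = sampling_grid(volume) if grid is None else grid
        # (N, 3, n) basis fields at grid points
        self._F = basis_field_matrix(self.grid.points, spec)

    def amplification(self, S: np.ndarray) -> NoiseAmplificationField:
        """Per-grid-point worst-case amplification and the summary q."""
        W, rank = interpolation_operator(S, self.spec)
        deficient = rank < self.spec.n_components
        if deficient:
            warnings.warn(
                "measurement matrix is rank-deficient; minimum-norm "
                "pseudoinverse used and q is optimistic",
                stacklevel=2,
            )
        n_pts = self._F.shape[0]
        G = (self._F.reshape(n_pts * 3, -1) @ W).reshape(n_pts, 3, W.shape[1])
        M = G @ G.transpose(0, 2, 1)  # (N, 3, 3) Gram matrices
        amp = np.sqrt(np.maximum(_max_eig_sym3(M), 0.0))
        return NoiseAmplificationField(
            grid=self.grid,
            per_point_amp=amp,
            q=float(amp.max()),
            mean_amp=float(amp.mean()),
            rank=rank,
            rank_deficient=deficient,
        )

    def evaluate_array(self, array: SensorArray) -> NoiseAmplificationField:
        from .basis import basis_matrix

        return self.amplification(basis_matrix(array, self.spec))


def figure_of_merit(
    array: SensorArray,
    volume: SamplingVolume,
    spec: MultipoleBasisSpec,
    grid: SamplingGrid | None = None,
) -> NoiseAmplificationField:
    """Worst-case noise amplification ``q`` of an array over a sampling volume.

    Convenience wrapper around :class:`NoiseEvaluator` for one-off
    evaluations; build the evaluator directly to amortize grid setup.
    """
    return NoiseEvaluator(volume, spec, grid).evaluate_array(array)
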