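# Methods

## The field model

`megarray` treats an MEG measurement as a sampling problem for a source-free
magnetic field in the volume around the head.  In a source-free region, `B`
is the gradient of a harmonic scalar potential, which can be expanded in
multipole components of two families:

* **internal** components, with potentials `Y_lm(θ, φ) / r^(l+1)` that decay
  with radius — fields produced by sources inside the helmet (the brain);
* **external** components, with potentials `r^l · Y_lm(θ, φ)` that grow with
  radius — environmental interference produced far away.

The expansion is truncated at degree `L_int` for the internal part and
`L_ext` for the external part, giving `n = L_int(L_int+2) + L_ext(L_ext+2)`
components (each degree `l` contributes `2l+1` orders).  The defaults
`L_int = 10`, `L_ext = 3` give `n = 135`.  This is the same basis that
signal-space separation (SSS) uses; a test cross-validates our measurement
matrices against MNE-Python's SSS implementation (they agree to machine
precision up to a fixed per-column scale).

Conventions: real orthonormal spherical harmonics; components ordered
internal-first, degree ascending, order ascending within degree; `B = -∇V`
with unit leading coefficients.  The per-component normalization is provably
immaterial for the figure-of-merit (see below), so any fixed convention is
equivalent; ours is documented in `megarray.basis`.

Evaluation uses the spherical-coordinate gradient with
`scipy.special.sph_harm_y_all` supplying all harmonics and their θ/φ
derivatives in one call.  Points on the polar axis are displaced off-axis by
1e-12 m before evaluation; the polar angle is computed with `arctan2` so the
displacement survives rounding.  The error this introduces is of order
(1e-12 m) × |∇B| — far below every tolerance used here.  Correctness is
anchored by finite-difference oracles: the analytic field matches the
central-difference gradient of the potential to better than 1e-6 relative,
and numerically estimated divergence and curl vanish to 1e-4 relative.

## The figure-of-merit

For an array ξ of `m` point sensors (position `r_i`, unit orientation
`e_i`), the measurement matrix `S(ξ)` has rows `s_(r,e)` whose entries are
the basis fields projected on the sensor orientation.  If `S` has full
column rank and the true field lies in the model, least squares recovers the
coefficient vector and the field can be *interpolated* to any virtual sensor
in the sampling volume; applying the diagonal selector `I_int` first
restricts the estimate to the internal (neuronal) part and rejects
interference.

With i.i.d. sensor noise of standard deviation σ, the noise of the virtual
estimate at `(r, e)` has standard deviation `‖s_(r,e) I_int S⁺‖ σ`.  The
ratio to σ is the *noise amplification*; its worst case over the sampling
volume and all orientations,

    q(ξ) = max over r in V, ‖e‖=1 of ‖s_(r,e) I_int S⁺(ξ)‖,

is the scalar figure-of-merit.  The orientation maximum is computed exactly
as the spectral norm of the 3×m matrix `F(r) I_int S⁺` (the rows of `F(r)`
are the Cartesian components of the basis fields at `r`); a dense-orientation
brute force is kept only as a test oracle.  The spatial maximum is taken over
a discrete grid: 1000 quasi-uniform surface points for a 2D volume, 5
concentric shells of 500 points (2500 total) for the 3D shell.  `q` is
therefore a grid approximation of a continuous maximum; grid density is a
configuration parameter, not auto-refined.  We also report `mean_amp`, the
arithmetic mean over grid points of the per-point worst-case (i.e. the
orientation maximum is taken before averaging).

**Numerical choices.**  The pseudoinverse is always the SVD-based
Moore–Penrose inverse, never the normal-equations form, so rank-deficient
configurations (`m < n`, or degenerate geometries visited mid-optimization)
are handled by the minimum-norm inverse with a warning flag.  Columns are
equilibrated to unit norm before the SVD: the multipole columns span ~10
orders of magnitude in scale (radial factors `R^-(l+2)` vs `R^(l-1)`), which
would otherwise masquerade as rank deficiency; for full-rank matrices the
equilibration is mathematically a no-op since `(S D)⁺ = D⁻¹ S⁺`.  Singular
values below `max(m, n)·eps·s_max` of the equilibrated matrix count as zero.
This same identity makes `q` invariant to any per-component rescaling of the
basis — the property that renders the normalization convention immaterial —
and it is asserted to 1e-10 relative in the tests.  The per-grid-point 3×3
Gram eigenvalue uses the closed-form trigonometric solution of the
characteristic cubic (cross-checked against LAPACK), which keeps a full-grid
evaluation near one millisecond and makes the optimization loop tractable.

## Geometry

The sampling volume is helmet-shaped: a hemisphere of radius R (z ≥ 0)
joined to a cylindrical band of height 0.15 m below the equator, with a π/2
azimuthal sector of the band removed for the face (centered on +x; the
absolute azimuth is immaterial by symmetry).  The closed-form area is
`2πR² + (2π − γ)Rh` ≈ 0.247 m² at the defaults.  The 3D volume is the shell
swept between the R = 0.15 m and R = 0.25 m surfaces.  Containment uses a
1e-9 m boundary tolerance so optimizer iterates on the boundary remain
admissible.

Quasi-uniform point sets are laid with a generalized spiral: the surface of
revolution is parameterized by cumulative area along the meridian, a single
spiral advances in (area fraction, azimuth) with the azimuth step inversely
proportional to the local ring radius, and candidates inside the face
opening are rejected, growing the candidate count until the requested number
survive (trailing extras at the bottom band edge are dropped).  The
construction is deterministic; nearest-neighbor spacing has a coefficient of
variation of 0.02–0.04 for 100–1600 points.  The *uniformly-spaced radial
array* — the non-optimized reference design — places sensors at spiral
points with orientations along the outward surface normal (spherical-radial
on the hemisphere, cylinder-radial on the band).

## Optimization

Sensor placement minimizes `q` with `scipy.optimize.dual_annealing`
(generalized simulated annealing with local search), as a continuous
problem.  Each sensor contributes surface coordinates `(u, v)` — cumulative
area fraction and normalized admissible azimuth, so the rectangular box maps
exactly onto the admissible set — plus a radial coordinate `t ∈ [0, 1]` for
3D shells, and two orientation angles.  `u` jumps in azimuth meaning at the
hemisphere/band junction; the cost is continuous there and the annealer does
not require smoothness.  Defaults mirror the standard budget (1000 global
iterations, 1e7 cost evaluations); a single seed drives all randomness, and
trajectories (best-q is non-increasing by construction) plus array snapshots
are logged.  One annealer "iteration" means one global iteration of
`dual_annealing`.  Each local-search polish is capped at 20 L-BFGS-B
iterations: the gradient is numerical (161 cost calls per step at 40
sensors), so uncapped polishing dominates run time without changing the
search's character.

Full-scale runs (240 sensors, n = 135, 1000 iterations) take days of CPU
time and are not exercised automatically.  The automated scaled-down study
uses 40 sensors with cutoffs 4/2 (n = 32) on the 2D R = 0.15 m surface for
50 iterations (seed 0, ~3 minutes): the worst-case amplification improves
several-hundred-fold, echoing the two-orders-of-magnitude improvement of the
full-scale experiment.  A smaller 3D pilot (20 sensors, cutoffs 2/1, 500
grid points) reproduces the qualitative migration of sensors from the outer
toward the inner shell surface.

## Channel information capacity

For independent validation, arrays are scored by Shannon capacity under a
random-dipole source model: `p = 1000` dipoles uniform in a 0.07 m ball
(inverse-CDF radius sampling), orientations uniform on the sphere, diagonal
amplitude covariance with root-sum-squared total moment 2e-8 A·m, sensor
noise 1e-14 T.  The forward model is the closed-form field of a current
dipole in a spherically symmetric conductor (Sarvas' formula) centered at
the expansion origin — the model whose silent sources (radial dipoles)
motivate the whole separation problem; silence is preserved to machine
precision.  Capacity is `½ Σ log2(1 + λ_i/σ²)` over eigenvalues of
`L Σ Lᵀ` (symmetric eigensolve on the m×m Gram matrix; negative eigenvalues
beyond -1e-12 of the largest raise, tiny negatives are clipped).  The
ensemble is fixed per evaluation run by its seed; comparisons between arrays
reuse one ensemble.

In the scaled-down 2D optimization, capacity behaves as in the full-scale
experiment's early phase: it drops once the optimizer abandons the radial
orientation pattern and climbs back only as the run approaches convergence.
Fifty iterations capture the drop and partial recovery; the final capacity
at that budget remains somewhat below the radial starting point's even
though the noise amplification has improved by orders of magnitude.

## What the synthetic conditions do and do not show

All evaluation inputs are generated internally (helmet geometries, spiral
point sets, random bandlimited coefficient vectors, random dipole
ensembles); there are no recorded data.  Passing tests therefore demonstrate
the internal consistency of the model chain — exact interpolation of
in-model fields, exact interference rejection, the stated invariances, and
the optimizer's ability to drive `q` down — under the model's own
assumptions: point sensors, i.i.d. Gaussian sensor noise, fields that are
exactly bandlimited in the multipole domain, and a spherically symmetric
conductor.  They do not validate truncation error for real neuromagnetic
fields, correlated or non-Gaussian noise, realistic head conductors, or
physical sensor housings (no collision constraints).  Interpolation noise is
modeled per virtual sensor; noise at different virtual sensors is correlated,
so a virtual *array* is not equivalent to a physical one.

## Known limitations

* An anatomically-constrained sampling volume (MRI head surface) is not
  implemented; the volume abstraction (`contains`, parameterization) is the
  hook a subclass would fill.
* `q` from a rank-deficient measurement matrix (m < n) uses the minimum-norm
  pseudoinverse and is flagged optimistic; comparisons across ranks should
  be read with that flag in mind.
* The 2D/3D grids approximate a continuous maximum; highly localized
  amplification spikes between grid points would be missed at the default
  densities.
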