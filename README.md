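# megarray

Minimum-assumption design of magnetoencephalography (MEG) sensor arrays.

MEG measures the magnetic field outside the head with an array of
magnetometers and tries to learn about the neuronal currents that produced
it.  Rather than scoring candidate arrays by how well they serve some
assumed source model, `megarray` scores them by how accurately they measure
the *neuronal component of the field itself* anywhere a sensor could have
been placed — a well-posed engineering question that needs almost no
assumptions about the brain.  The package is aimed at instrumentation
researchers designing on-scalp (e.g. optically-pumped magnetometer) arrays,
where sensor positions and orientations are genuinely free.

## The model and the figure-of-merit

A source-free magnetic field around the head is expanded in vector
spherical harmonics (the signal-space-separation basis): internal
components (potentials `∝ Y_lm/r^(l+1)`, brain side, degrees `l ≤ L_int`)
and external components (potentials `∝ r^l Y_lm`, interference side,
`l ≤ L_ext`), `n = L_int(L_int+2) + L_ext(L_ext+2)` components in total
(135 at the defaults `L_int = 10`, `L_ext = 3`).  An array ξ of m point
sensors measures `φ = S(ξ) x`; least squares then *interpolates* the
neuronal field component to any virtual sensor `(r, e)` in the helmet-shaped
sampling volume:

    φ_int(r, e) = s_(r,e) · I_int · S⁺(ξ) · φ .

This is exact for noiseless, in-model fields — so any non-degenerate array
would do — and the only thing that distinguishes arrays is how they amplify
sensor noise.  With i.i.d. noise of standard deviation σ, the interpolation
noise at `(r, e)` is Gaussian with standard deviation
`‖s_(r,e) I_int S⁺‖ σ`, and the figure-of-merit is the worst case

    q(ξ) = max over r ∈ V, ‖e‖ = 1 of ‖s_(r,e) I_int S⁺(ξ)‖ ,

the array's worst-case noise amplification factor.  `megarray` evaluates
`q` on a quasi-uniform grid (orientation maximum in closed form), minimizes
it over sensor positions and orientations with dual annealing, and
independently validates designs by their Shannon channel capacity under a
random-dipole source model in a spherical conductor.

## Worked example

Build the non-optimized reference design — 240 radially-oriented sensors
quasi-uniformly spread over the default helmet surface (R = 0.15 m) — and
evaluate it:

```bash
$ megarray radial-array -n 240 -o radial240.tsv
$ megarray evaluate --array radial240.tsv --seed 0
{
  "n_sensors": 240,
  "q": 2788.1467133934707,
  "mean_amp": 1670.9933674657234,
  "rank": 135,
  "rank_deficient": false,
  "capacity_bits": 31.902985730078996,
  ...
}
```

Reading the numbers: the measurement matrix has full column rank (135), so
the array can represent every modeled field component — but its worst-case
noise amplification is `q ≈ 2.8e3`: estimating the neuronal field at the
worst spot of the helmet is ~2800 times noisier than a single sensor
reading.  Radial arrays separate internal from external components poorly,
which is exactly what optimization improves: a scaled-down annealing run
(`megarray optimize --n-sensors 40 --l-int 4 --l-ext 2 --max-iterations 50
--seed 0 --output-dir out/`) drives `q` from ~889 down to ~1.5 by tilting
sensor orientations away from radial.  The channel capacity
(`capacity_bits`, here 31.9 bits per sample for a fixed seeded ensemble of
1000 random dipoles) is the independent yardstick: more bits mean the array
resolves more about the sources.

The same machinery is available as a library:

```python
from megarray import (MultipoleBasisSpec, HelmetSurface, radial_array,
                      figure_of_merit)
surface = HelmetSurface(radius=0.15)
spec = MultipoleBasisSpec(l_max_internal=10, l_max_external=3)
f = figure_of_merit(radial_array(surface, 240), surface, spec)
print(f.q, f.mean_amp)      # 2788.15 1670.99
```

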