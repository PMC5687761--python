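# nanofil

Measurement pipeline for the mechanics, shape dynamics and cross-stream
migration of extremely flexible filaments (electrospun hydrogel
nanofilaments, and by extension semiflexible biopolymers such as actin or
DNA) transported by an oscillatory flow in a shallow rectangular
microchannel.

## What it computes

A filament observed under an epifluorescence microscope is reduced, frame
by frame, to a smooth planar contour; from ensembles of contours the
package estimates the worm-like-chain mechanical parameters, and from the
contour's center-of-mass trajectory the phase-locked transport statistics:

* **Persistence length** `l_p` by the tangent-cosine-correlation method:
  the correlation `C(s) = ⟨cos(θ(s₀+s) − θ(s₀))⟩` of a thermally
  fluctuating, planar-projected contour decays as `exp(−s/(2 l_p))`, and a
  weighted nonlinear fit over an ensemble of tangent profiles inverts it
  (bootstrap confidence interval over filaments).
* **Bending stiffness** `κ = k_B T l_p`, **bending Young modulus**
  `E = 64 κ / (π d⁴)` for an equivalent cylindrical rod, and the
  **effective diameter** `d = (64 κ / (π E))^{1/4}` when `E` is known
  independently — for these hydrogel filaments, more accurate than reading
  `d` off diffraction-limited images.
* **Shape descriptors** per frame: the buckling degree (smallest enclosing
  circle diameter over contour length, computed exactly by Welzl's
  algorithm), the signed inclination angle of the second-moment-ellipse
  major axis, and the end-to-end ratio.
* **Transport statistics** sampled phase-locked to the sinusoidal forcing
  `V(x_rel, t) = V_max (1 − |x_rel|^{4.5}) sin(ωt)`: the lateral migration
  velocity `U_r = ⟨|Δx|/Δt⟩ / V_max` at flow zero-crossings (phase nπ) and
  the slip velocity `U_s = V_filament / V_fluid` at flow extrema (odd
  nπ/2), with the local fluid velocity from the blunted
  observation-plane profile.
* **Dimensionless groups** `A = E d / (32 η V_max)`,
  `K = E_x d² / (4 L η V_max)`, the Sperm number
  `Sp = 32 π η V_max (L/d)⁴ / (E W)` and the Peclet number
  `Pe = L V_max / D`.

Since the original microscope recordings are not publicly deposited, a
first-class synthetic module generates worm-like-chain contours, rendered
fluorescence stacks (Gaussian line-spread, Poisson noise) and advected
trajectories with full ground truth; every measurement stage is validated
against it.

## Worked example

Generate a synthetic U-shaped-filament recording and run the full
pipeline on it:

```
nanofil synthesize U-shaped-stretched --out run/ --seed 0
nanofil analyze run/U-shaped-stretched.tif \
    --config run/U-shaped-stretched_config.yaml \
    --out run/out --origin-um -18.02 -27.08
nanofil report run/out
```

(the `synthesize` step prints the `origin_um` pair to use). The report
prints the stage counts and measured properties:

```
frames in:          160
contours extracted: 160
contours kept:      160
filaments analyzed: 1

properties.csv:
 filament      L_um    group    lp_um  ...   E_Pa       d_nm         A          K
        0 29.676703 U-shaped 5.852639  ... 2000.0 125.562663 83.708442 28.333753

migration.csv:
 filament    group      U_r  direction  U_s_mean
        0 U-shaped 0.003224          1  0.951582
```

Reading it: the filament's contour length is recovered as 29.7 µm (the
generating chain measures 30.9 µm; sub-resolution thermal wiggle erased
by the diffraction-limited imaging accounts for the difference),
classifying it as U-shaped (L < 40 µm). Its persistence length estimate
of 5.9 µm matches the correlation actually realized by the particular
generated chain (a single realization of a 7.5 µm ensemble). At the
imposed bending modulus of 2 kPa the effective diameter is 126 nm,
inside the fabricated 105–181 nm range. The filament was advected with
slip factor 0.95 and a lateral drift of 0.4 µm/s toward the wall at
V_max = 125 µm/s; the pipeline recovers `U_s = 0.952` and
`U_r = 3.2·10⁻³` with direction +1 (wallward).

The same stages are available as a library (`nanofil.flow`,
`nanofil.synthetics`, `nanofil.contours`, `nanofil.mechanics`,
`nanofil.shapes`, `nanofil.migration`, `nanofil.pipeline`).

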