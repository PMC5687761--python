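# Methods

## Flow model

The channel is a shallow rectangular duct, 200 µm wide (x) by 60 µm deep
(z), driven sinusoidally at 0.12–0.64 Hz with peak centerline velocities
of 0.05–0.95 mm/s. The working fluid (ρ = 984 kg/m³, η = 7.5·10⁻⁴
kg/(m·s), T = 302 K) gives channel Reynolds numbers `Re = V_max W ρ/η` of
at most 0.25, and Womersley numbers far below one at these forcing
frequencies, so the flow is treated as quasi-steady creeping flow: the
time dependence enters only through the factor `sin(ωt + φ)` and no
unsteady (Womersley) correction is applied.

Two cross-channel profiles are provided. The ideal parabola
`V_max (1 − x_rel²)` describes the inlet forcing; the observation-plane
profile in the wide dimension of a shallow duct is flatter and is modeled
as the blunted parabola `V_max (1 − |x_rel|^n)` with `n = 4.5` by default
(`x_rel = 2x/W`, origin at the centerline). The exponent is a config
value; fitting it per dataset against measured tracer velocities is
supported. As an internal consistency anchor, the package carries the
classical steady Fourier-series solution for pressure-driven flow in a
rectangular duct (series over the narrow dimension, 51 odd terms by
default, relative truncation error < 10⁻⁶ at the center). Fitting the
blunted form to that series on the mid-depth plane of the experimental
geometry yields n ≈ 4.7, inside the [4, 5] band that brackets the default;
the same series reproduces the textbook peak-to-mean ratios 2.096 (square
duct) and 1.5 (plane-Poiseuille limit of a very wide duct).

The shear rate is the analytic x-derivative of the blunted profile. The
observation plane sits 30 µm below the top wall, i.e. at mid-depth, where
the z-gradient vanishes by symmetry; z-direction shear is not modeled.

## Synthetic data

No recordings are deposited with the study this emulates, so a generator
produces every input with known ground truth.

**Contours.** Discrete planar worm-like chains: points at arc spacing Δs
(Δs ≤ L/20 enforced) whose tangent-angle increments are i.i.d.
N(0, Δs/l_p). For a chain confined to or projected onto a plane this
gives the tangent-cosine decay `⟨cos Δθ(s)⟩ = exp(−s/(2 l_p))` exactly at
the sampled separations. The planar convention (decay constant 2 l_p) is
the default because the imaging geometry observes projected contours
within a 10 µm focal slab; the 3-D convention (decay constant l_p) is a
switch. Emulated parameter ranges: L = 26–83 µm, l_p = 3–25 µm.

**Images.** A contour is rendered as the line integral of an isotropic
Gaussian kernel (the line-spread function, σ = 1.2 px at 0.4 µm/px by
default), normalized so a straight ridge reaches the configured peak
intensity (1000 counts over a 100-count background), plus Poisson
counting noise by default — SNR ≈ 10. The study does not report its
camera noise statistics, so these are config values, not claims.
Gaussian and noise-free modes exist for calibration tests.

**Trajectories.** Transport is kinematic: per frame, the longitudinal
displacement is `slip_factor ×` the local blunted-profile velocity
(midpoint rule in time), and the lateral displacement is an imposed
drift plus a Brownian step of variance 2DΔt. Walls reflect the position,
and a wall contact also reverses the deterministic drift direction
(billiard bounce) so a drifting particle traverses rather than pins.
Frame rate 10 Hz and 500–2000 frames per run are the emulated recording
conditions. Filament sequences apply a deformation schedule to a base
chain — `static`, `periodic-rotation` (rigid, hence isometric), or
`periodic-bend` (uniform arc bending, also isometric by construction) —
then translate it along the simulated trajectory. A bead-spring
elastohydrodynamic simulation is deliberately out of scope: the
kinematic generator suffices to validate every measurement operation,
which is what it exists for.

All randomness flows from explicit integer seeds; identical configs are
bit-identical.

## Contour pipeline

Segmentation thresholds at `background + k·MAD` (background = image
median, k = 5) with a floor of 10% of the robust peak excess so
noise-free images do not degenerate to a bare-background threshold. The
mask's morphological skeleton is converted to a graph; spurs shorter
than 6 px are pruned and the longest geodesic path between endpoints is
the ordered chain (filaments are open curves; closed loops fall back to
a double-sweep farthest pair). Frames with zero or multiple objects
yield per-frame rejection records, not exceptions.

Two sub-pixel corrections matter quantitatively. A 5-point moving
average removes the stair-step zigzag of the 8-connected pixel chain,
which otherwise inflates the arc length of oblique filaments by several
percent. Skeletonization also misplaces the filament tips by up to a
line-width; because the ridge intensity of a Gaussian line-spread falls
to half its interior value exactly at the true tip, each end is moved
along the local tangent to the interpolated half-maximum crossing
(extending eroded ends, trimming overshot ones). With both corrections
the recovered length of straight filaments is orientation-independent to
within 1%.

The ordered points are fit by a parametric cubic smoothing spline
against a chord-length parameter. The smoothing budget is chosen by
two-fold (even/odd) cross-validation over a log-spaced grid by default
and can be fixed explicitly; a guard refits with a larger budget if the
fitted curve's arc length exceeds the input polyline's by more than 10%
(a wildly oscillating interpolant is never a valid contour). The curve
is reparametrized to arc length numerically; the reported L is the
fitted curve's total arc length. Tangent angles come from the analytic
spline derivative at equally spaced stations and are unwrapped;
ground-truth polylines bypass the spline and use exact segment angles.

Quality control mirrors the experimental protocol: a run is rejected
when the relative spread of its per-frame contour lengths,
`(max−min)/mean`, exceeds 10% (apparent length changes indicate
out-of-plane deformation), and frames whose z lies outside the 10 µm
focal slab are excluded.

Known resolution limit: thermal wiggle at scales below the line-spread
width is genuinely erased by imaging, so image-derived lengths of very
flexible chains (l_p ≲ 10 µm) run a few percent short of the generating
polyline's length, and strongly coiled chains whose arms approach within
a line-width self-merge in the mask. The 3% round-trip accuracy claim
therefore applies to straight and gently curved filaments; the synthetic
tests encode exactly that.

## Mechanics

The cosine correlation is averaged over all start stations of all
profiles in an ensemble, then fit by weighted nonlinear least squares to
`exp(−s/(c l_p))` (weights ∝ √pair-count). The fit window starts at
s ≤ L/2 and is iterated once to `s ≤ min(L/2, 2 l̂_p)` to keep the
noise-dominated tail from biasing the estimate — standard practice for
exponential-decay fits. Confidence intervals are a 95% percentile
bootstrap over profiles (200 resamples). For image-derived contours the
fit optionally includes a free amplitude, because uncorrelated tangent
noise from pixelation depresses C(s) by a constant factor without
changing the decay length; ground-truth ensembles are fit with amplitude
pinned to 1. Degenerate inputs are flagged (`rigid limit` for zero
angular variance, `non-decaying` when the windowed correlation does not
fall), never fit. On 500-chain ensembles (L = 4 l_p) the estimator
recovers l_p with ≈ 2–4% error and batch-to-batch spread of ≈ 3%.

The stiffness chain uses CODATA k_B and T = 302 K: κ = k_B T l_p,
E = 64κ/(πd⁴), and the inversion d = (64κ/(πE))^{1/4} with E = 2 kPa
(the study's consolidated bending-modulus estimate) when the diameter is
wanted from mechanics rather than imaging. The extensional modulus
E_x = 20 kPa is an input constant from a scaled-down macroscopic tensile
test, not something this package can measure.

Dimensionless numbers follow the printed formulas with one reading fixed
deliberately: the Sperm number `Sp = 32 π η V_max 𝓛⁴/(E W)` is
dimensionless only if 𝓛 is the slenderness L/d, so it is implemented
that way. Under this reading the ratio between group exemplars
(65 µm/31 µm)⁴ ≈ 19 reproduces the reported order (≈ 21), while the
absolute values do not match the published group means — the published
unit convention for Sp, A, K of the literature comparison rows cannot be
reconstructed, and those absolute values are treated as non-reproducible
metadata. Likewise no formula for the longitudinal diffusivity D is
published; the package defaults to the slender-body expression
`D = k_B T ln(L/d)/(2π η L)` (pluggable), so Peclet numbers are
order-of-magnitude quantities. Group classification is by contour
length: bent-like for L ≥ 40 µm, U-shaped below.

## Shape descriptors

The smallest enclosing circle is exact: Welzl's move-to-front
construction over deduplicated points with a fixed shuffle seed,
cross-checked in the tests against an O(n⁴) candidate-circle search.
Collinear support triples fall back to the farthest-pair two-point
circle. Buckling degree = circle diameter / L; end-to-end ratio = chord
/ L; both lie in (0, 1] with r ≤ c.

The "encircling ellipse" for the inclination angle is the second-moment
(inertia-equivalent) ellipse — stable under noise and standard in
particle-shape analysis — not the minimum-area enclosing ellipse. The
signed angle is measured from the cross-channel axis toward the flow
axis in [−π/2, +π/2] by folding the undirected major axis to a positive
cross-channel component; the exactly flow-aligned case takes its sign
from the more downstream endpoint, ties positive. Isotropic point
clouds (eigenvalue ratio below 1 + 10⁻⁶) return an undefined-orientation
flag. Trend analysis samples descriptors at flow zero-crossings, splits
even/odd crossings into forward/reverse branches, fits a linear trend
per branch, and reports initial- and final-cycle values for histograms.

## Migration statistics

The oscillation phase is recovered by least-squares fitting
`V_max sin(ωt + φ)` to a reference longitudinal velocity series
(frequency initialized from the periodogram, four phase starts), with at
least three periods of data and a minimum R² of 0.5 required; frames
nearest each nπ and odd nπ/2 phase are the zero-crossing and extremum
labels. `U_r` averages `|Δx|/Δt` over consecutive zero-crossing pairs
(per-interval convention) normalized by V_max; the migration direction
is reported separately as the sign of the net change of |x|, because
magnitude and direction are independent observables. `U_s` divides the
filament's longitudinal velocity at each extremum — a centered 3-frame
finite difference, deconvolved by the exact sin(ωh)/(ωh) attenuation a
centered difference applies to a sinusoid — by the blunted-profile fluid
velocity at the center-of-mass lateral position (contour-averaged
velocity is an option; the point estimate matches the short-fragment
calibration the protocol uses). The COM is the arithmetic mean of
contour points (uniform line density). Track linking is greedy
nearest-neighbor under a displacement gate, deterministic under ties.

On noise-free synthetic transport the recovery accuracy is: U_r bias
≤ 1.3% over the drift grid 0.1–7 µm/s × V_max {125, 250} µm/s (20
periods, 10 start positions; the residual bias is the interval that
contains a wall bounce), and U_s within 0.007 of the programmed slip
factor at every extremum.

## Pipeline and problem sizes

`run_pipeline` chains segmentation → QC → spline fit → descriptors →
mechanics → migration over a TIFF stack and writes CSV/JSON outputs plus
a manifest (config snapshot, seed, per-stage counts — monotone
non-increasing through QC). The phase reference for a filament run is
its own longitudinal COM velocity, which is valid because the slip
factor only rescales the sinusoid's amplitude, not its phase. Canned
scenarios parametrize the synthetic generator to the study conditions
(U-shaped stretched at V_max = 125 µm/s, U-shaped buckled at 250 µm/s,
bent-like at 125 µm/s; drifts inside the observed 0.1–7 µm/s range;
tracer runs at the fast end of the forcing band, 0.64 Hz, so several
periods fit a short recording).

Default validation sizes are chosen to exercise the statistics without
excess: 500-chain ensembles for estimator recovery, 160-frame rendered
stacks (512×256 px) for end-to-end runs, 1000 seeded instances (n ≤ 25)
for the circle oracle, and a 10-seed × 10-cell grid for migration
recovery. All are config/argument values, not hard-coded limits.

## Known limitations

- No hydrodynamic filament model: deformation schedules are kinematic,
  so the pipeline is validated as a measurement chain, not as a
  predictor of filament dynamics.
- Single-filament frames only; multi-filament tracking and
  disambiguation are out of scope (multiple objects reject the frame).
- 2-D projected analysis; out-of-plane shape is handled only by the
  QC exclusions.
- Published absolute Sp/A/K/Pe group means are not reproducible from
  the printed formulas (see Mechanics); internally consistent
  quantities are the validation anchors.
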