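# Methods

This note records the models implemented by `halffield`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Experimental geometry

A half-field dish is modelled in mm with the origin at the dish centre.
The shield edge is the vertical line `x = boundary_x` (default 0); the
irradiated half is `x < boundary_x`.  Defaults: 60 mm dish diameter, 2 Gy
nominal dose.  The published exclusion criterion — a "20 mm exclusion
region" around the shield boundary — is read as a 20 mm-wide band, i.e.
`exclusion_half_width = 10` mm; the alternative reading (20 mm half-width)
is available by setting 20.  Region assignment uses a cell's **first-frame
position only**: 24 h path lengths are of order 10² μm, two orders of
magnitude below the 10 mm band half-width, so analyzable cells essentially
never cross a region boundary during a movie.

The penumbral dose falloff is a normal CDF,
`D(x) = D₀·Φ((x_b − x)/σ_p)`, with `σ_p` a free parameter (default 1 mm):
no numeric film profile is available to fit, and the sigmoid shape with
half dose at the field edge is the standard description of a collimated
edge.  Dose is metadata for reporting; it does not drive cell behaviour.
Dose from secondary-electron scatter is deliberately not modelled.

## Synthetic migration model

Each cell draws a speed `s_i` from a lognormal law
`log s_i ~ N(log m, σ²)`.  The median `m` is the published group median
velocity; `σ` is fitted to the published IQR by least squares over the two
log-ratios, which has the closed form `σ = log(q3/q1) / (2·z₀.₇₅)`.  The
lognormal was chosen because the published distributions are strongly
right-skewed (Q3 − median far exceeds median − Q1) and it is the simplest
positive-valued skewed two-parameter family.

Calibrated presets (μm/h, with fitted `σ` ≈ 0.78–0.80):

| preset | control | uniform | in-field | out-of-field |
|--------|---------|---------|----------|--------------|
| fig2 (radiation alone) | 5.73 | 4.99 | 5.86 | 4.66 |
| fig4 (cisplatin + radiation) | 4.83 | 5.28 | 5.03 | 5.17 |

Movies are 97 frames at 15 min ("15 min intervals over 24 h" including
both endpoints).  Steps have uniform random directions, blended with the
previous direction by a persistence weight `ρ ∈ [0, 1)` (0 = pure random
walk, the default for all presets, matching the linear-MSD behaviour of
the real data).  Two step-length laws are provided:

- `fixed_length` (default): every step is exactly `s_i·Δt`.  This makes
  the path-over-time velocity estimator recover `s_i` *exactly*, so
  calibration recovery is unbiased by construction and the cohort median
  velocity estimates the preset median with only sampling error.
- `gaussian`: isotropic Gaussian steps with mean length `s_i·Δt`
  (per-axis SD `s_i·Δt·√(2/π)`), for which the ensemble MSD obeys the
  diffusion closed form `MSD(kΔt) = 2σ_axis²·k` exactly in expectation.

Start positions are uniform over the group's analyzable sub-region (the
matching half outside the exclusion band for In-/Out-of-field groups, the
whole dish for Control/Uniform), at least one cell radius (default 5 μm)
from region edges.  `n_cells_per_group` is the total per group, split
evenly across replicates (default 3); one master seed deterministically
derives a stream per (group, replicate), so outputs are byte-identical
across runs and independent of which groups are simulated.

**What the generator does not emulate:** cell division and death, contact
interactions, brightfield/fluorescence textures, an explicit diffusing
bystander-signal field (group speed differences are imposed directly), or
localisation noise.  Passing tests therefore validate the pipeline's
estimators and inference on data that *satisfy* the random-walk and
independence assumptions; they cannot certify segmentation quality or
behaviour under tracking errors on real movies.

FUCCI states are i.i.d. draws over (G1 red, early-S yellow, S/G2/M green).
The cisplatin preset uses the published green arrest fraction 0.703; the
split of the remaining mass (0.200 red / 0.097 yellow) and the untreated
distribution (0.40 / 0.15 / 0.45, a typical asynchronously cycling
population) are synthetic stand-ins, as no source values are printed.

## Tracking

Detection reduces each labelled object to the unweighted mean of its pixel
centres.  Linking is greedy nearest-neighbour per frame pair in ascending
distance order with a hard gate (`max_step`, default 30 μm per 15-min
frame ≈ 120 μm/h, roughly 10× the observed median speed), no gap closing
and no division handling — disappearing objects end their track, new
objects start new (necessarily incomplete) tracks.  Greedy linking is
deterministic and auditable, and on fixtures whose inter-cell separation
dominates per-frame motion it provably coincides with the optimal
assignment; the test suite bounds its behaviour against a brute-force
minimum-cost matching oracle.

Inclusion filters mirror the published criteria: tracks must span all
frames, stay inside the observation field, and start outside the
exclusion band; "nonviable" cells are operationalised as a total path
length below a motion floor (default 0.1 μm; set `motion_floor=None` to
disable).  Reject reasons are machine-readable
(`INCOMPLETE`, `EXITED_FIELD`, `EXCLUDED_REGION`, `NONVIABLE`).

## Metrics

The ensemble MSD is computed from each cell's initial position (no
time-averaging over sliding windows), exactly as the defining formula
states, over complete tracks of equal length.  The linear fit uses all 96
lags with equal weight and a **free intercept**: localisation noise in
real data offsets the whole curve without changing its slope, so forcing
the line through zero would bias the slope.  R² of this fit is the
linearity measure; `classify_motion` labels a curve random-walk-consistent
at R² ≥ 0.99 (configurable) and always reports R² alongside the label.
Velocity defaults to path-length/elapsed-time; the per-step-mean
alternative is exposed and is identical under uniform sampling.

Convergence note: for speed-homogeneous cohorts the MSD fit reaches
R² ≥ 0.99 by ~200 cells, but the heavy-tailed lognormal speed mixture of
the calibrated presets inflates ensemble noise (the relative variance of
`s²` is `e^{4σ²} ≈ 11`), so heterogeneous cohorts need ~2000 cells to
reach the same R².  Property tests use those sizes.

## Steel's many-to-one test

Construction (two-sided throughout, chosen because published effects go in
both directions):

1. For each treatment `g`, the mid-rank Wilcoxon rank-sum statistic of
   `g` vs the shared control, standardized with tie-corrected variance to
   `z_g` (ties arise from file rounding even for continuous velocities).
2. Shared-control dependence: `corr(Z_g, Z_h) = λ_g λ_h` with
   `λ_g = √(n_g/(n_g+n_0))` — an exact one-factor structure (ρ = 1/2 at
   equal sizes).
3. Adjusted p: `p_g = P(max_j |Z_j| ≥ c_g)` under that multivariate
   normal.  The one-factor structure reduces the orthant probability to a
   one-dimensional integral over the shared factor, evaluated by
   Gauss–Hermite quadrature (96 nodes; `mc_error` reports the change on
   halving the node count, typically ≤ 1e-10).  A deterministic quadrature
   was preferred over Monte-Carlo integration because the factor structure
   makes it exact to machine precision at any correlation.
4. Small samples: the normal approximation of a discrete rank statistic is
   poor at n ≲ 10 (errors up to ~0.04 even with continuity correction), so
   for tie-free samples with max(n₀, n_g) ≤ 25 the marginal threshold
   `c_g` is taken from the exact Wilcoxon null via a normal-score
   transform, `c_g = Φ⁻¹(1 − p_exact/2)`.  This brings agreement with the
   fully enumerated permutation null at n = 4+4+4 to ≤ 0.003.  Larger or
   tied samples use the continuity-corrected normal `|z|`.
5. Permutation mode relabels the pooled observations (exhaustively when
   the count of distinct relabelings is small, otherwise sampling with the
   given seed, capped at 10⁶) and recomputes `max_j |z_j|`; its p-values
   are exact multiples of 1/(relabelings used).

Replicates are pooled into one sample per group for the primary test,
matching the published pooling of ≥3 replicates into per-group cell
populations; replicate ids are retained in all tables for sensitivity
analyses.  Significance threshold α = 0.05.

The chi-square test is the plain Pearson statistic with margin-derived
expected counts and no continuity correction.  Group summaries use
linear-interpolation quartiles and report in the order Control, Uniform,
In-field, Out-of-field.

## Cohort sizes for the end-to-end pattern checks

The qualitative significance patterns (radiation alone: Uniform and
Out-of-field slower than Control, In-field unchanged; cisplatin: all three
irradiated groups faster) are checked on power-sized cohorts derived from
the calibrated effect sizes: for lognormal groups the rank-test effect is
`AUC = Φ(Δlog/√(σ₁²+σ₂²))` and `E|z| ≈ (AUC − ½)·√(6n)`.  The
radiation-alone run uses n = 1500/group, large enough for the Uniform and
Out-of-field effects (~99 % and ~100 % power at the familywise 0.05
critical value ≈ 2.35) while keeping the small In-field difference
(median ratio 1.023) non-significant with ~94 % probability.  The
cisplatin run uses n = 20 000/group because its weakest effect (In-field,
median ratio 1.041) needs that scale for ~99 % power.  No single cohort
size reproduces both patterns reliably — the In-field non-significance in
one experiment caps n near 4000 while the In-field significance in the
other requires n ≳ 10⁴ — which indicates that printed median/IQR pairs
under a lognormal law do not fully pin down the published rank-test
p-values (real velocity distributions evidently differ from lognormal in
their tails or within-replicate structure).  Calibration-recovery checks
use n = 1000 with a 3-standard-error tolerance on the sample median,
`SE ≈ (2 f(m) √n)⁻¹` with `f` the fitted lognormal density.

## Known limitations

- The generator's fixed-length step law has zero within-cell speed
  variance; per-cell velocity estimates carry no estimator noise.  This is
  intentional for calibration recovery but understates the dispersion real
  trackers add.
- The exclusion-band width interpretation (±10 mm) is a documented
  reading of an ambiguous printed value; both readings are configurable.
- Greedy linking is only guaranteed optimal on well-separated scenes; at
  high densities a global assignment (LAP) tracker should replace it.
- The FUCCI model is static: states do not progress during the movie and
  are not coupled to speed.
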