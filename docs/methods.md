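# Methods

This note documents the models implemented in `dichopt`, the synthetic
data they are verified against, the numerical choices, and what the
passing tests do and do not establish.

## Laminar fMRI arm

### Cortical ribbon and equivolume depth

The ribbon is a pair of triangle meshes (pial, white) with 1:1 vertex
correspondence; a vertex's cortical column is the segment between its two
positions.  Neighborhood area per vertex is the barycentric 1-ring area
(each triangle contributes a third of its area to each corner); the
1-ring is the assumed neighborhood for the curvature correction.

For a column with pial area `A_p` and white area `A_w`, the tissue volume
up to Euclidean fraction `x` is modeled with linearly interpolated area,
`V(x) = ∫₀ˣ [(1−t)A_p + tA_w] dt`.  Setting `V(x) = α·V(1)` gives the
closed-form `x(α) = (A_p − √((1−α)A_p² + αA_w²)) / (A_p − A_w)`, with
`x = α` in the parallel (slab) limit.  Eleven intermediate surfaces at
equispaced `α` are generated by default (nine is the allowed minimum; the
choice only bounds the piecewise-linear interpolation error, ~1e-3 in
depth), and each gray-matter voxel's depth is interpolated linearly
between the two surfaces bracketing its Euclidean position.  Layer
compartments are the exact equivolume-depth tertiles (cuts at 1/3, 2/3):
in this coordinate equal depth intervals enclose equal volume, so the
tertile rule is independent of voxel sampling density, which an empirical
voxel-count tertile would not be.

Voxelization assigns each grid voxel to its nearest column segment (among
eight nearest-midpoint candidates).  A voxel is gray matter if its
projection lies within the column and its perpendicular distance is below
0.8 of the local vertex spacing, where spacing is the square root of the
median neighborhood area interpolated between the two surfaces at the
voxel's depth.  Making the inclusion radius scale with the local surface
area keeps edge effects depth-unbiased on curved ribbons; on the wedge
fixture at 0.15-mm voxels the three compartments hold one third of the
volume each to within ~0.4 %.  A residual limitation is grid aliasing:
strongly folded fixtures (the sinusoidal sheet) show coherent moiré
between the voxel lattice and the fold period, so quantitative volume
checks use the wedge, whose radial columns decorrelate the two grids.

### Fixtures

* `slab` — parallel planes; equivolume depth must equal Euclidean depth.
* `wedge` — a cylindrical sector: triangle areas scale exactly with
  radius, giving a constant pial:white area ratio (2:1 by default) and an
  analytic depth `α(ρ) = (R_p²−ρ²)/(R_p²−R_w²)` used as the oracle.
* `sinusoidal` — a folded sheet for geometric validity checks.

### BOLD simulation and GLM

Stimulus blocks (AE / FE / binocular, 18 s, separated by 12-s fixation;
3 blocks per condition = 282 s per run) are convolved with a
gamma-difference block response (peak 6 s, undershoot 16 s at 1:6,
sampled at 0.1 s) normalized so one isolated block peaks at 1.0 — a beta
is then the block amplitude in the data's units.  The same kernel object
drives the simulator and the GLM: the exact shape is a convention, and
sharing it makes noiseless recovery exact, which is what the recovery
tests need.  The GLM is voxelwise OLS on [stimulus regressors | Legendre
drift to order 3 | optional motion columns], with a named-column
rank-deficiency diagnostic.  Betas are rescaled to percent signal change
against the voxel temporal mean; to keep that convention consistent with
exact recovery, the simulator plants amplitudes relative to the run mean
(stimulus regressors are centered into the baseline).  Noise is AR(1)
Gaussian (ρ = 0.3, a typical fMRI autocorrelation; the default amplitude
0.2 PSC per TR puts the 4-run beta SNR in the low tens).

Each vertex carries non-negative mixing weights `(w_AE, w_FE)` drawn from
a smoothed sinusoidal band pattern (2-mm bands) mimicking ocular
dominance columns, recentred so neither eye is over-represented in the
population; `contrast` sets the partial-volume strength and the weights
sum to `gain ≤ 1`.  Voxel amplitude per condition is the weight-channel
dot product, with binocular channel responses scaled by `1 − BSI(depth)`.
Planted vein columns get a 15× response gain and 0.6× baseline intensity,
placing them beyond both arms of the exclusion rule.

### Vein exclusion, profiles, ADI, ROIs

Voxel values are mapped to the surface as the mean over each vertex's
column.  A vertex is flagged as a large vein if its mean EPI intensity
falls below 70 % of the across-vertex average or its across-condition
mean response exceeds 10 PSC (the across-condition mean realizes the
"averaged responses" reading); all voxels of a flagged column are
excluded, never a partial column.  Depth profiles average betas in
equivolume-depth bins (three by default), reporting voxel counts and
flagging empty bins as missing.  `ADI = (FE − AE)/FE` per bin, undefined
where FE ≤ 0.  Ocular-bias ROIs take the top and bottom 10 % of the
pooled AE−FE surface distribution (pooled, not per hemisphere — the
fixtures have one sheet), ties broken by vertex index; the split-half
scheme uses odd runs to select vertices read out in even runs and vice
versa, averaging the two — the tests show this removes the selection
(circularity) bias that single-sample selection provably incurs.

A caveat the tests make explicit: the profile-level ADI equals the
planted ADI exactly only when the sampled voxel population weights the
two eyes equally; with banded weights on a finite patch, the ratio
acquires a small sampling bias even without noise (the flatness across
layers — the substantive feedforward prediction — is exact regardless).

### Inverted encoding model

Weights are fit per voxel by non-negative least squares (negative
monocular betas are clamped, not excluded, since such voxels are kept in
the published procedure); `scipy.optimize.nnls` handles general channel
designs, while the identity design short-circuits to clamping.  Channel
inversion pools all voxels of a depth bin × ROI in one OLS solve — a
per-voxel inversion is impossible (one observation, two unknowns) — and a
bin whose weight matrix has condition number above 1e8 is flagged
ill-posed rather than patched with regularization.  `BSI = 1 − C_bino`.

Known property: when the weights themselves are noisy, the inversion is
an errors-in-variables regression whose attenuation bias is set by the
weight noise, not the voxel count; adding voxels shrinks the scatter but
not this bias.  The tests therefore check bias → 0 as weight noise → 0
and scatter → 0 as N grows, and the noisy acceptance check uses
multi-run-averaged betas where the attenuation is ≪ 0.05.

## SSVEP EEG arm

### Simulator

Six-second dichoptic trials on a 15-electrode occipito-parietal montage
(central O1, Oz, O2, PO3, POz, PO4; surround P5, P3, P1, Pz, P2, P4, P6,
PO7, PO8) at 1000 Hz.  Flicker is modeled as a fundamental plus a second
harmonic with planted amplitudes (an on/off rectified waveform would fix
the harmonic ratio; planting it directly keeps the truth explicit), tags
7.2/8 Hz with both eye↔frequency assignments, monocular conditions carry
only the stimulated eye, binocular conditions carry both eyes scaled by
`1 − BSI` plus an intermodulation cosine at 15.2 Hz.  A planted per-eye
latency τ enters as phase `−2πfτ`.  Projection is a fixed 5:1
central:surround gain (no head model is attempted).  Noise is
1/f-shaped plus a 20 % white floor, RMS 2 µV per channel by default —
with 20 trials this puts the averaged-signal SNR near 10.  Trials are
separated by 1–1.5-s jittered stimulus-free gaps (sessions are
self-initiated); the jitter also randomizes the phase at which one
trial's content leaks into a neighbor's analysis window through the long
zero-phase filter kernel, which would otherwise add a small deterministic
phase bias (6 s is a non-integer number of 7.2-Hz cycles).  The full
crossing 2 spatial frequencies × 3 ocularities × 2 assignments gives 12
conditions; the cohort analyses run the low-SF half, with high SF a
planted amplitude scale.

### Amplitude and phase pipelines

Amplitude: band-pass 1–30 Hz, keep the last 5 s of each 6-s trial
(dropping the onset transient), average all trials of a condition
pointwise, subtract the surround-electrode mean from the central-electrode
mean (surface Laplacian), FFT to a single-sided amplitude spectrum
normalized so a unit sinusoid on an exact bin reads 1.0.  The 5-s window
gives 0.2-Hz bins, putting 7.2, 8, 14.4, 16 and 15.2 Hz exactly on bins;
`check_exact_bins` asserts this at pipeline start and off-grid queries
raise with the nearest-bin offset.  First and second harmonic amplitudes
are summed per tag assignment first, then the two assignments are
averaged per condition.  `ADI` and `BSI` follow from the tagged
amplitudes; an index whose monocular amplitude does not exceed the noise
floor (mean of the 10 nearest non-signal bins) is flagged unreliable.

Filters are symmetric (linear-phase) FIR kernels designed with `firwin`
(Hamming; transition width 0.4 of the low edge, ≥ 0.4 Hz) and applied in
a single pass by FFT convolution with exact group-delay compensation and
reflective padding — identically zero phase with the designed magnitude
response (a forward-backward pass would square the magnitude), measured
passband ripple < 1 % and > 50 dB at 0.2 Hz.

Phase: band-pass 6–9 Hz (fundamentals only — the band itself excludes
second harmonics), average the 1251–5000-ms window (3750 samples = 27
cycles of 7.2 Hz = 30 cycles of 8 Hz, making the two quadrature
regressors exactly orthogonal), then fit `a·cos(2πft) + b·sin(2πft)` by
least squares at the single tag frequency (a joint two-frequency fit is
available but changes nothing on integer-cycle windows).  Phase is
`atan2(−b, a)` — cosine convention, so a pure cosine reads 0 — and only
phase *differences* matter downstream, which are convention-invariant.
`phase_to_delay` wraps the difference to (−π, π] and divides by 2πf;
the sign convention is **positive = second argument later**, i.e. a
delayed (lagging) signal yields a positive delay.  Per-subject AE−FE
differences are formed at each tag frequency, converted to ms, and
averaged across the two frequencies in the ms domain (radians at
different frequencies are not commensurable).

## Group statistics

* **Mahalanobis outliers**: each subject's measurements form a point;
  D² against the sample (or supplied) mean and ordinary sample covariance
  is referred to χ² with d degrees of freedom, flagging upper-tail
  probability < 1 % — the tail-probability reading of "likelihood below
  1 %", which makes the 1 % flag rate under the null exact by
  construction.  Affine invariance holds when moments are estimated from
  the sample; a near-singular covariance raises with its condition
  number.
* **Bootstrap CI**: percentile bootstrap of the mean, 10,000 resamples,
  seeded.  Coverage is near-nominal for n ≳ 50 and width shrinks ~1/√n.
* **Circular mean test** (the within-subject phase-delay test): the mean
  direction's confidence interval is built with the standard chi-squared
  construction (two branches, mean resultant length below/above 0.9);
  the null direction is rejected iff it falls outside the CI.  The
  reported `p_proxy` is the CI level at which the null direction touches
  the boundary, found by bisection.  The construction is mildly
  *conservative* at low concentration (empirical type-I ≈ 3.5 % at
  nominal 5 % for von Mises κ = 2, n = 20) and nominal at higher
  concentration; it never exceeds the nominal level in the null
  simulations.
* **Watson–Williams**: the standard two-sample F statistic for equal
  mean directions with the `1 + 3/(8κ)` correction (κ from the pooled
  resultant length via Fisher's three-branch approximation).  The usual
  concentration assumption (pooled r̄ ≥ 0.45) is reported as a warning
  flag, not a hard error.  Empirical type-I error is nominal and power
  against a 0.6-rad offset (κ = 5, n = 20) exceeds 0.9.
* **ADI–BSI correlation**: plain Pearson r with two-sided p on
  outlier-cleaned pairs of (binocular − monocular ADI) and (AE − FE BSI).

## Synthetic cohorts and problem sizes

The generator's physics follows the study conditions: 282-s runs, 18/12-s
blocks, 6-s trials at 1000 Hz, 7.2/8-Hz tags, 20 trials per condition,
a planted 12.81-ms amblyopic-eye latency, and mean suppression asymmetry
BSI_AE ≈ 0.40 vs BSI_FE ≈ 0.05 with a mean monocular ADI of 0.35.
Cohort and grid sizes are chosen for desk-scale runs: 12 synthetic
subjects for the EEG cohort, a ~900-vertex ribbon with 0.4-mm voxels and
4 runs for the fMRI session, and the 2500-vertex/0.15-mm wedge for volume
checks; all scale up by config without code changes.

What passing tests show: the implementations invert their own generative
assumptions correctly (linear mixing, sinusoidal tags, 1/f noise, AR(1)
BOLD noise, exact tag frequencies).  What they do not show: robustness to
real-data violations — nonlinear BOLD, non-sinusoidal flicker responses,
eye movements and blinks, imperfect segmentation/registration, electrode
artifacts — none of which the generator emulates.

## Reproducibility

Every stochastic routine takes an explicit seed; identical seeds give
byte-identical outputs.  Pipeline outputs embed a config hash and seed in
a provenance header, and rerunning a config reproduces its tables
exactly.  The analysis scripts and `scripts/acceptance.py` are thin,
deterministic drivers over the library.
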