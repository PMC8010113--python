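# Methods

## The problem

A region of silence is a contiguous patch of cortex with no
electrophysiological activity — resected, ischemic, or lesional tissue.
Localizing it from scalp EEG inverts the usual source-localization
question: instead of finding where activity *is*, the task is to find
where background activity is *missing*, which means background brain
activity must be treated as signal rather than noise.  This package
implements a two-stage algorithm for that task, a synthetic study
framework to exercise it end to end, silence-adapted versions of three
classical source localizers for comparison, and evaluation metrics.

## Model

The forward model is linear: `X = A S + E`, with `A` the n x p lead field,
`S` the p source time courses, and `E` spatially white sensor noise with
per-electrode variances (diagonal `C_z`).  Only differential potentials
are observable, so recordings are `Y = M (A S + E)` where `M` subtracts
one reference electrode's channel; the referenced lead field is
`A~ = M A`.

Non-silent sources are zero-mean, wide-sense stationary, with a spatial
exponential-decay covariance

    c_ij = sigma_s^2 exp(-gamma ||f_i - f_j||^2),

identical variance `sigma_s^2` for every active source; the k silent
sources have identically zero rows and columns.  A silent patch is assumed
contiguous (a connected subgraph of the z-nearest-neighbor source graph),
small (`p - k >> k`), and confined to one hemisphere.

## The algorithm

**Contribution measures.**  The projection `mu_qt = a~_q^T y_t` measures
how much source q's forward pattern is present in the data at time t.  Its
variance decomposes into contributions of all sources plus sensor noise;
subtracting the noise quadratic form and normalizing by the silence-free
value yields, per source,

* `beta_q` (low resolution; uncorrelated-source normalization; range
  `[0, sigma_s^2]`),
* `beta_high_q` (high resolution; normalized by the full-covariance
  prediction; range `[0, 1]`).

Deep or tangential sources have intrinsically weak `Var(mu)`; the
normalization is what makes these measures comparable across the cortex.

**Hemispheric baseline.**  Healthy cortex has approximately
mirror-symmetric average power across the longitudinal fissure.  The
mirrored ratio `beta~_q = min(beta_q / beta_{q_m}, 1)` (with `q_m` the
mirror partner; midline-strip sources fixed at 1) judges each source
against its contralateral twin and cancels spatially varying but
symmetric source variance — the regime where the raw measure fails.  A
true baseline recording, when available, replaces the mirror by the same
source's baseline contribution.  The denominator is safeguarded at
`1e-6 * max(beta)`, and a doubly silent mirrored pair resolves to 1.

**Convex spectral clustering (CSpeC).**  Silent sources are selected by a
relaxed indicator `g in [0, 1]^p` (small = silent) minimizing
`beta^T (1 - g) + lambda (1 - g)^T L (1 - g)` subject to
`||g||_1 <= p - k`, with `L` the Laplacian of the z = k nearest-neighbor
graph with Gaussian weights.  The Laplacian term equals
`1/2 sum w_ij (g_i - g_j)^2` and enforces contiguity.  `lambda` is tuned
on a log grid by minimizing the sum of the two squared objective terms,
each normalized by its grid maximum; the patch size k is tuned by matching
modeled to observed channel powers (max-normalized in the low-resolution
pass where `sigma_s` is unknown; absolute in the high-resolution pass
where it has been fitted).

**Two passes.**  Pass 1 runs on a coarse grid (symmetric farthest-point
decimation, default 15% of sources) where sources are far enough apart to
be treated as uncorrelated.  Pass 2 initializes at the single
high-resolution source nearest the pass-1 center of mass and iterates:

1. fit `(gamma, sigma_s)` by least squares on the `phi` electrodes whose
   modeled power is least reduced by the current silence estimate
   (power-ratio selection); for fixed `gamma` the optimal `sigma_s^2` is
   closed-form, leaving a 1-D problem in `log gamma` that is bracketed by
   a coarse grid scan (the cost flattens once the modeled covariance is
   effectively diagonal, so a bare line search can stall on the plateau)
   and then refined by bounded minimization;
2. recompute `beta_high` (mirror-ratioed in baseline mode) and re-solve
   CSpeC with per-electrode power constraints
   `(c_i^T g + sigma_z_i^2 - Var(y_i))^2 <= zeta_i` on those electrodes,
   where `zeta_i` is the squared residual of the fitted silence-free model;
3. stop when the patch center of mass moves less than `delta` (default:
   one grid spacing) over two consecutive iterations, or after R = 10
   iterations.

The candidate reference electrode (ten 10-5 midline labels) with the
smallest normalized scalp power mismatch wins.

**zeta flooring.**  When the covariance fit is nearly exact, the raw
residual `zeta_i` can fall below the sampling noise of `Var-hat(y_i)`
itself, demanding a power match tighter than the data supports and making
the program infeasible for k > 0.  The pipeline floors `sqrt(zeta_i)` at
`sqrt(2/T) * Var-hat(y_i)`, the relative standard error of a length-T
variance estimate.

## The QP solver

The clustering program is a convex QP: box constraints, one l1-budget row,
and (in pass 2) a few two-sided linear power rows (each scalar quadratic
constraint splits into a linear pair).  It is solved by a dense primal-dual
interior-point method (Mehrotra predictor-corrector) written for this
package: the Newton system condenses to a p x p Cholesky, and the
`[I; 1^T; C]` constraint structure is exploited so assembly is
`O(p * phi)` per iteration.  Near-equality rows (interval width below
5e-5 of the equilibrated row scale) are widened to that floor — far below
the statistical noise of the quantities behind such constraints —
otherwise the side multipliers diverge.  Convergence tolerance is 1e-7 on
relative residuals, typically reached in 15-35 iterations; the returned
`g` is polished by exact projection onto the box and budget constraints,
so those hold to machine precision.  Tests validate the solver against
scipy's `trust-constr` on identical programs and against exhaustive
contiguous-subset enumeration on small graphs.

## Synthetic study framework

The generator emulates the study conditions without any imaging data:

* **Cortex**: a mirror-symmetric spherical cap (radius 79 mm inside a
  92 mm scalp sphere), quasi-uniform Fibonacci placement; points in the
  right half are reflected to make pairing exact.  An optional midline
  strip of configurable width has no mirror partners.  The cap covers the
  same solid angle as the electrode montage so every source is observable.
* **Montage**: ten midline electrodes with standard 10-5 labels
  (Fpz ... Iz) serving as reference candidates, plus exactly mirrored
  lateral pairs spread evenly over the scalp cap.
* **Lead field**: the exact closed form for a radial current dipole in a
  homogeneous conducting sphere with insulating boundary,
  `V = m/(4 pi sigma R^2) [2 (cos a - f)/g^3 + (1/g - 1)/f]`.
  Conductivity is a pure global scale and cancels from every ratio the
  method uses; it is retained as a knob for robustness experiments.
* **Sources**: `gamma = 0.12 mm^-2`, `sigma_s = 1 a.u.`, patches drawn as
  a seed source plus its k-1 same-hemisphere nearest neighbors.
* **Noise**: spatially white at the n raw electrodes; per-electrode
  variances uniform on `[0, sigma_z_max]` with `sigma_z_max` calibrated so
  the silence-free average scalp SNR hits the 9 dB operating point.  (The
  SNR definition divides channel power by `sigma_z_max`; only the
  power/power reading is dimensionally consistent, so `sigma_z_max` is
  interpreted as the maximum noise *variance*.)  Noise is simulated before
  referencing so that all candidate references see a coherent instance;
  the algorithm uses the exact differential noise covariance `M C_z M^T`.
* **Temporal shaping**: an optional linear-phase FIR with 1/f magnitude
  (order 128, frequency sampling) converts the flat temporal PSD into a
  brain-like one.  Shaping rescales the zero-lag spatial covariance by
  `rho_h(0)` and leaves its shape intact, which is why localization is
  insensitive to the temporal PSD; the filter is a generic stand-in for a
  PSD profile extracted from intracranial recordings.

What the generator does **not** emulate: realistic skull/CSF layering and
its spatial filtering, cortical folding and tangential dipole components,
artifacts (ocular, muscular, cardiac), non-stationary background activity,
and structural hemispheric asymmetry.  Passing tests therefore demonstrate
the algorithm's statistical machinery under its stated assumptions, not
clinical performance on real recordings.

## Modified comparators

MNE (`S-hat = A~^T (A~ A~^T + lambda I)^-1 Y`, L-curve lambda), sLORETA
(minimum-norm power standardized by the resolution-matrix diagonal, fixed
reference), and MUSIC (noise-subspace score
`||P-perp a~_q||^2 / ||a~_q||^2`, signal subspace at 95% energy) are each
adapted to silence localization by the same tail: rank sources per time
point, accumulate a normalized membership histogram, estimate the silence
size at the knee of the sorted curve (`argmin of score^2 + (rank/p)^2`),
and return the k-hat nearest neighbors of the center of mass of the
top-2k-hat sources.  MUSIC's score is static, so the histogram step
collapses to the score itself.

## Problem sizes and defaults

| parameter | default | note |
| --- | --- | --- |
| high-res sources p | 500 (benchmark) | grid spacing ~9 mm |
| low-res fraction | 0.15 | symmetric farthest-point decimation |
| electrodes n | 64 (benchmark) | 10 midline + 27 mirrored pairs |
| patch size k | 20 (benchmark) | drawn per seed |
| samples T | 100 000 (library default); 20 000 in the benchmark | variance SE ~ sqrt(2/T) |
| SNR_avg | 9 dB | calibration target |
| gamma, sigma_s | 0.12 mm^-2, 1 a.u. | source covariance |
| lambda grid | 16 points, 1e-4..1e2 x (beta/Laplacian scale); 6 in the benchmark | log-spaced |
| k grid | 8 points, geometric on [2, p/4] | includes realistic sizes |
| phi | ceil((n-1)/4) | electrodes for the covariance fit |
| R, delta | 10 iterations, one grid spacing; R = 5 in the benchmark | convergence |
| references | 10 midline candidates; Cz alone in the benchmark | power-mismatch selection |

The benchmark reductions (T, grids, single reference, 20 regions) keep a
full comparison to the three comparators at desk scale; on symmetric
synthetic instances the power mismatch varies little across midline
references, so the single-reference benchmark measures the same thing the
full search would.

## Numerical choices

* k smallest entries of `g`, k-NN lists, and electrode selections break
  ties by lowest index — determinism everywhere.
* Negative contribution numerators (noise over-subtraction) clip to 0;
  `beta_high` and the mirrored ratio clip into `[0, 1]`.
* The graph kernel scale `theta^2` is the spread of all pairwise
  inter-source distances with `1/(N-1)` normalization of both moments,
  computed exactly up to p = 3000 and by seeded pair subsampling above.
* Channel variances default to exact sample moments (the simulated data
  are white); a Welch estimator (2 s Hann segments, 50% overlap,
  integrated over 1-100 Hz) is available for band-limited real data,
  where out-of-band noise should not count toward signal power.
* The sample-covariance identity `Var(mu_q) = a~_q^T C-hat_y a~_q` avoids
  forming the p x T projection matrix.
* Cholesky of the active-source covariance uses a tiny jitter ladder
  (up to 1e-6 of the mean diagonal) for numerically semidefinite cases.

## Known limitations

Single region only (no multi-region clustering); stationary silences;
unilateral patches (bilateral silence breaks the hemispheric baseline);
silences touching the midline dim their own mirror partners and weaken
the ratio — the configurable midline strip exists for exactly that band;
size estimation by power matching carries ~20-30% relative error at
benchmark scale; the homogeneous-sphere forward model understates the
skull's spatial low-pass effect relative to layered head models.
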