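# Methods

## Model

The tracker estimates dense sub-sample displacement between two beamformed
RF frames `I1, I2` (shape `m × n`; axis 0 axial/depth, axis 1 lateral) by
minimising a regularized energy in the incremental fields `(Δa, Δl)`
around a running estimate `(a, l)`:

* **Data fidelity.** Squared residual `I1(i,j) − I2(i+a+Δa, j+l+Δl)`.
  `I2` is evaluated by bicubic-spline interpolation; its axial/lateral
  gradients at the warped coordinates come from the spline derivatives.
  The residual is linearised in `(Δa, Δl)` by a first-order Taylor
  expansion. Pixels warped outside the frame are masked out of the data
  term (regularizers stay active there).
* **Adaptive first-order continuity.** Backward differences of the total
  displacement are pulled toward locally expected strain offsets
  `ε` — moving-window means (default 21×21, `mode="nearest"`) of the
  initial field's derivatives — rather than toward zero, so uniform
  compression is not penalised. Weights `wf·{α1s, α2s}` act on the axial
  field's axial/lateral derivatives, `wf·{β1s, β2s}` on the lateral
  field's.
* **Second-order continuity.** Unmixed three-point curvature stencils
  (weights `ws·{α1s, α2s, β1s, β2s}`) plus the mixed cross-derivative
  stencil `f(i,j) − f(i,j−1) − f(i−1,j) + f(i−1,j−1)` (weights
  `ws·αmix`, `ws·βmix`). The unmixed terms regularize axial/lateral strain
  along their own direction and the shears orthogonally; the mixed terms
  supply the missing directions, completing the second-order scheme.
  Zeroing the mixed weights reproduces the unmixed baseline bit-exactly
  (the assembly skips zero-weight terms entirely).
* **Mechanical consistency.** `∂x l + ν(i,j)·∂y a` with the pixelwise
  effective Poisson's ratio `ν`, weight `α3s`. `ν` starts at a nominal
  value (default 0.49, near-incompressible soft tissue) and is
  re-estimated each iteration as `−(∂x l)/(∂y a)` (3-sample least-squares
  slopes, sample units — the ratio is spacing-independent) wherever
  `|∂y a| ≥ 1e−4`, then 3×3 median-smoothed and clamped to `[0, 0.5]`.

Every L1 factor is smoothed to `φ(x) = sqrt(x² + δ²)` with `δ = 1e−4` in
strain-like units — small against typical strains (0.5–8% compression)
but large enough to keep the IRLS weights `λ/(2φ)` finite.

## Optimisation

Iteratively reweighted least squares: each outer iteration freezes the
Taylor linearisation and the IRLS weights at the current state and solves
the exact normal equations of the resulting quadratic. Unknowns are
interleaved `(Δa, Δl)` per pixel, column-major over the grid, which makes
the data block symmetric tridiagonal; the full matrix (order `2mn`) is
symmetric positive definite for positive weights and is factorised by
sparse LU (SuperLU/COLAMD; the solution's relative residual is checked
against 1e−8). A near-zero right-hand side short-circuits to the zero
increment.

Two safeguards that the energy formulation itself does not provide:

* **Backtracking step control.** Gauss–Newton relinearisation does not
  guarantee descent of the true smoothed cost, so the increment is halved
  (up to 10 times) until the re-warped objective does not increase. If no
  step helps, iteration stops.
* **Guarded Poisson update.** Updating `ν` changes the objective; the new
  map is kept only when it does not increase the cost at the current
  state. Together the two make the logged cost trace non-increasing by
  construction.

Iteration ends after `n_outer_iters` (default 10) or when the sup-norm of
the applied increment drops below `conv_tol` (default 1e−3 samples). A
divergence guard aborts if the cost rises by >10% in two consecutive
iterations (unreachable with the safeguards, kept as a hard invariant).
The adaptive `ε` maps are computed once, from the integer seed.

Frames are normalised by the RMS of `I1` before tracking: the preset
weights are absolute numbers while the data term scales with squared RF
amplitude, and RF units are arbitrary across scanners and simulators.

### Integer seeding

Gross integer lags come from per-column dynamic programming over the 2-D
(axial × lateral) lag lattice. The per-sample data cost is a hybrid: the
mean squared RF difference over a short axial window (`support`, default
9 samples) plus `envelope_weight` (default 2) times the same measure on
the axial-envelope images. A pointwise RF cost is carrier-phase
ambiguous — a lag error of one period (~fs/f0 samples) realigns the
cosine almost perfectly, and for some speckle realisations the exact DP
optimum locks long depth ranges one cycle off; the envelope term is
cycle-unambiguous and removes that failure mode while the RF term keeps
sample-level precision. Frames and envelopes are RMS-normalised;
out-of-bounds lags are priced prohibitively. Consecutive samples pay an
L1 lag-jump penalty (`smoothness_weight`, default 0.5) between their lag
pairs. The centre column is solved first;
remaining columns propagate outward with an extra L1 anchor to the
neighbouring solved column. The min-convolution with the L1 penalty uses
forward/backward cumulative-minimum passes (O(states) per sample); final
ties prefer the smaller-magnitude lag, axial before lateral. Each column
is an exact optimum of its own objective — tested against constant-lag
paths and an exhaustive per-pixel search.

### Parameters

| name | default (simulated preset) | role |
| --- | --- | --- |
| `wf`, `ws` | 0.001, 0.025 | global first-/second-order strengths |
| `alpha1s`, `alpha2s` | 150, 0.2 | axial-field continuity weights |
| `alpha3s` | 0.045 | mechanical-consistency weight |
| `alpha_mix` | 56.25 | mixed weight, axial field |
| `beta1s`, `beta2s`, `beta_mix` | 2α1s/3, α2s/4, αmix/2 | lateral-field analogues (fixed ratios) |
| `l1_delta` | 1e−4 | smoothed-|·| constant (strain units) |
| `n_outer_iters`, `conv_tol` | 10, 1e−3 samples | iteration control |
| `nu_nominal`, `nu_bounds` | 0.49, (0, 0.5) | Poisson initialisation/clamp |
| `eps_window` | 21 samples | adaptive-offset averaging window |

Presets `simulated`, `phantom` and `in_vivo` carry cross-validated weight
sets for the three acquisition classes; softer tissue and noisier data use
weaker continuity (`in_vivo`: α1s=20, αmix=7.5).

## Synthetic phantoms

The generator emulates fully developed speckle: uniformly random point
scatterers with standard-normal amplitudes (default 100/mm², ≥10 per
resolution cell for the default PSF — below that the field is flagged),
deformed in closed form and imaged by a separable convolution PSF
(Gaussian-windowed cosine axially — 7.27 MHz centre, 60% fractional
bandwidth; Gaussian laterally — 0.8 mm FWHM chosen as a realistic
focused-beam width) on a 40 MHz / 0.21 mm grid. White Gaussian RF noise
can be added at a prescribed SNR (the realised PSNR is logged for
information). The scatterer cloud is padded by 3 axial σ beyond the imaged
grid so deformation does not advect a void into view.

Deformation modes: `uniform_compression` (axial `a(y) = −s·y` from the
compressed surface, lateral `l(x) = ν·s·(x − x₀)` about the lateral
centre — the homogeneous-medium closed form, with exact constant
ground-truth strains `(−s, νs, 0, 0)`), `rigid_shift`, and
`parametric_inclusion` (a smooth radial blend of two strain levels around
a disk; qualitative only, no finite-element accuracy).

What a green synthetic test does **not** establish: performance under
depth-dependent attenuation and focusing, beamforming artefacts,
physically consistent inclusion mechanics (stress concentration, slip
boundaries), elevational decorrelation, or probe-pressure nonuniformity.
The generator's role is controlled ground truth, not acoustic realism.

## Strain estimation

Displacements are converted to millimetres, then differentiated with a
per-pixel least-squares line fit over a 3-sample window (the smallest
kernel — larger windows smooth the strain in a non-data-driven way; they
are supported via `kernel=`). For kernel 3 the estimator reduces to the
central difference; borders reuse the nearest full window. No outlier
masking is applied before differentiation.

## Evaluation metrics

MAE is the mean absolute difference to a ground-truth strain map. MSSIM
uses the standard structural-similarity defaults (11×11 Gaussian window,
σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range = truth max − min; computed
through scikit-image). Elastographic SNR = |mean|/std of a background ROI
(the magnitude guards compressive, negative-mean strain — the convention
choice is recorded here); CNR = `sqrt(2(s̄b − s̄t)²/(σb² + σt²))`. The
multi-ROI sweep evaluates SNR per background ROI and CNR per
(target, background) pair — the standard protocol is 30 3×3 mm
backgrounds and 4 targets, i.e. 30 SNR and 120 CNR values — and reports
mean ± std. ROIs are specified in mm and rounded to whole samples toward
the inside. Shear-strain CNR is not computed (target/background shear
contrast is not physically meaningful in quasi-static compression).

## Numerical choices and limitations

* Speed of sound defaults to 1540 m/s for the axial-spacing conversion
  (configurable); the B-mode display clips at the requested dynamic range
  (50 dB typical).
* The solver is single-CPU sparse LU; no ADMM/exact-L1 optimisation and
  no GPU path. Runtime is dominated by the factorisation
  (~tens of seconds at 1200×128 per iteration).
* The DP seed is computed once; it is not refreshed between outer
  iterations.
* Sign convention: compression from the top gives negative axial strain
  internally; the CLI offers `--signed-strain/--no-signed-strain` for
  display.
* With zero regularization the normal matrix is singular (per-pixel
  rank-1 data blocks); the solver refuses such systems unless the
  right-hand side is numerically zero.
* The homogeneous closed-form deformation ignores the stiffness contrast
  of inclusions; quantitative inclusion benchmarks would require
  finite-element fields, which are out of scope.
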