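# Methods

## Forward model

**Geometry.** The image lives on the square `[-1, 1]^2` circumscribing the
unit disc; `Ns` sensors sit at uniform angles on the unit circle and record
at `Nt` uniform times in `[0, 2]` (unit sound speed; 2 is the disc
diameter).  Pixel centers form the symmetric lattice
`c(i) = ((2 i1 - N - 1)/N, (2 i2 - N - 1)/N)`, spacing `2/N`, flattened as
`N (i1 - 1) + i2`.  The no-data region is the diagonal stripe
`I = {r : |r . u| < w/2}` with `u = (1, -1)/sqrt(2)` (configurable to the
anti-diagonal), default width `w = 0.34`.  The stripe is not clipped to the
disc: only pixel centers matter.

**Kaiser–Bessel atoms.** The initial pressure is a sum of translates of the
radial profile
`psi(rho) = (1 - rho^2/R^2)^{m/2} I_m(gamma sqrt(1 - rho^2/R^2)) / I_m(gamma)`
supported on `rho <= R`.  Defaults `m = 2`, `gamma = 3`, `R = 2 * spacing`:
standard tomographic choices giving a smooth, essentially band-limited atom
two pixels wide; all three are configurable and no test depends on the
defaults.

**Atom traces.** Each matrix entry is the 3D free-space wave solution of a
radial initial pressure, evaluated via the Poisson–Kirchhoff formula
specialized to radial profiles:
`p(d, t) = (1/(2d)) [g(d+t) - sign(t-d) g(|d-t|)]` with `g(rho) = rho
psi(rho)`.  This closed form is exact; the test suite checks it against an
independent spherical-mean quadrature plus central time differencing to
max relative error `1e-4` over `(d, t) in [0.2, 2] x [0, 2]`.  Sensors lie
on the unit circle and atoms strictly inside, so `d > 0` always; `d < 1e-9`
is rejected rather than handling the removable singularity.

**Truncated SVD.** The masked matrix `W diag(mask)` gets a dense SVD;
singular values `<= sigma_star` are dropped (default `1e-3` relative to the
largest — masking creates a near-null space that would otherwise dominate
`A^+`).  The operator object stores the retained factors; the forward map,
pseudoinverse, Gram matrix and the solver's implicit step are all spectral,
so the expensive factorization happens exactly once.  Dense assembly is
refused above `N = 192` per axis unless the cap is raised explicitly.

## Phantoms

Square-ring phantoms: a square annulus (outer side drawn from
`[0.35, 0.7]`, thickness from `[0.06, 0.14]`) at a uniform random center
chosen so the ring always fits strictly inside the unit disc, with
intensity `base + amplitude * (low-order polynomial in the centered
coordinates)` clipped to `[0, 1]`, `base ~ U[0.4, 1]`, amplitude 0.3.  The
polynomial modulation realizes "random smooth profile" without inventing a
sharper law; ranges are configurable.  Rings per image defaults to 1
(configurable to 3).  The out-of-distribution phantom is a fixed set of
four filled discs.

Training pairs couple each clean phantom with `h_a = A^+(A x_a + eta_a)`,
`eta_a` i.i.d. Gaussian with standard deviation `sigma ||A x_a||_inf`,
`sigma = 0.01` by default.  Per-item seeds derive from one master seed via
`numpy.random.SeedSequence`, so corpora regenerate bit-identically; the
held-out test set uses a disjoint fixed seed stream.

What the generator does **not** emulate: anatomical structure, detector
impulse response / band-limiting, acoustic heterogeneity, and 3D effects.
Passing tests show the method behaves as designed on this controlled family,
not that it meets clinical image quality.

## Regularizer

`R(x) = ||x - Phi(x)||_2^2 + beta ||grad x||_{1,eps}` with
`||grad x||_{1,eps} = sum sqrt((D1 x)^2 + (D2 x)^2 + eps^2)` (forward
differences, replicate boundary, so constant images give exactly
`N^2 eps`).  `beta = 15` throughout the study.

`Phi` is a residual U-Net: per scale two 3x3 conv+ReLU blocks, 2x2 average
pooling down / nearest-neighbour upsampling up, concatenating skips, base
32 channels doubled per scale (the study uses 16 to keep the CPU budget
modest), and a final 1x1 convolution added to the input.  The network,
backpropagation (to parameters *and* to the input — the vector-Jacobian
product needed for `grad R`) and the Adam optimizer are implemented in
NumPy inside the package; gradient exactness is enforced by
finite-difference tests at relative `1e-5`.

Training minimizes `sum_a ||Phi(h_a) - x_a||_1 + gamma ||Phi(x_a) - x_a||_1`
(`gamma = 0.1`, Adam, learning rate `0.01`) over minibatches (batch 8); the
parameters of the best epoch are kept.  Average pooling (rather than max)
keeps `Phi` piecewise smooth except for the ReLUs, which matters because
`grad R` feeds a gradient-based solver.

## Solver

Forward-backward iteration

    x_{k+1} = (s A^T A + I)^{-1} (s A^T y + x_k - s alpha grad R(x_k)),

`s = 0.25`, `Niter = 15`, `alpha in {0.015, 0.016, 0.02}` for noise levels
`{0, 0.01, 0.1}`.  The implicit step is the spectral closed form
`z + V [1/(s sigma_i^2 + 1) - 1] V^T z`; a dense-factorization path exists
and is tested to agree to `1e-10`.  Initialization `x0 = Phi(A^+ y)`
(matching the inputs `Phi` was trained on); `Phi(A^T y)`, `A^+ y` and `0`
are selectable.  On null-space components the data term is inert, so
inpainting of the masked stripe comes from `x0` and the regularizer
gradient.

**TV smoothing at solve time.** The smoothed-TV Hessian is bounded by
`8/eps`, so the explicit step is non-expansive only if
`s * alpha * beta * 8/eps <= 2`.  With the study's `s, alpha, beta` and a
tiny `eps` (the regularizer default is `1e-3`, fine for value/gradient
evaluation) the TV flow oscillates and the objective trace rises.  The
study harness therefore raises `eps` to `8 s alpha beta` (the bound with a
factor-2 margin, about `0.5` at `alpha = 0.016`) before solving; with that
choice every recorded objective trace in the study is monotone.  This makes
the TV term Huber-like: quadratic for gradients below `eps`, linear above.

**Degenerate inputs.** `Niter = 0` returns the initialization; non-finite
iterates or training losses raise immediately with the iteration/epoch
named; zero data maps to zero through every linear path.

## Convergence-rate experiment

Toy operator: diagonal with geometric spectrum `0.5^i`, 12 modes
(optionally truncated to the first `n_keep`, creating a genuine null
space).  Quadratic regularizer `R(x) = ||x||^2`; the true solution
`x+ = A^T eta / 2` satisfies the source condition `R'(x+) = A^T eta`
exactly.  For each noise norm `eps` in a decreasing schedule (default
`1e-1` to `1e-4`, 7 points) and each of 20 replications, noise of exact
norm `eps` is added, `alpha = eps`, and the minimizer is computed in closed
form — so measured Bregman distances `B = ||x_alpha - x+||^2` carry no
iterative-solver error.  The theory's noise level is the squared-norm
discrepancy `delta = eps^2`; with `alpha ∝ eps` the expected decay is
`B = O(eps)`, i.e. log-log slope 1, and a schedule checker rejects
parameter choices with `alpha` or `(delta + discrepancy)/alpha` not
tending to 0.  Adding a null-space component to `x+` (source condition
violated) flattens the measured slope — the experiment measures the
exponent rather than assuming it.

The Bregman distance for the *learned* (non-convex) regularizer is
available through the same function but is diagnostic only; slope
assertions use the quadratic case, where the distance is exact.

## Study scale and runtime choices

The end-to-end study runs at `N = 64`, `Ns = 75`, `Nt = 64`, 200 training
pairs, a depth-1 / 16-channel network, 5 epochs, three independent seeds —
about a quarter of the full-scale design in every dimension, sized so the
whole study (operator SVD included) completes in minutes on one CPU.  The
operator is deterministic and shared across seeds.  Training uses float32;
all operator and solver algebra is float64.

## Known limitations

* Dense-matrix pipeline only; no matrix-free operators, so memory grows as
  `N^4`-ish and full 3D is out of reach by design.
* The small study-scale network is a weak denoiser: one-shot post-processing
  hallucinates little, so NETT's data-consistency advantage on
  out-of-distribution structure shows up clearly only at noise levels at or
  above the training level (and in aggregate over noise levels), whereas a
  deeper network at full scale separates the methods more sharply.
* ReLU makes `R` only piecewise differentiable; finite-difference gradient
  checks avoid measure-zero kinks but a probe landing exactly on one would
  disagree.
* No detector impulse response, band-limiting or attenuation in the wave
  model.
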