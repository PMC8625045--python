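# nettpat

Learned (NETT) regularization for a masked limited-data problem in 2D
photoacoustic tomography (PAT).

## The problem

In PAT a short laser pulse deposits an initial acoustic pressure `f` inside
tissue; the outgoing wave is recorded by sensors on a circle around the
object, and the image-reconstruction task is to invert the wave propagation.
Here a diagonal stripe `I` through the object generates **no data at all**
(e.g. the pressure there is too weak to record), so the inverse problem is a
combination of wave inversion and inpainting: the operator has a large null
space and classical reconstructions leave a blank stripe plus artifacts.

## The method

The initial pressure is expanded in generalized **Kaiser–Bessel** atoms
`psi` on an `N x N` grid; each system-matrix entry is the analytic 3D wave
solution of one atom evaluated at a sensor and time ("pseudo-3D" modelling).
The masked matrix `W M_I` is stabilized by a **truncated SVD**
`A = U S* V^T`, giving an explicit pseudoinverse `A^+`.

Reconstruction minimizes the **NETT** (network Tikhonov) functional

    T(x) = 1/2 ||A x - y||^2 + alpha * R(x),
    R(x) = ||x - Phi(x)||^2 + beta * ||grad x||_{1,eps},

where `Phi` is a residual U-Net trained so that clean phantoms are near
fixed points while pseudoinverse reconstructions of noisy data are mapped
back toward the clean image, and the second term is a smoothed isotropic
total variation.  `T` is minimized by a forward-backward scheme: an explicit
gradient step on `alpha R` (exact backpropagation through `Phi`) followed by
an implicit step on the data term, realized once-and-for-all through the
operator's SVD factors.

Training corpus: square-shaped rings with random smooth intensity profile
and random location; pairs `(x_a, h_a = A^+(A x_a + eta_a))` with Gaussian
noise of standard deviation `sigma ||A x_a||_inf`.  Baselines: plain `A^+ y`
and one-shot post-processing `Phi(A^+ y)`.

A separate toy experiment verifies the convergence-rate theory: for a
quadratic regularizer whose true solution satisfies the source condition
`R'(x+) = A^T eta`, the (absolute) Bregman distance of the Tikhonov
minimizer to `x+` decays linearly in the noise norm when `alpha` is chosen
proportional to it (log-log slope 1).

## Worked example

```python
import numpy as np
from nettpat import *
from nettpat.phantoms import default_ood_circles, generate_dataset
from nettpat.experiments import build_study_operator, masked_pat_study

op, grid = build_study_operator(N=64, Ns=75, Nt=64)   # masked + truncated SVD
run = masked_pat_study(op, grid, seed=101)            # train + evaluate
print(run["report"].means.to_string(index=False))
```

prints (seed 101; your exact numbers are reproduced bit-for-bit with the
same seed):

```
  method  sigma  mean_mse
 nett:R1   0.00  0.007527
 nett:R1   0.01  0.007663
 nett:R1   0.10  0.015793
    pinv   0.00  0.003562
    pinv   0.01  0.065578
    pinv   0.10  6.002556
postproc   0.00  0.003456
postproc   0.01  0.004804
postproc   0.10  0.126775
```

Reading: the pseudoinverse is exact-data optimal but collapses as noise
grows (MSE 6.0 at sigma=0.1); post-processing denoises well at the training
noise but breaks at 10x that noise (0.127); NETT stays within a factor ~2
of its matched-noise error even there (0.016) because every iterate is
pulled back to the measured data.  `run["ood"]` holds the same comparison
on the out-of-distribution circles phantom, where NETT's advantage over
post-processing at high noise is again about an order of magnitude
(0.047 vs 0.121 at sigma=0.1).

The same objects drive the CLI (`nett-pat build-forward / simulate / train /
reconstruct / study / rates`), all YAML-configured and bit-reproducible for
a fixed seed.

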