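# diffusefit

Estimation of the absorption coefficient `mu_a` and the reduced scattering
coefficient `mu_s'` of highly diffuse materials (milk, white paint
dilutions, paper stacks) from a **single spatially resolved
diffuse-reflectance profile** — the re-emitted intensity measured by a
linear detector array at increasing distance from a point-like light entry
spot.

## The model and the inverse problem

The forward model is the steady-state diffusion dipole for a semi-infinite
turbid medium:

```
Rd(r) = alpha/(4 pi mu_t) [ (mu_eff + 1/r1) e^{-mu_eff r1} / r1^2
                            + C (mu_eff + 1/r2) e^{-mu_eff r2} / r2^2 ]
```

with `mu_t = mu_a + mu_s'`, `alpha = mu_s'/mu_t`,
`mu_eff = sqrt(3 mu_a mu_t)`, dipole distances
`r1 = sqrt(r^2 + (1/mu_t)^2)`, `r2 = sqrt(r^2 + (C/mu_t)^2)` and boundary
constant `C = 1 + 4A/3`, where `A = (1 + Fd)/(1 - Fd)` and `Fd` is the
diffuse Fresnel reflectance of the interface (a polynomial in the relative
refractive index `eta`). All lengths are in mm, coefficients in mm^-1.

Fitting both unknowns jointly to one normalized profile is ill-posed: the
sum-of-squares cost has near-straight degenerate valleys in the
`(mu_a, mu_s')` plane (see `cost_surface`). The profile is therefore split
at the peak of `f(r) = r^2 R(r)`: the near-source segment constrains
`mu_t`, the far-source decay constrains `mu_eff`. Bounded trust-region
least-squares fits alternate between the segments, and the coefficients
follow exactly from

```
mu_a = mu_eff^2 / (3 mu_t),      mu_s' = mu_t - mu_a
```

The package also provides the acquisition simulator (512-element array,
25 um pitch, multiplicative detector noise), validation statistics
(regression of estimates against fat content or pigment concentration,
95 % confidence intervals), the anisotropy conversion
`mu_s = mu_s'/(1 - g)`, and CIE / ASTM E313 whiteness indices.

## Worked example

Simulate ten noisy acquisitions of a whole-milk-like sample and invert the
averaged record:

```python
import numpy as np
from diffusefit import (OpticalProperties, NoiseModel, simulate_record_set,
                        invert_record_set, ci95_halfwidth, fit_two_segment)

truth = OpticalProperties(mu_a=5.3e-3, mu_s_prime=1.05, eta=1.347)
records = simulate_record_set(truth, noise=NoiseModel(relative_sigma=0.01, seed=0),
                              n_records=10)
result = invert_record_set(records, eta=1.347, variant="average-first")
per_rec = [fit_two_segment(r, eta=1.347).mu_s_prime_hat for r in records]
hw = ci95_halfwidth(np.std(per_rec, ddof=1), len(per_rec))
print(f"mu_a_hat       = {result.mu_a_hat:.4e} mm^-1  (truth 5.30e-03)")
print(f"mu_s_prime_hat = {result.mu_s_prime_hat:.4f} mm^-1    (truth 1.0500)")
print(f"R^2 of fit     = {result.r_squared_fit:.4f}")
print(f"CI95 half-width of per-record mu_s' = {hw:.4f} mm^-1")
```

prints

```
mu_a_hat       = 5.3068e-03 mm^-1  (truth 5.30e-03)
mu_s_prime_hat = 1.0496 mm^-1    (truth 1.0500)
R^2 of fit     = 1.0000
CI95 half-width of per-record mu_s' = 0.0015 mm^-1
```

i.e. at 1 % detector noise the reduced scattering coefficient comes back
to 0.04 % and the (much smaller, harder) absorption coefficient to 0.13 %,
with a tight confidence interval across repeated acquisitions.

The same estimator composes with scikit-learn:

```python
from diffusefit import TwoSegmentInversion
est = TwoSegmentInversion(eta=1.347).fit(records[0].distances,
                                         records[0].intensities)
est.mu_a_, est.mu_s_prime_, est.r_squared_
```

A command-line surface mirrors the library:

```sh
diffusefit simulate --mu-a 0.0053 --mu-s-prime 1.05 --noise-sigma 0.01 \
    --seed 0 --n-records 10 --out milk.csv
diffusefit invert milk.csv --eta 1.347
```

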