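# Methods

## Forward model

The diffuse reflectance of a semi-infinite, highly scattering medium under
a normally incident pencil beam is modelled with the steady-state
diffusion dipole: an isotropic point source at depth `1/mu_t` below the
surface plus a mirrored negative source above the extrapolated boundary.
The model depends on three physical parameters — the absorption
coefficient `mu_a` (mm^-1), the reduced scattering coefficient `mu_s'`
(mm^-1) and the relative refractive index `eta` — through the derived
quantities `mu_t = mu_a + mu_s'`, `mu_eff = sqrt(3 mu_a mu_t)`, the
reduced albedo `alpha = mu_s'/mu_t` and the boundary constant
`C = 1 + 4A/3` with `A = (1+Fd)/(1-Fd)`.

Assumptions: the medium is effectively semi-infinite (thick and wide
relative to the photon path), scattering dominates absorption
(`mu_s' >> mu_a`, the regime in which the diffusion approximation is
valid), and `eta` is constant over the channel bandwidth.

The diffuse Fresnel reflectance `Fd(eta)` is a polynomial approximation
with separate branches for `eta < 1` and `eta > 1`. The two branches
disagree at `eta = 1`, so `eta = 1` raises an error rather than silently
picking a branch (physically the interface is index-matched there and the
boundary term should be rederived, not interpolated).

The model is finite at `r = 0` (the dipole distances tend to `1/mu_t` and
`C/mu_t`), but the default simulated grid starts at a positive offset so
the specular entry region is never sampled.

### Asymptotic regimes

Peak-normalizing a measured profile discards the amplitude prefactor
`alpha/(4 pi mu_t)`; all information lives in the shape. Two limits of
the shape motivate the inversion design:

* near the source the shape level is set by `mu_t` (the diagnostic
  constant `mu_t/3 (1 + 1/C^2)` is implemented as `asymptote_near`; it is
  exposed for inspection only and never used in fitting, since its
  derivation involves intermediate approximations that are not needed by
  the algorithm);
* far from the source the shape collapses to
  `(1+C)(mu_eff + 1/r) e^{-mu_eff r}/r^2`, an exponential decay governed
  by `mu_eff` alone. The leading relative error of this approximation is
  `mu_eff C^2/(2 mu_t^2 r)`; it vanishes as `mu_t r -> infinity` but
  slowly when `mu_eff/mu_t` is not small, which is why the default
  inversion fits the full dipole bracket on the far segment rather than
  the asymptote (an `asymptotic` mode is available behind
  `segment_model="asymptotic"` and is measurably biased — order 5 % on
  `mu_s'` in self-tests).

## Inversion

A joint two-parameter fit to one normalized shape is ill-posed: the SSR
surface over `(mu_a, mu_s')` shows near-straight degenerate valleys
(`cost_surface` reproduces this). The two-segment scheme converts the two
asymptotic sensitivities into two well-posed one-parameter fits:

1. **Normalization.** Peak (max) normalization of the intensities; the
   grid is untouched. Negative intensities (possible after dark
   subtraction) are clipped to zero and excluded from the fit, with the
   count logged.
2. **Split.** `f(r) = r^2 R(r)` is smoothed with a centered moving
   average (default window 11 samples, odd, truncated at the edges) and
   the split is placed at the first positive-to-negative sign change of
   its gradient; if no interior peak exists the global argmax of the
   smoothed curve is used. The index is clamped so each segment keeps at
   least `min_points = 10` samples (a warning is logged when clamping
   fires).
3. **Alternating segment fits.** Far segment: bounded trust-region
   least squares over `(scale_far, mu_eff)` with `mu_t` fixed. Near
   segment: over `(scale_near, mu_t)` with `mu_eff` fixed. Each segment
   fits the full dipole bracket with its own free amplitude. Rounds
   alternate until both parameters change by less than `1e-6` relative,
   or 50 rounds (then `converged_` is False and a warning is raised).
4. **Recovery.** `mu_a = mu_eff^2/(3 mu_t)` and `mu_s' = mu_t - mu_a`,
   so the closure `mu_a + mu_s' = mu_t` holds exactly by construction.

### Numerical choices

* **Log residuals.** Segment residuals are taken on log intensities. The
  profile spans orders of magnitude across the array; linear residuals
  are dominated by the few brightest detectors next to the split, which
  carry almost no `mu_eff` information, and the alternation can then
  stall in a `mu_eff = 0` local minimum for low-absorption media. Log
  residuals weight the decay rate evenly and converge to machine
  precision on model-generated data for every parameter set tested.
* **Bounds.** `mu_eff` in `[0, sqrt(3) mu_t]` (upper bound = the physical
  `alpha >= 0` constraint; a warning is raised when the fit sits on it)
  and `mu_t >= mu_eff/sqrt(3)` on the near segment, which keeps
  `mu_a, mu_s' >= 0` through the recovery identities. The lower bound 0
  on `mu_eff` admits the zero-absorption limit.
* **Initialization.** Deterministic: `mu_t0 = 1.0` mm^-1,
  `mu_eff0 = 0.1` mm^-1, mid-range for highly diffuse materials
  (`mu_s'` of order 0.4–3.5 mm^-1, `mu_a` of order 1e-3–1e-1 mm^-1). No
  random restarts; the same input always returns the same estimate.
* **Solver.** `scipy.optimize.least_squares(method="trf")` with
  ftol = xtol = 1e-10.
* **Ties.** Multiple gradient sign changes: the first is taken.

### Record sets

Repeated acquisitions of one sample can be combined two ways:
`average-first` (default; average the intensity records, invert once —
averaging suppresses detector noise before the nonlinear step) and
`invert-first` (invert every record, average the per-record estimates).
They coincide on noiseless or identical records; on 1 % noise they agree
on `mu_s'` to well under a percent in self-tests.

## Synthetic acquisition

The simulator emulates a translucency meter with a linear NMOS photodiode
array: 512 elements at 25 um pitch (12.8 mm span), first element 0.25 mm
from the light entry point. The offset is a design choice — the physical
position of the array relative to the entry spot is not published — and a
positive offset keeps the grid out of the specular entry region.

Noise is multiplicative Gaussian, `I_i = Rd(r_i)(1 + eps_i) + dark_floor`
with `eps_i ~ N(0, relative_sigma)`, default `relative_sigma = 0.01` and
`dark_floor = 0`. This is the simplest law consistent with a photodiode
array whose dark current is far below signal level; it does **not**
emulate shot-noise scaling, detector saturation/clipping, optical PSF or
crosstalk, LED spectral bandwidth, or temperature drift. Passing
recovery tests on these profiles therefore demonstrates correctness of
the algorithm under the stated noise law, not robustness to every real
instrument artifact.

Seeding is deterministic and documented: record `i` of a set with master
seed `s` uses seed `s + i`; entry `k` of a material series uses base seed
`s + 1009 k`.

Dilution series are generated from affine covariate-to-coefficient maps
per colour channel. The default milk maps are obtained by OLS on the
published per-channel mean coefficients of a pooled milk series (fat
contents 0.1–4 %), so simulated series inherit the measured linear
covariate dependence with realistic magnitudes.

## Validation statistics

Regression of per-sample mean estimates on the covariate uses OLS; the
p-value is the two-sided t-test on the slope with `n - 2` degrees of
freedom (equivalent to the F-test in simple regression — the standard
choice). Error bars for `N` repeated acquisitions use the normal
approximation `CI95 = 1.96 sigma/sqrt(N)`. The anisotropy conversion
`mu_s = mu_s'/(1 - g)` requires `g < 1`. Whiteness indices: CIE
`WI = Y + 800(xn - x) + 1700(yn - y)` with D50/2-degree neutral point
`(xn, yn) = (0.3457, 0.3585)` by default (overridable), and ASTM E313
(1998) `WI = 3.388 Z - 3 Y`.

## Known limitations and out-of-scope quantities

* Published absolute coefficient tables for milk, paper and paint cannot
  be re-derived here: the raw instrument signals are not deposited. They
  are used as generative ground truths (`diffusefit.datasets`) instead.
* Regressions recomputed from rounded published means reproduce the
  published R^2 for the robust reduced-scattering channels; p-values and
  the weakest absorption channels differ in the last digits because the
  original fits used unrounded per-acquisition estimates.
* The relative differences between the two record-averaging variants
  reported for the real milk data (−6.3 % on `mu_a`, −0.3 % on `mu_s'`)
  reflect real-sensor noise structure and cannot be reproduced from the
  synthetic noise law; the tests check only that the variants agree
  closely on simulated data.
* Time-resolved/frequency-domain variants, layered media, Monte Carlo
  transport, spectrally coupled multi-channel inversion, and anisotropic
  (e.g. paper-fibre) media are out of scope; for strongly anisotropic
  surfaces the semi-infinite isotropic dipole is the wrong model and the
  fit quality degrades accordingly.

## Problem sizes

Self-tests run the full pipeline at the native grid size (512 detectors);
the noiseless recovery sweep covers 25 `(mu_a, mu_s')` pairs per
refractive index (`eta` = 1.347 and 1.557), and noisy checks use 10
records at 1 % relative noise — the acquisition count used for the
published dilution series.
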