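"""Two-segment inversion of spatially resolved reflectance profiles.

A single reflectance shape does not pin down (mu_a, mu_s') directly: the
sum-of-squares cost over the (mu_a, mu_s') plane is degenerate along
near-straight valleys (see :func:`cost_surface`).  The profile does,
however, carry two separable pieces of information: close to the source
its level and curvature are governed by the extinction coefficient
mu_t = mu_a + mu_s', while far from the source the decay rate is set by
the effective attenuation coefficient mu_eff = sqrt(3 mu_a mu_t).

The inversion therefore

1. peak-normalizes the profile (amplitude carries no information here),
2. splits it at the peak of f(r) = r^2 R(r), located from the first
   positive-to-negative sign change of the smoothed gradient,
3. alternates bounded trust-region least-squares fits: the far segment
   fits (scale_far, mu_eff) with mu_t held fixed, the near segment fits
   (scale_near, mu_t) with mu_eff held fixed, each segment fitting the
   full dipole bracket with a free amplitude, until the parameters
   stabilise,
4. recovers the physical coefficients through the exact identities
   mu_a = mu_eff^2 / (3 mu_t) and mu_s' = mu_t - mu_a.

Residuals are taken on log intensities: the profile decays by orders of
magnitude across the detector array, and log residuals weight the decay
rate evenly along the segment instead of letting the few brightest
detectors dominate.

The estimator follows the scikit-learn protocol (``fit(r, intensity)``,
fitted attributes with trailing underscores, ``get_params`` /
``set_params``), so it composes with sklearn model-selection tooling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import (
    OpticalProperties,
    derive_coefficients,
    diffuse_fresnel_reflectance,
    dipole_bracket,
    internal_reflection_coefficient,
)
from .profile import ReflectanceProfile

logger = logging.getLogger(__name__)

__all__ = [
    "SplitResult",
    "InversionResult",
    "TwoSegmentInversion",
    "normalize_profile",
    "find_split",
    "fit_two_segment",
    "invert_record_set",
    "fit_r_squared",
    "cost_surface",
]


@dataclass(frozen=True)
class SplitResult:
    """Where a profile is divided into near and far segments.

    index          -- split position in the radial grid (start of the far
                      segment), clamped so both segments keep at least
                      ``min_points`` samples
    r_split        -- distance at the split, mm
    smoothed_curve -- the smoothed f(r) = r^2 R(r) used to locate the peak
    """

    index: int
    r_split: float
    smoothed_curve: NDArray[np.float64]


@dataclass(frozen=True)
class InversionResult:
    """Estimates and diagnostics of one two-segment inversion.

    All coefficients in mm^-1.  The identity
    ``mu_a_hat + mu_s_prime_hat == mu_t_hat`` holds exactly by
    construction (mu_s' is computed as mu_t - mu_a).
    """

    mu_t_hat: float
    mu_eff_hat: float
    mu_a_hat: float
    mu_s_prime_hat: float
    scale_near: float
    scale_far: float
    split_index: int
    r_squared_fit: float
    n_iterations: int
    converged: bool


def normalize_profile(profile: ReflectanceProfile) -> ReflectanceProfile:
    """Scale a profile to unit peak intensity; the grid is unchanged."""
    peak = float(np.max(profile.intensities))
    if peak <= 0:
        raise ValueError("cannot normalize a profile with no positive intensity")
    return profile.with_intensities(profile.intensities / peak)


def _moving_average(y: NDArray[np.float64], window: int) -> NDArray[np.float64]:
    """Centered moving average; the window is truncated at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sums / counts


def find_split(
    profile: ReflectanceProfile,
    smoothing_window: int = 11,
    min_points: int = 10,
) -> SplitResult:
    """Locate the near/far split at the peak of f(r) = r^2 R(r).

    The gradient of the smoothed f is scanned for its first positive to
    negative sign change; if f has no interior peak the global argmax of
    the smoothed curve is used instead.  The returned index is clamped so
    that both segments retain at least ``min_points`` samples.
    """
    n = len(profile)
    if n < 2 * min_points + 1:
        raise ValueError(
            f"profile has {n} samples; need at least {2 * min_points + 1} "
            f"to keep {min_points} per segment"
        )
    f = profile.distances**2 * profile.intensities
    smoothed = _moving_average(f, smoothing_window)
    grad = np.diff(smoothed)
    index = None
    sign_changes = np.flatnonzero((grad[:-1] > 0) & (grad[1:] <= 0))
    if sign_changes.size:
        index = int(sign_changes[0]) + 1
    else:
        index = int(np.argmax(smoothed))
    clamped = int(np.clip(index, min_points, n - min_points))
    if clamped != index:
        logger.warning(
            "split index %d clamped to %d to keep %d points per segment",
            index, clamped, min_points,
        )
    return SplitResult(
        index=clamped,
        r_split=float(profile.distances[clamped]),
        smoothed_curve=smoothed,
    )


class TwoSegmentInversion(BaseEstimator):
    """Recover (mu_a, mu_s') from one reflectance profile.

    Parameters
    ----------
    eta : float, default 1.347
        Relative refractive index of the medium (1.347 for milk,
        1.557 for white paper).
    segment_model : {"full", "asymptotic"}, default "full"
        "full" fits the complete dipole bracket on both segments with a
        free amplitude each; "asymptotic" fits the far-field limit
        (1+C)(mu_eff + 1/r) exp(-mu_eff r)/r^2 on the far segment
        instead.  "full" is exact on model-generated data and is the
        default.
    smoothing_window : int, default 11
        Odd moving-average window (samples) used when locating the split.
    min_points : int, default 10
        Minimum number of samples each segment must keep.
    mu_t0, mu_eff0 : float
        Deterministic initial values, mm^-1; mid-range for highly
        diffuse materials (mu_s' of order 1 mm^-1, mu_a of order
        1e-3..1e-1 mm^-1).  No random restarts.
    outer_tol : float, default 1e-6
        Relative parameter change at which the alternation stops.
    max_outer : int, default 50
        Maximum number of alternation rounds.
    solver_tol : float, default 1e-10
        ftol/xtol handed to the bounded trust-region solver.

    Attributes (after ``fit``)
    --------------------------
    mu_a_, mu_s_prime_, mu_t_, mu_eff_ : float
        Estimated coefficients, mm^-1.
    scale_near_, scale_far_ : float
        Free per-segment amplitudes of the normalized fit.
    split_index_ : int
        Index at which the profile was divided.
    r_squared_ : float
        Goodness of fit of the normalized model to the normalized data.
    n_iter_ : int
        Alternation rounds used.
    converged_ : bool
        Whether the alternation met ``outer_tol`` within ``max_outer``.
    result_ : InversionResult
        All of the above as one record.
    """

    def __init__(
        self,
        eta: float = 1.347,
        segment_model: Literal["full", "asymptotic"] = "full",
        smoothing_window: int = 11,
        min_points: int = 10,
        mu_t0: float = 1.0,
        mu_eff0: float = 0.1,
        outer_tol: float = 1e-6,
        max_outer: int = 50,
        solver_tol: float = 1e-10,
    ) -> None:
        self.eta = eta
        self.segment_model = segment_model
        self.smoothing_window = smoothing_window
        self.min_points = min_points
        self.mu_t0 = mu_t0
        self.mu_eff0 = mu_eff0
        self.outer_tol = outer_tol
        self.max_outer = max_outer
        self.solver_tol = solver_tol

    # -- internal pieces ------------------------------------------------

    def _c_coef(self) -> float:
        f_d = diffuse_fresnel_reflectance(self.eta)
        return 1.0 + 4.0 * internal_reflection_coefficient(f_d) / 3.0

    @staticmethod
    def _far_asymptote(r, mu_eff, c_coef):
        return (1.0 + c_coef) * (mu_eff + 1.0 / r) * np.exp(-mu_eff * r) / (r * r)

    def fit(self, r: ArrayLike, intensity: ArrayLike | None = None):
        """Fit the inversion to one profile.

        Parameters
        ----------
        r : array_like or ReflectanceProfile
            Radial distances, mm (or a profile object carrying both
            arrays, in which case ``intensity`` is ignored).
        intensity : array_like
            Detected intensities on the same grid, arbitrary units.
        """
        if isinstance(r, ReflectanceProfile):
            profile = r
        else:
            r = np.asarray(r, dtype=float).ravel()
            if intensity is None:
                raise ValueError("intensity is required when r is an array")
            profile = ReflectanceProfile(
                distances=r, intensities=np.asarray(intensity, dtype=float).ravel()
            )
        if self.segment_model not in ("full", "asymptotic"):
            raise ValueError(f"unknown segment_model {self.segment_model!r}")

        # clip negatives (e.g. after dark subtraction); zeros are excluded
        # from the log-residual fit below
        raw = profile.intensities
        n_clipped = int(np.sum(raw < 0))
        if n_clipped:
            logger.info("clipped %d negative intensities to 0", n_clipped)
            profile = profile.with_intensities(np.maximum(raw, 0.0))
        profile = normalize_profile(profile)

        split = find_split(profile, self.smoothing_window, self.min_points)
        c_coef = self._c_coef()
        dist, inten = profile.distances, profile.intensities
        positive = inten > 0
        if np.sum(positive) < 2 * self.min_points:
            raise ValueError("too few positive intensities to fit")
        log_i = np.log(inten, out=np.zeros_like(inten), where=positive)

        idx = split.index
        r_near, y_near = dist[:idx][positive[:idx]], log_i[:idx][positive[:idx]]
        r_far, y_far = dist[idx:][positive[idx:]], log_i[idx:][positive[idx:]]

        mu_t, mu_eff = float(self.mu_t0), float(self.mu_eff0)
        s_near = s_far = 1.0
        tiny = np.finfo(float).tiny
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_outer + 1):
            mu_t_prev, mu_eff_prev = mu_t, mu_eff

            if self.segment_model == "full":
                def far_res(p, _mt=mu_t):
                    return (
                        np.log(p[0]) + np.log(dipole_bracket(r_far, _mt, p[1], c_coef))
                        - y_far
                    )
            else:
                def far_res(p):
                    return (
                        np.log(p[0]) + np.log(self._far_asymptote(r_far, p[1], c_coef))
                        - y_far
                    )
            sol = least_squares(
                far_res,
                x0=[s_far, min(mu_eff, np.sqrt(3.0) * mu_t)],
                bounds=([tiny, 0.0], [np.inf, np.sqrt(3.0) * mu_t]),
                method="trf",
                ftol=self.solver_tol,
                xtol=self.solver_tol,
            )
            s_far, mu_eff = float(sol.x[0]), float(sol.x[1])

            def near_res(p, _me=mu_eff):
                return (
                    np.log(p[0]) + np.log(dipole_bracket(r_near, p[1], _me, c_coef))
                    - y_near
                )
            mu_t_floor = mu_eff / np.sqrt(3.0) + tiny
            sol = least_squares(
                near_res,
                x0=[s_near, max(mu_t, mu_t_floor)],
                bounds=([tiny, mu_t_floor], [np.inf, np.inf]),
                method="trf",
                ftol=self.solver_tol,
                xtol=self.solver_tol,
            )
            s_near, mu_t = float(sol.x[0]), float(sol.x[1])

            if (
                abs(mu_t - mu_t_prev) <= self.outer_tol * mu_t_prev
                and abs(mu_eff - mu_eff_prev)
                <= self.outer_tol * max(mu_eff_prev, 1e-12)
            ):
                converged = True
                break
        if not converged:
            warnings.warn(
                f"two-segment alternation did not converge in {self.max_outer} rounds",
                RuntimeWarning,
                stacklevel=2,
            )
        if mu_eff >= np.sqrt(3.0) * mu_t * (1.0 - 1e-12):
            warnings.warn(
                "mu_eff at its physical bound sqrt(3)*mu_t (alpha -> 0)",
                RuntimeWarning,
                stacklevel=2,
            )

        mu_a = mu_eff**2 / (3.0 * mu_t)
        mu_s_prime = mu_t - mu_a

        self.mu_t_ = mu_t
        self.mu_eff_ = mu_eff
        self.mu_a_ = mu_a
        self.mu_s_prime_ = mu_s_prime
        self.scale_near_ = s_near
        self.scale_far_ = s_far
        self.split_index_ = idx
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.r_squared_ = _shape_r_squared(dist, inten, mu_t, mu_eff, c_coef)
        self.result_ = InversionResult(
            mu_t_hat=mu_t,
            mu_eff_hat=mu_eff,
            mu_a_hat=mu_a,
            mu_s_prime_hat=mu_s_prime,
            scale_near=s_near,
            scale_far=s_far,
            split_index=idx,
            r_squared_fit=self.r_squared_,
            n_iterations=n_iter,
            converged=converged,
        )
        return self

    def predict(self, r: ArrayLike) -> NDArray[np.float64]:
        """Unit-peak model reflectance at the fitted parameters."""
        if not hasattr(self, "mu_t_"):
            raise AttributeError("estimator is not fitted")
        r = np.asarray(r, dtype=float)
        curve = dipole_bracket(r, self.mu_t_, self.mu_eff_, self._c_coef())
        return curve / curve.max()

    @property
    def optical_properties_(self) -> OpticalProperties:
        if not hasattr(self, "mu_a_"):
            raise AttributeError("estimator is not fitted")
        return OpticalProperties(
            mu_a=max(self.mu_a_, 0.0), mu_s_prime=self.mu_s_prime_, eta=self.eta
        )


def _shape_r_squared(dist, inten, mu_t, mu_eff, c_coef) -> float:
    model = dipole_bracket(dist, mu_t, mu_eff, c_coef)
    model = model / model.max()
    ss_res = float(np.sum((inten - model) ** 2))
    ss_tot = float(np.sum((inten - inten.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant profile: R^2 undefined")
    return 1.0 - ss_res / ss_tot


def fit_two_segment(
    profile: ReflectanceProfile, eta: float, **options
) -> InversionResult:
    """Functional wrapper around :class:`TwoSegmentInversion`."""
    est = TwoSegmentInversion(eta=eta, **options)
    est.fit(profile)
    return est.result_


def invert_record_set(
    profiles: Sequence[ReflectanceProfile],
    eta: float,
    variant: Literal["average-first", "invert-first"] = "average-first",
    **options,
) -> InversionResult:
    """Invert a set of repeated acquisitions of the same sample.

    variant "average-first" (default) averages the intensity records,
    which suppresses sensor noise, and inverts the mean profile once.
    variant "invert-first" inverts every record separately and averages
    the per-record estimates.  Both reduce to the same answer for a
    single or noiseless record set.
    """
    if not profiles:
        raise ValueError("need at least one record")
    grid = profiles[0].distances
    for p in profiles[1:]:
        if p.distances.shape != grid.shape or not np.array_equal(p.distances, grid):
            raise ValueError("all records must share the same radial grid")
    if variant == "average-first":
        mean = profiles[0].with_intensities(
            np.mean([p.intensities for p in profiles], axis=0)
        )
        return fit_two_segment(mean, eta, **options)
    if variant == "invert-first":
        results = [fit_two_segment(p, eta, **options) for p in profiles]
        mu_a = float(np.mean([r.mu_a_hat for r in results]))
        mu_sp = float(np.mean([r.mu_s_prime_hat for r in results]))
        mu_t = mu_a + mu_sp
        return InversionResult(
            mu_t_hat=mu_t,
            mu_eff_hat=float(np.sqrt(3.0 * mu_a * mu_t)),
            mu_a_hat=mu_a,
            mu_s_prime_hat=mu_sp,
            scale_near=float(np.mean([r.scale_near for r in results])),
            scale_far=float(np.mean([r.scale_far for r in results])),
            split_index=int(round(np.mean([r.split_index for r in results]))),
            r_squared_fit=float(np.mean([r.r_squared_fit for r in results])),
            n_iterations=max(r.n_iterations for r in results),
            converged=all(r.converged for r in results),
        )
    raise ValueError(f"unknown variant {variant!r}")


def fit_r_squared(
    profile: ReflectanceProfile, result: InversionResult, eta: float
) -> float:
    """Coefficient of determination of the fitted shape.

    1 - SS_res/SS_tot between the peak-normalized data and the
    peak-normalized model curve at the estimated (mu_t, mu_eff).
    """
    profile = normalize_profile(profile)
    f_d = diffuse_fresnel_reflectance(eta)
    c_coef = 1.0 + 4.0 * internal_reflection_coefficient(f_d) / 3.0
    return _shape_r_squared(
        profile.distances, profile.intensities,
        result.mu_t_hat, result.mu_eff_hat, c_coef,
    )


def cost_surface(
    profile: ReflectanceProfile,
    mu_a_grid: ArrayLike,
    mu_s_grid: ArrayLike,
    eta: float,
) -> NDArray[np.float64]:
    """Sum of squared residuals over a (mu_a, mu_s') grid.

    Evaluates the peak-normalized model against the peak-normalized data
    at every grid combination.  The near-straight valleys of this surface
    are what make a direct joint fit of (mu_a, mu_s') ill-posed and
    motivate the two-segment scheme.

    Returns an array of shape (len(mu_a_grid), len(mu_s_grid)).
    """
    profile = normalize_profile(profile)
    mu_a_grid = np.asarray(mu_a_grid, dtype=float)
    mu_s_grid = np.asarray(mu_s_grid, dtype=float)
    f_d = diffuse_fresnel_reflectance(eta)
    c_coef = 1.0 + 4.0 * internal_reflection_coefficient(f_d) / 3.0
    out = np.empty((mu_a_grid.size, mu_s_grid.size))
    for i, mu_a in enumerate(mu_a_grid):
        for j, mu_s in enumerate(mu_s_grid):
            mu_t = mu_a + mu_s
            if mu_t <= 0:
                out[i, j] = np.inf
                continue
            mu_eff = np.sqrt(3.0 * mu_a * mu_t)
            model = dipole_bracket(profile.distances, mu_t, mu_eff, c_coef)
            model = model / model.max()
            out[i, j] = float(np.sum((profile.intensities - model) ** 2))
    return out
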