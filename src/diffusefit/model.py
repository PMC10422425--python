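"""Steady-state diffusion dipole model of spatially resolved reflectance.

The diffuse reflectance of a pencil beam normally incident on a
semi-infinite turbid medium is modelled with an isotropic point source
buried at depth ``1/mu_t`` and a mirrored negative image source above an
extrapolated boundary (the dipole approximation):

    Rd(r) = alpha / (4 pi mu_t) * [ (mu_eff + 1/r1) exp(-mu_eff r1) / r1^2
                                    + C (mu_eff + 1/r2) exp(-mu_eff r2) / r2^2 ]

with ``r1 = sqrt(r^2 + (1/mu_t)^2)``, ``r2 = sqrt(r^2 + (C/mu_t)^2)`` and
``C = 1 + 4A/3``, where ``A`` is the internal reflection coefficient
derived from the diffuse Fresnel reflectance of the medium/air interface.

Units: distances in mm, coefficients in mm^-1, everything else
dimensionless.  The model assumes a semi-infinite, highly scattering
medium (mu_s' >> mu_a) with a constant relative refractive index eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "OpticalProperties",
    "DerivedCoefficients",
    "diffuse_fresnel_reflectance",
    "internal_reflection_coefficient",
    "derive_coefficients",
    "dipole_bracket",
    "diffuse_reflectance",
    "normalized_shape",
    "asymptote_far",
    "asymptote_near",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a turbid medium.

    Attributes
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.  Non-negative.
    mu_s_prime : float
        Reduced scattering coefficient mu_s(1-g), mm^-1.  Positive.
    eta : float
        Relative refractive index of the medium against air.  Positive
        and different from 1 (the Fresnel polynomial branches are split
        at eta = 1 and the model is left undefined there).
    """

    mu_a: float
    mu_s_prime: float
    eta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise ValueError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise ValueError(
                f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}"
            )
        if not np.isfinite(self.eta) or self.eta <= 0:
            raise ValueError(f"eta must be finite and > 0, got {self.eta}")
        if self.eta == 1.0:
            raise ValueError("eta = 1 is outside the model's domain")


@dataclass(frozen=True)
class DerivedCoefficients:
    """Coefficients derived from :class:`OpticalProperties`.

    alpha      -- reduced albedo mu_s' / mu_t, in [0, 1]
    mu_t       -- extinction coefficient mu_a + mu_s', mm^-1
    mu_eff     -- effective attenuation sqrt(3 mu_a mu_t), mm^-1
    f_d        -- diffuse Fresnel reflectance of the boundary
    a_coef     -- internal reflection coefficient A = (1+f_d)/(1-f_d)
    c_coef     -- dipole boundary constant C = 1 + 4A/3
    """

    alpha: float
    mu_t: float
    mu_eff: float
    f_d: float
    a_coef: float
    c_coef: float


def diffuse_fresnel_reflectance(eta: float) -> float:
    """Diffuse Fresnel reflectance of the medium/air boundary.

    Rational polynomial approximation in the relative refractive index,
    with separate branches for eta < 1 and eta > 1.

    Parameters
    ----------
    eta : float
        Relative refractive index, > 0 and != 1.
    """
    if not np.isfinite(eta) or eta <= 0:
        raise ValueError(f"eta must be finite and > 0, got {eta}")
    if eta == 1.0:
        raise ValueError(
            "eta = 1: the two polynomial branches disagree and the "
            "approximation is undefined; use the actual interface physics"
        )
    if eta < 1.0:
        return -0.4299 + 0.7099 * eta - 0.3319 * eta**2 + 0.0636 * eta**3
    return -1.4399 / eta**2 + 0.7099 / eta + 0.6681 + 0.0636 * eta


def internal_reflection_coefficient(f_d: float) -> float:
    """Internal reflection coefficient A = (1 + f_d) / (1 - f_d)."""
    if f_d == 1.0:
        raise ZeroDivisionError("f_d = 1 gives an infinite reflection coefficient")
    return (1.0 + f_d) / (1.0 - f_d)


def derive_coefficients(props: OpticalProperties) -> DerivedCoefficients:
    """Compute all model coefficients implied by a property set."""
    mu_t = props.mu_a + props.mu_s_prime
    alpha = props.mu_s_prime / mu_t
    mu_eff = float(np.sqrt(3.0 * props.mu_a * mu_t))
    f_d = diffuse_fresnel_reflectance(props.eta)
    a_coef = internal_reflection_coefficient(f_d)
    c_coef = 1.0 + 4.0 * a_coef / 3.0
    return DerivedCoefficients(
        alpha=alpha, mu_t=mu_t, mu_eff=mu_eff,
        f_d=f_d, a_coef=a_coef, c_coef=c_coef,
    )


def dipole_bracket(
    r: ArrayLike, mu_t: float, mu_eff: float, c_coef: float
) -> NDArray[np.float64]:
    """Shape term of the dipole reflectance (the bracket of the model).

    This is the reflectance up to the constant prefactor
    ``alpha / (4 pi mu_t)``; peak normalisation of measured profiles
    discards that prefactor, so the inversion works on this term alone.
    Finite at r = 0 because r1 -> 1/mu_t and r2 -> C/mu_t there.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be >= 0")
    if mu_t <= 0:
        raise ValueError(f"mu_t must be > 0, got {mu_t}")
    if mu_eff < 0:
        raise ValueError(f"mu_eff must be >= 0, got {mu_eff}")
    r1 = np.sqrt(r * r + (1.0 / mu_t) ** 2)
    r2 = np.sqrt(r * r + (c_coef / mu_t) ** 2)
    near = (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / (r1 * r1)
    far = c_coef * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / (r2 * r2)
    return near + far


def diffuse_reflectance(r: ArrayLike, props: OpticalProperties) -> NDArray[np.float64]:
    """Diffuse reflectance Rd(r) of the dipole model.

    Parameters
    ----------
    r : array_like
        Radial source-detector distance(s), mm, >= 0.
    props : OpticalProperties
        Medium properties.

    Returns
    -------
    ndarray
        Rd(r), strictly positive, monotonically decaying in r.
    """
    d = derive_coefficients(props)
    prefactor = d.alpha / (4.0 * np.pi * d.mu_t)
    return prefactor * dipole_bracket(r, d.mu_t, d.mu_eff, d.c_coef)


def normalized_shape(
    r_grid: ArrayLike, props: OpticalProperties
) -> NDArray[np.float64]:
    """Unit-peak reflectance curve on a radial grid.

    The amplitude prefactor of the model carries no shape information and
    is discarded; only the relative decay of Rd along the grid remains.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0:
        raise ValueError("empty radial grid")
    if r_grid.ndim != 1 or (r_grid.size > 1 and np.any(np.diff(r_grid) <= 0)):
        raise ValueError("r_grid must be 1-D and strictly increasing")
    curve = diffuse_reflectance(r_grid, props)
    return curve / curve.max()


def asymptote_far(r: ArrayLike, props: OpticalProperties) -> NDArray[np.float64]:
    """Far-field limit of the normalized reflectance shape.

    For mu_t * r >> 1 both dipole distances approach r and the bracket
    collapses to ``(1 + C)(mu_eff + 1/r) exp(-mu_eff r) / r^2``: an
    exponential decay governed by mu_eff alone.  Valid for r > 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("far-field asymptote requires r > 0")
    d = derive_coefficients(props)
    return (
        (1.0 + d.c_coef)
        * (d.mu_eff + 1.0 / r)
        * np.exp(-d.mu_eff * r)
        / (r * r)
    )


def asymptote_near(props: OpticalProperties) -> float:
    """Near-field constant ``mu_t / 3 * (1 + 1/C^2)`` of the shape.

    Diagnostic only: it shows that the r -> 0 level of the shape is set
    by the extinction coefficient mu_t, which motivates fitting mu_t on
    the near segment.  It is not used in the inversion itself, whose
    segments fit the full dipole bracket.
    """
    d = derive_coefficients(props)
    return d.mu_t / 3.0 * (1.0 + 1.0 / d.c_coef**2)
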