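"""Validation statistics and colorimetric utilities.

Linear regression of estimated coefficients against a dilution covariate
(fat content, pigment drops, whiteness index), 95 % confidence intervals
for repeated acquisitions, the reduced-to-full scattering conversion, and
two whiteness indices used to characterise white substrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike
from scipy import stats as _sps

__all__ = [
    "RegressionResult",
    "TristimulusSample",
    "linear_regression",
    "ci95_halfwidth",
    "scattering_from_reduced",
    "whiteness_cie",
    "whiteness_e313",
]


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line fit with its test statistics.

    p_value is the two-sided t-test on the slope with n - 2 degrees of
    freedom (equivalent to the F-test for a simple regression).
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float


@dataclass(frozen=True)
class TristimulusSample:
    """Colour coordinates of a sample for whiteness computation.

    x, y are chromaticity coordinates; Y, Z tristimulus values; (xn, yn)
    the neutral-point chromaticities of the illuminant/observer pair
    (default: D50, 2 degree observer).
    """

    x: float
    y: float
    Y: float
    Z: float = 0.0
    xn: float = 0.3457
    yn: float = 0.3585

    def __post_init__(self) -> None:
        if not (0.0 < self.x < 1.0 and 0.0 < self.y < 1.0):
            raise ValueError("chromaticities x, y must lie in (0, 1)")
        if self.Y < 0 or self.Z < 0:
            raise ValueError("tristimulus values must be >= 0")


def linear_regression(x: ArrayLike, y: ArrayLike) -> RegressionResult:
    """OLS regression of responses ``y`` on a covariate ``x``.

    Requires at least 3 points and a non-degenerate covariate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points to regress")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; regression is degenerate")
    fit = _sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope_stderr=float(fit.stderr),
    )


def ci95_halfwidth(sigma: float, n: int) -> float:
    """Half-width of the normal 95 % confidence interval, 1.96 sigma/sqrt(n)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.96 * sigma / np.sqrt(n)


def scattering_from_reduced(mu_s_prime: float, g: float) -> float:
    """Scattering coefficient mu_s = mu_s' / (1 - g).

    g is the anisotropy factor (mean cosine of the single-scattering
    angle); g must be < 1.  Highly forward-scattering media like milk
    have g > 0.8, so mu_s exceeds mu_s' by a factor of 5-10.
    """
    if g >= 1:
        raise ValueError(f"anisotropy factor must be < 1, got {g}")
    return mu_s_prime / (1.0 - g)


def whiteness_cie(sample: TristimulusSample) -> float:
    """CIE whiteness index WI = Y + 800 (xn - x) + 1700 (yn - y)."""
    return sample.Y + 800.0 * (sample.xn - sample.x) + 1700.0 * (sample.yn - sample.y)


def whiteness_e313(Y: float, Z: float) -> float:
    """ASTM E313 (1998) whiteness index WI = 3.388 Z - 3 Y."""
    if Y < 0 or Z < 0:
        raise ValueError("tristimulus values must be >= 0")
    return 3.388 * Z - 3.0 * Y
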