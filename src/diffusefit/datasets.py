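"""Published reference optical properties of highly diffuse materials.

Per-channel (mu_a, mu_s') estimates, in mm^-1, reported for dilution
series measured with a spatially resolved translucency meter and inverted
with the two-segment scheme implemented here:

* ``MILK_Q``  -- supermarket milk samples of one brand, by fat content (%).
* ``MILK_MIX`` -- milk samples pooled across brands, by fat content (%).
* ``WHITE_PAINT`` -- tap water tainted with white acrylic paint, by the
  number of paint drops added to ~850 ml of water.

These serve as realistic ground-truth inputs for forward simulation and
for regression of coefficients against the dilution covariate.  Channel
labels follow the device LEDs (R = 630 nm, G = 525 nm, B = 472 nm).
The relative refractive index used for the liquid samples is 1.347.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MILK_ETA",
    "PAPER_ETA",
    "CHANNELS",
    "MILK_Q",
    "MILK_MIX",
    "WHITE_PAINT",
    "covariates",
    "channel_values",
]

#: Relative refractive index assumed for milk (and the paint/water mixes).
MILK_ETA = 1.347
#: Relative refractive index of white paper substrates.
PAPER_ETA = 1.557

CHANNELS = ("R", "G", "B")

# fat content %  ->  {"mu_a": (R, G, B), "mu_s_prime": (R, G, B)}  [mm^-1]
MILK_Q = {
    0.1: {"mu_a": (3.2e-9, 2.4e-3, 1.0e-2), "mu_s_prime": (0.62, 0.74, 0.81)},
    0.5: {"mu_a": (1.4e-3, 3.7e-3, 1.2e-2), "mu_s_prime": (0.62, 0.75, 0.84)},
    1.0: {"mu_a": (3.0e-3, 7.8e-3, 1.6e-2), "mu_s_prime": (0.69, 0.84, 0.95)},
    4.0: {"mu_a": (5.3e-3, 1.5e-2, 3.6e-2), "mu_s_prime": (1.05, 1.35, 1.52)},
}

MILK_MIX = {
    0.1: {"mu_a": (1.7e-5, 3.4e-3, 8.6e-3), "mu_s_prime": (0.60, 0.70, 0.78)},
    0.5: {"mu_a": (1.2e-3, 4.0e-3, 1.3e-2), "mu_s_prime": (0.61, 0.75, 0.83)},
    0.7: {"mu_a": (1.9e-3, 5.0e-3, 1.4e-2), "mu_s_prime": (0.67, 0.82, 0.91)},
    1.0: {"mu_a": (3.3e-3, 6.6e-3, 1.9e-2), "mu_s_prime": (0.68, 0.84, 0.92)},
    1.2: {"mu_a": (4.3e-3, 5.8e-3, 1.9e-2), "mu_s_prime": (0.71, 0.90, 0.98)},
    3.5: {"mu_a": (5.1e-3, 1.2e-2, 2.7e-2), "mu_s_prime": (0.92, 1.26, 1.40)},
    4.0: {"mu_a": (5.3e-3, 1.1e-2, 3.5e-2), "mu_s_prime": (0.98, 1.36, 1.51)},
}

# drops of white paint -> per-channel coefficients.  The 2- and 4-drop
# mixtures were too dilute to behave as diffuse media (mu_a collapses to
# ~1e-11); keep them in the table but exclude them from regressions.
WHITE_PAINT = {
    2: {"mu_a": (6.1e-12, 2.8e-11, 1.5e-11), "mu_s_prime": (0.45, 0.46, 0.50)},
    4: {"mu_a": (2.0e-12, 1.4e-13, 1.4e-11), "mu_s_prime": (0.40, 0.43, 0.44)},
    6: {"mu_a": (2.3e-5, 6.4e-5, 9.3e-5), "mu_s_prime": (0.43, 0.48, 0.48)},
    8: {"mu_a": (1.1e-10, 3.8e-5, 6.5e-5), "mu_s_prime": (0.44, 0.49, 0.49)},
    10: {"mu_a": (1.3e-4, 3.5e-4, 5.5e-4), "mu_s_prime": (0.47, 0.53, 0.52)},
    12: {"mu_a": (5.7e-4, 1.0e-3, 1.4e-3), "mu_s_prime": (0.51, 0.56, 0.56)},
    14: {"mu_a": (1.0e-3, 1.1e-3, 1.8e-3), "mu_s_prime": (0.53, 0.60, 0.59)},
    16: {"mu_a": (1.5e-3, 1.1e-3, 2.3e-3), "mu_s_prime": (0.55, 0.64, 0.63)},
    18: {"mu_a": (2.0e-3, 1.7e-3, 3.0e-3), "mu_s_prime": (0.56, 0.68, 0.65)},
    20: {"mu_a": (2.7e-3, 2.0e-3, 3.9e-3), "mu_s_prime": (0.57, 0.72, 0.68)},
}


def covariates(table: dict) -> np.ndarray:
    """Sorted covariate values (fat % or drop count) of a table."""
    return np.array(sorted(table))


def channel_values(table: dict, coefficient: str, channel: str) -> np.ndarray:
    """One coefficient column of a table for one channel, covariate-sorted.

    Parameters
    ----------
    coefficient : {"mu_a", "mu_s_prime"}
    channel : {"R", "G", "B"}
    """
    j = CHANNELS.index(channel)
    return np.array([table[c][coefficient][j] for c in sorted(table)])
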