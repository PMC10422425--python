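"""Synthetic reflectance profiles with the acquisition device's structure.

Emulates a translucency meter whose detector is a linear NMOS photodiode
array (512 elements at 25 um pitch, spanning 12.8 mm) reading the light
re-emitted at increasing distance from a point-like entry spot.  Profiles
are generated from the diffusion dipole model with multiplicative
Gaussian detector noise and an optional additive dark floor:

    I_i = Rd(r_i) * (1 + eps_i) + dark_floor,   eps_i ~ N(0, relative_sigma)

The first detector is placed 0.25 mm from the entry point so the grid
avoids the specular entry region.  Noise defaults to 1 % relative sigma,
a realistic level for a photodiode array with low dark current; the dark
floor defaults to 0.  Seeding is deterministic: a record set with master
seed ``s`` gives record ``i`` the seed ``s + i``, and a material series
gives entry ``k`` the base seed ``s + 1009 * k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray

from . import datasets
from .model import OpticalProperties, diffuse_reflectance
from .profile import ReflectanceProfile

__all__ = [
    "SensorGeometry",
    "NoiseModel",
    "ChannelMap",
    "SeriesEntry",
    "make_grid",
    "simulate_profile",
    "simulate_record_set",
    "simulate_material_series",
    "default_milk_maps",
]

#: Fixed seed increment between entries of a material series.
_SERIES_SEED_STRIDE = 1009


@dataclass(frozen=True)
class SensorGeometry:
    """Linear detector array geometry.

    n_detectors  -- number of photodiode elements (default 512)
    pitch        -- element spacing, mm (default 0.025)
    first_offset -- distance of the first element from the light entry
                    point, mm (default 0.25)
    """

    n_detectors: int = 512
    pitch: float = 0.025
    first_offset: float = 0.25

    def __post_init__(self) -> None:
        if self.n_detectors < 2:
            raise ValueError("need at least 2 detectors")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.first_offset < 0:
            raise ValueError("first_offset must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: multiplicative Gaussian plus optional dark floor."""

    relative_sigma: float = 0.01
    dark_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be >= 0")
        if self.dark_floor < 0:
            raise ValueError("dark_floor must be >= 0")


@dataclass(frozen=True)
class ChannelMap:
    """Affine map from a dilution covariate to optical properties.

    mu_a = a_intercept + a_slope * c ;  mu_s' = s_intercept + s_slope * c
    """

    a_slope: float
    a_intercept: float
    s_slope: float
    s_intercept: float

    def __call__(self, covariate: float, eta: float) -> OpticalProperties:
        mu_a = self.a_intercept + self.a_slope * covariate
        mu_sp = self.s_intercept + self.s_slope * covariate
        if mu_sp <= 0:
            raise ValueError(
                f"channel map yields mu_s_prime = {mu_sp} <= 0 at covariate {covariate}"
            )
        return OpticalProperties(mu_a=max(mu_a, 0.0), mu_s_prime=mu_sp, eta=eta)


@dataclass(frozen=True)
class SeriesEntry:
    """One (covariate, channel) cell of a simulated material series."""

    covariate: float
    channel: str
    truth: OpticalProperties
    records: list[ReflectanceProfile] = field(default_factory=list)


def make_grid(geometry: SensorGeometry = SensorGeometry()) -> NDArray[np.float64]:
    """Radial grid r_i = first_offset + i * pitch, mm, strictly increasing."""
    return geometry.first_offset + geometry.pitch * np.arange(geometry.n_detectors)


def simulate_profile(
    props: OpticalProperties,
    geometry: SensorGeometry = SensorGeometry(),
    noise: NoiseModel = NoiseModel(relative_sigma=0.0),
    channel: str = "R",
    record_id: str = "rec0",
) -> ReflectanceProfile:
    """One simulated acquisition on the detector grid.

    With ``relative_sigma = 0`` and ``dark_floor = 0`` the intensities are
    exactly the model reflectance on the grid.  Fixed seeds reproduce
    identical profiles.
    """
    r = make_grid(geometry)
    clean = diffuse_reflectance(r, props)
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.relative_sigma, size=r.size) if noise.relative_sigma else 0.0
    intensities = clean * (1.0 + eps) + noise.dark_floor
    return ReflectanceProfile(
        distances=r, intensities=intensities, channel=channel, record_id=record_id
    )


def simulate_record_set(
    props: OpticalProperties,
    geometry: SensorGeometry = SensorGeometry(),
    noise: NoiseModel = NoiseModel(),
    n_records: int = 10,
    channel: str = "R",
) -> list[ReflectanceProfile]:
    """Repeated acquisitions of the same sample with independent noise.

    Record ``i`` uses seed ``noise.seed + i``, so a record set is fully
    reproducible from the master seed and ``n_records = 1`` coincides with
    :func:`simulate_profile` at that derived seed.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    return [
        simulate_profile(
            props,
            geometry,
            NoiseModel(noise.relative_sigma, noise.dark_floor, noise.seed + i),
            channel=channel,
            record_id=f"rec{i}",
        )
        for i in range(n_records)
    ]


def default_milk_maps(
    table: Mapping | None = None,
) -> dict[str, ChannelMap]:
    """Per-channel affine fat-content -> (mu_a, mu_s') maps for milk.

    Constants are obtained by ordinary least squares on the published
    per-channel mean coefficients of the pooled milk dilution series, so
    the simulated series inherits the measured covariate dependence.
    """
    if table is None:
        table = datasets.MILK_MIX
    fat = datasets.covariates(table)
    maps = {}
    for channel in datasets.CHANNELS:
        a_slope, a_int = np.polyfit(fat, datasets.channel_values(table, "mu_a", channel), 1)
        s_slope, s_int = np.polyfit(
            fat, datasets.channel_values(table, "mu_s_prime", channel), 1
        )
        maps[channel] = ChannelMap(
            a_slope=float(a_slope),
            a_intercept=float(a_int),
            s_slope=float(s_slope),
            s_intercept=float(s_int),
        )
    return maps


def simulate_material_series(
    covariate_values: Sequence[float],
    coefficient_maps: Mapping[str, ChannelMap] | None = None,
    eta: float = datasets.MILK_ETA,
    geometry: SensorGeometry = SensorGeometry(),
    noise: NoiseModel = NoiseModel(),
    n_records: int = 10,
) -> list[SeriesEntry]:
    """Simulate a dilution series: one record set per (covariate, channel).

    The default maps emulate the milk fat-content series.  Ground-truth
    properties are retained on every entry so recovery can be scored.
    """
    if coefficient_maps is None:
        coefficient_maps = default_milk_maps()
    entries: list[SeriesEntry] = []
    k = 0
    for cov in covariate_values:
        for channel, cmap in coefficient_maps.items():
            props = cmap(cov, eta)
            entry_noise = NoiseModel(
                noise.relative_sigma,
                noise.dark_floor,
                noise.seed + _SERIES_SEED_STRIDE * k,
            )
            records = simulate_record_set(
                props, geometry, entry_noise, n_records, channel=channel
            )
            entries.append(
                SeriesEntry(covariate=float(cov), channel=channel, truth=props, records=records)
            )
            k += 1
    return entries
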